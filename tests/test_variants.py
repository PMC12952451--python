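"""Variant parsing, the rare non-synonymous filter, zygosity classes, and
predisposition-catalog matching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hccnet.errors import ConfigurationError, FormatError, SchemaError
from hccnet.variants import (
    NONSYNONYMOUS_CONSEQUENCES,
    Origin,
    VariantRecord,
    Zygosity,
    filter_rare_nonsynonymous,
    match_predisposition,
    normalize_consequence,
    read_variants,
    summarize_zygosity,
    write_variants,
)

from .conftest import make_variant

ALL_CONSEQUENCES = sorted(NONSYNONYMOUS_CONSEQUENCES) + [
    "synonymous_variant",
    "intron_variant",
    "5_prime_UTR_variant",
]


# ----------------------------------------------------------------------
# parsing
# ----------------------------------------------------------------------

class TestReadVariants:
    HEADER = "patient_id\tgene\torigin\tconsequence\tgnomad_af\tzygosity\tvariant_id\n"

    def test_identity_parse(self, tmp_path):
        f = tmp_path / "v.tsv"
        f.write_text(self.HEADER + "P1\tTP53\tsomatic\tmissense_variant\t0.0001\thet\trs1\n")
        (rec,) = read_variants(f, Origin.SOMATIC)
        assert rec.patient_id == "P1"
        assert rec.gene == "TP53"
        assert rec.origin is Origin.SOMATIC
        assert rec.consequence == "missense_variant"
        assert rec.gnomad_af == pytest.approx(0.0001)
        assert rec.zygosity is Zygosity.HET

    def test_empty_file_with_header(self, tmp_path):
        f = tmp_path / "v.tsv"
        f.write_text(self.HEADER)
        assert read_variants(f, "somatic") == []

    def test_missing_column_names_the_column(self, tmp_path):
        f = tmp_path / "v.tsv"
        f.write_text("patient_id\tgene\tconsequence\n")
        with pytest.raises(SchemaError, match="zygosity"):
            read_variants(f, "somatic")

    def test_missing_af_preserved_as_missing(self, tmp_path):
        f = tmp_path / "v.tsv"
        f.write_text(self.HEADER + "P1\tTP53\tsomatic\tstop_gained\t\thom\trs2\n")
        (rec,) = read_variants(f, "somatic")
        assert rec.gnomad_af is None

    def test_malformed_row_skipped_with_line_number(self, tmp_path, caplog):
        f = tmp_path / "v.tsv"
        f.write_text(
            self.HEADER
            + "P1\tTP53\tsomatic\tmissense_variant\t0.0001\thet\trs1\n"
            + "P2\tKRAS\tsomatic\tmissense_variant\tnot_a_number\thet\trs2\n"
        )
        with caplog.at_level("WARNING"):
            records = read_variants(f, "somatic")
        assert len(records) == 1
        assert "line 3" in caplog.text

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(FormatError):
            read_variants(tmp_path / "absent.tsv", "somatic")

    def test_roundtrip(self, tmp_path):
        records = [
            make_variant(variant_id=f"rs{i}", af=None if i % 2 else 0.001, pos=10 + i, ref="A", alt="C", chrom="7")
            for i in range(6)
        ]
        write_variants(records, tmp_path / "out.tsv")
        back = read_variants(tmp_path / "out.tsv", Origin.SOMATIC)
        assert back == records

    def test_synthetic_cohort_record_count_matches_generator(self, tmp_path):
        from hccnet.synth import SyntheticConfig, generate_cohort
        from hccnet.variants import write_variants

        cohort = generate_cohort(SyntheticConfig(seed=5))
        write_variants(cohort.somatic, tmp_path / "s.tsv")
        write_variants(cohort.germline, tmp_path / "g.tsv")
        assert len(read_variants(tmp_path / "s.tsv", "somatic")) == cohort.truth["n_somatic_records"]
        assert len(read_variants(tmp_path / "g.tsv", "germline")) == cohort.truth["n_germline_records"]


class TestRecordInvariants:
    def test_af_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            make_variant(af=1.5)

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(FormatError):
            make_variant(ref="A", alt="A", pos=5)

    def test_position_one_based(self):
        with pytest.raises(FormatError):
            make_variant(pos=0)


class TestVcfReader:
    VCF = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Annotation. '
        'Format: Consequence|SYMBOL|gnomAD_AF">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\n"
        "1\t1000\trs10\tA\tG\t.\t.\tCSQ=missense_variant|TP53|0.0001\tGT\t0/1\t1/1\n"
        "2\t2000\trs20\tC\tT\t.\t.\tCSQ=synonymous_variant|BRCA1|0.2\tGT\t0/0\t0/1\n"
    )

    def test_one_record_per_nonref_genotype(self, tmp_path):
        pytest.importorskip("cyvcf2")
        f = tmp_path / "x.vcf"
        f.write_text(self.VCF)
        records = read_variants(f, "germline")
        by_id = {}
        for r in records:
            by_id.setdefault(r.variant_id, []).append(r)
        assert len(by_id["rs10"]) == 2  # P1 het, P2 hom
        zyg = {r.patient_id: r.zygosity for r in by_id["rs10"]}
        assert zyg == {"P1": Zygosity.HET, "P2": Zygosity.HOM}
        (syn,) = by_id["rs20"]
        assert syn.patient_id == "P2" and syn.gene == "BRCA1"
        assert syn.gnomad_af == pytest.approx(0.2)


# ----------------------------------------------------------------------
# rare non-synonymous filter
# ----------------------------------------------------------------------

def naive_filter(records, threshold=0.01):
    """Independent per-record re-check of the two filter clauses."""
    out = []
    for r in records:
        rare = r.gnomad_af is None or r.gnomad_af < threshold
        nonsyn = normalize_consequence(r.consequence) in NONSYNONYMOUS_CONSEQUENCES
        if rare and nonsyn:
            out.append(r)
    return out


class TestRareNonsynonymousFilter:
    @pytest.mark.parametrize(
        "consequence,af,kept",
        [
            ("missense_variant", 0.05, False),   # common -> excluded
            ("missense_variant", 0.01, False),   # boundary AF: strict <
            ("stop_gained", 0.001, True),
            ("frameshift_variant", 0.009, True),
            ("splice_acceptor_variant", None, True),   # absent from gnomAD = rare
            ("splice_donor_variant", 0.0, True),
            ("start_lost", 0.001, True),
            ("Start Loss", 0.001, True),         # free-text alias
            ("synonymous_variant", 0.0001, False),
            ("intron_variant", None, False),
        ],
    )
    def test_filter_clauses(self, consequence, af, kept):
        rec = make_variant(consequence=consequence, af=af)
        assert (filter_rare_nonsynonymous([rec]) == [rec]) is kept

    def test_invalid_threshold(self):
        with pytest.raises(ConfigurationError):
            filter_rare_nonsynonymous([], af_threshold=0.0)

    variant_strategy = st.builds(
        make_variant,
        consequence=st.sampled_from(ALL_CONSEQUENCES),
        af=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
        variant_id=st.text(st.characters(categories=["Lu"]), min_size=1, max_size=4),
    )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(variant_strategy, max_size=50))
    def test_matches_naive_oracle(self, records):
        assert filter_rare_nonsynonymous(records) == naive_filter(records)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(variant_strategy, max_size=50))
    def test_idempotent(self, records):
        once = filter_rare_nonsynonymous(records)
        assert filter_rare_nonsynonymous(once) == once

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(variant_strategy, max_size=50),
        st.floats(0.001, 0.5),
        st.floats(0.001, 0.5),
    )
    def test_monotone_in_threshold(self, records, t1, t2):
        lo, hi = sorted((t1, t2))
        assert set(r.variant_id for r in filter_rare_nonsynonymous(records, lo)) <= set(
            r.variant_id for r in filter_rare_nonsynonymous(records, hi)
        )


# ----------------------------------------------------------------------
# zygosity summary
# ----------------------------------------------------------------------

class TestSummarizeZygosity:
    def test_compound_het_from_two_distinct_hets(self):
        recs = [
            make_variant(gene="BRCA2", zygosity=Zygosity.HET, variant_id="rs1"),
            make_variant(gene="BRCA2", zygosity=Zygosity.HET, variant_id="rs2"),
        ]
        (s,) = summarize_zygosity(recs)
        assert (s.n_com_hete, s.n_hete, s.n_homo) == (1, 0, 0)

    def test_single_hom(self):
        (s,) = summarize_zygosity([make_variant(zygosity=Zygosity.HOM)])
        assert (s.n_com_hete, s.n_hete, s.n_homo) == (0, 0, 1)

    def test_empty_input(self):
        assert summarize_zygosity([]) == []

    def test_duplicate_variant_id_not_compound(self):
        # same variant reported twice is not two distinct het variants
        recs = [
            make_variant(gene="G1", zygosity=Zygosity.HET, variant_id="rs1"),
            make_variant(gene="G1", zygosity=Zygosity.HET, variant_id="rs1"),
        ]
        (s,) = summarize_zygosity(recs)
        assert s.n_com_hete == 0 and s.n_hete == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.builds(
                make_variant,
                gene=st.sampled_from(["G1", "G2", "G3"]),
                patient=st.sampled_from(["P1", "P2"]),
                zygosity=st.sampled_from([Zygosity.HET, Zygosity.HOM]),
                variant_id=st.sampled_from([f"rs{i}" for i in range(6)]),
            ),
            max_size=30,
        )
    )
    def test_record_conservation(self, records):
        """2*com_hete + hete + homo conserves the per-gene record count."""
        summaries = summarize_zygosity(records)
        total = sum(2 * s.n_com_hete + s.n_hete + s.n_homo for s in summaries)
        assert total == len(records)
        assert all(s.n_hete >= 0 and s.n_homo >= 0 for s in summaries)


# ----------------------------------------------------------------------
# predisposition matching
# ----------------------------------------------------------------------

class TestMatchPredisposition:
    def test_carriers_with_zygosity(self):
        cohort = [
            make_variant(patient="case1", variant_id="rs152451", zygosity=Zygosity.HET),
            make_variant(patient="case6", variant_id="rs152451", zygosity=Zygosity.HET),
            make_variant(patient="case14", variant_id="rs152451", zygosity=Zygosity.HOM),
            make_variant(patient="case2", variant_id="rs999", zygosity=Zygosity.HET),
        ]
        df = match_predisposition(cohort, {"rs152451"})
        assert len(df) == 3
        assert dict(zip(df.patient_id, df.zygosity)) == {
            "case1": "het", "case6": "het", "case14": "hom",
        }

    def test_absent_catalog_variant(self):
        df = match_predisposition([make_variant(variant_id="rs1")], {"rs_not_here"})
        assert df.empty

    def test_empty_catalog_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            match_predisposition([], set())

    def test_planted_carriers_recovered(self):
        from hccnet.synth import SyntheticConfig, generate_cohort

        cohort = generate_cohort(SyntheticConfig(seed=9))
        df = match_predisposition(cohort.germline, cohort.catalog)
        found = {(r.patient_id, r.variant_id, r.zygosity) for r in df.itertuples()}
        planted = {
            (c["patient_id"], c["variant_id"], c["zygosity"])
            for c in cohort.truth["planted_carriers"]
        }
        assert found == planted
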