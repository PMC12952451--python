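"""Variant parsing, rare non-synonymous filtering, and zygosity summaries.

The filtering model keeps *rare non-synonymous* variants: population allele
frequency (gnomAD exomes combined) strictly below a threshold (default 0.01,
with absence from gnomAD counted as evidence of rarity), and a consequence
term in the protein-altering set — the five high-impact truncating classes
(stop gained, frameshift, splice acceptor/donor, start lost) plus missense.
Zygosity summaries classify, per patient and gene, homozygous calls,
putative compound heterozygotes (two or more distinct heterozygous variants
in one gene, called without phase and therefore an upper bound), and
remaining heterozygous calls.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError, SchemaError

logger = logging.getLogger(__name__)


class Origin(str, Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"


#: High-impact protein-truncating consequence classes.
HIGH_IMPACT_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
    }
)

#: Full non-synonymous set used by the rare-variant filter.
NONSYNONYMOUS_CONSEQUENCES = HIGH_IMPACT_CONSEQUENCES | {"missense_variant"}


def normalize_consequence(term: str) -> str:
    """Map a consequence term to its canonical Sequence Ontology spelling.

    Matching is case-insensitive and tolerant of spaces instead of
    underscores, so "Stop Gained" and "start loss" map to ``stop_gained``
    and ``start_lost``.
    """
    t = term.strip().lower().replace(" ", "_")
    if t == "start_loss":  # common free-text alias
        t = "start_lost"
    return t


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call for one patient."""

    patient_id: str
    gene: str
    origin: Origin
    consequence: str
    gnomad_af: float | None
    zygosity: Zygosity
    variant_id: str
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None

    def __post_init__(self) -> None:
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise FormatError(
                f"gnomad_af must lie in [0, 1], got {self.gnomad_af!r} "
                f"for {self.variant_id}"
            )
        if self.pos is not None and self.pos < 1:
            raise FormatError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.ref is not None and self.ref == self.alt:
            raise FormatError(f"ref equals alt ({self.ref!r}) for {self.variant_id}")


@dataclass(frozen=True)
class ZygositySummary:
    """Per patient x gene classification of filtered variant calls."""

    patient_id: str
    gene: str
    n_com_hete: int
    n_homo: int
    n_hete: int


_TSV_REQUIRED = ("patient_id", "gene", "consequence", "zygosity", "variant_id")


def read_variants(path: str | Path, origin: Origin | str) -> list[VariantRecord]:
    """Read a variant table (TSV, or VCF if the suffix says so).

    TSV files need columns ``patient_id, gene, consequence, zygosity,
    variant_id`` plus an optional ``gnomad_af`` (empty cell = missing, i.e.
    not observed in gnomAD) and optional ``chrom/pos/ref/alt``. Malformed
    data rows are skipped with a logged line number; a missing mandatory
    column raises :class:`SchemaError`.
    """
    path = Path(path)
    origin = Origin(origin)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        return read_variants_vcf(path, origin)
    return _read_variants_tsv(path, origin)


def _parse_af(raw: str) -> float | None:
    raw = raw.strip()
    if raw in {"", ".", "NA", "nan"}:
        return None
    return float(raw)


def _read_variants_tsv(path: Path, origin: Origin) -> list[VariantRecord]:
    try:
        handle = open(path, newline="")
    except OSError as exc:
        raise FormatError(f"cannot read variant table {path}: {exc}") from exc
    records: list[VariantRecord] = []
    with handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        missing = [c for c in _TSV_REQUIRED if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                row_origin = Origin(row.get("origin", origin.value) or origin.value)
                records.append(
                    VariantRecord(
                        patient_id=row["patient_id"],
                        gene=row["gene"],
                        origin=row_origin,
                        consequence=row["consequence"],
                        gnomad_af=_parse_af(row.get("gnomad_af", "") or ""),
                        zygosity=Zygosity(row["zygosity"].strip().lower()),
                        variant_id=row["variant_id"],
                        chrom=row.get("chrom") or None,
                        pos=int(row["pos"]) if row.get("pos") else None,
                        ref=row.get("ref") or None,
                        alt=row.get("alt") or None,
                    )
                )
            except (KeyError, ValueError, FormatError) as exc:
                logger.warning("%s line %d: skipping malformed row (%s)", path, lineno, exc)
    return records


def read_variants_vcf(
    path: str | Path,
    origin: Origin | str,
    csq_fields: Sequence[str] | None = None,
    csq_tag: str = "CSQ",
) -> list[VariantRecord]:
    """Read variants from an annotated VCF.

    Consequence, gene symbol and population AF are taken from a CSQ-style
    INFO annotation whose ``|``-separated layout is either declared in the
    header (``Format: ...``) or passed via ``csq_fields``. One record is
    emitted per non-reference genotype per sample. Requires :mod:`cyvcf2`.
    """
    from cyvcf2 import VCF  # heavy import kept local

    path = str(path)
    origin = Origin(origin)
    vcf = VCF(path)
    fields = list(csq_fields) if csq_fields else None
    if fields is None:
        try:
            desc = vcf.get_header_type(csq_tag)["Description"]
            fields = desc.split("Format:")[-1].strip().strip('"').split("|")
            fields = [f.strip() for f in fields]
        except KeyError as exc:
            raise SchemaError(
                f"{path}: no {csq_tag} INFO header and no csq_fields given"
            ) from exc
    wanted = {"Consequence", "SYMBOL", "gnomAD_AF"}
    if not wanted.issubset(fields):
        raise SchemaError(
            f"{path}: {csq_tag} layout {fields} lacks {sorted(wanted - set(fields))}"
        )
    idx = {name: fields.index(name) for name in wanted}
    samples = vcf.samples
    records: list[VariantRecord] = []
    for rec in vcf:
        raw = rec.INFO.get(csq_tag)
        if raw is None:
            logger.warning("%s %s:%s: no %s annotation, skipped", path, rec.CHROM, rec.POS, csq_tag)
            continue
        ann = str(raw).split(",")[0].split("|")
        consequence = ann[idx["Consequence"]].split("&")[0]
        gene = ann[idx["SYMBOL"]]
        af = _parse_af(ann[idx["gnomAD_AF"]])
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for sample, gt in zip(samples, rec.gt_types):
            if gt == 1:
                zyg = Zygosity.HET
            elif gt == 3:
                zyg = Zygosity.HOM
            else:
                continue
            records.append(
                VariantRecord(
                    patient_id=sample,
                    gene=gene,
                    origin=origin,
                    consequence=consequence,
                    gnomad_af=af,
                    zygosity=zyg,
                    variant_id=vid,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0] if rec.ALT else None,
                )
            )
    return records


def filter_rare_nonsynonymous(
    variants: Iterable[VariantRecord], af_threshold: float = 0.01
) -> list[VariantRecord]:
    """Keep rare non-synonymous records.

    A record is retained iff its population AF is missing or strictly below
    ``af_threshold`` AND its consequence normalizes into the non-synonymous
    set. Order is preserved; the operation is idempotent and monotone in
    the threshold. Unknown consequence terms are excluded and logged.
    """
    if not (0.0 < af_threshold <= 1.0):
        raise ConfigurationError(f"af_threshold must lie in (0, 1], got {af_threshold}")
    kept: list[VariantRecord] = []
    for v in variants:
        cons = normalize_consequence(v.consequence)
        if cons not in NONSYNONYMOUS_CONSEQUENCES:
            logger.debug("excluded %s: consequence %r not non-synonymous", v.variant_id, v.consequence)
            continue
        if v.gnomad_af is None:
            logger.debug("%s: AF missing, treated as rare", v.variant_id)
        elif v.gnomad_af >= af_threshold:
            continue
        kept.append(v)
    return kept


def summarize_zygosity(variants: Iterable[VariantRecord]) -> list[ZygositySummary]:
    """Classify filtered calls per patient x gene.

    Homozygous records count into ``n_homo``. A gene carrying >= 2 distinct
    heterozygous variants (distinct by variant id) in one patient is called
    a putative compound heterozygote: ``n_com_hete = 1``, consuming two of
    the het records; remaining het records count into ``n_hete`` so that
    ``2 * n_com_hete + n_hete + n_homo`` conserves the record count.
    """
    buckets: dict[tuple[str, str], dict[str, set | int]] = {}
    for v in variants:
        b = buckets.setdefault((v.patient_id, v.gene), {"het_ids": set(), "n_het": 0, "n_hom": 0})
        if v.zygosity is Zygosity.HOM:
            b["n_hom"] += 1
        else:
            b["het_ids"].add(v.variant_id)
            b["n_het"] += 1
    out = []
    for (patient, gene), b in sorted(buckets.items()):
        com = 1 if len(b["het_ids"]) >= 2 else 0
        out.append(
            ZygositySummary(
                patient_id=patient,
                gene=gene,
                n_com_hete=com,
                n_homo=b["n_hom"],
                n_hete=b["n_het"] - 2 * com,
            )
        )
    return out


def load_gene_panel(path: str | Path) -> list[str]:
    """Read a one-gene-per-line panel file (blank lines and # comments ignored)."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def load_predisposition_catalog(path: str | Path) -> set[str]:
    """Read a one-variant-id-per-line predisposition catalog; must be nonempty."""
    ids = set(load_gene_panel(path))
    if not ids:
        raise ConfigurationError(f"predisposition catalog {path} is empty")
    return ids


def match_predisposition(
    variants: Iterable[VariantRecord], catalog: set[str]
) -> pd.DataFrame:
    """Report patients carrying cataloged predisposition variants.

    Returns one row per (patient, catalog variant) with the observed
    zygosity, sorted by patient then variant id.
    """
    if not catalog:
        raise ConfigurationError("predisposition catalog is empty")
    rows = [
        {"patient_id": v.patient_id, "variant_id": v.variant_id, "zygosity": v.zygosity.value}
        for v in variants
        if v.variant_id in catalog
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "variant_id", "zygosity"])
    return df.drop_duplicates().sort_values(["patient_id", "variant_id"]).reset_index(drop=True)


def panel_restrict(
    variants: Iterable[VariantRecord], panel: Iterable[str]
) -> list[VariantRecord]:
    """Keep records whose gene is in the panel (order preserved)."""
    panel_set = set(panel)
    return [v for v in variants if v.gene in panel_set]


def write_variants(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records back out as the canonical TSV."""
    cols = [
        "patient_id", "gene", "origin", "consequence", "gnomad_af",
        "zygosity", "variant_id", "chrom", "pos", "ref", "alt",
    ]
    rows = []
    for v in records:
        rows.append(
            {
                "patient_id": v.patient_id,
                "gene": v.gene,
                "origin": v.origin.value,
                "consequence": v.consequence,
                "gnomad_af": "" if v.gnomad_af is None else repr(v.gnomad_af),
                "zygosity": v.zygosity.value,
                "variant_id": v.variant_id,
                "chrom": v.chrom or "",
                "pos": "" if v.pos is None else v.pos,
                "ref": v.ref or "",
                "alt": v.alt or "",
            }
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
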