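"""Synthetic cohort and network generator.

Generates every pipeline input — a scale-free-ish weighted interaction
network with a planted high-prize module, per-patient somatic and germline
variant tables with group-specific enrichment on a designated pharmacogene
panel, gene lengths, a predisposition catalog with planted carriers, and a
differential-expression table — with full ground truth recorded in a
manifest, so every stage can be tested against planted truth without any
external download.

The generative model is deliberately simple: per-gene per-patient variant
counts are Poisson and independent across genes and patients; edge
confidence scores are drawn so a configurable fraction clears the
score >= 700 filter; planted module edges receive high scores. The same
seed reproduces byte-identical outputs. What this emulates (and what it
does not — mutational signatures, LD, realistic degree mixing) is spelled
out in the methods note.

Also houses the packaged mutation-count tables of the reference cohort of
13 sorafenib-treated HCC patients (3 sensitive, 10 resistant), used by the
resistance-comparison stage's worked example.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .pcst import PrizeMap
from .resistance import MutationCountMatrix, read_count_matrix
from .variants import (
    HIGH_IMPACT_CONSEQUENCES,
    Origin,
    VariantRecord,
    Zygosity,
)

# rng stream tags: one independent stream per generated artifact
_TAG_NETWORK, _TAG_COHORT, _TAG_DE, _TAG_LENGTHS, _TAG_PRIZES = 11, 12, 13, 14, 15

SENSITIVE, RESISTANT, UNTREATED = "sensitive", "resistant", "untreated"


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror the desk-scale cohort.

    16 patients (3 sorafenib-sensitive, 10 resistant, 3 untreated), 300
    genes, a 42-gene synthetic pharmacogene panel, Poisson background
    mutation rates, and a mean of 2 planted qualifying germline panel
    variants per resistant patient (carrier probability ~0.86, in line with
    7-8 of 10 resistant carriers).
    """

    seed: int = 0
    n_genes: int = 300
    n_patients: int = 16
    n_sensitive: int = 3
    n_resistant: int = 10
    attachment: int = 2
    score_pass_fraction: float = 0.5
    module_size: int = 6
    module_prize_scale: float = 100.0
    background_prize_mean: float = 0.002
    somatic_rate: float = 0.01
    germline_rate: float = 0.002
    enrichment_rate: float = 2.0
    qualifying_fraction: float = 0.6
    panel_size: int = 42
    de_fraction: float = 0.036
    n_predisposition: int = 5
    n_predisposition_carriers: int = 3
    median_gene_length: float = 2e4
    sd_log_length: float = 0.8

    def __post_init__(self) -> None:
        for name in ("score_pass_fraction", "qualifying_fraction", "de_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_sensitive + self.n_resistant > self.n_patients:
            raise ConfigurationError("group split exceeds the number of patients")
        if self.n_genes < 10:
            raise ConfigurationError("need at least 10 genes")
        if self.module_size > self.n_genes:
            raise ConfigurationError("planted module larger than the gene universe")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _rng(cfg: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def gene_names(cfg: SyntheticConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(cfg.n_genes)]


def patient_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(cfg.n_patients)]


def group_labels(cfg: SyntheticConfig) -> dict[str, str]:
    """Deterministic split: first the sensitive, then the resistant, then untreated."""
    labels = {}
    for i, p in enumerate(patient_ids(cfg)):
        if i < cfg.n_sensitive:
            labels[p] = SENSITIVE
        elif i < cfg.n_sensitive + cfg.n_resistant:
            labels[p] = RESISTANT
        else:
            labels[p] = UNTREATED
    return labels


# ----------------------------------------------------------------------
# network
# ----------------------------------------------------------------------

def generate_network(cfg: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Scale-free-ish weighted edge list with a planted high-score module.

    Background scores clear the 700 filter with probability
    ``score_pass_fraction``; the spanning edges of the planted module are
    forced into [900, 1000] so the module survives filtering intact.
    Returns the edge table and a planted-truth record.
    """
    rng = _rng(cfg, _TAG_NETWORK)
    genes = gene_names(cfg)
    g = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, dict(enumerate(genes)))
    # plant a connected module by BFS growth from a random gene
    start = genes[int(rng.integers(cfg.n_genes))]
    module: list[str] = []
    for node in nx.bfs_tree(g, start):
        module.append(node)
        if len(module) == cfg.module_size:
            break
    if len(module) < cfg.module_size:
        raise ConfigurationError("graph too sparse for the requested module size")
    module_set = set(module)
    module_edges = {
        (min(u, v), max(u, v))
        for u, v in nx.bfs_tree(g, start).edges()
        if u in module_set and v in module_set
    }
    rows = []
    n_pass = 0
    for u, v in sorted((min(a, b), max(a, b)) for a, b in g.edges()):
        if (u, v) in module_edges:
            score = int(rng.integers(900, 1001))
        elif rng.random() < cfg.score_pass_fraction:
            score = int(rng.integers(700, 1001))
        else:
            score = int(rng.integers(400, 700))
        n_pass += score >= 700
        rows.append((u, v, score))
    edges = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    truth = {
        "genes": genes,
        "module_genes": sorted(module_set),
        "module_edges": sorted(map(list, module_edges)),
        "n_nodes": cfg.n_genes,
        "n_edges": len(rows),
        "n_pass_700": int(n_pass),
    }
    return edges, truth


def generate_gene_lengths(cfg: SyntheticConfig) -> dict[str, int]:
    """Log-normal gene lengths in bases (median ~20 kb), floored at 500."""
    rng = _rng(cfg, _TAG_LENGTHS)
    raw = rng.lognormal(np.log(cfg.median_gene_length), cfg.sd_log_length, cfg.n_genes)
    return {g: max(500, int(l)) for g, l in zip(gene_names(cfg), raw)}


def planted_prizes(cfg: SyntheticConfig, module_genes, patient_id: str = "planted") -> PrizeMap:
    """Prize map with the planted module boosted ``module_prize_scale``-fold
    over the background mean prize."""
    rng = _rng(cfg, _TAG_PRIZES)
    prizes = {
        g: float(rng.uniform(0, 2 * cfg.background_prize_mean)) for g in gene_names(cfg)
    }
    for g in module_genes:
        prizes[g] = cfg.module_prize_scale * cfg.background_prize_mean
    return PrizeMap(patient_id, prizes)


# ----------------------------------------------------------------------
# cohort
# ----------------------------------------------------------------------

_CONSEQUENCE_POOL = sorted(HIGH_IMPACT_CONSEQUENCES)


def _draw_variant(
    rng: np.random.Generator,
    patient: str,
    gene: str,
    origin: Origin,
    qualifying: bool,
    counter: list[int],
) -> VariantRecord:
    counter[0] += 1
    if qualifying:
        # rare non-synonymous: mostly missense, AF < 0.01 or absent from gnomAD
        if rng.random() < 0.6:
            consequence = "missense_variant"
        else:
            consequence = _CONSEQUENCE_POOL[int(rng.integers(len(_CONSEQUENCE_POOL)))]
        af = None if rng.random() < 0.15 else float(rng.uniform(0, 0.0099))
    elif rng.random() < 0.5:
        consequence = "synonymous_variant"
        af = float(rng.uniform(0, 0.0099))
    else:
        consequence = "missense_variant"
        af = float(rng.uniform(0.02, 0.5))
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    return VariantRecord(
        patient_id=patient,
        gene=gene,
        origin=origin,
        consequence=consequence,
        gnomad_af=af,
        zygosity=Zygosity.HOM if rng.random() < 0.1 else Zygosity.HET,
        variant_id=f"rs{1_000_000 + counter[0]}",
        chrom=str(int(rng.integers(1, 23))),
        pos=int(rng.integers(1, 100_000_000)),
        ref=str(ref),
        alt=str(alt),
    )


@dataclass
class SyntheticCohort:
    somatic: list[VariantRecord]
    germline: list[VariantRecord]
    labels: dict[str, str]
    gene_lengths: dict[str, int]
    panel: list[str]
    catalog: set[str]
    truth: dict = field(default_factory=dict)


def generate_cohort(cfg: SyntheticConfig, genes: list[str] | None = None) -> SyntheticCohort:
    """Per-patient variant tables with planted resistant-only enrichment.

    Background counts per gene/patient/origin are Poisson; each background
    variant qualifies for the rare non-synonymous filter with probability
    ``qualifying_fraction``. Resistant patients additionally receive
    Poisson(``enrichment_rate``) planted *qualifying germline* variants on
    the pharmacogene panel. Predisposition-catalog carriers are planted in
    the germline table. The truth record holds, per patient x gene x
    origin, the count of filter-passing variants.
    """
    rng = _rng(cfg, _TAG_COHORT)
    genes = genes or gene_names(cfg)
    patients = patient_ids(cfg)
    labels = group_labels(cfg)
    panel = sorted(rng.choice(genes, size=cfg.panel_size, replace=False).tolist())
    counter = [0]
    qualifying_counts: dict[tuple[str, str, str], int] = {}
    tables: dict[Origin, list[VariantRecord]] = {Origin.SOMATIC: [], Origin.GERMLINE: []}

    for origin, rate in ((Origin.SOMATIC, cfg.somatic_rate), (Origin.GERMLINE, cfg.germline_rate)):
        counts = rng.poisson(rate, size=(len(patients), len(genes)))
        for i, patient in enumerate(patients):
            for j, gene in enumerate(genes):
                for _ in range(int(counts[i, j])):
                    qual = bool(rng.random() < cfg.qualifying_fraction)
                    tables[origin].append(_draw_variant(rng, patient, gene, origin, qual, counter))
                    if qual:
                        key = (patient, gene, origin.value)
                        qualifying_counts[key] = qualifying_counts.get(key, 0) + 1

    # planted resistant-only germline enrichment on the panel
    enrichment_counts: dict[str, int] = {}
    for patient in patients:
        if labels[patient] != RESISTANT:
            continue
        n_extra = int(rng.poisson(cfg.enrichment_rate))
        enrichment_counts[patient] = n_extra
        for _ in range(n_extra):
            gene = str(rng.choice(panel))
            tables[Origin.GERMLINE].append(
                _draw_variant(rng, patient, gene, Origin.GERMLINE, True, counter)
            )
            key = (patient, gene, Origin.GERMLINE.value)
            qualifying_counts[key] = qualifying_counts.get(key, 0) + 1

    # predisposition catalog with planted carriers
    catalog = {f"rs{9_000_000 + i}" for i in range(cfg.n_predisposition)}
    carrier_patients = sorted(
        rng.choice(patients, size=cfg.n_predisposition_carriers, replace=False).tolist()
    )
    planted_carriers = []
    catalog_ids = sorted(catalog)
    for patient in carrier_patients:
        vid = catalog_ids[int(rng.integers(len(catalog_ids)))]
        base = _draw_variant(rng, patient, str(rng.choice(genes)), Origin.GERMLINE, True, counter)
        rec = VariantRecord(
            patient_id=base.patient_id, gene=base.gene, origin=base.origin,
            consequence=base.consequence, gnomad_af=base.gnomad_af,
            zygosity=base.zygosity, variant_id=vid,
            chrom=base.chrom, pos=base.pos, ref=base.ref, alt=base.alt,
        )
        tables[Origin.GERMLINE].append(rec)
        key = (patient, rec.gene, Origin.GERMLINE.value)
        qualifying_counts[key] = qualifying_counts.get(key, 0) + 1
        planted_carriers.append(
            {"patient_id": patient, "variant_id": vid, "zygosity": rec.zygosity.value}
        )

    truth = {
        "n_somatic_records": len(tables[Origin.SOMATIC]),
        "n_germline_records": len(tables[Origin.GERMLINE]),
        "qualifying_counts": {"|".join(k): v for k, v in qualifying_counts.items()},
        "enrichment_counts": enrichment_counts,
        "planted_carriers": planted_carriers,
        "panel": panel,
    }
    return SyntheticCohort(
        somatic=tables[Origin.SOMATIC],
        germline=tables[Origin.GERMLINE],
        labels=labels,
        gene_lengths=generate_gene_lengths(cfg),
        panel=panel,
        catalog=catalog,
        truth=truth,
    )


# ----------------------------------------------------------------------
# differential expression
# ----------------------------------------------------------------------

def generate_de_table(cfg: SyntheticConfig, genes: list[str] | None = None) -> tuple[pd.DataFrame, dict]:
    """DE statistics with an exact planted count of (logFC > 2, FDR < 0.01)
    passers."""
    rng = _rng(cfg, _TAG_DE)
    genes = genes or gene_names(cfg)
    n_pass = int(round(cfg.de_fraction * len(genes)))
    passers = set(rng.choice(genes, size=n_pass, replace=False).tolist())
    rows = []
    for g in genes:
        if g in passers:
            logfc = float(rng.uniform(2.01, 8.0))
            fdr = float(10.0 ** rng.uniform(-45, -2.1))
        elif rng.random() < 0.5:
            logfc = float(rng.uniform(-2.0, 2.0))
            fdr = float(10.0 ** rng.uniform(-45, 0))
        else:
            logfc = float(rng.uniform(2.01, 8.0))
            fdr = float(rng.uniform(0.01, 0.9))
        rows.append((g, logfc, fdr))
    df = pd.DataFrame(rows, columns=["gene", "logFC", "FDR"])
    return df, {"de_genes": sorted(passers), "n_de": n_pass}


# ----------------------------------------------------------------------
# orchestration + files
# ----------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    network_edges: pd.DataFrame
    cohort: SyntheticCohort
    de_table: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every input file the pipeline readers consume, plus a
        manifest.json with the planted truth."""
        from .variants import write_variants

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": outdir / "network.tsv",
            "somatic": outdir / "variants_somatic.tsv",
            "germline": outdir / "variants_germline.tsv",
            "labels": outdir / "labels.tsv",
            "gene_lengths": outdir / "gene_lengths.tsv",
            "panel": outdir / "panel_sorafenib.txt",
            "catalog": outdir / "predisposition.txt",
            "de_table": outdir / "de_table.tsv",
            "manifest": outdir / "manifest.json",
        }
        self.network_edges.to_csv(paths["network"], sep="\t", index=False)
        write_variants(self.cohort.somatic, paths["somatic"])
        write_variants(self.cohort.germline, paths["germline"])
        pd.DataFrame(
            sorted(self.cohort.labels.items()), columns=["patient_id", "group"]
        ).to_csv(paths["labels"], sep="\t", index=False)
        pd.DataFrame(
            sorted(self.cohort.gene_lengths.items()), columns=["gene", "length"]
        ).to_csv(paths["gene_lengths"], sep="\t", index=False)
        paths["panel"].write_text("\n".join(self.cohort.panel) + "\n")
        paths["catalog"].write_text("\n".join(sorted(self.cohort.catalog)) + "\n")
        self.de_table.to_csv(paths["de_table"], sep="\t", index=False)
        manifest = {"config": asdict(self.config), **self.truth}
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return paths


def generate_all(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full input bundle (network, cohort, DE table) with one
    shared planted-truth manifest."""
    edges, net_truth = generate_network(cfg)
    cohort = generate_cohort(cfg)
    de_table, de_truth = generate_de_table(cfg)
    truth = {"network": net_truth, "cohort": cohort.truth, "de": de_truth}
    return SyntheticDataset(cfg, edges, cohort, de_table, truth)


# ----------------------------------------------------------------------
# packaged reference-cohort tables
# ----------------------------------------------------------------------

def load_fixture_tables() -> tuple[MutationCountMatrix, MutationCountMatrix]:
    """Packaged mutation-count matrices for the reference cohort of 13
    sorafenib-treated HCC patients (3 sensitive, 10 resistant).

    Returns (somatic counts on the 17 mutated sorafenib pharmacogenes,
    germline counts on the 9 mutated candidate genes).
    """
    data = resources.files("hccnet") / "data"
    somatic = read_count_matrix(str(data / "sorafenib_somatic_counts.tsv"))
    germline = read_count_matrix(str(data / "candidate_germline_counts.tsv"))
    return somatic, germline
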