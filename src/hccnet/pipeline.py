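"""End-to-end orchestration of the analysis stages.

filter -> per-patient prizes -> PCST module per patient -> cohort
aggregate; bait panel -> RWR -> top-k candidate genes; count matrices ->
sensitive-vs-resistant comparison. Every run writes a manifest (config
snapshot, input checksums, per-stage runtimes, output paths) sufficient to
re-run it; deterministic stages reproduce bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .network import filter_confidence, load_network
from .pcst import (
    PCSTSolution,
    add_de_prizes,
    aggregate_modules,
    compute_prizes,
    load_gene_lengths,
    select_de_genes,
    solve_pcst,
)
from .resistance import (
    compare_resistance,
    count_matrix,
    write_count_matrix,
)
from .rwr import RWRConfig, rwr, top_k_genes
from .synth import SyntheticConfig, generate_all, load_fixture_tables
from .variants import (
    Origin,
    filter_rare_nonsynonymous,
    load_gene_panel,
    read_variants,
    write_variants,
)

logger = logging.getLogger(__name__)


@dataclass
class RunParams:
    """Stage parameters with the pipeline defaults."""

    af_threshold: float = 0.01          # germline rarity threshold
    somatic_af_threshold: float = 1.0   # somatic comparison: consequence filter only
    min_score: int = 700
    beta: float = 1.0
    de_bonus: float = 0.0
    gamma: float = 0.15
    top_k: int = 5000
    exclude_seeds: bool = False


@dataclass
class RunManifest:
    version: str
    params: dict
    inputs: dict[str, str]
    input_checksums: dict[str, str]
    runtimes: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _solution_record(sol: PCSTSolution) -> dict:
    return {
        "patient_id": sol.patient_id,
        "n_nodes": len(sol.tree_nodes),
        "n_edges": len(sol.tree_edges),
        "nodes": sorted(sol.tree_nodes),
        "edges": sorted(map(list, sol.tree_edges)),
        "objective": sol.objective,
        "beta": sol.beta,
    }


def run_fixture_comparison(outdir: str | Path) -> dict:
    """Resistance comparison on the packaged reference-cohort tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    somatic, germline = load_fixture_tables()
    report = compare_resistance(somatic, germline)
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    (outdir / "report.md").write_text(_report_markdown(report))
    return report


def _report_markdown(report: dict) -> str:
    lines = ["# Sensitive vs resistant mutation-burden comparison", ""]
    for origin in ("somatic", "germline"):
        r = report[origin]
        lines += [
            f"## {origin.capitalize()} panel",
            "",
            f"- Resistant carriers: {r['resistant_carriers']} / {r['resistant_total']}",
            f"- Sensitive carriers: {r['sensitive_carriers']} / {r['sensitive_total']}",
            f"- Two-sided Fisher exact p = {r['p_value_rounded']:.2f}"
            f" (raw {r['p_value']:.6g})",
            f"- Carrier patients: {', '.join(r['carrier_patients']) or 'none'}",
            "",
        ]
    return "\n".join(lines)


def run_all(
    inputs: dict[str, str] | None,
    outdir: str | Path,
    params: RunParams | None = None,
    synthetic: SyntheticConfig | None = None,
) -> RunManifest:
    """Execute the full pipeline.

    ``inputs`` names the file paths (somatic, germline, network,
    gene_lengths, panel, labels; optional de_table). With ``synthetic`` the
    inputs are generated first and read back from disk, so the run also
    validates the file round-trip.
    """
    params = params or RunParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}

    if synthetic is not None:
        t0 = time.perf_counter()
        dataset = generate_all(synthetic)
        paths = dataset.write(outdir / "data")
        inputs = {k: str(v) for k, v in paths.items() if k != "manifest"}
        timers["synthesize"] = time.perf_counter() - t0
    if inputs is None:
        raise ConfigurationError("run_all needs input paths or a synthetic config")
    required = ("somatic", "germline", "network", "gene_lengths", "panel", "labels")
    missing = [k for k in required if k not in inputs]
    if missing:
        raise ConfigurationError(f"missing input path(s): {missing}")

    manifest = RunManifest(
        version=__version__,
        params=asdict(params),
        inputs=dict(inputs),
        input_checksums={k: _sha256(v) for k, v in inputs.items() if Path(v).is_file()},
    )

    # -- stage: variant filtering --------------------------------------
    t0 = time.perf_counter()
    somatic = read_variants(inputs["somatic"], Origin.SOMATIC)
    germline = read_variants(inputs["germline"], Origin.GERMLINE)
    rare_somatic = filter_rare_nonsynonymous(somatic, params.af_threshold)
    rare_germline = filter_rare_nonsynonymous(germline, params.af_threshold)
    nonsyn_somatic = filter_rare_nonsynonymous(somatic, params.somatic_af_threshold)
    write_variants(rare_somatic, outdir / "filtered_somatic.tsv")
    write_variants(rare_germline, outdir / "filtered_germline.tsv")
    timers["filter"] = time.perf_counter() - t0

    # -- stage: network -------------------------------------------------
    t0 = time.perf_counter()
    net = filter_confidence(load_network(inputs["network"]), params.min_score)
    timers["network"] = time.perf_counter() - t0
    logger.info("filtered network: %d nodes, %d edges", net.n_nodes, net.n_edges)

    # -- stage: per-patient PCST ----------------------------------------
    t0 = time.perf_counter()
    gene_lengths = load_gene_lengths(inputs["gene_lengths"])
    de_genes: set[str] = set()
    if params.de_bonus > 0 and inputs.get("de_table"):
        de_genes = select_de_genes(pd.read_csv(inputs["de_table"], sep="\t"))
    by_patient: dict[str, list] = {}
    for v in rare_somatic + rare_germline:
        by_patient.setdefault(v.patient_id, []).append(v)
    solutions = []
    for patient in sorted(by_patient):
        prizes = compute_prizes(by_patient[patient], gene_lengths, patient)
        if de_genes:
            prizes = add_de_prizes(prizes, de_genes, params.de_bonus)
        prizes = prizes.restrict_to(net.nodes)
        if not prizes.prizes:
            logger.info("patient %s: no prized gene in the network, skipped", patient)
            continue
        solutions.append(solve_pcst(net, prizes, params.beta))
    aggregate = aggregate_modules(solutions)
    (outdir / "pcst_solutions.json").write_text(
        json.dumps([_solution_record(s) for s in solutions], indent=2) + "\n"
    )
    aggregate.frequent_genes().to_csv(outdir / "module_gene_frequency.tsv", sep="\t", index=False)
    timers["pcst"] = time.perf_counter() - t0

    # -- stage: RWR ------------------------------------------------------
    t0 = time.perf_counter()
    panel = load_gene_panel(inputs["panel"])
    k = min(params.top_k, net.n_nodes)
    scores = rwr(net, panel, RWRConfig(gamma=params.gamma, k=k))
    candidates = top_k_genes(scores, k, exclude_seeds=params.exclude_seeds)
    scores.to_frame().to_csv(outdir / "rwr_scores.tsv", sep="\t", index=False)
    timers["rwr"] = time.perf_counter() - t0

    # -- stage: resistance comparison ------------------------------------
    t0 = time.perf_counter()
    labels_df = pd.read_csv(inputs["labels"], sep="\t")
    labels = {
        str(p): g
        for p, g in zip(labels_df.iloc[:, 0], labels_df.iloc[:, 1])
        if g in ("sensitive", "resistant")
    }
    # untreated patients carry no sensitivity label and stay out of the test
    treated_somatic = [v for v in nonsyn_somatic if v.patient_id in labels]
    treated_germline = [v for v in rare_germline if v.patient_id in labels]
    somatic_m = count_matrix(treated_somatic, panel, labels, Origin.SOMATIC)
    germline_m = count_matrix(treated_germline, candidates, labels, Origin.GERMLINE)
    report = compare_resistance(somatic_m, germline_m)
    write_count_matrix(somatic_m, outdir / "matrix_somatic.tsv")
    write_count_matrix(germline_m, outdir / "matrix_germline.tsv")
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    (outdir / "report.md").write_text(_report_markdown(report))
    timers["compare"] = time.perf_counter() - t0

    manifest.runtimes = timers
    manifest.outputs = {
        "pcst_solutions": str(outdir / "pcst_solutions.json"),
        "module_gene_frequency": str(outdir / "module_gene_frequency.tsv"),
        "rwr_scores": str(outdir / "rwr_scores.tsv"),
        "matrix_somatic": str(outdir / "matrix_somatic.tsv"),
        "matrix_germline": str(outdir / "matrix_germline.tsv"),
        "report": str(outdir / "report.json"),
    }
    manifest.write(outdir / "run_manifest.json")
    return manifest
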