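"""Sensitive-vs-resistant mutation-burden comparison.

Gene x patient mutation-count matrices are built on a gene panel (somatic
counts on the sorafenib pharmacogene panel; germline counts on the RWR
top-k candidate panel). The comparison unit is *carrier status*: a patient
carries if at least one qualifying variant falls in the panel. Carriers
per group form a 2x2 table (group x carries-any) tested with a two-sided
Fisher exact test using the point-probability definition — the sum of
hypergeometric probabilities of all tables (with the observed margins) no
more likely than the observed one — evaluated in exact rational
arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, DataError
from .variants import Origin, VariantRecord

logger = logging.getLogger(__name__)

SENSITIVE = "sensitive"
RESISTANT = "resistant"


@dataclass
class MutationCountMatrix:
    """Panel genes (rows) x patients (columns) nonnegative integer counts."""

    counts: pd.DataFrame
    groups: dict[str, str]  # patient -> sensitive | resistant
    origin: Origin

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise DataError("mutation counts must be nonnegative")
        unlabeled = [p for p in self.counts.columns if p not in self.groups]
        if unlabeled:
            raise DataError(f"unlabeled patient column(s): {unlabeled}")
        bad = {p: g for p, g in self.groups.items() if g not in (SENSITIVE, RESISTANT)}
        if bad:
            raise DataError(f"group labels must be sensitive/resistant, got {bad}")

    @property
    def patients(self) -> list[str]:
        return list(self.counts.columns)

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def carriers(self) -> list[str]:
        """Patients with at least one panel mutation."""
        totals = self.column_totals()
        return [p for p in self.patients if totals[p] > 0]


def count_matrix(
    variants: Iterable[VariantRecord],
    panel: Iterable[str],
    labels: Mapping[str, str],
    origin: Origin | str,
) -> MutationCountMatrix:
    """Count qualifying variants of one origin per panel gene per patient.

    Every labeled patient appears as a column (all-zero if no qualifying
    variant); a variant from an unlabeled patient is a data error.
    """
    origin = Origin(origin)
    panel = list(dict.fromkeys(panel))
    patients = list(labels.keys())
    counts = pd.DataFrame(0, index=panel, columns=patients, dtype=int)
    panel_set = set(panel)
    for v in variants:
        if v.origin is not origin or v.gene not in panel_set:
            continue
        if v.patient_id not in labels:
            raise DataError(f"patient {v.patient_id} has no group label")
        counts.loc[v.gene, v.patient_id] += 1
    return MutationCountMatrix(counts, dict(labels), origin)


def carriers_per_group(matrix: MutationCountMatrix) -> np.ndarray:
    """2x2 carrier table: rows (resistant, sensitive), columns (carrier, non-carrier)."""
    totals = matrix.column_totals()
    table = np.zeros((2, 2), dtype=int)
    for patient in matrix.patients:
        row = 0 if matrix.groups[patient] == RESISTANT else 1
        col = 0 if totals[patient] > 0 else 1
        table[row, col] += 1
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ContractError("both patient groups must be nonempty")
    return table


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Point-probability method: with margins fixed, sum the hypergeometric
    probabilities of every table whose probability does not exceed the
    observed one. Computed with exact :class:`fractions.Fraction`
    arithmetic, so no floating-point ties are mistaken. A degenerate
    margin (an empty row or column) yields p = 1.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {t.shape}")
    a, b, c, d = (int(x) for x in t.ravel())
    if min(a, b, c, d) < 0:
        raise DataError("table cells must be nonnegative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom) for x in range(lo, hi + 1)
    }
    observed = probs[a]
    p = sum(pr for pr in probs.values() if pr <= observed)
    return float(min(p, Fraction(1)))


def compare_resistance(
    somatic_matrix: MutationCountMatrix, germline_matrix: MutationCountMatrix
) -> dict:
    """Full sensitive-vs-resistant report for one cohort.

    Both matrices must label the same patients identically. The report
    carries both carrier 2x2 tables, raw and display-rounded p-values,
    per-patient totals and carrier lists.
    """
    if somatic_matrix.groups != germline_matrix.groups:
        raise DataError("somatic and germline matrices disagree on patient labels")
    report: dict = {"patients": somatic_matrix.groups}
    for name, m in (("somatic", somatic_matrix), ("germline", germline_matrix)):
        table = carriers_per_group(m)
        p = fisher_exact_two_sided(table)
        report[name] = {
            "carrier_table": table.tolist(),
            "resistant_carriers": int(table[0, 0]),
            "resistant_total": int(table[0].sum()),
            "sensitive_carriers": int(table[1, 0]),
            "sensitive_total": int(table[1].sum()),
            "p_value": p,
            "p_value_rounded": round(p, 2),
            "per_patient_totals": {p_: int(t) for p_, t in m.column_totals().items()},
            "carrier_patients": m.carriers(),
        }
    return report


# ----------------------------------------------------------------------
# matrix I/O: TSV with one '#group' comment line per patient
# ----------------------------------------------------------------------

def write_count_matrix(matrix: MutationCountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#origin\t{matrix.origin.value}\n")
        for patient, group in matrix.groups.items():
            fh.write(f"#group\t{patient}\t{group}\n")
        matrix.counts.to_csv(fh, sep="\t", index_label="gene")


def read_count_matrix(path: str | Path) -> MutationCountMatrix:
    groups: dict[str, str] = {}
    origin = None
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#origin"):
            origin = Origin(line.split("\t")[1])
        elif line.startswith("#group"):
            _, patient, group = line.split("\t")
            groups[patient] = group
        else:
            body.append(line)
    if origin is None:
        raise DataError(f"{path}: missing '#origin' header line")
    from io import StringIO

    counts = pd.read_csv(StringIO("\n".join(body)), sep="\t", index_col="gene")
    counts.columns = counts.columns.astype(str)
    return MutationCountMatrix(counts.astype(int), groups, origin)
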