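"""Positional cohort analysis of truncating variants.

Truncating variants are classified as N- or C-terminal relative to the
amino-acid position of the internal (Cronos) promoter on the meta-transcript
(human default: residue 14,760, inclusive on the C side). Variants in the
Novex-3-exclusive terminal exon are excluded from the N/C ratio (the isoform
is minor and its truncations are not comparable) but retained in the table
for prevalence comparisons. Cohorts are compared with a pooled two-proportion
z-test (no continuity correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import math

import pandas as pd
from scipy.stats import norm

from .errors import InputError

DEFAULT_BOUNDARY_AA = 14760


class PositionalClass(str, Enum):
    N = "N"
    C = "C"
    NOVEX3_EXCLUDED = "NOVEX3_EXCLUDED"


@dataclass(frozen=True)
class CohortVariantRow:
    subject_id: str
    cohort_label: str
    aa_position: int
    novex3: bool
    truncating: bool


class CohortVariantTable:
    """One row per subject-variant; thin wrapper over a DataFrame."""

    COLUMNS = ["subject_id", "cohort_label", "aa_position", "novex3", "truncating"]

    def __init__(self, rows: Sequence[CohortVariantRow]):
        self.rows = list(rows)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortVariantTable":
        df = pd.read_csv(path, sep="\t")
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise InputError(f"{path}: missing columns {sorted(missing)}")
        rows = [
            CohortVariantRow(
                subject_id=str(r.subject_id),
                cohort_label=str(r.cohort_label),
                aa_position=int(r.aa_position),
                novex3=bool(r.novex3),
                truncating=bool(r.truncating),
            )
            for r in df.itertuples()
        ]
        return cls(rows)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([r.__dict__ for r in self.rows]).to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.rows)


def classify_relative_to_cronos(
    aa_position: int,
    boundary_aa: int = DEFAULT_BOUNDARY_AA,
    novex3: bool = False,
) -> PositionalClass:
    """N/C classification; the boundary residue itself is C (inclusive)."""
    if boundary_aa < 1:
        raise InputError("boundary_aa must be >= 1")
    if aa_position <= 0:
        raise InputError(f"amino-acid position must be positive, got {aa_position}")
    if novex3:
        return PositionalClass.NOVEX3_EXCLUDED
    return PositionalClass.C if aa_position >= boundary_aa else PositionalClass.N


@dataclass(frozen=True)
class PositionalSummary:
    cohort_label: str
    n_c: int
    n_n: int
    n_novex3_excluded: int

    @property
    def ratio_text(self) -> str:
        return f"{self.n_c}:{self.n_n}"

    @property
    def total_truncating(self) -> int:
        return self.n_c + self.n_n + self.n_novex3_excluded


def summarize_cohorts(
    table: CohortVariantTable, boundary_aa: int = DEFAULT_BOUNDARY_AA
) -> dict[str, PositionalSummary]:
    """Per-cohort C/N counts among truncating rows (Novex-3 rows excluded
    from the ratio but tallied)."""
    if len(table) == 0:
        raise InputError("cohort table is empty")
    counts: dict[str, dict[str, int]] = {}
    for row in table.rows:
        bucket = counts.setdefault(row.cohort_label, {"C": 0, "N": 0, "X": 0})
        if not row.truncating:
            continue
        cls = classify_relative_to_cronos(row.aa_position, boundary_aa, row.novex3)
        if cls is PositionalClass.C:
            bucket["C"] += 1
        elif cls is PositionalClass.N:
            bucket["N"] += 1
        else:
            bucket["X"] += 1
    return {
        label: PositionalSummary(label, b["C"], b["N"], b["X"])
        for label, b in sorted(counts.items())
    }


@dataclass(frozen=True)
class ProportionTestResult:
    p1: float
    p2: float
    z: float
    p_value: float

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = False
) -> ProportionTestResult:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    With ``continuity`` a Yates-style correction of (1/n1 + 1/n2)/2 shrinks
    the difference toward zero. Degenerate pooled proportions (0 or 1) give
    z = 0, p = 1 by convention.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise InputError("group sizes must be positive")
        if not 0 <= x <= n:
            raise InputError(f"successes must satisfy 0 <= x <= n, got x={x}, n={n}")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(p1, p2, 0.0, 1.0)
    diff = p1 - p2
    if continuity:
        correction = 0.5 * (1 / n1 + 1 / n2)
        diff = math.copysign(max(0.0, abs(diff) - correction), diff)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = diff / se
    p_value = 2.0 * float(norm.sf(abs(z)))
    return ProportionTestResult(p1, p2, z, min(p_value, 1.0))


def fold_ratio(p1: float, p2: float) -> float:
    """Fold difference between two rates (p1 relative to p2)."""
    if p2 <= 0:
        raise InputError("reference rate must be positive for a fold ratio")
    return p1 / p2
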