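"""Paired-technique comparison statistics.

Exact Wilcoxon signed-rank testing for small paired cohorts (the regime of
ten-patient planning studies), cohort summaries, and loaders for the
packaged reference cohorts: per-patient mean parotid doses under a sparing
strategy and per-patient limiting prescriptions under isotoxic escalation,
for a fixed-field (IMRT) versus rotational (VMAT) technique comparison.

The exact test enumerates all 2^n sign assignments of the ranked absolute
differences (average ranks for ties, zero differences discarded), so the
p-value is exact rather than asymptotic; above n = 20 a normal
approximation with tie correction is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: enumerate exactly up to this many nonzero differences
EXACT_N_MAX = 20


@dataclass
class PairedSample:
    """Per-case paired scalars (e.g. Gy under technique A vs technique B)."""

    labels: list[str]
    a_values: np.ndarray
    b_values: np.ndarray
    subgroups: list[str] | None = None
    #: an independently supplied per-case difference column (e.g. the
    #: rounded values printed in a report), kept separate because printed
    #: differences are not always the exact column difference
    printed_diff: np.ndarray | None = None

    def __post_init__(self):
        self.a_values = np.asarray(self.a_values, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if len(self.labels) != self.a_values.size or self.a_values.size != self.b_values.size:
            raise ValueError("labels, a_values and b_values must have equal length")
        if self.a_values.size < 1:
            raise ValueError("paired sample must contain at least one case")
        if self.subgroups is not None and len(self.subgroups) != self.a_values.size:
            raise ValueError("subgroup labels must match the number of cases")

    @property
    def n(self) -> int:
        return self.a_values.size

    @property
    def differences(self) -> np.ndarray:
        return self.a_values - self.b_values


@dataclass
class WilcoxonResult:
    w: float  # smaller of the two signed-rank sums
    p: float  # exact (or tie-corrected normal) two-sided p
    n_used: int  # nonzero differences entering the test
    exact: bool


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks of |differences| after discarding zeros, plus signs."""
    nz = diffs[diffs != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    order = np.argsort(np.abs(nz), kind="stable")
    ranks = np.empty(nz.size)
    ranks[order] = np.arange(1, nz.size + 1)
    # average ranks over ties
    absvals = np.abs(nz)
    for v in np.unique(absvals):
        tie = absvals == v
        if tie.sum() > 1:
            ranks[tie] = ranks[tie].mean()
    return ranks, np.sign(nz)


def _exact_distribution(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Counts of W+ over all sign assignments, on a half-rank integer grid.

    Ranks are doubled so tied average ranks (multiples of 0.5) become
    integers; the distribution is built by polynomial convolution.
    """
    scaled = np.rint(ranks * 2).astype(int)
    total = scaled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts, total


def wilcoxon_exact(pairs: PairedSample) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on a paired sample.

    Zero differences are discarded (the classical treatment); ties among
    the remaining absolute differences receive average ranks.  For n <= 20
    the two-sided p-value is computed from the full enumeration of the
    2^n sign-assignment distribution of W+; beyond that a normal
    approximation with tie correction is used.
    """
    ranks, signs = _signed_ranks(pairs.differences)
    n = ranks.size
    w_plus = float(ranks[signs > 0].sum())
    w_minus = float(ranks[signs < 0].sum())
    w = min(w_plus, w_minus)
    if n <= EXACT_N_MAX:
        counts, total = _exact_distribution(ranks)
        obs = int(round(w_plus * 2))
        denom = counts.sum()  # 2^n
        p_le = counts[: obs + 1].sum() / denom
        p_ge = counts[obs:].sum() / denom
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w=w, p=float(p), n_used=n, exact=True)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, counts_per = np.unique(np.abs(pairs.differences[pairs.differences != 0]),
                              return_counts=True)
    var -= ((counts_per**3 - counts_per).sum()) / 48.0
    z = (w_plus - mean) / math.sqrt(var)
    p = 2.0 * (1.0 - 0.5 * (1.0 + math.erf(abs(z) / math.sqrt(2.0))))
    return WilcoxonResult(w=w, p=min(1.0, float(p)), n_used=n, exact=False)


@dataclass
class PairedSummary:
    mean_a: float
    mean_b: float
    mean_diff: float  # of exact differences a - b
    mean_printed_diff: float | None
    max_abs_diff: float
    range_a: tuple[float, float]
    range_b: tuple[float, float]


def paired_summary(pairs: PairedSample) -> PairedSummary:
    """Cohort arithmetic: means, ranges and the largest per-case difference.

    When the sample carries an independently printed difference column its
    mean is reported alongside the exact column difference.
    """
    d = pairs.differences
    printed = (
        float(np.mean(pairs.printed_diff)) if pairs.printed_diff is not None else None
    )
    return PairedSummary(
        mean_a=float(pairs.a_values.mean()),
        mean_b=float(pairs.b_values.mean()),
        mean_diff=float(d.mean()),
        mean_printed_diff=printed,
        max_abs_diff=float(np.abs(d).max()),
        range_a=(float(pairs.a_values.min()), float(pairs.a_values.max())),
        range_b=(float(pairs.b_values.min()), float(pairs.b_values.max())),
    )


def subgroup_abs_difference(pairs: PairedSample) -> dict[str, tuple[float, float | None]]:
    """Per-subgroup mean and sample (n-1) SD of |a - b|.

    Subgroups with fewer than two cases report an absent SD (None).
    """
    if pairs.subgroups is None:
        raise ValueError("paired sample carries no subgroup labels")
    out: dict[str, tuple[float, float | None]] = {}
    absd = np.abs(pairs.differences)
    for g in dict.fromkeys(pairs.subgroups):  # preserve first-seen order
        vals = absd[[s == g for s in pairs.subgroups]]
        sd = float(vals.std(ddof=1)) if vals.size >= 2 else None
        out[g] = (float(vals.mean()), sd)
    return out


# ---------------------------------------------------------------------------
# packaged reference cohorts


def _load_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("autoplan.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def load_sparing_cohort() -> PairedSample:
    """Ten-patient reference cohort of minimum mean parotid doses (Gy),
    IMRT (a) vs VMAT (b), with the printed per-case difference column."""
    df = _load_fixture("sparing_cohort.csv")
    return PairedSample(
        labels=df["patient"].tolist(),
        a_values=df["imrt_gy"].to_numpy(),
        b_values=df["vmat_gy"].to_numpy(),
        printed_diff=df["delta_printed"].to_numpy(),
    )


def load_escalation_cohort() -> PairedSample:
    """Ten-patient reference cohort of limiting prescription doses (Gy),
    IMRT (a) vs VMAT (b), with nodal-laterality subgroup labels."""
    df = _load_fixture("escalation_cohort.csv")
    return PairedSample(
        labels=df["patient"].tolist(),
        a_values=df["imrt_gy"].to_numpy(),
        b_values=df["vmat_gy"].to_numpy(),
        subgroups=df["laterality"].tolist(),
        printed_diff=df["delta_printed"].to_numpy(),
    )
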