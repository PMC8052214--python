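"""Study-evaluation statistics.

The two-attempt design yields per-subject paired values of each
performance index.  Improvement from attempt A to attempt B is tested
with the Wilcoxon signed-rank test (two-tailed, significant at p < 0.1),
descriptives are reported as median with first and third quartiles, and
usability responses are scored with the standard 10-item System Usability
Scale.

The signed-rank test is authored here: zero differences are dropped
before ranking (the classic treatment; Pratt's method is available as an
option), tied absolute differences receive mid-ranks, and the two-tailed
p-value is exact — full enumeration of all 2^n sign assignments — for up
to 12 effective pairs, switching to the normal approximation with
tie-corrected variance and continuity correction above that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "PairedStudy",
    "StatsResult",
    "Descriptives",
    "SUSResponse",
    "CohortReport",
    "wilcoxon_signed_rank",
    "describe",
    "sus_score",
    "cohort_report",
    "EXACT_ENUMERATION_MAX_N",
    "ALPHA",
]

ALPHA = 0.1
#: largest n_effective for which the exact 2^n enumeration is used
EXACT_ENUMERATION_MAX_N = 12
#: smallest n_effective at which a two-tailed exact p can fall below ALPHA
MIN_POWERED_N = 5

PERFORMANCE_INDEXES = ("insertion_angle", "relative_error", "duration", "n_total_errors")


@dataclass
class PairedStudy:
    """Per-subject (attempt A, attempt B) values of one performance index."""

    pairs: np.ndarray  # (n, 2)
    metric: str = ""
    group: str = ""
    platform: str = ""

    def __post_init__(self) -> None:
        self.pairs = np.atleast_2d(np.asarray(self.pairs, dtype=float))
        if self.pairs.shape[1] != 2 or len(self.pairs) < 1:
            raise ValueError("pairs must be a non-empty (n, 2) array")

    @property
    def differences(self) -> np.ndarray:
        return self.pairs[:, 0] - self.pairs[:, 1]


@dataclass(frozen=True)
class StatsResult:
    """Signed-rank test outcome; ``significant`` is p < 0.1 two-tailed."""

    w_statistic: float
    p_two_tailed: float
    n_effective: int
    significant: bool
    method: str  # "exact" | "normal_approx" | "degenerate"
    underpowered: bool = False


@dataclass(frozen=True)
class Descriptives:
    median: float
    q1: float
    q3: float

    def __str__(self) -> str:
        return f"{self.median:g} ({self.q1:g}–{self.q3:g})"


def _exact_two_tailed_p(ranks: np.ndarray, w_plus: float) -> float:
    """P-value by full enumeration of all 2^n sign assignments of the ranks."""
    n = len(ranks)
    # all sign vectors as a bit matrix: (2^n, n)
    codes = np.arange(2**n, dtype=np.uint32)
    bits = (codes[:, None] >> np.arange(n, dtype=np.uint32)[None, :]) & 1
    T = bits @ ranks
    eps = 1e-9
    p_le = np.count_nonzero(T <= w_plus + eps) / len(T)
    p_ge = np.count_nonzero(T >= w_plus - eps) / len(T)
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    pairs, zero_method: str = "wilcox", alpha: float = ALPHA
) -> StatsResult:
    """Paired two-tailed Wilcoxon signed-rank test.

    ``pairs`` is an (n, 2) array, a :class:`PairedStudy`, or a 1-D array
    already holding the paired differences.  ``zero_method='wilcox'``
    drops zero differences before ranking; ``'pratt'`` ranks them and
    drops their ranks from both sums.
    """
    if isinstance(pairs, PairedStudy):
        d = pairs.differences
    else:
        arr = np.asarray(pairs, dtype=float)
        d = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
    if len(d) < 1:
        raise ValueError("need at least one pair")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")

    nz = d != 0.0
    n_eff = int(np.count_nonzero(nz))
    if n_eff == 0:
        return StatsResult(0.0, 1.0, 0, False, "degenerate", underpowered=True)

    if zero_method == "wilcox":
        d_used = d[nz]
        ranks = rankdata(np.abs(d_used))
    else:  # pratt: rank zeros too, then discard their ranks
        ranks_all = rankdata(np.abs(d))
        d_used = d[nz]
        ranks = ranks_all[nz]

    w_plus = float(np.sum(ranks[d_used > 0]))
    w_minus = float(np.sum(ranks[d_used < 0]))
    w_stat = min(w_plus, w_minus)

    if n_eff <= EXACT_ENUMERATION_MAX_N:
        p = _exact_two_tailed_p(ranks, w_plus)
        method = "exact"
    else:
        mu = float(np.sum(ranks)) / 2.0
        # Var(W+) = sum(r_i^2)/4 — the tie-corrected n(n+1)(2n+1)/24 form
        var = float(np.sum(ranks**2)) / 4.0
        sigma = np.sqrt(var)
        z = (abs(w_plus - mu) - 0.5) / sigma if sigma > 0 else 0.0
        p = min(1.0, 2.0 * float(norm.sf(z)))
        method = "normal_approx"
    return StatsResult(
        w_statistic=float(w_stat),
        p_two_tailed=float(p),
        n_effective=n_eff,
        significant=bool(p < alpha),
        method=method,
        underpowered=bool(n_eff < MIN_POWERED_N),
    )


def describe(values, method: str = "linear") -> Descriptives:
    """Median and quartiles (linear interpolation between order statistics).

    ``method`` is any quantile method numpy accepts, so the quartile
    convention is config-selectable.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("describe() needs at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method=method)
    return Descriptives(median=float(med), q1=float(q1), q3=float(q3))


@dataclass(frozen=True)
class SUSResponse:
    """One System Usability Scale response: 10 items rated 1-5."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValueError("SUS response needs exactly 10 items")
        if any(not 1 <= int(i) <= 5 for i in self.items):
            raise ValueError("SUS ratings must be integers in 1..5")


def sus_score(response: SUSResponse | list[int] | tuple[int, ...]) -> float:
    """Standard SUS score in [0, 100].

    Odd-positioned (positively worded) items contribute (rating - 1),
    even-positioned ones (5 - rating); the sum is scaled by 2.5.
    """
    if not isinstance(response, SUSResponse):
        response = SUSResponse(tuple(int(i) for i in response))
    total = 0
    for pos, rating in enumerate(response.items, start=1):
        total += (rating - 1) if pos % 2 == 1 else (5 - rating)
    return 2.5 * total


# ---------------------------------------------------------------------------
# Cohort report


@dataclass
class CohortReport:
    """Per-index descriptives (attempts A and B) and paired test results.

    ``cells`` maps (group, platform) -> {index -> {"A": Descriptives,
    "B": Descriptives, "test": StatsResult, "improvement": Descriptives}}.
    The improvement is the per-subject delta A - B (positive = better in
    attempt B for cost-like indexes).
    """

    cells: dict = field(default_factory=dict)
    excluded_subjects: list[str] = field(default_factory=list)
    alpha: float = ALPHA

    def summary(self) -> str:
        """Human-readable table: median (Q1-Q3) per cell/attempt plus p-values."""
        lines = []
        header = f"{'group/platform':<24}{'index':<20}{'Attempt A':>18}{'Attempt B':>18}{'p':>9}"
        lines.append(header)
        lines.append("-" * len(header))
        for (group, platform), indexes in self.cells.items():
            cell = f"{group}/{platform}"
            for index, entry in indexes.items():
                test: StatsResult = entry["test"]
                star = "*" if test.significant else ""
                lines.append(
                    f"{cell:<24}{index:<20}{str(entry['A']):>18}{str(entry['B']):>18}"
                    f"{test.p_two_tailed:>8.4f}{star}"
                )
        if self.excluded_subjects:
            lines.append(f"excluded (unpaired): {', '.join(self.excluded_subjects)}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        out = {"alpha": self.alpha, "excluded_subjects": self.excluded_subjects, "cells": {}}
        for key, indexes in self.cells.items():
            cell = {}
            for index, e in indexes.items():
                t: StatsResult = e["test"]
                cell[index] = {
                    "A": vars(e["A"]).copy(),
                    "B": vars(e["B"]).copy(),
                    "improvement": vars(e["improvement"]).copy(),
                    "test": {
                        "w_statistic": t.w_statistic,
                        "p_two_tailed": t.p_two_tailed,
                        "n_effective": t.n_effective,
                        "significant": t.significant,
                        "method": t.method,
                        "underpowered": t.underpowered,
                    },
                }
            out["cells"]["/".join(key)] = cell
        return out


def _metrics_frame(metrics) -> pd.DataFrame:
    if isinstance(metrics, pd.DataFrame):
        return metrics.copy()
    return pd.DataFrame([m.as_dict() for m in metrics])


def cohort_report(
    metrics,
    grouping: str = "by_group",
    indexes=PERFORMANCE_INDEXES,
    alpha: float = ALPHA,
    zero_method: str = "wilcox",
    quantile_method: str = "linear",
) -> CohortReport:
    """Descriptives and A-vs-B paired tests over a cohort's metrics.

    ``metrics`` is a list of :class:`vnsim.scoring.InsertionMetrics` or an
    equivalent DataFrame with subject/group/platform/attempt columns.
    ``grouping`` is ``"by_group"`` (group x platform cells), ``"merged"``
    (platform cells, expertise-independent) or ``"all"`` (one cell).
    Subjects missing either attempt are excluded with a warning entry.
    """
    df = _metrics_frame(metrics)
    if "n_total_errors" not in df and {"n_forbidden_contacts", "n_wrong_orientation"} <= set(df):
        df["n_total_errors"] = df["n_forbidden_contacts"] + df["n_wrong_orientation"]

    counts = df.groupby("subject")["attempt"].nunique()
    unpaired = sorted(counts.index[counts < 2])
    df = df[~df["subject"].isin(unpaired)]
    if df.empty:
        raise ValueError("no paired subjects to report on")

    if grouping == "by_group":
        keys = ["group", "platform"]
    elif grouping == "merged":
        keys = ["platform"]
    elif grouping == "all":
        keys = []
    else:
        raise ValueError("grouping must be 'by_group', 'merged' or 'all'")

    report = CohortReport(alpha=alpha, excluded_subjects=[str(s) for s in unpaired])
    grouped = [((), df)] if not keys else list(df.groupby(keys, dropna=False))
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        label = tuple(str(k) for k in key) if key else ("all", "all")
        if len(label) == 1:
            label = ("all", label[0])
        wide = sub.pivot_table(index="subject", columns="attempt", values=list(indexes))
        entry: dict = {}
        for index in indexes:
            a = wide[index]["A"].to_numpy(dtype=float)
            b = wide[index]["B"].to_numpy(dtype=float)
            pairs = np.column_stack([a, b])
            entry[index] = {
                "A": describe(a, method=quantile_method),
                "B": describe(b, method=quantile_method),
                "improvement": describe(a - b, method=quantile_method),
                "test": wilcoxon_signed_rank(pairs, zero_method=zero_method, alpha=alpha),
            }
        report.cells[label] = entry
    return report
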