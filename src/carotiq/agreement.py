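"""Method-agreement statistics: Bland–Altman analysis with exact limits-of-
agreement confidence intervals, Sørensen–Dice overlap, and paired tests.

For paired measurements (a_i, b_i), i = 1..n, the differences d_i = a_i − b_i
are summarized by the bias d̄ and sample SD s (divisor n−1). The 95% limits
of agreement (LoA) are d̄ ± 1.96 s.  Confidence limits for each LoA use the
exact noncentral-t construction: with T' ~ t'_{n−1}(δ), δ = 1.96 √n, the
interval

    d̄ + k s/√n,   k ∈ [K_L, K_U]

has exact coverage for the upper LoA μ + 1.96σ whenever
P(K_L ≤ T' ≤ K_U) = level.  Two variants are provided:

* ``tails="symmetric"`` (default): equal halfwidth above and below the LoA,
  i.e. K_U = (1.96 + h)√n, K_L = (1.96 − h)√n with h solved so the coverage
  equals ``level``;
* ``tails="equal"``: equal tail probabilities, K_L and K_U the
  (1∓level)/2 noncentral-t quantiles.

Both are exact (coverage equals the nominal level under normality); they
differ in how the 5% miss probability is split between the two tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import GridMismatchError, SampleSizeError
from .imagevol import BinaryMask
from .quant import UptakeStats

QUANTITIES = ("vol_ml", "suv_mean", "suv_max", "suv_total")


@dataclass
class PairedMeasurements:
    """One quantity measured by two methods on the same subjects."""

    subject_ids: list
    method_a: np.ndarray
    method_b: np.ndarray
    quantity: str = "vol_ml"
    side: str = "left"

    def __post_init__(self):
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if not (len(self.subject_ids) == len(self.method_a) == len(self.method_b)):
            raise ValueError("subject ids and measurement arrays must have equal length")
        if len(self.method_a) < 2:
            raise SampleSizeError("need at least 2 paired observations")
        if np.any(~np.isfinite(self.method_a)) or np.any(~np.isfinite(self.method_b)):
            raise ValueError("missing or non-finite measurements are not allowed")

    @property
    def differences(self) -> np.ndarray:
        return self.method_a - self.method_b


@dataclass(frozen=True)
class DiffSummary:
    """Paired-difference summary: n, bias (a − b) and sample SD."""

    n: int
    mean_diff: float
    sd_diff: float

    def __post_init__(self):
        if self.n < 2:
            raise SampleSizeError(f"need n >= 2, got {self.n}")
        if self.sd_diff < 0:
            raise ValueError("sd_diff must be nonnegative")


@dataclass(frozen=True)
class BlandAltmanResult:
    summary: DiffSummary
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]


@dataclass(frozen=True)
class DiceResult:
    value: float
    intersection_voxels: int
    size_a: int
    size_b: int
    both_empty: bool = False


def summarize_differences(pairs: PairedMeasurements) -> DiffSummary:
    """Mean and sample SD (divisor n−1) of the paired differences a − b."""
    d = pairs.differences
    return DiffSummary(n=len(d), mean_diff=float(np.mean(d)),
                       sd_diff=float(np.std(d, ddof=1)))


def limits_of_agreement(summary: DiffSummary, z: float = 1.96) -> tuple[float, float]:
    """Bland–Altman limits of agreement: mean ± z·SD."""
    m, s = summary.mean_diff, summary.sd_diff
    return (m - z * s, m + z * s)


def bias_confidence_interval(summary: DiffSummary, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for the bias."""
    t = stats.t.ppf((1 + level) / 2, summary.n - 1)
    half = t * summary.sd_diff / np.sqrt(summary.n)
    return (summary.mean_diff - half, summary.mean_diff + half)


def _nct_k_factors(n: int, level: float, z: float, tails: str) -> tuple[float, float]:
    """Noncentral-t multipliers (K_L, K_U) for the upper-LoA interval."""
    df, delta = n - 1, z * np.sqrt(n)
    if tails == "equal":
        k_lo = stats.nct.ppf((1 - level) / 2, df, delta)
        k_hi = stats.nct.ppf((1 + level) / 2, df, delta)
        return float(k_lo), float(k_hi)
    if tails != "symmetric":
        raise ValueError(f"unknown tails {tails!r}")

    def coverage(h):
        return (stats.nct.cdf((z + h) * np.sqrt(n), df, delta)
                - stats.nct.cdf((z - h) * np.sqrt(n), df, delta)) - level

    # bracket: h=0 gives coverage −level < 0; expand upper bound as needed
    hi = 1.0
    while coverage(hi) < 0 and hi < 1e3:
        hi *= 2
    h = optimize.brentq(coverage, 1e-12, hi, xtol=1e-10)
    return float((z - h) * np.sqrt(n)), float((z + h) * np.sqrt(n))


def exact_loa_confidence_limits(summary: DiffSummary, level: float = 0.95,
                                z: float = 1.96, tails: str = "symmetric",
                                ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Exact confidence limits for the lower and upper limits of agreement.

    Returns ``(lower_loa_ci, upper_loa_ci)``, each an interval with exact
    ``level`` coverage for the corresponding LoA under normality, built from
    noncentral-t quantiles (see module docstring).  With ``sd_diff == 0``
    both intervals collapse to the mean.
    """
    m, s, n = summary.mean_diff, summary.sd_diff, summary.n
    try:
        k_lo, k_hi = _nct_k_factors(n, level, z, tails)
    except Exception as exc:  # pragma: no cover - scipy failure surface
        raise ArithmeticError(
            f"noncentral-t evaluation failed for n={n}, level={level}: {exc}"
        ) from exc
    rt = np.sqrt(n)
    upper_ci = (m + k_lo * s / rt, m + k_hi * s / rt)
    lower_ci = (m - k_hi * s / rt, m - k_lo * s / rt)
    return lower_ci, upper_ci


def bland_altman(pairs_or_summary, level: float = 0.95, z: float = 1.96,
                 tails: str = "symmetric") -> BlandAltmanResult:
    """Full Bland–Altman result from paired data or a difference summary."""
    if isinstance(pairs_or_summary, DiffSummary):
        summary = pairs_or_summary
    else:
        summary = summarize_differences(pairs_or_summary)
    lo, hi = limits_of_agreement(summary, z=z)
    lower_ci, upper_ci = exact_loa_confidence_limits(summary, level=level, z=z, tails=tails)
    return BlandAltmanResult(
        summary=summary, loa_lower=lo, loa_upper=hi,
        bias_ci=bias_confidence_interval(summary, level=level),
        loa_lower_ci=lower_ci, loa_upper_ci=upper_ci,
    )


def dice(a: BinaryMask, b: BinaryMask) -> DiceResult:
    """Sørensen–Dice coefficient 2|A∩B| / (|A| + |B|).

    Two empty masks agree perfectly on absence: value 1, flagged.
    """
    if a.grid != b.grid:
        raise GridMismatchError("masks are on different grids")
    na, nb = a.count, b.count
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    if na + nb == 0:
        return DiceResult(1.0, 0, 0, 0, both_empty=True)
    return DiceResult(2.0 * inter / (na + nb), inter, na, nb)


def paired_t_test(pairs: PairedMeasurements) -> tuple[float, float]:
    """Two-sided paired t-test on a − b; returns (statistic, p)."""
    d = pairs.differences
    if np.allclose(np.std(d), 0.0):
        if np.allclose(np.mean(d), 0.0):
            return 0.0, 1.0
        # zero variance, nonzero mean: evidence is off the t scale
        return float(np.inf) * np.sign(np.mean(d)), float(np.finfo(float).tiny)
    t, p = stats.ttest_rel(pairs.method_a, pairs.method_b)
    return float(t), float(p)


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch two-sample t-test (used to compare Dice populations)."""
    t, p = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(t), float(p)


def percent_volume_deviation(pairs: PairedMeasurements) -> float:
    """Mean percent deviation: 100·|a − b| / ((a + b)/2), averaged over subjects."""
    a, b = pairs.method_a, pairs.method_b
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("percent deviation requires strictly positive volumes")
    return float(np.mean(200.0 * np.abs(a - b) / (a + b)))


# ---------------------------------------------------------------------------
# report assembly


def _stats_table(rows: dict[tuple[str, str], UptakeStats]) -> pd.DataFrame:
    recs = [{"case_id": cid, "side": side, **st.as_dict()}
            for (cid, side), st in rows.items()]
    return pd.DataFrame(recs)


def agreement_report(stats_a: pd.DataFrame, stats_b: pd.DataFrame,
                     level: float = 0.95, z: float = 1.96) -> pd.DataFrame:
    """Per-quantity, per-side agreement summary between two methods.

    Both inputs are long tables with columns
    ``case_id, side, vol_ml, suv_mean, suv_max, suv_total``.  Rows are
    matched on (case_id, side); a mismatch raises with the offending ids.
    """
    key = ["case_id", "side"]
    a = stats_a.set_index(key).sort_index()
    b = stats_b.set_index(key).sort_index()
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise KeyError(
            f"case/side mismatch between methods: only in A {list(only_a)}, "
            f"only in B {list(only_b)}"
        )
    quantities = [q for q in QUANTITIES if q in a.columns and q in b.columns]
    rows = []
    for side in sorted(a.index.get_level_values("side").unique()):
        asel = a.xs(side, level="side")
        bsel = b.xs(side, level="side")
        for q in quantities:
            pairs = PairedMeasurements(list(asel.index), asel[q].to_numpy(),
                                       bsel[q].to_numpy(), quantity=q, side=side)
            res = bland_altman(pairs, level=level, z=z)
            t, p = paired_t_test(pairs)
            rows.append({
                "side": side, "quantity": q, "n": res.summary.n,
                "mean_a": float(np.mean(pairs.method_a)),
                "sd_a": float(np.std(pairs.method_a, ddof=1)),
                "mean_b": float(np.mean(pairs.method_b)),
                "sd_b": float(np.std(pairs.method_b, ddof=1)),
                "bias": res.summary.mean_diff, "sd_diff": res.summary.sd_diff,
                "bias_ci_lo": res.bias_ci[0], "bias_ci_hi": res.bias_ci[1],
                "loa_lower": res.loa_lower, "loa_upper": res.loa_upper,
                "loa_lower_ci_lo": res.loa_lower_ci[0],
                "loa_lower_ci_hi": res.loa_lower_ci[1],
                "loa_upper_ci_lo": res.loa_upper_ci[0],
                "loa_upper_ci_hi": res.loa_upper_ci[1],
                "t": t, "p": p,
            })
    return pd.DataFrame(rows)
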