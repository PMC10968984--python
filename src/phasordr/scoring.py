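"""Percentage-of-drug-response (%DR) statistic and NR/Resp classification.

A treated sample "responds" when its fractional NAD(P)H distribution shifts
toward the bound (oxidative, less proliferative) side relative to control.
The %DR statistic is computed from the control and treated mean curves in
two stages:

1.  Global gate: one-sided Welch t-test on the per-FOV mean bound fractions,
    alternative "treated > control".  If the gate is not significant at
    alpha, %DR = 0 — this keeps the expected per-bin false-positive area out
    of null comparisons.
2.  Per-bin comparison: two-sided Welch t-tests across FOVs on the curve
    densities (computable from the per-bin mean/sd/n summaries).  The
    significant region is the set of bins where the treated mean density
    exceeds the control's and p < alpha; %DR is 100 x the area of the
    treated curve inside that region (the "green area under the treated
    curve").

Samples are classified non-responder (NR) when %DR < 5 and responder (Resp)
when %DR >= 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fractions import MeanCurve

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_DR_THRESHOLD = 5.0


@dataclass
class DRResult:
    """%DR value, per-bin significance and NR/Resp label for one comparison."""

    percent_dr: float
    label: str
    alpha: float
    threshold: float
    per_bin_p: np.ndarray
    significant_bins: np.ndarray
    shift_direction_p: float

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DRResult):
            return NotImplemented
        return (self.percent_dr == other.percent_dr
                and self.label == other.label
                and self.alpha == other.alpha
                and self.threshold == other.threshold
                and self.shift_direction_p == other.shift_direction_p
                and np.array_equal(self.per_bin_p, other.per_bin_p)
                and np.array_equal(self.significant_bins,
                                   other.significant_bins))


def classify(percent_dr: float,
             threshold: float = DEFAULT_DR_THRESHOLD) -> str:
    """NR/Resp label: responder iff %DR >= threshold (default 5)."""
    if percent_dr < 0:
        raise ValueError("percent_dr must be >= 0")
    return "Resp" if percent_dr >= threshold else "NR"


def _welch_one_sided_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Welch p-value for mean(x) > mean(y), degenerate-safe."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 and y.std() == 0:
        return 0.0 if x.mean() > y.mean() else 1.0
    res = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
    return float(res.pvalue)


def _welch_per_bin(curve_a: MeanCurve, curve_b: MeanCurve) -> np.ndarray:
    """Two-sided Welch p-values per bin from the curve summaries."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind_from_stats(
            mean1=curve_a.mean_density, std1=curve_a.sd_density,
            nobs1=curve_a.n_fov,
            mean2=curve_b.mean_density, std2=curve_b.sd_density,
            nobs2=curve_b.n_fov,
            equal_var=False)
        p = np.asarray(res.pvalue, float)
    # bins with zero variance in both arms: identical means are not a
    # difference (p = 1); distinct means with no spread are (p = 0)
    degenerate = ~np.isfinite(p)
    equal = np.isclose(curve_a.mean_density, curve_b.mean_density)
    p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    return p


def percent_dr(control: MeanCurve, treated: MeanCurve,
               alpha: float = DEFAULT_ALPHA,
               threshold: float = DEFAULT_DR_THRESHOLD) -> DRResult:
    """Compute the %DR statistic from control vs treated mean curves."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not np.array_equal(control.bin_edges, treated.bin_edges):
        raise ValueError("control and treated curves have mismatched bins")
    if control.n_fov < 2 or treated.n_fov < 2:
        raise ValueError("need n_fov >= 2 in each arm")
    if control.fov_means is None or treated.fov_means is None:
        raise ValueError(
            "per-FOV mean bound fractions are required for the response gate")

    gate_p = _welch_one_sided_greater(treated.fov_means, control.fov_means)
    per_bin_p = _welch_per_bin(treated, control)
    shifted = treated.mean_density > control.mean_density
    significant = shifted & (per_bin_p < alpha)

    if gate_p >= alpha:
        pdr = 0.0
    else:
        widths = np.diff(treated.bin_edges)
        area = float(np.sum(treated.mean_density[significant]
                            * widths[significant]))
        pdr = float(np.clip(100.0 * area, 0.0, 100.0))

    return DRResult(percent_dr=pdr, label=classify(pdr, threshold),
                    alpha=alpha, threshold=threshold,
                    per_bin_p=per_bin_p, significant_bins=significant,
                    shift_direction_p=gate_p)
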