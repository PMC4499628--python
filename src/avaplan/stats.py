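"""Method-comparison statistics for validating planimetry measurements.

Two instruments measuring the same valve never agree exactly; the question is
whether they agree well enough to interchange.  This module implements the
standard toolkit used to answer it:

* relative difference between paired measurements,
  ``|a - b| * 100 / mean(a, b)`` (%), for intra-/interobserver variability;
* Bland–Altman analysis: per-pair differences, their mean (bias), SD, and the
  95% limits of agreement ``mean ± 1.96 SD``, plus a two-sided one-sample
  t test of zero bias.  The confidence interval of the *mean* difference is
  reported separately — limits of agreement describe where individual
  differences fall, not how precisely the bias is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import InputError

__all__ = [
    "AgreementResult",
    "VariabilityResult",
    "relative_difference",
    "bland_altman",
    "observer_variability",
    "bland_altman_plot",
]

LOA_FACTOR = 1.96  # normal 95% central range


@dataclass
class AgreementResult:
    """Bland–Altman agreement between two paired measurement series (cm²)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean_low: float   # 95% CI of the mean difference (t-based)
    ci_mean_high: float
    bias_p: float
    n: int
    means: np.ndarray    # per-pair means, for plotting
    diffs: np.ndarray    # per-pair differences (x - y)


@dataclass
class VariabilityResult:
    """Observer variability as per-pair relative differences (%)."""

    per_pair_relative_diff: np.ndarray
    mean_rd: float
    sd_rd: float
    n_excluded: int = 0


def relative_difference(a: float, b: float) -> float:
    """Absolute difference as a percentage of the pair mean.

    Symmetric in its arguments and invariant to rescaling both measurements;
    undefined when the pair mean is zero.
    """
    mean = (a + b) / 2.0
    if mean == 0:
        raise InputError("relative difference undefined for a zero pair mean")
    return abs(a - b) * 100.0 / mean


def bland_altman(x, y) -> AgreementResult:
    """Bland–Altman agreement analysis of paired series ``x`` and ``y``.

    Differences are ``x - y``; SD uses the n-1 denominator; limits of
    agreement are mean ± 1.96 SD.  ``bias_p`` is the two-sided one-sample
    t test of zero mean difference; with zero-variance differences the test
    is degenerate and p is reported as 1.0 for zero bias and 0.0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise InputError("need at least 3 pairs")
    diffs = x - y
    means = (x + y) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    if sd_diff == 0.0:
        bias_p = 1.0 if mean_diff == 0.0 else 0.0
        ci_half = 0.0
    else:
        bias_p = float(sstats.ttest_1samp(diffs, 0.0).pvalue)
        ci_half = float(sstats.t.ppf(0.975, n - 1) * sd_diff / np.sqrt(n))
    return AgreementResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - LOA_FACTOR * sd_diff,
        loa_high=mean_diff + LOA_FACTOR * sd_diff,
        ci_mean_low=mean_diff - ci_half,
        ci_mean_high=mean_diff + ci_half,
        bias_p=bias_p,
        n=n,
        means=means,
        diffs=diffs,
    )


def observer_variability(m1, m2) -> VariabilityResult:
    """Per-pair relative differences with mean ± SD summary.

    Pairs whose mean is zero have no defined relative difference; they are
    excluded with a warning and counted in ``n_excluded``.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise InputError("measurement series must be 1-D and equal length")
    rds = []
    n_excluded = 0
    for a, b in zip(m1, m2):
        try:
            rds.append(relative_difference(a, b))
        except InputError:
            n_excluded += 1
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} pair(s) with zero mean from variability",
            stacklevel=2,
        )
    rds = np.asarray(rds, dtype=float)
    if rds.size == 0:
        raise InputError("no valid pairs for variability computation")
    return VariabilityResult(
        per_pair_relative_diff=rds,
        mean_rd=float(rds.mean()),
        sd_rd=float(rds.std(ddof=1)) if rds.size > 1 else 0.0,
        n_excluded=n_excluded,
    )


def bland_altman_plot(result: AgreementResult, path=None, title: str | None = None):
    """Standard Bland–Altman scatter (pair means vs differences) with the bias
    and limits-of-agreement lines; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.0, 4.0))
    ax.scatter(result.means, result.diffs, s=18, color="#1f4e79", zorder=3)
    ax.axhline(result.mean_diff, color="k", lw=1.2, label=f"bias {result.mean_diff:.2f}")
    for loa in (result.loa_low, result.loa_high):
        ax.axhline(loa, color="gray", lw=1.0, ls="--")
    ax.set_xlabel("mean of methods (cm²)")
    ax.set_ylabel("difference (cm²)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
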