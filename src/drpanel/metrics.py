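"""Summary metrics for panel analyses: CV_G, bias, replicability, power.

CV_G — the coefficient of genetic variation in response — is the
among-strain SD of the diet effect divided by the absolute overall
effect.  It is unitless, so estimates on the mean-difference (days) and
log-hazard-ratio scales can be compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "cv_g",
    "power_estimate",
    "bias_summary",
    "replicability",
    "BiasSummary",
    "ReplicabilityResult",
    "StudyCell",
]


def cv_g(sigma: float, overall: float) -> float:
    """Coefficient of genetic variation in response: sigma / |overall|.

    ``overall = 0`` makes the ratio undefined; infinity is returned so
    the degenerate case is visible rather than silently dropped.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if overall == 0:
        return float("inf") if sigma > 0 else float("nan")
    return float(sigma / abs(overall))


def power_estimate(p_values, alpha: float = 0.05) -> float:
    """Fraction of p-values below ``alpha``; NaN entries are ignored."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    return float(np.mean(p < alpha))


@dataclass(frozen=True)
class BiasSummary:
    median: float
    iqr: float
    q1: float
    q3: float
    bias: float  # median minus the true value
    n: int


def bias_summary(estimates, true_value: float) -> BiasSummary:
    """Median and IQR of replicate estimates; bias = median - truth.

    Quartiles use linear interpolation (numpy's default, type 7), the
    convention the reported IQRs depend on.
    """
    est = np.asarray(estimates, dtype=float)
    est = est[~np.isnan(est)]
    if est.size == 0:
        raise ValueError("no estimates supplied")
    q1, med, q3 = np.percentile(est, [25, 50, 75])
    return BiasSummary(
        median=float(med),
        iqr=float(q3 - q1),
        q1=float(q1),
        q3=float(q3),
        bias=float(med - true_value),
        n=int(est.size),
    )


@dataclass(frozen=True)
class ReplicabilityResult:
    mean_correlation: float
    n_pairs: int      # pairs contributing a correlation
    n_dropped: int    # degenerate pairs (zero variance in either member)


def _pair_correlation(est_a, est_b) -> float:
    a = np.asarray(est_a, dtype=float)
    b = np.asarray(est_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def replicability(pairs) -> ReplicabilityResult:
    """Mean Pearson correlation of strain-level estimates across
    paired experiments on the same genotypes.

    ``pairs`` is an iterable of ``(fit_a, fit_b)`` where each member
    exposes a ``strain_effects`` table with ``strain`` and ``estimate``
    columns (any :class:`~drpanel.panels.PanelFit`).  Pairs in which
    either member has zero variance among estimates (e.g. complete
    shrinkage) leave the correlation undefined; they are dropped and
    counted rather than scored as zero.
    """
    cors = []
    dropped = 0
    total = 0
    for fit_a, fit_b in pairs:
        total += 1
        ta = fit_a.strain_effects.set_index("strain")["estimate"]
        tb = fit_b.strain_effects.set_index("strain")["estimate"]
        common = ta.index.intersection(tb.index)
        r = _pair_correlation(ta.loc[common].to_numpy(), tb.loc[common].to_numpy())
        if np.isnan(r):
            dropped += 1
        else:
            cors.append(r)
    if not cors:
        raise ValueError("no valid pairs: every pair was degenerate")
    return ReplicabilityResult(
        mean_correlation=float(np.mean(cors)), n_pairs=len(cors), n_dropped=dropped
    )


@dataclass
class StudyCell:
    """Replicated-simulation summary for one (n, CV_G, estimator) cell."""

    estimator: str
    n_per_arm: int
    true_cv_g: float
    cvg_median: float
    cvg_iqr: float
    cvg_bias: float
    replicability: float
    replicability_n_dropped: int
    power: float
    n_replicates: int
    n_converged: int

    def as_row(self) -> dict:
        return dict(self.__dict__)
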