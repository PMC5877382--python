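"""Between-system agreement statistics.

The validation compares per-stride gait parameters measured by the two
systems (inertial vs optical) over repeated strides from several
subjects:

* **Bland-Altman**: bias (mean difference), limits of agreement at
  bias +/- 1.96 SD of the differences, with confidence intervals that
  account for repeated strides per subject through one-way
  variance components (between-subject + within-subject), and the
  regression slope of difference on mean for trend inspection.
* **ICC**: intra-class correlation from a subject-grouped
  random-intercept model, ``t00 / (t00 + sigma2 / nj)`` with ``t00`` the
  intercept (between-subject) variance, ``sigma2`` the residual variance
  and ``nj`` the (mean) group size.
* **Residual statistics**: RMSE, mean residual and SD of residuals
  between two synchronized, aligned signals.

Both a per-stride and a trial-mean level are supported; averaging
within trials first shrinks the within-trial noise, so trial-mean limits
of agreement are systematically narrower.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signals import TimeSeries

Z95 = 1.96


@dataclass
class PairedMeasurements:
    """Per-stride paired values from the two systems, grouped by subject."""

    value_a: np.ndarray
    value_b: np.ndarray
    subject_id: np.ndarray
    trial_id: np.ndarray | None = None
    stride_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.value_a = np.asarray(self.value_a, dtype=float)
        self.value_b = np.asarray(self.value_b, dtype=float)
        n = len(self.value_a)
        if len(self.value_b) != n:
            raise ValueError("paired values must have equal length")
        self.subject_id = np.asarray(self.subject_id)
        if len(self.subject_id) != n:
            raise ValueError("subject_id must match the number of pairs")
        if self.trial_id is None:
            self.trial_id = np.zeros(n, dtype=int)
        else:
            self.trial_id = np.asarray(self.trial_id)
        if self.stride_index is None:
            self.stride_index = np.arange(n)
        keep = np.isfinite(self.value_a) & np.isfinite(self.value_b)
        if not keep.all():
            self.value_a = self.value_a[keep]
            self.value_b = self.value_b[keep]
            self.subject_id = self.subject_id[keep]
            self.trial_id = self.trial_id[keep]
            self.stride_index = np.asarray(self.stride_index)[keep]

    def __len__(self) -> int:
        return len(self.value_a)


@dataclass(frozen=True)
class BlandAltmanReport:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    regression_slope: float
    n: int
    level: str


@dataclass(frozen=True)
class IccReport:
    t00: float
    sigma2: float
    nj: float
    icc: float
    n_groups: int
    n_obs: int


def residual_stats(sig_a: TimeSeries, sig_b: TimeSeries) -> tuple[float, float, float]:
    """(RMSE, mean residual, SD of residuals) of ``a - b`` per sample."""
    if len(sig_a) != len(sig_b):
        raise ValueError("signals must be aligned and of equal length")
    valid = ~(sig_a.gap_mask | sig_b.gap_mask)
    if not valid.any():
        raise ValueError("no overlapping valid samples")
    r = np.asarray(sig_a.data, dtype=float)[valid] - np.asarray(sig_b.data, dtype=float)[valid]
    rmse = float(np.sqrt(np.mean(r ** 2)))
    return rmse, float(np.mean(r)), float(np.std(r, ddof=1))


def _variance_components(d: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """One-way ANOVA variance components of the differences.

    Returns (between-subject variance, within-subject variance, n0) where
    n0 is the effective group size for unbalanced data.
    """
    labels, inv = np.unique(groups, return_inverse=True)
    k = len(labels)
    n = len(d)
    counts = np.bincount(inv)
    means = np.bincount(inv, weights=d) / counts
    grand = d.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((d - means[inv]) ** 2))
    if k < 2 or n == k:
        return 0.0, ssw / max(n - k, 1) if n > k else float(np.var(d, ddof=1)), 1.0
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - np.sum(counts ** 2) / n) / (k - 1)
    s2b = max((msb - msw) / n0, 0.0)
    return s2b, msw, float(n0)


def bland_altman(pm: PairedMeasurements, level: str = "per_stride") -> BlandAltmanReport:
    """Bland-Altman agreement of the two systems.

    ``level='per_stride'`` uses every pair; ``level='trial_mean'``
    averages within (subject, trial) first.  The SD of a single
    difference combines the between- and within-subject variance
    components, so repeated strides per subject do not shrink the limits
    of agreement artificially; the LOA confidence intervals follow the
    delta method on the same components.
    """
    if level not in ("per_stride", "trial_mean"):
        raise ValueError("level must be 'per_stride' or 'trial_mean'")
    a, b = pm.value_a, pm.value_b
    subj = np.asarray(pm.subject_id)
    if level == "trial_mean":
        df = pd.DataFrame({"a": a, "b": b, "s": subj, "t": pm.trial_id})
        g = df.groupby(["s", "t"], sort=False).mean()
        a = g["a"].to_numpy()
        b = g["b"].to_numpy()
        subj = g.index.get_level_values(0).to_numpy()
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 pairs for a Bland-Altman analysis")
    d = a - b
    mean = (a + b) / 2.0
    bias = float(d.mean())
    n_subj = len(np.unique(subj))
    if n_subj < 2:
        warnings.warn("single subject: falling back to naive Bland-Altman CIs",
                      stacklevel=2)
        sd = float(np.std(d, ddof=1))
        se_bias = sd / math.sqrt(n)
        se_loa = sd * math.sqrt(3.0 / n)
    else:
        s2b, s2w, _ = _variance_components(d, subj)
        sd = math.sqrt(s2b + s2w)
        counts = np.bincount(np.unique(subj, return_inverse=True)[1])
        # variance of the bias under the random-intercept structure
        se_bias = math.sqrt(max(s2b / len(counts) + s2w / n, 1e-300))
        # delta-method SE of the LOAs: var(bias) + z^2 var(sd)
        var_sd = (s2b ** 2 / max(len(counts) - 1, 1)
                  + s2w ** 2 / max(n - len(counts), 1)) / (2.0 * max(sd, 1e-12) ** 2)
        se_loa = math.sqrt(se_bias ** 2 + Z95 ** 2 * var_sd)
    loa_lo = bias - Z95 * sd
    loa_hi = bias + Z95 * sd
    slope = float(np.polyfit(mean, d, 1)[0]) if np.ptp(mean) > 1e-12 else 0.0
    return BlandAltmanReport(
        bias=bias, sd_diff=sd, loa_lower=loa_lo, loa_upper=loa_hi,
        bias_ci=(bias - Z95 * se_bias, bias + Z95 * se_bias),
        loa_lower_ci=(loa_lo - Z95 * se_loa, loa_lo + Z95 * se_loa),
        loa_upper_ci=(loa_hi - Z95 * se_loa, loa_hi + Z95 * se_loa),
        regression_slope=slope, n=n, level=level,
    )


def icc_mixed(pm: PairedMeasurements, response: str = "difference") -> IccReport:
    """ICC from a subject-grouped random-intercept model (REML).

    ``response='difference'`` models the per-stride between-system
    differences; ``response='mean'`` the per-stride two-system means;
    ``response='stacked'`` both systems' values as repeated measurements
    per subject.  ``t00`` and ``sigma2`` are estimated by restricted maximum
    likelihood; the ICC is ``t00 / (t00 + sigma2 / nj)`` with ``nj`` the
    mean group size, clipped to [0, 1].
    """
    if response == "difference":
        y = pm.value_a - pm.value_b
        groups = np.asarray(pm.subject_id)
    elif response == "mean":
        y = (pm.value_a + pm.value_b) / 2.0
        groups = np.asarray(pm.subject_id)
    elif response == "stacked":
        # both systems' values as repeated measurements of the same subject:
        # high ICC = subjects separate cleanly relative to stride-to-stride
        # and system-to-system scatter
        y = np.concatenate([pm.value_a, pm.value_b])
        groups = np.concatenate([pm.subject_id, pm.subject_id])
    else:
        raise ValueError("response must be 'difference', 'mean' or 'stacked'")
    labels, inv = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("ICC needs at least 2 subjects")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("ICC needs at least 2 observations per subject")
    if np.var(y) < 1e-300:
        raise ValueError("zero total variance; ICC undefined")
    t00, sigma2 = _reml_variance_components(y, inv, counts)
    nj = float(counts.mean())
    icc = t00 / (t00 + sigma2 / nj) if (t00 + sigma2 / nj) > 0 else 0.0
    return IccReport(t00=t00, sigma2=sigma2, nj=nj,
                     icc=float(np.clip(icc, 0.0, 1.0)),
                     n_groups=len(labels), n_obs=len(y))


def _reml_loglik(sigma2: float, t00: float, counts: np.ndarray,
                 means: np.ndarray, ssw: float) -> float:
    """Restricted log-likelihood of the one-way random-intercept model
    (up to an additive constant), from group sufficient statistics."""
    lam = sigma2 + counts * t00  # variance of each group total's mean part
    w = counts / lam
    wsum = float(np.sum(w))
    mu = float(np.sum(w * means) / wsum)
    logdet_v = float(np.sum((counts - 1) * np.log(sigma2) + np.log(lam)))
    quad = ssw / sigma2 + float(np.sum(w * (means - mu) ** 2))
    return -0.5 * (logdet_v + math.log(wsum) + quad)


def _reml_variance_components(y: np.ndarray, inv: np.ndarray,
                              counts: np.ndarray) -> tuple[float, float]:
    """REML estimates of (t00, sigma2) for a one-way random-intercept model.

    The restricted likelihood reduces to group sufficient statistics
    (group means, within-group sum of squares), and is maximized
    numerically over (log sigma2, t00 >= 0).  For balanced data the
    maximizer coincides with the ANOVA estimator
    ``t00 = (MSB - MSW) / n_per_group`` whenever that is non-negative.
    """
    from scipy import optimize

    k = len(counts)
    n = len(y)
    means = np.bincount(inv, weights=y) / counts
    ssw = float(np.sum((y - means[inv]) ** 2))
    sigma2_0 = max(ssw / max(n - k, 1), 1e-12)
    grand = float(y.mean())
    msb = float(np.sum(counts * (means - grand) ** 2)) / (k - 1)
    n0 = (n - float(np.sum(counts.astype(float) ** 2)) / n) / (k - 1)
    t00_0 = max((msb - sigma2_0) / n0, 0.0)
    scale = sigma2_0 + t00_0

    def neg(params):
        log_s2, t00 = params
        return -_reml_loglik(math.exp(log_s2), max(t00, 0.0), counts, means, ssw)

    res = optimize.minimize(
        neg, x0=[math.log(sigma2_0), t00_0],
        bounds=[(math.log(sigma2_0) - 20.0, math.log(sigma2_0) + 20.0),
                (0.0, None)],
        method="L-BFGS-B",
        options={"ftol": 1e-15, "gtol": 1e-12 * scale, "maxiter": 500},
    )
    sigma2 = math.exp(float(res.x[0]))
    t00 = max(float(res.x[1]), 0.0)
    return t00, sigma2
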