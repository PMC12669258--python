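"""Estimation statistics for paired within-subject designs.

The analysis layer mirrors modern estimation-statistics practice: effect
sizes with bias-corrected and accelerated (BCa) bootstrap confidence
intervals, sign-flip permutation p-values, repeated-measures correlation for
within-subject trends, and exact noncentral-t power / sample-size planning.

Conventions
-----------
* Paired Cohen's d defaults to mean difference over the average of the two
  condition SDs (the estimation-statistics convention); ``variant="dz"``
  (mean over SD of differences) is available.
* Permutation p-values use the add-one correction ``(1 + hits) / (1 + B)``
  so p is never zero; when ``2**n <= n_perm`` the full sign-flip set is
  enumerated instead and p is exact (``hits / 2**n``, the identity flip
  guaranteeing p > 0).
* Power computations are exact via the noncentral t distribution,
  ``ncp = d * sqrt(n)``, df = n - 1, and default to one-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PairedSample",
    "EstimationResult",
    "paired_cohens_d",
    "bca_ci",
    "permutation_ttest",
    "estimate_paired",
    "rm_corr",
    "ttest_power",
    "required_n",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedSample:
    """Aligned condition values per subject; incomplete pairs dropped listwise."""

    subjects: np.ndarray
    condition1: np.ndarray
    condition2: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.subjects)
        x = np.asarray(self.condition1, float)
        y = np.asarray(self.condition2, float)
        if not (len(s) == len(x) == len(y)):
            raise ValueError("subjects and conditions must have equal length")
        keep = ~(np.isnan(x) | np.isnan(y))
        if not keep.all():
            logger.info("PairedSample: dropped %d incomplete pair(s)",
                        int((~keep).sum()))
        s, x, y = s[keep], x[keep], y[keep]
        if len(x) < 2:
            raise ValueError("need at least 2 complete pairs")
        object.__setattr__(self, "subjects", s)
        object.__setattr__(self, "condition1", x)
        object.__setattr__(self, "condition2", y)

    @classmethod
    def from_csv(cls, path, contrast: tuple[str, str],
                 subject_col="subject", condition_col="condition",
                 value_col="value") -> "PairedSample":
        """Build from a tidy table (subject, condition, value)."""
        df = pd.read_csv(path)
        a, b = contrast
        wide = df.pivot_table(index=subject_col, columns=condition_col,
                              values=value_col)
        return cls(wide.index.to_numpy(), wide[a].to_numpy(), wide[b].to_numpy())

    @property
    def n(self) -> int:
        return len(self.condition1)

    def differences(self) -> np.ndarray:
        return self.condition2 - self.condition1


def paired_cohens_d(sample: PairedSample, variant: str = "average") -> float:
    """Paired Cohen's d.

    ``variant="average"``: mean(diff) / sqrt((sd1^2 + sd2^2) / 2), sample
    SDs (ddof=1). ``variant="dz"``: mean(diff) / sd(diff).
    """
    d = sample.differences()
    if variant == "average":
        s = np.sqrt(
            (sample.condition1.var(ddof=1) + sample.condition2.var(ddof=1)) / 2.0
        )
    elif variant == "dz":
        s = d.std(ddof=1)
    else:
        raise ValueError("variant must be 'average' or 'dz'")
    if s == 0:
        return 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    return float(d.mean() / s)


# ----------------------------------------------------------------------
# BCa bootstrap
# ----------------------------------------------------------------------

def bca_ci(
    data: np.ndarray,
    statistic,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    ``data`` is resampled along its first axis (rows stay together, so a
    paired statistic can take an ``(n, 2)`` array). The bias constant z0
    comes from the bootstrap CDF at the observed statistic (ties counted at
    half weight), the acceleration from jackknife skewness. When every
    bootstrap value falls on one side of the estimate z0 is infinite and the
    plain percentile interval is returned (logged).
    """
    rng = np.random.default_rng(seed)
    data = np.asarray(data, float)
    n = data.shape[0]
    theta = float(statistic(data))
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.array([statistic(data[i]) for i in idx], dtype=float)
    alpha = (1.0 - level) / 2.0

    prop = ((boot < theta).sum() + 0.5 * (boot == theta).sum()) / n_boot
    if prop <= 0.0 or prop >= 1.0:
        logger.info("bca_ci: all bootstrap values on one side; "
                    "falling back to percentile interval")
        return (
            float(np.quantile(boot, alpha)),
            float(np.quantile(boot, 1.0 - alpha)),
        )
    z0 = stats.norm.ppf(prop)

    jack = np.array(
        [statistic(np.delete(data, i, axis=0)) for i in range(n)], dtype=float
    )
    dev = jack.mean() - jack
    denom = (dev**2).sum() ** 1.5
    a = (dev**3).sum() / (6.0 * denom) if denom > 0 else 0.0

    def adj(q: float) -> float:
        z = stats.norm.ppf(q)
        return float(stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z))))

    return (
        float(np.quantile(boot, adj(alpha))),
        float(np.quantile(boot, adj(1.0 - alpha))),
    )


# ----------------------------------------------------------------------
# permutation test
# ----------------------------------------------------------------------

def _dz_stat(diff: np.ndarray) -> np.ndarray:
    """Standardised mean of (possibly sign-flipped) differences, vectorised.

    ``diff`` may be (n,) or (B, n); zero-variance rows get statistic 0.
    """
    diff = np.atleast_2d(diff)
    m = diff.mean(axis=1)
    s = diff.std(axis=1, ddof=1)
    out = np.zeros_like(m)
    nz = s > 0
    out[nz] = m[nz] / s[nz]
    return out


def permutation_ttest(
    sample: PairedSample,
    n_perm: int = 5000,
    sides: str = "two",
    seed: int | np.random.Generator = 0,
) -> float:
    """Sign-flip permutation test on paired differences.

    The test statistic is the standardised paired effect (d_z); under the
    null of exchangeable condition labels each difference's sign is random.
    Exhaustive enumeration replaces Monte-Carlo sampling whenever
    ``2**n <= n_perm``.
    """
    if sides not in ("two", "greater", "less"):
        raise ValueError("sides must be 'two', 'greater' or 'less'")
    diff = sample.differences()
    n = diff.size
    observed = float(_dz_stat(diff)[0])
    exhaustive = 2**n <= n_perm
    if exhaustive:
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        signs = 1.0 - 2.0 * bits
        perm = _dz_stat(signs * diff)
        if sides == "two":
            hits = (np.abs(perm) >= abs(observed) - 1e-12).sum()
        elif sides == "greater":
            hits = (perm >= observed - 1e-12).sum()
        else:
            hits = (perm <= observed + 1e-12).sum()
        return float(hits / 2**n)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm = _dz_stat(signs * diff)
    if sides == "two":
        hits = (np.abs(perm) >= abs(observed) - 1e-12).sum()
    elif sides == "greater":
        hits = (perm >= observed - 1e-12).sum()
    else:
        hits = (perm <= observed + 1e-12).sum()
    return float((1 + hits) / (1 + n_perm))


@dataclass(frozen=True)
class EstimationResult:
    """Paired effect size with BCa CI and permutation p-value."""

    d: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    n_perm: int
    sides: str
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.d <= self.ci_high):
            raise ValueError("effect size must lie inside its CI")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must be in (0, 1]")


def estimate_paired(
    sample: PairedSample,
    variant: str = "average",
    n_boot: int = 5000,
    n_perm: int = 5000,
    sides: str = "two",
    level: float = 0.95,
    seed: int = 0,
) -> EstimationResult:
    """Full estimation-statistics readout for one paired contrast."""
    d = paired_cohens_d(sample, variant=variant)
    paired = np.column_stack([sample.condition1, sample.condition2])

    def stat(rows: np.ndarray) -> float:
        s = PairedSample(np.arange(rows.shape[0]), rows[:, 0], rows[:, 1])
        return paired_cohens_d(s, variant=variant)

    lo, hi = bca_ci(paired, stat, n_boot=n_boot, level=level, seed=seed)
    p = permutation_ttest(sample, n_perm=n_perm, sides=sides, seed=seed + 1)
    return EstimationResult(d=d, ci_low=min(lo, d), ci_high=max(hi, d), p=p,
                            n_boot=n_boot, n_perm=n_perm, sides=sides, seed=seed)


# ----------------------------------------------------------------------
# repeated-measures correlation
# ----------------------------------------------------------------------

def rm_corr(subjects, x, y) -> tuple[float, float, int]:
    """Common within-subject correlation (ANCOVA with subject factor).

    Centres x and y within each subject, fits the common slope, and returns
    ``(r, p, df)`` with ``df = N_obs - n_subjects - 1``; p is two-sided from
    the t distribution on that df.
    """
    subjects = np.asarray(subjects)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not (len(subjects) == len(x) == len(y)):
        raise ValueError("inputs must have equal length")
    xc = x.copy()
    yc = y.copy()
    for s in np.unique(subjects):
        m = subjects == s
        xc[m] -= x[m].mean()
        yc[m] -= y[m].mean()
    df = len(x) - len(np.unique(subjects)) - 1
    if df < 1:
        raise ValueError("not enough observations for rm_corr")
    sxx = (xc**2).sum()
    if sxx == 0 or (yc**2).sum() == 0:
        raise ValueError("no within-subject variance")
    slope = (xc * yc).sum() / sxx
    ss_err = ((yc - slope * xc) ** 2).sum()
    ss_measure = (yc**2).sum() - ss_err
    r = float(np.sign(slope) * np.sqrt(ss_measure / (ss_measure + ss_err)))
    if abs(r) >= 1.0:
        return r, 0.0, df
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, df


# ----------------------------------------------------------------------
# power / sample size
# ----------------------------------------------------------------------

def ttest_power(
    d: float, n: float, alpha: float = 0.05, sides: str = "one"
) -> float:
    """Exact power of a one-sample / paired t-test via the noncentral t.

    ``ncp = d * sqrt(n)``, ``df = n - 1``; one-sided tests reject when
    T > t_{1-alpha, df}. Real-valued ``n`` is accepted (used by the
    continuous sample-size solve).
    """
    if n <= 1:
        raise ValueError("need n > 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 1.0
    ncp = d * np.sqrt(n)
    if sides == "one":
        crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    if sides == "two":
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
    raise ValueError("sides must be 'one' or 'two'")


def required_n(
    d: float,
    power: float = 0.80,
    alpha: float = 0.05,
    sides: str = "one",
    rounding: str = "nearest",
) -> int:
    """Sample size for a target power.

    Solves the continuous root of ``ttest_power(d, n) = power`` (the value
    power software reports) and rounds it to an integer.
    ``rounding="nearest"`` matches the common reporting convention;
    ``rounding="ceil"`` guarantees the integer n itself attains the target
    power.
    """
    if d == 0:
        raise ValueError("zero effect size never reaches the target power")
    if rounding not in ("nearest", "ceil"):
        raise ValueError("rounding must be 'nearest' or 'ceil'")
    d = abs(d)
    lo, hi = 2.0, 4.0
    if ttest_power(d, lo, alpha, sides) >= power:
        return 2  # minimum size with a defined df
    while ttest_power(d, hi, alpha, sides) < power:
        hi *= 2.0
        if hi > 1e7:
            raise ValueError("required n exceeds 1e7")
    n_cont = optimize.brentq(
        lambda n: ttest_power(d, n, alpha, sides) - power, lo, hi, xtol=1e-8
    )
    n_int = int(round(n_cont)) if rounding == "nearest" else int(np.ceil(n_cont - 1e-9))
    return max(n_int, 2)
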