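"""Agreement statistics: ICC, interpretation bands, Fisher-z ICC comparison.

The intraclass correlation coefficient is computed from scratch from the
two-way ANOVA mean squares of the subjects × methods table (single-rater
forms).  Three models are available:

* ``oneway``             — ICC(1):   (MSR − MSW) / (MSR + (k−1)·MSW)
* ``twoway-consistency`` — ICC(C,1): (MSR − MSE) / (MSR + (k−1)·MSE)
* ``twoway-agreement``   — ICC(A,1): (MSR − MSE) /
                            (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

The default is absolute agreement, appropriate when the measured quantity
itself (IPH volume in mm³) must match across methods, not merely correlate.

Confidence intervals default to the Fisher-z construction
z(ICC) ± z_{α/2} / √(n−3); exact F-based (Shrout–Fleiss / McGraw–Wong)
intervals are available via ``ci_method='f'``.  Two ICCs from independent
cohorts are compared by the normal test on the difference of Fisher-z
transforms with SE √(1/(n_a−3) + 1/(n_b−3)); a subject-resampling bootstrap
is provided for the dependent case (shared cohort), as an extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements", "ICCEstimate", "ICCComparison",
    "icc", "interpret_icc", "fisher_z", "fisher_z_inverse",
    "compare_icc", "compare_icc_bootstrap", "bonferroni",
]

_MODELS = ("oneway", "twoway-consistency", "twoway-agreement")

_BANDS = (  # upper edge (inclusive), label — the six-band interpretation scale
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


@dataclass
class PairedMeasurements:
    """Per-subject measurements of the same quantity by two methods."""
    subjects: list
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if not (len(self.subjects) == len(self.values_a) == len(self.values_b)):
            raise ValueError("subjects, values_a and values_b must have equal length")
        if not (np.all(np.isfinite(self.values_a)) and np.all(np.isfinite(self.values_b))):
            raise ValueError("measurements must be finite")

    @property
    def n(self) -> int:
        return len(self.subjects)

    def table(self) -> np.ndarray:
        return np.column_stack([self.values_a, self.values_b])


@dataclass
class ICCEstimate:
    value: float
    ci_low: float
    ci_high: float
    n: int
    model: str
    band: str
    k: int = 2


@dataclass
class ICCComparison:
    statistic: float
    p_raw: float
    p_adjusted: float
    alternative: str
    m: int


def _anova_mean_squares(table: np.ndarray):
    """Mean squares of the subjects × methods two-way layout (no replication)."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_total = float(((table - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = ss_within / (n * (k - 1))
    return msr, msc, mse, msw, ss_total


def _point_estimate(table: np.ndarray, model: str) -> float:
    n, k = table.shape
    msr, msc, mse, msw, ss_total = _anova_mean_squares(table)
    if ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    if model == "oneway":
        denom = msr + (k - 1) * msw
        return (msr - msw) / denom if denom > 0 else 1.0
    if model == "twoway-consistency":
        denom = msr + (k - 1) * mse
        return (msr - mse) / denom if denom > 0 else 1.0
    if model == "twoway-agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        return (msr - mse) / denom if denom > 0 else 1.0
    raise ValueError(f"unknown ICC model {model!r} (expected one of {_MODELS})")


def _ci_fisher(value: float, n: int, alpha: float):
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    v = np.clip(value, -1 + 1e-12, 1 - 1e-12)
    z = fisher_z(v)
    return fisher_z_inverse(z - zc * se), fisher_z_inverse(z + zc * se)


def _ci_f(table: np.ndarray, model: str, alpha: float):
    """Exact/approximate F-based intervals (Shrout–Fleiss; McGraw–Wong for
    absolute agreement, with Satterthwaite degrees of freedom)."""
    n, k = table.shape
    msr, msc, mse, msw, _ = _anova_mean_squares(table)
    if model == "oneway":
        f = msr / msw
        df1, df2 = n - 1, n * (k - 1)
        fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
        return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)
    if model == "twoway-consistency":
        f = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
        return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)
    # twoway-agreement
    icc_a = _point_estimate(table, model)
    a = (k * icc_a) / (n * (1 - icc_a)) if icc_a < 1 else np.inf
    b = 1 + (k * icc_a * (n - 1)) / (n * (1 - icc_a)) if icc_a < 1 else np.inf
    if not np.isfinite(a):
        return 1.0, 1.0
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f_star_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_star_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = (n * (msr - f_star_u * mse)) / (
        f_star_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = (n * (f_star_l * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_star_l * msr)
    return lo, hi


def icc(pairs: PairedMeasurements, model: str = "twoway-agreement", *,
        alpha: float = 0.05, ci_method: str = "fisher",
        min_n: int = 3, min_n_ci: int = 5) -> ICCEstimate:
    """Single-rater ICC of two paired methods, with a 95% CI.

    Raises on fewer than ``min_n`` subjects, on zero total variance, and —
    when a CI is requested — on fewer than ``min_n_ci`` subjects.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown ICC model {model!r} (expected one of {_MODELS})")
    n = pairs.n
    if n < min_n:
        raise ValueError(f"need at least {min_n} subjects for ICC, got {n}")
    if n < min_n_ci:
        raise ValueError(f"need at least {min_n_ci} subjects for a CI, got {n}")
    table = pairs.table()
    # rounding in the sums of squares can push a perfect ICC past 1 by ~1e-15
    value = float(np.clip(_point_estimate(table, model), -1.0, 1.0))
    if ci_method == "fisher":
        lo, hi = _ci_fisher(value, n, alpha)
    elif ci_method == "f":
        lo, hi = _ci_f(table, model, alpha)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo = float(min(lo, value))
    hi = float(max(hi, value))
    return ICCEstimate(value=value, ci_low=lo, ci_high=hi, n=n, model=model,
                       band=interpret_icc(value), k=2)


def interpret_icc(value: float) -> str:
    """Map an ICC to the six-band verbal scale.

    poor (0 and below), slight (0.01–0.20), fair (0.21–0.40), moderate
    (0.41–0.60), substantial (0.61–0.80), almost perfect (0.81–1.00).
    Boundary values belong to the band whose printed interval contains them
    (0.20 → slight, 0.81 → almost perfect); negative values are reported as
    poor.
    """
    if abs(value) > 1 + 1e-9:
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    value = float(np.clip(value, -1.0, 1.0))
    for upper, label in _BANDS:
        if value <= upper:
            return label
    return "almost perfect"


def fisher_z(rho: float) -> float:
    """Fisher's variance-stabilising transform z = ½·ln((1+ρ)/(1−ρ))."""
    rho = float(rho)
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    return float(np.arctanh(rho))


def fisher_z_inverse(z: float) -> float:
    return float(np.tanh(z))


def compare_icc(est_a: ICCEstimate, est_b: ICCEstimate,
                alternative: str = "greater", *, m: int = 1) -> ICCComparison:
    """Normal test on the difference of Fisher-z-transformed ICCs.

    Assumes the two estimates come from independent cohorts; the SE is
    √(1/(n_a−3) + 1/(n_b−3)).  ``alternative='greater'`` tests H_A: ρ_a > ρ_b
    against H_0: ρ_a = ρ_b.  ``m`` is the Bonferroni multiplier applied to
    ``p_adjusted``.
    """
    if est_a.model != est_b.model:
        raise ValueError("cannot compare ICCs from different models")
    for est in (est_a, est_b):
        if est.n <= 3:
            raise ValueError("comparison requires n > 3 in each arm")
    za = fisher_z(np.clip(est_a.value, -1 + 1e-12, 1 - 1e-12))
    zb = fisher_z(np.clip(est_b.value, -1 + 1e-12, 1 - 1e-12))
    se = np.sqrt(1.0 / (est_a.n - 3) + 1.0 / (est_b.n - 3))
    z = (za - zb) / se
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return ICCComparison(statistic=float(z), p_raw=p,
                         p_adjusted=float(min(1.0, m * p)),
                         alternative=alternative, m=m)


def compare_icc_bootstrap(pairs_a: PairedMeasurements, pairs_b: PairedMeasurements,
                          model: str = "twoway-agreement",
                          alternative: str = "greater", *, n_boot: int = 2000,
                          seed: int = 0, m: int = 1) -> ICCComparison:
    """Subject-resampling bootstrap comparison of two ICCs (extension).

    Unlike :func:`compare_icc` this does not assume independent cohorts: each
    bootstrap replicate resamples subjects within each table and recomputes
    the ICC difference; the p-value is the bootstrap tail probability of the
    difference falling at or below zero (for ``alternative='greater'``).
    Intended for the shared-cohort design where the same subjects appear in
    both comparisons.
    """
    rng = np.random.default_rng(seed)
    ta, tb = pairs_a.table(), pairs_b.table()
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        ia = rng.integers(0, len(ta), len(ta))
        ib = rng.integers(0, len(tb), len(tb))
        try:
            diffs[i] = (_point_estimate(ta[ia], model)
                        - _point_estimate(tb[ib], model))
        except ValueError:
            diffs[i] = np.nan
    diffs = diffs[np.isfinite(diffs)]
    if alternative == "greater":
        p = float((np.sum(diffs <= 0) + 1) / (len(diffs) + 1))
    elif alternative == "two-sided":
        p_low = float((np.sum(diffs <= 0) + 1) / (len(diffs) + 1))
        p = float(min(1.0, 2 * min(p_low, 1 - p_low)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    observed = (_point_estimate(ta, model) - _point_estimate(tb, model))
    return ICCComparison(statistic=float(observed), p_raw=p,
                         p_adjusted=float(min(1.0, m * p)),
                         alternative=alternative, m=m)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p becomes min(1, m·p)."""
    p_values = [float(p) for p in p_values]
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
    if m is None:
        m = len(p_values)
    return [min(1.0, m * p) for p in p_values]
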