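"""Per-SNP Wald estimation, IVW pooling, MR-Egger and weighted-median
estimators for two-sample Mendelian randomization.

The estimators are written in the scikit-learn idiom: each is a
``BaseEstimator``/``RegressorMixin`` fitted on the SNP-exposure effects
``X = bx`` (shape ``(n, 1)`` or ``(n,)``) and SNP-outcome effects ``y = by``,
with the per-SNP standard errors passed as the fit keywords ``x_se`` and
``y_se``. Fitted attributes carry a trailing underscore (``effect_``,
``se_``, ``ci_``, ...). Thin module-level functions (:func:`wald_ratio`,
:func:`ivw_fixed`, :func:`egger_fit`, ...) wrap the classes for a
table-in/table-out workflow.

Model
-----
For instrument *i* with true SNP-exposure effect γ_i and SNP-outcome effect
Γ_i, a causal effect β of the exposure implies Γ_i = β·γ_i for a valid
instrument (Γ_i = β·γ_i + α_i when the instrument has a direct, pleiotropic
effect α_i on the outcome). The per-SNP Wald ratio β̂_i = by_i / bx_i
estimates β; the fixed-effect inverse-variance weighted (IVW) mean pools the
ratios; MR-Egger adds a free intercept that absorbs (and tests) directional
pleiotropy; the weighted median tolerates up to half of the weight coming
from invalid instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .summary_io import InstrumentSet

__all__ = [
    "IVWEstimator",
    "EggerEstimator",
    "WeightedMedianEstimator",
    "PooledResult",
    "HeterogeneityResult",
    "wald_ratio",
    "wald_ratio_table",
    "ivw_fixed",
    "cochran_q",
    "i2_from_q",
    "heterogeneity",
    "units_to_days",
    "weighted_median_value",
]

#: exact two-sided 95% normal multiplier (not 1.96 rounded)
Z_95 = float(stats.norm.ppf(0.975))

#: I² threshold (percent) above which between-instrument heterogeneity is
#: declared present and read as a proxy for pleiotropy
I2_HETEROGENEITY_THRESHOLD = 25.0


# ---------------------------------------------------------------------------
# results containers


@dataclass
class HeterogeneityResult:
    """Cochran's Q and the derived I² heterogeneity index (percent)."""

    q_stat: float
    df: int
    i2_point: float
    i2_ci_low: float
    i2_ci_high: float

    @property
    def heterogeneity_flag(self) -> bool:
        return self.i2_point > I2_HETEROGENEITY_THRESHOLD


@dataclass
class PooledResult:
    """A pooled causal-effect estimate with optional heterogeneity block."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    heterogeneity: HeterogeneityResult | None = None
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = dict(
            method=self.method, beta=self.beta, se=self.se,
            ci_low=self.ci_low, ci_high=self.ci_high,
            pvalue=self.pvalue, n_snps=self.n_snps,
        )
        h = self.heterogeneity
        row.update(
            q_stat=h.q_stat if h else np.nan,
            q_df=h.df if h else np.nan,
            i2=h.i2_point if h else np.nan,
            i2_ci_low=h.i2_ci_low if h else np.nan,
            i2_ci_high=h.i2_ci_high if h else np.nan,
        )
        row.update(self.extra)
        return row


# ---------------------------------------------------------------------------
# closed-form cores


def wald_ratio(by, bx, sy, sx=None, se_order: str = "second"):
    """Per-SNP Wald ratio estimate and Delta-method standard error.

    ``beta_iv = by / bx``. The first-order Delta SE is ``sy / |bx|``;
    the second-order SE adds the exposure-uncertainty term:
    ``sqrt(sy^2/bx^2 + by^2 * sx^2 / bx^4)``.

    Accepts scalars or arrays; returns ``(beta_iv, se_iv)``.
    """
    by = np.asarray(by, dtype=float)
    bx = np.asarray(bx, dtype=float)
    sy = np.asarray(sy, dtype=float)
    if np.any(bx == 0):
        raise ValueError("Wald ratio undefined for bx = 0")
    beta = by / bx
    if se_order == "first":
        se = sy / np.abs(bx)
    elif se_order == "second":
        if sx is None:
            raise ValueError("second-order Delta SE requires sx")
        sx = np.asarray(sx, dtype=float)
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        raise ValueError("se_order must be 'first' or 'second'")
    if beta.ndim == 0:
        return float(beta), float(se)
    return beta, se


def cochran_q(beta: np.ndarray, se: np.ndarray, pooled_beta: float) -> tuple[float, int]:
    """Cochran's Q statistic and its degrees of freedom ``n - 1``.

    ``Q = sum w_i (beta_i - pooled)^2`` with ``w_i = 1/se_i^2``. Requires at
    least two estimates.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if beta.size < 2:
        raise ValueError("Cochran's Q requires at least 2 estimates")
    w = 1.0 / se**2
    q = float(np.sum(w * (beta - pooled_beta) ** 2))
    return q, beta.size - 1


def i2_from_q(q_stat: float, df: int, ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """I² point estimate (percent) and its test-based confidence interval.

    The point estimate is ``max(0, 100*(Q - df)/Q)`` (0 when Q = 0). The CI
    uses the Higgins–Thompson test-based method: a normal interval for
    ``ln H`` with ``H = sqrt(Q/df)`` and

    * ``se(ln H) = (ln Q - ln df) / (2*(sqrt(2Q) - sqrt(2df - 1)))`` if Q > df,
    * ``se(ln H) = sqrt( (1/(2(df-1))) * (1 - 1/(3(df-1)^2)) )`` otherwise,

    back-transformed through ``I² = 100*(H² - 1)/H²`` and truncated to
    [0, 100]. For ``df == 1`` with Q <= df the CI is undefined and NaN is
    returned.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if q_stat < 0:
        raise ValueError("Q must be >= 0")
    point = 0.0 if q_stat == 0 else max(0.0, 100.0 * (q_stat - df) / q_stat)

    z = float(stats.norm.ppf(0.5 + ci_level / 2))
    if q_stat > df:
        se_ln_h = (np.log(q_stat) - np.log(df)) / (
            2.0 * (np.sqrt(2.0 * q_stat) - np.sqrt(2.0 * df - 1.0))
        )
        ln_h = 0.5 * (np.log(q_stat) - np.log(df))
    elif df > 1:
        se_ln_h = np.sqrt((1.0 / (2.0 * (df - 1))) * (1.0 - 1.0 / (3.0 * (df - 1) ** 2)))
        ln_h = 0.0 if q_stat == 0 else 0.5 * (np.log(q_stat) - np.log(df))
    else:
        return point, (np.nan, np.nan)

    def _h_to_i2(h: float) -> float:
        if h <= 1.0:
            return 0.0
        return min(100.0, 100.0 * (h**2 - 1.0) / h**2)

    lo = _h_to_i2(float(np.exp(ln_h - z * se_ln_h)))
    hi = _h_to_i2(float(np.exp(ln_h + z * se_ln_h)))
    return point, (lo, hi)


def heterogeneity(
    beta: np.ndarray, se: np.ndarray, pooled_beta: float, ci_level: float = 0.95
) -> HeterogeneityResult:
    """Q + I² (with CI) for a set of per-SNP estimates around a pooled value."""
    q, df = cochran_q(beta, se, pooled_beta)
    point, (lo, hi) = i2_from_q(q, df, ci_level)
    return HeterogeneityResult(q_stat=q, df=df, i2_point=point,
                               i2_ci_low=lo, i2_ci_high=hi)


def weighted_median_value(values, weights) -> float:
    """Weighted median with linear interpolation in cumulative weight.

    Values are ordered; the cumulative normalized weight of each order
    statistic is taken at its midpoint (``cumsum(w) - w/2``) and the estimate
    is the linear interpolation of the ordered values at cumulative weight
    0.5. With equal weights this reduces to the ordinary interpolated median.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted median of empty set")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, v))


@dataclass
class EffectInYears:
    """An effect re-expressed from SD units to years and days of education."""

    years: float
    days: float

    @property
    def days_rounded(self) -> int:
        return int(round(self.days))


def units_to_days(beta_sd: float, sd_years: float = 3.6) -> EffectInYears:
    """Convert an effect in SD units of time in education to years and days.

    ``years = beta_sd * sd_years``; ``days = years * 365.25``. The default
    scale of 3.6 years per SD is the reported standard deviation of time
    spent in education in the outcome GWAS.
    """
    if sd_years <= 0:
        raise ValueError("sd_years must be > 0")
    years = beta_sd * sd_years
    return EffectInYears(years=years, days=years * 365.25)


def _normal_p(z) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# scikit-learn style estimators


class _BaseMREstimator(RegressorMixin, BaseEstimator):
    """Shared validation and prediction for summary-data MR estimators."""

    @staticmethod
    def _validate(X, y, x_se, y_se, need_x_se: bool):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be 1-d or a single-column 2-d array of bx")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-d or a single-column 2-d array of bx")
        y = np.asarray(y, dtype=float)
        if y.shape != X.shape:
            raise ValueError("X and y must have the same length")
        if y_se is None:
            raise ValueError("y_se (outcome standard errors) is required")
        y_se = np.broadcast_to(np.asarray(y_se, dtype=float), X.shape).copy()
        if np.any(y_se <= 0):
            raise ValueError("y_se must be > 0")
        if x_se is not None:
            x_se = np.broadcast_to(np.asarray(x_se, dtype=float), X.shape).copy()
            if np.any(x_se < 0):
                raise ValueError("x_se must be >= 0")
        elif need_x_se:
            raise ValueError("x_se (exposure standard errors) is required")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in X or y")
        return X, y, x_se, y_se

    def predict(self, X):
        """Predicted SNP-outcome effects ``intercept + effect * bx``."""
        check_is_fitted(self, "effect_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return getattr(self, "intercept_", 0.0) + self.effect_ * X


class IVWEstimator(_BaseMREstimator):
    """Fixed-effect inverse-variance weighted pooling of per-SNP Wald ratios.

    Parameters
    ----------
    se_order : {"second", "first"}, default "second"
        Delta-method order for the per-SNP ratio SE. ``"first"`` ignores the
        exposure uncertainty (``se = sy/|bx|``) and makes IVW identical to a
        zero-intercept WLS regression of ``by`` on ``bx`` with weights
        ``1/sy²``; ``"second"`` adds the ``by²·sx²/bx⁴`` term.
    ci_level : float, default 0.95
        Two-sided confidence level (normal quantiles).

    Attributes
    ----------
    effect_, se_, ci_, pvalue_ : pooled estimate block.
    n_snps_ : number of instruments used.
    ratio_estimates_ : DataFrame of per-SNP ``beta_iv, se_iv, weight``.
    heterogeneity_ : :class:`HeterogeneityResult` (``None`` for a single SNP).
    """

    def __init__(self, se_order: str = "second", ci_level: float = 0.95):
        self.se_order = se_order
        self.ci_level = ci_level

    def fit(self, X, y, *, x_se=None, y_se=None):
        bx, by, sx, sy = self._validate(
            X, y, x_se, y_se, need_x_se=(self.se_order == "second")
        )
        beta_iv, se_iv = wald_ratio(by, bx, sy, sx, se_order=self.se_order)
        beta_iv = np.atleast_1d(beta_iv)
        se_iv = np.atleast_1d(se_iv)
        w = 1.0 / se_iv**2
        beta = float(np.sum(w * beta_iv) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        z = float(stats.norm.ppf(0.5 + self.ci_level / 2))

        self.effect_ = beta
        self.se_ = se
        self.ci_ = (beta - z * se, beta + z * se)
        self.pvalue_ = _normal_p(beta / se)
        self.n_snps_ = int(beta_iv.size)
        self.ratio_estimates_ = pd.DataFrame(
            dict(beta_iv=beta_iv, se_iv=se_iv, weight=w)
        )
        self.heterogeneity_ = (
            heterogeneity(beta_iv, se_iv, beta, self.ci_level)
            if beta_iv.size >= 2 else None
        )
        return self


class EggerEstimator(_BaseMREstimator):
    """MR-Egger: weighted regression of ``by`` on ``bx`` with a free intercept.

    The slope is the causal estimate, robust to directional pleiotropy under
    the InSIDE assumption (pleiotropic effects independent of instrument
    strength); the intercept estimates the average directional pleiotropic
    effect and its test is the Egger pleiotropy test. The fit is
    orientation-dependent, so instruments are re-oriented to ``bx >= 0``
    (flipping ``by`` jointly) before fitting.

    Standard errors use a multiplicative residual-variance scale floored at 1
    (no under-dispersion credit); inference uses t(n-2) quantiles.

    Attributes
    ----------
    effect_, se_, ci_, pvalue_ : slope (causal estimate) block.
    intercept_, intercept_se_, intercept_ci_, intercept_pvalue_ : pleiotropy
        intercept block.
    i2_gx_ : heterogeneity (percent) of the SNP-exposure estimates when
        ``x_se`` is supplied — values near 100 indicate negligible
        regression-dilution bias; ``None`` otherwise.
    scale_ : residual variance scale after flooring.
    """

    def __init__(self, ci_level: float = 0.95):
        self.ci_level = ci_level

    def fit(self, X, y, *, x_se=None, y_se=None):
        bx, by, sx, sy = self._validate(X, y, x_se, y_se, need_x_se=False)
        n = bx.size
        if n < 3:
            raise ValueError("MR-Egger requires at least 3 instruments")
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx, by = bx * flip, by * flip
        if np.allclose(bx, bx[0]):
            raise ValueError("slope unidentifiable: all bx equal")

        import statsmodels.api as sm

        w = 1.0 / sy**2
        design = sm.add_constant(bx)
        res = sm.WLS(by, design, weights=w).fit()
        # multiplicative residual scale floored at 1: never shrink the
        # model-based SEs when the fit is under-dispersed
        scale = float(res.scale)
        inflation = np.sqrt(max(1.0, scale) / scale)
        bse = res.bse * inflation
        tq = float(stats.t.ppf(0.5 + self.ci_level / 2, df=n - 2))

        self.intercept_ = float(res.params[0])
        self.effect_ = float(res.params[1])
        self.intercept_se_ = float(bse[0])
        self.se_ = float(bse[1])
        self.intercept_ci_ = (
            self.intercept_ - tq * self.intercept_se_,
            self.intercept_ + tq * self.intercept_se_,
        )
        self.ci_ = (self.effect_ - tq * self.se_, self.effect_ + tq * self.se_)
        self.pvalue_ = float(
            2 * stats.t.sf(abs(self.effect_ / self.se_), df=n - 2)
        )
        self.intercept_pvalue_ = float(
            2 * stats.t.sf(abs(self.intercept_ / self.intercept_se_), df=n - 2)
        )
        self.scale_ = max(1.0, scale)
        self.n_snps_ = int(n)
        if sx is not None and n >= 2 and np.all(sx > 0):
            wx = 1.0 / sx**2
            bx_bar = np.sum(wx * bx) / np.sum(wx)
            q_gx = float(np.sum(wx * (bx - bx_bar) ** 2))
            self.i2_gx_ = 0.0 if q_gx == 0 else max(0.0, 100.0 * (q_gx - (n - 1)) / q_gx)
        else:
            self.i2_gx_ = None
        return self


class WeightedMedianEstimator(_BaseMREstimator):
    """Weighted median of per-SNP Wald ratios with a parametric bootstrap SE.

    The per-SNP ratio estimates are ordered and the 50% weighted percentile
    (weights = inverse ratio variances, linear interpolation in cumulative
    weight) is the causal estimate; it is consistent when at least half of
    the total weight comes from valid instruments. The SE is the standard
    deviation of the estimate over ``n_boot`` parametric resamples drawing
    ``bx* ~ N(bx, sx)`` and ``by* ~ N(by, sy)`` per SNP and recomputing the
    weighted median (weights included).

    Parameters
    ----------
    n_boot : int, default 10000
        Bootstrap iterations; a warning is emitted below 1000.
    random_state : int, default 0
        Bootstrap seed; always recorded in ``random_state_``.
    se_order : {"second", "first"}, default "second"
        Delta-method order for the per-SNP ratio weights.
    ci_method : {"normal", "percentile"}, default "normal"
        Normal-approximation CI (``estimate ± z·SE``) or bootstrap
        percentile CI.
    """

    def __init__(
        self,
        n_boot: int = 10000,
        random_state: int = 0,
        se_order: str = "second",
        ci_method: str = "normal",
        ci_level: float = 0.95,
    ):
        self.n_boot = n_boot
        self.random_state = random_state
        self.se_order = se_order
        self.ci_method = ci_method
        self.ci_level = ci_level

    def fit(self, X, y, *, x_se=None, y_se=None):
        bx, by, sx, sy = self._validate(
            X, y, x_se, y_se, need_x_se=(self.se_order == "second")
        )
        if bx.size < 3:
            raise ValueError("weighted median requires at least 3 instruments")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.n_boot < 1000:
            warnings.warn(
                f"n_boot={self.n_boot} < 1000: bootstrap SE will be noisy",
                UserWarning,
            )
        beta_iv, se_iv = wald_ratio(by, bx, sy, sx, se_order=self.se_order)
        w = 1.0 / np.asarray(se_iv) ** 2
        est = weighted_median_value(beta_iv, w)

        rng = np.random.default_rng(self.random_state)
        boots = self._bootstrap(bx, by, sx, sy, rng)
        se = float(np.std(boots, ddof=1))
        z = float(stats.norm.ppf(0.5 + self.ci_level / 2))
        if self.ci_method == "normal":
            ci = (est - z * se, est + z * se)
        elif self.ci_method == "percentile":
            alpha = 1 - self.ci_level
            ci = tuple(np.quantile(boots, [alpha / 2, 1 - alpha / 2]))
        else:
            raise ValueError("ci_method must be 'normal' or 'percentile'")

        self.effect_ = float(est)
        self.se_ = se
        self.ci_ = (float(ci[0]), float(ci[1]))
        self.pvalue_ = _normal_p(est / se) if se > 0 else (1.0 if est == 0 else 0.0)
        self.n_snps_ = int(bx.size)
        self.n_boot_ = int(self.n_boot)
        self.random_state_ = self.random_state
        self.bootstrap_estimates_ = boots
        return self

    def _bootstrap(self, bx, by, sx, sy, rng) -> np.ndarray:
        n = bx.size
        if sx is None:
            sx = np.zeros(n)
        out = np.empty(self.n_boot)
        chunk = max(1, int(2_000_000 // max(n, 1)))
        pos = 0
        while pos < self.n_boot:
            m = min(chunk, self.n_boot - pos)
            bxs = rng.normal(bx, sx, size=(m, n))
            bys = rng.normal(by, sy, size=(m, n))
            # guard exact zeros from degenerate draws
            bxs[bxs == 0] = np.finfo(float).tiny
            beta = bys / bxs
            if self.se_order == "first":
                se = sy / np.abs(bxs)
            else:
                se = np.sqrt(sy**2 / bxs**2 + bys**2 * sx**2 / bxs**4)
            wts = 1.0 / se**2
            for j in range(m):
                out[pos + j] = weighted_median_value(beta[j], wts[j])
            pos += m
        return out


# ---------------------------------------------------------------------------
# table-level wrappers


def _as_arrays(instruments: InstrumentSet | pd.DataFrame):
    if isinstance(instruments, InstrumentSet):
        return instruments.arrays()
    t = instruments
    return (
        t["bx"].to_numpy(float),
        t["sx"].to_numpy(float),
        t["by"].to_numpy(float),
        t["sy"].to_numpy(float),
    )


def wald_ratio_table(
    instruments: InstrumentSet | pd.DataFrame,
    se_order: str = "second",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-SNP Wald ratio estimates as a table.

    Columns: ``snp_id, beta_iv, se_iv, weight, ci_low, ci_high, pvalue``.
    """
    bx, sx, by, sy = _as_arrays(instruments)
    beta, se = wald_ratio(by, bx, sy, sx, se_order=se_order)
    beta = np.atleast_1d(beta)
    se = np.atleast_1d(se)
    z = float(stats.norm.ppf(0.5 + ci_level / 2))
    snp_id = (
        instruments.table["snp_id"].to_numpy()
        if isinstance(instruments, InstrumentSet)
        else instruments["snp_id"].to_numpy()
    )
    return pd.DataFrame(
        dict(
            snp_id=snp_id,
            beta_iv=beta,
            se_iv=se,
            weight=1.0 / se**2,
            ci_low=beta - z * se,
            ci_high=beta + z * se,
            pvalue=2 * stats.norm.sf(np.abs(beta / se)),
        )
    )


def ivw_fixed(
    instruments: InstrumentSet | pd.DataFrame,
    se_order: str = "second",
    ci_level: float = 0.95,
) -> PooledResult:
    """Fixed-effect IVW pooled causal estimate with heterogeneity block."""
    bx, sx, by, sy = _as_arrays(instruments)
    est = IVWEstimator(se_order=se_order, ci_level=ci_level).fit(
        bx, by, x_se=sx, y_se=sy
    )
    return PooledResult(
        method="ivw_fixed",
        beta=est.effect_,
        se=est.se_,
        ci_low=est.ci_[0],
        ci_high=est.ci_[1],
        pvalue=est.pvalue_,
        n_snps=est.n_snps_,
        heterogeneity=est.heterogeneity_,
    )
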