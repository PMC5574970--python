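"""Sensitivity analyses for two-sample MR.

Wraps the estimator classes into the five analyses used to probe the
robustness of the main IVW result:

* MR-Egger regression with the I²_GX regression-dilution diagnostic;
* weighted median with parametric-bootstrap confidence interval;
* re-estimation after excluding a user-supplied SNP list (e.g. instruments
  also associated with BMI at genome-wide significance);
* unweighted allele-score association test (IVW pooling of the SNP-outcome
  effects themselves, immune to winner's-curse weighting bias);
* negative-control comparison of the allele score in a population that does
  not experience the exposure (men, for age at menarche).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import (
    EggerEstimator,
    IVWEstimator,
    PooledResult,
    WeightedMedianEstimator,
    _normal_p,
)
from .summary_io import InstrumentSet

__all__ = [
    "EggerFit",
    "MedianFit",
    "AlleleScoreResult",
    "NegativeControlResult",
    "egger_fit",
    "i2_gx",
    "weighted_median",
    "exclude_snps",
    "allele_score_test",
    "negative_control",
]


@dataclass
class EggerFit:
    """MR-Egger slope (causal estimate) and intercept (directional pleiotropy)."""

    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    slope_p: float
    intercept: float
    intercept_se: float
    intercept_ci: tuple[float, float]
    intercept_p: float
    i2_gx: float
    n_snps: int

    def as_pooled(self) -> PooledResult:
        return PooledResult(
            method="mr_egger",
            beta=self.slope,
            se=self.slope_se,
            ci_low=self.slope_ci[0],
            ci_high=self.slope_ci[1],
            pvalue=self.slope_p,
            n_snps=self.n_snps,
            extra=dict(
                egger_intercept=self.intercept,
                egger_intercept_se=self.intercept_se,
                egger_intercept_ci_low=self.intercept_ci[0],
                egger_intercept_ci_high=self.intercept_ci[1],
                egger_intercept_p=self.intercept_p,
                i2_gx=self.i2_gx,
            ),
        )


@dataclass
class MedianFit:
    """Weighted-median estimate with parametric-bootstrap uncertainty."""

    beta: float
    se: float
    ci: tuple[float, float]
    p: float
    n_boot: int
    seed: int
    n_snps: int

    def as_pooled(self) -> PooledResult:
        return PooledResult(
            method="weighted_median",
            beta=self.beta,
            se=self.se,
            ci_low=self.ci[0],
            ci_high=self.ci[1],
            pvalue=self.p,
            n_snps=self.n_snps,
            extra=dict(n_boot=self.n_boot, seed=self.seed),
        )


@dataclass
class AlleleScoreResult:
    """Unweighted allele-score association of instruments with the outcome."""

    population: str
    beta: float
    se: float
    p: float
    n_snps: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class NegativeControlResult:
    """Side-by-side allele-score comparison across two populations.

    ``passed`` is True when the exposed population shows a significant
    association while the unexposed (control) population does not — the
    pattern expected if the association is mediated by the exposure.
    """

    exposed: AlleleScoreResult
    control: AlleleScoreResult
    alpha: float = 0.05

    @property
    def passed(self) -> bool:
        return self.exposed.p < self.alpha and self.control.p >= self.alpha

    def as_table(self) -> pd.DataFrame:
        rows = [
            dict(population=r.population, beta=r.beta, se=r.se, p=r.p,
                 n_snps=r.n_snps, significant=r.significant)
            for r in (self.exposed, self.control)
        ]
        return pd.DataFrame(rows)


def egger_fit(instruments: InstrumentSet, ci_level: float = 0.95) -> EggerFit:
    """Fit MR-Egger on a harmonized instrument set (re-orients to bx >= 0)."""
    bx, sx, by, sy = instruments.arrays()
    est = EggerEstimator(ci_level=ci_level).fit(bx, by, x_se=sx, y_se=sy)
    return EggerFit(
        slope=est.effect_,
        slope_se=est.se_,
        slope_ci=est.ci_,
        slope_p=est.pvalue_,
        intercept=est.intercept_,
        intercept_se=est.intercept_se_,
        intercept_ci=est.intercept_ci_,
        intercept_p=est.intercept_pvalue_,
        i2_gx=est.i2_gx_,
        n_snps=est.n_snps_,
    )


def i2_gx(instruments: InstrumentSet) -> float:
    """Heterogeneity (percent) of the SNP-exposure estimates.

    ``Q_GX = sum (1/sx²)(bx - weighted mean)²`` with inverse-variance
    weights; returned as ``max(0, 100*(Q_GX - (n-1))/Q_GX)``. Values close
    to 100% indicate that measurement error in the exposure associations
    causes little regression-dilution bias in MR-Egger.
    """
    bx, sx, _, _ = instruments.arrays()
    if bx.size < 2:
        raise ValueError("I²_GX requires at least 2 instruments")
    w = 1.0 / sx**2
    bx_bar = np.sum(w * bx) / np.sum(w)
    q = float(np.sum(w * (bx - bx_bar) ** 2))
    return 0.0 if q == 0 else max(0.0, 100.0 * (q - (bx.size - 1)) / q)


def weighted_median(
    instruments: InstrumentSet,
    n_boot: int = 10000,
    seed: int = 0,
    se_order: str = "second",
    ci_method: str = "normal",
    ci_level: float = 0.95,
) -> MedianFit:
    """Weighted-median causal estimate with parametric-bootstrap CI.

    The instrument table is sorted by ``snp_id`` before fitting so that ties
    among identical ratio estimates are broken deterministically.
    """
    t = instruments.table.sort_values("snp_id", kind="stable")
    est = WeightedMedianEstimator(
        n_boot=n_boot, random_state=seed, se_order=se_order,
        ci_method=ci_method, ci_level=ci_level,
    ).fit(
        t["bx"].to_numpy(float),
        t["by"].to_numpy(float),
        x_se=t["sx"].to_numpy(float),
        y_se=t["sy"].to_numpy(float),
    )
    return MedianFit(
        beta=est.effect_,
        se=est.se_,
        ci=est.ci_,
        p=est.pvalue_,
        n_boot=est.n_boot_,
        seed=seed,
        n_snps=est.n_snps_,
    )


def exclude_snps(
    instruments: InstrumentSet,
    exclusion_list,
    reason: str = "excluded",
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Remove listed SNPs from an instrument set, keeping an audit report.

    Returns the reduced set and a report with one row per listed SNP
    (``removed`` or ``not_found``) plus a summary row of retained counts.
    Raises if the exclusion would empty the set.
    """
    exclusion = list(dict.fromkeys(str(s) for s in exclusion_list))
    present = set(instruments.table["snp_id"])
    removed = [s for s in exclusion if s in present]
    not_found = [s for s in exclusion if s not in present]
    keep = instruments.table[~instruments.table["snp_id"].isin(set(removed))]
    if len(keep) == 0:
        raise ValueError("exclusion list removes every instrument")
    rows = [dict(snp_id=s, status="removed", reason=reason) for s in removed]
    rows += [dict(snp_id=s, status="not_found", reason=reason) for s in not_found]
    report = pd.DataFrame(rows, columns=["snp_id", "status", "reason"])
    report.attrs["n_removed"] = len(removed)
    report.attrs["n_retained"] = len(keep)
    reduced = InstrumentSet(
        keep.reset_index(drop=True),
        instruments.exposure_name,
        instruments.outcome_name,
        instruments.population,
    )
    return reduced, report


def _outcome_arrays(assocs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (snp_id, by, sy) from an InstrumentSet or association frame."""
    if isinstance(assocs, InstrumentSet):
        t = assocs.table
        return t["snp_id"].to_numpy(), t["by"].to_numpy(float), t["sy"].to_numpy(float)
    t = assocs
    if "by" in t.columns:
        return t["snp_id"].to_numpy(), t["by"].to_numpy(float), t["sy"].to_numpy(float)
    return t["snp_id"].to_numpy(), t["beta"].to_numpy(float), t["se"].to_numpy(float)


def allele_score_test(outcome_assocs, population: str = "women") -> AlleleScoreResult:
    """Unweighted allele-score test of instrument-outcome association.

    Fixed-effect IVW pooling of the SNP-outcome effects themselves (weights
    ``1/sy²``), with every effect oriented to the exposure-increasing allele.
    Because it never touches the discovery-stage SNP-exposure effect sizes,
    the test is immune to winner's-curse weighting bias; it tests for a
    causal effect but does not estimate its magnitude.
    """
    snp_id, by, sy = _outcome_arrays(outcome_assocs)
    if by.size == 0:
        raise ValueError("allele score requires at least 1 SNP")
    w = 1.0 / sy**2
    beta = float(np.sum(w * by) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = _normal_p(beta / se)
    return AlleleScoreResult(
        population=population, beta=beta, se=se, p=p, n_snps=int(by.size)
    )


def negative_control(
    exposed: InstrumentSet,
    control_outcome,
    control_population: str = "men",
    alpha: float = 0.05,
) -> NegativeControlResult:
    """Allele-score comparison between the exposed and a control population.

    The control population must cover exactly the same instruments (same
    ``snp_id`` universe, same orientation). A pass requires a significant
    allele-score association in the exposed population together with a
    non-significant one in the control.
    """
    exp_ids = set(exposed.table["snp_id"])
    ctl_ids = set(_outcome_arrays(control_outcome)[0])
    if exp_ids != ctl_ids:
        only_exp = sorted(exp_ids - ctl_ids)
        only_ctl = sorted(ctl_ids - exp_ids)
        raise ValueError(
            "negative control requires identical snp_id universes; "
            f"only in exposed: {only_exp[:5]}; only in control: {only_ctl[:5]}"
        )
    women = allele_score_test(exposed, population=exposed.population)
    men = allele_score_test(control_outcome, population=control_population)
    return NegativeControlResult(exposed=women, control=men, alpha=alpha)
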