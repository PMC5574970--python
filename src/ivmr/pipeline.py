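"""End-to-end orchestration: read, harmonize, estimate, sensitivity-check,
emit plot data and a structured report.

:func:`run_full_analysis` chains every stage of the analysis —

read -> harmonize -> instrument strength -> Wald ratios -> fixed-effect IVW
(+ I²_MR) -> MR-Egger (+ I²_GX) -> weighted median -> exclusion-list re-run
-> allele scores (exposed population, and control population if provided)
-> negative-control comparison -> SD-to-days conversion -> plot data ->
report

— writing every intermediate table to the output directory together with a
manifest (package version, configuration, seeds, per-stage row counts).
Reports are deterministic: identical config + seed give byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import PooledResult, ivw_fixed, units_to_days, wald_ratio_table
from .sensitivity import (
    allele_score_test,
    egger_fit,
    exclude_snps,
    negative_control,
    weighted_median,
)
from .summary_io import (
    InstrumentSet,
    flag_weak_instruments,
    harmonize,
    read_summary_table,
)

__all__ = [
    "RunConfig",
    "PlotData",
    "ReportBundle",
    "PipelineStageError",
    "run_full_analysis",
    "build_plot_data",
    "render_figures",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Paths may be None only where the corresponding analysis is optional
    (control-population outcome, exclusion list). ``sd_years`` is the SD of
    time spent in education used for the years/days conversion (3.6 years
    per the outcome GWAS).
    """

    exposure: str | Path
    outcome: str | Path
    out_dir: str | Path
    outcome_control: str | Path | None = None
    exclude: str | Path | None = None
    palindromic_policy: str = "align_by_frequency"
    se_order: str = "second"
    n_boot: int = 10000
    seed: int = 0
    sd_years: float = 3.6
    ci_method: str = "normal"
    exposure_name: str = "age_at_menarche"
    outcome_name: str = "time_in_education"
    population: str = "women"
    control_population: str = "men"
    column_preset: str = "generic"
    weak_f_threshold: float = 10.0
    maf_corrected_funnel: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value (YAML) config file; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


@dataclass
class PlotData:
    """Plot-ready tables for the scatter, funnel and forest diagnostics."""

    scatter: pd.DataFrame
    lines: pd.DataFrame
    funnel: pd.DataFrame
    forest: pd.DataFrame
    funnel_symmetry_score: float
    funnel_symmetry_p: float


@dataclass
class ReportBundle:
    """Everything a run produced, plus warnings and the resulting exit code."""

    config: RunConfig
    instruments: InstrumentSet
    harmonization_report: pd.DataFrame
    weak_instruments: pd.DataFrame
    ratio_estimates: pd.DataFrame
    pooled: dict[str, PooledResult]
    allele_scores: pd.DataFrame | None
    negative_control_passed: bool | None
    plot_data: PlotData
    report: dict
    warnings: list[str] = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        return 2 if self.warnings else 0


def _pooled_table(pooled: dict[str, PooledResult]) -> pd.DataFrame:
    return pd.DataFrame([p.as_row() for p in pooled.values()])


def build_plot_data(
    instruments: InstrumentSet,
    ratios: pd.DataFrame,
    pooled: dict[str, PooledResult],
    maf_corrected: bool = False,
) -> PlotData:
    """Assemble scatter/funnel/forest tables from fitted results.

    The scatter carries per-SNP (bx, by) points and one line per pooled
    estimator (IVW and weighted median through the origin, MR-Egger with its
    intercept). The funnel plots per-SNP precision 1/se_iv against the ratio
    estimate with vertical reference lines at the IVW and Egger estimates;
    when ``maf_corrected`` is set an extra column carries the SNP-exposure
    effects standardized to per-SD-of-genotype units,
    ``bx * sqrt(2*maf*(1-maf))`` (SNPs lacking maf are omitted from that
    column only). Funnel asymmetry is quantified two ways: a precision-
    weighted sign score of ``beta_iv - beta_IVW`` (≈0 when symmetric) and
    the Egger intercept p-value.
    """
    t = instruments.table
    scatter = t[["snp_id", "bx", "sx", "by", "sy"]].copy()

    lines_rows = []
    for key, label in (("ivw", "ivw_fixed"), ("weighted_median", "weighted_median")):
        if key in pooled:
            lines_rows.append(
                dict(method=label, slope=pooled[key].beta, intercept=0.0)
            )
    if "egger" in pooled:
        p = pooled["egger"]
        lines_rows.append(
            dict(method="mr_egger", slope=p.beta,
                 intercept=p.extra.get("egger_intercept", 0.0))
        )
    lines = pd.DataFrame(lines_rows, columns=["method", "slope", "intercept"])

    funnel = ratios[["snp_id", "beta_iv", "se_iv"]].copy()
    funnel["precision"] = 1.0 / funnel["se_iv"]
    if maf_corrected:
        maf = t.set_index("snp_id")["maf"].reindex(funnel["snp_id"]).to_numpy(float)
        bx = t.set_index("snp_id")["bx"].reindex(funnel["snp_id"]).to_numpy(float)
        funnel["bx_maf_corrected"] = bx * np.sqrt(2.0 * maf * (1.0 - maf))
    for key, col in (("ivw", "ref_ivw"), ("egger", "ref_egger")):
        if key in pooled:
            funnel[col] = pooled[key].beta

    beta_ivw = pooled["ivw"].beta
    w = funnel["precision"].to_numpy() ** 2
    signs = np.sign(funnel["beta_iv"].to_numpy() - beta_ivw)
    score = float(np.sum(w * signs) / np.sum(w))
    sym_p = pooled.get("egger", PooledResult("", 0, 1, 0, 0, np.nan, 0)).extra.get(
        "egger_intercept_p", np.nan
    )

    forest_rows = [
        dict(label=r.snp_id, beta=r.beta_iv, ci_low=r.ci_low, ci_high=r.ci_high,
             kind="snp")
        for r in ratios.itertuples()
    ]
    for p in pooled.values():
        forest_rows.append(
            dict(label=p.method, beta=p.beta, ci_low=p.ci_low, ci_high=p.ci_high,
                 kind="pooled")
        )
    forest = pd.DataFrame(forest_rows)

    return PlotData(
        scatter=scatter, lines=lines, funnel=funnel, forest=forest,
        funnel_symmetry_score=score, funnel_symmetry_p=float(sym_p),
    )


def _read_exclusion_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    ids = [ln.strip().split("\t")[0].split(",")[0] for ln in lines if ln.strip()]
    if ids and ids[0].lower() in ("snp_id", "snp", "rsid"):
        ids = ids[1:]
    return ids


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute the full MR analysis described by ``config``.

    Writes all intermediate tables, plot data, ``report.json`` and
    ``manifest.yaml`` into ``config.out_dir`` and returns the in-memory
    bundle. Raises :class:`PipelineStageError` naming the failing stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings_list: list[str] = []
    counts: dict[str, int] = {}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, str(exc)) from exc

    exposure = _stage("read_exposure", read_summary_table, config.exposure,
                      preset=config.column_preset)
    outcome = _stage("read_outcome", read_summary_table, config.outcome,
                     preset=config.column_preset)
    counts["exposure_rows"] = len(exposure)
    counts["outcome_rows"] = len(outcome)

    instruments, harm_report = _stage(
        "harmonize", harmonize, exposure, outcome,
        palindromic_policy=config.palindromic_policy,
        exposure_name=config.exposure_name,
        outcome_name=config.outcome_name,
        population=config.population,
    )
    counts["harmonized_instruments"] = instruments.n_snps

    # weak instruments are reported (report + weak_instruments.tsv) but never
    # removed and never a run warning
    weak = _stage("instrument_strength", flag_weak_instruments,
                  instruments, config.weak_f_threshold)

    ratios = _stage("wald_ratios", wald_ratio_table, instruments,
                    se_order=config.se_order)
    pooled: dict[str, PooledResult] = {}
    pooled["ivw"] = _stage("ivw", ivw_fixed, instruments, se_order=config.se_order)

    eg = _stage("mr_egger", egger_fit, instruments)
    pooled["egger"] = eg.as_pooled()

    wm = _stage("weighted_median", weighted_median, instruments,
                n_boot=config.n_boot, seed=config.seed,
                se_order=config.se_order, ci_method=config.ci_method)
    pooled["weighted_median"] = wm.as_pooled()

    exclusion_ids: list[str] = []
    if config.exclude is not None:
        exclusion_ids = _stage("read_exclusion_list", _read_exclusion_list,
                               config.exclude)
    if exclusion_ids:
        reduced, excl_report = _stage("exclusion_rerun", exclude_snps,
                                      instruments, exclusion_ids,
                                      reason="exclusion_list")
        res = _stage("exclusion_rerun", ivw_fixed, reduced,
                     se_order=config.se_order)
        res.method = "ivw_fixed_after_exclusion"
        res.extra["n_excluded"] = excl_report.attrs["n_removed"]
        pooled["ivw_excluded"] = res
        excl_report.to_csv(out_dir / "exclusion_report.tsv", sep="\t", index=False)
        counts["instruments_after_exclusion"] = reduced.n_snps

    score_rows = []
    women_score = _stage("allele_score", allele_score_test, instruments,
                         config.population)
    score_rows.append(dataclasses.asdict(women_score))
    nc_passed: bool | None = None
    if config.outcome_control is not None:
        control_raw = _stage("read_control_outcome", read_summary_table,
                             config.outcome_control, preset=config.column_preset)
        # align the control population onto the exposure's oriented alleles
        control_set, _ = _stage(
            "harmonize_control", harmonize, exposure, control_raw,
            palindromic_policy=config.palindromic_policy,
            exposure_name=config.exposure_name,
            outcome_name=config.outcome_name + "_control",
            population=config.control_population,
        )
        shared = sorted(set(instruments.snp_ids) & set(control_set.snp_ids))
        nc = _stage("negative_control", negative_control,
                    instruments.subset(shared), control_set.subset(shared),
                    config.control_population)
        score_rows.append(dataclasses.asdict(nc.control))
        nc_passed = nc.passed
        if not nc_passed:
            warnings_list.append(
                "negative control did not pass (exposed "
                f"p={nc.exposed.p:.3g}, control p={nc.control.p:.3g})"
            )
    allele_scores = pd.DataFrame(score_rows)

    main = pooled["ivw"]
    scale = _stage("units_conversion", units_to_days, main.beta, config.sd_years)
    ci_years = (units_to_days(main.ci_low, config.sd_years).years,
                units_to_days(main.ci_high, config.sd_years).years)

    plot_data = _stage("plot_data", build_plot_data, instruments, ratios, pooled,
                       maf_corrected=config.maf_corrected_funnel)

    report = {
        "main": {
            "method": "ivw_fixed",
            "beta_sd_per_year": main.beta,
            "se": main.se,
            "ci": [main.ci_low, main.ci_high],
            "pvalue": main.pvalue,
            "n_snps": main.n_snps,
            "effect_years_per_year": scale.years,
            "effect_days_per_year": scale.days_rounded,
            "effect_ci_years": list(ci_years),
            "i2_mr": main.heterogeneity.i2_point if main.heterogeneity else None,
            "i2_mr_ci": [main.heterogeneity.i2_ci_low,
                         main.heterogeneity.i2_ci_high]
            if main.heterogeneity else None,
        },
        "sensitivity": {k: p.as_row() for k, p in pooled.items() if k != "ivw"},
        "instrument_strength": {
            "f_min": float(instruments.table["f_stat"].min()),
            "f_median": float(instruments.table["f_stat"].median()),
            "f_max": float(instruments.table["f_stat"].max()),
            "n_weak": int(len(weak)),
        },
        "allele_scores": score_rows,
        "negative_control_passed": nc_passed,
        "funnel_symmetry": {
            "score": plot_data.funnel_symmetry_score,
            "egger_intercept_p": plot_data.funnel_symmetry_p,
        },
        "warnings": warnings_list,
    }

    # persist everything
    instruments.table.to_csv(out_dir / "harmonized_instruments.tsv",
                             sep="\t", index=False)
    harm_report.to_csv(out_dir / "harmonization_report.tsv", sep="\t", index=False)
    weak.to_csv(out_dir / "weak_instruments.tsv", sep="\t", index=False)
    ratios.to_csv(out_dir / "ratio_estimates.tsv", sep="\t", index=False)
    _pooled_table(pooled).to_csv(out_dir / "pooled_results.tsv",
                                 sep="\t", index=False)
    allele_scores.to_csv(out_dir / "allele_scores.tsv", sep="\t", index=False)
    plot_data.scatter.to_csv(out_dir / "plot_scatter.tsv", sep="\t", index=False)
    plot_data.lines.to_csv(out_dir / "plot_scatter_lines.tsv", sep="\t", index=False)
    plot_data.funnel.to_csv(out_dir / "plot_funnel.tsv", sep="\t", index=False)
    plot_data.forest.to_csv(out_dir / "plot_forest.tsv", sep="\t", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=float) + "\n")
    manifest = {
        "package": "ivmr",
        "version": __version__,
        "config": config.as_dict(),
        "seed": config.seed,
        "row_counts": counts,
        "warnings": warnings_list,
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest,
                                                          sort_keys=True))

    return ReportBundle(
        config=config,
        instruments=instruments,
        harmonization_report=harm_report,
        weak_instruments=weak,
        ratio_estimates=ratios,
        pooled=pooled,
        allele_scores=allele_scores,
        negative_control_passed=nc_passed,
        plot_data=plot_data,
        report=report,
        warnings=warnings_list,
    )


def render_figures(run_dir: str | Path) -> list[Path]:
    """Render SVG scatter/funnel/forest figures from a run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    scatter = pd.read_csv(run_dir / "plot_scatter.tsv", sep="\t")
    lines = pd.read_csv(run_dir / "plot_scatter_lines.tsv", sep="\t")
    funnel = pd.read_csv(run_dir / "plot_funnel.tsv", sep="\t")
    forest = pd.read_csv(run_dir / "plot_forest.tsv", sep="\t")
    out: list[Path] = []

    styles = {"ivw_fixed": ("red", "-"), "mr_egger": ("blue", "--"),
              "weighted_median": ("black", "--")}
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.errorbar(scatter["bx"], scatter["by"], xerr=scatter["sx"],
                yerr=scatter["sy"], fmt="o", ms=3, lw=0.6, alpha=0.6,
                color="grey")
    xs = np.linspace(0, scatter["bx"].max() * 1.05, 50)
    for r in lines.itertuples():
        color, ls = styles.get(r.method, ("green", ":"))
        ax.plot(xs, r.intercept + r.slope * xs, color=color, ls=ls,
                label=r.method)
    ax.set_xlabel("SNP-exposure effect (GX)")
    ax.set_ylabel("SNP-outcome effect (GY)")
    ax.legend(frameon=False, fontsize=8)
    p = run_dir / "scatter.svg"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    out.append(p)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(funnel["beta_iv"], funnel["precision"], s=10, alpha=0.6,
               color="grey")
    if "ref_ivw" in funnel:
        ax.axvline(funnel["ref_ivw"].iloc[0], color="red", ls="--",
                   label="IVW")
    if "ref_egger" in funnel:
        ax.axvline(funnel["ref_egger"].iloc[0], color="blue", ls="-",
                   label="MR-Egger")
    ax.set_xlabel("per-SNP MR estimate")
    ax.set_ylabel("precision (1/SE)")
    ax.legend(frameon=False, fontsize=8)
    p = run_dir / "funnel.svg"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    out.append(p)

    fig, ax = plt.subplots(figsize=(6, max(3, 0.12 * len(forest))))
    ypos = np.arange(len(forest))[::-1]
    colors = forest["kind"].map({"snp": "grey", "pooled": "red"})
    ax.hlines(ypos, forest["ci_low"], forest["ci_high"], color=colors, lw=1)
    ax.scatter(forest["beta"], ypos, s=8, color=colors)
    ax.axvline(0, color="black", lw=0.5)
    ax.set_yticks(ypos)
    ax.set_yticklabels(forest["label"], fontsize=5)
    ax.set_xlabel("MR estimate")
    p = run_dir / "forest.svg"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    out.append(p)
    return out
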