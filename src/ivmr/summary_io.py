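"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization needs, for every genetic instrument, the
per-allele association with the exposure and with the outcome expressed on the
*same* effect allele. Public summary-statistic tables rarely agree on allele
labelling, strand, or orientation, so this module provides

* :func:`read_summary_table` — delimited-text ingestion with schema presets
  and strict row-level validation;
* :func:`harmonize` — allele alignment (direct match, allele swap, strand
  flip) of the outcome table onto the exposure table, with a configurable
  policy for palindromic (A/T, C/G) variants, followed by re-orientation of
  every instrument to its exposure-increasing allele;
* :func:`f_statistic` / :func:`flag_weak_instruments` — instrument-strength
  diagnostics.

The canonical per-SNP association schema is a :class:`pandas.DataFrame` with
columns ``snp_id, effect_allele, other_allele, eaf, beta, se, pvalue``
(``eaf`` and ``pvalue`` may be missing). Harmonized instruments live in an
:class:`InstrumentSet`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ASSOCIATION_COLUMNS",
    "COLUMN_PRESETS",
    "ConfigurationError",
    "SummaryDataError",
    "HarmonizationError",
    "InstrumentSet",
    "read_summary_table",
    "validate_associations",
    "harmonize",
    "f_statistic",
    "flag_weak_instruments",
]

#: canonical column order of a validated association table
ASSOCIATION_COLUMNS = [
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
]

_MANDATORY = ["snp_id", "effect_allele", "other_allele", "beta", "se"]

#: named header dialects; values map canonical name -> column name in file
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    # our own canonical headers
    "generic": {c: c for c in ASSOCIATION_COLUMNS},
    # GWAS-Catalog / GWAS-SSF style headers
    "gwas_catalog": {
        "snp_id": "rsid",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "effect_allele_frequency",
        "beta": "beta",
        "se": "standard_error",
        "pvalue": "p_value",
    },
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


class ConfigurationError(ValueError):
    """A column mapping or option does not match the input file."""


class SummaryDataError(ValueError):
    """One or more rows of a summary-statistics table violate the schema."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        shown = "; ".join(self.problems[:10])
        extra = "" if len(self.problems) <= 10 else f" (+{len(self.problems) - 10} more)"
        super().__init__(f"{len(self.problems)} invalid row(s): {shown}{extra}")


class HarmonizationError(ValueError):
    """Exposure and outcome tables cannot be aligned."""


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    preset: str = "generic",
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited GWAS summary-statistics table into canonical form.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file, optionally gzip-compressed.
    column_map
        Explicit mapping canonical name -> file column name; overrides the
        entries of ``preset`` for the keys it contains.
    preset
        Named header dialect from :data:`COLUMN_PRESETS`.
    sep
        Field delimiter; sniffed from the header line when ``None``.

    Returns
    -------
    pandas.DataFrame
        Validated table with columns :data:`ASSOCIATION_COLUMNS`.

    Raises
    ------
    ConfigurationError
        If a mandatory mapped column is absent from the file.
    SummaryDataError
        Listing every invalid row (non-numeric beta/se, se <= 0, bad alleles,
        out-of-range eaf or p-value, duplicate SNP ids). Invalid rows are
        never silently dropped.
    """
    if preset not in COLUMN_PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; available: {sorted(COLUMN_PRESETS)}"
        )
    mapping = dict(COLUMN_PRESETS[preset])
    if column_map:
        mapping.update(column_map)

    # sep=None lets pandas sniff the delimiter; gzip handled transparently
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                      dtype=str)

    missing = [mapping[c] for c in _MANDATORY if mapping[c] not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"mandatory column(s) {missing} not found in {path}; "
            f"columns present: {list(raw.columns)}"
        )

    out = pd.DataFrame(index=raw.index)
    for canon in ASSOCIATION_COLUMNS:
        src = mapping.get(canon)
        out[canon] = raw[src] if src in raw.columns else np.nan
    return validate_associations(out, source=str(path))


def validate_associations(table: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate and coerce a raw association table to the canonical schema.

    Collects *all* row-level problems and raises :class:`SummaryDataError`
    if any are found, so a malformed file is reported in one pass.
    """
    df = table.copy()
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{source}: missing mandatory column(s) {missing}")
    for c in ASSOCIATION_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan

    problems: list[str] = []
    df["snp_id"] = df["snp_id"].astype(str).str.strip()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()

    for col in ("beta", "se", "eaf", "pvalue"):
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        for snp in df.loc[bad, "snp_id"]:
            problems.append(f"{source}: {snp}: non-numeric {col}")
        df[col] = num

    mandatory_nan = df["beta"].isna() | df["se"].isna()
    for snp in df.loc[mandatory_nan, "snp_id"]:
        problems.append(f"{source}: {snp}: missing beta or se")

    bad_se = df["se"].notna() & (df["se"] <= 0)
    for snp in df.loc[bad_se, "snp_id"]:
        problems.append(f"{source}: {snp}: se must be > 0")

    for col in ("effect_allele", "other_allele"):
        bad = ~df[col].isin(_VALID_ALLELES)
        for snp in df.loc[bad, "snp_id"]:
            problems.append(f"{source}: {snp}: invalid {col} (must be A/C/G/T)")
    same = df["effect_allele"] == df["other_allele"]
    for snp in df.loc[same, "snp_id"]:
        problems.append(f"{source}: {snp}: effect and other allele identical")

    bad_eaf = df["eaf"].notna() & ~df["eaf"].between(0, 1, inclusive="neither")
    for snp in df.loc[bad_eaf, "snp_id"]:
        problems.append(f"{source}: {snp}: eaf outside (0, 1)")
    bad_p = df["pvalue"].notna() & ~(
        (df["pvalue"] > 0) & (df["pvalue"] <= 1)
    )
    for snp in df.loc[bad_p, "snp_id"]:
        problems.append(f"{source}: {snp}: p-value outside (0, 1]")

    dup = df["snp_id"][df["snp_id"].duplicated()]
    for snp in dup.unique():
        problems.append(f"{source}: duplicate snp_id {snp}")

    if problems:
        raise SummaryDataError(problems)
    return df[ASSOCIATION_COLUMNS].reset_index(drop=True)


def f_statistic(bx, sx):
    """Instrument-strength F statistic ``(bx / sx)**2``.

    Equals the square of the Wald z statistic of the SNP-exposure
    association; values above ~10 conventionally indicate a strong
    instrument. Accepts scalars or arrays.
    """
    bx = np.asarray(bx, dtype=float)
    sx = np.asarray(sx, dtype=float)
    if np.any(sx <= 0):
        raise ValueError("standard error sx must be > 0")
    out = (bx / sx) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass
class InstrumentSet:
    """An ordered set of harmonized instruments for one exposure/outcome pair.

    ``table`` columns: ``snp_id, bx, sx, by, sy, eaf, maf, f_stat`` with every
    instrument oriented to its exposure-increasing allele (``bx >= 0``).
    ``eaf``/``maf`` may be NaN when the sources did not report frequencies.
    """

    table: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    population: str = "women"

    def __post_init__(self) -> None:
        t = self.table
        required = ["snp_id", "bx", "sx", "by", "sy"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"InstrumentSet table missing column(s) {missing}")
        if len(t) == 0:
            raise ValueError("InstrumentSet must contain at least one instrument")
        if t["snp_id"].duplicated().any():
            dups = t["snp_id"][t["snp_id"].duplicated()].tolist()
            raise ValueError(f"duplicate snp_id(s): {dups}")
        if (t["sx"] <= 0).any() or (t["sy"] <= 0).any():
            raise ValueError("all standard errors must be > 0")
        if (t["bx"] < 0).any():
            raise ValueError("instruments must be oriented so that bx >= 0")
        t = t.reset_index(drop=True).copy()
        if "maf" not in t.columns:
            t["maf"] = np.where(t.get("eaf", pd.Series(np.nan, index=t.index)) <= 0.5,
                                t.get("eaf", np.nan), 1 - t.get("eaf", np.nan))
        if "f_stat" not in t.columns:
            t["f_stat"] = f_statistic(t["bx"].to_numpy(), t["sx"].to_numpy())
        self.table = t

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(bx, sx, by, sy)`` as float arrays."""
        t = self.table
        return (
            t["bx"].to_numpy(float),
            t["sx"].to_numpy(float),
            t["by"].to_numpy(float),
            t["sy"].to_numpy(float),
        )

    def subset(self, snp_ids: Iterable[str]) -> "InstrumentSet":
        keep = self.table["snp_id"].isin(set(snp_ids))
        return InstrumentSet(
            self.table[keep].reset_index(drop=True),
            self.exposure_name,
            self.outcome_name,
            self.population,
        )


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_policy: str = "align_by_frequency",
    ambiguity_window: tuple[float, float] = (0.42, 0.58),
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    population: str = "women",
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Align outcome associations onto the exposure's effect alleles.

    For every SNP present in both tables the outcome effect is matched to the
    exposure's effect allele directly, by allele swap (sign flip), or by
    strand complement; afterwards each instrument is re-oriented so that the
    exposure effect is non-negative (exposure-increasing allele convention,
    required by MR-Egger and by the allele-score tests).

    Palindromic variants (A/T or C/G), whose strand cannot be resolved from
    the allele labels, are handled per ``palindromic_policy``:

    ``"drop"``
        excluded;
    ``"align_by_frequency"`` (default)
        aligned by comparing effect-allele frequencies, excluded when either
        frequency is missing or falls inside ``ambiguity_window``;
    ``"keep_as_is"``
        allele labels taken at face value.

    Returns
    -------
    (InstrumentSet, pandas.DataFrame)
        The harmonized instruments and a per-SNP report with columns
        ``snp_id, status, action, reason`` covering *every* SNP seen in
        either input (kept, excluded, or missing from one source).

    Raises
    ------
    HarmonizationError
        If no SNP is shared between the tables or none survives alignment.
    """
    policies = {"drop", "align_by_frequency", "keep_as_is"}
    if palindromic_policy not in policies:
        raise ConfigurationError(
            f"palindromic_policy must be one of {sorted(policies)}"
        )

    exp = validate_associations(exposure, source=exposure_name)
    out = validate_associations(outcome, source=outcome_name)

    exp_ids = set(exp["snp_id"])
    out_ids = set(out["snp_id"])
    shared = exp_ids & out_ids
    report_rows: list[dict] = []
    for snp in sorted(exp_ids - out_ids):
        report_rows.append(
            dict(snp_id=snp, status="excluded", action="none",
                 reason="missing_in_outcome")
        )
    for snp in sorted(out_ids - exp_ids):
        report_rows.append(
            dict(snp_id=snp, status="excluded", action="none",
                 reason="missing_in_exposure")
        )
    if not shared:
        raise HarmonizationError("no shared snp_id between exposure and outcome")

    exp_idx = exp.set_index("snp_id")
    out_idx = out.set_index("snp_id")
    lo, hi = ambiguity_window

    kept: list[dict] = []
    # preserve exposure table order for the shared SNPs
    for snp in exp["snp_id"]:
        if snp not in shared:
            continue
        e = exp_idx.loc[snp]
        o = out_idx.loc[snp]
        ea_x, oa_x = e["effect_allele"], e["other_allele"]
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        by, eaf_y = float(o["beta"]), o["eaf"]
        palindromic = _is_palindromic(ea_x, oa_x)
        action = "direct"

        if palindromic:
            # strand is unresolvable from labels: complement == swap
            face_direct = (ea_y, oa_y) == (ea_x, oa_x)
            face_swap = (ea_y, oa_y) == (oa_x, ea_x)
            if not (face_direct or face_swap):
                report_rows.append(dict(snp_id=snp, status="excluded",
                                        action="none", reason="allele_mismatch"))
                continue
            if palindromic_policy == "drop":
                report_rows.append(dict(snp_id=snp, status="excluded",
                                        action="none", reason="palindromic_dropped"))
                continue
            if face_swap:
                by, eaf_y = -by, (1 - eaf_y if pd.notna(eaf_y) else np.nan)
                action = "swap"
            if palindromic_policy == "align_by_frequency":
                eaf_x = e["eaf"]
                if pd.isna(eaf_x) or pd.isna(eaf_y):
                    report_rows.append(dict(snp_id=snp, status="excluded",
                                            action="none",
                                            reason="palindromic_missing_eaf"))
                    continue
                if lo < eaf_x < hi or lo < eaf_y < hi:
                    report_rows.append(dict(snp_id=snp, status="excluded",
                                            action="none",
                                            reason="palindromic_ambiguous_eaf"))
                    continue
                if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                    # frequencies disagree: reported allele is on the other
                    # strand, i.e. actually the exposure's other allele
                    by, eaf_y = -by, 1 - eaf_y
                    action = "frequency_flip"
        else:
            comp = (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y])
            if (ea_y, oa_y) == (ea_x, oa_x):
                action = "direct"
            elif (ea_y, oa_y) == (oa_x, ea_x):
                by, eaf_y = -by, (1 - eaf_y if pd.notna(eaf_y) else np.nan)
                action = "swap"
            elif comp == (ea_x, oa_x):
                action = "strand_flip"
            elif comp == (oa_x, ea_x):
                by, eaf_y = -by, (1 - eaf_y if pd.notna(eaf_y) else np.nan)
                action = "strand_flip_swap"
            else:
                report_rows.append(dict(snp_id=snp, status="excluded",
                                        action="none", reason="allele_mismatch"))
                continue

        bx, sx, sy = float(e["beta"]), float(e["se"]), float(o["se"])
        eaf = e["eaf"] if pd.notna(e["eaf"]) else np.nan
        if bx < 0:  # orient to the exposure-increasing allele
            bx, by = -bx, -by
            eaf = 1 - eaf if pd.notna(eaf) else np.nan
            action += "+reorient"
        maf = min(eaf, 1 - eaf) if pd.notna(eaf) else np.nan
        kept.append(dict(snp_id=snp, bx=bx, sx=sx, by=by, sy=sy,
                         eaf=eaf, maf=maf, f_stat=(bx / sx) ** 2))
        report_rows.append(dict(snp_id=snp, status="kept", action=action,
                                reason=""))

    if not kept:
        raise HarmonizationError("no SNP survived harmonization")
    table = pd.DataFrame(kept)
    report = pd.DataFrame(report_rows, columns=["snp_id", "status", "action", "reason"])
    iset = InstrumentSet(table, exposure_name, outcome_name, population)
    return iset, report


def flag_weak_instruments(
    instruments: InstrumentSet, threshold: float = 10.0
) -> pd.DataFrame:
    """List instruments whose F statistic falls below ``threshold``.

    Reporting only — weak instruments are flagged, never removed.
    """
    t = instruments.table
    weak = t[t["f_stat"] < threshold]
    return weak[["snp_id", "f_stat"]].reset_index(drop=True)
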