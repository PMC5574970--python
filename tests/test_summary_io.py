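"""Ingestion, validation, harmonization and instrument-strength checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivmr import (
    InstrumentSet,
    f_statistic,
    flag_weak_instruments,
    harmonize,
    read_summary_table,
    scramble_alleles,
    simulate,
)
from ivmr.simulate import SimulationTruth
from ivmr.summary_io import ConfigurationError, HarmonizationError, SummaryDataError

from conftest import make_associations


class TestReadSummaryTable:
    def _write(self, tmp_path, df, name="t.tsv", sep="\t"):
        p = tmp_path / name
        df.to_csv(p, sep=sep, index=False)
        return p

    def test_well_formed_table_roundtrips(self, tmp_path):
        df = make_associations(
            ["rs1", "rs2", "rs3"], [("A", "G"), ("T", "C"), ("G", "T")],
            [0.1, -0.05, 0.02], [0.01, 0.02, 0.005], eafs=[0.3, 0.4, 0.1],
        )
        out = read_summary_table(self._write(tmp_path, df))
        assert len(out) == 3
        assert list(out["snp_id"]) == ["rs1", "rs2", "rs3"]
        np.testing.assert_allclose(out["beta"], [0.1, -0.05, 0.02])

    def test_comma_delimited_and_gzip(self, tmp_path):
        df = make_associations(["rs1", "rs2", "rs3"],
                               [("A", "G")] * 3, [0.1, 0.2, 0.3], [0.01] * 3)
        p = tmp_path / "t.csv.gz"
        df.to_csv(p, index=False, compression="gzip")
        out = read_summary_table(p, sep=",")
        assert len(out) == 3

    def test_gwas_catalog_preset_and_column_map(self, tmp_path):
        df = pd.DataFrame(
            dict(rsid=["rs1"], effect_allele=["A"], other_allele=["G"],
                 beta=[0.1], standard_error=[0.01],
                 effect_allele_frequency=[0.2], p_value=[1e-9]),
        )
        out = read_summary_table(self._write(tmp_path, df), preset="gwas_catalog")
        assert out.loc[0, "se"] == 0.01 and out.loc[0, "eaf"] == 0.2
        # explicit column_map override wins over the preset
        df2 = df.rename(columns={"rsid": "marker"})
        out2 = read_summary_table(
            self._write(tmp_path, df2, "t2.tsv"), preset="gwas_catalog",
            column_map={"snp_id": "marker"},
        )
        assert out2.loc[0, "snp_id"] == "rs1"

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        df = make_associations(["rs1"], [("A", "G")], [0.1], [0.01]).drop(columns="se")
        with pytest.raises(ConfigurationError, match="se"):
            read_summary_table(self._write(tmp_path, df))

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda d: d.assign(se=[0.01, 0.0]), "se must be > 0"),
            (lambda d: d.assign(beta=["0.1", "oops"]), "non-numeric beta"),
            (lambda d: d.assign(snp_id=["rs1", "rs1"]), "duplicate snp_id rs1"),
            (lambda d: d.assign(effect_allele=["A", "N"]), "invalid effect_allele"),
            (lambda d: d.assign(other_allele=["A", "C"]), "identical"),
            (lambda d: d.assign(eaf=[0.3, 1.2]), "eaf outside"),
        ],
    )
    def test_row_level_validation_errors(self, tmp_path, mutate, match):
        df = make_associations(["rs1", "rs2"], [("A", "G"), ("T", "C")],
                               [0.1, 0.2], [0.01, 0.02], eafs=[0.3, 0.4])
        with pytest.raises(SummaryDataError, match=match):
            read_summary_table(self._write(tmp_path, mutate(df)))

    def test_all_problems_reported_not_just_first(self, tmp_path):
        df = make_associations(["rs1", "rs2"], [("A", "G"), ("T", "C")],
                               ["bad", 0.2], [0.01, -1.0])
        with pytest.raises(SummaryDataError) as exc:
            read_summary_table(self._write(tmp_path, df))
        assert len(exc.value.problems) >= 2


class TestFStatistic:
    def test_closed_form(self):
        assert f_statistic(0.10, 0.02) == pytest.approx(25.0)
        assert f_statistic(0.0, 0.5) == 0.0

    def test_equals_squared_wald_z_exactly(self):
        rng = np.random.default_rng(0)
        bx = rng.normal(size=50)
        sx = rng.uniform(0.01, 1, size=50)
        np.testing.assert_array_equal(f_statistic(bx, sx), (bx / sx) ** 2)

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


class TestFlagWeakInstruments:
    def test_strong_set_yields_empty_flag_list(self, small_instruments):
        assert len(flag_weak_instruments(small_instruments, threshold=10)) == 0

    def test_weak_snp_flagged_but_not_removed(self, small_instruments):
        t = small_instruments.table.copy()
        t.loc[0, "bx"], t.loc[0, "sx"] = 0.02, 0.01  # F = 4
        t["f_stat"] = (t["bx"] / t["sx"]) ** 2
        iset = InstrumentSet(t)
        flagged = flag_weak_instruments(iset, threshold=10)
        assert list(flagged["snp_id"]) == ["rs1"]
        assert iset.n_snps == 4

    def test_infinite_threshold_flags_all(self, small_instruments):
        flagged = flag_weak_instruments(small_instruments, threshold=np.inf)
        assert len(flagged) == small_instruments.n_snps


class TestHarmonize:
    def test_allele_swap_flips_outcome_sign(self):
        exp = make_associations(["rs1"], [("A", "G")], [0.05], [0.01])
        out = make_associations(["rs1"], [("G", "A")], [0.02], [0.01])
        iset, report = harmonize(exp, out)
        assert iset.table.loc[0, "by"] == pytest.approx(-0.02)
        assert report.loc[report.snp_id == "rs1", "action"].item() == "swap"

    def test_strand_flip_without_swap_keeps_sign(self):
        exp = make_associations(["rs1"], [("A", "G")], [0.05], [0.01])
        out = make_associations(["rs1"], [("T", "C")], [0.02], [0.01])
        iset, _ = harmonize(exp, out)
        assert iset.table.loc[0, "by"] == pytest.approx(0.02)

    def test_reorientation_preserves_ratio(self):
        # negative exposure effect: both betas flip jointly, ratio unchanged
        exp = make_associations(["rs1"], [("A", "G")], [-0.05], [0.01])
        out = make_associations(["rs1"], [("A", "G")], [-0.02], [0.01])
        iset, _ = harmonize(exp, out)
        row = iset.table.iloc[0]
        assert row["bx"] == pytest.approx(0.05)
        assert row["by"] == pytest.approx(0.02)

    def test_irreconcilable_alleles_excluded_with_reason(self):
        exp = make_associations(["rs1", "rs2"], [("A", "G"), ("A", "G")],
                                [0.05, 0.06], [0.01, 0.01])
        out = make_associations(["rs1", "rs2"], [("A", "G"), ("A", "C")],
                                [0.02, 0.02], [0.01, 0.01])
        iset, report = harmonize(exp, out)
        assert iset.snp_ids == ["rs1"]
        row = report[report.snp_id == "rs2"].iloc[0]
        assert row["status"] == "excluded" and row["reason"] == "allele_mismatch"

    def test_missing_in_outcome_reported(self):
        exp = make_associations(["rs1", "rs2"], [("A", "G")] * 2,
                                [0.05, 0.06], [0.01, 0.01])
        out = make_associations(["rs1"], [("A", "G")], [0.02], [0.01])
        _, report = harmonize(exp, out)
        assert (report[report.snp_id == "rs2"]["reason"] == "missing_in_outcome").all()

    def test_empty_intersection_raises(self):
        exp = make_associations(["rs1"], [("A", "G")], [0.05], [0.01])
        out = make_associations(["rs9"], [("A", "G")], [0.02], [0.01])
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    @pytest.mark.parametrize(
        "policy, eaf_x, eaf_y, expect",
        [
            ("drop", 0.2, 0.2, "palindromic_dropped"),
            ("align_by_frequency", 0.2, 0.2, "kept_same_sign"),
            ("align_by_frequency", 0.2, 0.8, "kept_flipped"),
            ("align_by_frequency", 0.5, 0.2, "palindromic_ambiguous_eaf"),
            ("align_by_frequency", np.nan, 0.2, "palindromic_missing_eaf"),
            ("keep_as_is", np.nan, np.nan, "kept_same_sign"),
        ],
    )
    def test_palindromic_policies(self, policy, eaf_x, eaf_y, expect):
        exp = make_associations(["rs1", "rs2"], [("A", "T"), ("C", "A")],
                                [0.05, 0.05], [0.01, 0.01], eafs=[eaf_x, 0.3])
        out = make_associations(["rs1", "rs2"], [("A", "T"), ("C", "A")],
                                [0.02, 0.02], [0.01, 0.01], eafs=[eaf_y, 0.3])
        iset, report = harmonize(exp, out, palindromic_policy=policy)
        row = report[report.snp_id == "rs1"].iloc[0]
        if expect.startswith("kept"):
            assert row["status"] == "kept"
            by = iset.table.set_index("snp_id").loc["rs1", "by"]
            assert by == pytest.approx(0.02 if expect == "kept_same_sign" else -0.02)
        else:
            assert row["status"] == "excluded" and row["reason"] == expect

    def test_idempotence(self, paper_like_instruments):
        """Harmonizing an already-aligned pair changes nothing."""
        t = paper_like_instruments.table
        exp = make_associations(t["snp_id"], [("A", "G")] * len(t),
                                t["bx"], t["sx"], eafs=t["eaf"])
        out = make_associations(t["snp_id"], [("A", "G")] * len(t),
                                t["by"], t["sy"], eafs=t["eaf"])
        iset2, report = harmonize(exp, out)
        assert (report["status"] == "kept").all()
        merged = t.merge(iset2.table, on="snp_id", suffixes=("", "_2"))
        np.testing.assert_allclose(merged["bx"], merged["bx_2"])
        np.testing.assert_allclose(merged["by"], merged["by_2"])

    @pytest.mark.parametrize("scramble_seed", [1, 2, 3])
    def test_scrambling_oracle_ratios_invariant(self, scramble_seed):
        """Allele/strand scrambling never changes the per-SNP causal ratio."""
        ds = simulate(SimulationTruth(n_snps=60, seed=scramble_seed))
        ref, _ = harmonize(ds.exposure, ds.outcome)
        scr = scramble_alleles(ds, seed=100 + scramble_seed)
        got, _ = harmonize(scr.exposure, scr.outcome)
        merged = ref.table.merge(got.table, on="snp_id", suffixes=("_a", "_b"))
        assert len(merged) == ref.n_snps
        np.testing.assert_allclose(
            merged["by_a"] / merged["bx_a"], merged["by_b"] / merged["bx_b"]
        )

    def test_instrument_set_invariants(self, paper_like_instruments):
        t = paper_like_instruments.table
        assert (t["bx"] >= 0).all()
        assert (t["sx"] > 0).all() and (t["sy"] > 0).all()
        assert t["snp_id"].is_unique
        np.testing.assert_allclose(t["f_stat"], (t["bx"] / t["sx"]) ** 2)
        assert ((t["maf"] > 0) & (t["maf"] <= 0.5)).all()


@given(st.integers(min_value=0, max_value=10**6))
@settings(max_examples=15, deadline=None)
def test_ratio_invariance_property(seed):
    """by/bx invariant to any random allele re-labelling (hypothesis seeds)."""
    ds = simulate(SimulationTruth(n_snps=10, seed=7))
    ref, _ = harmonize(ds.exposure, ds.outcome)
    scr = scramble_alleles(ds, seed=seed)
    got, _ = harmonize(scr.exposure, scr.outcome)
    merged = ref.table.merge(got.table, on="snp_id", suffixes=("_a", "_b"))
    np.testing.assert_allclose(
        merged["by_a"] / merged["bx_a"], merged["by_b"] / merged["bx_b"]
    )
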