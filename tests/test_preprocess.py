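"""Missingness, Box-Cox lambda selection, plate correction, heritability."""

import numpy as np
import pandas as pd
import pytest

from pleioscope.errors import ValidationError
from pleioscope.preprocess import (
    boxcox_by_strain,
    filter_missing,
    heritability,
    outlier_filter,
    plate_correct,
    preprocess_pipeline,
)


def _table(rng, n_strains=6, n_cells=40, traits=("l001", "l002")):
    rows = n_strains * n_cells
    df = pd.DataFrame({
        "cell_id": np.arange(rows),
        "strain": np.repeat([f"s{i}" for i in range(n_strains)], n_cells),
        "replicate": rng.integers(1, 4, size=rows),
        "cell_type": "large",
    })
    for t in traits:
        df[t] = rng.normal(10, 1, size=rows)
    return df


class TestFilterMissing:
    def test_trait_over_threshold_removed(self, rng):
        df = _table(rng)
        n = len(df)
        idx = rng.choice(n, size=int(0.11 * n), replace=False)
        df.loc[idx, "l002"] = np.nan
        out, report = filter_missing(df)
        assert "l002" in report.traits_dropped
        assert "l002" not in out.columns

    def test_no_missing_is_identity(self, rng):
        df = _table(rng)
        out, report = filter_missing(df)
        pd.testing.assert_frame_equal(out, df)
        assert not report.traits_dropped

    def test_incomplete_cell_removed(self, rng):
        df = _table(rng)
        df.loc[3, "l001"] = np.nan  # under threshold, trait retained
        out, report = filter_missing(df)
        assert "l001" in out.columns
        assert len(out) == len(df) - 1
        assert report.cells_dropped["incomplete"] == 1

    def test_all_traits_dropped_is_hard_error(self, rng):
        df = _table(rng)
        df["l001"] = np.nan
        df["l002"] = np.nan
        with pytest.raises(ValidationError):
            filter_missing(df)


class TestBoxCox:
    def test_lognormal_selects_log(self, rng):
        df = _table(rng, n_strains=15, n_cells=150, traits=())
        eff = rng.normal(0, 0.3, 15)
        codes = pd.factorize(df["strain"])[0]
        df["l001"] = np.exp(rng.normal(0, 0.5, len(df)) + eff[codes])
        _, report = boxcox_by_strain(df)
        assert abs(report.boxcox_lambda["l001"]) <= 0.1

    def test_gaussian_selects_identity_region(self, rng):
        df = _table(rng, n_strains=15, n_cells=150, traits=())
        eff = rng.normal(0, 0.5, 15)
        codes = pd.factorize(df["strain"])[0]
        df["l001"] = rng.normal(10, 1, len(df)) + eff[codes]
        out, report = boxcox_by_strain(df)
        lam = report.boxcox_lambda["l001"]
        assert abs(lam - 1.0) <= 0.2
        # lambda=1 transform is affine: correlation with input stays 1
        assert np.corrcoef(out["l001"], df["l001"])[0, 1] > 0.999

    def test_log_branch_exact_value(self):
        from pleioscope.preprocess import _boxcox
        assert _boxcox(np.array([np.e]), 0.0)[0] == pytest.approx(1.0)

    def test_constant_trait_flagged(self, rng):
        df = _table(rng)
        df["l001"] = 5.0
        _, report = boxcox_by_strain(df)
        assert "l001" in report.flagged_traits
        assert "l001" not in report.boxcox_lambda


class TestPlateCorrect:
    def test_identical_controls_change_nothing(self, rng):
        df = _table(rng)
        df.loc[df["strain"].isin(["s0", "s1"]), ["l001", "l002"]] = 5.0
        out, report = plate_correct(df, ("s0", "s1"))
        assert np.allclose(report.plate_offsets["offset"], 0.0)
        assert np.allclose(out[["l001", "l002"]], df[["l001", "l002"]])

    def test_shifted_plate_corrected_back(self, rng):
        df = _table(rng)
        df[["l001", "l002"]] = 10.0
        df.loc[df["replicate"] == 2, ["l001", "l002"]] += 2.0
        out, _ = plate_correct(df, ("s0", "s1"))
        # plate 2's offset is 2 * (n_plates-1)/n_plates relative to the grand
        # mid-parent mean; after correction all plates agree
        for t in ("l001", "l002"):
            plate_means = out.groupby("replicate")[t].mean()
            assert plate_means.std() == pytest.approx(0.0, abs=1e-12)

    def test_simulated_plate_effects_removed(self, rng):
        df = _table(rng, n_strains=8, n_cells=60)
        offs = {1: 0.5, 2: -0.4, 3: 0.8}
        for plate, off in offs.items():
            df.loc[df["replicate"] == plate, "l001"] += off
        out, _ = plate_correct(df, ("s0", "s1"))
        ctrl = out[out["strain"].isin(["s0", "s1"])]
        between_plate = ctrl.groupby("replicate")["l001"].mean().var()
        assert between_plate < 0.01

    def test_missing_control_names_plate(self, rng):
        df = _table(rng)
        df = df[~((df["strain"] == "s0") & (df["replicate"] == 2))]
        with pytest.raises(ValidationError, match="plate 2"):
            plate_correct(df, ("s0", "s1"))


class TestOutlierFilter:
    def test_no_outliers_no_removal(self, rng):
        df = _table(rng)
        out, report = outlier_filter(df, k=5.0)
        assert len(out) == len(df)
        assert report.cells_dropped["outlier"] == 0

    def test_injected_outlier_removed(self, rng):
        df = _table(rng)
        mu, sd = df["l001"].mean(), df["l001"].std()
        df.loc[17, "l001"] = mu + 6 * sd
        out, report = outlier_filter(df, k=5.0)
        assert report.cells_dropped["outlier"] == 1
        assert 17 not in out["cell_id"].values

    def test_infinite_k_is_identity(self, rng):
        df = _table(rng)
        out, _ = outlier_filter(df, k=np.inf)
        pd.testing.assert_frame_equal(out, df)


class TestHeritability:
    def test_equal_strain_means_clip_to_zero(self, rng):
        df = _table(rng, n_strains=4, n_cells=30)
        for s in df["strain"].unique():
            df.loc[df["strain"] == s, "l001"] -= df.loc[df["strain"] == s, "l001"].mean()
        assert heritability(df, "l001") == 0.0

    def test_variance_component_recovery(self, rng):
        # sigma_B=1, sigma_W=9 -> H2 = 0.10
        J, n = 300, 40
        df = pd.DataFrame({
            "strain": np.repeat([f"s{i}" for i in range(J)], n),
            "replicate": 1, "cell_type": "large",
            "l001": (np.repeat(rng.normal(0, 1.0, J), n)
                     + rng.normal(0, 3.0, J * n)),
        })
        assert heritability(df, "l001") == pytest.approx(0.10, abs=0.02)

    def test_zero_within_variance_gives_one(self):
        df = pd.DataFrame({"strain": ["a", "a", "b", "b"], "replicate": 1,
                           "cell_type": "large", "l001": [1.0, 1.0, 2.0, 2.0]})
        assert heritability(df, "l001") == 1.0

    def test_single_strain_rejected(self, rng):
        df = _table(rng, n_strains=1)
        with pytest.raises(ValidationError):
            heritability(df, "l001")


def test_pipeline_idempotent_with_neutral_settings(rng):
    df = _table(rng, n_strains=6, n_cells=50)
    clean, _ = preprocess_pipeline(df, control_strains=("s0", "s1"),
                                   boxcox=False, compute_heritability=False)
    again, _ = preprocess_pipeline(clean, control_strains=("s0", "s1"),
                                   boxcox=False, outlier_sd=np.inf,
                                   compute_heritability=False)
    pd.testing.assert_frame_equal(
        again.reset_index(drop=True), clean.reset_index(drop=True),
        check_dtype=False, atol=1e-12)
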