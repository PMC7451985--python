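"""Generator contracts: recombination model, covariance targets, determinism."""

import numpy as np
import pandas as pd
import pytest

from pleioscope.errors import ConfigError, MapError
from pleioscope.simulate import (
    QtlEffect,
    SimConfig,
    SimTruth,
    haldane_fraction,
    simulate_cells,
    simulate_cross,
    simulate_dose_series,
    simulate_ma_panel,
)


class TestCross:
    def test_zero_distance_markers_identical(self):
        mm = pd.DataFrame({"marker": ["a", "b"], "chromosome": [1, 1],
                           "position_cM": [5.0, 5.0]})
        cfg = SimConfig(n_strains=200, n_traits_per_celltype=(0, 0, 2), seed=1)
        g, _ = simulate_cross(cfg, marker_map=mm)
        assert (g["a"] == g["b"]).all()

    def test_haldane_discordance_at_10_cM(self):
        # closed form: r = (1 - exp(-0.2))/2 = 0.090635
        mm = pd.DataFrame({"marker": ["a", "b"], "chromosome": [1, 1],
                           "position_cM": [0.0, 10.0]})
        n = 10_000
        cfg = SimConfig(n_strains=n, n_traits_per_celltype=(0, 0, 2), seed=2)
        g, _ = simulate_cross(cfg, marker_map=mm)
        r = float(haldane_fraction(10.0))
        se = np.sqrt(r * (1 - r) / n)
        disc = (g["a"] != g["b"]).mean()
        assert abs(disc - r) < 3 * se

    def test_single_strain(self):
        cfg = SimConfig(n_strains=1, n_markers=5, n_chromosomes=1,
                        n_traits_per_celltype=(0, 0, 2), seed=3)
        g, _ = simulate_cross(cfg)
        assert len(g) == 1

    def test_allele_frequency_near_half(self):
        cfg = SimConfig(n_strains=2000, n_markers=10, n_chromosomes=2,
                        n_traits_per_celltype=(0, 0, 2), seed=4)
        g, _ = simulate_cross(cfg)
        freq = (g.to_numpy() > 0).mean(axis=0)
        assert np.all(np.abs(freq - 0.5) < 4 * np.sqrt(0.25 / 2000))

    def test_nonincreasing_positions_rejected(self):
        mm = pd.DataFrame({"marker": ["a", "b"], "chromosome": [1, 1],
                           "position_cM": [10.0, 5.0]})
        cfg = SimConfig(n_strains=5, n_traits_per_celltype=(0, 0, 2), seed=5)
        with pytest.raises(MapError):
            simulate_cross(cfg, marker_map=mm)

    def test_negative_distance_rejected(self):
        with pytest.raises(MapError):
            haldane_fraction(-1.0)


class TestCells:
    def test_zero_variance_no_qtl_gives_baseline(self):
        cfg = SimConfig(n_strains=3, n_markers=4, n_chromosomes=1,
                        n_traits_per_celltype=(0, 0, 3), cells_per_strain=10,
                        strain_var=0.0, cell_var=0.0, plate_effect_sd=0.0, seed=6)
        g, _ = simulate_cross(cfg)
        cells, _ = simulate_cells(g, cfg)
        traits = ["l001", "l002", "l003"]
        assert np.allclose(cells[traits].to_numpy(), 0.0)

    def test_pooled_within_correlation_converges(self):
        base = np.eye(2)
        base[0, 1] = base[1, 0] = 0.5
        cfg = SimConfig(n_strains=100, n_markers=4, n_chromosomes=1,
                        n_traits_per_celltype=(0, 0, 2), cells_per_strain=1000,
                        strain_var=0.0, plate_effect_sd=0.0, seed=7,
                        base_within_corr={"large": base})
        g, _ = simulate_cross(cfg)
        cells, truth = simulate_cells(g, cfg)
        r = np.corrcoef(cells["l001"], cells["l002"])[0, 1]
        assert abs(r - 0.5) < 0.02
        row = truth.pair_truth.query("trait_x=='l001' and trait_y=='l002'")
        assert row["r_within"].iloc[0] == pytest.approx(0.5)

    def test_qtl_beta_sets_between_strain_variance(self):
        # coded +-1 alleles, balanced: between-strain variance of the strain
        # mean approx beta^2
        beta = 0.5
        cfg = SimConfig(n_strains=400, n_markers=4, n_chromosomes=1,
                        n_traits_per_celltype=(0, 0, 2), cells_per_strain=200,
                        strain_var=0.0, plate_effect_sd=0.0, seed=8,
                        qtl_spec=[QtlEffect("m2", "direct_horizontal",
                                            ("l001",), beta=beta)])
        g, _ = simulate_cross(cfg)
        cells, _ = simulate_cells(g, cfg)
        strain_means = cells.groupby("strain")["l001"].mean()
        v = strain_means.var()
        assert abs(v - beta**2) < 0.05 * beta**2 + 3 * 1.0 / 200

    def test_corr_modifying_context_truth(self, small_cross):
        _, genotypes, _, cells, truth = small_cross
        per_allele = truth.pair_truth.query(
            "trait_x=='l004' and trait_y=='l005' and context!='all'")
        assert set(per_allele["context"]) == {"-", "+"}
        lo = per_allele.set_index("context")["r_within"]
        assert lo["-"] == pytest.approx(0.1, abs=1e-9)
        assert lo["+"] == pytest.approx(0.7, abs=1e-9)

    def test_identical_seeds_bit_identical(self):
        cfg = SimConfig(n_strains=10, n_markers=6, n_chromosomes=2,
                        n_traits_per_celltype=(1, 1, 2), cells_per_strain=30,
                        seed=9)
        g1, _ = simulate_cross(cfg)
        c1, _ = simulate_cells(g1, cfg)
        g2, _ = simulate_cross(cfg)
        c2, _ = simulate_cells(g2, cfg)
        pd.testing.assert_frame_equal(c1, c2)

    def test_invalid_corr_modifying_rejected(self):
        with pytest.raises(ConfigError):
            QtlEffect("m1", "corr_modifying", ("a", "b"), rho0=0.8, delta=0.5)

    def test_non_psd_base_corr_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        cfg = SimConfig(n_strains=4, n_traits_per_celltype=(0, 0, 3),
                        base_within_corr={"large": bad}, seed=10)
        with pytest.raises(ConfigError):
            cfg.validate()


class TestMaPanel:
    def test_unaltered_lines_vary_only_by_sampling(self):
        # SD of per-line r across lines should be near the Fisher SE of r
        n_per = 500
        base = np.eye(2)
        base[0, 1] = base[1, 0] = 0.3
        cfg = SimConfig(n_traits_per_celltype=(0, 0, 2), cells_per_strain=n_per,
                        strain_var=0.0, plate_effect_sd=0.0, seed=11,
                        base_within_corr={"large": base})
        cells, _ = simulate_ma_panel(cfg, n_lines=40, n_altered=0)
        rs = cells.groupby("strain").apply(
            lambda d: np.corrcoef(d["l001"], d["l002"])[0, 1],
            include_groups=False)
        z_sd = np.arctanh(rs).std()
        fisher_se = 1.0 / np.sqrt(n_per - 3)
        assert z_sd < 1.5 * fisher_se

    def test_altered_line_recorded(self):
        cfg = SimConfig(n_traits_per_celltype=(0, 0, 2), cells_per_strain=60,
                        strain_var=0.0, seed=12)
        cells, truth = simulate_ma_panel(cfg, n_lines=10, n_altered=2, delta=0.5)
        assert truth.ma_lines["altered"].sum() == 2
        assert cells["strain"].nunique() == 10

    def test_out_of_range_alteration_rejected(self):
        base = np.eye(2)
        base[0, 1] = base[1, 0] = 0.7
        cfg = SimConfig(n_traits_per_celltype=(0, 0, 2), cells_per_strain=60,
                        base_within_corr={"large": base}, seed=13)
        with pytest.raises(ConfigError):
            simulate_ma_panel(cfg, n_lines=5, n_altered=1, delta=0.5)

    def test_n_altered_exceeds_lines_rejected(self):
        cfg = SimConfig(n_traits_per_celltype=(0, 0, 2), seed=14)
        with pytest.raises(ConfigError):
            simulate_ma_panel(cfg, n_lines=2, n_altered=3)


class TestDoseSeries:
    def test_zero_shift_gives_identical_conditions(self):
        cfg = SimConfig(n_strains=5, n_traits_per_celltype=(0, 0, 2),
                        cells_per_strain=50, seed=15)
        cells, _ = simulate_dose_series(
            cfg, doses=[1.0], corr_shift_per_dose={("l001", "l002"): [0.0]})
        drug = cells[cells["condition"] == "drug"].reset_index(drop=True)
        ctrl = cells[cells["condition"] == "control"].reset_index(drop=True)
        traits = ["l001", "l002"]
        assert np.array_equal(drug[traits].to_numpy(), ctrl[traits].to_numpy())

    def test_recovered_deltas_ordered_with_dose(self):
        cfg = SimConfig(n_strains=20, n_traits_per_celltype=(0, 0, 2),
                        cells_per_strain=600, strain_var=0.02, seed=16)
        cells, _ = simulate_dose_series(
            cfg, doses=[1.0, 2.0, 3.0],
            corr_shift_per_dose={("l001", "l002"): [0.05, 0.15, 0.3]})
        deltas = []
        for dose in (1.0, 2.0, 3.0):
            sub = cells[cells["dose"] == dose]
            rs = {}
            for cond in ("drug", "control"):
                d = sub[sub["condition"] == cond]
                rs[cond] = np.corrcoef(d["l001"], d["l002"])[0, 1]
            deltas.append(abs(rs["drug"] - rs["control"]))
        assert deltas[0] < deltas[1] < deltas[2]

    def test_out_of_range_shift_rejected(self):
        base = np.eye(2)
        base[0, 1] = base[1, 0] = 0.8
        cfg = SimConfig(n_strains=3, n_traits_per_celltype=(0, 0, 2),
                        cells_per_strain=30, base_within_corr={"large": base},
                        seed=17)
        with pytest.raises(ConfigError):
            simulate_dose_series(cfg, doses=[1.0],
                                 corr_shift_per_dose={("l001", "l002"): [0.5]})


def test_simtruth_roundtrip(tmp_path, small_cross):
    _, _, _, _, truth = small_cross
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = SimTruth.from_json(path)
    pd.testing.assert_frame_equal(
        truth.pair_truth.reset_index(drop=True), back.pair_truth)
    pd.testing.assert_frame_equal(truth.qtl.reset_index(drop=True), back.qtl)
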