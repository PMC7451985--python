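import numpy as np
import pytest

from pleioscope.simulate import QtlEffect, SimConfig, simulate_cells, simulate_cross


@pytest.fixture(scope="session")
def small_cross():
    """60-strain cross with one QTL of each mechanism; session-scoped."""
    config = SimConfig(
        n_strains=60, n_markers=20, n_chromosomes=4, chrom_length_cM=100.0,
        n_traits_per_celltype=(0, 0, 5), cells_per_strain=300, n_replicates=3,
        strain_var=0.05, plate_effect_sd=0.1, seed=101,
        qtl_spec=[
            QtlEffect("m3", "vertical", ("l001", "l002"), beta=0.15,
                      loadings=(1.0, 1.0)),
            QtlEffect("m8", "direct_horizontal", ("l003", "l004"), beta=0.3),
            QtlEffect("m14", "corr_modifying", ("l004", "l005"),
                      rho0=0.1, delta=0.6),
        ],
    )
    genotypes, marker_map = simulate_cross(config)
    cells, truth = simulate_cells(genotypes, config)
    return config, genotypes, marker_map, cells, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def hierarchical_pair(rng, J=8, n_per=25, rho_w=0.4, rho_b=0.2,
                      sd_b=1.0, sd_w=1.0):
    """Two traits with known between/within correlation structure."""
    cb = np.array([[1.0, rho_b], [rho_b, 1.0]])
    cw = np.array([[1.0, rho_w], [rho_w, 1.0]])
    ub = rng.multivariate_normal([0, 0], sd_b**2 * cb, size=J)
    x = np.empty(J * n_per)
    y = np.empty(J * n_per)
    groups = np.repeat(np.arange(J), n_per)
    for j in range(J):
        e = rng.multivariate_normal([0, 0], sd_w**2 * cw, size=n_per)
        x[groups == j] = ub[j, 0] + e[:, 0]
        y[groups == j] = ub[j, 1] + e[:, 1]
    return x, y, groups
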