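"""Within/between-strain partitioning of trait-pair correlations.

For hierarchical data (cells nested in strains), every observation of a trait
``x`` decomposes into a between-group deviation ``b_ij = xbar_j - xbar`` and a
within-group deviation ``w_ij = x_ij - xbar_j``. The Pearson correlation of
the b-scores of two traits over all observations is the between-strain
component ``r_B`` (the size-weighted correlation of strain means); the
correlation of the w-scores is the pooled within-strain component ``r_W``.
With ``eta_B = sqrt(SS_B / SS_total)`` and ``eta_W = sqrt(SS_W / SS_total)``
per trait, the total correlation obeys the exact identity

    r_total = eta_Bx * eta_By * r_B + eta_Wx * eta_Wy * r_W,
    eta_B**2 + eta_W**2 = 1.

For clonal strains, ``r_W`` estimates the environmental (inherent) trait
correlation and ``r_B`` the genetic one, so an excess of ``r_B`` over ``r_W``
is the signature of horizontal pleiotropy. The excess is tested on the
Fisher z scale with effective sample sizes J (strains) for ``r_B`` and N - J
for ``r_W``; magnitudes are compared, with ``|r_B|`` negated when the two
components disagree in sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "CorrPartition",
    "partition_pair",
    "compare_rB_rW",
    "critical_z",
    "sign_adjust",
    "partition_all",
    "pseudo_strain_null",
    "AceResult",
    "ace_max_correlation",
]

_ATANH_CAP = 1.0 - 1e-12


@dataclass
class CorrPartition:
    """Correlation decomposition for one trait pair."""

    pair: tuple[str, str]
    n_cells: int
    n_strains: int
    eta_b_x: float
    eta_w_x: float
    eta_b_y: float
    eta_w_y: float
    r_b: float
    r_w: float
    r_total: float
    z: float = np.nan
    p: float = np.nan
    significant: bool = False


def _scores(x: np.ndarray, codes: np.ndarray, n_groups: int):
    """Between/within deviation scores for one variable."""
    sums = np.bincount(codes, weights=x, minlength=n_groups)
    counts = np.bincount(codes, minlength=n_groups)
    means = sums / counts
    b = means[codes] - x.mean()
    w = x - means[codes]
    return b, w


def partition_pair(
    x: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: tuple[str, str] = ("x", "y"),
) -> CorrPartition:
    """Partition the correlation of paired cell-level measurements.

    ``x`` and ``y`` must be measured on the same cells; ``groups`` carries the
    strain label of each cell. Requires >= 2 groups with >= 2 observations
    each and nonzero within-group variance for both traits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    J = len(uniques)
    N = len(x)
    if not (len(y) == N == len(codes)):
        raise ValidationError("x, y and groups must have equal length")
    if J < 2:
        raise ValidationError("r_B undefined with a single group")
    if np.bincount(codes).min() < 2:
        raise ValidationError("every group needs >= 2 observations")

    bx, wx = _scores(x, codes, J)
    by, wy = _scores(y, codes, J)
    ss_x, ss_y = np.sum((x - x.mean()) ** 2), np.sum((y - y.mean()) ** 2)
    for name, w in zip(names, (wx, wy)):
        if np.allclose(w, 0):
            raise ValidationError(f"zero within-group variance for trait {name!r}")
    if ss_x == 0 or ss_y == 0:
        raise ValidationError("constant trait; correlation undefined")

    eta_b_x = float(np.sqrt(np.sum(bx**2) / ss_x))
    eta_w_x = float(np.sqrt(np.sum(wx**2) / ss_x))
    eta_b_y = float(np.sqrt(np.sum(by**2) / ss_y))
    eta_w_y = float(np.sqrt(np.sum(wy**2) / ss_y))
    r_b = _corr(bx, by)
    r_w = _corr(wx, wy)
    r_total = _corr(x - x.mean(), y - y.mean())
    return CorrPartition(
        pair=tuple(names), n_cells=N, n_strains=J,
        eta_b_x=eta_b_x, eta_w_x=eta_w_x, eta_b_y=eta_b_y, eta_w_y=eta_w_y,
        r_b=r_b, r_w=r_w, r_total=r_total,
    )


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.sqrt(np.sum(a * a)), np.sqrt(np.sum(b * b))
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.dot(a, b) / (sa * sb))


def sign_adjust(r_b, r_w):
    """Magnitude comparison convention: ``|r_W|``, and ``|r_B|`` negated when
    the two components have opposite signs."""
    r_b = np.asarray(r_b, dtype=float)
    r_w = np.asarray(r_w, dtype=float)
    opposite = np.sign(r_b) * np.sign(r_w) < 0
    return np.where(opposite, -np.abs(r_b), np.abs(r_b)), np.abs(r_w)


def critical_z(alpha: float = 0.01, m: int = 5645) -> float:
    """One-tailed normal quantile at the Bonferroni-corrected level alpha/m."""
    return float(stats.norm.isf(alpha / m))


def compare_rB_rW(
    part: CorrPartition, m: int = 5645, alpha: float = 0.01
) -> tuple[float, float, bool]:
    """Fisher r-to-z test of whether ``r_B`` exceeds ``r_W`` in magnitude.

    Effective sample sizes are J strains for the between component and
    N - J for the within component. Returns ``(z, one-tailed p,
    significant at the Bonferroni cutoff)`` and stores them on ``part``.
    """
    J, N = part.n_strains, part.n_cells
    if J < 4 or N - J < 4:
        raise ValidationError("need J >= 4 strains and N - J >= 4 cells for the z test")
    z = zscore_rB_vs_rW(part.r_b, part.r_w, J, N)
    p = float(stats.norm.sf(z))
    significant = bool(z > critical_z(alpha, m))
    part.z, part.p, part.significant = float(z), p, significant
    return float(z), p, significant


def zscore_rB_vs_rW(r_b, r_w, J, N):
    """Vectorized z statistic for r_B vs r_W (sign-adjusted magnitudes)."""
    rb_adj, rw_adj = sign_adjust(r_b, r_w)
    rb_adj = np.clip(rb_adj, -_ATANH_CAP, _ATANH_CAP)
    rw_adj = np.clip(rw_adj, -_ATANH_CAP, _ATANH_CAP)
    se = np.sqrt(1.0 / (np.asarray(J) - 3) + 1.0 / (np.asarray(N) - np.asarray(J) - 3))
    return (np.arctanh(rb_adj) - np.arctanh(rw_adj)) / se


# --------------------------------------------------------------------------
# all-pairs driver
# --------------------------------------------------------------------------

def _trait_columns(table: pd.DataFrame) -> list[str]:
    meta = {"cell_id", "strain", "replicate", "cell_type", "condition", "dose",
            "true_pseudotime", "pseudotime", "bin"}
    return [c for c in table.columns
            if c not in meta and pd.api.types.is_numeric_dtype(table[c])]


def partition_all(
    table: pd.DataFrame,
    alpha: float = 0.01,
    m: int | None = None,
    min_cells_per_strain: int = 2,
) -> pd.DataFrame:
    """Partition every within-cell-type trait pair of a cell table.

    Pairs are formed only among traits measured in the same cell type (traits
    of different types are never observed in the same cell). Returns one row
    per unordered pair with the full decomposition, the r_B-vs-r_W z test and
    its Bonferroni-corrected significance over all ``m`` pairs (``m`` defaults
    to the number of pairs tested).
    """
    records: list[dict] = []
    for ct, sub in table.groupby("cell_type", sort=True, observed=True):
        traits = [c for c in _trait_columns(sub) if sub[c].notna().all()]
        if len(traits) < 2:
            continue
        counts = sub.groupby("strain", observed=True).size()
        keep = counts[counts >= min_cells_per_strain].index
        sub = sub[sub["strain"].isin(keep)]
        if sub["strain"].nunique() < 2:
            continue
        X = sub[traits].to_numpy(dtype=float)
        codes, _ = pd.factorize(sub["strain"].to_numpy())
        J = codes.max() + 1
        N = len(sub)
        counts_vec = np.bincount(codes, minlength=J).astype(float)
        means = np.zeros((J, X.shape[1]))
        np.add.at(means, codes, X)
        means /= counts_vec[:, None]
        B = means[codes] - X.mean(axis=0)
        W = X - means[codes]
        ss_tot = ((X - X.mean(axis=0)) ** 2).sum(axis=0)
        ss_b = (B**2).sum(axis=0)
        ss_w = (W**2).sum(axis=0)
        eta_b = np.sqrt(ss_b / ss_tot)
        eta_w = np.sqrt(ss_w / ss_tot)
        r_b_mat = _corr_matrix(B)
        r_w_mat = _corr_matrix(W)
        r_tot_mat = _corr_matrix(X - X.mean(axis=0))
        iu, ju = np.triu_indices(len(traits), k=1)
        for i, j in zip(iu, ju):
            records.append(dict(
                cell_type=ct, trait_x=traits[i], trait_y=traits[j],
                n_cells=N, n_strains=int(J),
                eta_b_x=eta_b[i], eta_w_x=eta_w[i],
                eta_b_y=eta_b[j], eta_w_y=eta_w[j],
                r_b=r_b_mat[i, j], r_w=r_w_mat[i, j], r_total=r_tot_mat[i, j],
            ))
    out = pd.DataFrame(records)
    if out.empty:
        return out
    if m is None:
        m = len(out)
    out["z"] = zscore_rB_vs_rW(out["r_b"].to_numpy(), out["r_w"].to_numpy(),
                               out["n_strains"].to_numpy(), out["n_cells"].to_numpy())
    out["p"] = stats.norm.sf(out["z"])
    out["significant"] = out["z"] > critical_z(alpha, m)
    out.attrs["m"] = m
    out.attrs["alpha"] = alpha
    return out


def _corr_matrix(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0)
    sd = np.where(sd > 0, sd, np.nan)
    Mc = (M - M.mean(axis=0)) / sd
    return (Mc.T @ Mc) / len(M)


def pseudo_strain_null(
    table: pd.DataFrame,
    seed: int,
    n_reps: int = 1,
    alpha: float = 0.01,
    m: int | None = None,
) -> pd.DataFrame:
    """Re-partition after randomly reassigning cells to pseudo-strains.

    Within each cell type, strain labels are permuted across cells so the
    group-size multiset is preserved exactly while any genetic signal is
    destroyed. Returns the concatenated partition tables with a ``rep``
    column.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_reps):
        shuffled = table.copy()
        for _, idx in table.groupby("cell_type", observed=True).groups.items():
            labels = table.loc[idx, "strain"].to_numpy()
            shuffled.loc[idx, "strain"] = rng.permutation(labels)
        part = partition_all(shuffled, alpha=alpha, m=m)
        part["rep"] = rep
        out.append(part)
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------------
# ACE maximal correlation
# --------------------------------------------------------------------------

@dataclass
class AceResult:
    correlation: float
    x_grid: np.ndarray
    phi_grid: np.ndarray
    y_grid: np.ndarray
    theta_grid: np.ndarray
    converged: bool
    n_iter: int


def _bin_smooth(z: np.ndarray, target: np.ndarray, n_bins: int):
    """Estimate E[target | z] by equal-count binning with linear interpolation
    between bin centers (ends clamped). Returns (fitted, grid_z, grid_mean)."""
    order = np.argsort(z, kind="mergesort")
    splits = np.array_split(order, n_bins)
    grid_z = np.array([z[s].mean() for s in splits if len(s)])
    grid_m = np.array([target[s].mean() for s in splits if len(s)])
    # merge duplicate grid abscissae (heavy ties) to keep interp monotone
    if len(np.unique(grid_z)) != len(grid_z):
        dfg = pd.DataFrame({"z": grid_z, "m": grid_m}).groupby("z", as_index=False).mean()
        grid_z, grid_m = dfg["z"].to_numpy(), dfg["m"].to_numpy()
    fitted = np.interp(z, grid_z, grid_m)
    return fitted, grid_z, grid_m


def ace_max_correlation(
    x: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-5,
    n_bins: int = 50,
) -> AceResult:
    """Maximal correlation via alternating conditional expectations.

    Iterates theta(y) proportional to E[phi(x) | y] and phi(x) proportional to
    E[theta(y) | x] (each standardized), with conditional expectations
    estimated by an equal-count binned local-mean smoother. For a bivariate
    Gaussian the fixed point equals |rho| (Gebelein); for nonlinear
    dependence (e.g. y = x**2) it recovers the transform-achievable
    correlation that the Pearson coefficient misses.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 50:
        raise ValidationError("ACE needs at least 50 observations")

    def std(v):
        s = v.std()
        return (v - v.mean()) / (s if s > 0 else 1.0)

    theta = std(y)
    corr_prev = 0.0
    converged = False
    phi = std(x)
    for it in range(1, max_iter + 1):
        phi_raw, gx, gphi = _bin_smooth(x, theta, n_bins)
        phi = std(phi_raw)
        theta_raw, gy, gtheta = _bin_smooth(y, phi, n_bins)
        theta = std(theta_raw)
        corr = float(np.corrcoef(theta, phi)[0, 1])
        if abs(corr - corr_prev) < tol:
            converged = True
            break
        corr_prev = corr
    corr = abs(float(np.corrcoef(theta, phi)[0, 1]))
    return AceResult(
        correlation=corr,
        x_grid=gx, phi_grid=gphi, y_grid=gy, theta_grid=gtheta,
        converged=converged, n_iter=it,
    )
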