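"""Trait-by-trait QTL mapping for a homozygous recombinant panel.

Strains are modeled as doubled haploids with genotypes coded -1/+1, so the
Haley-Knott regression at a fully observed marker reduces to an ordinary
regression of the strain phenotype on the marker code, with

    LOD = -(n/2) * log10(1 - R^2).

Between markers, the expected genotype is computed from the flanking markers
through Haldane recombination fractions and used as the regressor.
Significance is assessed per trait against the empirical distribution of
genome-wide maximum LOD scores over phenotype permutations; across traits,
per-chromosome peak p-values are converted to Benjamini-Hochberg q-values.
Peaks within 5 cM on a chromosome are chained into a single locus whose
pleiotropy degree is the number of distinct traits it affects.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .simulate import haldane_fraction

__all__ = [
    "strain_phenotypes",
    "expected_genotypes",
    "hk_scan",
    "perm_threshold",
    "fdr_across_traits",
    "scan_all",
    "cluster_qtl",
    "effect_size",
]


def strain_phenotypes(
    table: pd.DataFrame, per_replicate: bool = False
) -> pd.DataFrame:
    """Strain x trait matrix of mean trait values over each strain's cells.

    Traits not measured in a cell (other cell types) are skipped via NaN
    means. With ``per_replicate=True`` the index is (strain, replicate).
    """
    meta = {"cell_id", "strain", "replicate", "cell_type", "condition", "dose",
            "true_pseudotime", "pseudotime", "bin"}
    traits = [c for c in table.columns
              if c not in meta and pd.api.types.is_numeric_dtype(table[c])]
    keys = ["strain", "replicate"] if per_replicate else ["strain"]
    return table.groupby(keys, observed=True)[traits].mean()


# --------------------------------------------------------------------------
# expected genotypes along the map
# --------------------------------------------------------------------------

def expected_genotypes(
    genotypes: pd.DataFrame, marker_map: pd.DataFrame, step_cM: float = 0.0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Expected -1/+1 genotype at every marker and (optionally) pseudomarker.

    Returns ``(X, positions)`` where ``X`` is strains x positions and
    ``positions`` has columns (chromosome, position_cM, marker) with
    ``marker`` empty for pseudomarkers. ``step_cM = 0`` scans markers only.
    """
    n = len(genotypes)
    cols: list[np.ndarray] = []
    rows: list[tuple] = []
    for chrom, grp in marker_map.groupby("chromosome", sort=True):
        pos = grp["position_cM"].to_numpy(dtype=float)
        if np.any(np.diff(pos) < 0):
            raise ValidationError(f"marker positions not sorted on chromosome {chrom}")
        G = genotypes[grp["marker"].tolist()].to_numpy(dtype=float)
        grid = list(pos)
        if step_cM > 0 and len(pos) > 1:
            extra = np.arange(pos[0], pos[-1], step_cM)
            grid = sorted(set(np.round(np.concatenate([pos, extra]), 9)))
        for p in grid:
            j = int(np.searchsorted(pos, p))
            if j < len(pos) and np.isclose(pos[j], p):
                cols.append(G[:, j])
                rows.append((chrom, float(p), grp["marker"].iloc[j]))
                continue
            # strictly between markers j-1 and j
            gl, gr = G[:, j - 1], G[:, j]
            r_l = haldane_fraction(p - pos[j - 1])
            r_r = haldane_fraction(pos[j] - p)
            r_lr = haldane_fraction(pos[j] - pos[j - 1])
            same = gl == gr
            p_same = (1 - r_l) * (1 - r_r) / (1 - r_lr)
            p_left = (1 - r_l) * r_r / r_lr if r_lr > 0 else 0.5
            e = np.where(same, gl * (2 * p_same - 1), gl * (2 * p_left - 1))
            cols.append(e)
            rows.append((chrom, float(p), ""))
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    positions = pd.DataFrame(rows, columns=["chromosome", "position_cM", "marker"])
    return X, positions


def _residualize(v: np.ndarray, covar: np.ndarray) -> np.ndarray:
    """Residuals of v on [1, covar] via least squares (v may be 2-D)."""
    beta, *_ = np.linalg.lstsq(covar, v, rcond=None)
    return v - covar @ beta


def _lod_matrix(X: np.ndarray, Y: np.ndarray, covariate: np.ndarray | None = None):
    """LOD for every (position, phenotype) pair.

    X: n x P expected genotypes; Y: n x T phenotypes. Both are residualized
    on the intercept (and optional covariate); LOD is the single-regressor
    Haley-Knott form on the residuals.
    """
    n = X.shape[0]
    ones = np.ones((n, 1))
    C = ones if covariate is None else np.column_stack([ones, covariate])
    Xr = _residualize(X, C)
    Yr = _residualize(Y, C)
    sx = np.sqrt((Xr**2).sum(axis=0))
    sy = np.sqrt((Yr**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xr.T @ Yr) / np.outer(sx, sy)
    corr = np.nan_to_num(corr, nan=0.0)
    r2 = np.clip(corr**2, 0.0, 1.0 - 1e-15)
    monomorphic = sx == 0
    if monomorphic.any():
        warnings.warn("monomorphic marker region; LOD set to 0", stacklevel=2)
        r2[monomorphic, :] = 0.0
    return -(n / 2.0) * np.log10(1.0 - r2)


def hk_scan(
    phenotype: pd.Series | np.ndarray,
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    step_cM: float = 0.0,
    covariate: np.ndarray | None = None,
) -> pd.DataFrame:
    """Genome scan of one phenotype; returns the LOD curve as a DataFrame
    with columns (chromosome, position_cM, marker, lod).

    ``covariate`` (e.g. the expected genotype at a detected peak) supports a
    conditional second-QTL scan: the reported LOD is then the gain of adding
    each position to the covariate model.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(genotypes):
        raise ValidationError("phenotype not aligned to genotype rows")
    X, positions = expected_genotypes(genotypes, marker_map, step_cM)
    lod = _lod_matrix(X, y[:, None], covariate)
    out = positions.copy()
    out["lod"] = lod[:, 0]
    return out


def perm_threshold(
    phenotype: pd.Series | np.ndarray,
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step_cM: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Permutation threshold for the genome-wide maximum LOD.

    Shuffles the phenotype over strains ``n_perm`` times and returns the
    ``(1 - alpha)`` quantile of the null maxima together with the null
    distribution itself. P-values for observed peaks follow the plus-one
    rule ``(1 + #{null >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValidationError("need n_perm >= 100")
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(seed)
    X, _ = expected_genotypes(genotypes, marker_map, step_cM)
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    lod = _lod_matrix(X, perms)
    null_max = lod.max(axis=0) if lod.size else np.zeros(n_perm)
    threshold = float(np.quantile(null_max, 1.0 - alpha))
    return threshold, null_max


def perm_pvalue(observed_lod: float, null_max: np.ndarray) -> float:
    return float((1 + np.sum(null_max >= observed_lod)) / (len(null_max) + 1))


def fdr_across_traits(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg q-values over the pooled per-trait per-chromosome
    peak p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def scan_all(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step_cM: float = 0.0,
    parental_means: pd.DataFrame | None = None,
    return_all_peaks: bool = False,
) -> pd.DataFrame:
    """Scan every trait; returns the QTL hit table.

    One row per (trait, chromosome) peak exceeding that trait's permutation
    threshold, with columns (trait, chromosome, position_cM, marker, lod,
    perm_p, q, effect_size, allele_direction). q-values are BH over all
    per-trait per-chromosome peaks (hit or not), significant hits satisfy
    ``perm_p <= alpha``.
    """
    traits = list(phenotypes.columns)
    common = phenotypes.index.intersection(genotypes.index)
    phenos = phenotypes.loc[common]
    genos = genotypes.loc[common]
    X, positions = expected_genotypes(genos, marker_map, step_cM)
    Y = phenos[traits].to_numpy(dtype=float)
    # complete-case per trait handled by dropping NaN rows trait-wise
    rng = np.random.default_rng(seed)
    peak_rows: list[dict] = []
    for t_i, trait in enumerate(traits):
        y = Y[:, t_i]
        mask = np.isfinite(y)
        yv = y[mask]
        Xv = X[mask]
        n = mask.sum()
        if n < 10 or np.std(yv) == 0:
            continue
        lod = _lod_matrix(Xv, yv[:, None])[:, 0]
        perms = np.column_stack([rng.permutation(yv) for _ in range(n_perm)])
        null_max = _lod_matrix(Xv, perms).max(axis=0)
        threshold = float(np.quantile(null_max, 1.0 - alpha))
        for chrom in positions["chromosome"].unique():
            sel = positions["chromosome"] == chrom
            idx = np.flatnonzero(sel.to_numpy())
            best = idx[np.argmax(lod[idx])]
            peak_lod = float(lod[best])
            p = perm_pvalue(peak_lod, null_max)
            g = Xv[:, best]
            hi, lo = yv[g > 0], yv[g < 0]
            direction = float(np.sign(hi.mean() - lo.mean())) if len(hi) and len(lo) else 0.0
            eff = np.nan
            if parental_means is not None and trait in parental_means.columns:
                pdiff = float(parental_means[trait].iloc[0] - parental_means[trait].iloc[1])
                eff = effect_size(yv, g, pdiff)
            peak_rows.append(dict(
                trait=trait, chromosome=chrom,
                position_cM=float(positions.loc[best, "position_cM"]),
                marker=positions.loc[best, "marker"],
                lod=peak_lod, threshold=threshold, perm_p=p,
                effect_size=eff, allele_direction=direction,
                detected=peak_lod >= threshold,
            ))
    peaks = pd.DataFrame(peak_rows)
    if peaks.empty:
        return (peaks, peaks) if return_all_peaks else peaks
    peaks["q"] = fdr_across_traits(peaks["perm_p"].to_numpy())
    hits = peaks[peaks["detected"]].reset_index(drop=True)
    return (hits, peaks) if return_all_peaks else hits


def cluster_qtl(
    hits: pd.DataFrame, gap_cM: float = 5.0, span_warning_cM: float = 17.0
) -> pd.DataFrame:
    """Chain per-chromosome peaks into loci.

    Peaks on the same chromosome are sorted by position and chained into one
    cluster while consecutive gaps are <= ``gap_cM``; a gap larger than that
    starts a new cluster. Dense runs (all gaps <= 2 cM) are by construction
    never broken. Returns one row per cluster with its span, member hits and
    pleiotropy degree (number of distinct traits). A cluster spanning more
    than ``span_warning_cM`` triggers a warning and a flag.
    """
    if hits.empty:
        return pd.DataFrame(columns=["cluster", "chromosome", "start_cM", "end_cM",
                                     "span_cM", "n_hits", "degree", "traits",
                                     "span_flag"])
    rows = []
    cid = 0
    for chrom, grp in hits.groupby("chromosome", sort=True):
        grp = grp.sort_values("position_cM")
        pos = grp["position_cM"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > gap_cM)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            members = grp.iloc[s:e + 1]
            span = float(pos[e] - pos[s])
            flag = span > span_warning_cM
            if flag:
                warnings.warn(
                    f"QTL cluster on chromosome {chrom} spans {span:.1f} cM "
                    f"(> {span_warning_cM} cM sanity bound)", stacklevel=2)
            cid += 1
            rows.append(dict(
                cluster=f"Q{cid}", chromosome=chrom,
                start_cM=float(pos[s]), end_cM=float(pos[e]), span_cM=span,
                n_hits=len(members), degree=members["trait"].nunique(),
                traits=";".join(sorted(members["trait"].unique())),
                span_flag=flag,
            ))
    return pd.DataFrame(rows)


def effect_size(
    phenotype: np.ndarray, genotype: np.ndarray, parental_difference: float
) -> float:
    """QTL effect as a fraction of the parental trait difference.

    The allele-substitution effect is the difference of allele-group means;
    the fraction is its magnitude over the magnitude of the parental
    difference (NaN when the parents do not differ).
    """
    if parental_difference == 0 or not np.isfinite(parental_difference):
        return np.nan
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    hi, lo = y[g > 0], y[g < 0]
    if len(hi) == 0 or len(lo) == 0:
        return np.nan
    return float(abs(hi.mean() - lo.mean()) / abs(parental_difference))
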