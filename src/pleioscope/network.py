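"""Vertical/horizontal classification of trait pairs and the r_W network.

A pair is a *vertical-consistent* candidate when the traits correlate within
clonal populations (|r_W| above threshold) and share at least one QTL — the
genetic effect propagates through an inherent coupling. A pair is a
*horizontal* candidate when its between-strain correlation significantly
exceeds the within-strain one, i.e. genetic variation induces or strengthens
the correlation. The r_W magnitudes also define a fully connected weighted
graph over the traits of one cell type whose clustering structure is compared
against permutation nulls that reshuffle the same edge-weight multiset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "classify_pairs",
    "enrichment_summary",
    "rw_matrix",
    "weighted_clustering",
    "network_permutation_null",
    "NetworkNull",
]


def _cluster_trait_sets(clusters: pd.DataFrame) -> list[set[str]]:
    return [set(t.split(";")) for t in clusters["traits"]] if len(clusters) else []


def classify_pairs(
    partitions: pd.DataFrame,
    clusters: pd.DataFrame,
    rw_threshold: float = 0.2,
) -> pd.DataFrame:
    """Attach shared-QTL counts and pleiotropy categories to each pair.

    Categories: ``vertical-consistent`` (|r_W| > threshold, >= 1 shared QTL,
    r_B not significantly greater), ``horizontal-candidate`` (r_B
    significantly > r_W), ``both``, ``neither``.
    """
    known = set(partitions["trait_x"]) | set(partitions["trait_y"])
    trait_sets = _cluster_trait_sets(clusters)
    for s in trait_sets:
        unknown = s - known
        if unknown:
            raise ValidationError(f"cluster traits not in partition table: {unknown}")
    out = partitions.copy()
    shared = [
        sum(1 for s in trait_sets if x in s and y in s)
        for x, y in zip(out["trait_x"], out["trait_y"])
    ]
    out["shared_qtl"] = shared
    high_rw = out["r_w"].abs() > rw_threshold
    vert = high_rw & (out["shared_qtl"] >= 1) & ~out["significant"]
    horiz = out["significant"].astype(bool)
    both = high_rw & (out["shared_qtl"] >= 1) & horiz
    cat = np.select(
        [both, vert, horiz],
        ["both", "vertical-consistent", "horizontal-candidate"],
        default="neither",
    )
    out["category"] = cat
    return out


def enrichment_summary(calls: pd.DataFrame, rw_threshold: float = 0.2) -> dict:
    """Summary statistics linking shared-QTL counts to r_W.

    Reports the fraction of high-r_W vs low-r_W pairs sharing at least one
    QTL, the Pearson correlation between a pair's shared-QTL count and its
    |r_W| (NaN when all counts are equal), and the fraction of pairs with
    r_B significantly above r_W overall and among QTL-sharing pairs.
    """
    if len(calls) < 2:
        raise ValidationError("enrichment summary needs >= 2 pairs")
    rw = calls["r_w"].abs()
    high = rw > rw_threshold
    shares = calls["shared_qtl"] >= 1
    corr = np.nan
    if calls["shared_qtl"].nunique() > 1 and rw.nunique() > 1:
        corr = float(np.corrcoef(calls["shared_qtl"], rw)[0, 1])
    return dict(
        n_pairs=len(calls),
        frac_high_rw_sharing=float(shares[high].mean()) if high.any() else np.nan,
        frac_low_rw_sharing=float(shares[~high].mean()) if (~high).any() else np.nan,
        corr_sharedqtl_rw=corr,
        frac_significant=float(calls["significant"].mean()),
        frac_significant_sharing=(
            float(calls.loc[shares, "significant"].mean()) if shares.any() else np.nan),
    )


def rw_matrix(partitions: pd.DataFrame, cell_type: str) -> tuple[list[str], np.ndarray]:
    """Symmetric |r_W| weight matrix over the traits of one cell type."""
    sub = partitions[partitions["cell_type"] == cell_type]
    traits = sorted(set(sub["trait_x"]) | set(sub["trait_y"]))
    idx = {t: i for i, t in enumerate(traits)}
    W = np.zeros((len(traits), len(traits)))
    for x, y, r in zip(sub["trait_x"], sub["trait_y"], sub["r_w"]):
        W[idx[x], idx[y]] = W[idx[y], idx[x]] = abs(r)
    return traits, W


def weighted_clustering(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted clustering coefficient per node of a complete weighted graph.

    With weights normalized by the maximum, ``w_hat = w / max(w)``,

        wcc_i = sum_{j != k} w_hat_ij w_hat_jk w_hat_ki
                / ((sum_j w_hat_ij)^2 - sum_j w_hat_ij^2)

    which lies in [0, 1] for nonnegative weights. Nodes with a degenerate
    denominator (isolated, or fewer than two weighted neighbors) get wcc = 0
    and are flagged. Returns ``(wcc, flagged)``.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError("weights must be a square matrix")
    if np.any(W < 0):
        raise ValidationError("negative edge weight; pass magnitudes")
    if np.any(np.diag(W) != 0):
        raise ValidationError("diagonal must be zero")
    if not np.allclose(W, W.T):
        raise ValidationError("weights must be symmetric")
    mx = W.max()
    if mx == 0:
        return np.zeros(len(W)), np.ones(len(W), dtype=bool)
    Wh = W / mx
    numer = np.diag(np.linalg.matrix_power(Wh, 3))
    s1 = Wh.sum(axis=1)
    s2 = (Wh**2).sum(axis=1)
    denom = s1**2 - s2
    flagged = denom <= 1e-12
    wcc = np.where(flagged, 0.0, numer / np.where(flagged, 1.0, denom))
    return wcc, flagged


@dataclass
class NetworkNull:
    observed: np.ndarray          # wcc per node, observed weights
    null: np.ndarray              # n_perm x n_nodes wcc under permutation
    exceed_fraction: float        # fraction of perms whose mean wcc >= observed mean


def network_permutation_null(
    weights: np.ndarray, n_perm: int = 100, seed: int = 0
) -> NetworkNull:
    """Compare observed wcc to nulls that reshuffle the edge-weight multiset.

    Each permutation samples the off-diagonal weights without replacement and
    reassigns them to random trait pairs, preserving the weight distribution
    while destroying any clustering structure.
    """
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = W[iu]
    rng = np.random.default_rng(seed)
    observed, _ = weighted_clustering(W)
    null = np.empty((n_perm, n))
    for p in range(n_perm):
        perm = rng.permutation(vals)
        M = np.zeros_like(W)
        M[iu] = perm
        M = M + M.T
        null[p], _ = weighted_clustering(M)
    exceed = float(np.mean(null.mean(axis=1) >= observed.mean()))
    return NetworkNull(observed=observed, null=null, exceed_fraction=exceed)
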