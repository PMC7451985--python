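"""Ordering cells along the division cycle and re-partitioning per stage.

Fixed-cell snapshots of an asynchronous exponentially growing culture sample
the whole division cycle; a cell's morphology encodes its progression. The
ordering here is a single-branch diffusion pseudotime: standardize the
traits, build a k-nearest-neighbor graph, take the leading nontrivial
eigenvector of the normalized graph adjacency (the first diffusion-map
coordinate), orient it so an anchor "start" cell sits near 0, and rescale
ranks to [0, 1].

Cells are then split per strain into equal-count pseudotime bins and like
bins are merged across strains, holding genotype representation constant per
bin, so the within-strain correlation r_W can be recomputed at fixed
cell-cycle stage. The fraction of an r_B-over-r_W discrepancy recovered by
the best bin is the pair's percent-resolved score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError
from .partition import partition_all, sign_adjust

__all__ = [
    "infer_pseudotime",
    "bin_cells",
    "per_bin_partition",
    "percent_resolved",
]

_META = {"cell_id", "strain", "replicate", "cell_type", "condition", "dose",
         "true_pseudotime", "pseudotime", "bin"}


def _trait_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns
            if c not in _META and pd.api.types.is_numeric_dtype(table[c])]


def infer_pseudotime(
    table: pd.DataFrame,
    cell_type: str,
    anchor: int | dict[str, str],
    k: int = 30,
) -> pd.Series:
    """Pseudotime in [0, 1] for every cell of ``cell_type``.

    ``anchor`` selects the start cell: either a ``cell_id`` or a mapping of
    trait names to ``"min"``/``"max"`` (the cell extremizing the summed
    standardized criteria). The anchored end of the ordering gets pseudotime
    0; reversing the anchor reverses the ordering (pt -> 1 - pt). Returns a
    Series indexed by ``cell_id``.
    """
    sub = table[table["cell_type"] == cell_type]
    traits = [c for c in _trait_cols(sub) if sub[c].notna().all()]
    n = len(sub)
    if n < 200:
        raise ValidationError(f"need >= 200 cells of type {cell_type!r}")
    X = sub[traits].to_numpy(dtype=float)
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    k_eff = min(k, n - 1)
    while True:
        nn = NearestNeighbors(n_neighbors=k_eff).fit(X)
        A = nn.kneighbors_graph(X, mode="connectivity")
        A = ((A + A.T) > 0).astype(float)
        A = csr_matrix(A)
        n_comp, _ = connected_components(A, directed=False)
        if n_comp == 1 or k_eff >= n - 1:
            break
        k_eff = min(2 * k_eff, n - 1)
        warnings.warn(f"kNN graph disconnected; increasing k to {k_eff}", stacklevel=2)

    deg = np.asarray(A.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    M = A.multiply(d_inv_sqrt[:, None]).multiply(d_inv_sqrt[None, :])
    v0 = np.full(n, 1.0 / np.sqrt(n))
    vals, vecs = eigsh(csr_matrix(M), k=2, which="LA", v0=v0)
    lead = vecs[:, np.argsort(vals)[0]]  # second-largest eigenvalue
    coord = lead * d_inv_sqrt  # diffusion-map coordinate

    # anchor orientation
    if isinstance(anchor, dict):
        score = np.zeros(n)
        for t, how in anchor.items():
            col = sub[t].to_numpy(dtype=float)
            zs = (col - col.mean()) / (col.std() or 1.0)
            score += zs if how == "min" else -zs
        a_idx = int(np.argmin(score))
    else:
        pos = np.flatnonzero(sub["cell_id"].to_numpy() == anchor)
        if len(pos) == 0:
            raise ValidationError(f"anchor cell_id {anchor} not found")
        a_idx = int(pos[0])

    ranks = np.argsort(np.argsort(coord, kind="mergesort"), kind="mergesort")
    if ranks[a_idx] > (n - 1) / 2:
        ranks = (n - 1) - ranks
    pt = ranks / (n - 1)
    return pd.Series(pt, index=sub["cell_id"].to_numpy(), name="pseudotime")


def bin_cells(
    table: pd.DataFrame,
    pseudotime: pd.Series,
    n_bins: int = 16,
) -> pd.DataFrame:
    """Assign cells to equal-count pseudotime bins, separately per strain.

    Binning within each strain (and cell type) before merging like bins
    keeps genotype representation constant across bins. Strains with fewer
    than ``n_bins`` cells of the type are excluded (logged via warning).
    Returns the table restricted to binned cells with ``pseudotime`` and
    ``bin`` columns added.
    """
    out = table.copy()
    out["pseudotime"] = out["cell_id"].map(pseudotime)
    out = out[out["pseudotime"].notna()]
    keep_frames = []
    for (strain, ct), grp in out.groupby(["strain", "cell_type"], observed=True):
        m = len(grp)
        if m < n_bins:
            warnings.warn(
                f"strain {strain!r} has {m} < {n_bins} cells of type {ct!r}; excluded",
                stacklevel=2)
            continue
        order = np.argsort(grp["pseudotime"].to_numpy(), kind="mergesort")
        bins = np.empty(m, dtype=int)
        # equal-count split: bin sizes differ by at most 1
        edges = np.linspace(0, m, n_bins + 1).round().astype(int)
        for b in range(n_bins):
            bins[order[edges[b]:edges[b + 1]]] = b
        grp = grp.copy()
        grp["bin"] = bins
        keep_frames.append(grp)
    if not keep_frames:
        raise ValidationError("no strain had enough cells to bin")
    return pd.concat(keep_frames, ignore_index=True)


def per_bin_partition(
    binned: pd.DataFrame,
    n_bins: int | None = None,
    alpha: float = 0.01,
    m: int | None = None,
) -> pd.DataFrame:
    """Correlation partitioning within each pseudotime bin.

    Returns one row per trait pair with the unbinned r_W/r_B (computed on the
    binned cells pooled), per-bin r_W columns ``rw_bin_00..``, the best bin
    and the percent of the r_B-over-r_W discrepancy it resolves. Degenerate
    bins yield NaN for that bin.
    """
    if n_bins is None:
        n_bins = int(binned["bin"].max()) + 1
    overall = partition_all(binned, alpha=alpha, m=m)
    key = ["cell_type", "trait_x", "trait_y"]
    overall = overall.set_index(key)
    per_bin = {}
    for b in range(n_bins):
        part = partition_all(binned[binned["bin"] == b], alpha=alpha, m=m)
        per_bin[b] = (part.set_index(key)["r_w"] if len(part) else pd.Series(dtype=float))
    out = overall.reset_index()
    for b in range(n_bins):
        out[f"rw_bin_{b:02d}"] = out.set_index(key).index.map(per_bin[b]).to_numpy()
    bin_cols = [f"rw_bin_{b:02d}" for b in range(n_bins)]
    bins_mat = out[bin_cols].to_numpy(dtype=float)
    res, best = [], []
    for i in range(len(out)):
        pr, bb = percent_resolved(out.loc[i, "r_b"], out.loc[i, "r_w"], bins_mat[i])
        res.append(pr)
        best.append(bb)
    out["percent_resolved"] = res
    out["best_bin"] = best
    return out


def percent_resolved(
    r_b: float, r_w: float, rw_bins: np.ndarray
) -> tuple[float, int]:
    """Fraction of the r_B-over-r_W discrepancy recovered by the best bin.

    Magnitudes are sign-adjusted (|r| with the between component negated on
    sign disagreement). Requires the adjusted r_B to exceed the adjusted
    r_W; otherwise the pair has no discrepancy to resolve and NaN is
    returned. The score is floored at 0 (binning that only worsens the
    discrepancy counts as 0% resolution) and capped at 100.
    """
    rb_adj, rw_adj = sign_adjust(r_b, r_w)
    rb_adj, rw_adj = float(rb_adj), float(rw_adj)
    if not rb_adj > rw_adj:
        return np.nan, -1
    rw_bins = np.asarray(rw_bins, dtype=float)
    adj_bins = np.where(np.sign(rw_bins) == np.sign(r_b) if np.sign(r_b) != 0 else True,
                        np.abs(rw_bins), -np.abs(rw_bins))
    adj_bins = np.where(np.isfinite(rw_bins), adj_bins, -np.inf)
    if not np.any(np.isfinite(adj_bins) & (adj_bins > -np.inf)):
        return np.nan, -1
    best = int(np.argmax(adj_bins))
    pct = 100.0 * max(0.0, (adj_bins[best] - rw_adj) / (rb_adj - rw_adj))
    return float(min(pct, 100.0)), best
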