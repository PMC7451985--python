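"""Allele splits: eliminating genetic variation at a QTL's marker.

For a pleiotropic locus, strains are divided by the allele they carry at the
cluster's most-represented marker and correlation partitioning is repeated
within each subset. If the locus causes horizontal pleiotropy by jointly
shifting two trait means, r_B drops in *both* allele subsets (the correlation
was strongest in the mixed population). If instead one allele strengthens
the coupling between the traits, r_B drops in only *one* subset — the one
where that allele is absent retains the weak coupling. The size of each
drop is compared against a noise band from random strain bisections of
matching sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .partition import partition_all, sign_adjust

__all__ = [
    "select_split_marker",
    "split_and_repartition",
    "split_noise_band",
    "classify_mode",
    "allele_split_analysis",
]


def select_split_marker(
    cluster: pd.Series | dict, hits: pd.DataFrame, marker_map: pd.DataFrame
) -> str:
    """The marker nearest the largest number of the cluster's member hits.

    Each member hit is matched to its nearest genotyped marker on the
    cluster's chromosome; the most frequent such marker wins, with ties
    broken toward the smaller map position.
    """
    chrom = cluster["chromosome"]
    members = hits[(hits["chromosome"] == chrom)
                   & (hits["position_cM"] >= cluster["start_cM"] - 1e-9)
                   & (hits["position_cM"] <= cluster["end_cM"] + 1e-9)]
    if len(members) == 0:
        raise ValidationError("cluster has no member hits")
    mm = marker_map[marker_map["chromosome"] == chrom]
    mpos = mm["position_cM"].to_numpy()
    mnames = mm["marker"].to_numpy()
    nearest = [mnames[np.argmin(np.abs(mpos - p))] for p in members["position_cM"]]
    counts = pd.Series(nearest).value_counts()
    top = counts[counts == counts.max()].index
    if len(top) == 1:
        return str(top[0])
    pos_of = dict(zip(mnames, mpos))
    return str(min(top, key=lambda m: pos_of[m]))


def split_and_repartition(
    table: pd.DataFrame,
    genotypes: pd.DataFrame,
    marker: str,
    pairs: pd.DataFrame | None = None,
    alpha: float = 0.01,
    m: int | None = None,
    min_strains: int = 4,
) -> pd.DataFrame:
    """Re-partition trait correlations within each allele subset at ``marker``.

    Returns one row per trait pair with the all-strain r_B/r_W, the per-subset
    values, and the per-subset drop ``delta_rb = r_B*(all) - r_B*(subset)``
    (sign-adjusted magnitudes, the all-strain r_W providing the reference
    sign). ``pairs`` optionally restricts to a subset of (trait_x, trait_y)
    rows. A subset with fewer than ``min_strains`` strains raises.
    """
    if marker not in genotypes.columns:
        raise ValidationError(f"marker {marker!r} not in genotype table")
    allele = genotypes[marker]
    plus = set(allele.index[allele > 0])
    minus = set(allele.index[allele < 0])
    if len(plus) < min_strains or len(minus) < min_strains:
        raise ValidationError(
            f"allele subset at {marker} too small ({len(plus)}/{len(minus)} strains)")
    key = ["cell_type", "trait_x", "trait_y"]
    full = partition_all(table, alpha=alpha, m=m)
    sub_p = partition_all(table[table["strain"].isin(plus)], alpha=alpha, m=m)
    sub_m = partition_all(table[table["strain"].isin(minus)], alpha=alpha, m=m)
    out = full.set_index(key)
    for tag, sub in (("plus", sub_p), ("minus", sub_m)):
        sub = sub.set_index(key)
        out[f"r_b_{tag}"] = sub["r_b"]
        out[f"r_w_{tag}"] = sub["r_w"]
    out = out.reset_index()
    if pairs is not None:
        sel = pd.MultiIndex.from_frame(out[["trait_x", "trait_y"]]).isin(
            pd.MultiIndex.from_frame(pairs[["trait_x", "trait_y"]]))
        out = out[sel].reset_index(drop=True)
    rb_all, _ = sign_adjust(out["r_b"].to_numpy(), out["r_w"].to_numpy())
    for tag in ("plus", "minus"):
        rb_sub, _ = sign_adjust(out[f"r_b_{tag}"].to_numpy(), out["r_w"].to_numpy())
        out[f"delta_rb_{tag}"] = rb_all - rb_sub
        rw_sub = np.abs(out[f"r_w_{tag}"].to_numpy())
        out[f"delta_rw_{tag}"] = np.abs(out["r_w"].to_numpy()) - rw_sub
    out["marker"] = marker
    return out


def split_noise_band(
    table: pd.DataFrame,
    n_plus: int,
    n_minus: int,
    n_boot: int = 200,
    seed: int = 0,
    quantile: float = 0.95,
    pairs: pd.DataFrame | None = None,
) -> float:
    """Noise band for r_B drops: the ``quantile`` of |delta r_B| over random
    strain bisections of the given subset sizes (no genetic signal at any
    particular locus is aligned with a random bisection)."""
    strains = np.asarray(sorted(table["strain"].unique()))
    if n_plus + n_minus > len(strains):
        raise ValidationError("subset sizes exceed the number of strains")
    rng = np.random.default_rng(seed)
    key = ["cell_type", "trait_x", "trait_y"]
    full = partition_all(table)
    if pairs is not None:
        sel = pd.MultiIndex.from_frame(full[["trait_x", "trait_y"]]).isin(
            pd.MultiIndex.from_frame(pairs[["trait_x", "trait_y"]]))
        full = full[sel]
    full = full.set_index(key)
    rb_all, _ = sign_adjust(full["r_b"].to_numpy(), full["r_w"].to_numpy())
    deltas = []
    for _ in range(n_boot):
        perm = rng.permutation(strains)
        for size, grp in ((n_plus, perm[:n_plus]), ((n_minus), perm[n_plus:n_plus + n_minus])):
            part = partition_all(table[table["strain"].isin(grp)]).set_index(key)
            part = part.reindex(full.index)
            rb_sub, _ = sign_adjust(part["r_b"].to_numpy(),
                                    full["r_w"].to_numpy())
            deltas.append(np.abs(rb_all - rb_sub))
    return float(np.nanquantile(np.concatenate(deltas), quantile))


def classify_mode(
    delta_plus: float, delta_minus: float, noise_band: float
) -> str:
    """Mode of a horizontal-pleiotropy signal at one locus for one pair.

    ``both-drop``: r_B falls beyond the noise band in both allele subsets
    (the locus jointly shifts the traits, so the mixed population carries the
    correlation). ``one-drop``: the fall is confined to one subset (one
    allele strengthens the trait coupling). ``none`` otherwise.
    """
    p = delta_plus > noise_band
    q = delta_minus > noise_band
    if p and q:
        return "both-drop"
    if p or q:
        return "one-drop"
    return "none"


def allele_split_analysis(
    table: pd.DataFrame,
    genotypes: pd.DataFrame,
    clusters: pd.DataFrame,
    hits: pd.DataFrame,
    marker_map: pd.DataFrame,
    noise_band: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
    pairs: pd.DataFrame | None = None,
    alpha: float = 0.01,
    m: int | None = None,
) -> pd.DataFrame:
    """Run the allele split for every QTL cluster and classify its mode.

    Adds ``percent_resolved``: how much of the r_B-over-r_W discrepancy the
    best allele subset removes, 100 * max(0, delta_rb / (r_B* - r_W*)).
    """
    frames = []
    for _, cluster in clusters.iterrows():
        marker = select_split_marker(cluster, hits, marker_map)
        try:
            res = split_and_repartition(table, genotypes, marker, pairs=pairs,
                                        alpha=alpha, m=m)
        except ValidationError:
            continue
        if noise_band is None:
            allele = genotypes[marker]
            band = split_noise_band(
                table, int((allele > 0).sum()), int((allele < 0).sum()),
                n_boot=n_boot, seed=seed, pairs=pairs)
        else:
            band = noise_band
        res["noise_band"] = band
        res["mode"] = [
            classify_mode(dp, dm, band)
            for dp, dm in zip(res["delta_rb_plus"], res["delta_rb_minus"])
        ]
        rb_adj, rw_adj = sign_adjust(res["r_b"].to_numpy(), res["r_w"].to_numpy())
        gap = rb_adj - rw_adj
        best = np.maximum(res["delta_rb_plus"], res["delta_rb_minus"])
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * np.clip(best / gap, 0.0, 1.0)
        res["percent_resolved"] = np.where(gap > 0, pct, np.nan)
        res["cluster"] = cluster["cluster"]
        frames.append(res)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
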