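"""Context dependence of trait correlations: MA lines and drug gradients.

Mutation-accumulation (MA) lines carry a handful of private spontaneous
mutations each, so their within-line trait correlations should agree up to
sampling noise — unless a rare mutation alters a correlation. Each line's
per-pair Pearson correlation is scored in standard deviations from the
leave-one-out mean of the other lines; scores beyond 4 SD flag candidate
correlation-altering mutations.

For a drug gradient, the within-strain correlation r_W in each drug
condition is compared to a paired drug-free control; the distribution of
|delta r_W| per dose, against a replicate-vs-replicate null, shows whether
(and how strongly) the environment reshapes the correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .partition import partition_all

__all__ = [
    "MaLineStats",
    "ma_pair_correlations",
    "flag_outliers",
    "dose_delta",
]

_META = {"cell_id", "strain", "replicate", "cell_type", "condition", "dose",
         "true_pseudotime", "pseudotime", "bin"}


@dataclass
class MaLineStats:
    """Per-line pair correlations and leave-one-out deviation scores."""

    correlations: pd.DataFrame   # line x pair matrix of Pearson r
    scores: pd.DataFrame         # same shape, leave-one-out z scores
    pair_info: pd.DataFrame      # pair -> (cell_type, trait_x, trait_y)


def ma_pair_correlations(
    table: pd.DataFrame,
    min_cells: int = 50,
    leave_one_out: bool = True,
) -> MaLineStats:
    """Within-line Pearson correlation of every within-type trait pair.

    The deviation score of line l on pair p is
    ``(r_lp - mean of the other lines) / SD of the other lines`` (leave-one-
    out by default; ``leave_one_out=False`` uses the inclusive mean/SD).
    Requires >= 4 lines with >= ``min_cells`` cells each. Degenerate traits
    within a line yield NaN for that (line, pair).
    """
    lines = table["strain"].unique()
    if len(lines) < 4:
        raise ValidationError("need >= 4 MA lines for leave-one-out scores")
    sizes = table.groupby("strain", observed=True).size()
    small = sizes[sizes < min_cells]
    if len(small):
        raise ValidationError(
            f"lines with < {min_cells} cells: {list(small.index)}")

    pair_rows = []
    cols: dict[str, dict[str, float]] = {}
    for ct, sub in table.groupby("cell_type", observed=True):
        traits = [c for c in sub.columns
                  if c not in _META and pd.api.types.is_numeric_dtype(sub[c])
                  and sub[c].notna().all()]
        if len(traits) < 2:
            continue
        for line, grp in sub.groupby("strain", observed=True):
            X = grp[traits].to_numpy(dtype=float)
            sd = X.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                C = np.corrcoef(X, rowvar=False)
            iu, ju = np.triu_indices(len(traits), k=1)
            for i, j in zip(iu, ju):
                pid = f"{ct}:{traits[i]}:{traits[j]}"
                r = C[i, j] if sd[i] > 0 and sd[j] > 0 else np.nan
                cols.setdefault(pid, {})[line] = r
        iu, ju = np.triu_indices(len(traits), k=1)
        for i, j in zip(iu, ju):
            pair_rows.append(dict(pair=f"{ct}:{traits[i]}:{traits[j]}",
                                  cell_type=ct, trait_x=traits[i], trait_y=traits[j]))

    corr = pd.DataFrame(cols).reindex(sorted(lines))
    corr.index.name = "line"
    scores = pd.DataFrame(np.nan, index=corr.index, columns=corr.columns)
    R = corr.to_numpy(dtype=float)
    n_lines = len(corr)
    for li in range(n_lines):
        if leave_one_out:
            others = np.delete(R, li, axis=0)
        else:
            others = R
        mu = np.nanmean(others, axis=0)
        sd = np.nanstd(others, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores.iloc[li] = (R[li] - mu) / sd
    return MaLineStats(
        correlations=corr, scores=scores,
        pair_info=pd.DataFrame(pair_rows).set_index("pair"),
    )


def flag_outliers(stats: MaLineStats, k: float = 4.0) -> pd.DataFrame:
    """Flag (line, pair) deviation scores beyond ``k`` SD and summarize lines.

    Returns the flag table (long format); per-line summaries (max |score| and
    mean |score| across pairs) are attached as ``.attrs["line_summary"]``.
    """
    S = stats.scores
    flags = []
    if np.isfinite(k):
        mask = S.abs() > k
        for line in S.index:
            for pair in S.columns[mask.loc[line]]:
                flags.append(dict(line=line, pair=pair,
                                  score=float(S.loc[line, pair]),
                                  r=float(stats.correlations.loc[line, pair])))
    out = pd.DataFrame(flags, columns=["line", "pair", "score", "r"])
    out.attrs["line_summary"] = pd.DataFrame({
        "max_abs_score": S.abs().max(axis=1),
        "mean_abs_score": S.abs().mean(axis=1),
    })
    return out


def dose_delta(
    table: pd.DataFrame,
    null_doses: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Change in r_W between each drug condition and its paired control.

    ``table`` must carry ``condition`` ("drug"/"control") and ``dose``
    columns; every dose needs both conditions. Returns one row per (pair,
    dose) with r_W in both conditions, ``delta = r_W(drug) - r_W(control)``
    and its magnitude. If ``null_doses`` names two doses, the r_W difference
    between their *control* conditions is appended with ``condition_pair =
    "null"`` as a replicate-vs-replicate reference.
    """
    if "condition" not in table.columns or "dose" not in table.columns:
        raise ValidationError("dose table needs condition and dose columns")
    key = ["cell_type", "trait_x", "trait_y"]
    rows = []
    controls: dict[float, pd.DataFrame] = {}
    for dose, grp in table.groupby("dose", sort=True):
        drug = grp[grp["condition"] == "drug"]
        ctrl = grp[grp["condition"] == "control"]
        if len(drug) == 0 or len(ctrl) == 0:
            raise ValidationError(f"dose {dose} lacks a paired condition")
        part_d = partition_all(drug).set_index(key)["r_w"]
        part_c = partition_all(ctrl).set_index(key)["r_w"]
        controls[float(dose)] = part_c
        aligned = pd.DataFrame({"r_w_drug": part_d, "r_w_control": part_c})
        aligned["delta"] = aligned["r_w_drug"] - aligned["r_w_control"]
        aligned["abs_delta"] = aligned["delta"].abs()
        aligned["dose"] = float(dose)
        aligned["condition_pair"] = "drug-vs-control"
        rows.append(aligned.reset_index())
    out = pd.concat(rows, ignore_index=True)
    if null_doses is not None:
        a, b = (float(d) for d in null_doses)
        if a not in controls or b not in controls:
            raise ValidationError("null_doses must name doses present in the table")
        null = pd.DataFrame({"r_w_drug": controls[a], "r_w_control": controls[b]})
        null["delta"] = null["r_w_drug"] - null["r_w_control"]
        null["abs_delta"] = null["delta"].abs()
        null["dose"] = np.nan
        null["condition_pair"] = "null"
        out = pd.concat([out, null.reset_index()], ignore_index=True)
    return out
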