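"""Trait filtering, Box-Cox transformation, plate correction and heritability.

The pipeline order is fixed: missingness filter -> Box-Cox -> plate
correction -> 5-SD outlier filter. Each trait belongs to one cell type and
is evaluated only over cells of that type; NaN entries for cells of other
types are structural, not missing data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PreprocessReport",
    "infer_trait_types",
    "filter_missing",
    "boxcox_by_strain",
    "plate_correct",
    "outlier_filter",
    "heritability",
    "preprocess_pipeline",
]

_META = {"cell_id", "strain", "replicate", "cell_type", "condition", "dose",
         "true_pseudotime", "pseudotime", "bin"}


@dataclass
class PreprocessReport:
    """Accumulated record of what each preprocessing step did."""

    boxcox_lambda: dict[str, float] = field(default_factory=dict)
    positivity_shift: dict[str, float] = field(default_factory=dict)
    traits_dropped: list[str] = field(default_factory=list)
    cells_dropped: dict[str, int] = field(default_factory=dict)
    plate_offsets: pd.DataFrame = field(default_factory=pd.DataFrame)
    heritability: dict[str, float] = field(default_factory=dict)
    flagged_traits: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def _traits(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns
            if c not in _META and pd.api.types.is_numeric_dtype(table[c])]


def infer_trait_types(table: pd.DataFrame) -> dict[str, str]:
    """Assign each trait to the cell type in which it is chiefly observed."""
    out = {}
    counts = table.groupby("cell_type", observed=True)[_traits(table)].count()
    for t in _traits(table):
        col = counts[t]
        if col.sum() == 0:
            out[t] = ""
        else:
            out[t] = col.idxmax()
    return out


def filter_missing(
    raw: pd.DataFrame,
    trait_missing_max: float = 0.10,
    report: PreprocessReport | None = None,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop traits missing in more than ``trait_missing_max`` of their cell
    type's cells, then drop cells not scored for every retained trait of
    their type."""
    report = report or PreprocessReport()
    if "cell_type" not in raw.columns:
        raise ValidationError("cell table lacks cell_type labels")
    types = infer_trait_types(raw)
    keep_traits = []
    for t in _traits(raw):
        sub = raw[raw["cell_type"] == types[t]]
        if len(sub) == 0:
            report.traits_dropped.append(t)
            continue
        frac_missing = sub[t].isna().mean()
        if frac_missing > trait_missing_max:
            report.traits_dropped.append(t)
        else:
            keep_traits.append(t)
    if not keep_traits:
        raise ValidationError("all traits exceeded the missingness threshold")
    out = raw.drop(columns=report.traits_dropped)
    # completeness per cell type
    keep_mask = pd.Series(True, index=out.index)
    for ct, sub in out.groupby("cell_type", observed=True):
        ct_traits = [t for t in keep_traits if types[t] == ct]
        if ct_traits:
            keep_mask.loc[sub.index] = sub[ct_traits].notna().all(axis=1)
    dropped = int((~keep_mask).sum())
    report.cells_dropped["incomplete"] = dropped
    report.log.append(
        f"filter_missing: dropped {len(report.traits_dropped)} traits, "
        f"{dropped} incomplete cells")
    return out[keep_mask].reset_index(drop=True), report


def _boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    return np.log(y) if lam == 0 else (np.power(y, lam) - 1.0) / lam


def _ppcc(residuals: np.ndarray) -> float:
    """Probability-plot correlation coefficient against the normal."""
    (osm, osr), (slope, intercept, r) = stats.probplot(residuals, dist="norm")
    return float(r)


def boxcox_by_strain(
    table: pd.DataFrame,
    lambda_grid: np.ndarray | None = None,
    criterion: str = "ppcc",
    report: PreprocessReport | None = None,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Box-Cox each trait with the lambda making strain-model residuals most
    normal.

    For each trait, a grid of lambda values in [-2, 2] (step 0.1) is scored
    by the normality of the residuals from the regression of the transformed
    phenotype on strain (a strain-mean model); the default normality score is
    the probability-plot correlation coefficient (``criterion="shapiro"``
    uses the Shapiro-Wilk W instead). Ties break toward lambda = 1.
    Nonpositive traits are shifted by ``-min + 1e-6 * range`` first; the
    shift is recorded. Constant traits are skipped and flagged.
    """
    report = report or PreprocessReport()
    if lambda_grid is None:
        lambda_grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)
    if table["strain"].nunique() < 2:
        raise ValidationError("Box-Cox by strain needs >= 2 strains")
    out = table.copy()
    codes_all, _ = pd.factorize(out["strain"].to_numpy())
    for t in _traits(table):
        mask = out[t].notna().to_numpy()
        y = out.loc[mask, t].to_numpy(dtype=float)
        if len(y) == 0 or np.ptp(y) == 0:
            report.flagged_traits.append(t)
            report.log.append(f"boxcox: skipped constant trait {t}")
            continue
        shift = 0.0
        if y.min() <= 0:
            shift = -y.min() + 1e-6 * np.ptp(y)
            y = y + shift
        report.positivity_shift[t] = shift
        codes = codes_all[mask]
        n_groups = codes.max() + 1
        counts = np.bincount(codes, minlength=n_groups)
        scorer = _ppcc if criterion == "ppcc" else (
            lambda r: float(stats.shapiro(r if len(r) <= 4500 else
                                          np.random.default_rng(0).choice(r, 4500,
                                                                          replace=False))[0]))
        best = None
        for lam in lambda_grid:
            ty = _boxcox(y, float(lam))
            means = np.bincount(codes, weights=ty, minlength=n_groups) / counts
            resid = ty - means[codes]
            if not np.all(np.isfinite(resid)) or np.ptp(resid) == 0:
                continue
            score = scorer(resid)
            key = (score, -abs(lam - 1.0))  # ties toward lambda = 1
            if best is None or key > best[0]:
                best = (key, float(lam), ty)
        if best is None:
            report.flagged_traits.append(t)
            continue
        _, lam, ty = best
        report.boxcox_lambda[t] = lam
        out.loc[mask, t] = ty
    report.log.append(f"boxcox: fitted {len(report.boxcox_lambda)} traits")
    return out, report


def plate_correct(
    table: pd.DataFrame,
    control_strains: tuple[str, str],
    report: PreprocessReport | None = None,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Remove plate effects via the mid-parent value of two control strains.

    For each (plate, trait): offset = plate mid-parent mean - grand mid-parent
    mean (averaged over plates); the offset is subtracted from every cell on
    the plate. Plates are identified by the ``replicate`` column. A plate
    lacking either control raises an error naming the plate.
    """
    report = report or PreprocessReport()
    a, b = control_strains
    plates = sorted(table["replicate"].unique())
    traits = _traits(table)
    offsets = []
    out = table.copy()
    for t in traits:
        mids = {}
        for plate in plates:
            sub = table[(table["replicate"] == plate) & table[t].notna()]
            ma = sub.loc[sub["strain"] == a, t]
            mb = sub.loc[sub["strain"] == b, t]
            if len(ma) == 0 or len(mb) == 0:
                raise ValidationError(
                    f"control strain missing on plate {plate} for trait {t}")
            mids[plate] = 0.5 * (ma.mean() + mb.mean())
        grand = float(np.mean(list(mids.values())))
        for plate in plates:
            off = mids[plate] - grand
            sel = out["replicate"] == plate
            out.loc[sel, t] = out.loc[sel, t] - off
            offsets.append(dict(plate=plate, trait=t, offset=off))
    report.plate_offsets = pd.DataFrame(offsets)
    report.log.append(f"plate_correct: {len(plates)} plates, {len(traits)} traits")
    return out, report


def outlier_filter(
    table: pd.DataFrame, k: float = 5.0, report: PreprocessReport | None = None
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Remove any cell whose |z| exceeds ``k`` on any of its type's traits.

    Means and SDs are computed per trait over all retained cells of the
    trait's cell type (on the transformed, plate-corrected scale).
    """
    report = report or PreprocessReport()
    if not np.isfinite(k):
        report.cells_dropped["outlier"] = 0
        return table, report
    drop = pd.Series(False, index=table.index)
    for t in _traits(table):
        col = table[t]
        mask = col.notna()
        mu, sd = col[mask].mean(), col[mask].std()
        if not np.isfinite(sd) or sd == 0:
            continue
        drop |= mask & ((col - mu).abs() > k * sd)
    n = int(drop.sum())
    report.cells_dropped["outlier"] = n
    report.log.append(f"outlier_filter: removed {n} cells at {k} SD")
    return table[~drop].reset_index(drop=True), report


def heritability(table: pd.DataFrame, trait: str) -> float:
    """Broad-sense heritability of one trait by one-way random-effects
    method of moments.

    H2 = sigma2_B / (sigma2_B + sigma2_W) with sigma2_B = max(0,
    (MSB - MSW) / n0) and n0 = (N - sum(n_j^2)/N) / (J - 1) for unbalanced
    group sizes; sigma2_W = MSW.
    """
    sub = table[table[trait].notna()]
    groups = sub.groupby("strain", observed=True)[trait]
    sizes = groups.size()
    sizes = sizes[sizes >= 2]
    if len(sizes) < 2:
        raise ValidationError("heritability needs >= 2 strains with >= 2 cells")
    sub = sub[sub["strain"].isin(sizes.index)]
    y = sub[trait].to_numpy(dtype=float)
    codes, _ = pd.factorize(sub["strain"].to_numpy())
    J = codes.max() + 1
    N = len(y)
    nj = np.bincount(codes, minlength=J).astype(float)
    means = np.bincount(codes, weights=y, minlength=J) / nj
    grand = y.mean()
    ssb = float(np.sum(nj * (means - grand) ** 2))
    ssw = float(np.sum((y - means[codes]) ** 2))
    msb = ssb / (J - 1)
    msw = ssw / (N - J)
    n0 = (N - np.sum(nj**2) / N) / (J - 1)
    sigma_b = max(0.0, (msb - msw) / n0)
    denom = sigma_b + msw
    if denom == 0:
        return np.nan
    return float(sigma_b / denom)


def preprocess_pipeline(
    raw: pd.DataFrame,
    control_strains: tuple[str, str] | None = None,
    trait_missing_max: float = 0.10,
    outlier_sd: float = 5.0,
    boxcox: bool = True,
    compute_heritability: bool = True,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run the fixed preprocessing order on a raw cell table."""
    table, report = filter_missing(raw, trait_missing_max)
    if boxcox:
        table, report = boxcox_by_strain(table, report=report)
    if control_strains is not None:
        table, report = plate_correct(table, control_strains, report=report)
    table, report = outlier_filter(table, outlier_sd, report=report)
    if compute_heritability:
        for t in _traits(table):
            try:
                report.heritability[t] = heritability(table, t)
            except ValidationError:
                report.flagged_traits.append(t)
    return table, report
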