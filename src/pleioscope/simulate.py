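"""Synthetic hierarchical single-cell trait data with known genetic architecture.

The generator emulates the structure of a two-parent yeast cross phenotyped by
high-throughput single-cell morphometry: a panel of homozygous recombinant
strains genotyped at biallelic markers, with hundreds of clonal cells measured
per strain across replicate plates.  Traits are partitioned among three cell
types (unbudded, small, large); a trait is only measured in cells of its type.

Cell-level trait values are built additively:

    value = direct QTL shifts + strain random effect + plate effect
            + trajectory(pseudotime) + correlated cell noise

Three QTL mechanisms are supported:

* ``vertical`` — the QTL shifts a latent factor shared by its target traits;
  the same factor fluctuates cell-to-cell, so the targets correlate within
  clonal populations and the genetic effect propagates through that inherent
  coupling.
* ``direct_horizontal`` — the QTL shifts each target trait's mean directly;
  the targets need not correlate within strains.
* ``corr_modifying`` — the QTL leaves trait means untouched but sets the
  correlation of one target pair to ``rho0`` for the -1 allele and
  ``rho0 + delta`` for the +1 allele, at both the cell-noise and the
  strain-effect level.

Every simulated dataset is accompanied by a :class:`SimTruth` recording the
realized parameters, so downstream inference can be scored against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MapError

CELL_TYPES = ("unbudded", "small", "large")

__all__ = [
    "CELL_TYPES",
    "QtlEffect",
    "SimConfig",
    "SimTruth",
    "simulate_cross",
    "simulate_cells",
    "simulate_ma_panel",
    "simulate_dose_series",
    "trait_names",
    "trajectory_value",
]


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass
class QtlEffect:
    """A single simulated locus effect.

    Parameters
    ----------
    marker:
        Marker name (``"m12"``) or 0-based marker index.
    mechanism:
        One of ``vertical``, ``direct_horizontal``, ``corr_modifying``.
    traits:
        Target trait names. For ``corr_modifying`` exactly two.
    beta:
        Allele-substitution effect (trait units per unit of the -1/+1 allele
        code). For ``vertical`` it shifts the shared latent factor; for
        ``direct_horizontal`` each target trait's mean.
    loadings:
        Per-target loadings of the vertical latent factor (default all 1).
    rho0, delta:
        ``corr_modifying`` only: target-pair correlation is ``rho0`` for the
        -1 allele and ``rho0 + delta`` for the +1 allele.
    """

    marker: int | str
    mechanism: str
    traits: tuple[str, ...]
    beta: float = 0.0
    loadings: tuple[float, ...] | None = None
    rho0: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        if self.mechanism not in ("vertical", "direct_horizontal", "corr_modifying"):
            raise ConfigError(f"unknown QTL mechanism {self.mechanism!r}")
        if self.mechanism == "corr_modifying":
            if len(self.traits) != 2:
                raise ConfigError("corr_modifying QTL needs exactly one trait pair")
            for rho in (self.rho0, self.rho0 + self.delta):
                if not -1.0 < rho < 1.0:
                    raise ConfigError(
                        f"corr_modifying correlation {rho} outside (-1, 1)"
                    )
        if self.mechanism == "vertical" and self.loadings is not None:
            if len(self.loadings) != len(self.traits):
                raise ConfigError("loadings must match number of target traits")


def trait_names(n_traits_per_celltype: Sequence[int]) -> dict[str, str]:
    """Map trait name -> cell type for the given per-type trait counts."""
    out: dict[str, str] = {}
    for ct, n in zip(CELL_TYPES, n_traits_per_celltype):
        for i in range(n):
            out[f"{ct[0]}{i + 1:03d}"] = ct
    return out


@dataclass
class SimConfig:
    """Generator settings. Defaults mirror the mapping-panel study design:
    374 recombinant strains, 225 markers on 16 chromosomes (~4,076 cM total
    map), 167 traits split 28/47/92 among the three cell types, ~800 cells
    per strain over 3 replicate plates, and a low-heritability regime
    (strain-level variance well under 15% of the total)."""

    n_strains: int = 374
    n_markers: int = 225
    n_chromosomes: int = 16
    chrom_length_cM: dict[int, float] | float = 254.75
    n_traits_per_celltype: tuple[int, int, int] = (28, 47, 92)
    cells_per_strain: int = 800
    n_replicates: int = 3
    qtl_spec: list[QtlEffect] = field(default_factory=list)
    base_within_corr: dict[str, np.ndarray] | None = None
    strain_var: float = 0.05
    cell_var: float = 1.0
    cellcycle_spec: dict[str, tuple[str, float]] | None = None
    plate_effect_sd: float = 0.1
    seed: int = 0

    # ---- derived helpers -------------------------------------------------
    def trait_map(self) -> dict[str, str]:
        return trait_names(self.n_traits_per_celltype)

    def traits_of(self, cell_type: str) -> list[str]:
        return [t for t, ct in self.trait_map().items() if ct == cell_type]

    def chrom_lengths(self) -> dict[int, float]:
        if isinstance(self.chrom_length_cM, dict):
            out = {int(k): float(v) for k, v in self.chrom_length_cM.items()}
        else:
            out = {c + 1: float(self.chrom_length_cM) for c in range(self.n_chromosomes)}
        for c, length in out.items():
            if length < 0:
                raise MapError(f"chromosome {c} has negative length {length}")
        return out

    def validate(self) -> None:
        if self.n_strains < 1:
            raise ConfigError("n_strains must be >= 1")
        if self.strain_var < 0 or self.cell_var < 0:
            raise ConfigError("variance components must be nonnegative")
        if self.plate_effect_sd < 0:
            raise ConfigError("plate_effect_sd must be nonnegative")
        if self.base_within_corr is not None:
            for ct, mat in self.base_within_corr.items():
                arr = np.asarray(mat, dtype=float)
                if arr.shape[0] != arr.shape[1]:
                    raise ConfigError(f"base_within_corr[{ct}] is not square")
                if not np.allclose(arr, arr.T, atol=1e-12):
                    raise ConfigError(f"base_within_corr[{ct}] is not symmetric")
                _check_psd(arr, f"base_within_corr[{ct}]")


def _check_psd(corr: np.ndarray, what: str) -> None:
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-10:
        raise ConfigError(f"{what} is not positive semi-definite (min eig {eigmin:.3g})")


def _chol_psd(corr: np.ndarray, what: str) -> np.ndarray:
    """Cholesky factor with a tiny ridge for exactly-singular PSD matrices."""
    _check_psd(corr, what)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * np.eye(corr.shape[0])
        return np.linalg.cholesky(corr + ridge)


# --------------------------------------------------------------------------
# ground truth container
# --------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Realized generator parameters, the oracle for downstream inference.

    ``pair_truth`` holds one row per (cell type, trait pair, allele context)
    with the true within-strain cell-noise correlation; context ``"all"`` is
    the pooled (allele-balanced) value. ``qtl`` tabulates every simulated
    locus with its mechanism and effect. ``pseudotime`` carries each cell's
    true position in [0, 1]. ``ma_lines`` and ``dose_targets`` are populated
    by the MA-panel and dose-series generators respectively.
    """

    qtl: pd.DataFrame = field(default_factory=pd.DataFrame)
    pair_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    pseudotime: pd.DataFrame = field(default_factory=pd.DataFrame)
    ma_lines: pd.DataFrame = field(default_factory=pd.DataFrame)
    dose_targets: pd.DataFrame = field(default_factory=pd.DataFrame)

    _TABLES = ("qtl", "pair_truth", "pseudotime", "ma_lines", "dose_targets")

    def to_json(self, path) -> None:
        payload = {
            name: getattr(self, name).to_dict(orient="list")
            for name in self._TABLES
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{name: pd.DataFrame(payload.get(name, {})) for name in cls._TABLES})


# --------------------------------------------------------------------------
# cross simulator
# --------------------------------------------------------------------------

def haldane_fraction(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction at map distance ``d`` cM: (1 - exp(-2d/100)) / 2."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise MapError("negative map distance")
    return (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0


def _default_marker_map(config: SimConfig) -> pd.DataFrame:
    lengths = config.chrom_lengths()
    chroms = sorted(lengths)
    n = config.n_markers
    # round-robin allocation of markers to chromosomes, at least 1 each
    per = {c: 1 for c in chroms}
    for i in range(n - len(chroms)):
        per[chroms[i % len(chroms)]] += 1
    rows = []
    idx = 1
    for c in chroms:
        k = per[c]
        pos = np.linspace(0.0, lengths[c], k) if k > 1 else np.array([0.0])
        for p in pos:
            rows.append((f"m{idx}", c, float(p)))
            idx += 1
    return pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"])


def simulate_cross(
    config: SimConfig, marker_map: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a panel of homozygous recombinant strains.

    Each strain is an independent recombinant gamete doubled to homozygosity,
    coded -1/+1 per marker. Crossovers between adjacent markers occur with
    the Haldane recombination fraction of their map distance; chromosomes
    segregate independently.

    Returns ``(genotypes, marker_map)`` where genotypes is a strains x
    markers DataFrame of int8 codes.
    """
    config.validate()
    if marker_map is None:
        marker_map = _default_marker_map(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    n = config.n_strains
    cols: dict[str, np.ndarray] = {}
    for chrom, grp in marker_map.groupby("chromosome", sort=True):
        pos = grp["position_cM"].to_numpy(dtype=float)
        if np.any(np.diff(pos) < 0):
            raise MapError(f"marker positions not increasing on chromosome {chrom}")
        k = len(pos)
        g = np.empty((n, k), dtype=np.int8)
        g[:, 0] = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
        if k > 1:
            r = haldane_fraction(np.diff(pos))
            flips = rng.random((n, k - 1)) < r[None, :]
            # cumulative XOR of crossover indicators
            cum = np.cumsum(flips, axis=1) % 2
            g[:, 1:] = g[:, [0]] * np.where(cum == 1, -1, 1).astype(np.int8)
        for j, name in enumerate(grp["marker"]):
            cols[name] = g[:, j]
    strains = [f"s{i + 1:03d}" for i in range(n)]
    genotypes = pd.DataFrame(cols, index=pd.Index(strains, name="strain"))
    genotypes = genotypes[marker_map["marker"].tolist()]
    return genotypes, marker_map


# --------------------------------------------------------------------------
# cell-level simulator
# --------------------------------------------------------------------------

def trajectory_value(shape: str, amplitude: float, u: np.ndarray) -> np.ndarray:
    """Deterministic mean trajectory over pseudotime u in [0, 1], centered.

    ``monotone`` is a smoothstep cubic rising by ``amplitude`` over the cycle;
    ``bump`` is a single Gaussian peak at mid-cycle. Both have (approximately)
    zero mean over Uniform(0,1) pseudotime so they perturb shape, not level.
    """
    u = np.asarray(u, dtype=float)
    if shape == "monotone":
        return amplitude * (3.0 * u**2 - 2.0 * u**3 - 0.5)
    if shape == "bump":
        raw = np.exp(-((u - 0.5) ** 2) / (2 * 0.15**2))
        return amplitude * (raw - 0.3758)  # mean of raw over U(0,1)
    if shape == "none":
        return np.zeros_like(u)
    raise ConfigError(f"unknown trajectory shape {shape!r}")


def _marker_name(marker: int | str, genotypes: pd.DataFrame) -> str:
    if isinstance(marker, str):
        if marker not in genotypes.columns:
            raise ConfigError(f"QTL marker {marker!r} not in genotype table")
        return marker
    try:
        return genotypes.columns[int(marker)]
    except IndexError as exc:
        raise ConfigError(f"QTL marker index {marker} out of range") from exc


def _celltype_corr(config: SimConfig, cell_type: str) -> np.ndarray:
    traits = config.traits_of(cell_type)
    k = len(traits)
    if config.base_within_corr is not None and cell_type in config.base_within_corr:
        corr = np.asarray(config.base_within_corr[cell_type], dtype=float).copy()
        if corr.shape != (k, k):
            raise ConfigError(
                f"base_within_corr[{cell_type}] has shape {corr.shape}, expected {(k, k)}"
            )
        return corr
    return np.eye(k)


def _apply_corr_mods(
    corr: np.ndarray,
    mods: list[tuple[int, int, float]],
) -> np.ndarray:
    out = corr.copy()
    for i, j, rho in mods:
        out[i, j] = out[j, i] = rho
    return out


def _context_key(alleles: tuple[int, ...]) -> str:
    return "all" if not alleles else "/".join("+" if a > 0 else "-" for a in alleles)


def simulate_cells(
    genotypes: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate clonal cells for every strain in ``genotypes``.

    Returns a cell table (one row per cell; NaN for traits outside the cell's
    type) and the :class:`SimTruth` with the realized architecture.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    trait_map = config.trait_map()
    all_traits = list(trait_map)
    strains = genotypes.index.to_list()
    n_strains = len(strains)

    qtl_rows = []
    for q in config.qtl_spec:
        name = _marker_name(q.marker, genotypes)
        for t in q.traits:
            if t not in trait_map:
                raise ConfigError(f"QTL target trait {t!r} not simulated")
        cts = {trait_map[t] for t in q.traits}
        if q.mechanism == "corr_modifying" and len(cts) != 1:
            raise ConfigError("corr_modifying pair must share a cell type")
        qtl_rows.append(
            dict(marker=name, mechanism=q.mechanism, traits=";".join(q.traits),
                 beta=q.beta, rho0=q.rho0, delta=q.delta)
        )
    qtl_table = pd.DataFrame(
        qtl_rows, columns=["marker", "mechanism", "traits", "beta", "rho0", "delta"]
    )

    # per-cell-type machinery ------------------------------------------------
    n_cells = config.cells_per_strain
    # split cells among cell types proportionally to trait counts? keep equal
    active_types = [ct for ct in CELL_TYPES if config.traits_of(ct)]
    counts = np.full(len(active_types), n_cells // len(active_types))
    counts[: n_cells % len(active_types)] += 1

    # plate effects: one offset per (replicate, trait)
    plate_fx = rng.normal(0.0, config.plate_effect_sd,
                          size=(config.n_replicates, len(all_traits)))

    frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    pt_rows: list[pd.DataFrame] = []
    cell_id0 = 0
    sd_cell = float(np.sqrt(config.cell_var))
    sd_strain = float(np.sqrt(config.strain_var))

    for ct, n_ct in zip(active_types, counts):
        traits = config.traits_of(ct)
        tidx = {t: i for i, t in enumerate(traits)}
        k = len(traits)
        base = _celltype_corr(config, ct)

        verticals = [q for q in config.qtl_spec
                     if q.mechanism == "vertical" and trait_map[q.traits[0]] == ct]
        directs = [q for q in config.qtl_spec
                   if q.mechanism == "direct_horizontal" and trait_map[q.traits[0]] == ct]
        cmods = [q for q in config.qtl_spec
                 if q.mechanism == "corr_modifying" and trait_map[q.traits[0]] == ct]

        # latent-factor loading matrix (k x n_factors)
        L = np.zeros((k, len(verticals)))
        for f, q in enumerate(verticals):
            loads = q.loadings or tuple(1.0 for _ in q.traits)
            for t, l in zip(q.traits, loads):
                L[tidx[t], f] = l

        # enumerate allele contexts over corr-modifying QTL of this type
        context_cache: dict[tuple[int, ...], dict] = {}

        def context(alleles: tuple[int, ...]) -> dict:
            if alleles not in context_cache:
                mods = [(tidx[q.traits[0]], tidx[q.traits[1]],
                         q.rho0 + (q.delta if a > 0 else 0.0))
                        for q, a in zip(cmods, alleles)]
                corr = _apply_corr_mods(base, mods)
                # residual noise sampled from corr; latent factors added on top,
                # so the realized cell-noise covariance is cell_var*corr + LL'
                context_cache[alleles] = dict(
                    chol=_chol_psd(corr, "cell noise corr"),
                    corr_cell=_safe_corr(config.cell_var * corr + L @ L.T),
                )
            return context_cache[alleles]

        spec = config.cellcycle_spec or {}
        traj_list = [spec.get(t, ("none", 0.0)) for t in traits]

        cmod_markers = [_marker_name(q.marker, genotypes) for q in cmods]
        direct_shift = np.zeros((n_strains, k))
        for q in directs:
            g = genotypes[_marker_name(q.marker, genotypes)].to_numpy(dtype=float)
            for t in q.traits:
                direct_shift[:, tidx[t]] += q.beta * g
        factor_shift = np.zeros((n_strains, len(verticals)))
        for f, q in enumerate(verticals):
            g = genotypes[_marker_name(q.marker, genotypes)].to_numpy(dtype=float)
            factor_shift[:, f] = q.beta * g

        # truth rows: pooled + per-context within-strain cell-noise correlation
        ref = context(tuple([-1] * len(cmods)))
        pooled = ref["corr_cell"].copy()
        if cmods:
            alts = context(tuple([1] * len(cmods)))["corr_cell"]
            pooled = 0.5 * (pooled + alts)
        for a in range(k):
            for b in range(a + 1, k):
                truth_rows.append(dict(cell_type=ct, trait_x=traits[a],
                                       trait_y=traits[b], context="all",
                                       r_within=float(pooled[a, b])))
        for q in cmods:
            i, j = tidx[q.traits[0]], tidx[q.traits[1]]
            for allele, rho in ((-1, q.rho0), (1, q.rho0 + q.delta)):
                # exact per-context value from the full covariance
                ctx_alleles = tuple(allele if qq is q else -1 for qq in cmods)
                cc = context(ctx_alleles)["corr_cell"]
                truth_rows.append(dict(cell_type=ct, trait_x=q.traits[0],
                                       trait_y=q.traits[1],
                                       context="+" if allele > 0 else "-",
                                       r_within=float(cc[i, j])))

        for s_i, strain in enumerate(strains):
            alleles = tuple(int(genotypes.at[strain, m]) for m in cmod_markers)
            ctx = context(alleles)
            # strain random effect shares the context's correlation structure
            if config.strain_var > 0:
                u_strain = sd_strain * (ctx["chol"] @ rng.standard_normal(k))
            else:
                u_strain = np.zeros(k)
            mean = direct_shift[s_i] + u_strain + L @ factor_shift[s_i]

            u = rng.random(n_ct)
            traj_mat = np.column_stack(
                [trajectory_value(shape, amp, u) for (shape, amp) in traj_list]
            ) if k else np.zeros((n_ct, 0))
            zc = rng.standard_normal((n_ct, k))
            fac = rng.standard_normal((n_ct, len(verticals)))
            vals = (mean[None, :] + traj_mat
                    + sd_cell * (zc @ ctx["chol"].T) + fac @ L.T)

            rep = rng.integers(0, config.n_replicates, size=n_ct)
            vals = vals + plate_fx[rep][:, [all_traits.index(t) for t in traits]]

            ids = np.arange(cell_id0, cell_id0 + n_ct)
            cell_id0 += n_ct
            df = pd.DataFrame(vals, columns=traits)
            df.insert(0, "cell_id", ids)
            df.insert(1, "strain", strain)
            df.insert(2, "replicate", rep + 1)
            df.insert(3, "cell_type", ct)
            df["true_pseudotime"] = u
            frames.append(df)
            pt_rows.append(pd.DataFrame({"cell_id": ids, "true_pseudotime": u}))

    cells = pd.concat(frames, ignore_index=True)
    # union of all trait columns, NaN where not measured
    meta = ["cell_id", "strain", "replicate", "cell_type"]
    cells = cells.reindex(columns=meta + all_traits + ["true_pseudotime"])
    truth = SimTruth(
        qtl=qtl_table,
        pair_truth=pd.DataFrame(
            truth_rows,
            columns=["cell_type", "trait_x", "trait_y", "context", "r_within"],
        ),
        pseudotime=pd.concat(pt_rows, ignore_index=True) if pt_rows else pd.DataFrame(),
    )
    return cells, truth


def _safe_corr(cov: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(cov))
    sd = np.where(sd > 0, sd, 1.0)
    return cov / np.outer(sd, sd)


# --------------------------------------------------------------------------
# mutation-accumulation panel
# --------------------------------------------------------------------------

def simulate_ma_panel(
    config: SimConfig,
    n_lines: int,
    n_altered: int,
    altered_pairs: list[tuple[str, str]] | None = None,
    delta: float = 0.5,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a panel of mutation-accumulation lines.

    All lines share ``base_within_corr`` except ``n_altered`` lines, in which
    the correlation of each designated pair is shifted by ``delta`` — the
    synthetic analog of a rare correlation-altering mutation. No genotype
    table is emitted (mutations are private to each line).
    """
    config.validate()
    if n_altered > n_lines:
        raise ConfigError("n_altered cannot exceed n_lines")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    trait_map = config.trait_map()
    active_types = [ct for ct in CELL_TYPES if config.traits_of(ct)]
    if altered_pairs is None:
        ct0 = active_types[0]
        tt = config.traits_of(ct0)
        if len(tt) < 2:
            raise ConfigError("need >= 2 traits in a cell type for an altered pair")
        altered_pairs = [(tt[0], tt[1])]
    for x, y in altered_pairs:
        if trait_map[x] != trait_map[y]:
            raise ConfigError(f"altered pair ({x}, {y}) spans cell types")

    altered = rng.choice(n_lines, size=n_altered, replace=False) if n_altered else []
    altered = set(int(i) for i in np.atleast_1d(altered))

    frames = []
    line_rows = []
    cell_id0 = 0
    for li in range(n_lines):
        line = f"L{li + 1:02d}"
        is_alt = li in altered
        sub_frames = []
        counts = np.full(len(active_types),
                         config.cells_per_strain // len(active_types))
        counts[: config.cells_per_strain % len(active_types)] += 1
        for ct, n_ct in zip(active_types, counts):
            traits = config.traits_of(ct)
            tidx = {t: i for i, t in enumerate(traits)}
            corr = _celltype_corr(config, ct)
            if is_alt:
                mods = []
                for x, y in altered_pairs:
                    if trait_map[x] != ct:
                        continue
                    rho = corr[tidx[x], tidx[y]] + delta
                    if not -1.0 < rho < 1.0:
                        raise ConfigError(
                            f"altered correlation {rho} for ({x},{y}) outside (-1,1)"
                        )
                    mods.append((tidx[x], tidx[y], rho))
                corr = _apply_corr_mods(corr, mods)
            chol = _chol_psd(corr, f"MA corr ({line},{ct})")
            z = rng.standard_normal((n_ct, len(traits)))
            vals = np.sqrt(config.cell_var) * (z @ chol.T)
            u = rng.random(n_ct)
            spec = config.cellcycle_spec or {}
            for t in traits:
                shape, amp = spec.get(t, ("none", 0.0))
                vals[:, tidx[t]] += trajectory_value(shape, amp, u)
            df = pd.DataFrame(vals, columns=traits)
            ids = np.arange(cell_id0, cell_id0 + n_ct)
            cell_id0 += n_ct
            df.insert(0, "cell_id", ids)
            df.insert(1, "strain", line)
            df.insert(2, "replicate", 1)
            df.insert(3, "cell_type", ct)
            sub_frames.append(df)
        frames.extend(sub_frames)
        line_rows.append(dict(
            line=line, altered=is_alt,
            pairs=";".join(f"{x}:{y}" for x, y in altered_pairs) if is_alt else "",
            delta=delta if is_alt else 0.0,
        ))

    all_traits = list(trait_map)
    cells = pd.concat(frames, ignore_index=True)
    cells = cells.reindex(
        columns=["cell_id", "strain", "replicate", "cell_type"] + all_traits
    )
    truth = SimTruth(ma_lines=pd.DataFrame(line_rows))
    return cells, truth


# --------------------------------------------------------------------------
# dose series
# --------------------------------------------------------------------------

def simulate_dose_series(
    config: SimConfig,
    doses: Sequence[float],
    corr_shift_per_dose: dict[tuple[str, str], Sequence[float]],
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate paired drug/control conditions across an ordered dose series.

    For each dose a drug table and a paired control table are generated from
    the *same* underlying random draws; only the within-strain correlation of
    the shifted pairs differs (by the dose's delta). A zero shift therefore
    yields bit-identical drug and control cells, mirroring a paired
    experiment where only the perturbation differs.
    """
    config.validate()
    rng_master = np.random.SeedSequence(config.seed).spawn(4)[3]
    trait_map = config.trait_map()
    active_types = [ct for ct in CELL_TYPES if config.traits_of(ct)]
    for (x, y), shifts in corr_shift_per_dose.items():
        if len(shifts) != len(doses):
            raise ConfigError("one shift per dose required for every pair")
        if trait_map[x] != trait_map[y]:
            raise ConfigError(f"shifted pair ({x}, {y}) spans cell types")

    frames = []
    target_rows = []
    cell_id0 = 0
    child_seeds = rng_master.spawn(len(doses))
    for d_i, dose in enumerate(doses):
        rng = np.random.default_rng(child_seeds[d_i])
        counts = np.full(len(active_types),
                         config.cells_per_strain // len(active_types))
        counts[: config.cells_per_strain % len(active_types)] += 1
        for strain_i in range(config.n_strains):
            strain = f"s{strain_i + 1:03d}"
            for ct, n_ct in zip(active_types, counts):
                traits = config.traits_of(ct)
                tidx = {t: i for i, t in enumerate(traits)}
                base = _celltype_corr(config, ct)
                mods = []
                for (x, y), shifts in corr_shift_per_dose.items():
                    if trait_map[x] != ct:
                        continue
                    rho = base[tidx[x], tidx[y]] + float(shifts[d_i])
                    if not -1.0 < rho < 1.0:
                        raise ConfigError(
                            f"shifted correlation {rho} for ({x},{y}) outside (-1,1)"
                        )
                    mods.append((tidx[x], tidx[y], rho))
                drug_corr = _apply_corr_mods(base, mods)
                chol_c = _chol_psd(base, "control corr")
                chol_d = _chol_psd(drug_corr, "drug corr")
                # shared randomness: same z, same strain effect, same pseudotime
                u_strain = rng.normal(0, np.sqrt(config.strain_var), size=len(traits))
                z = rng.standard_normal((n_ct, len(traits)))
                u = rng.random(n_ct)
                spec = config.cellcycle_spec or {}
                traj = np.column_stack(
                    [trajectory_value(*spec.get(t, ("none", 0.0)), u) for t in traits]
                )
                for cond, chol in (("control", chol_c), ("drug", chol_d)):
                    vals = (u_strain[None, :] + traj
                            + np.sqrt(config.cell_var) * (z @ chol.T))
                    df = pd.DataFrame(vals, columns=traits)
                    ids = np.arange(cell_id0, cell_id0 + n_ct)
                    cell_id0 += n_ct
                    df.insert(0, "cell_id", ids)
                    df.insert(1, "strain", strain)
                    df.insert(2, "replicate", 1)
                    df.insert(3, "cell_type", ct)
                    df.insert(4, "condition", cond)
                    df.insert(5, "dose", float(dose))
                    frames.append(df)
        for (x, y), shifts in corr_shift_per_dose.items():
            target_rows.append(dict(dose=float(dose), trait_x=x, trait_y=y,
                                    delta=float(shifts[d_i])))

    all_traits = list(trait_map)
    cells = pd.concat(frames, ignore_index=True)
    cells = cells.reindex(
        columns=["cell_id", "strain", "replicate", "cell_type", "condition", "dose"]
        + all_traits
    )
    truth = SimTruth(dose_targets=pd.DataFrame(target_rows))
    return cells, truth
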