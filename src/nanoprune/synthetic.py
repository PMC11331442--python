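"""Synthetic nanomaterial study generator with planted ground truth.

The generator emulates the data geometry of a doped metal-oxide library
study: a small material library (default 8 Fe-doped CuO materials)
exposed at a handful of soil concentrations, characterised by ~68
descriptors organised into ~15 strongly rank-correlated clusters, and
organism counts following the logarithmic response law
``y = -b ln c + b0`` with the steepness ``b`` planted as a function of
a few "true" descriptors.

Cluster structure is generated in rank space so that Spearman
correlation — the metric the clustering stage uses — is controlled
directly: each cluster has a latent rank vector (a permutation of the
material order chosen to have low rank correlation with every other
cluster's latent), and each member column applies a fixed number of
disjoint adjacent rank transpositions plus a random strictly monotone
value map (optionally decreasing).  Because every member carries the
same number of disjoint transpositions at distinct positions, all
within-cluster pairwise rank correlations are equal, which keeps the
dendrogram's within-cluster merge heights uniform — the regime in
which inconsistency-based tree cutting is reliable.

A geometric caveat that the generator enforces rather than hides: with
``m`` materials there are only ``m - 1`` independent rank dimensions,
so the number of mutually near-orthogonal cluster latents is bounded
(e.g. 15 latents over 8 materials cannot all have pairwise
|rho| <= 0.2).  The requested between-cluster ceiling is honoured when
geometrically feasible and otherwise approached greedily.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nanoprune.core_data import (
    BioassayRecord,
    DescriptorColumn,
    DescriptorKind,
    DescriptorMatrix,
    Material,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_descriptors",
    "generate_bioassay",
    "generate_block_matrix",
    "planted_b_table",
]

#: default sizes for 65 concentration-independent columns in 15 clusters
_DEFAULT_CLUSTER_SIZES = (5, 5, 5, 5, 5, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4)

_KIND_CYCLE = (
    DescriptorKind.SIZE,
    DescriptorKind.POTENTIAL_ENERGY,
    DescriptorKind.LATTICE_ENERGY,
    DescriptorKind.CONSTITUTIONAL,
    DescriptorKind.FORCE_VECTOR,
    DescriptorKind.TOPOLOGY,
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror a typical library study: 8 materials x 5 non-zero
    soil concentrations (mg/kg dry weight), 68 descriptor columns of
    which 3 are concentration-dependent, reproduction counts in the
    hundreds with 5% relative noise, and 4 control replicates.
    """

    n_materials: int = 8
    concentrations: tuple[float, ...] = (100.0, 320.0, 640.0, 1000.0, 3200.0)
    n_clusters: int = 15
    cluster_sizes: tuple[int, ...] = _DEFAULT_CLUSTER_SIZES
    within_cluster_abs_rho: float = 0.9  # floor on planted within-cluster |rho|
    between_cluster_abs_rho: float = 0.2  # target ceiling between latents
    true_descriptors: dict[str, float] = field(
        default_factory=lambda: {"diameter": 6.0, "SSA": 4.0, "force_vector_MO": -3.0}
    )
    b_center: float = 25.0
    b0_range: tuple[float, float] = (200.0, 400.0)
    noise_sd: float = 0.05  # fraction of the per-material control mean b0
    n_control_replicates: int = 4
    round_counts: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError(
                f"cluster_sizes has {len(self.cluster_sizes)} entries "
                f"but n_clusters = {self.n_clusters}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.within_cluster_abs_rho <= 1:
            raise ValueError("within_cluster_abs_rho must be in (0, 1]")

    @property
    def total_columns(self) -> int:
        """Concentration-independent columns plus the 3 dependent ones."""
        return sum(self.cluster_sizes) + 3


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    materials: list[Material]
    b: dict[str, float]  # material name -> steepness
    b0: dict[str, float]  # material name -> control-scale intercept
    cluster_labels: dict[str, int]  # independent column -> planted cluster id
    active_descriptors: list[str]


# ---------------------------------------------------------------------------
# rank-space block construction
# ---------------------------------------------------------------------------


def _rank_rho(p: np.ndarray, q: np.ndarray) -> float:
    """Spearman rho between two rank vectors (Pearson on the ranks)."""
    return float(np.corrcoef(p, q)[0, 1])


def _low_coherence_latents(
    n_rows: int, n_needed: int, ceiling: float, rng: np.random.Generator,
    max_tries: int = 4000,
) -> list[np.ndarray]:
    """Greedy search for permutations with pairwise |rho| <= ceiling.

    When the ceiling is geometrically infeasible (many clusters over few
    rows), the candidate minimising the worst coherence is used instead.
    """
    latents = [np.arange(n_rows)]
    for _ in range(1, n_needed):
        best_perm, best_coh = None, np.inf
        for _try in range(max_tries):
            cand = rng.permutation(n_rows)
            coh = max(abs(_rank_rho(cand, l)) for l in latents)
            if coh < best_coh:
                best_perm, best_coh = cand, coh
            if coh <= ceiling:
                break
        latents.append(best_perm)
    return latents


def _swaps_per_column(n_rows: int, cluster_size: int, within_floor: float) -> int:
    """Disjoint adjacent transpositions per column honouring the rho floor.

    A pair of columns with k disjoint transpositions each (at distinct
    even positions) differs by sum(d^2) = 4k, i.e.
    rho = 1 - 24k / (n (n^2 - 1)); k is capped so rho >= within_floor,
    and by the number of even positions available to the cluster.
    """
    if cluster_size <= 1:
        return 0
    k_floor = int((1.0 - within_floor) * n_rows * (n_rows**2 - 1) / 24.0)
    n_even = len(range(0, n_rows - 1, 2))
    return max(0, min(k_floor, n_even // cluster_size))


def _planted_rank_blocks(
    n_rows: int,
    cluster_sizes: tuple[int, ...],
    within_floor: float,
    between_ceiling: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (values, labels, signs): a column block matrix in value space.

    values is (n_rows, n_cols); labels[j] is the planted cluster of
    column j; signs[j] is +-1 (monotone increasing vs decreasing map).
    """
    latents = _low_coherence_latents(n_rows, len(cluster_sizes), between_ceiling, rng)
    even_positions = np.arange(0, n_rows - 1, 2)

    cols, labels, signs = [], [], []
    for ci, size in enumerate(cluster_sizes):
        latent = latents[ci]
        k = _swaps_per_column(n_rows, size, within_floor)
        slots = rng.permutation(even_positions)
        for j in range(size):
            ranks = latent.copy()
            for s in range(k):
                # transpose the adjacent rank VALUES v, v+1 (not positions),
                # so each swap contributes exactly 2 to sum(d^2) regardless
                # of the latent permutation
                v = slots[j * k + s]
                iv = ranks == v
                iw = ranks == v + 1
                ranks[iv], ranks[iw] = v + 1, v
            # random strictly monotone value map; the first member of a
            # cluster keeps the increasing orientation so planted
            # coefficient signs are interpretable
            sign = 1 if j == 0 else (1 if rng.random() < 0.5 else -1)
            scale = math.exp(rng.normal(0.0, 1.0))
            loc = rng.normal(0.0, 2.0)
            base = np.sort(rng.normal(loc, scale, size=n_rows))
            vals = base[ranks] if sign > 0 else base[::-1][ranks]
            cols.append(vals)
            labels.append(ci)
            signs.append(sign)
    return np.column_stack(cols), np.array(labels), np.array(signs)


def generate_block_matrix(
    n_rows: int = 40,
    cluster_sizes: tuple[int, ...] = _DEFAULT_CLUSTER_SIZES,
    within_cluster_abs_rho: float = 0.9,
    between_cluster_abs_rho: float = 0.2,
    seed: int = 0,
    n_extra_columns: int = 3,
) -> tuple[DescriptorMatrix, dict[str, int]]:
    """A flat planted-block matrix with independent rows.

    This is the benchmark object for validating the clustering stage
    (e.g. 40 rows x 68 columns with 15 blocks): rows are exchangeable
    samples, so the between-cluster correlation ceiling is honoured in
    a 39-dimensional rank space.  ``n_extra_columns`` appends
    unclustered concentration-dependent style columns so the total
    column count matches a study matrix; they carry label -1.
    """
    rng = np.random.default_rng(seed)
    values, labels, _ = _planted_rank_blocks(
        n_rows, cluster_sizes, within_cluster_abs_rho, between_cluster_abs_rho, rng
    )
    names = [f"desc_{ci:02d}_{j}" for ci, j in zip(labels, _within_counter(labels))]
    data = pd.DataFrame(values, columns=names)
    for e in range(n_extra_columns):
        data[f"extra_{e}"] = rng.normal(size=n_rows)
    index = pd.MultiIndex.from_arrays(
        [[f"S{i}" for i in range(n_rows)], np.zeros(n_rows)],
        names=["material", "concentration"],
    )
    data.index = index
    schema = [
        DescriptorColumn(name=c, kind=_KIND_CYCLE[i % len(_KIND_CYCLE)])
        for i, c in enumerate(names)
    ] + [
        DescriptorColumn(
            name=f"extra_{e}", kind=DescriptorKind.EXPERIMENTAL, concentration_dependent=True
        )
        for e in range(n_extra_columns)
    ]
    truth = {n: int(l) for n, l in zip(names, labels)}
    return DescriptorMatrix(data=data, schema=schema), truth


def _within_counter(labels) -> list[int]:
    seen: dict[int, int] = {}
    out = []
    for l in labels:
        seen[l] = seen.get(l, -1) + 1
        out.append(seen[l])
    return out


# ---------------------------------------------------------------------------
# the material-structured study
# ---------------------------------------------------------------------------


def _material_library(n: int) -> list[Material]:
    """CuO plus Fe-doped CuO with doping spread over 0-10%."""
    fracs = np.round(np.linspace(0.0, 10.0, n), 2)
    mats = []
    for f in fracs:
        name = "CuO" if f == 0 else f"{f:g}%Fe-CuO"
        mats.append(Material(name=name, fe_fraction=float(f)))
    return mats


def _column_names(cfg: SyntheticConfig) -> tuple[list[str], list[DescriptorKind]]:
    """Names for the concentration-independent columns.

    Planted active descriptors are placed as the first member of their
    own clusters; remaining columns get family-style names.
    """
    actives = list(cfg.true_descriptors)
    if len(actives) > cfg.n_clusters:
        raise ValueError("more active descriptors than clusters")
    names, kinds = [], []
    family_counter = 0
    for ci, size in enumerate(cfg.cluster_sizes):
        for j in range(size):
            if j == 0 and ci < len(actives):
                names.append(actives[ci])
                kinds.append(_KIND_CYCLE[ci % len(_KIND_CYCLE)])
                continue
            kind = _KIND_CYCLE[ci % len(_KIND_CYCLE)]
            names.append(f"{kind.value}_{ci:02d}_{j}")
            kinds.append(kind)
            family_counter += 1
    return names, kinds


def generate_descriptors(cfg: SyntheticConfig) -> tuple[DescriptorMatrix, GroundTruth]:
    """Generate the (material, concentration) x descriptor matrix.

    Concentration-independent columns are constant across
    concentrations for a given material; the three concentration-
    dependent columns (concentration itself, hydrodynamic size, zeta
    potential) follow a deterministic trend in ln c plus a
    material-specific offset.
    """
    if sum(cfg.cluster_sizes) < len(cfg.true_descriptors):
        raise ValueError("cluster sizes inconsistent with active descriptor count")
    rng = np.random.default_rng(cfg.seed)
    materials = _material_library(cfg.n_materials)
    n_mat = len(materials)
    concs = np.asarray(cfg.concentrations, dtype=float)

    values, labels, _ = _planted_rank_blocks(
        n_mat, cfg.cluster_sizes, cfg.within_cluster_abs_rho,
        cfg.between_cluster_abs_rho, rng,
    )
    names, kinds = _column_names(cfg)

    # planted steepness: linear in the standardized active descriptors
    per_mat = pd.DataFrame(values, columns=names, index=[m.name for m in materials])
    z = (per_mat - per_mat.mean()) / per_mat.std(ddof=1)
    b = np.full(n_mat, cfg.b_center)
    for name, coef in cfg.true_descriptors.items():
        b = b + coef * z[name].to_numpy()
    b = np.maximum(b, 0.0)
    b0 = rng.uniform(*cfg.b0_range, size=n_mat)
    # keep every noiseless response positive over the tested range so the
    # count floor at 0 never kinks the planted log-linear law; a single
    # global factor preserves linearity of b in the active descriptors
    ln_cmax = math.log(float(concs.max()))
    with np.errstate(divide="ignore"):
        factors = np.where(b > 0, 0.95 * b0 / (b * ln_cmax), np.inf)
    factor = min(1.0, float(factors.min()))
    b = b * factor

    # assemble rows: material x concentration
    rows = []
    index = []
    zeta_offset = rng.uniform(-14.0, 10.0, size=n_mat)
    hydro_base = rng.uniform(150.0, 400.0, size=n_mat)
    for i, mat in enumerate(materials):
        for c in concs:
            indep = per_mat.iloc[i].to_numpy()
            hydro = hydro_base[i] * (1.0 + 0.15 * math.log(c / concs[0] + 1.0))
            zeta = zeta_offset[i] - 1.5 * math.log(c / concs[0] + 1.0)
            rows.append(np.concatenate([indep, [c, hydro, zeta]]))
            index.append((mat.name, float(c)))

    all_names = names + ["concentration", "hydrodynamic_size", "zeta_potential"]
    data = pd.DataFrame(
        rows,
        columns=all_names,
        index=pd.MultiIndex.from_tuples(index, names=["material", "concentration"]),
    )
    schema = [
        DescriptorColumn(name=n, kind=k, concentration_dependent=False)
        for n, k in zip(names, kinds)
    ] + [
        DescriptorColumn("concentration", DescriptorKind.EXPERIMENTAL, True, "mg/kg"),
        DescriptorColumn("hydrodynamic_size", DescriptorKind.EXPERIMENTAL, True, "nm"),
        DescriptorColumn("zeta_potential", DescriptorKind.EXPERIMENTAL, True, "mV"),
    ]
    truth = GroundTruth(
        materials=materials,
        b={m.name: float(bi) for m, bi in zip(materials, b)},
        b0={m.name: float(b0i) for m, b0i in zip(materials, b0)},
        cluster_labels={n: int(l) for n, l in zip(names, labels)},
        active_descriptors=list(cfg.true_descriptors),
    )
    return DescriptorMatrix(data=data, schema=schema), truth


def generate_bioassay(cfg: SyntheticConfig, truth: GroundTruth) -> list[BioassayRecord]:
    """Organism counts following y = -b ln c + b0 with additive noise.

    Reproduction records are produced for days 21 and 49 (single
    replicate at non-zero concentrations, as in a material-limited
    study), survival records for day 21, and control replicates that
    satisfy the OECD validity criteria.
    """
    rng = np.random.default_rng((cfg.seed + 77_003) % 2**31)
    records: list[BioassayRecord] = []
    concs = np.asarray(cfg.concentrations, dtype=float)

    def emit(count: float, **kw):
        c = max(0.0, count)
        c = round(c) if cfg.round_counts else c
        records.append(BioassayRecord(count=int(c) if cfg.round_counts else c, **kw))

    for mat in truth.materials:
        b, b0 = truth.b[mat.name], truth.b0[mat.name]
        for day in (21, 49):
            # controls: near the intercept scale, tight spread
            for rep in range(1, cfg.n_control_replicates + 1):
                eps = rng.normal(0.0, max(cfg.noise_sd, 0.02) * b0)
                emit(
                    b0 + eps,
                    material=mat.name, concentration=0.0, replicate=rep,
                    day=day, endpoint="reproduction",
                )
            for c in concs:
                eps = rng.normal(0.0, cfg.noise_sd * b0) if cfg.noise_sd > 0 else 0.0
                emit(
                    -b * math.log(c) + b0 + eps,
                    material=mat.name, concentration=float(c), replicate=1,
                    day=day, endpoint="reproduction",
                )
        # adult survival, day 21: no planted effect
        for rep in range(1, cfg.n_control_replicates + 1):
            emit(
                10 if rng.random() < 0.9 else 9,
                material=mat.name, concentration=0.0, replicate=rep,
                day=21, endpoint="survival",
            )
        for c in concs:
            emit(
                10,
                material=mat.name, concentration=float(c), replicate=1,
                day=21, endpoint="survival",
            )
    return records


def planted_b_table(
    truth: GroundTruth, noise_sd: float = 0.0, seed: int = 0
) -> pd.Series:
    """The planted steepness values as a per-material table, with optional noise.

    ``noise_sd`` is relative to the spread (population sd) of the
    planted b values — the natural scale for a descriptor-recovery
    benchmark of the pruning loop, as opposed to noise propagated
    through organism counts and the log fit (for which use
    :func:`generate_bioassay` and refit).
    """
    names = [m.name for m in truth.materials]
    b = np.array([truth.b[n] for n in names])
    if noise_sd > 0:
        rng = np.random.default_rng((seed + 11_311) % 2**31)
        b = b + noise_sd * b.std() * rng.normal(size=len(b))
    return pd.Series(b, index=pd.Index(names, name="material"), name="b")
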