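"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the study design the pipeline targets:

* :func:`simulate_counts` — a two-species bulk RNA-seq time course over a
  shared ortholog list. Each gene follows one of ``k`` canonical temporal
  archetypes in log2 expression space; a planted fraction of genes follows
  a *different* archetype in the second species (the "shifted" genes the
  cross-species analysis should recover). Counts are negative-binomial
  around the compositional expectation, and a GMT-compatible term map is
  built so that gene-set enrichment and the term-shift arc graph are
  recoverable.
* :func:`simulate_lumen_stack` — a fluorescence z-stack phantom: a bright
  shell (a tight-junction-like surface marker) coating an analytic lumen
  surface, blurred and optionally noised, with the true surface area
  computed from a dense triangulation of the analytic surface.
* :func:`simulate_tracks` — division-event tracks with truncated-normal
  inter-division intervals for the cell-cycle utilities.

A note on compositional normalization: TPM is a within-sample proportion,
so the per-sample normalizer couples every gene's measured profile to the
whole transcriptome's temporal behavior. To keep planted log2 profiles
*exactly* affine in their archetype after TPM re-normalization, the
generator appends one balancing gene (a spike-in-like filler) that tops the
expected TPM column sum up to 1e6 at every timepoint. The filler is
excluded from the ground truth and from recovery scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.stats import truncnorm

from .exprpipe import CountMatrix, FuzzyClusterModel, ShiftSet, write_gmt
from .growth import DivisionTrackSet

__all__ = [
    "SynthExprConfig",
    "SynthGroundTruth",
    "LumenPhantomTruth",
    "default_archetypes",
    "simulate_counts",
    "simulate_lumen_stack",
    "simulate_tracks",
    "VolumeStack",
    "archetype_alignment",
    "score_shift_recovery",
]

FILLER_GENE = "SPIKE_BALANCE"


# ---------------------------------------------------------------------------
# expression time course


def default_archetypes(timepoints: Sequence[float], k: int = 10) -> np.ndarray:
    """``k`` canonical temporal shapes over the given timepoints.

    Shapes are defined on three anchor timepoints (first, middle, last) as
    ``k`` equally spaced directions in the plane of mean-zero 3-point
    profiles — which yields monotone rises and falls, early and late peaks,
    and transient dips — and linearly interpolated in time when more
    timepoints are simulated. Each returned row has mean 0 across
    timepoints.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    e1 = np.array([-1.0, 0.0, 1.0]) / math.sqrt(2.0)
    e2 = np.array([1.0, -2.0, 1.0]) / math.sqrt(6.0)
    anchors = np.array([t[0], t[t.size // 2], t[-1]])
    shapes = np.empty((k, t.size))
    for j in range(k):
        theta = 2.0 * math.pi * j / k
        on_anchor = math.cos(theta) * e1 + math.sin(theta) * e2
        shapes[j] = np.interp(t, anchors, on_anchor)
    shapes -= shapes.mean(axis=1, keepdims=True)
    return shapes


@dataclass(frozen=True)
class SynthExprConfig:
    """Design of the synthetic two-species RNA-seq time course.

    Defaults emulate the deposited study design: two species, seven
    collection days, three replicate batches, and a shared-ortholog gene
    list of 16,763 names. ``dispersion`` is the negative-binomial
    overdispersion (var = mu + dispersion*mu^2); 0.05 corresponds to ~22%
    biological CV between replicate organoid batches. ``amplitude`` is the
    log2 swing of the temporal archetypes (about a 4-fold peak-to-trough
    change for a monotone shape). ``noise_free=True`` returns the exact
    negative-binomial means instead of draws (the dispersion->infinity...0
    deterministic limit), useful for exactness checks.
    """

    n_genes: int = 16763
    timepoints: tuple[float, ...] = (0, 2, 3, 5, 10, 15, 25)
    n_replicates: int = 3
    species: tuple[str, str] = ("human", "gorilla")
    n_archetypes: int = 10
    archetypes: tuple[tuple[float, ...], ...] | None = None
    shift_fraction: float = 0.2
    shift_offset: int = 3
    silent_fraction: float = 0.1
    dispersion: float = 0.05
    depth: float = 1e7
    amplitude: float = 2.0
    baseline_log2: tuple[float, float] = (5.0, 9.0)
    gene_length_range: tuple[int, int] = (500, 5000)
    n_terms_per_archetype: int = 3
    n_shift_terms: int = 12
    term_size: int = 30
    term_purity: float = 0.8
    shift_term_archetype: int = 4
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shift_fraction <= 1.0):
            raise ValueError("shift_fraction must be in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per species")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.archetypes is not None:
            for a in self.archetypes:
                if len(a) != len(self.timepoints):
                    raise ValueError(
                        "every archetype must have one value per timepoint"
                    )

    def archetype_matrix(self) -> np.ndarray:
        if self.archetypes is not None:
            return np.asarray(self.archetypes, dtype=float)
        return default_archetypes(self.timepoints, self.n_archetypes)


@dataclass
class SynthGroundTruth:
    """Everything planted by :func:`simulate_counts`.

    ``archetype_of_gene`` maps each (non-filler) gene to its archetype index
    per species; ``shifted_genes`` is exactly the set whose two species
    archetypes differ; ``planted_arc`` is the archetype pair the dedicated
    shift terms should surface as the heaviest arc of the term-shift graph.
    """

    archetype_of_gene: dict[str, pd.Series]
    shifted_genes: frozenset[str]
    silent_genes: frozenset[str]
    expressed_genes: frozenset[str]
    term_map: dict[str, frozenset[str]]
    archetype_z: np.ndarray  # k x T, z-scaled archetype shapes
    planted_arc: tuple[int, int]
    filler_gene: str | None


def simulate_counts(config: SynthExprConfig) -> tuple[CountMatrix, SynthGroundTruth]:
    """Simulate the two-species count matrix plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    k = config.n_archetypes
    tps = np.asarray(config.timepoints, dtype=float)
    T = tps.size
    sp_a, sp_b = config.species
    shapes = config.archetype_matrix()
    if shapes.shape[0] != k:
        k = shapes.shape[0]

    width = len(str(max(config.n_genes - 1, 1)))
    genes = [f"g{i:0{width}d}" for i in range(config.n_genes)]

    n_silent = int(round(config.silent_fraction * config.n_genes))
    n_shift = int(round(config.shift_fraction * config.n_genes))
    if n_shift + n_silent > config.n_genes:
        raise ValueError("shift_fraction + silent_fraction exceed the gene pool")
    perm = rng.permutation(config.n_genes)
    silent_idx = np.sort(perm[:n_silent])
    expressed_idx = np.sort(perm[n_silent:])
    shifted_idx = np.sort(rng.choice(expressed_idx, size=n_shift, replace=False))

    arch_a = rng.integers(0, k, size=config.n_genes)
    arch_b = arch_a.copy()
    offset = config.shift_offset % k
    if offset == 0 and n_shift > 0:
        raise ValueError("shift_offset must be non-zero modulo the archetype count")
    arch_b[shifted_idx] = (arch_a[shifted_idx] + offset) % k

    # expected TPM: log2(TPM + 1) is exactly baseline + amplitude * shape
    baseline = rng.uniform(*config.baseline_log2, size=config.n_genes)
    tpm_true = {
        sp_a: 2.0 ** (baseline[:, None] + config.amplitude * shapes[arch_a]) - 1.0,
        sp_b: 2.0 ** (baseline[:, None] + config.amplitude * shapes[arch_b]) - 1.0,
    }
    silent_level = rng.uniform(0.5, 5.0, size=n_silent)
    for sp in config.species:
        tpm_true[sp][silent_idx, :] = silent_level[:, None]

    # balancing filler keeps every expected TPM column at exactly 1e6
    all_genes = list(genes)
    filler = FILLER_GENE
    col_sums = np.vstack([tpm_true[sp].sum(axis=0) for sp in config.species])
    if col_sums.max() >= 1e6:
        raise ValueError(
            "expected TPM exceeds 1e6 before balancing; lower baseline_log2 "
            "or n_genes"
        )
    for sp in config.species:
        fill_row = 1e6 - tpm_true[sp].sum(axis=0)
        tpm_true[sp] = np.vstack([tpm_true[sp], fill_row])
    all_genes.append(filler)

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1,
        size=len(all_genes),
    ).astype(float)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for sp in config.species:
        for ti, day in enumerate(tps):
            # expected read share is length-weighted composition
            weights = tpm_true[sp][:, ti] * lengths
            lam = config.depth * weights / weights.sum()
            for rep in range(1, config.n_replicates + 1):
                name = f"{sp}_d{day:g}_r{rep}"
                if config.noise_free:
                    col = lam.copy()
                elif config.dispersion == 0:
                    col = rng.poisson(lam).astype(float)
                else:
                    r_nb = 1.0 / config.dispersion
                    p_nb = r_nb / (r_nb + lam)
                    col = rng.negative_binomial(r_nb, p_nb).astype(float)
                columns[name] = col
                meta_rows.append(
                    {"sample": name, "species": sp, "day": day, "replicate": rep}
                )

    counts = pd.DataFrame(columns, index=all_genes)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    cm = CountMatrix(
        counts=counts,
        sample_meta=meta,
        gene_length=pd.Series(lengths, index=all_genes, name="length"),
    )

    gene_arr = np.array(genes)
    silent_genes = frozenset(gene_arr[silent_idx])
    expressed_genes = frozenset(gene_arr[expressed_idx])
    shifted_genes = frozenset(gene_arr[shifted_idx])
    term_map = _build_term_map(
        config, rng, gene_arr, arch_a, shifted_idx, expressed_idx
    )

    z_shapes = shapes - shapes.mean(axis=1, keepdims=True)
    sd = z_shapes.std(axis=1, ddof=1, keepdims=True)
    z_shapes = np.divide(z_shapes, np.where(sd == 0, 1.0, sd))

    truth = SynthGroundTruth(
        archetype_of_gene={
            sp_a: pd.Series(arch_a, index=genes),
            sp_b: pd.Series(arch_b, index=genes),
        },
        shifted_genes=shifted_genes,
        silent_genes=silent_genes,
        expressed_genes=expressed_genes,
        term_map=term_map,
        archetype_z=z_shapes,
        planted_arc=(
            config.shift_term_archetype,
            (config.shift_term_archetype + offset) % k,
        ),
        filler_gene=filler,
    )
    return cm, truth


def _build_term_map(
    config: SynthExprConfig,
    rng: np.random.Generator,
    gene_arr: np.ndarray,
    arch_a: np.ndarray,
    shifted_idx: np.ndarray,
    expressed_idx: np.ndarray,
) -> dict[str, frozenset[str]]:
    """Terms correlated with archetypes.

    Per archetype, ``n_terms_per_archetype`` terms draw ``term_purity`` of
    their genes from stably expressed (non-shifted) genes of that archetype
    and the rest from the expressed background — these enrich at the same
    cluster in both species. ``n_shift_terms`` additional terms draw from
    the *shifted* genes whose first-species archetype is
    ``shift_term_archetype``; these enrich at different clusters per species
    and should dominate the term-shift graph.
    """
    k = config.n_archetypes
    shifted_set = set(shifted_idx.tolist())
    expressed = expressed_idx
    stable = np.array(sorted(set(expressed.tolist()) - shifted_set), dtype=int)
    term_map: dict[str, frozenset[str]] = {}
    n_core = int(round(config.term_purity * config.term_size))
    n_bg = config.term_size - n_core

    def _draw(pool: np.ndarray, n: int) -> np.ndarray:
        if len(pool) == 0 or n == 0:
            return np.empty(0, dtype=int)
        return rng.choice(pool, size=min(n, len(pool)), replace=False)

    for j in range(k):
        pool = stable[arch_a[stable] == j]
        for t in range(config.n_terms_per_archetype):
            core = _draw(pool, n_core)
            bg = _draw(np.setdiff1d(expressed, core), n_bg)
            term_map[f"TERM_A{j}_{t}"] = frozenset(gene_arr[np.concatenate([core, bg])])
    shift_pool = np.array(
        [i for i in shifted_idx if arch_a[i] == config.shift_term_archetype],
        dtype=int,
    )
    for t in range(config.n_shift_terms):
        core = _draw(shift_pool, n_core)
        bg = _draw(np.setdiff1d(expressed, core), n_bg)
        term_map[f"TERM_SHIFT_{t}"] = frozenset(gene_arr[np.concatenate([core, bg])])
    return term_map


# ---------------------------------------------------------------------------
# ground-truth-aware evaluation helpers


def archetype_alignment(
    model: FuzzyClusterModel, truth: SynthGroundTruth
) -> np.ndarray:
    """Map each fitted cluster to its nearest planted archetype.

    Cluster labels from an unsupervised run are an arbitrary permutation of
    the planted archetype indices; this aligns them by maximal Pearson
    correlation between centroid and z-scaled archetype shape.
    """
    cent = model.centroids - model.centroids.mean(axis=1, keepdims=True)
    arch = truth.archetype_z - truth.archetype_z.mean(axis=1, keepdims=True)
    cn = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    an = arch / np.linalg.norm(arch, axis=1, keepdims=True)
    corr = cn @ an.T
    return corr.argmax(axis=1)


def score_shift_recovery(
    shifts: ShiftSet, truth: SynthGroundTruth, which: str = "assigned"
) -> dict[str, float]:
    """Sensitivity and precision of shift detection against the planted set.

    Sensitivity counts every planted shifted gene, including those the
    filters or the consistency assignment discarded; precision is over the
    called set.
    """
    called = shifts.assigned_shift if which == "assigned" else shifts.robust_shift
    planted = truth.shifted_genes
    tp = len(called & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    precision = tp / len(called) if called else float("nan")
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_called": float(len(called)),
        "n_planted": float(len(planted)),
    }


# ---------------------------------------------------------------------------
# lumen phantoms


@dataclass
class VolumeStack:
    """Calibrated single-channel intensity volume (z, y, x)."""

    intensity: np.ndarray
    voxel: tuple[float, float, float]  # (dz, dy, dx) in microns
    channel: str = "ZO1"

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3 or self.intensity.shape[0] < 2:
            raise ValueError("stack must be 3D with at least 2 z-slices")
        if any(v <= 0 for v in self.voxel):
            raise ValueError("voxel sizes must be positive")


@dataclass(frozen=True)
class LumenPhantomTruth:
    """Analytic surface areas of the phantom's lumens (um^2)."""

    areas: tuple[float, ...]

    @property
    def largest(self) -> float:
        return max(self.areas)

    @property
    def total(self) -> float:
        return sum(self.areas)


def _analytic_area(radii: tuple[float, float, float]) -> float:
    """Surface area from a dense triangulation of the analytic ellipsoid."""
    mesh = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
    mesh.apply_scale(radii)
    return float(mesh.area)


def simulate_lumen_stack(
    shape: Literal["sphere", "ellipsoid", "two_lobed"],
    radii: float | Sequence[float],
    voxel: tuple[float, float, float] = (2.0, 1.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    shell_thickness_um: float = 2.0,
    lobe_gap_um: float = 10.0,
) -> tuple[VolumeStack, LumenPhantomTruth]:
    """Z-stack phantom of one or two lumens bounded by a bright shell.

    The shell (value 1.0 over background 0.1) coats the *outside* of the
    analytic surface, mimicking an apical surface marker surrounding a dark
    lumen; it is blurred with a 1-voxel Gaussian PSF before optional
    Gaussian noise. ``two_lobed`` places two spheres with radii
    ``(r1, r2)`` separated along x by ``lobe_gap_um``. The returned truth
    holds each lumen's analytic surface area.
    """
    dz, dy, dx = voxel
    if shape == "sphere":
        r = float(np.atleast_1d(radii)[0])
        components = [((0.0, 0.0, 0.0), (r, r, r))]
    elif shape == "ellipsoid":
        rx, ry, rz = (float(v) for v in radii)  # radii given as (x, y, z)
        components = [((0.0, 0.0, 0.0), (rx, ry, rz))]
    elif shape == "two_lobed":
        r1, r2 = (float(v) for v in radii)
        # surface-to-surface gap along x equals lobe_gap_um
        components = [
            ((-(r1 + lobe_gap_um / 2.0), 0.0, 0.0), (r1, r1, r1)),
            ((r2 + lobe_gap_um / 2.0, 0.0, 0.0), (r2, r2, r2)),
        ]
    else:
        raise ValueError(f"unknown phantom shape {shape!r}")

    for _c, rads in components:
        if min(rads) < 3 * max(voxel):
            raise ValueError(
                f"radii {rads} too small for voxel {voxel}; need >= 3 voxels per axis"
            )

    margin = shell_thickness_um + 4 * max(voxel)
    xs = [c[0] for c, _ in components]
    rx_max = max(r[0] for _, r in components)
    ry_max = max(r[1] for _, r in components)
    rz_max = max(r[2] for _, r in components)
    x_lo, x_hi = min(xs) - rx_max - margin, max(xs) + rx_max + margin
    y_half = ry_max + margin
    z_half = rz_max + margin

    z = np.arange(-z_half, z_half + dz, dz)
    y = np.arange(-y_half, y_half + dy, dy)
    x = np.arange(x_lo, x_hi + dx, dx)
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")

    vol = np.full(Z.shape, 0.1)
    for (cx, cy, cz), (rx, ry, rz) in components:
        rad = np.sqrt(
            ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2
        )
        # membrane-like shell straddling the analytic surface, ~constant
        # micron thickness (the marked surface runs through the ridge line)
        r_min = min(rx, ry, rz)
        half = 0.5 * shell_thickness_um / r_min
        shell = (rad >= 1.0 - half) & (rad <= 1.0 + half)
        vol[shell] = 1.0

    # PSF has a fixed physical width (one in-plane voxel, in um), so the
    # phantom's optics do not change when the z-sampling interval does
    sigma_um = min(dy, dx)
    vol = ndimage.gaussian_filter(
        vol, sigma=(sigma_um / dz, sigma_um / dy, sigma_um / dx)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
        vol = np.clip(vol, 0.0, None)

    areas = tuple(_analytic_area(r) for _c, r in components)
    return VolumeStack(vol, voxel), LumenPhantomTruth(areas)


# ---------------------------------------------------------------------------
# division tracks


def simulate_tracks(
    mean_hours: float,
    sd_hours: float,
    n_cells: int,
    seed: int = 0,
    divisions_per_track: int = 2,
) -> DivisionTrackSet:
    """Division-event tracks with truncated-normal (>0) cycle intervals."""
    if mean_hours <= 0:
        raise ValueError("mean_hours must be positive")
    if sd_hours < 0:
        raise ValueError("sd_hours must be non-negative")
    if divisions_per_track < 2:
        raise ValueError("a track needs at least 2 divisions")
    rng = np.random.default_rng(seed)
    tracks = []
    n_int = divisions_per_track - 1
    for i in range(n_cells):
        start = float(rng.uniform(0.0, 5.0))
        if sd_hours == 0:
            intervals = np.full(n_int, mean_hours)
        else:
            a = (0.0 - mean_hours) / sd_hours
            intervals = truncnorm.rvs(
                a, np.inf, loc=mean_hours, scale=sd_hours, size=n_int,
                random_state=rng,
            )
        times = start + np.concatenate([[0.0], np.cumsum(intervals)])
        tracks.append((f"cell{i:04d}", tuple(float(t) for t in times)))
    return DivisionTrackSet(tuple(tracks))


# ---------------------------------------------------------------------------
# writers (text formats used by the CLI)


def write_expr_dataset(
    cm: CountMatrix, truth: SynthGroundTruth, outdir: str | Path
) -> None:
    """Write counts/meta/lengths TSVs, the GMT term map and a truth TSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cm.counts.to_csv(out / "counts.tsv", sep="\t")
    cm.sample_meta.to_csv(out / "sample_meta.tsv", sep="\t")
    cm.gene_length.rename("length").to_csv(out / "gene_lengths.tsv", sep="\t")
    write_gmt(truth.term_map, out / "terms.gmt")
    species = sorted(truth.archetype_of_gene)
    tdf = pd.DataFrame(
        {f"archetype_{sp}": truth.archetype_of_gene[sp] for sp in species}
    )
    tdf["shifted"] = tdf.index.isin(truth.shifted_genes)
    tdf["silent"] = tdf.index.isin(truth.silent_genes)
    tdf.to_csv(out / "ground_truth.tsv", sep="\t", index_label="gene")


def write_tracks(tracks: DivisionTrackSet, path: str | Path) -> None:
    tracks.to_frame().to_csv(path, index=False)
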