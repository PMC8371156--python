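"""Synthetic cohorts for exercising the pipeline end to end.

Two levels of synthesis:

* :func:`simulate_feature_table` draws per-cell feature tables directly,
  with planted statistical structure — a case/control cohort with a
  genotype shift on a configurable subset of the 124 features,
  per-individual Gaussian random effects shared by all of an individual's
  cells, block-equicorrelated within-family cell noise, optional per-run
  batch offsets, and a simulated treatment that reverts a configurable
  fraction of the planted shift.
* :func:`render_field` rasterises a five-channel fluorescence field
  (nucleus ellipses, star-shaped cell bodies, elongated mitochondrial
  blobs, tubulin filament strokes, textured phase contrast) with
  ground-truth masks, so segmentation and feature extraction can be
  validated against known geometry.

All outputs are pure functions of the configuration and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .core import FieldImage, LabelMask
from .features import FEATURE_NAMES, MARKERS, METADATA_COLUMNS, N_FEATURES


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated case/control fibroblast cohort.

    effect_size is the group mean shift in pooled-SD units (cell noise
    plus between-individual variance); individual_sd is the SD of the
    per-individual random effect on each feature; within_family_corr is
    the equicorrelation of cell noise among features of the same
    (marker, family) block; treatment_reversion is the fraction of the
    planted shift removed in treated cells (overridable per marker).
    """

    n_group0: int = 9
    n_group1: int = 10
    cells_per_individual: int = 500
    effect_size: float = 1.5
    affected_count: int = 40
    individual_sd: float = 0.3
    within_family_corr: float = 0.3
    treatment_reversion: float = 0.0
    reversion_by_marker: dict | None = None
    n_runs: int = 1
    run_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_group0, self.n_group1, self.cells_per_individual,
               self.n_runs) < 1:
            raise ValueError("counts must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.treatment_reversion <= 1:
            raise ValueError("treatment_reversion must be in [0, 1]")
        if not 0 <= self.within_family_corr < 1:
            raise ValueError("within_family_corr must be in [0, 1)")
        if self.individual_sd < 0 or self.run_offset_sd < 0:
            raise ValueError("SDs must be >= 0")
        if not 0 <= self.affected_count <= N_FEATURES:
            raise ValueError(
                f"affected_count must be in [0, {N_FEATURES}]")

    @classmethod
    def from_affected_fraction(cls, fraction: float, **kwargs) -> "CohortConfig":
        return cls(affected_count=int(round(fraction * N_FEATURES)), **kwargs)


# (marker, family) blocks over which cell noise is equicorrelated
_FAMILY_OF = np.array([name.split(".")[1] for name in FEATURE_NAMES])
_MARKER_OF = np.array([name.split(".")[0] for name in FEATURE_NAMES])
_BLOCK_KEYS = [f"{m}.{f}" for m, f in zip(_MARKER_OF, _FAMILY_OF)]
_BLOCK_INDEX = {k: i for i, k in enumerate(dict.fromkeys(_BLOCK_KEYS))}
_BLOCK_OF = np.array([_BLOCK_INDEX[k] for k in _BLOCK_KEYS])
N_BLOCKS = len(_BLOCK_INDEX)


def planted_effect_vector(config: CohortConfig) -> np.ndarray:
    """Per-feature group-1 mean shift the generator plants (length 124).

    The shift is ``effect_size`` in pooled-SD units on ``affected_count``
    features chosen reproducibly from the seed, zero elsewhere.  Exposed
    so tests can compare recovered effects against the generator's truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xAFFEC]))
    affected = rng.choice(N_FEATURES, size=config.affected_count, replace=False)
    pooled_sd = math.sqrt(1.0 + config.individual_sd**2)
    delta = np.zeros(N_FEATURES)
    delta[affected] = config.effect_size * pooled_sd
    return delta


def _cell_noise(rng: np.random.Generator, n_cells: int,
                rho: float) -> np.ndarray:
    """Unit-variance noise, equicorrelated (rho) within feature families."""
    indep = rng.standard_normal((n_cells, N_FEATURES))
    if rho == 0:
        return indep
    shared = rng.standard_normal((n_cells, N_BLOCKS))
    return math.sqrt(rho) * shared[:, _BLOCK_OF] + math.sqrt(1 - rho) * indep


def _reversion_of(config: CohortConfig) -> np.ndarray:
    rev = np.full(N_FEATURES, config.treatment_reversion)
    for marker, r in (config.reversion_by_marker or {}).items():
        if marker not in MARKERS:
            raise ValueError(f"unknown marker {marker!r}")
        if not 0 <= r <= 1:
            raise ValueError("reversion must be in [0, 1]")
        rev[_MARKER_OF == marker] = r
    return rev


def simulate_feature_table(config: CohortConfig,
                           include_treated: bool = False) -> pd.DataFrame:
    """Simulate a per-cell feature table with planted group structure.

    Each cell's 124-vector is global mean + group shift (group-1
    individuals, affected features only) + per-individual random effect +
    correlated unit-variance cell noise (+ optional per-run batch offset).
    With ``include_treated`` a treated copy of every group-1 individual is
    appended whose shift is multiplied by (1 - reversion); the treated
    cells share their individual's random effect but draw fresh noise.

    Returns a DataFrame with metadata columns
    ``individual_id, group, treatment, run, well`` plus the 124 canonical
    feature columns.  Identical config (including seed) gives a
    bit-identical table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0407]))
    delta = planted_effect_vector(config)
    reversion = _reversion_of(config)
    run_names = [f"run{r + 1}" for r in range(config.n_runs)]
    run_offsets = rng.normal(0.0, config.run_offset_sd,
                             (config.n_runs, N_FEATURES)) \
        if config.run_offset_sd > 0 else np.zeros((config.n_runs, N_FEATURES))

    individuals = (
        [(f"C{i + 1:02d}", 0) for i in range(config.n_group0)]
        + [(f"P{i + 1:02d}", 1) for i in range(config.n_group1)]
    )
    frames = []
    for idx, (ind_id, group) in enumerate(individuals):
        b = rng.normal(0.0, config.individual_sd, N_FEATURES)
        arms = [("untreated", 1.0)]
        if include_treated and group == 1:
            arms.append(("treated", None))  # per-feature reversion applied below
        for treatment, _ in arms:
            shift = delta * group
            if treatment == "treated":
                shift = shift * (1.0 - reversion)
            noise = _cell_noise(rng, config.cells_per_individual,
                                config.within_family_corr)
            runs = np.arange(config.cells_per_individual) % config.n_runs
            values = shift + b + noise + run_offsets[runs]
            df = pd.DataFrame(values, columns=list(FEATURE_NAMES))
            df.insert(0, "individual_id", ind_id)
            df.insert(1, "group", group)
            df.insert(2, "treatment", treatment)
            df.insert(3, "run", [run_names[r] for r in runs])
            df.insert(4, "well", f"{'ABCDEFGH'[idx % 8]}{idx // 8 + 1}")
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return table[list(METADATA_COLUMNS) + list(FEATURE_NAMES)]


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and noise of one rendered five-channel field."""

    n_cells: int = 12
    image_size: int = 512
    nucleus_radius: float = 9.0
    nucleus_eccentricity: float = 0.3
    cell_radius: float = 26.0
    protrusions: int = 4
    protrusion_depth: float = 0.25
    mito_count: int = 10
    mito_length: float = 7.0
    mito_elongation: float = 3.0
    tubulin_filaments: int = 8
    tubulin_intensity: float = 1.0
    noise_gaussian: float = 0.01
    noise_photons: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.image_size < 32:
            raise ValueError("need n_cells >= 1 and image_size >= 32")
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus must be smaller than the cell")


@dataclass
class RenderedField:
    """A rendered field plus its ground truth, for oracle tests."""

    field: FieldImage
    nuclei: LabelMask
    cells: LabelMask
    mito_blobs: LabelMask
    cell_params: list = field(default_factory=list)


class PlacementError(RuntimeError):
    pass


def _place_centres(rng, spec: SceneSpec, max_tries: int = 200) -> np.ndarray:
    margin = spec.cell_radius * (1 + spec.protrusion_depth) + 2
    min_sep = 2.05 * spec.cell_radius * (1 + spec.protrusion_depth)
    lo, hi = margin, spec.image_size - margin
    if hi <= lo:
        raise PlacementError("image too small for the configured cell radius")
    centres: list[np.ndarray] = []
    for i in range(spec.n_cells):
        for _ in range(max_tries):
            cand = rng.uniform(lo, hi, 2)
            if all(np.hypot(*(cand - c)) >= min_sep for c in centres):
                centres.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place cell {i} after {max_tries} tries; "
                "reduce n_cells or enlarge image_size")
    return np.array(centres)


def _cell_polygon(rng, spec: SceneSpec, centre) -> tuple[np.ndarray, np.ndarray]:
    theta = np.linspace(0, 2 * math.pi, 120, endpoint=False)
    phase = rng.uniform(0, 2 * math.pi)
    radius = spec.cell_radius * (
        1 + spec.protrusion_depth * np.cos(spec.protrusions * theta + phase))
    return (centre[0] + radius * np.sin(theta),
            centre[1] + radius * np.cos(theta))


def render_field(spec: SceneSpec) -> RenderedField:
    """Render one five-channel field with non-overlapping cells.

    Channels: nucleus = smoothed ellipses; cellmask = filled star-shaped
    cell bodies; mito = elongated blobs inside the cytoplasm; aat =
    filament strokes radiating from the nucleus; phase = textured cell
    body.  Ground-truth nucleus/cell/mitochondrion label masks and the
    per-cell geometry parameters are returned for oracle tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5CE9E]))
    size = spec.image_size
    shape = (size, size)
    centres = _place_centres(rng, spec)

    nuc_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    mito_labels = np.zeros(shape, dtype=np.int32)
    chan = {name: np.zeros(shape) for name in
            ("nucleus", "mito", "aat", "cellmask", "phase")}
    params = []
    mito_id = 0

    for k, centre in enumerate(centres, start=1):
        rr, cc = _cell_polygon(rng, spec, centre)
        crr, ccc = draw.polygon(rr, cc, shape)
        cell_labels[crr, ccc] = k

        angle = rng.uniform(0, math.pi)
        a = spec.nucleus_radius * (1 + spec.nucleus_eccentricity)
        b = spec.nucleus_radius * (1 - spec.nucleus_eccentricity)
        nrr, ncc = draw.ellipse(centre[0], centre[1], a, b,
                                shape=shape, rotation=angle)
        nuc_labels[nrr, ncc] = k
        chan["nucleus"][nrr, ncc] = 1.0

        cell_mask = cell_labels == k
        chan["cellmask"][cell_mask] = 1.0
        chan["phase"][cell_mask] = 0.5 + 0.25 * rng.random(int(cell_mask.sum()))

        cyto = cell_mask & (nuc_labels != k)
        cyto_coords = np.column_stack(np.nonzero(cyto))
        for _ in range(spec.mito_count):
            mito_id += 1
            p = cyto_coords[rng.integers(len(cyto_coords))]
            ang = rng.uniform(0, math.pi)
            half = spec.mito_elongation * spec.mito_length / 2.0
            d = np.array([math.sin(ang), math.cos(ang)])
            p0 = np.clip(p - half * d, 0, size - 1).astype(int)
            p1 = np.clip(p + half * d, 0, size - 1).astype(int)
            mrr, mcc = draw.line(p0[0], p0[1], p1[0], p1[1])
            stamp = np.zeros(shape, dtype=bool)
            stamp[mrr, mcc] = True
            stamp = ndimage.binary_dilation(stamp, iterations=1)
            mito_labels[stamp] = mito_id
            chan["mito"][stamp] = 1.0

        nuc_edge = centre + np.array([0.0, 0.0])
        for _ in range(spec.tubulin_filaments):
            ang = rng.uniform(0, 2 * math.pi)
            d = np.array([math.sin(ang), math.cos(ang)])
            p0 = (nuc_edge + spec.nucleus_radius * 0.8 * d).astype(int)
            p1 = (nuc_edge + spec.cell_radius * 0.95 * d).astype(int)
            p0, p1 = np.clip(p0, 0, size - 1), np.clip(p1, 0, size - 1)
            trr, tcc = draw.line(p0[0], p0[1], p1[0], p1[1])
            chan["aat"][trr, tcc] += spec.tubulin_intensity

        params.append({"centre": tuple(centre), "nucleus_angle": angle,
                       "nucleus_axes": (a, b)})

    for name, sigma in (("nucleus", 1.0), ("mito", 0.8), ("aat", 0.8),
                        ("cellmask", 1.0), ("phase", 0.5)):
        img = ndimage.gaussian_filter(chan[name], sigma)
        if spec.noise_photons > 0:
            img = rng.poisson(img * spec.noise_photons) / spec.noise_photons
        img = img + rng.normal(0, spec.noise_gaussian, shape)
        chan[name] = np.clip(img, 0, None)

    field_img = FieldImage(channels=chan, pixel_size=1.0,
                           provenance={"seed": spec.seed, "n_cells": spec.n_cells})
    return RenderedField(field=field_img,
                         nuclei=LabelMask(nuc_labels),
                         cells=LabelMask(cell_labels),
                         mito_blobs=LabelMask(mito_labels),
                         cell_params=params)


def simulate_run_pair(config: CohortConfig, shift: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two acquisition runs of the same cell lines.

    The individuals (and their random effects) are shared between runs —
    only the cell-level noise is redrawn, as when the same lines are
    re-imaged on different days.  Each run carries half of
    ``cells_per_individual``.  The second run optionally adds a global
    batch ``shift`` to every feature — the positive control for
    reproducibility checks.
    """
    both = simulate_feature_table(replace(config, n_runs=2))
    table_a = both[both["run"] == "run1"].reset_index(drop=True).copy()
    table_b = both[both["run"] == "run2"].reset_index(drop=True).copy()
    if shift:
        table_b[list(FEATURE_NAMES)] += shift
    table_a["run"] = "runA"
    table_b["run"] = "runB"
    return table_a, table_b
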