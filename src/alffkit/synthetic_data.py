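"""Synthetic inputs for every pipeline stage: 4D BOLD-like volumes with
controlled band-limited amplitude structure, label atlases and brain masks,
clinical tables drawn at configured group summary statistics, and feature
matrices for the classifier experiment.

The voxel generative model is sinusoids plus white noise: each voxel's
series is a constant baseline plus a fixed number of sinusoids whose
frequencies are drawn uniformly inside the low-frequency band (0.02-0.07 Hz)
with random phases, plus Gaussian noise. This is chosen over filtered 1/f
noise because the band-limited amplitude ground truth is then analytic
(a noiseless unit sinusoid has variance 1/2 and a known single-bin
amplitude); an optional 1/f background can be added for realism checks.
Inside planted regions, subjects of the elevated group ("treatment") have
their sinusoid amplitudes multiplied by the region's multiplier, creating a
known group difference for the recovery experiments.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import CLINICAL_COLUMNS, GROUPS, BrainMask, ClinicalTable, LabelAtlas, TimeSeriesVolume

__all__ = [
    "PlantedRegion",
    "SimulationConfig",
    "ClinicalSimConfig",
    "default_atlas",
    "simulate_subject",
    "simulate_cohort",
    "simulate_clinical",
    "simulate_feature_table",
]

#: the study acquisition geometry (64x64 in-plane, 30 slices, 260 volumes)
FULL_GRID = (64, 64, 30)
#: reduced grid used for fast end-to-end runs
TEST_GRID = (24, 24, 12)


@dataclass(frozen=True)
class PlantedRegion:
    """An atlas label whose band-limited amplitude is scaled (elevated group
    only) by ``band_amplitude_multiplier``."""

    label: int
    band_amplitude_multiplier: float

    def __post_init__(self) -> None:
        if self.band_amplitude_multiplier <= 0:
            raise ValueError("multiplier must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the BOLD simulator.

    The defaults match the study's acquisition timing (TR 2 s, 260 volumes
    of which the first 20 are discarded downstream) on the reduced grid;
    ``grid_shape=FULL_GRID`` reproduces the full 64x64x30 geometry. Voxel
    size on the reduced grid is 6x6x10 mm so the grid spans a head-like
    field of view and default 6 mm smoothing stays sub-voxel.
    """

    grid_shape: tuple[int, int, int] = TEST_GRID
    n_timepoints: int = 260
    tr_seconds: float = 2.0
    voxel_size_mm: tuple[float, float, float] = (6.0, 6.0, 10.0)
    n_sinusoids: int = 3
    sinusoid_amplitude: float = 1.0
    freq_band: tuple[float, float] = (0.02, 0.07)
    baseline: float = 100.0
    noise_sd: float = 1.0
    pink_noise_sd: float = 0.0
    planted_regions: tuple[PlantedRegion, ...] = ()

    def __post_init__(self) -> None:
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be > 0")
        if self.noise_sd < 0 or self.pink_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        low, high = self.freq_band
        if not (0 < low < high <= 1.0 / (2 * self.tr_seconds)):
            raise ValueError("freq_band must lie in (0, Nyquist]")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag((*self.voxel_size_mm, 1.0))
        return aff


def default_atlas(grid_shape: tuple[int, int, int] = TEST_GRID) -> tuple[LabelAtlas, BrainMask]:
    """Ellipsoidal brain mask plus a two-region atlas.

    Region 1 is a 5x4x3 (60-voxel) box in the low-x half of the grid
    ("left"); region 2 is a mirrored box in the high-x half. Both sit well
    inside the mask. Planting an effect in region 1 only leaves the other
    hemisphere as a built-in negative control.
    """
    nx, ny, nz = grid_shape
    centre = (np.array(grid_shape) - 1) / 2.0
    semi = np.maximum(np.array(grid_shape) / 2.0 - 1.0, 1.0)
    ii, jj, kk = np.indices(grid_shape)
    dist = (
        ((ii - centre[0]) / semi[0]) ** 2
        + ((jj - centre[1]) / semi[1]) ** 2
        + ((kk - centre[2]) / semi[2]) ** 2
    )
    mask = dist <= 1.0

    atlas = np.zeros(grid_shape, dtype=np.int32)
    x0 = max(nx // 4 - 2, 0)
    y0, z0 = ny // 2 - 2, nz // 2 - 1
    atlas[x0 : x0 + 5, y0 : y0 + 4, z0 : z0 + 3] = 1
    x1 = min(3 * nx // 4 - 2, nx - 5)
    atlas[x1 : x1 + 5, y0 : y0 + 4, z0 : z0 + 3] = 2
    atlas[~mask] = 0
    affine = np.diag((6.0, 6.0, 10.0, 1.0))
    return (
        LabelAtlas(data=atlas, names={1: "region_1", 2: "region_2"}, affine=affine),
        BrainMask(data=mask, affine=affine),
    )


def _pink_background(rng: np.random.Generator, n_voxels: int, n: int, tr: float, sd: float) -> np.ndarray:
    """Zero-mean 1/f-amplitude background, scaled to per-voxel SD ``sd``."""
    freqs = np.fft.rfftfreq(n, d=tr)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_voxels, freqs.size)) + 1j * rng.standard_normal((n_voxels, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    scale = x.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return sd * x / scale


def simulate_subject(
    config: SimulationConfig,
    group: str,
    seed,
    atlas: LabelAtlas | None = None,
) -> TimeSeriesVolume:
    """One subject's 4D volume under the sinusoid-plus-noise model.

    ``atlas`` supplies the planted-region geometry; when omitted, the default
    atlas for the configured grid is used. Deterministic given seed.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if atlas is None:
        atlas, _ = default_atlas(config.grid_shape)
    rng = np.random.default_rng(seed)
    shape = config.grid_shape
    n_vox = int(np.prod(shape))
    n = config.n_timepoints
    k = config.n_sinusoids

    amp = np.full(n_vox, config.sinusoid_amplitude, dtype=np.float64)
    if group == "treatment":
        flat_labels = atlas.data.reshape(-1)
        for region in config.planted_regions:
            amp[flat_labels == region.label] *= region.band_amplitude_multiplier

    low, high = config.freq_band
    freqs = rng.uniform(low, high, size=(n_vox, k))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_vox, k))
    t = np.arange(n, dtype=np.float64) * config.tr_seconds
    # per-voxel amplitude is shared by all its sinusoids, so scale after summing
    arg = 2.0 * np.pi * freqs[:, :, None] * t[None, None, :] + phases[:, :, None]
    signal = amp[:, None] * np.sin(arg).sum(axis=1)
    data = config.baseline + signal
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=(n_vox, n))
    if config.pink_noise_sd > 0:
        data = data + _pink_background(rng, n_vox, n, config.tr_seconds, config.pink_noise_sd)
    return TimeSeriesVolume(
        data=data.reshape(*shape, n),
        tr_seconds=config.tr_seconds,
        affine=config.affine,
        voxel_size_mm=np.asarray(config.voxel_size_mm),
    )


def subject_seeds(seed: int, n_total: int) -> list[np.random.SeedSequence]:
    """Per-subject child seeds, reproducibly derived from a cohort seed."""
    return np.random.SeedSequence(seed).spawn(n_total)


def simulate_cohort(
    config: SimulationConfig, n_per_group: int, seed: int
) -> tuple[list[tuple[str, str, TimeSeriesVolume]], LabelAtlas, BrainMask]:
    """A full two-group cohort plus its atlas and mask.

    Subject ids are ``treatment_00`` .. ``control_NN``; the treatment group
    carries the planted amplitude elevation.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group for group statistics")
    atlas, mask = default_atlas(config.grid_shape)
    seeds = subject_seeds(seed, 2 * n_per_group)
    subjects = []
    for g_idx, group in enumerate(GROUPS):
        for i in range(n_per_group):
            child = seeds[g_idx * n_per_group + i]
            vol = simulate_subject(config, group, child, atlas=atlas)
            subjects.append((f"{group}_{i:02d}", group, vol))
    return subjects, atlas, mask


# ---------------------------------------------------------------------------
# Clinical tables

# Printed group summaries (mean, SD): VAS points at baseline and weeks 1-4,
# continuous sleep hours at weeks 1-4. The control-group VAS at weeks 1-2 is
# not printed and is linearly interpolated between baseline and week 3
# (flagged: non-printed values).
TREATMENT_VAS = ((8.3, 1.1), (6.5, 0.8), (6.5, 0.8), (3.1, 0.3), (2.3, 0.4))
CONTROL_VAS = ((8.3, 1.2), (7.4, 0.8), (6.4, 0.8), (5.5, 0.5), (4.6, 0.5))
TREATMENT_SLEEP = ((3.6, 0.3), (4.8, 0.5), (5.1, 0.4), (5.8, 0.6))
CONTROL_SLEEP = ((2.5, 0.4), (3.3, 0.3), (3.9, 0.3), (4.1, 0.4))


@dataclass(frozen=True)
class ClinicalSimConfig:
    """Per-group, per-week (mean, SD) for VAS and sleep plus group size.

    Defaults are the study's printed summaries; VAS draws are truncated to
    [0, 10] and sleep to >= 0 (the configured SDs make truncation rare).
    """

    vas: dict = field(
        default_factory=lambda: {"treatment": TREATMENT_VAS, "control": CONTROL_VAS}
    )
    sleep: dict = field(
        default_factory=lambda: {"treatment": TREATMENT_SLEEP, "control": CONTROL_SLEEP}
    )
    n_per_group: int = 20

    def __post_init__(self) -> None:
        for table, n_weeks in ((self.vas, 5), (self.sleep, 4)):
            for group in GROUPS:
                entries = table[group]
                if len(entries) != n_weeks:
                    raise ValueError(f"{group} needs {n_weeks} (mean, SD) pairs")
                if any(sd < 0 for _, sd in entries):
                    raise ValueError("SDs must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def simulate_clinical(config: ClinicalSimConfig = ClinicalSimConfig(), seed: int = 0) -> ClinicalTable:
    """Draw a clinical table cell-wise from Normal(mean, SD) at the
    configured summaries; deterministic given seed."""
    rng = np.random.default_rng(seed)
    rows: dict[str, list] = {c: [] for c in CLINICAL_COLUMNS}
    vas_cols = ["vas_baseline", "vas_week1", "vas_week2", "vas_week3", "vas_week4"]
    sleep_cols = ["sleep_week1", "sleep_week2", "sleep_week3", "sleep_week4"]
    for group in GROUPS:
        for i in range(config.n_per_group):
            rows["subject_id"].append(f"{group}_{i:02d}")
            rows["group"].append(group)
            for col, (mean, sd) in zip(vas_cols, config.vas[group]):
                value = rng.normal(mean, sd) if sd > 0 else mean
                rows[col].append(float(np.clip(value, 0.0, 10.0)))
            for col, (mean, sd) in zip(sleep_cols, config.sleep[group]):
                value = rng.normal(mean, sd) if sd > 0 else mean
                rows[col].append(float(max(value, 0.0)))
    return ClinicalTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Feature matrices for the classifier experiment


def simulate_feature_table(
    n_per_class: int,
    n_features: int,
    structure: str = "nonlinear",
    seed: int = 0,
    n_classes: int = 2,
    class_sep: float = 3.0,
    blob_sd: float = 0.06,
    nuisance_sd: float = 0.25,
    shell_gap: float = 0.6,
    shell_noise: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Region-level feature matrix (rows scaled to [0, 1]) plus class labels.

    ``linear``: Gaussian blobs whose means are ``class_sep`` apart along a
    random direction — separable by a hyperplane. ``nonlinear``: interleaved
    clusters in two informative coordinates (the exclusive-or layout: each
    class occupies two diagonally opposite corners of the unit square, with
    cluster SD ``blob_sd``), embedded among Gaussian nuisance features of SD
    ``nuisance_sd`` — no hyperplane separates the classes, while a nonlinear
    transform of two coordinates does. ``shells``: concentric hyperspherical
    shells (class c at radius 1 + c*shell_gap with radial noise), an
    alternative nonlinear layout whose decision surface involves every
    coordinate. Features are min-max scaled to [0, 1] (the domain required
    by the cross-entropy reconstruction loss).
    """
    if structure not in ("linear", "nonlinear", "shells"):
        raise ValueError("structure must be 'linear', 'nonlinear' or 'shells'")
    if n_per_class < 2 or n_features < 2 or n_classes < 2:
        raise ValueError("need n_per_class >= 2, n_features >= 2, n_classes >= 2")
    if structure == "nonlinear" and n_classes != 2:
        raise ValueError("the interleaved-cluster layout is two-class; use 'shells' for more")
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(n_classes), n_per_class)
    n = y.size
    if structure == "linear":
        direction = rng.standard_normal(n_features)
        direction /= np.linalg.norm(direction)
        x = rng.standard_normal((n, n_features))
        x += np.outer(y * class_sep, direction)
    elif structure == "nonlinear":
        if n_features < 3:
            raise ValueError("need n_features >= 3 (two informative + nuisance)")
        corners = {0: ((0.0, 0.0), (1.0, 1.0)), 1: ((0.0, 1.0), (1.0, 0.0))}
        x = rng.normal(0.5, nuisance_sd, size=(n, n_features))
        which = np.tile([0, 1], n)[:n]
        for i in range(n):
            cx, cy = corners[int(y[i])][which[i]]
            x[i, 0] = cx + rng.normal(0.0, blob_sd)
            x[i, 1] = cy + rng.normal(0.0, blob_sd)
    else:
        u = rng.standard_normal((n, n_features))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = 1.0 + y * shell_gap + rng.normal(0.0, shell_noise, size=n)
        x = u * radii[:, None]
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    x = (x - lo) / span
    perm = rng.permutation(n)
    return x[perm], y[perm]
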