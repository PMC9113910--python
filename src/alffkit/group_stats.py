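"""Voxel-wise group statistics and cluster-extent thresholding.

Two-sample comparisons use the pooled-variance Student t (groups here are
equal-sized); within-group comparisons use the paired t on differences.
Suprathreshold voxels (p below the voxel threshold) are split by the sign of
t into increase/decrease sets, decomposed into connected components at the
configured connectivity (26 by default, the common neuroimaging choice), and
components whose size does not exceed the extent threshold are discarded —
the fixed-extent rule "voxel size > 36" at voxel-level p < 0.001. The rule is
strictly greater-than: a 36-voxel component at extent 36 is discarded.
No random-field or permutation cluster-level p-value is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io_core import BrainMask, LabelAtlas, StatMap

logger = logging.getLogger(__name__)

__all__ = [
    "TestConfig",
    "two_sample_t",
    "paired_t",
    "cluster_threshold",
    "label_clusters",
]

CLUSTER_COLUMNS = [
    "cluster_id",
    "size_voxels",
    "peak_i",
    "peak_j",
    "peak_k",
    "peak_x_mm",
    "peak_y_mm",
    "peak_z_mm",
    "peak_t",
    "sign",
    "region_label",
]


@dataclass(frozen=True)
class TestConfig:
    """Voxel-wise test and cluster thresholds.

    ``extent`` is the minimum cluster size exclusive: clusters survive only
    if size_voxels > extent. ``connectivity`` counts neighbours sharing a
    face (6), face or edge (18), or face, edge or vertex (26).
    """

    __test__ = False  # config object, not a pytest case

    test: str = "two_sample"
    voxel_p: float = 0.001
    extent: int = 36
    connectivity: int = 26
    tail: str = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 < self.voxel_p < 1.0):
            raise ValueError("voxel_p must be in (0, 1)")
        if self.extent < 0:
            raise ValueError("extent must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.test not in ("two_sample", "paired"):
            raise ValueError("test must be 'two_sample' or 'paired'")
        if self.tail != "two_sided":
            raise ValueError("only two-sided tests are supported")


def _stack(maps: list[StatMap] | np.ndarray, mask: BrainMask) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        arr = maps
    else:
        arr = np.stack([m.data for m in maps])
    if arr.ndim != 4:
        raise ValueError("expected a stack of 3D maps")
    mask.check_shape(arr.shape[1:])
    return arr[:, mask.data]  # (n_subjects, n_voxels)


def _as_maps(t_in, p_in, mask: BrainMask, affine: np.ndarray) -> tuple[StatMap, StatMap]:
    t_map = np.full(mask.data.shape, np.nan)
    p_map = np.full(mask.data.shape, np.nan)
    t_map[mask.data] = t_in
    p_map[mask.data] = p_in
    return (
        StatMap(data=t_map, kind="t", affine=affine, mask=mask),
        StatMap(data=p_map, kind="p", affine=affine, mask=mask),
    )


def two_sample_t(
    maps_a: list[StatMap] | np.ndarray,
    maps_b: list[StatMap] | np.ndarray,
    mask: BrainMask,
    affine: np.ndarray | None = None,
) -> tuple[StatMap, StatMap]:
    """Pooled-variance Student t per voxel, df = nA + nB - 2, two-sided p.

    Voxels with zero pooled variance get t = 0, p = 1 (logged).
    """
    if affine is None:
        affine = maps_a[0].affine if not isinstance(maps_a, np.ndarray) else mask.affine
    a = _stack(maps_a, mask)
    b = _stack(maps_b, mask)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    df = na + nb - 2
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    ssq = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    pooled_var = ssq / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    degenerate = se == 0
    if degenerate.any():
        logger.warning("%d voxels with zero pooled variance: t=0, p=1", int(degenerate.sum()))
    t = np.divide(mean_diff, se, out=np.zeros_like(mean_diff), where=~degenerate)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[degenerate] = 1.0
    return _as_maps(t, p, mask, affine)


def paired_t(
    maps_before: list[StatMap] | np.ndarray,
    maps_after: list[StatMap] | np.ndarray,
    mask: BrainMask,
    affine: np.ndarray | None = None,
) -> tuple[StatMap, StatMap]:
    """One-sample t on after-before differences, df = n - 1, two-sided p.

    Subjects must be in matching order. A voxel whose differences have zero
    variance gets |t| = inf and p at the float floor (0.0) when the mean
    difference is nonzero, and t = 0, p = 1 when it is exactly zero (logged).
    """
    if affine is None:
        affine = maps_before[0].affine if not isinstance(maps_before, np.ndarray) else mask.affine
    before = _stack(maps_before, mask)
    after = _stack(maps_after, mask)
    if before.shape[0] != after.shape[0]:
        raise ValueError(
            f"paired test needs matched groups: {before.shape[0]} vs {after.shape[0]} subjects"
        )
    n = before.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paired subjects")
    d = after - before
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    degenerate = se == 0
    if degenerate.any():
        logger.warning("%d voxels with zero difference variance", int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    t[degenerate & (mean > 0)] = np.inf
    t[degenerate & (mean < 0)] = -np.inf
    t[degenerate & (mean == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p[degenerate & (mean == 0)] = 1.0
    p[degenerate & (mean != 0)] = 0.0
    return _as_maps(t, p, mask, affine)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def cluster_threshold(t_map: StatMap, p_map: StatMap, config: TestConfig = TestConfig()) -> pd.DataFrame:
    """Suprathreshold connected components above the extent threshold.

    Binarizes p < voxel_p, splits by the sign of t into increase/decrease
    sets, labels connected components at the configured connectivity, and
    retains those with size_voxels > extent. Rows sorted by size descending,
    ties by peak |t| descending, then lexicographic peak index. Peaks are
    reported in 0-based voxel indices and in world mm through the affine.
    An empty table is a valid result.
    """
    if t_map.data.shape != p_map.data.shape:
        raise ValueError("t and p maps differ in shape")
    structure = _connectivity_structure(config.connectivity)
    valid = ~np.isnan(p_map.data)
    supra = valid & (p_map.data < config.voxel_p)
    rows = []
    for sign_name, sign_sel in (("increase", t_map.data > 0), ("decrease", t_map.data < 0)):
        labeled, n_comp = ndimage.label(supra & sign_sel, structure=structure)
        for comp in range(1, n_comp + 1):
            idx = np.argwhere(labeled == comp)
            size = len(idx)
            if size <= config.extent:
                continue
            t_vals = t_map.data[tuple(idx.T)]
            peak_pos = int(np.argmax(np.abs(t_vals)))
            peak = idx[peak_pos]
            peak_mm = (t_map.affine @ np.array([*peak, 1.0]))[:3]
            rows.append(
                {
                    "size_voxels": size,
                    "peak_i": int(peak[0]),
                    "peak_j": int(peak[1]),
                    "peak_k": int(peak[2]),
                    "peak_x_mm": float(peak_mm[0]),
                    "peak_y_mm": float(peak_mm[1]),
                    "peak_z_mm": float(peak_mm[2]),
                    "peak_t": float(t_vals[peak_pos]),
                    "sign": sign_name,
                    "region_label": "unlabeled",
                }
            )
    rows.sort(
        key=lambda r: (-r["size_voxels"], -abs(r["peak_t"]), r["peak_i"], r["peak_j"], r["peak_k"])
    )
    for i, r in enumerate(rows, start=1):
        r["cluster_id"] = i
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def label_clusters(table: pd.DataFrame, atlas: LabelAtlas) -> pd.DataFrame:
    """Assign each cluster the atlas region name at its peak voxel
    (background -> "unlabeled")."""
    out = table.copy()
    labels = [
        atlas.name_at((int(r.peak_i), int(r.peak_j), int(r.peak_k)))
        for r in table.itertuples()
    ]
    out["region_label"] = labels if len(table) else out.get("region_label")
    return out
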