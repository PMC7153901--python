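"""smFISH focus detection and spatial binning along the gonad axis.

mRNA molecules appear as diffraction-limited foci. Foci are detected
as connected components of above-threshold voxels (26-connectivity by
default) with a minimum voxel count, then assigned to cell-diameter
bins by projecting each focus onto the axis: a focus within half the
band width (default 100 px, about 10 um) of the axis is counted in the
cd interval containing its arc-length position, otherwise excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .axisquant import AxisTrace
from .profilepipe import ComparisonResult, compare_levels

__all__ = ["FociSet", "detect_foci", "assign_to_cd", "density_summary", "DensitySummary"]


@dataclass
class FociSet:
    """Detected foci and, after assignment, their per-cd counts.

    ``foci`` has one row per focus with columns z, y, x (intensity
    weighted centroid), voxels, peak_intensity and -- once assigned --
    cd_bin (1-based; 0 marks a focus excluded as too far off axis).
    """

    foci: pd.DataFrame
    threshold_used: float
    min_voxels: int
    per_cd_counts: np.ndarray | None = None
    excluded_count: int = 0
    n_cd: int = field(default=0)

    @property
    def n_foci(self) -> int:
        return len(self.foci)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: np.ones((3, 3, 3), dtype=bool),
}


def detect_foci(
    stack: np.ndarray,
    threshold: float,
    min_voxels: int = 2,
    connectivity: int = 26,
) -> FociSet:
    """Connected components of voxels strictly above ``threshold``.

    Components smaller than ``min_voxels`` are discarded (single-voxel
    noise suppression). Centroids are intensity-weighted means of the
    component voxel positions. A threshold above the stack maximum
    yields an empty set, not an error.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) stack")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6 or 26")
    mask = stack > threshold
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    rows = []
    if n:
        idx = np.arange(1, n + 1)
        sizes = ndimage.sum_labels(mask, labels, idx)
        keep = idx[sizes >= min_voxels]
        if keep.size:
            centroids = ndimage.center_of_mass(stack, labels, keep)
            peaks = ndimage.maximum(stack, labels, keep)
            sizes_kept = sizes[keep - 1]
            for (z, y, x), vox, pk in zip(centroids, sizes_kept, peaks):
                rows.append((z, y, x, int(vox), float(pk)))
    foci = pd.DataFrame(rows, columns=["z", "y", "x", "voxels", "peak_intensity"])
    return FociSet(foci=foci, threshold_used=float(threshold), min_voxels=min_voxels)


def assign_to_cd(foci: FociSet, axis: AxisTrace, band_px: int = 100) -> FociSet:
    """Assign each focus to the cd bin of its nearest axis point.

    Uses in-plane (y, x) distance -- stacks cover a single surface
    layer of nuclei, so depth carries no axis information. A focus is
    counted when its perpendicular distance is <= band_px / 2, else
    excluded; an arc position falling exactly on a boundary goes to the
    distal (lower) cd.
    """
    positions, points, _ = axis.sample(step=1.0)
    counts = np.zeros(axis.n_cd, dtype=int)
    bins = np.zeros(len(foci.foci), dtype=int)
    excluded = 0
    markers = axis.cd_markers
    fy = foci.foci["y"].to_numpy(float)
    fx = foci.foci["x"].to_numpy(float)
    for i, (y, x) in enumerate(zip(fy, fx)):
        d2 = (points[:, 0] - y) ** 2 + (points[:, 1] - x) ** 2
        j = int(np.argmin(d2))
        if np.sqrt(d2[j]) > band_px / 2.0 or positions[j] > markers[-1]:
            excluded += 1
            bins[i] = 0
            continue
        k = int(np.searchsorted(markers, positions[j], side="left"))
        k = min(max(k, 1), axis.n_cd)
        bins[i] = k
        counts[k - 1] += 1
    out = foci.foci.copy()
    out["cd_bin"] = bins
    return FociSet(
        foci=out,
        threshold_used=foci.threshold_used,
        min_voxels=foci.min_voxels,
        per_cd_counts=counts,
        excluded_count=excluded,
        n_cd=axis.n_cd,
    )


@dataclass
class DensitySummary:
    mean: np.ndarray
    sd: np.ndarray
    n_germlines: int
    window_a: tuple[int, int]
    window_b: tuple[int, int]
    comparison: ComparisonResult


def density_summary(
    foci_sets: list[FociSet],
    window_a: tuple[int, int] = (1, 10),
    window_b: tuple[int, int] = (11, 25),
) -> DensitySummary:
    """Per-cd mean density across germlines plus a two-window comparison.

    Each germline contributes its mean per-cd count within each
    (inclusive) cd window; the two per-germline samples are compared
    with the t/Z rule. Windows must not overlap.
    """
    if len(foci_sets) < 2:
        raise ValueError("need at least two germlines")
    if not (window_a[1] < window_b[0] or window_b[1] < window_a[0]):
        raise ValueError("comparison windows overlap")
    counts = np.stack([np.asarray(f.per_cd_counts, dtype=float) for f in foci_sets])
    means_a = counts[:, window_a[0] - 1 : window_a[1]].mean(axis=1)
    means_b = counts[:, window_b[0] - 1 : window_b[1]].mean(axis=1)
    return DensitySummary(
        mean=counts.mean(axis=0),
        sd=counts.std(axis=0, ddof=1),
        n_germlines=counts.shape[0],
        window_a=window_a,
        window_b=window_b,
        comparison=compare_levels(means_a, means_b),
    )
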