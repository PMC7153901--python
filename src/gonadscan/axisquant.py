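"""Cell-diameter coordinate system and wide linescan extraction.

Distance along the gonad's distal-proximal axis is measured in cell
diameters (cd): one row of germ nuclei per unit. The axis is a
polyline starting at the distal tip and threading successive DAPI
nucleus centroids; cd boundaries sit midway between successive
centroids. Intensity is collected in a wide perpendicular band
(default 75 px) at 1-px arc steps, taking the per-pixel maximum over
the selected z-slices, then binned per cd.

Pixel coordinates are 0-based in (z, y, x) order; axis geometry lives
in the (y, x) plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .profilepipe import IntensityProfile

__all__ = [
    "AxisTrace",
    "LineScan",
    "InsufficientAxisError",
    "detect_nuclei",
    "trace_axis",
    "linescan",
    "profile_by_cd",
]


class InsufficientAxisError(ValueError):
    """Fewer chainable nuclei than the requested number of cell diameters."""


@dataclass
class AxisTrace:
    """Axis polyline plus the arc-length positions bounding each cd.

    ``polyline`` is an ordered (N, 2) array of (y, x) points starting at
    the distal tip; ``cd_markers`` holds n_cd + 1 strictly increasing
    arc-length positions (px) with the first at 0, so cd ``k`` covers
    arc lengths ``[cd_markers[k-1], cd_markers[k])``.
    """

    polyline: np.ndarray
    cd_markers: np.ndarray
    n_cd: int
    band_width_px: int = 100

    def __post_init__(self) -> None:
        self.polyline = np.atleast_2d(np.asarray(self.polyline, dtype=float))
        self.cd_markers = np.asarray(self.cd_markers, dtype=float)
        if self.polyline.shape[1] != 2:
            raise ValueError("polyline must be an (N, 2) array of (y, x) points")
        if self.cd_markers[0] != 0:
            raise ValueError("first cd marker must sit at arc length 0 (the distal tip)")
        if np.any(np.diff(self.cd_markers) <= 0):
            raise ValueError("cd markers must be strictly increasing")
        if self.n_cd != self.cd_markers.size - 1:
            raise ValueError("n_cd must equal the number of marker intervals")

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)))

    def sample(self, step: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Resample the polyline at fixed arc steps.

        Returns (positions, points, normals): arc positions, the
        linearly interpolated (y, x) points and unit normals obtained by
        rotating the local tangent 90 degrees.
        """
        seg = np.diff(self.polyline, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        arcs = np.concatenate([[0.0], np.cumsum(seglen)])
        positions = np.arange(0.0, arcs[-1] + 0.5 * step, step)
        positions = positions[positions <= arcs[-1] + 1e-9]
        y = np.interp(positions, arcs, self.polyline[:, 0])
        x = np.interp(positions, arcs, self.polyline[:, 1])
        points = np.column_stack([y, x])
        tangents = np.gradient(points, axis=0)
        norms = np.linalg.norm(tangents, axis=1)
        norms[norms == 0] = 1.0
        tangents /= norms[:, None]
        normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
        return positions, points, normals


def detect_nuclei(dapi_stack: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Centroids of DAPI-stained nuclei by simple blob detection.

    The stack is max-projected over z, thresholded (default: halfway
    between min and max) and connected components give one centroid per
    nucleus, returned as an (N, 2) array of (y, x) positions.
    """
    stack = np.asarray(dapi_stack, dtype=float)
    proj = stack.max(axis=0) if stack.ndim == 3 else stack
    if threshold is None:
        threshold = proj.min() + 0.5 * (proj.max() - proj.min())
    labels, n = ndimage.label(proj > threshold)
    if n == 0:
        return np.empty((0, 2))
    centroids = ndimage.center_of_mass(proj, labels, range(1, n + 1))
    return np.asarray(centroids, dtype=float)


def trace_axis(
    nuclei: np.ndarray,
    distal_tip: tuple[float, float],
    n_cd: int,
    band_width_px: int = 100,
) -> AxisTrace:
    """Chain nucleus centroids from the distal tip into a cd axis.

    ``nuclei`` is either an (N, 2)/(N, 3) array of centroids (last two
    columns are y, x) or a DAPI stack, in which case centroids are
    detected first. Successive nuclei are picked greedily by nearest
    neighbor starting from the tip; cd boundaries are placed midway
    between successive centroids, with the first marker at the tip. If
    only n_cd nuclei can be chained the final boundary is extrapolated
    by half the last spacing.

    For a hand-drawn axis (e.g. exported from Fiji) construct
    :class:`AxisTrace` directly with the polyline and markers.
    """
    nuclei = np.asarray(nuclei, dtype=float)
    if nuclei.ndim == 3 or (nuclei.ndim == 2 and nuclei.shape[1] > 3):
        nuclei = detect_nuclei(nuclei)
    if nuclei.ndim != 2 or nuclei.shape[0] == 0:
        raise InsufficientAxisError("no nucleus centroids available")
    pts = nuclei[:, -2:]
    tip = np.asarray(distal_tip, dtype=float)

    remaining = list(range(pts.shape[0]))
    chain: list[int] = []
    cursor = tip
    want = min(n_cd + 1, pts.shape[0])
    for _ in range(want):
        dists = np.linalg.norm(pts[remaining] - cursor, axis=1)
        j = remaining.pop(int(np.argmin(dists)))
        chain.append(j)
        cursor = pts[j]
    if len(chain) < n_cd:
        raise InsufficientAxisError(
            f"only {len(chain)} chainable nuclei for {n_cd} cell diameters"
        )

    polyline = np.vstack([tip[None, :], pts[chain]])
    seglen = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    arcs = np.cumsum(seglen)  # arc position of each chained nucleus
    mids = (arcs[:-1] + arcs[1:]) / 2.0
    markers = np.concatenate([[0.0], mids])
    if markers.size < n_cd + 1:
        # n_cd nuclei only: extrapolate the final boundary
        last_spacing = arcs[-1] - arcs[-2] if arcs.size > 1 else arcs[-1]
        markers = np.append(markers, arcs[-1] + last_spacing / 2.0)
        extra = markers[-1] - arcs[-1]
        direction = polyline[-1] - polyline[-2]
        direction /= np.linalg.norm(direction)
        polyline = np.vstack([polyline, polyline[-1] + direction * extra])
    markers = markers[: n_cd + 1]
    return AxisTrace(polyline=polyline, cd_markers=markers, n_cd=n_cd, band_width_px=band_width_px)


@dataclass
class LineScan:
    """Band-averaged intensity per unit arc step along an axis."""

    positions: np.ndarray
    values: np.ndarray
    width_px: int
    slice_policy: str

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must align")


def _resolve_stack(image, channel: str | None) -> np.ndarray:
    if hasattr(image, "channels"):
        if channel is None or channel not in image.channels:
            raise KeyError(f"channel {channel!r} not present in image")
        stack = np.asarray(image.channels[channel], dtype=float)
    else:
        stack = np.asarray(image, dtype=float)
    if stack.ndim == 2:
        stack = stack[None, :, :]
    if stack.ndim != 3:
        raise ValueError("expected a (z, y, x) stack or (y, x) image")
    return stack


def linescan(
    image,
    channel: str | None,
    axis: AxisTrace,
    width_px: int = 75,
    slices=None,
) -> LineScan:
    """Wide linescan along the axis with a per-pixel max over z-slices.

    At every 1-px arc step, ``width_px`` samples are taken along the
    local normal (nearest-pixel lookup). Each sample takes the maximum
    over the selected slices; the position's value is the mean over the
    in-bounds band. ``slices`` may be an explicit list of z indices
    (two or more) or None, which selects the two brightest slices by
    band mean -- the reproducible stand-in for ad hoc focal-plane
    choice.
    """
    stack = _resolve_stack(image, channel)
    nz, ny, nx = stack.shape
    positions, points, normals = axis.sample(step=1.0)

    offsets = np.arange(width_px) - width_px // 2
    # (n_positions, width, 2) sample coordinates
    coords = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    iy = np.rint(coords[..., 0]).astype(int)
    ix = np.rint(coords[..., 1]).astype(int)
    inside = (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
    if not inside.all():
        warnings.warn("linescan band extends outside the image; outside pixels excluded")
    if not inside.any(axis=1).all():
        raise ValueError("axis leaves the image: some positions have an empty band")
    iy_c = np.clip(iy, 0, ny - 1)
    ix_c = np.clip(ix, 0, nx - 1)

    if slices is None:
        if nz == 1:
            chosen = [0]
        else:
            band_means = [
                float(np.mean(stack[z][iy_c, ix_c], where=inside)) for z in range(nz)
            ]
            chosen = list(np.argsort(band_means)[-2:])
        policy = f"brightest {len(chosen)} of {nz} slices by band mean"
    else:
        chosen = [int(z) for z in slices]
        if len(chosen) < 2 and nz >= 2:
            raise ValueError("select at least two slices")
        if any(z < 0 or z >= nz for z in chosen):
            raise ValueError("slice index outside stack")
        policy = f"slices {chosen}"

    # per-pixel max over the chosen slices, then mean over the band
    sampled = np.max(stack[chosen][:, iy_c, ix_c], axis=0)
    sampled = np.where(inside, sampled, np.nan)
    values = np.nanmean(sampled, axis=1)
    return LineScan(positions=positions, values=values, width_px=width_px, slice_policy=policy)


def profile_by_cd(
    scan: LineScan,
    axis: AxisTrace,
    genotype_label: str = "",
    replicate_id: str = "",
) -> IntensityProfile:
    """Average linescan values within each cd interval.

    Scan positions beyond the last cd boundary are ignored. An empty
    interval indicates a marker/scan geometry mismatch and raises.
    """
    markers = axis.cd_markers
    values = np.empty(axis.n_cd)
    eps = 1e-6  # absorb float fuzz in marker positions from centroid arithmetic
    for k in range(axis.n_cd):
        lo, hi = markers[k], markers[k + 1]
        mask = (scan.positions >= lo - eps) & (scan.positions < hi - eps)
        if not mask.any():
            raise ValueError(f"no linescan positions fall in cd interval {k + 1}")
        values[k] = scan.values[mask].mean()
    return IntensityProfile(
        values=values,
        genotype_label=genotype_label,
        replicate_id=replicate_id,
        state="raw",
        max_cd=axis.n_cd,
    )
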