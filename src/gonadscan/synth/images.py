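"""Synthetic gonad image stacks with planted ground truth.

A gonad is modeled as a tube around a polyline axis. The DAPI channel
carries one Gaussian nucleus per cell diameter along the axis; the
marker (antibody) channel follows a per-cd mean intensity profile
evaluated at each pixel's cd coordinate (arc length of its nearest
axis point, in nucleus spacings); the smFISH channel carries Gaussian
foci planted at recorded positions with a configurable per-cd density.
Camera noise is Poisson shot noise plus Gaussian read noise with an
offset. No attempt is made to model a realistic PSF, photobleaching
or optical sectioning beyond these Gaussian profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .profiles import ProfileConfig

__all__ = ["ImageConfig", "GermlineImage", "ImageTruth", "generate_gonad_image", "straight_tube"]


@dataclass
class GermlineImage:
    """Multi-channel z-stack of one synthetic gonad.

    ``channels`` maps channel name (dapi / marker / smfish) to a
    (z, y, x) array. Metadata mirrors what an acquisition sidecar
    would carry.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    genotype_label: str
    tagged: bool
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class ImageTruth:
    """Everything planted into a generated stack."""

    axis_polyline: np.ndarray
    distal_tip: tuple[float, float]
    nucleus_spacing_px: float
    nucleus_centroids: np.ndarray  # (N, 3) z, y, x
    focus_centroids: np.ndarray  # (M, 3) z, y, x
    per_cd_focus_counts: np.ndarray
    marker_mean_by_cd: np.ndarray
    seed: int


@dataclass
class ImageConfig:
    """Geometry, channel content and camera model for one stack."""

    marker: ProfileConfig
    control_points: list[tuple[float, float]] = field(default_factory=list)
    radius_px: float = 50.0
    nucleus_spacing_px: float = 30.0
    nucleus_radius_px: float = 6.0
    pixel_size_um: float = 0.1
    z_slices: int = 3
    marker_scale: float = 1.0
    dapi_amplitude: float = 1000.0
    smfish_density_per_cd: float | list[float] = 0.0
    smfish_amplitude: float = 800.0
    smfish_sigma_px: float = 1.5
    #: minimum in-plane distance between planted foci (0 = unconstrained);
    #: keeps spots resolvable so planted counts are recoverable
    smfish_min_separation_px: float = 8.0
    surface_layer: bool = True
    gaussian_sd: float = 0.0
    camera_offset: float = 0.0
    poisson: bool = False

    def __post_init__(self) -> None:
        if self.radius_px <= self.nucleus_radius_px:
            raise ValueError("tube radius must exceed the nucleus radius")
        if self.z_slices < 2:
            raise ValueError("need at least two z-slices")
        dens = np.atleast_1d(np.asarray(self.smfish_density_per_cd, dtype=float))
        if (dens < 0).any():
            raise ValueError("smFISH densities must be non-negative")
        if not self.control_points:
            # default: straight horizontal tube with margins
            margin = self.radius_px + 5.0
            length = (self.marker.max_cd + 1) * self.nucleus_spacing_px + 10.0
            self.control_points = [(margin, margin), (margin, margin + length)]

    def densities(self) -> np.ndarray:
        dens = np.atleast_1d(np.asarray(self.smfish_density_per_cd, dtype=float))
        if dens.size == 1:
            dens = np.full(self.marker.max_cd, float(dens[0]))
        if dens.size != self.marker.max_cd:
            raise ValueError("per-cd density must be scalar or length max_cd")
        return dens


def straight_tube(cfg_marker: ProfileConfig, **kwargs) -> ImageConfig:
    """Convenience: an ImageConfig with the default straight geometry."""
    return ImageConfig(marker=cfg_marker, **kwargs)


def _resample(polyline: np.ndarray, step: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense 1-px resampling of a polyline; returns (arcs, points, normals)."""
    polyline = np.asarray(polyline, dtype=float)
    seg = np.diff(polyline, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arcs = np.concatenate([[0.0], np.cumsum(seglen)])
    positions = np.arange(0.0, arcs[-1] + 0.5 * step, step)
    positions = positions[positions <= arcs[-1] + 1e-9]
    y = np.interp(positions, arcs, polyline[:, 0])
    x = np.interp(positions, arcs, polyline[:, 1])
    points = np.column_stack([y, x])
    tangents = np.gradient(points, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1), 1e-12)[:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    return positions, points, normals


def _add_gaussian(vol: np.ndarray, center: tuple[float, float, float], amp: float,
                  sigma_z: float, sigma_xy: float) -> None:
    """Add a 3D Gaussian blob in place, restricted to a local patch."""
    nz, ny, nx = vol.shape
    cz, cy, cx = center
    rz, rxy = int(np.ceil(3 * sigma_z)), int(np.ceil(3 * sigma_xy))
    z0, z1 = max(0, int(cz) - rz), min(nz, int(cz) + rz + 1)
    y0, y1 = max(0, int(cy) - rxy), min(ny, int(cy) + rxy + 1)
    x0, x1 = max(0, int(cx) - rxy), min(nx, int(cx) + rxy + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    blob = amp * np.exp(
        -((zz - cz) ** 2 / (2 * sigma_z**2) + ((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_xy**2))
    )
    vol[z0:z1, y0:y1, x0:x1] += blob


def generate_gonad_image(cfg: ImageConfig, seed: int) -> tuple[GermlineImage, ImageTruth]:
    """Render one synthetic gonad stack; bit-identical for fixed seed."""
    rng = np.random.default_rng(seed)
    marker_cfg = cfg.marker
    max_cd = marker_cfg.max_cd
    spacing = cfg.nucleus_spacing_px

    arcs, points, normals = _resample(np.asarray(cfg.control_points, dtype=float))
    needed = (max_cd + 1) * spacing
    if arcs[-1] < needed:
        raise ValueError(
            f"tube axis too short: {arcs[-1]:.0f} px for {max_cd} cd at {spacing} px spacing"
        )

    pad = cfg.radius_px + 2.0
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    if (lo < 0).any():
        raise ValueError("tube leaves image bounds; shift control points away from the origin")
    ny, nx = int(np.ceil(hi[0])) + 1, int(np.ceil(hi[1])) + 1
    nz = cfg.z_slices

    # per-pixel cd coordinate from the nearest axis point
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    dist, idx = cKDTree(points).query(pix, workers=-1)
    dist = dist.reshape(ny, nx)
    pixel_arc = arcs[idx].reshape(ny, nx)
    tube = dist <= cfg.radius_px
    cd_map = np.clip(np.floor(pixel_arc / spacing).astype(int) + 1, 1, max_cd)

    # marker channel: background everywhere, per-cd signal inside the tube
    signal_by_cd = cfg.marker_scale * marker_cfg.signal_at(np.arange(1, max_cd + 1))
    marker_plane = np.full((ny, nx), cfg.marker_scale * marker_cfg.background_level)
    if marker_cfg.tagged:
        marker_plane[tube] += signal_by_cd[cd_map[tube] - 1]
    marker = np.repeat(marker_plane[None, :, :], nz, axis=0)

    # DAPI: one nucleus per cd, centered within its interval, plus one
    # extra so the proximal boundary of the last cd is defined
    dapi = np.zeros((nz, ny, nx))
    mid_z = (nz - 1) / 2.0
    nucleus_arcs = spacing / 2.0 + spacing * np.arange(max_cd + 1)
    centers = points[np.searchsorted(arcs, nucleus_arcs)]
    nuclei = np.column_stack([np.full(len(centers), mid_z), centers])
    sigma_xy = cfg.nucleus_radius_px / 2.0
    for cz, cy, cx in nuclei:
        _add_gaussian(dapi, (cz, cy, cx), cfg.dapi_amplitude, sigma_z=1.0, sigma_xy=sigma_xy)

    # smFISH: Poisson number of foci per cd at the configured density
    smfish = np.zeros((nz, ny, nx))
    densities = cfg.densities()
    foci = []
    per_cd_counts = np.zeros(max_cd, dtype=int)
    min_sep2 = cfg.smfish_min_separation_px**2
    for k in range(1, max_cd + 1):
        n_k = rng.poisson(densities[k - 1]) if densities[k - 1] > 0 else 0
        for _ in range(n_k):
            cz = nz - 1.5 if cfg.surface_layer and nz > 2 else mid_z
            for _try in range(50):
                arc = rng.uniform((k - 1) * spacing, k * spacing)
                off = rng.uniform(-0.7, 0.7) * cfg.radius_px
                j = int(np.searchsorted(arcs, arc))
                cy, cx = points[j] + off * normals[j]
                if min_sep2 == 0 or all((cy - fy) ** 2 + (cx - fx) ** 2 >= min_sep2 for _, fy, fx in foci):
                    break
            foci.append((cz, cy, cx))
            per_cd_counts[k - 1] += 1
    for cz, cy, cx in foci:
        _add_gaussian(smfish, (cz, cy, cx), cfg.smfish_amplitude,
                      sigma_z=1.0, sigma_xy=cfg.smfish_sigma_px)

    channels = {"dapi": dapi, "marker": marker, "smfish": smfish}
    for name, vol in channels.items():
        if cfg.poisson:
            vol = rng.poisson(np.clip(vol, 0, None)).astype(float)
        if cfg.gaussian_sd > 0:
            vol = vol + rng.normal(0.0, cfg.gaussian_sd, size=vol.shape)
        vol = vol + cfg.camera_offset
        channels[name] = np.clip(vol, 0.0, None)

    image = GermlineImage(
        channels=channels,
        pixel_size_um=cfg.pixel_size_um,
        genotype_label=marker_cfg.genotype_label,
        tagged=marker_cfg.tagged,
        metadata={
            "channel_order": ["dapi", "marker", "smfish"],
            "axis_convention": "0-based (z, y, x)",
            "nucleus_spacing_px": spacing,
            "max_cd": max_cd,
            "seed": seed,
        },
    )
    truth = ImageTruth(
        axis_polyline=points,
        distal_tip=(float(points[0, 0]), float(points[0, 1])),
        nucleus_spacing_px=spacing,
        nucleus_centroids=nuclei,
        focus_centroids=np.asarray(foci, dtype=float).reshape(-1, 3),
        per_cd_focus_counts=per_cd_counts,
        marker_mean_by_cd=cfg.marker_scale * marker_cfg.background_level + signal_by_cd
        if marker_cfg.tagged
        else np.full(max_cd, cfg.marker_scale * marker_cfg.background_level),
        seed=seed,
    )
    return image, truth
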