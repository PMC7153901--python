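"""Direct (fast-path) generation of per-cd intensity profiles.

Each genotype is described by a piecewise-linear mean signal over cd
plus a flat non-specific background; tagged strains show background +
signal, untagged strains background only. Replicate gonads add
independent Gaussian noise per cd. This emulates the measured
genotype panels without rendering images; the image generator provides
the slow path through the full linescan pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..profilepipe import IntensityProfile

__all__ = ["ProfileConfig", "ProfileTruth", "generate_profiles"]


@dataclass
class ProfileConfig:
    """Ground-truth description of one genotype's profile panel.

    ``breakpoints`` are (cd, signal level) pairs in arbitrary
    fluorescence units; the mean signal is linear between breakpoints
    and constant beyond the first/last. ``background_level`` is the
    untagged (non-specific) staining added to every strain; for
    ``tagged=False`` the signal term is dropped entirely.
    """

    genotype_label: str
    breakpoints: list[tuple[float, float]]
    tagged: bool = True
    noise_sd: float = 0.0
    background_level: float = 0.0
    n_germlines: int = 1
    max_cd: int = 25

    def __post_init__(self) -> None:
        cds = [bp[0] for bp in self.breakpoints]
        levels = [bp[1] for bp in self.breakpoints]
        if not cds:
            raise ValueError("at least one breakpoint is required")
        if any(b <= a for a, b in zip(cds, cds[1:])):
            raise ValueError("breakpoint cds must be strictly increasing")
        if cds[0] < 1 or cds[-1] > self.max_cd:
            raise ValueError(f"breakpoint cds must lie within [1, {self.max_cd}]")
        if any(level < 0 for level in levels):
            raise ValueError("breakpoint levels must be non-negative")
        if self.n_germlines < 1:
            raise ValueError("n_germlines must be >= 1")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be non-negative")

    def signal_at(self, cd) -> np.ndarray:
        """Piecewise-linear mean signal evaluated at cd (0 if untagged)."""
        cd = np.asarray(cd, dtype=float)
        if not self.tagged:
            return np.zeros_like(cd)
        xs = np.array([bp[0] for bp in self.breakpoints], dtype=float)
        ys = np.array([bp[1] for bp in self.breakpoints], dtype=float)
        return np.interp(cd, xs, ys)

    def mean_profile(self) -> np.ndarray:
        """Expected total intensity (background + signal) at cd 1..max_cd."""
        cds = np.arange(1, self.max_cd + 1)
        return self.background_level + self.signal_at(cds)


@dataclass
class ProfileTruth:
    """Planted ground truth for a generated profile panel."""

    genotype_label: str
    mean_profile: np.ndarray
    signal_profile: np.ndarray
    background_level: float
    noise_sd: float
    n_germlines: int
    seed: int
    extras: dict = field(default_factory=dict)


def generate_profiles(cfg: ProfileConfig, seed: int) -> tuple[list[IntensityProfile], ProfileTruth]:
    """Generate replicate raw profiles for one genotype.

    Deterministic for fixed (cfg, seed); with noise_sd = 0 every
    replicate equals the configured means exactly.
    """
    rng = np.random.default_rng(seed)
    mean = cfg.mean_profile()
    profiles = []
    for rep in range(cfg.n_germlines):
        noise = rng.normal(0.0, cfg.noise_sd, size=cfg.max_cd) if cfg.noise_sd > 0 else 0.0
        profiles.append(
            IntensityProfile(
                values=np.clip(mean + noise, 0.0, None),
                genotype_label=cfg.genotype_label,
                replicate_id=f"{cfg.genotype_label}_{rep:03d}",
                state="raw",
                max_cd=cfg.max_cd,
            )
        )
    cds = np.arange(1, cfg.max_cd + 1)
    truth = ProfileTruth(
        genotype_label=cfg.genotype_label,
        mean_profile=mean,
        signal_profile=cfg.signal_at(cds),
        background_level=cfg.background_level,
        noise_sd=cfg.noise_sd,
        n_germlines=cfg.n_germlines,
        seed=seed,
    )
    return profiles, truth
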