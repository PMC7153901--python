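"""Synthetic count matrices with planted regulatory structure.

Emulates the two experimental designs used to call Notch pathway
targets: (i) a signaling-ON vs signaling-OFF contrast in which a
planted set of pathway-dependent genes is elevated in ON by a per-gene
log2 fold change, and (ii) a regulator-degradation time course in
which planted genes decay exponentially from their t = 0 level,

    level(t) = floor + (1 - floor) * 2**(-(t - lag) / half_life)

for t > lag. Primary targets respond immediately (lag 0); secondary
targets begin decaying only after the primaries' protein products have
been lost (default lag 2 h, the upper bound on their protein
half-life). Counts are negative binomial with configurable dispersion
around these means. A targets-null contrast (ON vs primaries removed)
is generated for the dependence evidence flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionConfig", "ExpressionData", "ExpressionTruth", "generate_expression", "decay_level"]


def decay_level(t: float, half_life: float, floor: float = 0.0, lag: float = 0.0) -> float:
    """Expected relative level at time t after regulator loss."""
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    dt = max(t - lag, 0.0)
    return floor + (1.0 - floor) * 2.0 ** (-dt / half_life)


@dataclass
class ExpressionConfig:
    """Design of a planted expression dataset.

    ``effect_log2fc`` (ON over OFF) and ``half_life_hours`` are per-gene
    maps covering every planted dependent gene; ``decay_lag_hours``
    applies to genes that respond only through the primary targets.
    ``targets_effect_log2fc`` drives the ON vs primaries-null contrast.
    """

    n_genes: int
    gene_ids: list[str]
    bound_genes: list[str]
    planted_primaries: list[str]
    planted_secondaries: list[str]
    planted_dependent: list[str]  # full dependent set incl. primaries + secondaries
    effect_log2fc: dict[str, float]
    half_life_hours: dict[str, float]
    targets_effect_log2fc: dict[str, float] = field(default_factory=dict)
    decay_lag_hours: float = 2.0
    dispersion: float = 0.05
    library_size: float = 2_000_000.0
    reps_contrast: int = 5
    reps_timecourse: int = 4
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 48.0)
    floor_fraction: float = 0.05
    base_cpm_range_dependent: tuple[float, float] = (110.0, 1100.0)
    base_cpm_range_null: tuple[float, float] = (0.2, 2000.0)

    def __post_init__(self) -> None:
        if set(self.planted_primaries) & set(self.planted_secondaries):
            raise ValueError("primaries and secondaries must be disjoint")
        if not set(self.planted_primaries) <= set(self.bound_genes):
            raise ValueError("planted primaries must be bound")
        if set(self.planted_secondaries) & set(self.bound_genes):
            raise ValueError("planted secondaries must not be bound")
        if self.reps_contrast < 2 or self.reps_timecourse < 2:
            raise ValueError("need at least two replicates per condition")
        if any(h <= 0 for h in self.half_life_hours.values()):
            raise ValueError("half-lives must be positive")
        missing = set(self.planted_dependent) - set(self.effect_log2fc)
        if missing:
            raise ValueError(f"effect_log2fc missing for {sorted(missing)[:3]}...")


@dataclass
class ExpressionTruth:
    planted_primaries: list[str]
    planted_secondaries: list[str]
    planted_dependent: list[str]
    bound_genes: list[str]
    effect_log2fc: dict[str, float]
    half_life_hours: dict[str, float]
    decay_lag_hours: float
    base_cpm: pd.Series
    seed: int


@dataclass
class ExpressionData:
    """Generated matrices: each is genes x samples of integer counts."""

    counts_on: pd.DataFrame
    counts_off: pd.DataFrame
    counts_targets_off: pd.DataFrame
    timecourse: dict[float, pd.DataFrame]
    bound_genes: list[str]
    truth: ExpressionTruth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.clip(mean, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_expression(cfg: ExpressionConfig, seed: int) -> ExpressionData:
    """Draw all count matrices for one design; deterministic per seed."""
    rng = np.random.default_rng(seed)
    genes = pd.Index(cfg.gene_ids, name="gene")
    n = len(genes)
    if n != cfg.n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    lo, hi = cfg.base_cpm_range_null
    base_cpm = pd.Series(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)), index=genes)
    dlo, dhi = cfg.base_cpm_range_dependent
    dep = pd.Index(cfg.planted_dependent)
    base_cpm[dep] = np.exp(rng.uniform(np.log(dlo), np.log(dhi), size=len(dep)))
    # make the draws a true composition so configured values are CPM
    base_cpm *= 1e6 / base_cpm.sum()

    on_mean = base_cpm / 1e6 * cfg.library_size
    lfc = pd.Series(0.0, index=genes)
    for g, v in cfg.effect_log2fc.items():
        lfc[g] = v
    off_mean = on_mean / 2.0**lfc

    def draw(mean: pd.Series, reps: int, prefix: str) -> pd.DataFrame:
        cols = {}
        for r in range(reps):
            cols[f"{prefix}{r + 1}"] = _nb_draw(rng, mean.to_numpy(), cfg.dispersion)
        return pd.DataFrame(cols, index=genes)

    counts_on = draw(on_mean, cfg.reps_contrast, "on_")
    counts_off = draw(off_mean, cfg.reps_contrast, "off_")

    t_lfc = pd.Series(0.0, index=genes)
    for g, v in cfg.targets_effect_log2fc.items():
        t_lfc[g] = v
    counts_targets_off = draw(on_mean / 2.0**t_lfc, cfg.reps_contrast, "toff_")

    primaries = set(cfg.planted_primaries)
    timecourse = {}
    for t in cfg.timepoints:
        mean_t = on_mean.copy()
        for g, hl in cfg.half_life_hours.items():
            lag = 0.0 if g in primaries else cfg.decay_lag_hours
            mean_t[g] = on_mean[g] * decay_level(t, hl, cfg.floor_fraction, lag)
        timecourse[t] = draw(mean_t, cfg.reps_timecourse, f"t{t:g}_")

    truth = ExpressionTruth(
        planted_primaries=list(cfg.planted_primaries),
        planted_secondaries=list(cfg.planted_secondaries),
        planted_dependent=list(cfg.planted_dependent),
        bound_genes=list(cfg.bound_genes),
        effect_log2fc=dict(cfg.effect_log2fc),
        half_life_hours=dict(cfg.half_life_hours),
        decay_lag_hours=cfg.decay_lag_hours,
        base_cpm=base_cpm,
        seed=seed,
    )
    return ExpressionData(
        counts_on=counts_on,
        counts_off=counts_off,
        counts_targets_off=counts_targets_off,
        timecourse=timecourse,
        bound_genes=list(cfg.bound_genes),
        truth=truth,
    )
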