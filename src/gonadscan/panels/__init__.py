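"""Named panel configurations and the end-to-end profile pipeline.

Each YAML file in this package describes either a genotype panel of
intensity profiles (levels in percent of the control peak, converted
to arbitrary fluorescence units by ``signal_scale``) or an expression
design. ``process_panel`` runs the full profile pipeline on a panel:
generate replicate profiles, subtract the untagged background,
normalize to the internal control's peak, summarize per genotype and
compute peak/base statistics, plus the percent-contribution
decomposition where the panel defines one.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from ..decomp import Decomposition, decompose
from ..profilepipe import (
    IntensityProfile,
    PeakBase,
    ProfileSummary,
    normalize_to_control,
    peak_base,
    subtract_background,
    summarize,
)
from ..synth.expression import ExpressionConfig
from ..synth.profiles import ProfileConfig, generate_profiles

__all__ = [
    "Panel",
    "PanelResult",
    "available_panels",
    "load_panel",
    "load_expression_config",
    "process_panel",
]


@dataclass
class Panel:
    """A named genotype panel of profile configurations."""

    name: str
    protein: str
    max_cd: int
    peak_window: list[int]
    peak_stat: str
    base_cd: int
    control: str
    untagged: str
    genotypes: dict[str, ProfileConfig]
    decomposition: dict[str, str] | None = None


@dataclass
class PanelResult:
    """Output of the full pipeline on one panel."""

    panel: Panel
    profiles: dict[str, list[IntensityProfile]]
    summaries: dict[str, ProfileSummary]
    peaks: dict[str, PeakBase]
    decomposition: Decomposition | None = None


def _read_yaml(name: str) -> dict:
    ref = resources.files(__package__).joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise FileNotFoundError(f"no panel named {name!r}")
    return yaml.safe_load(ref.read_text())


def available_panels() -> list[str]:
    return sorted(
        p.name[:-5] for p in resources.files(__package__).iterdir() if p.name.endswith(".yaml")
    )


def load_panel(name: str, noise_sd_pct: float | None = None, n_germlines: int | None = None) -> Panel:
    """Load a profile panel by name (fig3, figS3, fig6, figS10).

    ``noise_sd_pct`` / ``n_germlines`` override the shipped defaults,
    e.g. noise 0 for exactness tests.
    """
    raw = _read_yaml(name)
    if "genotypes" not in raw:
        raise ValueError(f"{name!r} is not a profile panel")
    scale = float(raw["signal_scale"])
    noise_pct = float(raw["noise_sd_pct"]) if noise_sd_pct is None else noise_sd_pct
    n_reps = int(raw["n_germlines"]) if n_germlines is None else n_germlines
    genotypes = {}
    for label, spec in raw["genotypes"].items():
        genotypes[label] = ProfileConfig(
            genotype_label=label,
            breakpoints=[(float(cd), float(pct) * scale) for cd, pct in spec["levels_pct"]],
            tagged=bool(spec["tagged"]),
            noise_sd=noise_pct * scale,
            background_level=float(raw["background_level"]),
            n_germlines=n_reps,
            max_cd=int(raw["max_cd"]),
        )
    return Panel(
        name=raw["name"],
        protein=raw["protein"],
        max_cd=int(raw["max_cd"]),
        peak_window=[int(c) for c in raw["peak_window"]],
        peak_stat=raw["peak_stat"],
        base_cd=int(raw["base_cd"]),
        control=raw["control"],
        untagged=raw["untagged"],
        genotypes=genotypes,
        decomposition=raw.get("decomposition"),
    )


def load_expression_config(name: str = "paper_like") -> ExpressionConfig:
    """Assemble the full expression design from its YAML summary."""
    raw = _read_yaml(name)
    if "n_dependent" not in raw:
        raise ValueError(f"{name!r} is not an expression design")
    primaries = list(raw["primaries"])
    secondaries = list(raw["secondaries"])
    weak = list(raw["weak_dependent"])
    named = primaries + secondaries + weak
    n_genes = int(raw["n_genes"])
    filler = [f"g{i:04d}" for i in range(1, n_genes - len(named) + 1)]
    gene_ids = named + filler

    n_dep = int(raw["n_dependent"])
    other_dep = filler[: n_dep - len(named)]
    dependent = named + other_dep
    n_bound = int(raw["n_bound"])
    # bound set: the primaries plus non-dependent filler genes
    bound = primaries + filler[n_dep - len(named) : n_dep - len(named) + n_bound - len(primaries)]

    eff = raw["effect_log2fc"]
    effect = {g: float(eff["primary"]) for g in primaries}
    effect.update({g: float(eff["secondary"]) for g in secondaries + weak})
    spread = np.linspace(float(eff["other_min"]), float(eff["other_max"]), max(len(other_dep), 1))
    effect.update({g: float(v) for g, v in zip(other_dep, spread)})

    teff = raw["targets_effect_log2fc"]
    targets_effect = {g: float(teff["secondary"]) for g in secondaries}
    targets_effect.update({g: float(teff["weak"]) for g in weak})

    hl = raw["half_life_hours"]
    half_life = {g: float(hl["primary"]) for g in primaries}
    half_life.update({g: float(hl["secondary"]) for g in secondaries})
    half_life.update({g: float(hl["weak"]) for g in weak})
    half_life.update({g: float(hl["other"]) for g in other_dep})

    return ExpressionConfig(
        n_genes=n_genes,
        gene_ids=gene_ids,
        bound_genes=bound,
        planted_primaries=primaries,
        planted_secondaries=secondaries,
        planted_dependent=dependent,
        effect_log2fc=effect,
        half_life_hours=half_life,
        targets_effect_log2fc=targets_effect,
        decay_lag_hours=float(raw["decay_lag_hours"]),
        dispersion=float(raw["dispersion"]),
        library_size=float(raw["library_size"]),
        reps_contrast=int(raw["reps_contrast"]),
        reps_timecourse=int(raw["reps_timecourse"]),
        timepoints=tuple(float(t) for t in raw["timepoints"]),
        floor_fraction=float(raw["floor_fraction"]),
    )


def process_panel(panel: Panel, seed: int) -> PanelResult:
    """Run generate -> subtract -> normalize -> summarize -> peak/base."""
    children = np.random.SeedSequence(seed).spawn(len(panel.genotypes))
    raw = {
        label: generate_profiles(cfg, child)[0]
        for (label, cfg), child in zip(panel.genotypes.items(), children)
    }
    untagged_raw = raw[panel.untagged]
    corrected = {
        label: subtract_background(profs, untagged_raw)
        for label, profs in raw.items()
        if label != panel.untagged
    }
    control = corrected[panel.control]
    normalized = {
        label: normalize_to_control(profs, control, panel.peak_window)
        for label, profs in corrected.items()
    }
    summaries = {label: summarize(profs) for label, profs in normalized.items()}
    peaks = {
        label: peak_base(s, panel.peak_window, panel.base_cd, panel.peak_stat)
        for label, s in summaries.items()
    }
    decomposition = None
    if panel.decomposition:
        decomposition = decompose(
            peaks[panel.decomposition["reference"]].peak_mean,
            peaks[panel.decomposition["pathway_null"]].peak_mean,
            peaks[panel.decomposition["targets_null"]].peak_mean,
        )
    return PanelResult(
        panel=panel,
        profiles=normalized,
        summaries=summaries,
        peaks=peaks,
        decomposition=decomposition,
    )
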