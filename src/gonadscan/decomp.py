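"""Genetic percent-contribution decomposition of peak protein levels.

Given peak levels from an epistasis panel -- a reference genotype with
signaling intact, a pathway-null genotype (no Notch signaling) and a
targets-null genotype (signaling intact but the downstream target
genes removed) -- the peak is split into three additive fractions of
the reference:

* independent: what remains without the pathway,
  ``100 * pathway_null / ref``;
* via targets: what the target genes account for,
  ``100 * (ref - targets_null) / ref``;
* other pathway-dependent: the remainder.

The decomposition is scale invariant and sums to 100 before rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

from .profilepipe import ProfileSummary

__all__ = ["Decomposition", "FoldResult", "decompose", "fold_at"]


@dataclass
class Decomposition:
    independent_pct: float
    via_targets_pct: float
    other_dependent_pct: float
    #: unclipped values, retained when clipping to [0, 100] was applied
    raw_independent_pct: float
    raw_via_targets_pct: float
    raw_other_dependent_pct: float
    clipped: bool

    @property
    def dependent_pct(self) -> float:
        """Total pathway-dependent fraction (via targets + other)."""
        return self.via_targets_pct + self.other_dependent_pct

    def rounded(self) -> dict[str, int]:
        return {
            "independent": round(self.independent_pct),
            "via_targets": round(self.via_targets_pct),
            "other_dependent": round(self.other_dependent_pct),
        }


@dataclass
class FoldResult:
    ratio: float
    infinite: bool = False


def decompose(ref_peak: float, pathway_null_peak: float, targets_null_peak: float) -> Decomposition:
    """Split a reference peak level into pathway-independent, via-targets
    and other pathway-dependent percentages.

    If the targets-null peak falls below the pathway-null peak the
    "other" term goes negative; it is clipped to 0 and flagged rather
    than silently redistributed.
    """
    if ref_peak <= 0:
        raise ValueError("reference peak must be positive")
    if pathway_null_peak < 0 or targets_null_peak < 0:
        raise ValueError("peak levels must be non-negative")
    independent = 100.0 * pathway_null_peak / ref_peak
    via_targets = 100.0 * (ref_peak - targets_null_peak) / ref_peak
    other = 100.0 - independent - via_targets
    raw = (independent, via_targets, other)
    clipped_vals = [min(max(v, 0.0), 100.0) for v in raw]
    clipped = any(v != r for v, r in zip(clipped_vals, raw))
    return Decomposition(
        independent_pct=clipped_vals[0],
        via_targets_pct=clipped_vals[1],
        other_dependent_pct=clipped_vals[2],
        raw_independent_pct=raw[0],
        raw_via_targets_pct=raw[1],
        raw_other_dependent_pct=raw[2],
        clipped=clipped,
    )


def fold_at(summary_a: ProfileSummary, summary_b: ProfileSummary, cd: int) -> FoldResult:
    """Ratio of mean levels of two genotype summaries at one cd."""
    if summary_a.state != summary_b.state:
        raise ValueError("summaries must share processing state")
    a = summary_a.mean_at(cd)
    b = summary_b.mean_at(cd)
    if b == 0:
        return FoldResult(float("inf"), infinite=True)
    return FoldResult(a / b)
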