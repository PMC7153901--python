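"""Per-cell-diameter intensity profile processing.

Raw profiles extracted along the gonad axis are turned into
background-subtracted, internally normalized genotype summaries.
Background is estimated from staining of an untagged strain (no
epitope, hence no specific signal) and subtracted per cd; profiles are
then rescaled so that the internal control genotype (epitope-tagged
protein in an otherwise wild-type background) has mean peak intensity
100, which puts every co-processed genotype on a "% of control peak"
scale. Peak/base statistics and two-sample significance calls follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IntensityProfile",
    "ProfileSummary",
    "ComparisonResult",
    "PeakBase",
    "subtract_background",
    "normalize_to_control",
    "summarize",
    "peak_base",
    "compare_levels",
    "significance_tier",
]

#: ordering of processing states; transitions must move rightward
_STATES = ("raw", "corrected", "normalized")


@dataclass
class IntensityProfile:
    """Intensity at cd = 1..max_cd for one gonad.

    ``values[k]`` is the intensity at cell diameter ``k + 1`` in
    arbitrary fluorescence units (or "% of control peak" once
    normalized). ``raw_corrected`` retains the pre-clip values after
    background subtraction so that negative excursions remain
    auditable.
    """

    values: np.ndarray
    genotype_label: str
    replicate_id: str = ""
    state: str = "raw"
    max_cd: int = 0
    raw_corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if self.max_cd == 0:
            self.max_cd = self.values.size
        if self.values.size != self.max_cd:
            raise ValueError(
                f"expected {self.max_cd} values (cd 1..max_cd), got {self.values.size}"
            )
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")

    def value_at(self, cd: int) -> float:
        if not 1 <= cd <= self.max_cd:
            raise ValueError(f"cd {cd} outside 1..{self.max_cd}")
        return float(self.values[cd - 1])


@dataclass
class ProfileSummary:
    """Per-cd mean, sample SD and n for one genotype."""

    mean: np.ndarray
    sd: np.ndarray
    n: int
    genotype_label: str
    state: str
    max_cd: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.max_cd == 0:
            self.max_cd = self.mean.size

    def mean_at(self, cd: int) -> float:
        if not 1 <= cd <= self.max_cd:
            raise ValueError(f"cd {cd} outside 1..{self.max_cd}")
        return float(self.mean[cd - 1])


@dataclass
class ComparisonResult:
    """Two-sample comparison of peak (or other) levels.

    ``test_used`` follows the sample-size rule: Welch's t-test when
    min(n) < 30, otherwise a two-sample Z-test with per-sample SDs.
    """

    statistic: float
    p_value: float
    test_used: str
    n_a: int
    n_b: int
    tier: str = field(default="")

    def __post_init__(self) -> None:
        if not self.tier:
            self.tier = significance_tier(self.p_value)


@dataclass
class PeakBase:
    peak_mean: float
    base_mean: float
    fold_ratio: float
    infinite: bool = False


def _window_cds(peak_window: int | Sequence[int]) -> list[int]:
    """Normalize a peak-window spec to an explicit list of cds.

    Accepts a single cd, an inclusive (lo, hi) pair, or an explicit
    sequence of cds.
    """
    if np.isscalar(peak_window):
        return [int(peak_window)]
    window = [int(c) for c in peak_window]
    if len(window) == 2 and window[1] > window[0] + 1:
        return list(range(window[0], window[1] + 1))
    return window


def subtract_background(
    profiles: Iterable[IntensityProfile],
    untagged: Iterable[IntensityProfile],
) -> list[IntensityProfile]:
    """Subtract the mean untagged (no-epitope) profile per cd.

    Negative differences are clipped to 0; the unclipped values are
    kept on the returned profiles as ``raw_corrected``.
    """
    profiles = list(profiles)
    untagged = list(untagged)
    if not untagged:
        raise ValueError("untagged profile set is empty")
    max_cd = profiles[0].max_cd if profiles else untagged[0].max_cd
    for prof in [*profiles, *untagged]:
        if prof.max_cd != max_cd:
            raise ValueError("mismatched max_cd between profiles and untagged set")
    background = np.mean([u.values for u in untagged], axis=0)
    out = []
    for prof in profiles:
        if prof.state != "raw":
            raise ValueError("background subtraction expects raw profiles")
        diff = prof.values - background
        out.append(
            replace(
                prof,
                values=np.clip(diff, 0.0, None),
                state="corrected",
                raw_corrected=diff,
            )
        )
    return out


def normalize_to_control(
    profiles: Iterable[IntensityProfile],
    control: Iterable[IntensityProfile],
    peak_window: int | Sequence[int],
) -> list[IntensityProfile]:
    """Scale a co-processed batch so the control peak mean is 100.

    One scale factor (100 / control mean over ``peak_window``) is
    computed from the corrected control profiles and applied uniformly
    to every profile in ``profiles``; include the control replicates in
    ``profiles`` to obtain them on the same scale.
    """
    profiles = list(profiles)
    control = list(control)
    if not control:
        raise ValueError("control profile set is empty")
    for prof in [*profiles, *control]:
        if prof.state != "corrected":
            raise ValueError("normalization expects corrected (background-subtracted) profiles")
    cds = _window_cds(peak_window)
    idx = [c - 1 for c in cds]
    control_peak = float(np.mean([p.values[idx] for p in control]))
    if control_peak <= 0:
        raise ValueError("control mean over the peak window is not positive")
    factor = 100.0 / control_peak
    return [replace(p, values=p.values * factor, state="normalized") for p in profiles]


def summarize(profiles: Iterable[IntensityProfile]) -> ProfileSummary:
    """Per-cd mean and sample SD (n-1 denominator) of replicate profiles.

    With a single replicate the SD is reported as 0 (flag n = 1).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to summarize")
    states = {p.state for p in profiles}
    if len(states) > 1:
        raise ValueError(f"mixed processing states {sorted(states)}")
    labels = {p.genotype_label for p in profiles}
    label = labels.pop() if len(labels) == 1 else "mixed"
    values = np.stack([p.values for p in profiles])
    n = values.shape[0]
    sd = values.std(axis=0, ddof=1) if n > 1 else np.zeros(values.shape[1])
    return ProfileSummary(
        mean=values.mean(axis=0),
        sd=sd,
        n=n,
        genotype_label=label,
        state=states.pop(),
    )


def peak_base(
    summary: ProfileSummary,
    peak_window: int | Sequence[int],
    base_cd: int,
    peak_stat: str = "mean",
) -> PeakBase:
    """Peak and base levels of a summarized profile and their ratio.

    ``peak_stat="mean"`` averages the mean profile over the window
    (single-cd peaks such as 4 cd); ``"max"`` takes the maximum of the
    mean profile within the window (broad peaks such as 8-13 cd).
    """
    if summary.state == "raw":
        raise ValueError("peak/base expects a corrected or normalized summary")
    cds = _window_cds(peak_window)
    if max(cds) > summary.max_cd or base_cd > summary.max_cd:
        raise ValueError("peak window or base cd outside profile range")
    window_vals = summary.mean[[c - 1 for c in cds]]
    if peak_stat == "mean":
        peak = float(np.mean(window_vals))
    elif peak_stat == "max":
        peak = float(np.max(window_vals))
    else:
        raise ValueError(f"unknown peak_stat {peak_stat!r}")
    base = summary.mean_at(base_cd)
    if base == 0:
        return PeakBase(peak, base, float("inf"), infinite=True)
    return PeakBase(peak, base, peak / base)


def significance_tier(p: float) -> str:
    """Map a p-value to the conventional star tier.

    p <= 0.0001 -> ***, <= 0.001 -> **, <= 0.01 -> *, otherwise NS.
    """
    if p <= 0.0001:
        return "***"
    if p <= 0.001:
        return "**"
    if p <= 0.01:
        return "*"
    return "NS"


def compare_levels(values_a: Sequence[float], values_b: Sequence[float]) -> ComparisonResult:
    """Two-tailed comparison of two samples of per-gonad levels.

    Uses Welch's t-test when min(n) < 30 and a two-sample Z-test with
    per-sample SDs when both n >= 30.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return ComparisonResult(0.0, 1.0, "t" if min(a.size, b.size) < 30 else "Z", a.size, b.size)
        # degenerate but separated samples: infinitely significant
        return ComparisonResult(float("inf"), 0.0, "t" if min(a.size, b.size) < 30 else "Z", a.size, b.size)
    if min(a.size, b.size) < 30:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        return ComparisonResult(float(stat), float(p), "t", a.size, b.size)
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    z = (a.mean() - b.mean()) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult(float(z), float(p), "Z", a.size, b.size)
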