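"""Expression-side target identification.

Implements the gene-list machinery used to call Notch (GLP-1/LAG-1)
transcriptional targets: CPM normalization, a two-sample differential
test with Benjamini-Hochberg FDR, the three-way regulated-gene filter
(fold change >= 2, FDR < 0.05, mean CPM > 2), the intersection of
ChIP-bound genes with signaling-dependent genes, the degradation
time-course primary/secondary classifier, half-life upper bounds from
fold-drop kinetics, and ddCt relative quantitation for qPCR.

The moderated-variance models used on real sequencing data (limma-voom
with TMM scaling) are deliberately out of scope; ``de_table`` applies a
plain Welch t-test to log2(CPM + 0.5), which is adequate for synthetic
libraries of comparable size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cpm",
    "de_table",
    "timecourse_de",
    "fold_drops",
    "filter_regulated",
    "intersect_targets",
    "classify_timecourse",
    "half_life_bound",
    "delta_ct",
    "TargetCallSet",
]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: 1e6 * count / library size, per sample."""
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    libsizes = values.sum(axis=0)
    if (libsizes == 0).any():
        raise ValueError("zero library size in at least one sample")
    return counts / libsizes * 1e6


def de_table(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    contrast: str = "",
) -> pd.DataFrame:
    """Differential expression of group_b versus group_a.

    Returns a gene table with mean_cpm (across all samples of both
    groups), log2fc (b minus a, on log2(CPM + 0.5)), p_value (Welch
    t-test on the same scale; the pseudo-count keeps zero-variance
    degeneracies at bay) and fdr (Benjamini-Hochberg across all genes).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two samples per group")
    norm = cpm(counts[group_a + group_b])
    log_ = np.log2(norm + 0.5)
    a = log_[group_a].to_numpy()
    b = log_[group_b].to_numpy()
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with warnings.catch_warnings():
        # near-constant rows (e.g. all-zero genes) trip scipy's
        # precision warning; their p is set to 1 below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # identical constant rows
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "mean_cpm": norm.mean(axis=1),
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
        },
        index=counts.index,
    )
    table.attrs["contrast"] = contrast
    return table


def filter_regulated(
    table: pd.DataFrame,
    direction: str = "up",
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    cpm_min: float = 2.0,
) -> set[str]:
    """Genes passing the three-way regulated filter.

    Fold change is taken on the linear scale, 2**log2fc, and compared
    against ``fc_min`` inclusively in the stated direction; FDR must be
    strictly below ``fdr_max`` and mean CPM strictly above ``cpm_min``.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    fold = 2.0 ** table["log2fc"]
    if direction == "up":
        fc_ok = fold >= fc_min
    else:
        fc_ok = fold <= 1.0 / fc_min
    passed = table[fc_ok & (table["fdr"] < fdr_max) & (table["mean_cpm"] > cpm_min)]
    return set(passed.index)


def timecourse_de(timecourse: dict[float, pd.DataFrame], t0: float = 0.0) -> dict[float, pd.DataFrame]:
    """Per-time-point gene tables for a degradation time course.

    Each t > t0 is contrasted against the t0 samples (log2fc is t
    versus t0, so regulator-dependent genes go down).
    """
    if t0 not in timecourse:
        raise ValueError(f"baseline time point {t0} missing")
    base = timecourse[t0]
    tables = {}
    for t, counts in timecourse.items():
        if t == t0:
            continue
        joint = pd.concat([base, counts], axis=1)
        tables[t] = de_table(joint, list(base.columns), list(counts.columns), contrast=f"auxin_t{t:g}")
    return tables


def fold_drops(
    timecourse: dict[float, pd.DataFrame],
    genes: list[str],
    t0: float = 0.0,
) -> dict[float, float]:
    """Mean fold drop of a gene set relative to t0, per time point.

    The drop is the ratio of mean CPM at t0 to mean CPM at t, averaged
    over the genes; folds below 1 (no drop) are floored at 1 so the
    result feeds :func:`half_life_bound` directly.
    """
    if t0 not in timecourse:
        raise ValueError(f"baseline time point {t0} missing")
    base = cpm(timecourse[t0]).loc[genes].mean(axis=1)
    out = {}
    for t, counts in timecourse.items():
        if t == t0:
            continue
        level = cpm(counts).loc[genes].mean(axis=1)
        out[t] = float(np.maximum(base / level, 1.0).mean())
    return out


def intersect_targets(bound_genes: set[str], dependent_genes: set[str]) -> list[str]:
    """Intersection of ChIP-bound genes with signaling-dependent genes,
    returned sorted by gene id for stable downstream use."""
    return sorted(set(bound_genes) & set(dependent_genes))


@dataclass
class TargetCallSet:
    """Per-gene primary/secondary/unclassified calls with evidence."""

    calls: pd.DataFrame
    earliest_time: float

    def genes_in_class(self, cls: str) -> list[str]:
        return sorted(self.calls.index[self.calls["class"] == cls])


def classify_timecourse(
    tables: dict[float, pd.DataFrame],
    bound_genes: set[str],
    targets_dependence: pd.DataFrame | None = None,
    direction: str = "down",
    earliest_time: float = 2.0,
    filter_kwargs: dict | None = None,
) -> TargetCallSet:
    """Classify genes as primary or secondary pathway targets.

    ``tables`` maps hours after regulator loss to a gene table for the
    t-versus-0 contrast. A primary target changes expression at the
    earliest analyzed time AND carries a ChIP peak (bound); a secondary
    target is NOT bound and changes expression only at a later time --
    consistent with it responding to the loss of the primary targets'
    protein products rather than to the regulator itself.

    ``targets_dependence``, if given, is the gene table for the
    contrast between signaling-ON and primary-targets-null conditions;
    genes regulated there get evidence flag targets_dependent = True.
    """
    if earliest_time not in tables:
        raise ValueError(f"earliest analyzed time point {earliest_time} h missing")
    filter_kwargs = filter_kwargs or {}
    times = sorted(tables)
    regulated = {t: filter_regulated(tables[t], direction=direction, **filter_kwargs) for t in times}
    later_times = [t for t in times if t > earliest_time]

    genes = tables[earliest_time].index
    bound = pd.Series(genes.isin(list(bound_genes)), index=genes)
    dep_set: set[str] | None = None
    if targets_dependence is not None:
        # dependence contrast is ON vs targets-null: dependent genes are up in ON
        dep_set = filter_regulated(targets_dependence, direction="up", **filter_kwargs)

    rows = {}
    for g in genes:
        at_earliest = g in regulated[earliest_time]
        first_late = next((t for t in later_times if g in regulated[t]), None)
        if at_earliest and bound[g]:
            cls = "primary"
            regulated_at = earliest_time
        elif (not bound[g]) and (not at_earliest) and first_late is not None:
            cls = "secondary"
            regulated_at = first_late
        else:
            cls = "unclassified"
            regulated_at = earliest_time if at_earliest else first_late
        rows[g] = {
            "class": cls,
            "bound": bool(bound[g]),
            "regulated_at": regulated_at,
            "targets_dependent": (g in dep_set) if dep_set is not None else None,
        }
    calls = pd.DataFrame.from_dict(rows, orient="index")
    calls.index.name = "gene"
    # by construction a bound gene is never secondary, an unbound never primary
    assert not ((calls["class"] == "secondary") & calls["bound"]).any()
    assert not ((calls["class"] == "primary") & ~calls["bound"]).any()
    return TargetCallSet(calls=calls, earliest_time=earliest_time)


def half_life_bound(fold_drop_by_time: dict[float, float]) -> float | None:
    """Upper bound on half-life from sampled fold drops.

    The earliest sampled time at which the level has fallen at least
    two-fold is an upper bound on the half-life (the true half-life
    must have been reached at or before that sample). Returns None if
    no sampled time reaches a two-fold drop.
    """
    for t in sorted(fold_drop_by_time):
        fold = fold_drop_by_time[t]
        if fold < 1:
            raise ValueError("fold drops must be >= 1 where measured")
        if fold >= 2.0:
            return float(t)
    return None


def delta_ct(
    ct: pd.DataFrame,
    reference_gene: str = "ama-1",
    reference_condition: str | None = None,
) -> pd.DataFrame:
    """Relative mRNA abundance by the ddCt method.

    ``ct`` needs columns gene, condition, replicate, ct. Within each
    (condition, replicate), dCt = Ct(gene) - Ct(reference gene); the
    per-condition mean dCt is referenced to ``reference_condition``
    (ddCt) and abundance is 2**(-ddCt), so the reference condition is
    exactly 1 for every gene.
    """
    required = {"gene", "condition", "replicate", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    ref = ct[ct["gene"] == reference_gene].set_index(["condition", "replicate"])["ct"]
    targets = ct[ct["gene"] != reference_gene]
    keys = list(zip(targets["condition"], targets["replicate"]))
    if any(k not in ref.index for k in keys):
        raise ValueError(f"reference gene {reference_gene!r} missing for some (condition, replicate)")
    dct = targets["ct"].to_numpy() - ref.loc[keys].to_numpy()
    frame = targets.assign(dct=dct)
    mean_dct = frame.groupby(["gene", "condition"])["dct"].mean().unstack("condition")
    if reference_condition is None:
        reference_condition = mean_dct.columns[0]
    if reference_condition not in mean_dct.columns:
        raise ValueError(f"reference condition {reference_condition!r} not measured")
    if mean_dct[reference_condition].isna().any():
        raise ValueError("reference condition missing for some gene")
    ddct = mean_dct.sub(mean_dct[reference_condition], axis=0)
    rel = 2.0 ** (-ddct)
    rel.columns.name = "condition"
    return rel
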