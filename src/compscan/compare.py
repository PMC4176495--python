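"""Downstream comparisons: knock-down effects by binding bin, gene-length
effects, length-effect correlation, distances to high-affinity sites and
region/label overlap fractions.

No multiple-testing correction is applied: each comparison reports its raw
Mann-Whitney p-value, and reports carry the number of tests performed.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, RegionSet
from .expression import ExpressionError, ExpressionTable
from .stats import GroupComparison, compare_groups, pearson_correlation

log = logging.getLogger(__name__)

EFFECT_BINS = ("Unbound", "(3,4]", "(4,5]", "(5,inf)")


def knockdown_effect(
    table: ExpressionTable,
    treatment: str,
    control: str,
    threshold: float = 6.0,
) -> pd.Series:
    """log2(treatment) - log2(control) for genes expressed in the control.

    Genes below the detection floor in the control (wild-type or mock
    RNAi) are excluded.
    """
    for col in (treatment, control):
        if col not in table.data.columns:
            raise ExpressionError(f"missing expression column {col!r}")
    ctrl = table.data[control]
    keep = ctrl >= threshold
    delta = table.data.loc[keep, treatment] - ctrl[keep]
    return delta.rename("effect")


def compare_bins(
    effects: pd.Series,
    calls: pd.DataFrame,
    autosomal_effects: pd.Series,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-bin effect summaries and bin-vs-autosome Mann-Whitney tests.

    ``calls`` is the binding-call frame for the genes of interest (the X
    chromosome in the published analysis); each of the four bins is tested
    two-sided against the pooled autosomal effects.  Empty bins are
    skipped with a warning.
    """
    auto = autosomal_effects.dropna().to_numpy()
    rows = []
    comparisons = []
    for label in EFFECT_BINS:
        ids = calls.index[calls["bin"] == label]
        vals = effects.reindex(ids).dropna().to_numpy()
        if len(vals) == 0:
            log.warning("bin %s is empty; comparison skipped", label)
            continue
        rows.append(
            {
                "bin": label,
                "n": len(vals),
                "median": float(np.median(vals)),
                "mean": float(np.mean(vals)),
            }
        )
        if len(auto):
            comparisons.append(
                compare_groups({label: vals, "autosomes": auto}, (label, "autosomes"))
            )
    return pd.DataFrame(rows), comparisons


def length_split_comparison(
    effects: pd.Series,
    calls: pd.DataFrame,
    annotation: GenomeAnnotation,
    length_threshold: int = 10_000,
) -> GroupComparison:
    """Mann-Whitney of effects in bound long (>threshold) vs short genes.

    Genes exactly at the threshold go to the short class.  Only bound
    genes are considered.
    """
    bound_ids = [g for g in calls.index[calls["bound"]] if g in annotation]
    vals = effects.reindex(bound_ids).dropna()
    lengths = np.array([annotation[g].length for g in vals.index])
    long_vals = vals.to_numpy()[lengths > length_threshold]
    short_vals = vals.to_numpy()[lengths <= length_threshold]
    if len(long_vals) == 0 or len(short_vals) == 0:
        raise ValueError("need bound genes in both length classes")
    return compare_groups(
        {"long": long_vals, "short": short_vals}, ("long", "short")
    )


def length_effect_correlation(
    effects: pd.Series,
    calls: pd.DataFrame,
    annotation: GenomeAnnotation,
) -> dict:
    """Pearson R between transcript length and effect over bound genes.

    Reported on the bp scale and, as an alternative, on log10(length).
    """
    bound_ids = [g for g in calls.index[calls["bound"]] if g in annotation]
    vals = effects.reindex(bound_ids).dropna()
    if len(vals) < 3:
        raise ValueError("need >= 3 bound genes with effect scores")
    lengths = np.array([annotation[g].length for g in vals.index], dtype=float)
    r_bp, p_bp = pearson_correlation(lengths, vals.to_numpy())
    r_log, p_log = pearson_correlation(np.log10(lengths), vals.to_numpy())
    return {
        "n": len(vals),
        "r_bp": r_bp,
        "p_bp": p_bp,
        "r_log10": r_log,
        "p_log10": p_log,
    }


def has_distances(
    annotation: GenomeAnnotation,
    has: RegionSet,
    genes: Iterable[str] | None = None,
) -> pd.Series:
    """Distance from each gene span to the nearest high-affinity site.

    Zero when the span overlaps a site; otherwise the bp gap to the
    nearest site edge on the same arm.  Genes on arms without any site get
    NaN (undefined) and are excluded from group means downstream.
    """
    if len(has) == 0:
        ids = list(genes) if genes is not None else list(annotation.genes)
        return pd.Series(np.nan, index=pd.Index(ids, name="gene_id"), name="has_distance")
    by_arm: dict[str, list[tuple[int, int]]] = {}
    for arm, a, b in has.regions:
        by_arm.setdefault(arm, []).append((a, b))
    ids = list(genes) if genes is not None else list(annotation.genes)
    out = {}
    n_undef = 0
    for gid in ids:
        g = annotation[gid]
        sites = by_arm.get(g.arm)
        if not sites:
            out[gid] = np.nan
            n_undef += 1
            continue
        d = min(
            0 if (a < g.end and g.start < b) else (a - g.end if a >= g.end else g.start - b)
            for a, b in sites
        )
        out[gid] = float(max(d, 0))
    if n_undef:
        log.warning("%d genes on arms without HAS; distance undefined", n_undef)
    return pd.Series(out, name="has_distance").rename_axis("gene_id")


def has_distance_summary(
    distances: pd.Series,
    calls: pd.DataFrame,
    annotation: GenomeAnnotation,
    length_threshold: int = 10_000,
) -> pd.DataFrame:
    """Mean HAS distance of bound-long vs unbound-long genes."""
    rows = []
    for label, bound_flag in (("bound_long", True), ("unbound_long", False)):
        ids = [
            g
            for g in calls.index[calls["bound"] == bound_flag]
            if g in annotation and annotation[g].length > length_threshold
        ]
        vals = distances.reindex(ids).dropna()
        rows.append(
            {
                "group": label,
                "n": len(vals),
                "mean_distance": float(vals.mean()) if len(vals) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def overlap_fraction(
    annotation: GenomeAnnotation,
    genes: Iterable[str],
    regions: RegionSet,
) -> float:
    """Fraction of genes whose span overlaps >= 1 region by >= 1 bp."""
    ids = list(genes)
    if not ids:
        raise ValueError("overlap fraction undefined for an empty gene set")
    trees = regions.by_arm()
    n_hit = 0
    for gid in ids:
        g = annotation[gid]
        tree = trees.get(g.arm)
        if tree is not None and tree.overlap(g.start, g.end):
            n_hit += 1
    return n_hit / len(ids)


def flag_fraction(flags: Mapping[str, bool], genes: Iterable[str]) -> float:
    """Fraction of genes whose boolean label (e.g. housekeeping) is true."""
    ids = list(genes)
    if not ids:
        raise ValueError("flag fraction undefined for an empty gene set")
    return sum(bool(flags.get(g, False)) for g in ids) / len(ids)
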