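"""IP/input enrichment tracks, per-gene binding values and bound calls.

The track pipeline follows the published procedure step for step:

1. per-nucleotide read counts are median smoothed (10 bp window) and
   sampled onto a 10 bp grid;
2. at grid points where the smoothed IP has at least one read, the log2
   IP/input ratio is computed with the input floored at its genome-wide
   mean (itself floored at 4 reads);
3. ratios are median-centered to absorb the IP/input depth difference;
4. the centered ratio is median smoothed with a 200 bp window, discarding
   windows with fewer than 10 data points;
5. per gene, exonic grid values (excluding the first 200 bp of exonic
   sequence from the 5' end) are collected, and the binding value is the
   mean of the top 50% — genes with fewer than 10 points are unqualified.

Bound/unbound calls use a reference autosomal arm: bound means a binding
value strictly above the reference mean + 1 SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation
from .config import EnrichmentParams
from .tracks import SignalTrack, TrackError, exonic_grid_points, median_smooth, smooth_and_grid

log = logging.getLogger(__name__)

BIN_LABELS = ("Unbound", "(3,4]", "(4,5]", "(5,inf)", "unassigned")


def input_floor(input_track: SignalTrack, floor_min: float = 4.0) -> float:
    """Genome-wide floor for input counts: max(input mean, floor_min)."""
    vals = input_track.all_values()
    if len(vals) == 0:
        raise TrackError("input track has no values")
    return float(max(vals.mean(), floor_min))


def enrichment_ratio(
    ip: SignalTrack, input_track: SignalTrack, params: EnrichmentParams
) -> SignalTrack:
    """log2(IP / effective input) wherever the smoothed IP has >= 1 read.

    Effective input is the input value floored at the genome-wide input
    mean, the floor itself never below ``params.input_floor_min``.
    """
    if not ip.same_grid(input_track):
        raise TrackError("IP and input tracks are on different grids")
    floor = input_floor(input_track, params.input_floor_min)
    data = {}
    for arm in ip.data:
        ipv = ip.data[arm]
        inv = input_track.data[arm]
        eff = np.maximum(inv, floor)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.log2(ipv) - np.log2(eff)
        ratio[~(ipv >= 1)] = np.nan  # requires at least one mapped read
        ratio[np.isnan(inv)] = np.nan
        data[arm] = ratio
    return SignalTrack(ip.step, data)


def median_center(track: SignalTrack) -> SignalTrack:
    """Subtract the genome-wide median ratio (depth adjustment)."""
    vals = track.all_values()
    if len(vals) == 0:
        raise TrackError("cannot median-center an empty track")
    med = float(np.median(vals))
    return track.map(lambda v: v - med)


def smooth_ratio(track: SignalTrack, params: EnrichmentParams) -> SignalTrack:
    """Second-pass 200 bp median smoothing; sparse windows are discarded."""
    return median_smooth(
        track, params.smooth2_window, min_points=params.min_points_per_window
    )


def enrichment_pipeline(
    ip_raw: SignalTrack,
    input_raw: SignalTrack,
    params: EnrichmentParams | None = None,
) -> SignalTrack:
    """Full track pipeline from per-nucleotide counts to the final ratio."""
    params = params or EnrichmentParams()
    if ip_raw.step == params.grid_step:
        ip = median_smooth(ip_raw, params.smooth1_window)
        inp = median_smooth(input_raw, params.smooth1_window)
    else:
        ip = smooth_and_grid(ip_raw, params.smooth1_window, params.grid_step)
        inp = smooth_and_grid(input_raw, params.smooth1_window, params.grid_step)
    ratio = enrichment_ratio(ip, inp, params)
    centered = median_center(ratio)
    return smooth_ratio(centered, params)


# ---------------------------------------------------------------------------
# Gene binding values


@dataclass(frozen=True)
class GeneBindingValue:
    gene_id: str
    value: float  # NaN when unqualified
    n_points: int
    qualified: bool


def gene_binding_value(
    gene: GeneModel, ratio_track: SignalTrack, params: EnrichmentParams | None = None
) -> GeneBindingValue:
    """Mean of the top 50% of exonic ratio values for one gene.

    The first ``exclude_first_exonic_bp`` of exonic sequence (5' end,
    strand-aware by default) is excluded; genes with fewer than
    ``min_points_per_gene`` remaining points are unqualified.  The top
    count is ``ceil(top_fraction * n)``.
    """
    params = params or EnrichmentParams()
    _, vals = exonic_grid_points(
        gene,
        ratio_track,
        exclude_first_bp=params.exclude_first_exonic_bp,
        strand_aware=params.strand_aware_exclusion,
    )
    n = len(vals)
    if n < params.min_points_per_gene:
        return GeneBindingValue(gene.gene_id, float("nan"), n, False)
    k = ceil(params.top_fraction * n)
    top = np.sort(vals)[-k:]
    return GeneBindingValue(gene.gene_id, float(top.mean()), n, True)


def gene_binding_values(
    annotation: GenomeAnnotation,
    ratio_track: SignalTrack,
    params: EnrichmentParams | None = None,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Binding values for many genes as a frame indexed by gene id."""
    params = params or EnrichmentParams()
    ids = list(genes) if genes is not None else list(annotation.genes)
    rows = []
    for gid in ids:
        g = annotation[gid]
        if g.arm not in ratio_track.data:
            continue
        bv = gene_binding_value(g, ratio_track, params)
        rows.append((gid, g.arm, bv.value, bv.n_points, bv.qualified))
    df = pd.DataFrame(
        rows, columns=["gene_id", "arm", "value", "n_points", "qualified"]
    ).set_index("gene_id")
    n_unq = int((~df["qualified"]).sum()) if len(df) else 0
    if n_unq:
        log.info("%d genes unqualified (<%d points)", n_unq, params.min_points_per_gene)
    return df


def assign_bin(value: float, bound: bool) -> str:
    if not bound:
        return "Unbound"
    if value > 5:
        return "(5,inf)"
    if value > 4:
        return "(4,5]"
    if value > 3:
        return "(3,4]"
    return "unassigned"


@dataclass(frozen=True)
class BindingReference:
    arm: str
    n: int
    mean: float
    sd: float

    @property
    def cutoff(self) -> float:
        return self.mean + self.sd


def classify_binding(
    values: pd.DataFrame,
    annotation: GenomeAnnotation,
    reference_arm: str = "3L",
    expressed: set[str] | None = None,
) -> tuple[pd.DataFrame, BindingReference]:
    """Call genes bound when value > reference mean + 1 SD (strict).

    Reference statistics are computed over qualified genes on the
    reference arm, restricted to ``expressed`` genes when given.  Bound
    genes are assigned to the bins (3,4], (4,5], (5,inf); bound genes at
    or below 3 are 'unassigned' and excluded from binned analyses.
    """
    qual = values[values["qualified"]]
    ref = qual[qual["arm"] == reference_arm]
    if expressed is not None:
        ref = ref[ref.index.isin(expressed)]
    if len(ref) < 2:
        raise ValueError(
            f"reference arm {reference_arm!r}: need >= 2 qualified genes, "
            f"have {len(ref)}"
        )
    mean = float(ref["value"].mean())
    sd = float(ref["value"].std(ddof=1))
    reference = BindingReference(reference_arm, len(ref), mean, sd)
    cutoff = reference.cutoff
    calls = qual.copy()
    calls["bound"] = calls["value"] > cutoff
    calls["cutoff_used"] = cutoff
    calls["bin"] = [
        assign_bin(v, b) for v, b in zip(calls["value"], calls["bound"])
    ]
    return calls, reference
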