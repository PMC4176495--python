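"""Male/female copy-number ratios from input coverage.

Each input track is median smoothed with a 1 kb window and sampled on the
10 bp grid; per gene, smoothed values at grid positions across the whole
gene span (introns included) are averaged in each sex and the ratio of
means is reported on the log2 scale.  By default each track is first
normalized to its autosomal median to absorb the sequencing-depth
difference between the male and female inputs.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .config import EnrichmentParams
from .stats import GroupComparison, compare_groups
from .tracks import SignalTrack, TrackError, median_smooth, smooth_and_grid

log = logging.getLogger(__name__)


def _smoothed_grid(track: SignalTrack, params: EnrichmentParams) -> SignalTrack:
    if track.step == params.grid_step:
        return median_smooth(track, params.copy_smooth_window)
    return smooth_and_grid(track, params.copy_smooth_window, params.grid_step)


def _autosomal_median(track: SignalTrack, x_arm: str) -> float:
    parts = [v for a, v in track.data.items() if a != x_arm]
    if not parts:
        raise TrackError("no autosomal arm available for depth normalization")
    cat = np.concatenate(parts)
    cat = cat[~np.isnan(cat)]
    med = float(np.median(cat))
    if med <= 0:
        raise TrackError("autosomal median coverage is not positive")
    return med


def gene_copy_ratio(
    input_male: SignalTrack,
    input_female: SignalTrack,
    annotation: GenomeAnnotation,
    genes: Iterable[str] | None = None,
    params: EnrichmentParams | None = None,
    normalize_depth: bool = True,
    x_arm: str = "X",
) -> pd.DataFrame:
    """Per-gene log2 male/female input coverage ratio.

    Genes whose mean coverage is zero (or all-missing) in either sex get a
    NaN ratio and are logged.  Depth normalization divides each smoothed
    track by its autosomal median before the ratio (disable with
    ``normalize_depth=False``).
    """
    params = params or EnrichmentParams()
    sm = _smoothed_grid(input_male, params)
    sf = _smoothed_grid(input_female, params)
    if not sm.same_grid(sf):
        raise TrackError("male and female input tracks are on different grids")
    scale_m = _autosomal_median(sm, x_arm) if normalize_depth else 1.0
    scale_f = _autosomal_median(sf, x_arm) if normalize_depth else 1.0
    step = sm.step
    ids = list(genes) if genes is not None else list(annotation.genes)
    rows = []
    n_undef = 0
    for gid in ids:
        g = annotation[gid]
        if g.arm not in sm.data:
            continue
        arr_m = sm.data[g.arm]
        arr_f = sf.data[g.arm]
        j0 = (g.start + step - 1) // step
        j1 = min((g.end + step - 1) // step, len(arr_m))
        vm = arr_m[j0:j1]
        vf = arr_f[j0:j1]
        vm = vm[~np.isnan(vm)]
        vf = vf[~np.isnan(vf)]
        if len(vm) == 0 or len(vf) == 0 or vm.mean() <= 0 or vf.mean() <= 0:
            rows.append((gid, g.arm, float("nan"), 0))
            n_undef += 1
            continue
        ratio = np.log2(vm.mean() / scale_m) - np.log2(vf.mean() / scale_f)
        rows.append((gid, g.arm, float(ratio), min(len(vm), len(vf))))
    if n_undef:
        log.warning("%d genes have undefined copy ratios", n_undef)
    return pd.DataFrame(
        rows, columns=["gene_id", "arm", "log2_ratio", "n_points"]
    ).set_index("gene_id")


def compare_copy_x_vs_autosomes(
    ratios: pd.DataFrame, annotation: GenomeAnnotation, x_arm: str = "X"
) -> GroupComparison:
    """Two-sided Mann-Whitney U of X vs pooled autosomal copy ratios."""
    ok = ratios.dropna(subset=["log2_ratio"])
    x = ok.loc[ok["arm"] == x_arm, "log2_ratio"].to_numpy()
    auto = ok.loc[ok["arm"] != x_arm, "log2_ratio"].to_numpy()
    if len(x) == 0 or len(auto) == 0:
        raise ValueError("need at least one gene per group (X and autosomes)")
    return compare_groups({"X": x, "autosomes": auto}, ("X", "autosomes"))
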