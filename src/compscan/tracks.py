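"""Genomic signal tracks on a fixed-step grid, and median smoothing.

A :class:`SignalTrack` holds, per chromosome arm, values at grid positions
``0, step, 2*step, ...``.  Missing data is ``NaN`` and is distinct from 0.
Median smoothing uses a centered half-open window ``[pos - w/2, pos + w/2)``
and ignores missing values; a window with no observed value (or with fewer
than ``min_points`` observed values, where requested) yields a missing
value.  Windows are truncated at arm boundaries.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .annotation import GeneModel

log = logging.getLogger(__name__)


class TrackError(ValueError):
    """Malformed track input or incompatible grids."""


@dataclass
class SignalTrack:
    """Per-arm values on a fixed-step genomic grid (NaN = missing)."""

    step: int
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise TrackError(f"grid step must be positive, got {self.step}")
        for arm, arr in self.data.items():
            self.data[arm] = np.asarray(arr, dtype=float)

    def arms(self) -> list[str]:
        return sorted(self.data)

    def values(self, arm: str) -> np.ndarray:
        return self.data[arm]

    def positions(self, arm: str) -> np.ndarray:
        return np.arange(len(self.data[arm])) * self.step

    def all_values(self) -> np.ndarray:
        """Concatenated non-missing values across arms (arm-name order)."""
        parts = [self.data[a] for a in self.arms()]
        if not parts:
            return np.empty(0)
        cat = np.concatenate(parts)
        return cat[~np.isnan(cat)]

    def same_grid(self, other: "SignalTrack") -> bool:
        return (
            self.step == other.step
            and set(self.data) == set(other.data)
            and all(len(self.data[a]) == len(other.data[a]) for a in self.data)
        )

    def map(self, fn) -> "SignalTrack":
        return SignalTrack(self.step, {a: fn(v) for a, v in self.data.items()})

    def copy(self) -> "SignalTrack":
        return SignalTrack(self.step, {a: v.copy() for a, v in self.data.items()})


# ---------------------------------------------------------------------------
# Median smoothing


def _window_offsets(window: int, step: int) -> tuple[int, int]:
    """Inclusive grid-index offsets [lo, hi] covered by a centered window.

    Grid point ``j`` is in the window of ``i`` iff
    ``i*step - window/2 <= j*step < i*step + window/2``.
    """
    h = window / (2 * step)
    lo = math.ceil(-h)
    hi = math.ceil(h) - 1
    return lo, hi


def _sliding_median(
    arr: np.ndarray, lo: int, hi: int, min_points: int, sample_every: int = 1
) -> np.ndarray:
    """Median over windows [i+lo, i+hi] for centers i = 0, k, 2k, ... (NaN-aware)."""
    k = sample_every
    n = len(arr)
    width = hi - lo + 1
    if width <= 1:
        out = arr[::k].astype(float).copy()
        if min_points > 1:  # a one-point window can never satisfy min_points > 1
            out[:] = np.nan
        return out
    padded = np.full(n + width - 1, np.nan)
    padded[-lo : -lo + n] = arr
    win = np.lib.stride_tricks.sliding_window_view(padded, width)[::k]
    arr_has_nan = bool(np.isnan(arr).any())
    counts = None
    if arr_has_nan or min_points > 1:
        counts = np.sum(~np.isnan(win), axis=-1)
    if arr_has_nan:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmedian(win, axis=-1)
    else:
        # interior windows are NaN-free; only boundary windows see padding
        out = np.median(win, axis=-1)
        centers = np.arange(win.shape[0]) * k
        bdry = (centers + lo < 0) | (centers + hi > n - 1)
        if bdry.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[bdry] = np.nanmedian(win[bdry], axis=-1)
    if counts is not None:
        out[counts < max(min_points, 1)] = np.nan
    return out


def median_smooth(
    track: SignalTrack, window: int, min_points: int = 1
) -> SignalTrack:
    """Median-smooth every arm with a centered ``window`` (bp).

    Each grid value is replaced by the median of the non-missing values in
    its window; windows with fewer than ``min_points`` observed values give
    a missing value.
    """
    if window < track.step:
        raise TrackError(f"window {window} smaller than grid step {track.step}")
    lo, hi = _window_offsets(window, track.step)
    return track.map(lambda v: _sliding_median(v, lo, hi, min_points))


def smooth_and_grid(track: SignalTrack, window: int, grid_step: int) -> SignalTrack:
    """Median-smooth, then extract values at intervals of ``grid_step``.

    The canonical use is per-nucleotide read counts (step 1) smoothed with a
    10 bp (or 1 kb) window and sampled every 10 bp.
    """
    if grid_step % track.step:
        raise TrackError("grid_step must be a multiple of the track step")
    lo, hi = _window_offsets(window, track.step)
    k = grid_step // track.step
    return SignalTrack(
        grid_step,
        {a: _sliding_median(v, lo, hi, 1, k) for a, v in track.data.items()},
    )


# ---------------------------------------------------------------------------
# bedGraph I/O


def read_track(
    path: str | os.PathLike,
    grid_step: int,
    arm_lengths: dict[str, int] | None = None,
) -> SignalTrack:
    """Read a bedGraph file onto a grid of ``grid_step`` bp.

    The value at a grid point is the value of the interval covering it;
    uncovered grid points are missing.  Overlapping intervals are an error.
    """
    path = os.fspath(path)
    per_arm: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise TrackError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                arm, a, b, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise TrackError(f"{path}:{lineno}: {exc}") from exc
            if a >= b:
                raise TrackError(f"{path}:{lineno}: empty interval")
            per_arm.setdefault(arm, []).append((a, b, v))
    data: dict[str, np.ndarray] = {}
    for arm, ivals in per_arm.items():
        ivals.sort()
        for (a1, b1, _), (a2, _, _) in zip(ivals, ivals[1:]):
            if a2 < b1:
                raise TrackError(f"{path}: overlapping intervals on {arm} at {a2}")
        length = max(b for _, b, _ in ivals)
        if arm_lengths and arm in arm_lengths:
            length = max(length, arm_lengths[arm])
        n = (length + grid_step - 1) // grid_step
        arr = np.full(n, np.nan)
        for a, b, v in ivals:
            j0 = (a + grid_step - 1) // grid_step
            j1 = (b + grid_step - 1) // grid_step  # exclusive
            arr[j0:j1] = v
        data[arm] = arr
    n_rec = sum(len(v) for v in per_arm.values())
    log.info("read %d bedGraph records from %s (%d arms)", n_rec, path, len(data))
    return SignalTrack(grid_step, data)


def write_track(track: SignalTrack, path: str | os.PathLike) -> None:
    """Write a track as bedGraph, merging runs of equal values."""
    with open(path, "w") as fh:
        for arm in track.arms():
            arr = track.data[arm]
            s = track.step
            run_start = None
            run_val = None
            for j, v in enumerate(arr):
                if np.isnan(v):
                    if run_start is not None:
                        fh.write(f"{arm}\t{run_start}\t{j * s}\t{run_val:g}\n")
                        run_start = None
                    continue
                if run_start is None:
                    run_start, run_val = j * s, v
                elif v != run_val:
                    fh.write(f"{arm}\t{run_start}\t{j * s}\t{run_val:g}\n")
                    run_start, run_val = j * s, v
            if run_start is not None:
                fh.write(f"{arm}\t{run_start}\t{len(arr) * s}\t{run_val:g}\n")


# ---------------------------------------------------------------------------
# Exonic grid extraction


def exonic_grid_points(
    gene: GeneModel,
    track: SignalTrack,
    exclude_first_bp: int = 0,
    strand_aware: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Track values at grid points inside the gene's exons.

    Grid points whose cumulative exonic offset from the gene's 5' end is
    below ``exclude_first_bp`` are removed; the offset is strand-aware in
    spliced exonic coordinates (set ``strand_aware=False`` to always count
    from the genomic left end).  Missing grid points are skipped.  Returns
    ``(positions, values)`` in genomic order.
    """
    if gene.arm not in track.data:
        raise TrackError(f"arm {gene.arm} not present in track")
    arr = track.data[gene.arm]
    s = track.step
    exon_lens = [b - a for a, b in gene.exons]
    total = sum(exon_lens)
    cum_before = np.concatenate([[0], np.cumsum(exon_lens[:-1])]) if exon_lens else []
    pos_parts: list[np.ndarray] = []
    off_parts: list[np.ndarray] = []
    minus = strand_aware and gene.strand == "-"
    for (a, b), cb in zip(gene.exons, cum_before):
        j0 = (a + s - 1) // s
        j1 = min((b + s - 1) // s, len(arr))
        if j1 <= j0:
            continue
        p = np.arange(j0, j1) * s
        if minus:
            off = (total - cb - (b - a)) + (b - 1 - p)
        else:
            off = cb + (p - a)
        pos_parts.append(p)
        off_parts.append(off)
    if not pos_parts:
        return np.empty(0, dtype=int), np.empty(0)
    pos = np.concatenate(pos_parts)
    off = np.concatenate(off_parts)
    keep = off >= exclude_first_bp
    pos = pos[keep]
    vals = arr[pos // s]
    ok = ~np.isnan(vals)
    return pos[ok], vals[ok]
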