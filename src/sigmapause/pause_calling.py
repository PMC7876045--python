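"""Pause-score computation and pause-site calling.

A genomic position is a pause site when its 3'-end read count is at least
``min_fold`` times the median count in a centered odd-length window (default
51 nt, same strand) and its counts-per-million is at least ``min_cpm``.
Masked positions are never called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .track_io import STRANDS, EndCountTrack, MaskSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PauseSite:
    contig: str
    position: int  # 0-based 3'-end coordinate
    strand: str
    count: int
    window_median: float
    pause_score: float
    cpm: float

    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.strand)


def window_median(
    track: EndCountTrack,
    contig: str,
    position: int,
    strand: str,
    window: int = 51,
    exclude_center: bool = False,
    circular: bool = False,
) -> float:
    """Median count in the ``window`` positions centered at ``position``.

    The window includes the center position unless ``exclude_center``.  At
    contig edges the window is truncated to the available positions; with
    ``circular`` it wraps around instead.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    vec = track.get(contig, strand)
    n = len(vec)
    if not 0 <= position < n:
        raise ValueError(f"position {position} outside contig {contig} (length {n})")
    half = window // 2
    if circular:
        idx = (np.arange(position - half, position + half + 1)) % n
        vals = vec[idx]
        center = half
    else:
        lo, hi = max(0, position - half), min(n, position + half + 1)
        vals = vec[lo:hi]
        center = position - lo
    if exclude_center:
        vals = np.delete(vals, center)
    return float(np.median(vals))


def window_medians(
    vec: np.ndarray,
    window: int = 51,
    exclude_center: bool = False,
    circular: bool = False,
) -> np.ndarray:
    """Vectorised :func:`window_median` over every position of a count vector."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    n = len(vec)
    half = window // 2
    out = np.empty(n, dtype=float)
    if n == 0:
        return out
    if circular:
        padded = np.concatenate([vec[-half:], vec, vec[:half]]) if n > half else None
        if padded is None:  # tiny contig: fall back to modular gather
            for p in range(n):
                idx = (np.arange(p - half, p + half + 1)) % n
                vals = vec[idx]
                if exclude_center:
                    vals = np.delete(vals, half)
                out[p] = np.median(vals)
            return out
        windows = np.lib.stride_tricks.sliding_window_view(padded, window)
        if exclude_center:
            windows = np.delete(windows, half, axis=1)
        out[:] = np.median(windows, axis=1)
        return out
    # linear: interior via stride tricks, truncated edges individually
    if n >= window:
        windows = np.lib.stride_tricks.sliding_window_view(vec, window)
        if exclude_center:
            windows = np.delete(windows, half, axis=1)
        out[half : n - half] = np.median(windows, axis=1)
        edge_positions = list(range(half)) + list(range(n - half, n))
    else:
        edge_positions = list(range(n))
    for p in edge_positions:
        lo, hi = max(0, p - half), min(n, p + half + 1)
        vals = vec[lo:hi]
        if exclude_center:
            vals = np.delete(vals, p - lo)
        out[p] = np.median(vals)
    return out


def call_pauses(
    track: EndCountTrack,
    mask: MaskSet | None = None,
    min_fold: float = 20.0,
    min_cpm: float = 10.0,
    window: int = 51,
    median_floor: float = 1.0,
    exclude_center: bool = False,
    circular: bool = False,
) -> list[PauseSite]:
    """Call pause sites over the whole track by the dual threshold.

    A position is called iff ``count / max(window_median, median_floor) >=
    min_fold`` and ``count * 1e6 / total_reads >= min_cpm`` and the position
    is not masked.  Results are sorted by (contig, position, strand) and
    each site stores both the raw window median and the floored score.
    """
    if track.total_reads <= 0:
        logger.warning("empty track (total_reads == 0): no pauses callable")
        return []
    if median_floor <= 0:
        raise ValueError("median_floor must be > 0")
    cpm_factor = 1e6 / track.total_reads
    pauses: list[PauseSite] = []
    for contig in sorted(track.contig_lengths):
        length = track.contig_lengths[contig]
        masked = mask.mask_array(contig, length) if mask is not None else None
        for strand in STRANDS:
            vec = track.get(contig, strand)
            if not vec.any():
                continue
            med = window_medians(vec, window, exclude_center, circular)
            floored = np.maximum(med, median_floor)
            scores = vec / floored
            keep = (scores >= min_fold) & (vec * cpm_factor >= min_cpm)
            if masked is not None:
                keep &= ~masked
            for p in np.flatnonzero(keep):
                pauses.append(
                    PauseSite(
                        contig=contig,
                        position=int(p),
                        strand=strand,
                        count=int(vec[p]),
                        window_median=float(med[p]),
                        pause_score=float(scores[p]),
                        cpm=float(vec[p] * cpm_factor),
                    )
                )
    pauses.sort(key=lambda s: (s.contig, s.position, s.strand))
    return pauses
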