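"""Pause-set comparison, in vitro pause-strength arithmetic and group
summary statistics."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class OverlapResult:
    n_A_only: int
    n_B_only: int
    n_shared: int
    tolerance: int

    @property
    def fraction_A_shared(self) -> float:
        denom = self.n_shared + self.n_A_only
        return self.n_shared / denom if denom else 0.0

    @property
    def fraction_B_shared(self) -> float:
        denom = self.n_shared + self.n_B_only
        return self.n_shared / denom if denom else 0.0


def _keys(pauses) -> list[tuple[str, str, int]]:
    out = []
    for p in pauses:
        if hasattr(p, "contig"):
            out.append((p.contig, p.strand, p.position))
        else:  # bare (contig, position, strand) tuples are accepted too
            contig, position, strand = p
            out.append((contig, strand, position))
    out.sort()
    return out


def overlap_sets(A: Sequence, B: Sequence, tolerance: int = 0) -> OverlapResult:
    """Match pause sets by same-strand 3'-end coordinate within ±tolerance nt.

    Matching is greedy in position order and one-to-one: each B pause can
    absorb at most one A pause.  At tolerance 0 this reduces to exact
    coordinate intersection and is symmetric in the shared count.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    a_keys = _keys(A)
    b_keys = _keys(B)
    shared = 0
    j = 0
    used_b: set[int] = set()
    for contig, strand, pos in a_keys:
        # advance j past B entries that can no longer match anything in A
        while j < len(b_keys) and (
            b_keys[j][:2] < (contig, strand)
            or (b_keys[j][:2] == (contig, strand) and b_keys[j][2] < pos - tolerance)
        ):
            j += 1
        k = j
        while k < len(b_keys) and b_keys[k][:2] == (contig, strand) and b_keys[k][2] <= pos + tolerance:
            if k not in used_b:
                used_b.add(k)
                shared += 1
                break
            k += 1
    return OverlapResult(
        n_A_only=len(a_keys) - shared,
        n_B_only=len(b_keys) - shared,
        n_shared=shared,
        tolerance=tolerance,
    )


def pause_strength(intensity_paused: float, intensity_runoff: float) -> float:
    """paused / (paused + run-off) signal intensity, in [0, 1]."""
    if intensity_paused < 0 or intensity_runoff < 0:
        raise ValueError("intensities must be >= 0")
    total = intensity_paused + intensity_runoff
    if total == 0:
        raise ValueError("pause strength undefined: both intensities are zero")
    return intensity_paused / total


def relative_strength(ps: float, ps_reference: float) -> float:
    """Pause strength relative to a reference condition (reference -> 1)."""
    if ps_reference <= 0:
        raise ValueError("reference pause strength must be > 0")
    return ps / ps_reference


def group_summary(annotations: Sequence, value: str = "pause_score"):
    """Per-group score summaries and pairwise two-sided rank-sum tests.

    Returns ``(summary, tests)`` DataFrames.  The summary carries n, median,
    mean, quartiles and Tukey-style whiskers (most extreme data point within
    1.5 IQR of the box).  Groups with fewer than 2 values keep their
    quantiles but are skipped in testing, with a note.
    """
    import pandas as pd

    by_group: dict[str, list[float]] = {}
    for a in annotations:
        by_group.setdefault(a.group, []).append(float(getattr(a.pause, value)))
    rows = []
    for group in sorted(by_group):
        vals = np.sort(np.array(by_group[group]))
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        in_lo = vals[vals >= q1 - 1.5 * iqr]
        in_hi = vals[vals <= q3 + 1.5 * iqr]
        rows.append(
            {
                "group": group,
                "n": len(vals),
                "median": med,
                "mean": vals.mean(),
                "q1": q1,
                "q3": q3,
                "whisker_low": in_lo[0] if len(in_lo) else vals[0],
                "whisker_high": in_hi[-1] if len(in_hi) else vals[-1],
            }
        )
    summary = pd.DataFrame(rows)
    tests = []
    for g1, g2 in combinations(sorted(by_group), 2):
        x, y = by_group[g1], by_group[g2]
        if len(x) < 2 or len(y) < 2:
            tests.append(
                {"group_a": g1, "group_b": g2, "statistic": np.nan,
                 "p_value": np.nan, "note": "skipped: group with n < 2"}
            )
            continue
        method = "exact" if max(len(x), len(y)) <= 10 and _no_ties(x, y) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        tests.append(
            {"group_a": g1, "group_b": g2, "statistic": float(res.statistic),
             "p_value": float(res.pvalue), "note": method}
        )
    return summary, pd.DataFrame(tests)


def _no_ties(x, y) -> bool:
    pooled = list(x) + list(y)
    return len(set(pooled)) == len(pooled)
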