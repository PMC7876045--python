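"""Link pauses to TSSs, assign distance groups and feature categories.

Distance convention: d = pause 3'-end coordinate minus TSS coordinate on the
plus strand (mirrored on minus), so d = 0 means the pause 3' end sits on the
TSS base and positive d is downstream of the TSS.  Groups are inclusive
integer windows: G0 = [-2, 3], G1p = [10, 15], G1d = [16, 20], G2 = [31, 39];
everything else is "other".
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pause_calling import PauseSite
from .track_io import EndCountTrack, TssRecord

logger = logging.getLogger(__name__)

GROUPS = ("G0", "G1p", "G1d", "G2", "other")

GROUP_WINDOWS = {
    "G0": (-2, 3),
    "G1p": (10, 15),
    "G1d": (16, 20),
    "G2": (31, 39),
}

FEATURE_PRECEDENCE = ("rRNA", "tRNA", "ncRNA", "CDS", "UTR")

# GFF3 type aliases folded into the five same-strand categories
_TYPE_MAP = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "ncRNA": "ncRNA",
    "sRNA": "ncRNA",
    "antisense_RNA": "ncRNA",
    "tmRNA": "ncRNA",
    "RNase_P_RNA": "ncRNA",
    "SRP_RNA": "ncRNA",
    "CDS": "CDS",
    "five_prime_UTR": "UTR",
    "three_prime_UTR": "UTR",
    "UTR": "UTR",
}


@dataclass(frozen=True)
class GffFeature:
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    type: str
    attributes: str = ""


@dataclass(frozen=True)
class PauseAnnotation:
    pause: PauseSite
    tss_id: str | None
    distance: int | None
    group: str
    feature: str = "intergenic"


def classify_distance(distance: int | None) -> str:
    """Map a signed TSS distance to its group label (total over integers)."""
    if distance is None:
        return "other"
    for group, (lo, hi) in GROUP_WINDOWS.items():
        if lo <= distance <= hi:
            return group
    return "other"


class _TssIndex:
    """Sorted per-(contig, strand) TSS positions for nearest lookups."""

    def __init__(self, tss_list: Sequence[TssRecord]):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[TssRecord]]] = {}
        grouped: dict[tuple[str, str], list[TssRecord]] = {}
        for t in tss_list:
            grouped.setdefault((t.contig, t.strand), []).append(t)
        for key, recs in grouped.items():
            recs.sort(key=lambda r: r.position)
            self._by_key[key] = ([r.position for r in recs], recs)

    def candidates(self, contig: str, strand: str, position: int) -> list[TssRecord]:
        entry = self._by_key.get((contig, strand))
        if entry is None:
            return []
        positions, recs = entry
        i = bisect_left(positions, position)
        return [recs[j] for j in (i - 1, i, i + 1) if 0 <= j < len(recs)]


def signed_distance(pause_position: int, tss: TssRecord) -> int:
    if tss.strand == "+":
        return pause_position - tss.position
    return tss.position - pause_position


def nearest_tss(
    pause: PauseSite, tss_list: Sequence[TssRecord] | _TssIndex
) -> tuple[str | None, int | None]:
    """Nearest same-strand TSS and the signed distance to it.

    Ties in |distance| are broken toward the TSS upstream of the pause, i.e.
    the assignment with non-negative distance, since a pause is the product
    of transcription initiated upstream.
    """
    index = tss_list if isinstance(tss_list, _TssIndex) else _TssIndex(tss_list)
    best: tuple[int, int, int, str] | None = None
    for tss in index.candidates(pause.contig, pause.strand, pause.position):
        d = signed_distance(pause.position, tss)
        key = (abs(d), 0 if d >= 0 else 1, tss.position)
        if best is None or key < best[:3]:
            best = (*key, tss.id)
            best_d = d
    if best is None:
        return None, None
    return best[3], best_d


def annotate_pauses(
    pauses: Sequence[PauseSite],
    tss_list: Sequence[TssRecord],
    features: Sequence[GffFeature] = (),
) -> list[PauseAnnotation]:
    """Full annotation: nearest TSS, distance group and feature category."""
    index = _TssIndex(tss_list)
    findex = _FeatureIndex(features) if features else None
    out = []
    for p in pauses:
        tss_id, d = nearest_tss(p, index)
        feature = findex.category(p) if findex is not None else "intergenic"
        out.append(
            PauseAnnotation(
                pause=p,
                tss_id=tss_id,
                distance=d,
                group=classify_distance(d),
                feature=feature,
            )
        )
    return out


def strongest_per_tss(annotations: Iterable[PauseAnnotation]) -> list[PauseAnnotation]:
    """Keep, per TSS, only the annotation with the highest pause score.

    Ties go to the smaller |distance|, then the smaller coordinate.
    Annotations without a TSS link pass through untouched.
    """
    best: dict[str, PauseAnnotation] = {}
    unlinked: list[PauseAnnotation] = []
    for ann in annotations:
        if ann.tss_id is None:
            unlinked.append(ann)
            continue
        cur = best.get(ann.tss_id)
        if cur is None or _strength_key(ann) < _strength_key(cur):
            best[ann.tss_id] = ann
    kept = list(best.values()) + unlinked
    kept.sort(key=lambda a: (a.pause.contig, a.pause.position, a.pause.strand))
    return kept


def _strength_key(ann: PauseAnnotation) -> tuple:
    return (
        -ann.pause.pause_score,
        abs(ann.distance) if ann.distance is not None else np.inf,
        ann.pause.position,
    )


# ---------------------------------------------------------------------------
# feature categories


def load_features(path: str | Path) -> list[GffFeature]:
    """Parse GFF3 feature lines; unparseable lines are skipped with a warning."""
    path = Path(path)
    feats: list[GffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                logger.warning("%s:%d: not 9 GFF3 columns, skipped", path, lineno)
                continue
            contig, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
            try:
                start = int(start1) - 1  # GFF3 is 1-based inclusive
                end = int(end1)
            except ValueError:
                logger.warning("%s:%d: bad coordinates, skipped", path, lineno)
                continue
            if strand not in ("+", "-"):
                continue  # strandless features cannot take part in sense calls
            feats.append(GffFeature(contig, start, end, strand, ftype, attrs))
    return feats


class _FeatureIndex:
    def __init__(self, features: Sequence[GffFeature]):
        self._feats: dict[str, list[GffFeature]] = {}
        for f in features:
            cat = _TYPE_MAP.get(f.type)
            if cat is None:
                continue
            self._feats.setdefault(f.contig, []).append(replace(f, type=cat))
        for lst in self._feats.values():
            lst.sort(key=lambda f: f.start)

    def category(self, pause: PauseSite) -> str:
        return feature_category(pause, self._feats.get(pause.contig, ()))


def feature_category(pause: PauseSite, features: Sequence[GffFeature]) -> str:
    """Feature label for a pause 3' end.

    Same-strand overlap wins with precedence rRNA > tRNA > ncRNA > CDS > UTR;
    otherwise any opposite-strand overlap gives Antisense; otherwise
    intergenic.  ``features`` must already carry canonical type labels.
    """
    same: set[str] = set()
    opposite = False
    for f in features:
        if not (f.start <= pause.position < f.end) or f.contig != pause.contig:
            continue
        cat = _TYPE_MAP.get(f.type, f.type if f.type in FEATURE_PRECEDENCE else None)
        if cat is None:
            continue
        if f.strand == pause.strand:
            same.add(cat)
        else:
            opposite = True
    for cat in FEATURE_PRECEDENCE:
        if cat in same:
            return cat
    if opposite:
        return "Antisense"
    return "intergenic"


def derive_utrs(
    tss_list: Sequence[TssRecord],
    features: Sequence[GffFeature],
    max_span: int = 500,
) -> list[GffFeature]:
    """5' UTR intervals from each TSS to the nearest downstream same-strand
    CDS start within ``max_span`` nt; TSSs with no such CDS yield nothing."""
    cds = [f for f in features if f.type == "CDS"]
    utrs: list[GffFeature] = []
    for tss in tss_list:
        best: int | None = None
        for f in cds:
            if f.contig != tss.contig or f.strand != tss.strand:
                continue
            if tss.strand == "+":
                gap = f.start - tss.position
            else:
                gap = tss.position - (f.end - 1)
            if 0 < gap <= max_span and (best is None or gap < best):
                best = gap
        if best is None:
            continue
        if tss.strand == "+":
            utrs.append(GffFeature(tss.contig, tss.position, tss.position + best, "+", "UTR"))
        else:
            utrs.append(GffFeature(tss.contig, tss.position - best + 1, tss.position + 1, "-", "UTR"))
    return utrs


# ---------------------------------------------------------------------------
# TSS-anchored normalized region matrix


@dataclass
class RegionMatrix:
    """Per-TSS strand-oriented count lanes, self-normalized per row.

    ``sense`` rows lie in [0, 1] (max of each nonzero row is 1); ``antisense``
    rows lie in [-1, 0].  ``offsets`` is the TSS-relative position axis.
    """

    tss_ids: list[str]
    offsets: np.ndarray
    sense: np.ndarray
    antisense: np.ndarray


def region_matrix(
    track: EndCountTrack,
    tss_list: Sequence[TssRecord],
    window: tuple[int, int] = (-50, 200),
) -> RegionMatrix:
    """Build the normalized sense/antisense matrix around each TSS.

    Rows are oriented 5'->3' along the TSS strand.  Regions sharing the same
    (contig, position, strand) are collapsed to one row; rows that would run
    past a contig edge are dropped with a warning.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must satisfy lo < hi")
    offsets = np.arange(lo, hi + 1)
    width = len(offsets)
    rows_s, rows_a, ids = [], [], []
    seen: set[tuple[str, int, str]] = set()
    for tss in tss_list:
        key = (tss.contig, tss.position, tss.strand)
        if key in seen:
            continue
        seen.add(key)
        n = track.contig_lengths[tss.contig]
        if tss.strand == "+":
            gstart, gend = tss.position + lo, tss.position + hi + 1
        else:
            gstart, gend = tss.position - hi, tss.position - lo + 1
        if gstart < 0 or gend > n:
            logger.warning("TSS %s: region outside contig, row dropped", tss.id)
            continue
        sense_vec = track.get(tss.contig, tss.strand)[gstart:gend].astype(float)
        anti_strand = "-" if tss.strand == "+" else "+"
        anti_vec = track.get(tss.contig, anti_strand)[gstart:gend].astype(float)
        if tss.strand == "-":
            sense_vec = sense_vec[::-1]
            anti_vec = anti_vec[::-1]
        smax, amax = sense_vec.max(), anti_vec.max()
        rows_s.append(sense_vec / smax if smax > 0 else sense_vec)
        rows_a.append(-(anti_vec / amax) if amax > 0 else anti_vec)
        ids.append(tss.id)
    sense = np.vstack(rows_s) if rows_s else np.empty((0, width))
    anti = np.vstack(rows_a) if rows_a else np.empty((0, width))
    return RegionMatrix(tss_ids=ids, offsets=offsets, sense=sense, antisense=anti)


def annotations_to_frame(annotations: Sequence[PauseAnnotation]):
    """Flatten annotations into a pandas DataFrame for TSV export."""
    import pandas as pd

    rows = []
    for a in annotations:
        rows.append(
            {
                "contig": a.pause.contig,
                "position": a.pause.position,
                "strand": a.pause.strand,
                "count": a.pause.count,
                "window_median": a.pause.window_median,
                "pause_score": a.pause.pause_score,
                "cpm": a.pause.cpm,
                "tss_id": a.tss_id if a.tss_id is not None else "",
                "distance": a.distance if a.distance is not None else "",
                "group": a.group,
                "feature": a.feature,
            }
        )
    return pd.DataFrame(rows)
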