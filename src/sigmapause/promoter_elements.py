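"""Individual-information model of the -10 promoter hexamer and element
annotation around TSSs.

The model follows the individual-information formulation: per-position base
frequencies f(b, l) with pseudocount, per-position weights
w(b, l) = 2 + log2 f(b, l) in bits, Ri(s) = sum_l w(s_l, l), and
Rsequence = sum_l sum_b f(b, l) * w(b, l) (the training-set mean Ri at zero
pseudocount).  An Ri above 0 bits marks a recognizable site.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .track_io import TssRecord, revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_YRY_RE = re.compile(r"^[CT][AG][CT]$")

DEFAULT_SPACER_RANGE = range(3, 10)  # nt strictly between -10 hexamer and TSS


@dataclass(frozen=True)
class RiModel:
    """Per-position frequency/weight model of an aligned element."""

    freqs: np.ndarray  # (4, width), rows in ACGT order
    weights: np.ndarray  # (4, width), bits; -inf where f == 0
    rsequence: float  # bits
    n_train: int
    pseudocount: float

    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.freqs, axis=0))


def build_ri_model(
    aligned_seqs: Sequence[str], pseudocount: float = 0.25
) -> RiModel:
    """Fit the model from equal-length aligned training sequences.

    f(b, l) = (n(b, l) + pc) / (N + 4 pc).  Ambiguous bases are rejected with
    a position report.  ``pseudocount=0`` is permitted (weights of unseen
    bases become -inf and contribute nothing to Rsequence).
    """
    if len(aligned_seqs) < 2:
        raise ValueError("need at least 2 training sequences")
    width = len(aligned_seqs[0])
    counts = np.zeros((4, width), dtype=float)
    for i, seq in enumerate(aligned_seqs):
        seq = seq.upper()
        if len(seq) != width:
            raise ValueError(
                f"sequence {i} has length {len(seq)}, expected {width}"
            )
        for l, base in enumerate(seq):
            j = _BASE_INDEX.get(base)
            if j is None:
                raise ValueError(
                    f"ambiguous base {base!r} in sequence {i} at position {l}"
                )
            counts[j, l] += 1
    n = len(aligned_seqs)
    freqs = (counts + pseudocount) / (n + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        weights = 2.0 + np.log2(freqs)
    contrib = np.where(freqs > 0, freqs * np.where(np.isfinite(weights), weights, 0.0), 0.0)
    rsequence = float(contrib.sum())
    return RiModel(
        freqs=freqs,
        weights=weights,
        rsequence=rsequence,
        n_train=n,
        pseudocount=pseudocount,
    )


def ri_score(model: RiModel, sequence: str) -> float:
    """Individual information (bits) of ``sequence`` under ``model``."""
    sequence = sequence.upper()
    if len(sequence) != model.width:
        raise ValueError(
            f"sequence length {len(sequence)} != model width {model.width}"
        )
    total = 0.0
    for l, base in enumerate(sequence):
        j = _BASE_INDEX.get(base)
        if j is None:
            raise ValueError(f"ambiguous base {base!r} at position {l}")
        total += model.weights[j, l]
    return float(total)


# ---------------------------------------------------------------------------
# TSS-oriented sequence access


def oriented_slice(
    genome: Mapping[str, str], tss: TssRecord, lo: int, hi: int
) -> str | None:
    """Bases at TSS-relative oriented offsets lo..hi inclusive (0 = TSS base,
    positive downstream along the TSS strand).  None when out of bounds."""
    seq = genome[tss.contig]
    if tss.strand == "+":
        a, b = tss.position + lo, tss.position + hi + 1
        if a < 0 or b > len(seq):
            return None
        return seq[a:b].upper()
    a, b = tss.position - hi, tss.position - lo + 1
    if a < 0 or b > len(seq):
        return None
    return revcomp(seq[a:b].upper())


def _oriented_to_forward_start(tss: TssRecord, offset: int, width: int) -> int:
    """Forward-strand genomic start of a width-nt element whose oriented
    5'-most base sits at TSS-relative ``offset``."""
    if tss.strand == "+":
        return tss.position + offset
    return tss.position - offset - (width - 1)


@dataclass(frozen=True)
class ElementHit:
    start: int  # forward-strand genomic start
    sequence: str  # oriented (TSS-strand) sequence
    ri: float  # bits
    offset: int  # oriented offset of the element's 5'-most base from the TSS


@dataclass(frozen=True)
class PromoterElements:
    tss_id: str
    minus10: ElementHit | None
    spacer: int | None  # nt strictly between -10 hexamer 3' base and TSS
    tssr: str | None  # triplet at TSS-1..TSS+1
    is_yry: bool | None
    minus10_like: ElementHit | None


def find_minus10R(
    model: RiModel,
    genome: Mapping[str, str],
    tss: TssRecord,
    spacer_range: range = DEFAULT_SPACER_RANGE,
) -> tuple[ElementHit, int] | None:
    """Best-scoring upstream hexamer over the allowed spacer lengths.

    The spacer counts the bases strictly between the hexamer's 3' base and
    the TSS base.  Ri ties are resolved toward spacer 6, then 7, then the
    shortest remaining spacer.
    """
    width = model.width
    preference = [s for s in (6, 7) if s in spacer_range] + sorted(
        s for s in spacer_range if s not in (6, 7)
    )
    best: tuple[ElementHit, int] | None = None
    for spacer in preference:
        offset = -(spacer + width)  # oriented 5'-most base of the hexamer
        seq = oriented_slice(genome, tss, offset, offset + width - 1)
        if seq is None:
            logger.warning(
                "TSS %s: spacer %d window extends past contig start", tss.id, spacer
            )
            continue
        ri = ri_score(model, seq)
        if best is None or ri > best[0].ri:
            hit = ElementHit(
                start=_oriented_to_forward_start(tss, offset, width),
                sequence=seq,
                ri=ri,
                offset=offset,
            )
            best = (hit, spacer)
    return best


def classify_tssR(genome: Mapping[str, str], tss: TssRecord) -> tuple[str, bool] | None:
    """Triplet at TSS-1..TSS+1 on the TSS strand and its YRY flag.

    YRY = pyrimidine, purine (the TSS base), pyrimidine.  None at a contig
    edge.
    """
    triplet = oriented_slice(genome, tss, -1, 1)
    if triplet is None:
        return None
    return triplet, bool(_YRY_RE.match(triplet))


def scan_minus10LR(
    model: RiModel,
    genome: Mapping[str, str],
    tss: TssRecord,
    anchor_range: Sequence[int] = (-1, 0, 1, 2),
    anchor: str = "second_base",
) -> ElementHit | None:
    """Best -10-like hexamer in the initial transcribed region.

    With ``anchor='second_base'`` the hexamer's second base is placed at each
    TSS-relative offset in ``anchor_range`` (TSS = offset 0); with
    ``anchor='start'`` the first base is anchored instead.  The maximal-Ri
    placement is returned even when its Ri <= 0 (callers treat Ri <= 0 as a
    weak/absent site); ties go to the leftmost anchor.
    """
    if anchor not in ("second_base", "start"):
        raise ValueError(f"unknown anchor mode {anchor!r}")
    width = model.width
    shift = 1 if anchor == "second_base" else 0
    best: ElementHit | None = None
    for a in sorted(anchor_range):
        offset = a - shift
        seq = oriented_slice(genome, tss, offset, offset + width - 1)
        if seq is None:
            continue
        ri = ri_score(model, seq)
        if best is None or ri > best.ri:
            best = ElementHit(
                start=_oriented_to_forward_start(tss, offset, width),
                sequence=seq,
                ri=ri,
                offset=offset,
            )
    if best is None:
        logger.warning("TSS %s: insufficient sequence for -10-like scan", tss.id)
    return best


def annotate_promoter(
    model: RiModel,
    genome: Mapping[str, str],
    tss: TssRecord,
    spacer_range: range = DEFAULT_SPACER_RANGE,
) -> PromoterElements:
    """All promoter determinants for one TSS in a single record."""
    m10 = find_minus10R(model, genome, tss, spacer_range)
    tssr = classify_tssR(genome, tss)
    m10lr = scan_minus10LR(model, genome, tss)
    return PromoterElements(
        tss_id=tss.id,
        minus10=m10[0] if m10 else None,
        spacer=m10[1] if m10 else None,
        tssr=tssr[0] if tssr else None,
        is_yry=tssr[1] if tssr else None,
        minus10_like=m10lr,
    )


def spacer_ri_table(
    promoters: Sequence[PromoterElements],
    ri_bin_edges: Sequence[float] | None = None,
):
    """Joint (spacer length x Ri bin) count matrix with marginals.

    Returns ``(counts, spacer_marginal, ri_marginal)`` as pandas objects;
    rows are spacer lengths, columns Ri-bin interval labels.  Promoters
    lacking a located -10 hexamer are ignored.
    """
    import pandas as pd

    rows = [
        (p.spacer, p.minus10.ri)
        for p in promoters
        if p.minus10 is not None and p.spacer is not None
    ]
    if not rows:
        empty = pd.DataFrame()
        return empty, pd.Series(dtype=int), pd.Series(dtype=int)
    spacers = np.array([r[0] for r in rows])
    ris = np.array([r[1] for r in rows])
    if ri_bin_edges is None:
        lo = np.floor(ris.min())
        hi = np.ceil(ris.max()) + 1e-9
        ri_bin_edges = np.arange(lo, hi + 2.0, 2.0)
    ri_bin_edges = np.asarray(ri_bin_edges, dtype=float)
    span = np.arange(spacers.min(), spacers.max() + 1)
    labels = [
        f"[{ri_bin_edges[i]:g},{ri_bin_edges[i + 1]:g})"
        for i in range(len(ri_bin_edges) - 1)
    ]
    counts = pd.DataFrame(0, index=span, columns=labels, dtype=int)
    bin_idx = np.clip(
        np.digitize(ris, ri_bin_edges) - 1, 0, len(ri_bin_edges) - 2
    )
    for s, b in zip(spacers, bin_idx):
        counts.loc[s, labels[b]] += 1
    return counts, counts.sum(axis=1), counts.sum(axis=0)


def info_profile(aligned_seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-position information (logo column heights) of an alignment.

    Returns ``(info, heights)`` where ``info[l] = 2 - H(l)`` bits with
    H(l) the Shannon entropy of the base frequencies at position l, and
    ``heights[b, l] = f(b, l) * info[l]`` (rows in ACGT order).
    """
    model = build_ri_model(aligned_seqs, pseudocount=0.0)
    f = model.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -plogp.sum(axis=0)
    info = 2.0 - entropy
    return info, f * info[np.newaxis, :]
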