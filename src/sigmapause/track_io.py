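"""I/O for reads, count tracks, TSS tables, masks and pause tables.

All internal coordinates are 0-based half-open.  BED input is taken at face
value (BED is natively 0-based half-open); the 3-column TSV TSS dialect is
1-based and converted on load.  The RNA 3' end of an aligned read is the
last transcribed base: ``end - 1`` on the plus strand, ``start`` on the
minus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _norm_strand(s: str) -> str:
    # tolerate the unicode minus that sneaks in via copy/paste
    if s in ("-", "−"):
        return "-"
    if s == "+":
        return "+"
    raise ValueError(f"invalid strand {s!r}")


@dataclass(frozen=True)
class ReadRecord:
    """One aligned nascent-RNA fragment as a BED6-style interval."""

    contig: str
    start: int
    end: int
    strand: str
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"read {self.name}: end {self.end} <= start {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"read {self.name}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the RNA 3' end (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class TssRecord:
    contig: str
    position: int
    strand: str
    id: str


@dataclass
class EndCountTrack:
    """Strand-specific per-position counts of read 3' ends.

    ``counts[(contig, strand)]`` is an integer vector of length
    ``contig_lengths[contig]``.  ``total_reads`` is the library size used
    for counts-per-million normalisation.
    """

    contig_lengths: dict[str, int]
    counts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    total_reads: int = 0

    def __post_init__(self) -> None:
        for contig, length in self.contig_lengths.items():
            for strand in STRANDS:
                key = (contig, strand)
                if key not in self.counts:
                    self.counts[key] = np.zeros(length, dtype=np.int64)
                elif len(self.counts[key]) != length:
                    raise ValueError(
                        f"track length {len(self.counts[key])} != contig length "
                        f"{length} for {contig}{strand}"
                    )

    def get(self, contig: str, strand: str) -> np.ndarray:
        return self.counts[(contig, strand)]


class MaskSet:
    """Strandless exclusion intervals (rRNA/tRNA/repeats), merged and sorted."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._ivals: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for contig, ivs in intervals.items():
                self._ivals[contig] = _merge_intervals(ivs)

    def intervals(self, contig: str) -> list[tuple[int, int]]:
        return list(self._ivals.get(contig, []))

    def contains(self, contig: str, position: int) -> bool:
        for s, e in self._ivals.get(contig, []):
            if s <= position < e:
                return True
            if s > position:
                break
        return False

    def mask_array(self, contig: str, length: int) -> np.ndarray:
        """Boolean vector, True at excluded positions."""
        out = np.zeros(length, dtype=bool)
        for s, e in self._ivals.get(contig, []):
            out[max(s, 0) : min(e, length)] = True
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivals.values())


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"degenerate interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# loaders


def load_reads(path: str | Path) -> list[ReadRecord]:
    """Parse a BED6 file of aligned reads.

    Malformed lines (end <= start) are rejected individually and logged with
    their line number; a missing strand column rejects the whole file.
    """
    path = Path(path)
    reads: list[ReadRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated BED columns, "
                    f"got {len(fields)} (strand column required)"
                )
            contig, start, end, name, _score, strand = fields[:6]
            strand = _norm_strand(strand)
            start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                logger.warning("%s:%d: end <= start, line rejected", path, lineno)
                continue
            reads.append(ReadRecord(contig, start_i, end_i, strand, name))
    if not reads:
        logger.warning("%s: no reads loaded", path)
    return reads


def build_track(
    reads: Sequence[ReadRecord], contig_lengths: Mapping[str, int]
) -> EndCountTrack:
    """Tally read 3' ends into a strand-specific count track."""
    track = EndCountTrack(contig_lengths=dict(contig_lengths))
    for read in reads:
        if read.contig not in contig_lengths:
            raise ValueError(f"read {read.name}: unknown contig {read.contig}")
        if read.end > contig_lengths[read.contig] or read.start < 0:
            raise ValueError(
                f"read {read.name} [{read.start},{read.end}) outside contig "
                f"{read.contig} (length {contig_lengths[read.contig]})"
            )
        track.counts[(read.contig, read.strand)][read.three_prime_end] += 1
    track.total_reads = len(reads)
    return track


def load_tss(path: str | Path, dialect: str = "auto") -> list[TssRecord]:
    """Load TSS records from BED6 (0-based) or 3/4-column TSV (1-based).

    ``dialect`` is one of ``bed``, ``tsv`` or ``auto``; auto resolves only by
    file extension (.bed vs .tsv/.txt) and otherwise raises — the two
    dialects differ by one base and must never be guessed from content.
    """
    path = Path(path)
    if dialect == "auto":
        suffix = path.suffix.lower()
        if suffix == ".bed":
            dialect = "bed"
        elif suffix in (".tsv", ".txt"):
            dialect = "tsv"
        else:
            raise ValueError(
                f"cannot infer TSS dialect from extension {suffix!r}; "
                "pass dialect='bed' or dialect='tsv'"
            )
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown TSS dialect {dialect!r}")

    records: list[TssRecord] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
                contig, start, _end, name, _score, strand = fields[:6]
                position = int(start)
                tss_id = name if name != "." else f"tss_{lineno}"
            else:
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: TSV TSS requires chrom, position, strand"
                    )
                contig, pos1, strand = fields[:3]
                position = int(pos1) - 1  # declared 1-based
                tss_id = fields[3] if len(fields) > 3 else f"tss_{lineno}"
            if tss_id in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate TSS id {tss_id!r}")
            seen_ids.add(tss_id)
            records.append(TssRecord(contig, position, _norm_strand(strand), tss_id))
    return records


def load_mask(path: str | Path) -> MaskSet:
    """Load BED intervals (>= 3 columns) into a merged strandless mask."""
    path = Path(path)
    by_contig: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: mask BED requires >= 3 columns")
            by_contig.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return MaskSet(by_contig)


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA genome into an uppercase {contig: sequence} dict."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# pause table I/O

PAUSE_COLUMNS = ("contig", "position", "strand", "count", "window_median", "pause_score", "cpm")


def write_pauses(pauses: Sequence, path: str | Path) -> None:
    """Write pause sites as a TSV table plus a companion BED6 file.

    The BED file (same stem, ``.bed`` suffix) holds the single-base 3'-end
    interval [p, p+1) with the pause score in the score column.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(PAUSE_COLUMNS) + "\n")
        for p in pauses:
            fh.write(
                f"{p.contig}\t{p.position}\t{p.strand}\t{p.count}\t"
                f"{p.window_median:.6g}\t{p.pause_score:.6g}\t{p.cpm:.6g}\n"
            )
    bed_path = path.with_suffix(".bed")
    with open(bed_path, "w") as fh:
        for i, p in enumerate(pauses):
            fh.write(
                f"{p.contig}\t{p.position}\t{p.position + 1}\tpause_{i + 1}\t"
                f"{p.pause_score:.6g}\t{p.strand}\n"
            )


def load_pauses(path: str | Path) -> list:
    """Re-read a pause TSV written by :func:`write_pauses`."""
    from .pause_calling import PauseSite  # deferred: avoids import cycle

    path = Path(path)
    pauses = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in PAUSE_COLUMNS if c not in idx]
        if missing:
            raise ValueError(f"{path}: missing pause columns {missing}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            pauses.append(
                PauseSite(
                    contig=f[idx["contig"]],
                    position=int(f[idx["position"]]),
                    strand=_norm_strand(f[idx["strand"]]),
                    count=int(f[idx["count"]]),
                    window_median=float(f[idx["window_median"]]),
                    pause_score=float(f[idx["pause_score"]]),
                    cpm=float(f[idx["cpm"]]),
                )
            )
    return pauses


def write_bedgraph(track: EndCountTrack, path_prefix: str | Path) -> tuple[Path, Path]:
    """Emit per-strand bedGraph files (<prefix>.plus.bedgraph / .minus.bedgraph)."""
    prefix = Path(path_prefix)
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        out = prefix.parent / f"{prefix.name}.{tag}.bedgraph"
        with open(out, "w") as fh:
            for contig in sorted(track.contig_lengths):
                vec = track.get(contig, strand)
                nz = np.flatnonzero(vec)
                for pos in nz:
                    fh.write(f"{contig}\t{pos}\t{pos + 1}\t{vec[pos]}\n")
        paths.append(out)
    return tuple(paths)
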