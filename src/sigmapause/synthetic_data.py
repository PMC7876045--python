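"""Synthetic genomes, promoters and nascent-read datasets with ground truth.

The generator plants the promoter architecture the analysis stages look for:
a -10 hexamer (consensus TATAAT at strength 1) upstream of each TSS behind a
configurable spacer, a YRY triplet at strong proximal-pause promoters, a
secondary -10-like hexamer in the initial transcribed region of distal-pause
promoters (default geometry ~11 nt downstream of the -10 start), and a pause
spike of a configurable fold over the local background.  Background 3'-end
counts are Poisson; the spike is deterministic (round(fold * rate)) so that
threshold behaviour in tests is exact.

All randomness flows from ``numpy.random.default_rng``; the draw order is
fixed (genome bases, promoter placement, element sampling, then read counts
and lengths position by position) so a seed pins the whole dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .track_io import ReadRecord, TssRecord, revcomp, write_genome

CONSENSUS_MINUS10 = "TATAAT"

PYRIMIDINES = "CT"
PURINES = "AG"

CLASSES = ("none", "G1p", "G1d")

# pause-offset windows the planted classes are drawn from (inclusive)
CLASS_OFFSETS = {"G1p": (10, 15), "G1d": (16, 20)}


@dataclass
class SimConfig:
    seed: int = 0
    contig: str = "chrSim"
    genome_length: int = 80_000
    gc_content: float = 0.5
    n_promoters: dict[str, int] = field(
        default_factory=lambda: {"none": 20, "G1p": 20, "G1d": 20}
    )
    background_rate: float = 2.0  # mean 3' ends per transcribed position
    intergenic_rate: float = 0.02
    transcribed_span: int = 150  # nt downstream of each TSS
    fold: float = 30.0  # spike multiplier over the transcribed rate
    spacer_choices: tuple[int, ...] = (6, 7)
    minus10_strength: float = 1.0  # per-base consensus probability
    g1d_backtracked_mass: float = 0.3  # P(length > 18) at G1d promoters
    min_separation: int = 620  # promoters non-overlapping within +/- 300 nt

    def validate(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.min_separation < 600:
            raise ValueError("min_separation must keep promoters >= 600 nt apart")
        if not 0 <= self.g1d_backtracked_mass <= 1:
            raise ValueError("g1d_backtracked_mass must be in [0, 1]")
        unknown = set(self.n_promoters) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown promoter classes {sorted(unknown)}")

    @property
    def n_total_promoters(self) -> int:
        return sum(self.n_promoters.values())

    def expected_total_reads(self) -> float:
        """Closed-form expectation of the generated read count."""
        n_spikes = sum(n for c, n in self.n_promoters.items() if c != "none")
        n_span = self.n_total_promoters * self.transcribed_span
        spike = round(self.fold * self.background_rate)
        return (
            2 * self.genome_length * self.intergenic_rate
            - n_span * self.intergenic_rate
            + (n_span - n_spikes) * self.background_rate
            + n_spikes * spike
        )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SimConfig":
        kwargs = dict(data)
        if "n_promoters" in kwargs:
            kwargs["n_promoters"] = {k: int(v) for k, v in kwargs["n_promoters"].items()}
        if "spacer_choices" in kwargs:
            kwargs["spacer_choices"] = tuple(kwargs["spacer_choices"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class PromoterTruth:
    tss: TssRecord
    cls: str  # none | G1p | G1d
    spacer: int
    minus10_start: int  # forward-strand genomic start of planted hexamer
    minus10_seq: str  # oriented sequence
    tssr: str
    minus10lr_offset: int | None  # oriented start offset of planted -10LR
    minus10lr_seq: str | None
    pause_offset: int | None  # oriented distance of pause 3' end from TSS
    pause_position: int | None  # genomic coordinate of planted pause
    fold: float
    expected_count: int | None  # deterministic spike height


# ---------------------------------------------------------------------------
# genome generation


def _sample_hexamer(rng: np.random.Generator, strength: float) -> str:
    out = []
    for base in CONSENSUS_MINUS10:
        if rng.random() < strength:
            out.append(base)
        else:
            out.append("ACGT"[rng.integers(4)])
    return "".join(out)


def _write_oriented(seq: list[str], tss_pos: int, strand: str, offset: int, s: str) -> None:
    """Write oriented sequence ``s`` starting at TSS-relative ``offset``."""
    for i, ch in enumerate(s):
        o = offset + i
        if strand == "+":
            seq[tss_pos + o] = ch
        else:
            seq[tss_pos - o] = revcomp(ch)


def _read_oriented(seq: list[str], tss_pos: int, strand: str, lo: int, hi: int) -> str:
    if strand == "+":
        return "".join(seq[tss_pos + lo : tss_pos + hi + 1])
    return revcomp("".join(seq[tss_pos - hi : tss_pos - lo + 1]))


def generate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[PromoterTruth]]:
    """Random genome with planted promoter architecture plus its truth table.

    Raises before producing any output if the requested promoters cannot be
    placed at the configured separation.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.genome_length
    n_total = config.n_total_promoters
    margin = max(config.transcribed_span + 60, 300)
    usable = L - 2 * margin
    if n_total == 0:
        raise ValueError("no promoters configured")
    spacing = usable // n_total
    if spacing < config.min_separation or usable <= 0:
        raise ValueError(
            f"{n_total} promoters do not fit a {L}-nt genome at "
            f">= {config.min_separation} nt separation"
        )

    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list("".join(rng.choice(list("ACGT"), size=L, p=probs)))

    classes = [c for c in CLASSES for _ in range(config.n_promoters.get(c, 0))]
    classes = [classes[i] for i in rng.permutation(n_total)]

    jitter_room = max(1, spacing - config.min_separation)
    truths: list[PromoterTruth] = []
    for i, cls in enumerate(classes):
        tss_pos = margin + i * spacing + int(rng.integers(0, jitter_room))
        strand = "+" if rng.random() < 0.5 else "-"
        spacer = int(rng.choice(config.spacer_choices))

        minus10 = _sample_hexamer(rng, config.minus10_strength)
        m10_offset = -(spacer + 6)
        _write_oriented(seq, tss_pos, strand, m10_offset, minus10)

        if cls == "G1p":
            triplet = (
                PYRIMIDINES[rng.integers(2)]
                + PURINES[rng.integers(2)]
                + PYRIMIDINES[rng.integers(2)]
            )
            _write_oriented(seq, tss_pos, strand, -1, triplet)

        minus10lr_offset = minus10lr_seq = None
        if cls == "G1d":
            # default geometry: -10LR start ~11 nt downstream of the -10R
            # start, clamped so its second base stays in the -1..+2 scan
            minus10lr_offset = int(np.clip(m10_offset + 11, -2, 1))
            minus10lr_seq = _sample_hexamer(rng, config.minus10_strength)
            _write_oriented(seq, tss_pos, strand, minus10lr_offset, minus10lr_seq)

        pause_offset = pause_position = expected = None
        if cls in CLASS_OFFSETS:
            lo, hi = CLASS_OFFSETS[cls]
            pause_offset = int(rng.integers(lo, hi + 1))
            pause_position = tss_pos + pause_offset if strand == "+" else tss_pos - pause_offset
            expected = round(config.fold * config.background_rate)

        tss = TssRecord(config.contig, tss_pos, strand, f"p{i + 1:04d}")
        truths.append(
            PromoterTruth(
                tss=tss,
                cls=cls,
                spacer=spacer,
                minus10_start=(
                    tss_pos + m10_offset if strand == "+" else tss_pos - m10_offset - 5
                ),
                minus10_seq=_read_oriented(seq, tss_pos, strand, m10_offset, m10_offset + 5),
                tssr=_read_oriented(seq, tss_pos, strand, -1, 1),
                minus10lr_offset=minus10lr_offset,
                minus10lr_seq=(
                    _read_oriented(seq, tss_pos, strand, minus10lr_offset, minus10lr_offset + 5)
                    if minus10lr_offset is not None
                    else None
                ),
                pause_offset=pause_offset,
                pause_position=pause_position,
                fold=config.fold,
                expected_count=expected,
            )
        )
    return {config.contig: "".join(seq)}, truths


# ---------------------------------------------------------------------------
# read simulation

_NONE_LENGTHS = (16, 17, 18)
_NONE_PROBS = (0.25, 0.5, 0.25)


def _g1d_length_probs(backtracked_mass: float) -> tuple[tuple[int, ...], tuple[float, ...]]:
    m = backtracked_mass
    return (16, 17, 18, 19, 20), ((1 - m) / 3,) * 3 + (m / 2, m / 2)


def sample_lengths(
    cls: str, n: int, rng: np.random.Generator, config: SimConfig
) -> np.ndarray:
    """Draw ``n`` protected-fragment lengths from the class mixture."""
    if cls == "G1p":
        return rng.integers(10, 16, size=n)
    if cls == "G1d":
        lengths, probs = _g1d_length_probs(config.g1d_backtracked_mass)
        return rng.choice(lengths, size=n, p=probs)
    return rng.choice(_NONE_LENGTHS, size=n, p=_NONE_PROBS)


def simulate_reads(
    genome: Mapping[str, str],
    truth: Sequence[PromoterTruth],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadRecord]:
    """Strand-specific nascent reads: Poisson background plus planted spikes.

    Transcribed positions (TSS through TSS + span - 1, oriented) draw
    Poisson(background_rate) 3'-end counts, everything else
    Poisson(intergenic_rate); the planted pause position is set to
    round(fold * background_rate) exactly.  Read lengths come from the
    owning promoter's class mixture, 5' ends are truncated at the TSS for
    promoter reads, and intergenic read lengths are clamped to the contig.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    contig = config.contig
    seq = genome[contig]
    L = len(seq)
    counts = {"+": rng.poisson(config.intergenic_rate, L), "-": rng.poisson(config.intergenic_rate, L)}
    owner = {"+": np.full(L, -1, dtype=np.int64), "-": np.full(L, -1, dtype=np.int64)}

    for idx, t in enumerate(truth):
        span_counts = rng.poisson(config.background_rate, config.transcribed_span)
        pos = t.tss.position
        strand = t.tss.strand
        if strand == "+":
            sl = slice(pos, pos + config.transcribed_span)
            counts[strand][sl] = span_counts
            owner[strand][sl] = idx
        else:
            sl = slice(pos - config.transcribed_span + 1, pos + 1)
            counts[strand][sl] = span_counts[::-1]
            owner[strand][sl] = idx
        if t.pause_position is not None:
            counts[strand][t.pause_position] = round(config.fold * config.background_rate)

    reads: list[ReadRecord] = []
    serial = 0
    for strand in ("+", "-"):
        vec = counts[strand]
        own = owner[strand]
        for p in np.flatnonzero(vec):
            c = int(vec[p])
            idx = int(own[p])
            if idx >= 0:
                t = truth[idx]
                lengths = sample_lengths(t.cls, c, rng, config)
                # truncate the 5' end at the TSS
                dist = p - t.tss.position if strand == "+" else t.tss.position - p
                lengths = np.minimum(lengths, dist + 1)
            else:
                lengths = sample_lengths("none", c, rng, config)
            max_len = p + 1 if strand == "+" else L - p
            lengths = np.minimum(lengths, max_len)
            for length in lengths:
                length = int(length)
                serial += 1
                if strand == "+":
                    reads.append(ReadRecord(contig, p + 1 - length, p + 1, "+", f"r{serial}"))
                else:
                    reads.append(ReadRecord(contig, p, p + length, "-", f"r{serial}"))
    if not reads:
        raise ValueError("simulation produced zero reads")
    return reads


def simulate_dataset(
    config: SimConfig,
) -> tuple[dict[str, str], list[PromoterTruth], list[ReadRecord]]:
    """Genome, truth and reads from one seeded generator (fixed draw order)."""
    rng = np.random.default_rng(config.seed)
    genome, truth = generate_genome(config, rng)
    reads = simulate_reads(genome, truth, config, rng)
    return genome, truth, reads


# ---------------------------------------------------------------------------
# on-disk dataset for the CLI


def write_dataset(
    outdir: str | Path,
    genome: Mapping[str, str],
    truth: Sequence[PromoterTruth],
    reads: Sequence[ReadRecord],
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(genome, outdir / "genome.fa")
    with open(outdir / "reads.bed", "w") as fh:
        for r in reads:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")
    with open(outdir / "tss.bed", "w") as fh:
        for t in truth:
            fh.write(
                f"{t.tss.contig}\t{t.tss.position}\t{t.tss.position + 1}\t"
                f"{t.tss.id}\t0\t{t.tss.strand}\n"
            )
    (outdir / "mask.bed").write_text("")  # no masked regions by default
    cols = (
        "tss_id\tcontig\ttss_position\tstrand\tclass\tspacer\tminus10_start\t"
        "minus10_seq\ttssr\tminus10lr_offset\tminus10lr_seq\tpause_offset\t"
        "pause_position\tfold\texpected_count\n"
    )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(cols)
        for t in truth:
            fh.write(
                f"{t.tss.id}\t{t.tss.contig}\t{t.tss.position}\t{t.tss.strand}\t"
                f"{t.cls}\t{t.spacer}\t{t.minus10_start}\t{t.minus10_seq}\t{t.tssr}\t"
                f"{'' if t.minus10lr_offset is None else t.minus10lr_offset}\t"
                f"{t.minus10lr_seq or ''}\t"
                f"{'' if t.pause_offset is None else t.pause_offset}\t"
                f"{'' if t.pause_position is None else t.pause_position}\t"
                f"{t.fold:g}\t{'' if t.expected_count is None else t.expected_count}\n"
            )
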