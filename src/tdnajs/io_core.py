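"""Readers and writers for the external formats plus shared conventions.

All coordinates are 0-based half-open internally.  BED and bedGraph are
native; GFF3 is converted (1-based inclusive) at the boundary.  Every
tabular writer emits a ``#`` header comment carrying the tool version and,
when known, the seed, so any output file records its provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__version__ = "0.1.0"

TRACK_BIN = 50          # epigenetic tracks are binned every 50 bp
MASK_BIN = 400          # T0 hotspot mask bin width, bp
MOTIF_BIN = 400         # motif foreground/background bin width, bp
PROFILE_FLANK = 500     # metaprofile half-window, bp

log = logging.getLogger("tdnajs")
if not log.handlers:  # library default: stderr, overridable by applications
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _header_comment(seed: int | None = None) -> str:
    tail = "" if seed is None else f" seed={seed}"
    return f"# tdnajs v{__version__}{tail}\n"


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalRecord:
    """A genomic interval, 0-based half-open, with a class label."""

    chrom: str
    start: int
    end: int
    label: str
    strand: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )


class GenomeAssembly:
    """Named chromosome sequences over {A,C,G,T} (N tolerated on input)."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("no records")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate chromosome name: {name}")
            up = seq.upper()
            bad = set(up) - set("ACGTN")
            if bad:
                pos = next(i for i, c in enumerate(up) if c in bad)
                raise ValueError(
                    f"chromosome {name}: invalid symbol {up[pos]!r} at position {pos}"
                )
            self.sequences[name] = up

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chroms(self) -> list[str]:
        return list(self.sequences)


@dataclass
class SequencingRead:
    """One read: id, bases, per-base Phred qualities, timepoint once demuxed."""

    read_id: str
    seq: str
    qual: list[int]
    timepoint: str | None = None

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )


class EpigeneticTrack:
    """Fixed-width binned non-negative signal for one mark.

    ``values[chrom]`` holds one float per bin; ``covered[chrom]`` flags bins
    that carried data in the source file.  Uncovered bins read as 0 but are
    excluded from metaprofile means to avoid biasing them toward 0.
    """

    def __init__(self, mark: str, binsize: int = TRACK_BIN):
        self.mark = mark
        self.binsize = binsize
        self.values: dict[str, np.ndarray] = {}
        self.covered: dict[str, np.ndarray] = {}

    def add_chrom(self, chrom: str, values: np.ndarray, covered: np.ndarray | None = None):
        values = np.asarray(values, dtype=float)
        if (values < 0).any():
            raise ValueError(f"track {self.mark}, {chrom}: negative value")
        self.values[chrom] = values
        self.covered[chrom] = (
            np.ones(len(values), dtype=bool) if covered is None else np.asarray(covered, bool)
        )
        return self

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeAssembly:
    """Load a FASTA file into a :class:`GenomeAssembly` (uppercased)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate header: {rec.id}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no records in {path}")
    return GenomeAssembly(records)


def write_fasta(genome: GenomeAssembly, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[SequencingRead]:
    """Stream Phred+33 FASTQ records; seq/qual length mismatch raises."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield SequencingRead(
            read_id=rec.id,
            seq=str(rec.seq).upper(),
            qual=list(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[SequencingRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BED / GFF3 / bedGraph
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[IntervalRecord], path: str | Path,
              seed: int | None = None) -> None:
    """BED6 with the class label in the name column."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        for iv in intervals:
            strand = iv.strand or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{strand}\n")


def read_bed(path: str | Path) -> list[IntervalRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from e
            label = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            out.append(IntervalRecord(parts[0], start, end, label, strand))
    return out


def write_gff3(intervals: Iterable[IntervalRecord], path: str | Path,
               source: str = "tdnajs", seed: int | None = None) -> None:
    """GFF3 (1-based inclusive) view of a feature set."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_header_comment(seed))
        for i, iv in enumerate(intervals):
            strand = iv.strand or "."
            fh.write(
                f"{iv.chrom}\t{source}\t{iv.label}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\tID={iv.label}{i}\n"
            )


def write_track_bedgraph(track: EpigeneticTrack, lengths: dict[str, int],
                         path: str | Path, seed: int | None = None) -> None:
    bs = track.binsize
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        for chrom, vals in track.values.items():
            cov = track.covered[chrom]
            clen = lengths.get(chrom, len(vals) * bs)
            for i, v in enumerate(vals):
                if not cov[i]:
                    continue
                fh.write(f"{chrom}\t{i * bs}\t{min((i + 1) * bs, clen)}\t{v:g}\n")


def read_track_bedgraph(path: str | Path, lengths: dict[str, int],
                        mark: str = "signal", binsize: int = TRACK_BIN) -> EpigeneticTrack:
    """Resample a bedGraph onto a fixed grid of ``binsize`` bp bins.

    Each grid bin takes the coverage-weighted mean of the input intervals
    overlapping it; bins with no overlap are 0 with the coverage flag off.
    Negative input values raise.
    """
    track = EpigeneticTrack(mark, binsize)
    nbins = {c: -(-l // binsize) for c, l in lengths.items()}
    sums = {c: np.zeros(n) for c, n in nbins.items()}
    wts = {c: np.zeros(n) for c, n in nbins.items()}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            s, e, v = int(s), int(e), float(v)
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative track value {v}")
            if chrom not in sums:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            n_lines += 1
            first, last = s // binsize, (e - 1) // binsize
            for b in range(first, min(last, nbins[chrom] - 1) + 1):
                ov = min(e, (b + 1) * binsize) - max(s, b * binsize)
                sums[chrom][b] += v * ov
                wts[chrom][b] += ov
    if n_lines == 0:
        log.warning("bedGraph %s is empty; returning all-zero track", path)
    for chrom in lengths:
        covered = wts[chrom] > 0
        vals = np.zeros(nbins[chrom])
        vals[covered] = sums[chrom][covered] / wts[chrom][covered]
        track.add_chrom(chrom, vals, covered)
    return track


# ---------------------------------------------------------------------------
# Junction tables
# ---------------------------------------------------------------------------

JUNCTION_COLUMNS = [
    "chrom", "pos", "orient", "primer", "timepoint", "n_positions", "n_reads",
]


def write_junction_table(calls, path: str | Path, seed: int | None = None) -> None:
    """TSV of junction calls (accepts a DataFrame or JunctionCall iterable)."""
    if isinstance(calls, pd.DataFrame):
        df = calls[JUNCTION_COLUMNS]
    else:
        df = pd.DataFrame(
            [
                (c.chrom, c.pos, c.orient, c.primer, c.timepoint,
                 c.n_positions, c.n_reads)
                for c in calls
            ],
            columns=JUNCTION_COLUMNS,
        )
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t", index=False)


def read_junction_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing junction columns {sorted(missing)}")
    return df


def read_external_junctions(path: str | Path) -> list[tuple[str, int]]:
    """Positions from a BED file of externally mapped junctions.

    Single-base records (end == start+1) give the start; wider intervals are
    reduced to their midpoint with a warning.
    """
    positions = []
    widened = 0
    for iv in read_bed(path):
        if iv.end == iv.start + 1:
            positions.append((iv.chrom, iv.start))
        else:
            widened += 1
            positions.append((iv.chrom, (iv.start + iv.end) // 2))
    if widened:
        log.warning("%s: %d BED records wider than 1 bp reduced to midpoints",
                    path, widened)
    return positions
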