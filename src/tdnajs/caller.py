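"""Junction calling: filtering, anchoring, mapping, collapsing, masking.

The stages run in a fixed order and each only removes reads, so counts are
monotone non-increasing:

    quality_filter -> demultiplex -> subtract_t0 -> anchor_primer
    -> map_read -> select_best -> collapse -> build/apply T0 mask

Conventions, recorded here because several are deliberate choices:

* "Phred above 25" is read strictly: a read survives iff every base has
  quality >= 26.
* T0 subtraction is exact: a T6/T24 read is removed iff its (barcode-
  stripped) sequence is identical to, a prefix of, or an extension of some
  T0 read sequence.  An identity-threshold clustering hook exists but is off
  by default.
* Mapping is exact-match: the 3'-terminal 22-mer of the anchored genomic
  portion must occur verbatim in the genome, and the hit is extended 5'-ward
  base by base while identity holds.  The matched length is the score; the
  best hit wins, ties broken by (chromosome order, coordinate); reads whose
  best score is shared by more than ``max_equal_hits`` loci are discarded.
* Collapsing is anchor-based greedy clustering on sorted positions: the
  leftmost position opens a cluster and later positions join while within
  ``collapse_window`` bp of that anchor.
* The T0 hotspot mask thresholds per-400 bp-bin T0 counts at
  mean + 2 * population SD computed over ALL genome bins (zero bins
  included); bins strictly above the threshold are masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io_core import GenomeAssembly, SequencingRead, log, read_fastq, revcomp
from .synthdata import PURINES, PYRIMIDINES, TDNAModel

# ---------------------------------------------------------------------------
# Quality filter and demultiplexing
# ---------------------------------------------------------------------------


def quality_filter(reads: Iterable[SequencingRead], min_qual: int = 26,
                   ) -> list[SequencingRead]:
    """Keep reads whose every base has quality >= ``min_qual`` (above 25)."""
    return [r for r in reads if r.qual and min(r.qual) >= min_qual]


def _py_pu_pattern(barcode: str) -> str | None:
    out = []
    for c in barcode:
        if c in PURINES:
            out.append("R")
        elif c in PYRIMIDINES:
            out.append("Y")
        else:
            return None
    return "".join(out)


def demultiplex(reads: Iterable[SequencingRead], tdna: TDNAModel,
                ) -> tuple[dict[str, list[SequencingRead]], int]:
    """Assign reads to timepoints by their 6 nt purine/pyrimidine barcode.

    The barcode is stripped from the returned reads.  Reads shorter than
    6 nt or matching no timepoint pattern are discarded (count returned).
    """
    by_pattern = {pat: tp for tp, pat in tdna.barcodes.items()}
    out: dict[str, list[SequencingRead]] = {tp: [] for tp in tdna.barcodes}
    discarded = 0
    for r in reads:
        if len(r.seq) < 6:
            discarded += 1
            continue
        pattern = _py_pu_pattern(r.seq[:6])
        tp = by_pattern.get(pattern) if pattern else None
        if tp is None:
            discarded += 1
            continue
        out[tp].append(SequencingRead(r.read_id, r.seq[6:], r.qual[6:], tp))
    if discarded:
        log.info("demultiplex: %d reads matched no barcode pattern", discarded)
    return out, discarded


# ---------------------------------------------------------------------------
# T0 read subtraction
# ---------------------------------------------------------------------------


class _PrefixTrie:
    """Trie over sequences supporting containment-by-prefix queries."""

    __slots__ = ("root",)
    _END = "$"

    def __init__(self, seqs: Iterable[str]):
        self.root: dict = {}
        for s in seqs:
            node = self.root
            for c in s:
                node = node.setdefault(c, {})
            node[self._END] = True

    def matches(self, seq: str) -> bool:
        """True iff some stored sequence is a prefix of ``seq`` or vice versa."""
        node = self.root
        for c in seq:
            if self._END in node:
                return True          # a stored sequence is a prefix of seq
            node = node.get(c)
            if node is None:
                return False
        return bool(node)            # seq is a prefix of (or equals) a stored one


def subtract_t0(reads_t: Sequence[SequencingRead],
                reads_t0: Sequence[SequencingRead],
                matcher: Callable[[str, Sequence[str]], bool] | None = None,
                ) -> list[SequencingRead]:
    """Remove T6/T24 reads whose sequence matches a T0 read.

    Default rule: exact containment (identity, prefix or extension of a T0
    sequence).  A custom ``matcher(seq, t0_seqs) -> bool`` may be supplied to
    emulate threshold-based clustering; it is off by default.
    """
    t0_seqs = [r.seq for r in reads_t0]
    if matcher is not None:
        return [r for r in reads_t if not matcher(r.seq, t0_seqs)]
    trie = _PrefixTrie(t0_seqs)
    return [r for r in reads_t if not trie.matches(r.seq)]


# ---------------------------------------------------------------------------
# Primer anchoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchoredRead:
    """A read anchored at a T-DNA primer + 4 left-border bases.

    ``portion`` is everything 3' of the matched anchor; it may begin with
    further left-border bases when the junction removed less border than the
    primer offset — mapping tolerates that because only the 3'-terminal
    22 bases must match the genome.
    """

    read_id: str
    timepoint: str
    primer: str
    portion: str


def anchor_primer(read: SequencingRead, tdna: TDNAModel, min_match: int = 22,
                  ) -> AnchoredRead | None:
    """Anchor a (barcode-stripped) read at an exact primer+4 occurrence.

    Among primers whose anchor occurs in the read, the match extending
    furthest 3' wins.  Returns None (reject) when no anchor is found or the
    remaining genomic portion is shorter than ``min_match``.
    """
    best_end = -1
    best_primer = None
    for label in tdna.primers:
        anchor = tdna.primer_plus4(label)
        i = read.seq.rfind(anchor)
        if i == -1:
            continue
        end = i + len(anchor)
        if end > best_end:
            best_end, best_primer = end, label
    if best_primer is None:
        return None
    portion = read.seq[best_end:]
    if len(portion) < min_match:
        return None
    return AnchoredRead(read.read_id, read.timepoint or "", best_primer, portion)


# ---------------------------------------------------------------------------
# Exact-match mapping
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers of ``seq``; -1 where a non-ACGT base falls."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(len(arr), -1, dtype=np.int64)
    for base, c in _CODE.items():
        codes[arr == ord(base)] = c
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    keys = codes[:n].copy()
    valid = codes[:n] >= 0
    for j in range(1, k):
        keys = keys * 4 + np.where(codes[j:j + n] >= 0, codes[j:j + n], 0)
        valid &= codes[j:j + n] >= 0
    keys[~valid] = -1
    return keys


def _encode_one(seq: str) -> int | None:
    key = 0
    for c in seq:
        v = _CODE.get(c)
        if v is None:
            return None
        key = key * 4 + v
    return key


class GenomeIndex:
    """Sorted exact-match seed index (seed length = ``k``) over both strands."""

    def __init__(self, genome: GenomeAssembly, k: int = 22):
        self.genome = genome
        self.k = k
        self.chroms = genome.chroms()
        self.rc: dict[str, str] = {c: revcomp(genome[c]) for c in self.chroms}
        self._keys: dict[tuple[str, str], np.ndarray] = {}
        self._pos: dict[tuple[str, str], np.ndarray] = {}
        for chrom in self.chroms:
            for strand, seq in (("+", genome[chrom]), ("-", self.rc[chrom])):
                keys = _encode_kmers(seq, k)
                order = np.argsort(keys, kind="stable")
                self._keys[(chrom, strand)] = keys[order]
                self._pos[(chrom, strand)] = order.astype(np.int64)

    def seed_hits(self, kmer: str, chrom: str, strand: str) -> np.ndarray:
        key = _encode_one(kmer)
        if key is None:
            return np.empty(0, dtype=np.int64)
        keys = self._keys[(chrom, strand)]
        lo = np.searchsorted(keys, key, "left")
        hi = np.searchsorted(keys, key, "right")
        return np.sort(self._pos[(chrom, strand)][lo:hi])


@dataclass(frozen=True)
class MappingHit:
    chrom: str
    pos: int          # 0-based junction coordinate (first genomic base)
    orient: str
    score: int        # total exact-match length (22-mer seed + 5' extension)


def map_read(anchored: AnchoredRead, index: GenomeIndex) -> list[MappingHit]:
    """All maximal exact matches of the genomic portion's 3' end.

    Each seed hit of the 3'-terminal k-mer is extended 5'-ward while identity
    holds; the junction coordinate is the genomic position of the 5'-most
    matched base (the first genomic base after T-DNA sequence).
    """
    k = index.k
    portion = anchored.portion
    if len(portion) < k:
        return []
    tail = portion[-k:]
    hits = []
    for chrom in index.chroms:
        clen = len(index.genome[chrom])
        for strand in ("+", "-"):
            seq = index.genome[chrom] if strand == "+" else index.rc[chrom]
            for q in index.seed_hits(tail, chrom, strand):
                q = int(q)
                e = 0
                while (e < len(portion) - k and q - e - 1 >= 0
                       and portion[-k - e - 1] == seq[q - e - 1]):
                    e += 1
                start = q - e  # 5'-most matched base, in this strand's coords
                pos = start if strand == "+" else clen - 1 - start
                hits.append(MappingHit(chrom, pos, strand, k + e))
    return hits


def select_best(hits: Sequence[MappingHit], chrom_order: Sequence[str],
                max_equal_hits: int = 5) -> MappingHit | None:
    """Best-scoring hit; ties broken by lowest (chromosome order, coordinate).

    Reads whose best score is shared by more than ``max_equal_hits`` loci are
    treated as unmappable (None).
    """
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0]
    best = max(h.score for h in hits)
    top = [h for h in hits if h.score == best]
    if len(top) > max_equal_hits:
        return None
    rank = {c: i for i, c in enumerate(chrom_order)}
    return min(top, key=lambda h: (rank[h.chrom], h.pos, h.orient))


# ---------------------------------------------------------------------------
# Collapsing and masking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionCall:
    chrom: str
    pos: int          # collapse-cluster anchor (leftmost member)
    orient: str
    primer: str
    timepoint: str
    n_positions: int  # distinct mapped positions in the cluster
    n_reads: int      # total supporting reads


@dataclass(frozen=True)
class MappedRead:
    read_id: str
    timepoint: str
    primer: str
    chrom: str
    pos: int
    orient: str


def collapse(mapped: Iterable[MappedRead], window: int = 10) -> list[JunctionCall]:
    """Collapse positions within ``window`` bp (same chrom+primer+timepoint).

    Anchor-based greedy clustering on sorted positions: the leftmost position
    opens a cluster; subsequent positions join while within ``window`` of the
    cluster anchor; the call coordinate is the anchor.  Orientation is the
    cluster's majority (ties resolved toward the anchor's orientation).
    """
    groups: dict[tuple[str, str, str], list[MappedRead]] = {}
    for m in mapped:
        groups.setdefault((m.timepoint, m.primer, m.chrom), []).append(m)
    calls = []
    for (tp, primer, chrom), members in sorted(groups.items()):
        members.sort(key=lambda m: (m.pos, m.read_id))
        cluster: list[MappedRead] = []

        def emit():
            anchor = cluster[0].pos
            n_pos = len({m.pos for m in cluster})
            plus = sum(1 for m in cluster if m.orient == "+")
            minus = len(cluster) - plus
            if plus > minus:
                orient = "+"
            elif minus > plus:
                orient = "-"
            else:
                orient = cluster[0].orient
            calls.append(JunctionCall(chrom, anchor, orient, primer, tp,
                                      n_pos, len(cluster)))

        for m in members:
            if cluster and m.pos - cluster[0].pos > window:
                emit()
                cluster = []
            cluster.append(m)
        if cluster:
            emit()
    return calls


@dataclass
class HotspotMask:
    """400 bp bins excluded for T0 artifact preference, with audit fields."""

    bins: set[tuple[str, int]]
    threshold: float
    mean: float
    sd: float
    bin_width: int = 400
    sd_divisor: str = "N"  # population SD over all genome bins, zeros included


def build_t0_mask(t0_positions: Iterable[tuple[str, int]],
                  genome: GenomeAssembly, bin_width: int = 400) -> HotspotMask:
    """Mask 400 bp bins where T0 mapped-read counts exceed mean + 2 SD.

    Statistics are computed over every genome bin (zero-count bins included)
    with the population SD; only bins strictly above the threshold are masked.
    """
    nbins = {c: -(-l // bin_width) for c, l in genome.lengths.items()}
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in nbins.items()}
    n_pos = 0
    for chrom, pos in t0_positions:
        counts[chrom][pos // bin_width] += 1
        n_pos += 1
    allc = np.concatenate(list(counts.values())) if counts else np.zeros(0)
    if n_pos == 0:
        log.warning("no T0 reads mapped; hotspot mask is empty")
        return HotspotMask(set(), float("inf"), 0.0, 0.0, bin_width)
    mean = float(allc.mean())
    sd = float(allc.std())  # population SD (divisor N)
    threshold = mean + 2 * sd
    bins = {(c, int(b)) for c, arr in counts.items()
            for b in np.flatnonzero(arr > threshold)}
    return HotspotMask(bins, threshold, mean, sd, bin_width)


def apply_mask(calls: Sequence[JunctionCall], mask: HotspotMask,
               ) -> list[JunctionCall]:
    """Drop calls whose coordinate falls in a masked (half-open) bin."""
    if not mask.bins:
        return list(calls)
    kept, removed = [], {}
    for c in calls:
        key = (c.chrom, c.pos // mask.bin_width)
        if key in mask.bins:
            removed[key] = removed.get(key, 0) + 1
        else:
            kept.append(c)
    for (chrom, b), n in sorted(removed.items()):
        log.info("mask: removed %d call(s) in %s bin %d", n, chrom, b)
    return kept


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def position_match_fraction(queries: Sequence[tuple[str, int]],
                            targets: Sequence[tuple[str, int]],
                            tol: int = 10) -> float:
    """Fraction of query positions within ``tol`` bp of some target position.

    With calls as queries and ground truth as targets this is precision;
    swapped, recall.
    """
    by_chrom: dict[str, list[int]] = {}
    for c, p in targets:
        by_chrom.setdefault(c, []).append(p)
    sorted_t = {c: np.sort(ps) for c, ps in by_chrom.items()}
    n_hit = 0
    for c, p in queries:
        a = sorted_t.get(c)
        if a is None or len(a) == 0:
            continue
        i = int(np.searchsorted(a, p))
        if (i < len(a) and a[i] - p <= tol) or (i > 0 and p - a[i - 1] <= tol):
            n_hit += 1
    return n_hit / len(queries) if queries else float("nan")


@dataclass
class CallerParams:
    min_qual: int = 26          # strictly above Phred 25
    min_match: int = 22         # exact 3'-terminal genome match, bp
    collapse_window: int = 10   # bp
    mask_bin: int = 400         # bp
    max_equal_hits: int = 5


def _as_reads(source) -> list[SequencingRead]:
    if isinstance(source, (str, Path)):
        return list(read_fastq(source))
    return list(source)


def run_pipeline(fastq_by_timepoint: dict[str, object], genome: GenomeAssembly,
                 tdna: TDNAModel, params: CallerParams | None = None,
                 index: GenomeIndex | None = None,
                 ) -> tuple[pd.DataFrame, dict]:
    """Run every stage and return (junction table, per-stage QC report).

    ``fastq_by_timepoint`` maps timepoint labels to FASTQ paths or read
    lists; reads are pooled and re-assigned by barcode, so the labels only
    matter for the raw input counts in the QC report.
    """
    params = params or CallerParams()
    qc: dict = {"params": vars(params).copy(), "stages": {}}

    raw: list[SequencingRead] = []
    for tp, source in fastq_by_timepoint.items():
        tp_reads = _as_reads(source)
        qc["stages"].setdefault("raw", {})[tp] = len(tp_reads)
        raw.extend(tp_reads)

    filtered = quality_filter(raw, params.min_qual)
    qc["stages"]["quality_filter"] = {"total": len(filtered)}

    demuxed, n_nobarcode = demultiplex(filtered, tdna)
    qc["stages"]["demultiplex"] = {tp: len(rs) for tp, rs in demuxed.items()}
    qc["stages"]["demultiplex"]["discarded"] = n_nobarcode

    t0_reads = demuxed.get("T0", [])
    subtracted = {tp: subtract_t0(demuxed[tp], t0_reads)
                  for tp in demuxed if tp != "T0"}
    qc["stages"]["subtract_t0"] = {tp: len(rs) for tp, rs in subtracted.items()}

    index = index or GenomeIndex(genome, params.min_match)
    chrom_order = genome.chroms()

    def anchor_map(reads: list[SequencingRead]) -> list[MappedRead]:
        out = []
        for r in reads:
            a = anchor_primer(r, tdna, params.min_match)
            if a is None:
                continue
            best = select_best(map_read(a, index), chrom_order,
                               params.max_equal_hits)
            if best is None:
                continue
            out.append(MappedRead(a.read_id, a.timepoint, a.primer,
                                  best.chrom, best.pos, best.orient))
        return out

    mapped = {tp: anchor_map(rs) for tp, rs in subtracted.items()}
    t0_mapped = anchor_map(t0_reads)
    qc["stages"]["mapped"] = {tp: len(ms) for tp, ms in mapped.items()}
    qc["stages"]["mapped"]["T0"] = len(t0_mapped)

    calls = collapse([m for ms in mapped.values() for m in ms],
                     params.collapse_window)
    qc["stages"]["collapse"] = {"calls": len(calls)}

    mask = build_t0_mask([(m.chrom, m.pos) for m in t0_mapped], genome,
                         params.mask_bin)
    calls = apply_mask(calls, mask)
    qc["stages"]["mask"] = {
        "masked_bins": len(mask.bins),
        "threshold": mask.threshold,
        "mean": mask.mean,
        "sd": mask.sd,
        "calls_after_mask": len(calls),
    }

    table = pd.DataFrame(
        [(c.chrom, c.pos, c.orient, c.primer, c.timepoint, c.n_positions,
          c.n_reads) for c in calls],
        columns=["chrom", "pos", "orient", "primer", "timepoint",
                 "n_positions", "n_reads"],
    ).sort_values(["chrom", "pos", "primer", "timepoint"]).reset_index(drop=True)
    return table, qc
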