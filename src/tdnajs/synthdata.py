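"""Synthetic data emulating a selection-free T-DNA junction experiment.

The generator produces a random genome with gene/promoter/TE annotation and
pericentric blocks, 50 bp-binned epigenetic tracks (CG methylation,
nucleosome occupancy, H3K27me3) with heterochromatin-island structure,
"true" T-DNA-genome junctions, and adapter-ligation-mediated PCR junction
reads:

    barcode(6 nt, purine/pyrimidine timepoint code)
    + nested left-border primer oligo
    + remaining left-border bases down to the border truncation point
    + genomic flank in the junction's orientation,
      ending before the first EcoRI/HindIII/XbaI recognition site
      and at the read length.

A mock T0 timepoint carries only artifact reads (mis-primed genomic reads
concentrated at hotspot loci plus a uniform rain); copies of the hotspot
artifacts contaminate T6/T24 so that both T0 read subtraction and T0 bin
masking have something to do.  Everything is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from bisect import bisect_left, insort
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    TRACK_BIN,
    EpigeneticTrack,
    GenomeAssembly,
    IntervalRecord,
    SequencingRead,
    log,
    revcomp,
    write_bed,
    write_fasta,
    write_fastq,
    write_gff3,
    write_track_bedgraph,
)

#: recognition sites of the three digestion enzymes (all palindromic)
RESTRICTION_SITES = ("GAATTC", "AAGCTT", "TCTAGA")

#: left-border microhomology hexamer (3' end of the -11 primer)
LB_HEXAMER = "CACCAC"

TIMEPOINTS = ("T0", "T6", "T24")


# ---------------------------------------------------------------------------
# T-DNA model
# ---------------------------------------------------------------------------

PRIMER_SEQUENCES = {
    # label -> (oligo sequence, offset of its 3' base from the border terminus)
    "-70": ("GGTGAAAAGAAAAACCACCCCAGTAC", 70),
    "-30": ("GTACATTAAAAACGTCCGCAATGTGTTATTAAG", 30),
    "-11": ("GTCTAAGCGTCAATTTGTTTACACCAC", 11),
}

BARCODE_PATTERNS = {"T0": "RYRYRY", "T6": "RRYYRR", "T24": "RYYRYY"}

PURINES = "AG"
PYRIMIDINES = "CT"


@dataclass
class TDNAModel:
    """Left-border-proximal T-DNA sequence with nested primers and barcodes.

    ``lb_seq`` runs 5'→3' toward the border cleavage terminus; the primer
    with offset ``d`` has its 3' base at position ``-d`` from the terminus,
    i.e. at index ``len(lb_seq) - d``.  A junction with truncation ``t``
    retains ``lb_seq[:len(lb_seq) - t]``.
    """

    lb_seq: str
    primers: dict[str, tuple[str, int]] = field(
        default_factory=lambda: dict(PRIMER_SEQUENCES))
    barcodes: dict[str, str] = field(default_factory=lambda: dict(BARCODE_PATTERNS))

    def __post_init__(self):
        if len(self.lb_seq) < 120:
            raise ValueError("left-border-proximal sequence must be >= 120 nt")
        if not self.primers["-11"][0].endswith(LB_HEXAMER):
            raise ValueError("-11 primer must end in " + LB_HEXAMER)

    def primer_plus4(self, label: str) -> str:
        """Primer oligo plus the next 4 left-border bases (anchor sequence)."""
        oligo, d = self.primers[label]
        L = len(self.lb_seq)
        return oligo + self.lb_seq[L - d + 1:L - d + 5]

    def lb_remainder(self, label: str, truncation: int) -> str:
        """Left-border bases between the primer 3' base and the truncation point."""
        oligo, d = self.primers[label]
        L = len(self.lb_seq)
        end = L - truncation
        return self.lb_seq[L - d + 1:end]

    def primer_for_truncation(self, truncation: int) -> str:
        """Most border-proximal primer whose anchor survives the truncation.

        The anchor needs the primer site plus 4 downstream LB bases intact:
        offset d works iff d - truncation - 1 >= 4.
        """
        for label in ("-11", "-30", "-70"):
            d = self.primers[label][1]
            if d - truncation - 1 >= 4:
                return label
        raise ValueError(f"truncation {truncation} destroys every primer anchor")

    def sample_barcode(self, timepoint: str, rng: np.random.Generator) -> str:
        return "".join(
            rng.choice(list(PURINES if c == "R" else PYRIMIDINES))
            for c in self.barcodes[timepoint]
        )


def default_tdna(seed: int = 20170724) -> TDNAModel:
    """Synthetic LB-proximal sequence with the nested primers at their offsets.

    The published primer oligos overlap between the -30 and -11 positions with
    incompatible sequence, so the border-proximal primer wins the overlap: the
    -11 and -70 oligos are exact substrings at their stated offsets, while the
    last 8 bases of the -30 site are shadowed by the start of the -11 site
    (reads primed with the -30 oligo still carry its printed sequence, as a
    PCR product would).
    """
    rng = np.random.default_rng(seed)
    L = 120
    seq = list(rng.choice(list("ACGT"), size=L))
    for label in ("-70", "-30", "-11"):  # proximal written last -> wins overlaps
        oligo, d = PRIMER_SEQUENCES[label]
        start = L - d - len(oligo) + 1
        seq[start:L - d + 1] = list(oligo)
    return TDNAModel(lb_seq="".join(seq))


# ---------------------------------------------------------------------------
# Genome + features
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    lengths: list[int] = field(default_factory=lambda: [1_000_000, 1_000_000])
    gc: float = 0.36
    pericentric: list[tuple[int, int]] | None = None  # one block per chromosome
    pericentric_fraction: float = 0.083  # used when blocks are not given
    genes_per_mb: float = 200.0
    gene_length_mean: float = 2000.0
    tes_per_mb: float = 120.0
    te_length_mean: float = 700.0
    te_pericentric_weight: float = 0.5  # fraction of TEs placed in pericentric blocks
    promoter_len: int = 1000
    seed: int = 0

    def __post_init__(self):
        if any(l < 50_000 for l in self.lengths):
            raise ValueError("chromosome lengths must be >= 50,000 bp")
        if not 0 < self.gc < 1:
            raise ValueError("GC fraction must lie in (0, 1)")
        if self.pericentric is not None:
            if len(self.pericentric) != len(self.lengths):
                raise ValueError("need one pericentric block per chromosome")
            for (s, e), l in zip(self.pericentric, self.lengths):
                if not 0 <= s < e <= l:
                    raise ValueError(f"pericentric block ({s},{e}) outside chromosome")


@dataclass
class FeatureSet:
    genes: list[IntervalRecord] = field(default_factory=list)
    promoters: list[IntervalRecord] = field(default_factory=list)
    tes: list[IntervalRecord] = field(default_factory=list)
    pericentric: list[IntervalRecord] = field(default_factory=list)

    def by_class(self) -> dict[str, list[IntervalRecord]]:
        return {"TE": self.tes, "promoter": self.promoters, "gene": self.genes}

    def all_intervals(self) -> list[IntervalRecord]:
        return self.tes + self.genes + self.promoters


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=p)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()


class _Occupancy:
    """Sorted non-overlapping intervals with O(log n) overlap checks."""

    def __init__(self):
        self.starts: list[int] = []
        self.ends: list[int] = []

    def overlaps(self, s: int, e: int) -> bool:
        i = bisect_left(self.starts, e)
        return i > 0 and self.ends[i - 1] > s

    def add(self, s: int, e: int) -> None:
        i = bisect_left(self.starts, s)
        self.starts.insert(i, s)
        self.ends.insert(i, e)


def _place_intervals(n: int, length_mean: float, territory: list[tuple[str, int, int]],
                     occupied: dict[str, _Occupancy], label: str,
                     rng: np.random.Generator) -> list[IntervalRecord]:
    """Rejection-sample ``n`` non-overlapping intervals inside a territory."""
    if n == 0:
        return []
    weights = np.array([e - s for _, s, e in territory], dtype=float)
    if len(territory) == 0 or weights.sum() == 0:
        raise ValueError(f"no territory available to place {label} features")
    weights /= weights.sum()
    out = []
    attempts = 0
    max_attempts = 200 * n
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} {label} features (placed {len(out)}): "
                "chromosomes too small or territory too crowded"
            )
        chrom, ts, te = territory[rng.choice(len(territory), p=weights)]
        flen = max(100, int(rng.normal(length_mean, length_mean / 4)))
        if te - ts <= flen:
            continue
        s = int(rng.integers(ts, te - flen))
        e = s + flen
        if occupied[chrom].overlaps(s, e):
            continue
        occupied[chrom].add(s, e)
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(IntervalRecord(chrom, s, e, label, strand))
    return out


def generate_genome(config: GenomeConfig) -> tuple[GenomeAssembly, FeatureSet]:
    """Random genome with TE-rich pericentric blocks and annotated features."""
    rng = np.random.default_rng(config.seed)
    names = [f"chr{i + 1}" for i in range(len(config.lengths))]
    genome = GenomeAssembly({
        name: _random_sequence(l, config.gc, rng)
        for name, l in zip(names, config.lengths)
    })

    if config.pericentric is not None:
        blocks = config.pericentric
    else:
        blocks = []
        for l in config.lengths:
            half = int(l * config.pericentric_fraction / 2)
            blocks.append((l // 2 - half, l // 2 + half))
    peri = [IntervalRecord(n, s, e, "pericentric")
            for n, (s, e) in zip(names, blocks) if e > s]

    peri_territory = [(iv.chrom, iv.start, iv.end) for iv in peri]
    distal_territory = []
    for name, l in zip(names, config.lengths):
        pblocks = sorted((iv.start, iv.end) for iv in peri if iv.chrom == name)
        prev = 0
        for s, e in pblocks:
            if s > prev:
                distal_territory.append((name, prev, s))
            prev = e
        if prev < l:
            distal_territory.append((name, prev, l))

    occupied = {n: _Occupancy() for n in names}
    mb = sum(config.lengths) / 1e6
    n_genes = int(round(config.genes_per_mb * mb))
    n_tes = int(round(config.tes_per_mb * mb))
    n_tes_peri = int(round(n_tes * config.te_pericentric_weight)) if peri else 0

    tes = _place_intervals(n_tes_peri, config.te_length_mean, peri_territory,
                           occupied, "TE", rng)
    tes += _place_intervals(n_tes - n_tes_peri, config.te_length_mean,
                            distal_territory, occupied, "TE", rng)
    genes = _place_intervals(n_genes, config.gene_length_mean, distal_territory,
                             occupied, "gene", rng)

    promoters = []
    lengths = genome.lengths
    for g in genes:
        if g.strand == "+":
            s, e = g.start - config.promoter_len, g.start
        else:
            s, e = g.end, g.end + config.promoter_len
        s, e = max(0, s), min(lengths[g.chrom], e)
        if e > s:
            promoters.append(IntervalRecord(g.chrom, s, e, "promoter", g.strand))

    return genome, FeatureSet(genes=genes, promoters=promoters, tes=tes,
                              pericentric=peri)


# ---------------------------------------------------------------------------
# Epigenetic tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackConfig:
    meth_baseline: float = 0.05
    meth_te_boost: float = 0.5
    meth_pericentric_boost: float = 0.3
    nuc_baseline: float = 1.0
    nuc_promoter_drop: float = 0.6
    nuc_pericentric_boost: float = 0.3
    k27_baseline: float = 0.1
    island_amplitude: float = 1.0
    island_width: int = 2000
    island_count: int = 30
    islands_distal_only: bool = True
    noise_sd: float = 0.02
    seed: int = 0


@dataclass
class TrackBundle:
    methylation: EpigeneticTrack
    nucleosome: EpigeneticTrack
    h3k27me3: EpigeneticTrack
    islands: list[IntervalRecord]

    def as_dict(self) -> dict[str, EpigeneticTrack]:
        return {"methylation": self.methylation, "nucleosome": self.nucleosome,
                "h3k27me3": self.h3k27me3}


def _paint_bins(mask: np.ndarray, intervals: list[IntervalRecord], chrom: str,
                binsize: int) -> None:
    for iv in intervals:
        if iv.chrom != chrom:
            continue
        mask[iv.start // binsize:(iv.end - 1) // binsize + 1] = True


def generate_tracks(genome: GenomeAssembly, features: FeatureSet,
                    tc: TrackConfig) -> TrackBundle:
    """50 bp-binned methylation / nucleosome / H3K27me3 tracks.

    Methylation is boosted in TEs and pericentric blocks, nucleosome occupancy
    is boosted in pericentric blocks and dips in promoters, and H3K27me3 forms
    fixed-width islands placed (by default) only in distal territory — the
    heterochromatin-islands-in-euchromatin structure the metaprofiles probe.
    """
    rng = np.random.default_rng(tc.seed)
    width = tc.island_width
    if width % TRACK_BIN:
        width = (width // TRACK_BIN + 1) * TRACK_BIN
        log.warning("island width rounded up to %d bp (multiple of %d)",
                    width, TRACK_BIN)

    # choose island intervals
    lengths = genome.lengths
    islands: list[IntervalRecord] = []
    if tc.island_count > 0 and tc.island_amplitude > 0:
        territory = []
        for chrom, l in lengths.items():
            pblocks = sorted((iv.start, iv.end) for iv in features.pericentric
                             if iv.chrom == chrom)
            if tc.islands_distal_only and pblocks:
                prev = 0
                for s, e in pblocks:
                    if s - prev > width:
                        territory.append((chrom, prev, s))
                    prev = e
                if l - prev > width:
                    territory.append((chrom, prev, l))
            else:
                territory.append((chrom, 0, l))
        occupied = {c: _Occupancy() for c in lengths}
        weights = np.array([e - s for _, s, e in territory], dtype=float)
        weights /= weights.sum()
        attempts = 0
        while len(islands) < tc.island_count:
            attempts += 1
            if attempts > 200 * tc.island_count:
                raise ValueError("could not place requested H3K27me3 islands")
            chrom, ts, te = territory[rng.choice(len(territory), p=weights)]
            if te - ts <= width:
                continue
            s = int(rng.integers(ts, te - width)) // TRACK_BIN * TRACK_BIN
            if occupied[chrom].overlaps(s, s + width):
                continue
            occupied[chrom].add(s, s + width)
            islands.append(IntervalRecord(chrom, s, s + width, "island"))

    meth = EpigeneticTrack("methylation")
    nuc = EpigeneticTrack("nucleosome")
    k27 = EpigeneticTrack("h3k27me3")
    for chrom, l in lengths.items():
        nbins = -(-l // TRACK_BIN)
        te_m = np.zeros(nbins, bool)
        prom_m = np.zeros(nbins, bool)
        peri_m = np.zeros(nbins, bool)
        isl_m = np.zeros(nbins, bool)
        _paint_bins(te_m, features.tes, chrom, TRACK_BIN)
        _paint_bins(prom_m, features.promoters, chrom, TRACK_BIN)
        _paint_bins(peri_m, features.pericentric, chrom, TRACK_BIN)
        _paint_bins(isl_m, islands, chrom, TRACK_BIN)

        def noisy(base):
            return np.clip(base + rng.normal(0, tc.noise_sd, nbins), 0, None)

        meth.add_chrom(chrom, noisy(
            tc.meth_baseline + tc.meth_te_boost * te_m
            + tc.meth_pericentric_boost * peri_m))
        nuc.add_chrom(chrom, noisy(
            tc.nuc_baseline + tc.nuc_pericentric_boost * peri_m
            - tc.nuc_promoter_drop * prom_m))
        k27.add_chrom(chrom, noisy(
            tc.k27_baseline + tc.island_amplitude * isl_m))
    return TrackBundle(meth, nuc, k27, islands)


# ---------------------------------------------------------------------------
# True junctions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueJunction:
    """A planted T-DNA-genome junction.

    ``pos`` is the 0-based coordinate of the first genomic base at the
    junction; ``orient`` is the direction the genomic flank is read through
    ('+' rightward on the reference, '-' leftward as reverse complement);
    ``truncation`` is the number of left-border bases removed beyond the
    border terminus (0-65, so at least the -70 primer anchor survives).
    """

    chrom: str
    pos: int
    orient: str
    truncation: int
    microhomology: bool = False

    def __post_init__(self):
        if not 0 <= self.truncation <= 65:
            raise ValueError("truncation must be in 0..65")


MAX_TRUNCATION = 65


def _motif_positions(genome: GenomeAssembly) -> dict[str, dict[str, np.ndarray]]:
    """Junction coordinates adjacent to the LB hexamer, per chrom and strand."""
    out = {}
    rc = revcomp(LB_HEXAMER)
    for chrom, seq in genome.sequences.items():
        fwd, rev, i = [], [], seq.find(LB_HEXAMER)
        while i != -1:
            if i + 6 < len(seq):
                fwd.append(i + 6)      # genome[p-6:p] == hexamer, '+' junction
            i = seq.find(LB_HEXAMER, i + 1)
        i = seq.find(rc)
        while i != -1:
            if i - 1 >= 0:
                rev.append(i - 1)      # genome[p+1:p+7] == rc(hexamer), '-' junction
            i = seq.find(rc, i + 1)
        out[chrom] = {"+": np.array(fwd, dtype=int), "-": np.array(rev, dtype=int)}
    return out


def _qualifying_open_bins(features: FeatureSet, tracks: TrackBundle) -> list[IntervalRecord]:
    """Promoter 50 bp bins with low nucleosome occupancy and low methylation."""
    out = []
    for chrom, nucv in tracks.nucleosome.values.items():
        methv = tracks.methylation.values[chrom]
        prom_m = np.zeros(len(nucv), bool)
        _paint_bins(prom_m, features.promoters, chrom, TRACK_BIN)
        nuc_med = float(np.median(nucv))
        meth_med = float(np.median(methv))
        ok = prom_m & (nucv < nuc_med) & (methv <= meth_med)
        for b in np.flatnonzero(ok):
            out.append(IntervalRecord(chrom, int(b) * TRACK_BIN,
                                      (int(b) + 1) * TRACK_BIN, "open"))
    return out


def simulate_junctions(genome: GenomeAssembly, features: FeatureSet,
                       tracks: TrackBundle | None, n: int,
                       bias: str = "uniform", w: float = 0.5,
                       microhomology_fraction: float = 0.25,
                       seed: int = 0) -> list[TrueJunction]:
    """Draw ``n`` true junctions under a placement model.

    bias='uniform': coordinates i.i.d. uniform over the genome.
    bias='island-biased': fraction ``w`` drawn uniformly from within H3K27me3
    islands, the rest uniform.
    bias='open-chromatin-biased': fraction ``w`` drawn from low-nucleosome,
    unmethylated promoter bins, the rest uniform.

    A ``microhomology_fraction`` of junctions is placed so the 6 genomic bases
    on the T-DNA side of the junction equal the left-border hexamer CACCAC
    (drawn from hexamer occurrences inside the junction's placement stratum).
    Truncation lengths are i.i.d. uniform on 0..65; orientation is +/- with
    equal probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = genome.chroms()
    lengths = genome.lengths
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    motif_pos = _motif_positions(genome)

    if bias == "uniform":
        strata = [None] * n
    elif bias == "island-biased":
        if tracks is None or not tracks.islands:
            raise ValueError("island-biased placement requested but there are "
                             "no H3K27me3 islands")
        strata = [tracks.islands if rng.random() < w else None for _ in range(n)]
    elif bias == "open-chromatin-biased":
        if tracks is None:
            raise ValueError("open-chromatin-biased placement needs tracks")
        open_bins = _qualifying_open_bins(features, tracks)
        if not open_bins:
            raise ValueError("open-chromatin-biased placement requested but no "
                             "low-nucleosome unmethylated promoter bins exist")
        strata = [open_bins if rng.random() < w else None for _ in range(n)]
    else:
        raise ValueError(f"unknown bias mode: {bias}")

    def in_stratum(chrom, pos, stratum):
        return any(iv.chrom == chrom and iv.start <= pos < iv.end for iv in stratum)

    junctions = []
    for stratum in strata:
        orient = "+" if rng.random() < 0.5 else "-"
        micro = rng.random() < microhomology_fraction
        pos = chrom = None
        if micro:
            if stratum is None:
                cands = [(c, p) for c in chroms for p in motif_pos[c][orient]]
            else:
                cands = [(c, p) for c in chroms for p in motif_pos[c][orient]
                         if in_stratum(c, int(p), stratum)]
            if cands:
                chrom, pos = cands[rng.integers(len(cands))]
                pos = int(pos)
            else:
                micro = False  # stratum holds no hexamer; fall back to plain draw
        if pos is None:
            if stratum is None:
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                pos = int(rng.integers(lengths[chrom]))
            else:
                sw = np.array([iv.end - iv.start for iv in stratum], dtype=float)
                iv = stratum[rng.choice(len(stratum), p=sw / sw.sum())]
                chrom, pos = iv.chrom, int(rng.integers(iv.start, iv.end))
        junctions.append(TrueJunction(
            chrom=chrom, pos=pos, orient=orient,
            truncation=int(rng.integers(0, MAX_TRUNCATION + 1)),
            microhomology=micro,
        ))
    return junctions


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

@dataclass
class LibraryConfig:
    read_length: int = 100
    duplicate_mean: float = 3.0          # mean reads per junction (PCR duplicates)
    artifact_fraction: float = 0.05      # fraction of T6/T24 reads that are artifacts
    hotspot_count: int = 20
    hotspot_mean_reads: float = 30.0     # Poisson mean of T0 reads per hotspot
    rain_reads: int = 100                # uniform T0 artifact rain
    lowq_fraction: float = 0.1           # reads given one base with quality <= 25
    min_fragment: int = 50               # junction-to-cut distance window (bp);
    max_fragment: int | None = 500       # outside it the junction amplifies no reads
    seed: int = 0

    def __post_init__(self):
        for f in (self.artifact_fraction, self.lowq_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.read_length < 50:
            raise ValueError("read length must be >= 50")


def _oriented_flank(seq: str, pos: int, orient: str, max_len: int) -> str:
    if orient == "+":
        return seq[pos:pos + max_len]
    return revcomp(seq[max(0, pos - max_len + 1):pos + 1])


def _cut_distance(flank: str) -> int | None:
    """Distance from the junction to the first restriction-site start, or None."""
    hits = [flank.find(site) for site in RESTRICTION_SITES]
    hits = [h for h in hits if h != -1]
    return min(hits) if hits else None


def simulate_library(genome: GenomeAssembly, junctions: list[TrueJunction],
                     tdna: TDNAModel, lc: LibraryConfig,
                     timepoint_assignment: list[str] | None = None,
                     ) -> tuple[dict[str, list[SequencingRead]], pd.DataFrame]:
    """Emit junction reads per timepoint plus a ground-truth table.

    Junctions whose distance to the nearest restriction site falls outside the
    amplifiable fragment window (LibraryConfig.min_fragment..max_fragment,
    matching the observed amplicon size range) emit no reads and appear in the
    ground truth with ``n_reads`` 0.  T0 holds only artifact reads; identical
    copies of the hotspot artifacts are injected into T6/T24.
    """
    rng = np.random.default_rng(lc.seed)
    if timepoint_assignment is None:
        # two junctions observed at 6 h for every one at 24 h
        timepoint_assignment = [
            "T6" if rng.random() < 2 / 3 else "T24" for _ in junctions]
    if len(timepoint_assignment) != len(junctions):
        raise ValueError("timepoint assignment length != junction count")

    reads: dict[str, list[SequencingRead]] = {t: [] for t in TIMEPOINTS}
    truth_rows = []
    scan = (lc.max_fragment or lc.read_length) + max(len(s) for s in RESTRICTION_SITES)

    def qualities(length: int) -> list[int]:
        q = rng.integers(33, 41, size=length).tolist()
        if rng.random() < lc.lowq_fraction:
            q[int(rng.integers(length))] = int(rng.integers(3, 26))
        return q

    no_cut_in_read = 0
    for j_idx, (jn, tp) in enumerate(zip(junctions, timepoint_assignment)):
        flank_full = _oriented_flank(genome[jn.chrom], jn.pos, jn.orient, scan)
        cut = _cut_distance(flank_full)
        amplifiable = (
            cut is not None
            and cut >= lc.min_fragment
            and (lc.max_fragment is None or cut <= lc.max_fragment)
        )
        n_reads = 0
        if amplifiable:
            flank = flank_full[:cut]
            primer = tdna.primer_for_truncation(jn.truncation)
            oligo = tdna.primers[primer][0]
            lb_rest = tdna.lb_remainder(primer, jn.truncation)
            n_reads = 1 + int(rng.poisson(max(lc.duplicate_mean - 1, 0)))
            budget = lc.read_length - 6 - len(oligo) - len(lb_rest)
            if len(flank) > budget:
                if cut is not None and cut > budget:
                    no_cut_in_read += 1
                flank_in_read = flank[:budget]
            else:
                flank_in_read = flank
            for r in range(n_reads):
                barcode = tdna.sample_barcode(tp, rng)
                seq = barcode + oligo + lb_rest + flank_in_read
                reads[tp].append(SequencingRead(
                    read_id=f"j{j_idx:05d}:r{r}", seq=seq, qual=qualities(len(seq))))
        truth_rows.append((f"j{j_idx:05d}", jn.chrom, jn.pos, jn.orient,
                           jn.truncation, tp, n_reads))
    if no_cut_in_read:
        log.info("%d junctions had no restriction site within read range; "
                 "their flanks run to the read end", no_cut_in_read)

    # --- T0 artifacts: hotspot loci + uniform rain -------------------------
    chroms = genome.chroms()
    lengths = genome.lengths
    cweights = np.array([lengths[c] for c in chroms], dtype=float)
    cweights /= cweights.sum()
    anchor = tdna.primer_plus4("-11")

    def artifact_template(chrom: str, pos: int, orient: str) -> str:
        budget = lc.read_length - 6 - len(anchor)
        flank = _oriented_flank(genome[chrom], pos, orient, scan)
        cut = _cut_distance(flank)
        if cut is not None:
            flank = flank[:cut]
        return anchor + flank[:budget]

    hotspots = []
    for _ in range(lc.hotspot_count):
        chrom = chroms[rng.choice(len(chroms), p=cweights)]
        pos = int(rng.integers(lengths[chrom]))
        orient = "+" if rng.random() < 0.5 else "-"
        hotspots.append((chrom, pos, orient, artifact_template(chrom, pos, orient)))

    for chrom, pos, orient, template in hotspots:
        for r in range(int(rng.poisson(lc.hotspot_mean_reads))):
            seq = tdna.sample_barcode("T0", rng) + template
            reads["T0"].append(SequencingRead(
                read_id=f"t0hs:{chrom}:{pos}:r{r}", seq=seq,
                qual=qualities(len(seq))))
    for r in range(lc.rain_reads):
        chrom = chroms[rng.choice(len(chroms), p=cweights)]
        pos = int(rng.integers(lengths[chrom]))
        orient = "+" if rng.random() < 0.5 else "-"
        seq = tdna.sample_barcode("T0", rng) + artifact_template(chrom, pos, orient)
        reads["T0"].append(SequencingRead(
            read_id=f"t0rain:r{r}", seq=seq, qual=qualities(len(seq))))

    # --- shared hotspot artifacts contaminating T6/T24 ---------------------
    if hotspots:
        for tp in ("T6", "T24"):
            n_art = int(round(lc.artifact_fraction * len(reads[tp])))
            for r in range(n_art):
                chrom, pos, orient, template = hotspots[int(rng.integers(len(hotspots)))]
                seq = tdna.sample_barcode(tp, rng) + template
                reads[tp].append(SequencingRead(
                    read_id=f"art{tp}:r{r}", seq=seq, qual=qualities(len(seq))))

    truth = pd.DataFrame(truth_rows, columns=[
        "junction_id", "chrom", "pos0", "orient", "truncation", "timepoint",
        "n_reads"])
    return reads, truth


# ---------------------------------------------------------------------------
# One-call simulation to disk
# ---------------------------------------------------------------------------

def simulate_to_dir(outdir: str | Path, gconf: GenomeConfig | None = None,
                    tconf: TrackConfig | None = None,
                    lconf: LibraryConfig | None = None,
                    n_junctions: int = 500, bias: str = "uniform",
                    bias_weight: float = 0.5,
                    microhomology_fraction: float = 0.25,
                    seed: int = 0) -> dict[str, Path]:
    """Generate a full synthetic experiment and write every external file.

    One master seed derives the per-stage seeds, so a single integer pins the
    whole dataset.  Returns the path of every file written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gconf = gconf or GenomeConfig()
    tconf = tconf or TrackConfig()
    lconf = lconf or LibraryConfig()
    gconf.seed = seed
    tconf.seed = seed + 1
    lconf.seed = seed + 2

    genome, features = generate_genome(gconf)
    tracks = generate_tracks(genome, features, tconf)
    junctions = simulate_junctions(genome, features, tracks, n_junctions,
                                   bias=bias, w=bias_weight,
                                   microhomology_fraction=microhomology_fraction,
                                   seed=seed + 3)
    tdna = default_tdna()
    reads, truth = simulate_library(genome, junctions, tdna, lconf)

    paths = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["features_bed"] = outdir / "features.bed"
    write_bed(features.all_intervals(), paths["features_bed"], seed=seed)
    paths["features_gff3"] = outdir / "features.gff3"
    write_gff3(features.all_intervals(), paths["features_gff3"], seed=seed)
    paths["pericentric"] = outdir / "pericentric.bed"
    write_bed(features.pericentric, paths["pericentric"], seed=seed)
    lengths = genome.lengths
    for mark, track in tracks.as_dict().items():
        paths[mark] = outdir / f"{mark}.bedgraph"
        write_track_bedgraph(track, lengths, paths[mark], seed=seed)
    for tp, tp_reads in reads.items():
        paths[f"fastq_{tp}"] = outdir / f"{tp}.fastq"
        write_fastq(tp_reads, paths[f"fastq_{tp}"])
    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write(f"# tdnajs seed={seed}\n")
        truth.to_csv(fh, sep="\t", index=False)
    return paths
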