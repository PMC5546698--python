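"""Genomic-feature association of junction positions.

Positions are assigned a single class among {TE, promoter, gene, other}
under a configurable precedence (default TE > promoter > gene: TE
annotations are the most specific).  Genome-wide fractions are base-pair
weighted after flattening overlaps under the same precedence, so junction
class fractions and genome fractions are directly comparable, as in a
contingency-table chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GenomeAssembly, IntervalRecord
from .synthdata import FeatureSet

DEFAULT_PRECEDENCE = ("TE", "promoter", "gene")
CLASSES = ("TE", "gene", "promoter", "other")


@dataclass
class FeatureFractions:
    counts: dict[str, int]
    n: int

    @property
    def fractions(self) -> dict[str, float]:
        return {c: v / self.n for c, v in self.counts.items()}

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions)


def _merged(intervals: list[IntervalRecord], chrom: str) -> np.ndarray:
    """Merged (start, end) pairs for one chromosome, sorted; shape (m, 2)."""
    ivs = sorted((iv.start, iv.end) for iv in intervals if iv.chrom == chrom)
    if not ivs:
        return np.empty((0, 2), dtype=np.int64)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


class FeatureClassifier:
    """Vectorized point-in-feature classification under a precedence order."""

    def __init__(self, features: FeatureSet,
                 precedence: tuple[str, ...] = DEFAULT_PRECEDENCE):
        if sorted(precedence) != sorted(DEFAULT_PRECEDENCE):
            raise ValueError(f"precedence must order {DEFAULT_PRECEDENCE}")
        self.precedence = tuple(precedence)
        by_class = features.by_class()
        chroms = {iv.chrom for ivs in by_class.values() for iv in ivs}
        chroms |= {iv.chrom for iv in features.pericentric}
        self._merged: dict[tuple[str, str], np.ndarray] = {
            (cls, chrom): _merged(by_class[cls], chrom)
            for cls in DEFAULT_PRECEDENCE for chrom in chroms
        }

    def _member(self, cls: str, chrom: str, pos: np.ndarray) -> np.ndarray:
        m = self._merged.get((cls, chrom))
        if m is None or len(m) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(m[:, 0], pos, "right") - 1
        ok = idx >= 0
        member = np.zeros(len(pos), dtype=bool)
        member[ok] = pos[ok] < m[idx[ok], 1]
        return member

    def classify(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Class label per position (array of str)."""
        out = np.full(len(positions), "other", dtype=object)
        unset = np.ones(len(positions), dtype=bool)
        for cls in self.precedence:
            hit = unset & self._member(cls, chrom, positions)
            out[hit] = cls
            unset &= ~hit
        return out


def classify_position(chrom: str, pos: int, features: FeatureSet,
                      precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
                      genome: GenomeAssembly | None = None) -> str:
    """Single class for one position (TE/promoter/gene/other)."""
    if genome is not None and not (0 <= pos < genome.lengths[chrom]):
        raise ValueError(f"position {chrom}:{pos} outside genome")
    return FeatureClassifier(features, precedence).classify(
        chrom, np.array([pos]))[0]


def genome_fractions(genome: GenomeAssembly, features: FeatureSet,
                     precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
                     ) -> FeatureFractions:
    """Base-pair-weighted class fractions after flattening under precedence."""
    by_class = features.by_class()
    counts = {c: 0 for c in CLASSES}
    total = 0
    for chrom, clen in genome.lengths.items():
        # paint lowest precedence first so higher precedence overwrites
        labels = np.zeros(clen, dtype=np.uint8)
        code = {}
        for i, cls in enumerate(reversed(DEFAULT_PRECEDENCE)):
            code[cls] = i + 1
        for cls in sorted(by_class, key=lambda c: precedence.index(c), reverse=True):
            for iv in by_class[cls]:
                if iv.chrom == chrom:
                    labels[iv.start:iv.end] = code[cls]
        binc = np.bincount(labels, minlength=4)
        counts["other"] += int(binc[0])
        for cls, c in code.items():
            counts[cls] += int(binc[c]) if c < len(binc) else 0
        total += clen
    return FeatureFractions(counts, total)


def junction_fractions(positions: list[tuple[str, int]], features: FeatureSet,
                       precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
                       ) -> FeatureFractions:
    """Class fractions of a set of junction positions."""
    if not positions:
        raise ValueError("no positions")
    clf = FeatureClassifier(features, precedence)
    counts = {c: 0 for c in CLASSES}
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, pos in by_chrom.items():
        labels = clf.classify(chrom, np.asarray(pos))
        for cls, n in zip(*np.unique(labels, return_counts=True)):
            counts[str(cls)] += int(n)
    return FeatureFractions(counts, len(positions))


def chisq_compare(counts_a: dict[str, int],
                  counts_b: dict[str, int] | None = None,
                  expected_fractions: dict[str, float] | None = None,
                  ) -> tuple[float, int, float]:
    """Pearson chi-square comparison of class counts.

    Two count sets -> 2xK contingency test (no continuity correction).
    One count set + expected fractions -> goodness-of-fit against those
    fractions.  Returns (statistic, df, two-sided p).
    """
    classes = list(counts_a)
    obs_a = np.array([counts_a[c] for c in classes], dtype=float)
    if counts_b is not None:
        obs_b = np.array([counts_b.get(c, 0) for c in classes], dtype=float)
        table = np.vstack([obs_a, obs_b])
        if table.sum() == 0:
            raise ValueError("zero-total table")
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
        stat, p, df, expected = stats.chi2_contingency(table, correction=False)
        if (expected < 5).any():
            import warnings
            warnings.warn("chi-square: some expected cell counts are below 5")
        return float(stat), int(df), float(p)
    if expected_fractions is None:
        raise ValueError("need either counts_b or expected_fractions")
    if obs_a.sum() == 0:
        raise ValueError("zero-total table")
    f_exp = np.array([expected_fractions[c] for c in classes], dtype=float)
    keep = f_exp > 0
    f_exp = f_exp[keep] / f_exp[keep].sum()
    obs = obs_a[keep]
    exp = f_exp * obs.sum()
    if (exp < 5).any():
        import warnings
        warnings.warn("chi-square: some expected cell counts are below 5")
    stat, p = stats.chisquare(obs, exp)
    return float(stat), len(obs) - 1, float(p)


@dataclass
class DensityTrack:
    window: int
    step: int
    centers: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]


def chromosome_density(positions: list[tuple[str, int]],
                       genome: GenomeAssembly, window: int = 500_000,
                       step: int = 100_000) -> DensityTrack:
    """Sliding-window junction counts per chromosome."""
    if window < step:
        raise ValueError("window must be >= step")
    centers, counts = {}, {}
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    for chrom, clen in genome.lengths.items():
        starts = np.arange(0, max(clen - window, 0) + 1, step)
        if len(starts) == 0:
            starts = np.array([0])
        pos = np.sort(np.asarray(by_chrom.get(chrom, []), dtype=np.int64))
        lo = np.searchsorted(pos, starts, "left")
        hi = np.searchsorted(pos, np.minimum(starts + window, clen), "left")
        centers[chrom] = starts + window // 2
        counts[chrom] = hi - lo
    return DensityTrack(window, step, centers, counts)


def pericentric_share(positions: list[tuple[str, int]], features: FeatureSet,
                      genome: GenomeAssembly) -> tuple[float, float]:
    """(fraction of positions in pericentric intervals, pericentric genome fraction)."""
    peri = {c: _merged(features.pericentric, c) for c in genome.chroms()}
    n_in = 0
    for chrom, pos in positions:
        m = peri[chrom]
        if len(m):
            i = np.searchsorted(m[:, 0], pos, "right") - 1
            if i >= 0 and pos < m[i, 1]:
                n_in += 1
    peri_bp = sum(int((m[:, 1] - m[:, 0]).sum()) for m in peri.values())
    return (n_in / len(positions) if positions else 0.0,
            peri_bp / genome.total_length)


def composition_report(positions: list[tuple[str, int]],
                       genome: GenomeAssembly, flank: int = 200,
                       k_values: tuple[int, ...] = (1, 2, 3)) -> pd.DataFrame:
    """Descriptive mono/di/tri-nucleotide composition around positions.

    Compares k-mer frequencies in +-flank windows at the positions with
    genome-wide background frequencies.  Purely descriptive (no test).
    """
    rows = []
    for k in k_values:
        fg: dict[str, int] = {}
        bg: dict[str, int] = {}
        for chrom, pos in positions:
            seq = genome[chrom][max(0, pos - flank):pos + flank]
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                fg[kmer] = fg.get(kmer, 0) + 1
        for chrom in genome.chroms():
            seq = genome[chrom]
            for i in range(0, len(seq) - k + 1, 97):  # sparse background sample
                kmer = seq[i:i + k]
                bg[kmer] = bg.get(kmer, 0) + 1
        fg_tot = sum(fg.values()) or 1
        bg_tot = sum(bg.values()) or 1
        for kmer in sorted(set(fg) | set(bg)):
            rows.append((k, kmer, fg.get(kmer, 0) / fg_tot,
                         bg.get(kmer, 0) / bg_tot))
    return pd.DataFrame(rows, columns=["k", "kmer", "junction_freq",
                                       "genome_freq"])
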