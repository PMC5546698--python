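"""Bin-based k-mer motif enrichment around junction positions.

The genome is divided into non-overlapping 400 bp bins; bins containing at
least one junction are the foreground and randomly sampled other bins (or
every remaining bin) the background.  Enrichment is presence/absence per
bin — a motif either occurs in a bin (on either strand) or it does not —
scored with a hypergeometric upper tail on the pooled foreground+background
urn and Benjamini-Hochberg corrected within each k.  This is an exact,
deterministic statistic standing where PWM discovery tools would sit in a
full analysis; the qualitative read-out (which motifs rise to the top) is
the same.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import MOTIF_BIN, GenomeAssembly, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]", "K": "[GT]",
    "M": "[AC]", "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


@dataclass
class BinSet:
    """Non-overlapping fixed-width genome bins with extracted sequences."""

    role: str                       # "foreground" | "background"
    bins: list[tuple[str, int]]     # (chrom, bin index); start = width * index
    sequences: list[str]
    width: int = MOTIF_BIN

    def __len__(self) -> int:
        return len(self.bins)

    def keys(self) -> set[tuple[str, int]]:
        return set(self.bins)


def _complete_bins(genome: GenomeAssembly, width: int) -> dict[str, int]:
    """Number of complete bins per chromosome (trailing partial bins dropped)."""
    return {c: l // width for c, l in genome.lengths.items()}


def foreground_bins(positions: list[tuple[str, int]], genome: GenomeAssembly,
                    width: int = MOTIF_BIN) -> BinSet:
    """Unique complete bins containing at least one junction position."""
    nbins = _complete_bins(genome, width)
    keys = sorted({(c, p // width) for c, p in positions
                   if p // width < nbins[c]})
    seqs = [genome[c][b * width:(b + 1) * width] for c, b in keys]
    return BinSet("foreground", keys, seqs, width)


def sample_background(genome: GenomeAssembly, n_bins: int | None, seed: int,
                      exclude: BinSet | None = None,
                      width: int = MOTIF_BIN) -> BinSet:
    """Uniform sample of complete bins outside ``exclude``, without replacement.

    ``n_bins=None`` takes every available bin (whole-genome control).  The
    conventional default elsewhere is 10x the foreground size.
    """
    excluded = exclude.keys() if exclude is not None else set()
    avail = [(c, b) for c, n in _complete_bins(genome, width).items()
             for b in range(n) if (c, b) not in excluded]
    if n_bins is None:
        keys = sorted(avail)
    else:
        if n_bins > len(avail):
            raise ValueError(
                f"requested {n_bins} background bins but only {len(avail)} "
                "non-foreground bins exist")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(avail), size=n_bins, replace=False)
        keys = sorted(avail[i] for i in idx)
    seqs = [genome[c][b * width:(b + 1) * width] for c, b in keys]
    return BinSet("background", keys, seqs, width)


def _present_kmers(seq: str, k: int) -> set[str]:
    """Distinct k-mers present in a sequence or its reverse complement."""
    rc = revcomp(seq)
    out = {seq[i:i + k] for i in range(len(seq) - k + 1)}
    out |= {rc[i:i + k] for i in range(len(rc) - k + 1)}
    return {m for m in out if "N" not in m}


def kmer_enrichment(fg: BinSet, bg: BinSet, k_min: int = 4, k_max: int = 8,
                    min_support: int = 5) -> pd.DataFrame:
    """Hypergeometric presence/absence enrichment of all k-mers.

    For each k-mer seen in >= ``min_support`` foreground bins: with N total
    bins, K bins containing the motif, and n foreground bins of which a
    contain it, p = P[X >= a] for X ~ Hypergeometric(N, K, n).  q is the
    Benjamini-Hochberg adjustment across all tested k-mers of the same k.
    Rows are sorted by (q, p).
    """
    if k_max > 12:
        raise ValueError("k > 12 would enumerate too many k-mers")
    frames = []
    for k in range(k_min, k_max + 1):
        fg_count: dict[str, int] = {}
        bg_count: dict[str, int] = {}
        for seq in fg.sequences:
            for m in _present_kmers(seq, k):
                fg_count[m] = fg_count.get(m, 0) + 1
        for seq in bg.sequences:
            for m in _present_kmers(seq, k):
                bg_count[m] = bg_count.get(m, 0) + 1
        motifs = sorted(m for m, a in fg_count.items() if a >= min_support)
        if not motifs:
            continue
        n_fg, n_bg = len(fg), len(bg)
        N = n_fg + n_bg
        a = np.array([fg_count[m] for m in motifs])
        K = np.array([fg_count[m] + bg_count.get(m, 0) for m in motifs])
        p = stats.hypergeom.sf(a - 1, N, K, n_fg)
        p = np.clip(p, 0.0, 1.0)
        q = multipletests(p, method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "motif": motifs, "k": k, "fg_present": a, "fg_total": n_fg,
            "bg_present": [bg_count.get(m, 0) for m in motifs],
            "bg_total": n_bg, "fg_fraction": a / n_fg, "p": p, "q": q,
        }))
    if not frames:
        return pd.DataFrame(columns=["motif", "k", "fg_present", "fg_total",
                                     "bg_present", "bg_total", "fg_fraction",
                                     "p", "q"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["q", "p", "motif"]).reset_index(drop=True)


def iupac_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile("".join(IUPAC[c] for c in pattern.upper()))
    except KeyError as e:
        raise ValueError(f"invalid IUPAC code: {e.args[0]!r}") from None


def scan_iupac(bins: BinSet, pattern: str) -> tuple[int, float]:
    """Bins with >= 1 match of an IUPAC pattern on either strand.

    Returns (count, fraction of bins); a bin counts once no matter how many
    matches or strands.
    """
    rx = iupac_regex(pattern)
    count = sum(
        1 for seq in bins.sequences
        if rx.search(seq) or rx.search(revcomp(seq))
    )
    return count, count / len(bins) if len(bins) else 0.0
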