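"""Epigenetic metaprofiles around junction positions.

Signal is consumed as 50 bp-binned tracks.  For each anchor position the
window is the 20 track bins spanning [-500, +500) relative to the bin
containing the position (the anchor sits in bin 10), so profiles align to
the track grid.  Cross-site per-bin means give the spatial metaprofile;
per-site window means are the sampling unit for rank-based group
comparisons (Mann-Whitney U) against size-matched random controls.
Windows truncated by chromosome ends contribute their covered bins only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import PROFILE_FLANK, TRACK_BIN, EpigeneticTrack, GenomeAssembly, log
from .io_core import IntervalRecord

N_PROFILE_BINS = 2 * PROFILE_FLANK // TRACK_BIN  # 20


@dataclass
class MetaProfile:
    mark: str
    group: str                  # e.g. unselected | selected | random
    region: str                 # pericentric | distal | all
    offsets: np.ndarray         # left edge of each bin relative to position, bp
    means: np.ndarray           # per-bin cross-site mean
    n_sites: np.ndarray         # sites contributing to each bin


def split_regions(positions: list[tuple[str, int]],
                  pericentric: list[IntervalRecord],
                  ) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Partition positions into (pericentric, distal) by point membership."""
    if not pericentric:
        log.warning("empty pericentric set: all positions classed distal")
        return [], list(positions)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in pericentric:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    peri, distal = [], []
    for chrom, pos in positions:
        inside = any(s <= pos < e for s, e in by_chrom.get(chrom, ()))
        (peri if inside else distal).append((chrom, pos))
    return peri, distal


def _window_matrix(positions: list[tuple[str, int]], track: EpigeneticTrack,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(values, valid) arrays of shape (n_sites, 20) for the profile windows."""
    half = N_PROFILE_BINS // 2
    vals = np.zeros((len(positions), N_PROFILE_BINS))
    valid = np.zeros((len(positions), N_PROFILE_BINS), dtype=bool)
    for i, (chrom, pos) in enumerate(positions):
        tvals = track.values[chrom]
        tcov = track.covered[chrom]
        b0 = pos // track.binsize
        for j in range(N_PROFILE_BINS):
            b = b0 - half + j
            if 0 <= b < len(tvals) and tcov[b]:
                vals[i, j] = tvals[b]
                valid[i, j] = True
    return vals, valid


def metaprofile(positions: list[tuple[str, int]], track: EpigeneticTrack,
                group: str = "unselected", region: str = "all") -> MetaProfile:
    """Per-bin cross-site mean signal in +-500 bp around the positions."""
    if not positions:
        raise ValueError("no positions")
    vals, valid = _window_matrix(positions, track)
    n_sites = valid.sum(axis=0)
    means = np.full(N_PROFILE_BINS, np.nan)
    ok = n_sites > 0
    with np.errstate(invalid="ignore"):
        means[ok] = (vals * valid).sum(axis=0)[ok] / n_sites[ok]
    offsets = (np.arange(N_PROFILE_BINS) - N_PROFILE_BINS // 2) * track.binsize
    return MetaProfile(track.mark, group, region, offsets, means, n_sites)


def site_window_means(positions: list[tuple[str, int]], track: EpigeneticTrack,
                      ) -> np.ndarray:
    """One scalar per site: mean over its covered window bins.

    Sites with zero covered bins are dropped (logged).
    """
    vals, valid = _window_matrix(positions, track)
    nv = valid.sum(axis=1)
    keep = nv > 0
    if (~keep).any():
        log.info("site_window_means: dropped %d site(s) with no covered bins",
                 int((~keep).sum()))
    return (vals[keep] * valid[keep]).sum(axis=1) / nv[keep]


def random_controls(genome: GenomeAssembly, n: int, seed: int,
                    region: str | None = None,
                    pericentric: list[IntervalRecord] | None = None,
                    ) -> list[tuple[str, int]]:
    """Uniform random positions, optionally restricted to a region.

    region=None samples the whole genome; 'pericentric' and 'distal' restrict
    to (the complement of) the pericentric intervals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    territory: list[tuple[str, int, int]] = []
    if region is None:
        territory = [(c, 0, l) for c, l in genome.lengths.items()]
    else:
        if pericentric is None:
            raise ValueError("region-restricted controls need pericentric intervals")
        blocks: dict[str, list[tuple[int, int]]] = {}
        for iv in pericentric:
            blocks.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, clen in genome.lengths.items():
            pb = sorted(blocks.get(chrom, []))
            if region == "pericentric":
                territory += [(chrom, s, e) for s, e in pb]
            elif region == "distal":
                prev = 0
                for s, e in pb:
                    if s > prev:
                        territory.append((chrom, prev, s))
                    prev = e
                if prev < clen:
                    territory.append((chrom, prev, clen))
            else:
                raise ValueError(f"unknown region {region!r}")
    weights = np.array([e - s for _, s, e in territory], dtype=float)
    if len(territory) == 0 or weights.sum() == 0:
        raise ValueError(f"region {region!r} has no territory to sample")
    weights /= weights.sum()
    out = []
    for _ in range(n):
        chrom, s, e = territory[rng.choice(len(territory), p=weights)]
        out.append((chrom, int(rng.integers(s, e))))
    return out


def utest_compare(group_a: np.ndarray, group_b: np.ndarray,
                  alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U between two sets of per-site window means.

    Exact enumeration for untied groups of <= 20; otherwise the normal
    approximation with tie correction.  Identical constant groups give p=1.
    Returns (U for group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 sites")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = len(a) * len(b) / 2
        return float(u), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def profile_table(profiles: list[MetaProfile]) -> pd.DataFrame:
    rows = []
    for pr in profiles:
        for off, mean, n in zip(pr.offsets, pr.means, pr.n_sites):
            rows.append((pr.mark, pr.group, pr.region, int(off), mean, int(n)))
    return pd.DataFrame(rows, columns=["mark", "group", "region",
                                       "offset", "mean", "n_sites"])
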