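"""Junction caller: per-stage exactness, oracle equivalence, mapping soundness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdnajs import (
    GenomeAssembly,
    GenomeIndex,
    LibraryConfig,
    SequencingRead,
    anchor_primer,
    apply_mask,
    build_t0_mask,
    collapse,
    demultiplex,
    map_read,
    quality_filter,
    revcomp,
    run_pipeline,
    select_best,
    subtract_t0,
)
from tdnajs.caller import AnchoredRead, HotspotMask, MappedRead, MappingHit


def mkread(seq, q=30, read_id="r", timepoint=None):
    qual = [q] * len(seq) if isinstance(q, int) else list(q)
    return SequencingRead(read_id, seq, qual, timepoint)


# ---------------------------------------------------------------------------
# quality filter
# ---------------------------------------------------------------------------

class TestQualityFilter:
    def test_all_above_25_kept(self):
        assert len(quality_filter([mkread("ACGT", 30)])) == 1

    def test_single_base_at_25_removed(self):
        r = mkread("ACGT", [30, 25, 30, 30])
        assert quality_filter([r]) == []

    def test_boundary_26_kept(self):
        assert len(quality_filter([mkread("ACGT", 26)])) == 1

    def test_exactly_planted_low_quality_reads_removed(self):
        rng = np.random.default_rng(0)
        reads, bad_ids = [], set()
        for i in range(1000):
            q = rng.integers(26, 41, size=50).tolist()
            if rng.random() < 0.1:
                q[int(rng.integers(50))] = int(rng.integers(0, 26))
                bad_ids.add(f"r{i}")
            reads.append(mkread("A" * 50, q, read_id=f"r{i}"))
        kept = {r.read_id for r in quality_filter(reads)}
        assert kept == {r.read_id for r in reads} - bad_ids


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

class TestDemultiplex:
    def test_barcode_routing(self, tdna):
        reads = [mkread("AGTCAGGGGGGGG", read_id="t6"),   # RRYYRR
                 mkread("ACACACGGGGGGG", read_id="t0"),   # RYRYRY
                 mkread("ACCACCGGGGGGG", read_id="t24"),  # RYYRYY
                 mkread("AAAAAAGGGGGGG", read_id="no")]   # RRRRRR: no pattern
        out, discarded = demultiplex(reads, tdna)
        assert [r.read_id for r in out["T6"]] == ["t6"]
        assert [r.read_id for r in out["T0"]] == ["t0"]
        assert [r.read_id for r in out["T24"]] == ["t24"]
        assert discarded == 1

    def test_barcode_stripped_and_timepoint_set(self, tdna):
        out, _ = demultiplex([mkread("AGTCAGGATTACA")], tdna)
        r = out["T6"][0]
        assert r.seq == "GATTACA" and r.timepoint == "T6"
        assert len(r.qual) == 7

    def test_short_read_discarded(self, tdna):
        out, discarded = demultiplex([mkread("ACG")], tdna)
        assert discarded == 1 and not any(out.values())


# ---------------------------------------------------------------------------
# T0 subtraction
# ---------------------------------------------------------------------------

class TestSubtractT0:
    T0 = [mkread("GATTACAGATTACA", read_id="a"), mkread("CCCCCC", read_id="b")]

    def test_identical_removed(self):
        assert subtract_t0([mkread("GATTACAGATTACA")], self.T0) == []

    def test_one_mismatch_retained(self):
        kept = subtract_t0([mkread("GATTACAGATTACT")], self.T0)
        assert len(kept) == 1

    def test_prefix_and_extension_removed(self):
        assert subtract_t0([mkread("GATTACA")], self.T0) == []       # prefix
        assert subtract_t0([mkread("CCCCCCAAA")], self.T0) == []     # extension

    def test_custom_matcher_hook(self):
        kept = subtract_t0([mkread("TTTT")], self.T0,
                           matcher=lambda seq, t0: True)
        assert kept == []

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.text(alphabet="AC", min_size=1, max_size=8),
                    min_size=0, max_size=8),
           st.lists(st.text(alphabet="AC", min_size=1, max_size=8),
                    min_size=0, max_size=8))
    def test_matches_quadratic_containment_oracle(self, t0_seqs, t_seqs):
        t0 = [mkread(s, read_id=f"t0{i}") for i, s in enumerate(t0_seqs)]
        t = [mkread(s, read_id=f"t{i}") for i, s in enumerate(t_seqs)]
        kept = {r.read_id for r in subtract_t0(t, t0)}
        expect = {r.read_id for r in t
                  if not any(r.seq.startswith(s) or s.startswith(r.seq)
                             for s in t0_seqs)}
        assert kept == expect


# ---------------------------------------------------------------------------
# primer anchoring
# ---------------------------------------------------------------------------

class TestAnchorPrimer:
    def test_minus11_read_accepted(self, tdna):
        genomic = "ACGT" * 10
        read = mkread(tdna.primer_plus4("-11") + genomic, timepoint="T6")
        a = anchor_primer(read, tdna)
        assert a is not None and a.primer == "-11" and a.portion == genomic

    def test_mismatch_in_lb_bases_rejected(self, tdna):
        anchor = tdna.primer_plus4("-11")
        mutated = anchor[:-1] + ("A" if anchor[-1] != "A" else "C")
        assert anchor_primer(mkread(mutated + "ACGT" * 10), tdna) is None

    def test_furthest_3prime_match_wins(self, tdna):
        # an untruncated -70-primed amplicon contains the -11 anchor further 3'
        oligo70 = tdna.primers["-70"][0]
        L = len(tdna.lb_seq)
        read_body = oligo70 + tdna.lb_seq[L - 70 + 1:] + "ACGT" * 10
        a = anchor_primer(mkread(read_body), tdna)
        assert a is not None and a.primer == "-11"

    def test_no_primer_rejected(self, tdna):
        assert anchor_primer(mkread("ACGT" * 20), tdna) is None

    def test_short_genomic_portion_rejected(self, tdna):
        read = mkread(tdna.primer_plus4("-30") + "ACGTACGTACGT")  # 12 < 22
        assert anchor_primer(read, tdna) is None


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=20_000))
    return GenomeAssembly({"c1": seq, "c2": seq[:5000] + "N" * 0 + seq[10_000:15_000]})


@pytest.fixture(scope="module")
def toy_index(toy_genome):
    return GenomeIndex(toy_genome, k=22)


class TestMapRead:
    def test_unique_forward_hit_gives_junction_coordinate(self, toy_genome,
                                                          toy_index):
        portion = toy_genome["c1"][5000:5040]
        hits = map_read(AnchoredRead("r", "T6", "-11", portion), toy_index)
        best = [h for h in hits if h.score == 40]
        assert MappingHit("c1", 5000, "+", 40) in best

    def test_reverse_hit_coordinates(self, toy_genome, toy_index):
        # junction at c1:8039 read leftward: portion = revcomp(c1[8000:8040])
        portion = revcomp(toy_genome["c1"][8000:8040])
        hits = map_read(AnchoredRead("r", "T6", "-11", portion), toy_index)
        assert any(h.chrom == "c1" and h.pos == 8039 and h.orient == "-"
                   and h.score == 40 for h in hits)

    def test_two_loci_scores_40_and_22(self):
        rng = np.random.default_rng(7)
        insert = "".join(rng.choice(list("ACGT"), size=40))
        filler = "".join(rng.choice(list("ACGT"), size=3000))
        # full 40-mer at 500; only its 3'-terminal 22-mer at 2000
        seq = (filler[:500] + insert + filler[500:2000] + insert[18:]
               + filler[2000:])
        genome = GenomeAssembly({"c1": seq})
        index = GenomeIndex(genome, k=22)
        hits = map_read(AnchoredRead("r", "T6", "-11", insert), index)
        scores = sorted(h.score for h in hits)
        assert scores == [22, 40]

    def test_absent_portion_no_hits(self, toy_index):
        hits = map_read(AnchoredRead("r", "T6", "-11", "A" * 30), toy_index)
        assert hits == []

    def test_lb_tail_does_not_shift_coordinate_much(self, toy_genome,
                                                    toy_index):
        # a 6 nt LB tail 5' of the genomic part stops the extension near
        # the true junction
        genomic = toy_genome["c1"][3000:3030]
        portion = "GGCGCA" + genomic
        hits = map_read(AnchoredRead("r", "T6", "-11", portion), toy_index)
        best = max(hits, key=lambda h: h.score)
        assert best.chrom == "c1" and abs(best.pos - 3000) <= 6


class TestSelectBest:
    ORDER = ["c1", "c2"]

    def test_highest_score_wins(self):
        hits = [MappingHit("c1", 100, "+", 40), MappingHit("c2", 50, "+", 22)]
        assert select_best(hits, self.ORDER).score == 40

    def test_tie_broken_by_chrom_order_then_coordinate(self):
        hits = [MappingHit("c2", 50, "+", 30), MappingHit("c1", 100, "+", 30)]
        assert select_best(hits, self.ORDER).chrom == "c1"
        hits = [MappingHit("c1", 200, "+", 30), MappingHit("c1", 100, "-", 30)]
        assert select_best(hits, self.ORDER).pos == 100

    def test_single_hit_identity(self):
        h = MappingHit("c1", 5, "+", 25)
        assert select_best([h], self.ORDER) is h

    def test_excess_equal_hits_discarded(self):
        hits = [MappingHit("c1", i, "+", 30) for i in range(6)]
        assert select_best(hits, self.ORDER, max_equal_hits=5) is None


# ---------------------------------------------------------------------------
# collapsing: examples + oracle equivalence
# ---------------------------------------------------------------------------

def collapse_positions(positions, window=10):
    ms = [MappedRead(f"r{i}", "T6", "-11", "c1", p, "+")
          for i, p in enumerate(positions)]
    return sorted(c.pos for c in collapse(ms, window))


def brute_force_collapse(positions, window=10):
    """Independent restatement: repeatedly open a cluster at the smallest
    remaining position and absorb everything within the window of it."""
    remaining = sorted(positions)
    anchors = []
    while remaining:
        anchor = remaining[0]
        anchors.append(anchor)
        remaining = [p for p in remaining if p - anchor > window]
    return anchors


class TestCollapse:
    @pytest.mark.parametrize("positions,expected", [
        ([1000, 1005], [1000]),
        ([1000, 1011], [1000, 1011]),
        ([1000, 1005, 1012], [1000, 1012]),
    ])
    def test_published_collapse_rule(self, positions, expected):
        assert collapse_positions(positions) == expected

    def test_counts_and_orientation(self):
        ms = [MappedRead("r1", "T6", "-11", "c1", 1000, "+"),
              MappedRead("r2", "T6", "-11", "c1", 1005, "-"),
              MappedRead("r3", "T6", "-11", "c1", 1005, "-")]
        (call,) = collapse(ms)
        assert call.n_reads == 3 and call.n_positions == 2
        assert call.orient == "-"

    def test_groups_do_not_mix(self):
        ms = [MappedRead("r1", "T6", "-11", "c1", 1000, "+"),
              MappedRead("r2", "T6", "-30", "c1", 1005, "+"),
              MappedRead("r3", "T24", "-11", "c1", 1005, "+")]
        assert len(collapse(ms)) == 3

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=100))
    def test_matches_brute_force_oracle(self, positions):
        assert collapse_positions(positions) == brute_force_collapse(positions)

    def test_oracle_equivalence_200_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(1, 501))
            positions = rng.integers(0, 20_000, size=n).tolist()
            assert collapse_positions(positions) == brute_force_collapse(positions)


# ---------------------------------------------------------------------------
# T0 mask: examples + oracle equivalence
# ---------------------------------------------------------------------------

def mask_from_counts(counts):
    """Build a mask from explicit per-bin counts on one chromosome."""
    genome = GenomeAssembly({"c1": "A" * (400 * len(counts))})
    positions = [("c1", 400 * b + 1) for b, c in enumerate(counts)
                 for _ in range(c)]
    return build_t0_mask(positions, genome)


def brute_force_mask(counts):
    mean = sum(counts) / len(counts)
    sd = (sum((c - mean) ** 2 for c in counts) / len(counts)) ** 0.5
    return {("c1", b) for b, c in enumerate(counts) if c > mean + 2 * sd}


class TestT0Mask:
    def test_threshold_is_strict(self):
        # counts {1,1,1,1,6}: mean 2, SD 2, threshold exactly 6 -> no mask.
        # (For any counts {1,1,1,1,x} the threshold is exactly x, so the
        # strict inequality never masks this family.)
        assert mask_from_counts([1, 1, 1, 1, 6]).bins == set()
        # counts {1,1,1,1,1,7}: mean 2, SD sqrt(5), threshold ~6.47 -> masked
        m = mask_from_counts([1, 1, 1, 1, 1, 7])
        assert m.bins == {("c1", 5)}

    def test_constant_counts_mask_nothing(self):
        assert mask_from_counts([3, 3, 3, 3]).bins == set()

    def test_no_t0_reads_empty_mask(self):
        genome = GenomeAssembly({"c1": "A" * 4000})
        assert build_t0_mask([], genome).bins == set()

    def test_audit_fields_recorded(self):
        m = mask_from_counts([1, 1, 1, 1, 7])
        assert m.mean == pytest.approx(2.2)
        assert m.threshold == pytest.approx(m.mean + 2 * m.sd)
        assert m.bin_width == 400 and m.sd_divisor == "N"

    def test_oracle_equivalence_200_random_instances(self):
        rng = np.random.default_rng(321)
        for _ in range(200):
            nbins = int(rng.integers(2, 60))
            counts = rng.poisson(rng.uniform(0.1, 5), size=nbins).tolist()
            assert mask_from_counts(counts).bins == brute_force_mask(counts)

    def test_zero_bins_included_in_statistics(self):
        # a single loaded bin among many zeros is masked because the zeros
        # drag the mean and SD down
        m = mask_from_counts([0] * 50 + [5])
        assert ("c1", 50) in m.bins


class TestApplyMask:
    MASK = HotspotMask({("c1", 2)}, 1.0, 0.0, 0.0)

    def mkcall(self, pos):
        from tdnajs.caller import JunctionCall
        return JunctionCall("c1", pos, "+", "-11", "T6", 1, 1)

    def test_call_in_masked_bin_removed(self):
        assert apply_mask([self.mkcall(803)], self.MASK) == []

    def test_bin_boundary_half_open(self):
        assert apply_mask([self.mkcall(800)], self.MASK) == []     # in bin 2
        assert len(apply_mask([self.mkcall(1200)], self.MASK)) == 1  # bin 3

    def test_empty_mask_is_identity(self):
        calls = [self.mkcall(803)]
        empty = HotspotMask(set(), 1.0, 0.0, 0.0)
        assert apply_mask(calls, empty) == calls


# ---------------------------------------------------------------------------
# whole pipeline
# ---------------------------------------------------------------------------

class TestRunPipeline:
    def test_counts_monotone_and_qc_consistent(self, big_run, big_sim):
        qc = big_run["qc"]["stages"]
        n_raw = sum(qc["raw"].values())
        assert qc["quality_filter"]["total"] <= n_raw
        n_demux = sum(v for k, v in qc["demultiplex"].items() if k != "discarded")
        assert n_demux + qc["demultiplex"]["discarded"] == \
            qc["quality_filter"]["total"]
        for tp in ("T6", "T24"):
            assert qc["subtract_t0"][tp] <= qc["demultiplex"][tp]
            assert qc["mapped"][tp] <= qc["subtract_t0"][tp]

    def test_empty_t6_t24_gives_empty_table(self, small_world, tdna):
        table, qc = run_pipeline({"T0": [], "T6": [], "T24": []},
                                 small_world["genome"], tdna)
        assert len(table) == 0
        assert "stages" in qc

    def test_rerun_same_inputs_identical(self, small_world, tdna, library):
        t1, _ = run_pipeline(library["reads"], small_world["genome"], tdna)
        t2, _ = run_pipeline(library["reads"], small_world["genome"], tdna)
        assert t1.equals(t2)

    def test_per_chromosome_call_fractions_match_lengths(self, big_run,
                                                         big_sim):
        """Uniform simulation: chr1/chr2 call split within the multinomial
        99% CI of the length split (both chromosomes are 1 Mb)."""
        table = big_run["table"]
        n = len(table)
        k = (table.chrom == "chr1").sum()
        se = (0.5 * 0.5 / n) ** 0.5
        assert abs(k / n - 0.5) < 2.576 * se + 1e-9


@pytest.fixture(scope="module")
def library(small_world, tdna):
    from tdnajs import simulate_junctions, simulate_library
    juncs = simulate_junctions(small_world["genome"], small_world["features"],
                               small_world["tracks"], 150, seed=77)
    reads, _ = simulate_library(small_world["genome"], juncs, tdna,
                                LibraryConfig(seed=78))
    return {"reads": reads}
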