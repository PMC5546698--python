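# Methods

This note records the models behind `tdnajs`, the defaults and why they were
chosen, and what the synthetic data does and does not emulate.

## The assay being modelled

Adapter-ligation-mediated PCR recovers T-DNA left-border (LB) junctions:
genomic DNA is digested with EcoRI, HindIII and XbaI, adapters are ligated
to the cut ends, and fragments spanning a T-DNA–genome junction are
amplified between a nested LB primer and an adapter primer, then sequenced
as 100 bp reads. Three nested primers with 3′ ends at −11, −30 and −70 bp
from the LB cleavage terminus cover junctions in which up to ~65 bp of the
border was chewed back during integration. A 6 nt purine/pyrimidine barcode
ahead of the primer encodes the timepoint (RYRYRY = T0 mock, RRYYRR = 6 h,
RYYRYY = 24 h). The T0 sample, extracted before integration can occur,
defines the artifact background.

## T-DNA model

The LB-proximal T-DNA sequence is synthetic: 120 nt of random sequence with
the three published primer oligos written at their stated offsets. The
printed −30 and −11 oligos overlap (positions −37..−30) with incompatible
sequence, so no single template can contain both verbatim; the
border-proximal primer wins the overlap, making the −11 and −70 oligos exact
substrings while the last 8 bases of the −30 site are shadowed. Reads primed
with the −30 oligo still carry its full printed sequence — as a real PCR
product would — so exact primer+4 anchoring remains consistent throughout.
The −11 primer ends in the hexamer CACCAC used as the microhomology probe.

## Synthetic data

**Genome.** i.i.d. bases at GC 0.36 (Arabidopsis-like); default two 1 Mb
chromosomes, each with a central pericentric block covering 8.3% of its
length. Genes (200/Mb, ~2 kb) are placed in distal territory, transposable
elements (120/Mb, ~700 bp) with half their number inside pericentric blocks,
all non-overlapping by rejection sampling; each gene gets a fixed-length
promoter (1 kb) immediately upstream on its strand. The fixed-length
promoter is a modelling convention — annotation sets rarely define promoters
— and is configurable.

**Tracks** are 50 bp-binned, non-negative, with Gaussian noise (SD 0.02):
methylation = 0.05 baseline, +0.5 in TE bins, +0.3 in pericentric bins;
nucleosome occupancy = 1.0 baseline, +0.3 pericentric, −0.6 in promoters;
H3K27me3 = 0.1 baseline with 30 islands of 2 kb at amplitude 1.0 placed in
distal territory only — the "heterochromatin islands embedded in
euchromatin" structure whose association with junctions the metaprofiles are
designed to detect.

**Junctions.** Coordinates are uniform, island-biased (a weight `w`,
default 0.5, drawn uniformly from within H3K27me3 islands) or
open-chromatin-biased (drawn from low-nucleosome, unmethylated promoter
bins). Truncation lengths are uniform on 0–65 nt: the real truncation
distribution is not known, only that the assay recovers at most ~65 bp of
border loss, so the simulator stays uniform within the recoverable range. A
microhomology fraction (default 0.25, matching the observed share of
CACCAC-bearing junction bins) is placed so the six genomic bases on the
T-DNA side of the junction equal CACCAC, drawn from hexamer occurrences
inside the junction's placement stratum so bias invariants survive.

**Library.** Each amplifiable junction emits 1 + Poisson(duplicate mean − 1)
reads (default mean 3). The genomic flank runs in the junction's orientation
and stops before the first restriction-site occurrence and at the read
length; cut-end geometry is dropped because the caller never uses it. A
junction amplifies only if its distance to the nearest site lies in the
fragment window 50–500 bp, matching the amplicon smear the assay produces;
junctions outside the window appear in the ground truth with zero reads.
This window is what couples detected junctions to nearby restriction sites
and makes GAATTC/AAGCTT/TCTAGA genuine positive-control motifs. 10% of reads
receive one base at quality ≤ 25. T0 consists of artifact reads: 20 hotspot
loci each emitting Poisson(30) identical mis-primed reads (primer + 4 LB
bases followed by genomic sequence), plus a uniform rain of 100 reads;
copies of the hotspot artifacts contaminate T6/T24 at 5% of their read
count, so both T0 subtraction and T0 bin masking have real work to do.

## Caller conventions

* Coordinates are 0-based half-open everywhere internally; the junction
  coordinate is the first genomic base adjacent to T-DNA sequence.
* "Phred above 25" is read literally: keep iff min quality ≥ 26.
* T0 subtraction is exact containment (identity, prefix or extension),
  implemented with a trie; the published analysis used a clustering tool
  whose identity threshold is not stated, so the deterministic rule is the
  default and a matcher hook is exposed for threshold-based variants.
* Anchoring requires an exact primer + 4 LB-base occurrence; when several
  primers match, the match extending furthest 3′ wins. The portion after the
  anchor may begin with residual LB bases; mapping tolerates this because
  only the 3′-terminal 22 bases must match the genome.
* Mapping is exact-match with a sorted 22-mer index over both strands,
  extended 5′-ward while identity holds. The matched length stands in for an
  alignment bit score (it is a monotone surrogate on ungapped exact
  extensions); ties go to the lowest (chromosome order, coordinate), and
  reads whose best score is shared by more than 5 loci are discarded as
  unmappable.
* Collapsing is anchor-based greedy clustering on sorted positions within
  ±10 bp per (primer, timepoint, chromosome) — deterministic and immune to
  the unbounded chaining that single-linkage would allow. Orientation is
  ignored during clustering and reported as the cluster majority.
* The T0 mask thresholds per-400 bp-bin T0 counts at mean + 2 × population
  SD computed over all genome bins, zero bins included, masking bins
  strictly above threshold. Note the boundary family: for counts
  {1,1,1,1,x} the threshold is exactly x, so strictly-above masks nothing
  there; the threshold and SD convention are recorded in the mask object for
  audit.

## Feature association

A position gets one class under the precedence TE > promoter > gene
(configurable); TE annotations are the most specific so they win overlaps.
Genome fractions are base-pair weighted after flattening under the same
precedence, making junction and genome fractions directly comparable.
Comparisons between two junction sets use a 2×K Pearson χ² on class counts
without continuity correction; one set against the genome uses a
goodness-of-fit test against base-pair fractions.

## Motif enrichment

PWM discovery tools are deliberately not reimplemented. The statistic is
presence/absence per 400 bp bin — matching how the headline number ("present
in 25 percent of the input sequences") is expressed — on both strands:
foreground = complete bins containing ≥ 1 junction, background = bins
sampled without replacement outside the foreground (default 10× foreground;
`None` takes every remaining bin, the right choice on small genomes and the
analogue of testing against the whole genome). Each k-mer seen in ≥ 5
foreground bins gets a hypergeometric upper-tail p on the pooled urn and a
Benjamini–Hochberg q within its k.

Power note: with the fragment window active, each foreground bin carries a
guaranteed site-free stretch next to its junction, which depletes baseline
site presence and leaves a net per-enzyme presence excess of only ~0.07. At
a few hundred foreground bins that is a z of ~2.4 — too weak for a stable
rank — so the restriction-site positive control is evaluated on a run at the
published junction-set scale (2,500 junctions, ~650 foreground bins, z ≈ 5),
where all three enzyme motifs rank in the top 0.2% of 6-mers.

## Epigenetic metaprofiles

Windows are the 20 track bins spanning [−500, +500) around the bin
containing each position (the anchor sits at the bin-10 left edge), so
profiles align with the 50 bp track grid. Spatial profiles are per-bin
cross-site means; group comparisons use one scalar per site (the mean over
its covered window bins) as the Mann-Whitney sampling unit — the per-site
mean is the natural reading of "mean values 500 bp up- and downstream of
each site", and a per-site unit keeps the test's independence assumption
honest. Windows truncated by chromosome ends contribute covered bins only
(dropping the site instead is available); uncovered track bins are excluded
from means rather than read as zero. U tests are exact for untied groups of
≤ 20, otherwise normal approximation with tie correction; two identical
constant groups give p = 1 by convention. Random controls are uniform,
size-matched, and restrictable to pericentric or distal territory.

## Problem sizes and determinism

The standard demonstration uses a 2 Mb genome with 500 junctions (~150
amplified) for calling accuracy, 2,500 junctions for the motif control, and
1,000 island-biased junctions for the epigenetic contrast — sizes at which
every statistical property tested has comfortable power while the whole
suite runs in well under a minute per stage. All generators take explicit
seeds; `run-all` derives per-stage seeds from one master seed and writes a
manifest of SHA-256 checksums, and two runs with the same seed are
byte-identical.

## Known limitations

* The genome is i.i.d. random: no repeat families, so multi-mapping reads
  are rare and the >5-equal-hits discard path is exercised only lightly.
* Amplification is binary inside the fragment window; real PCR efficiency
  decays continuously with length and varies between junctions beyond the
  Poisson duplicate model.
* LB truncation is uniform by construction, not estimated from data.
* Right-border junctions, concatamers, gapped or mismatch-tolerant
  alignment, and methylation-context separation (CG vs CHG/CHH) are out of
  scope; tracks are in arbitrary units.
* Passing tests demonstrate correctness of the algorithms under the
  generative model above, not performance on real libraries with adapter
  chimeras, sequencing error, or structural variation.
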