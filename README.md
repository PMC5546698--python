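# tdnajs — selection-free T-DNA–genome junction analysis

*Agrobacterium tumefaciens* inserts a T-DNA segment into plant genomes, and
where it lands — genes, promoters, transposons, heterochromatin — has been
argued over for decades because most insertion maps come from
antibiotic-selected transformants, which only survive if the marker is
expressed. `tdnajs` re-implements, as a tested and reusable pipeline, the
selection-free alternative: adapter-ligation-mediated PCR libraries of
left-border (LB) junction amplicons are sequenced shortly after infection,
and junctions are called directly from reads, with a mock time-zero (T0)
infection supplying the background model. The package is aimed at people
building or stress-testing integration-site callers (T-DNA, transposon or
viral): every input is synthetic and seeded, so the whole analysis runs on a
laptop with known ground truth.

## What the pipeline does

**Library model** (`synthdata`). Junction reads have the layout

```
barcode(6 nt, purine/pyrimidine code) + nested LB primer (-11/-30/-70)
  + remaining LB bases down to the border truncation point
  + genomic flank, ending before the first EcoRI/HindIII/XbaI site
```

with PCR duplicates, per-base qualities, LB truncations of 0–65 nt, optional
LB-hexamer (CACCAC) microhomology at the junction, and a T0 timepoint made
only of artifact reads concentrated at hotspot loci. Junctions whose
distance to the nearest restriction site falls outside the amplifiable
fragment window (50–500 bp) emit no reads, which is what makes the
restriction sites a built-in positive control for the motif analysis.

**Junction caller** (`caller`), stage by stage:

1. keep reads with every base strictly above Phred 25;
2. demultiplex on the 6 nt purine/pyrimidine barcode (RYRYRY = T0,
   RRYYRR = T6, RYYRYY = T24);
3. remove T6/T24 reads whose sequence matches a T0 read;
4. anchor each read at an exact primer + 4 LB-base occurrence;
5. map the remainder by exact match: the 3′-terminal 22-mer must occur
   verbatim in the genome, extended 5′-ward while identity holds; the best
   (longest) hit wins;
6. collapse positions within ±10 bp from the same primer into one call;
7. mask 400 bp bins whose T0 read count exceeds mean + 2 SD.

**Downstream analyses**: feature-class fractions (TE / promoter / gene /
other, base-pair weighted, χ² comparisons), pericentric share and density
tracks (`features`); presence/absence k-mer enrichment in 400 bp junction
bins against sampled background bins, hypergeometric tails with
Benjamini–Hochberg correction (`motifs`); 50 bp-binned metaprofiles of CG
methylation, nucleosome occupancy and H3K27me3 in ±500 bp windows,
pericentric/distal split, Mann-Whitney U tests against size-matched random
controls (`epiprofiles`).

## Worked example

```python
from tdnajs import (GenomeConfig, LibraryConfig, TrackConfig, default_tdna,
                    generate_genome, generate_tracks, simulate_junctions,
                    simulate_library, run_pipeline, pericentric_share)
from tdnajs.caller import position_match_fraction

genome, features = generate_genome(GenomeConfig(seed=1))        # 2 x 1 Mb
tracks = generate_tracks(genome, features, TrackConfig(seed=2))
junctions = simulate_junctions(genome, features, tracks, 500, seed=3)
reads, truth = simulate_library(genome, junctions, default_tdna(),
                                LibraryConfig(seed=4))
table, qc = run_pipeline(reads, genome, default_tdna())

emitted = truth[truth.n_reads > 0]
calls = list(zip(table.chrom, table.pos))
print(f"amplified junctions: {len(emitted)}   calls: {len(table)}")
print(f"recall:    {position_match_fraction(list(zip(emitted.chrom, emitted.pos0)), calls):.3f}")
print(f"precision: {position_match_fraction(calls, list(zip(emitted.chrom, emitted.pos0))):.3f}")
share, gfrac = pericentric_share(calls, features, genome)
print(f"pericentric share of calls: {100*share:.1f}%  (genome: {100*gfrac:.1f}%)")
print(f"masked T0 hotspot bins: {qc['stages']['mask']['masked_bins']}")
```

prints

```
amplified junctions: 157   calls: 151
recall:    0.968
precision: 1.000
pericentric share of calls: 9.9%  (genome: 8.3%)
masked T0 hotspot bins: 19
```

Of 500 planted junctions, 157 fall inside the amplifiable fragment window
and emit reads; the caller recovers 96.8% of them at ±10 bp with no false
calls, the pericentric share of calls matches the pericentric genome
fraction (uniform placement), and 19 of the 20 planted artifact hotspots end
up masked (one collides with another bin's territory).

The same chain is available from the shell:

```bash
tdnajs simulate --outdir sim --seed 1 --n-junctions 500
tdnajs call --genome sim/genome.fa --fastq T0=sim/T0.fastq \
    --fastq T6=sim/T6.fastq --fastq T24=sim/T24.fastq \
    --out calls.tsv --qc qc.json
tdnajs run-all --outdir run --seed 1     # everything + manifest.json
```

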