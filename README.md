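# norgscan

Detection and comparative analysis of nuclear organellar DNA — NUMTs
(nuclear copies of mitochondrial DNA) and NUPTs (nuclear copies of plastid
DNA).

Fragments of organellar genomes are continually copied into nuclear
genomes by endosymbiotic DNA transfer. Quantifying them across species
requires three steps that are easy to get subtly wrong: finding the
fragments by local alignment, counting each nuclear insertion event
**once** even when several organellar regions match it, and comparing
abundances across species while respecting shared phylogeny. `norgscan`
implements all three for researchers studying organellar DNA transfer,
genome evolution, or any trait hypothesised to covary with it, and ships a
synthetic-data generator with planted ground truth so every step is
testable end to end.

## What it computes

**Detection.** Organellar queries are searched against nuclear assemblies
with a self-contained seed-and-extend aligner (match +2, mismatch −3, gap
5/2, word size 11) retaining hits with Karlin–Altschul
E = K·m·n·e^(−λS) ≤ 10⁻⁴. Short nuclear contigs (≤ 10 kb) almost fully
covered by organellar matches (≥ 95%) are discarded as assembly
contamination. Pre-computed 12-column hit tables from an external search
tool are a drop-in replacement (`--hits`).

**Counting.** Overlapping hit intervals on the same nuclear sequence are
unioned into segments: if mitochondrial regions M₁ and M₂ both match the
same nuclear locus N₂, that locus counts once — M₁→N₁, M₁→N₂, M₂→N₂,
M₂→N₃, M₂→N₄ yield four NUMTs, not five. Summaries report counts, total
lengths, and per-Mb densities, plus per-feature-class tallies (CDS, tRNA,
rRNA) and identity histograms.

**Comparative statistics.** Paired lineage designs are tested with exact
two-tailed Wilcoxon signed-rank tests (full sign-assignment distribution
for n ≤ 25 without ties); abundance vs assembly level uses phylogenetic
generalized least squares with Pagel's λ estimated by maximum likelihood
(error covariance σ²·V(λ); λ = 0 reduces to OLS); abundance vs genome size
uses Spearman rank correlation.

## Worked example

Simulate a genome with planted insertions and detect them:

```sh
norgscan simulate --preset detection --seed 5 --out sim \
    --nuclear-size 200000 --n-insertions 8
norgscan detect --nuclear sim/nuclear.fasta \
    --organelle sim/mitochondrion.fasta --gff sim/mitochondrion.gff3 \
    --kind mito --species synthetic --out-prefix det/run
```

which logs each filtering stage and prints the summary line
`NUMT  8  7701` — the 8 planted insertions recovered as 8 deduplicated
NUMT segments totalling 7,701 bp, after the two planted contaminant
contigs were flagged and removed:

```
INFO norgscan: internal search found 10 hits (E <= 0.0001)
INFO norgscan: contamination filter: 2 sequence(s) flagged, 2 hit(s) removed
INFO norgscan: deduplicated 8 hits into 8 NUMT segment(s)
```

Outputs: segments as BED and TSV, a content summary (count, total length,
count/Mb, length/Mb), per-feature-class tallies, an identity histogram,
the contamination report, and a JSON run manifest (config snapshot, input
checksums, per-stage counts) whose reruns are byte-identical.

The same library surface is scripted in `analysis/01...04`, which
simulate inputs (into `scratch/data/`), run detection, and produce the
paired-comparison and PGLS tables under `results/`. For example,
`analysis/02_detect_norgs.py` prints:

```
detection: 20 NUMT segments, 25161 bp total (40.0 per Mb)
recovery vs truth: recall 1.000, per-base precision 0.9995, 14/20 with exact boundaries
```

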