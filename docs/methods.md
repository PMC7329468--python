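# Methods

`norgscan` quantifies endosymbiotic DNA transfer: it detects nuclear copies
of organellar DNA (NUMTs from mitochondria, NUPTs from plastids) in genome
assemblies, deduplicates them into countable segments, and provides the
comparative statistics used to relate their abundance to assembly quality,
genome size, and paired lineage designs. This note documents the models,
the defaults and why they are what they are, the synthetic-data generator,
and the numerical choices.

## Detection model

Organellar genomes are used as queries in a local-alignment search against
every nuclear sequence. The scoring configuration mirrors a standard
nucleotide megablast setup: match +2, mismatch −3, gap existence 5, gap
extension 2 (a gap of length *g* costs 5 + 2·*g*; a configuration flag
switches to the 5 + 2·(*g*−1) convention), word size 11, and an E-value
cutoff of 10⁻⁴. Hits are found by exact 11-mer seeding, ungapped X-drop
extension (X = 20 score units), and banded affine-gap refinement around the
seed diagonal (band half-width 16, widened and re-run whenever the optimum
touches the window edge). Both subject strands are searched; circular
organellar queries are logically doubled, hits starting in the second copy
are discarded, and query coordinates are reported modulo the genome length
so origin-spanning insertions are captured once.

Significance uses Karlin–Altschul statistics, E = K·m·n·e^(−λS), with m and
n the raw query and subject lengths (no edge-effect correction). λ is the
unique positive root of Σᵢⱼ pᵢpⱼ·e^(λ·sᵢⱼ) = 1, solved by bisection to
1e-12; K uses the classical lattice-case series
K = δλ·e^(−2σ)/(H·(1−e^(−λδ))) with
σ = Σₖ (1/k)[P(Sₖ ≥ 0) + E(e^(λSₖ); Sₖ < 0)], truncated when a term falls
below 1e-12 (at most 80 convolutions of the per-column score distribution).
For match/mismatch +1/−2 on uniform composition this reproduces the
published ungapped constants (λ ≈ 1.33, K ≈ 0.62). The gapped search reuses
the ungapped parameters — an approximation, but one applied uniformly, so
every retained hit is judged by the same internally consistent yardstick.
N residues are universal mismatches, which prevents N-runs from inflating
hits. A DUST-style low-complexity filter is exposed as a configuration
placeholder but not implemented.

An exact affine-gap Smith–Waterman with deterministic tie-breaking (lowest
subject start, then query start) is included purely as an oracle: on seeded
instances the heuristic's best score must equal the exact optimum, and the
test suite verifies this on random planted pairs, with the oracle itself
cross-checked against an independent implementation (biotite).

## Contamination filter

Organellar reads misassembled into the nuclear assembly masquerade as
enormous insertions. A nuclear sequence is discarded when **both** hold:
length ≤ 10 kb and organellar-hit coverage (union, not sum) ≥ 95% of the
sequence. Both thresholds are configurable; the source procedure leaves
"short" and "completely matched" unquantified, so the defaults make the
rule explicit and tunable. Flagged sequence length is subtracted from the
genome size used for per-Mb densities; densities otherwise use the total
assembly length including N runs, which is what is recoverable from public
assemblies.

## Deduplication into segments

The counting unit is the nuclear interval, not the alignment: when two
different organellar regions match the same nuclear locus, that locus arose
from a single insertion event and counts once. Retained hits are grouped
per nuclear sequence and their subject intervals unioned; intervals that
overlap or are book-ended (zero bases between them) merge, matching the
per-base-coverage view of the genome and the default behaviour of
`bedtools merge`; a configurable `merge_gap` additionally joins intervals
separated by at most that many bases (default 0). Each segment records its
contributing hits and the maximum identity among them. Segment counts,
total lengths (reported in bp, and as half-up-rounded kb in human-readable
output), and per-Mb densities summarise each species × organelle kind.

Nuclear regions matched by both organelle kinds ("promiscuous" DNA, in
plants) have no published partition rule; the package assigns the kind of
the higher-bitscore hit and can report the ambiguous pairs. Segments are
attributed to organellar feature classes (CDS, tRNA, rRNA) when any
contributing hit's query interval overlaps such a feature by ≥ 1 bp; a
segment may carry several classes, and unannotated overlap yields `other`.

## Comparative layer

**Lineage averaging.** In the paired design (desiccation-tolerant lineage
vs closest desiccation-sensitive relative), a lineage represented by two
species contributes the arithmetic mean of their metrics; single species
pass through.

**Wilcoxon signed-rank.** Two-tailed, on four metrics (count, total length,
and both per Mb). Zero differences are dropped (Wilcoxon's original
treatment); W = min(positive-rank sum, negative-rank sum) over mid-ranks.
The p-value is exact — the full sign-assignment distribution — when the
effective n ≤ 25 and |differences| are tie-free, otherwise a normal
approximation with tie and continuity corrections. The exact path is
verified against full 2ⁿ enumeration for all n ≤ 12, and its type-I error
is calibrated by simulation at the study's design size of 24 pairs.
Subgroup reruns (taxonomic groups, genome-size halves) reuse the same test.

**PGLS with Pagel's λ.** The trait–predictor regression assumes errors with
covariance σ²·V(λ), where V[i,j] is the shared root-to-tip path length of
tips i and j and λ multiplies the off-diagonal entries. λ = 0 recovers OLS;
a star phylogeny is OLS for every λ (both asserted to 1e-8 in tests). λ is
estimated by maximum likelihood — profiled on a 0.01 grid over [0, 1] plus
golden-section refinement, so the reported λ is a global grid maximum —
with REML deliberately not the default (ML is the common default of the
comparative packages of the era this analysis style comes from). The slope
p-value uses a t distribution with n − 2 degrees of freedom regardless of λ
being estimated (standard PGLS practice; a known anticonservative caveat),
and R² = 1 − RSS/TSS is computed in the V(λ)^(−1/2)-whitened space against
the GLS intercept-only model. Abundances enter untransformed by default;
`log10(1+y)` is available because count data are skewed. Near-singular
V(λ) (duplicated tips) receives a 1e-10-relative jitter before Cholesky.

**Assembly-level codes.** Scheme 1: contig → 1, scaffold/chromosome/
complete → 2. Scheme 2: scaffold → 3, chromosome/complete → 4, contig-level
species excluded. A species contributing both NUMT and NUPT data enters as
two observations (never a combined one); its tip is duplicated in V with a
negligible (1e-8) separating branch so the covariance stays nonsingular.

**Spearman.** ρ is the Pearson correlation of mid-ranked vectors; p by full
permutation enumeration for n ≤ 9, else the t approximation.

## Synthetic data

The generator produces every input with known truth. Organellar genomes are
i.i.d. sequences at a chosen GC with disjoint CDS/tRNA/rRNA features at
typical organellar gene sizes (CDS 300–1500 bp, tRNA 70–90 bp, rRNA
900–1600 bp), placed longest-first. Insertions are random organellar
substrings replacing a background slice, mutated by per-site substitutions
at rate (100 − identity)/100 with a 2:1 transition:transversion ratio
(indels off by default), in random orientation. Truth records store both
the target and the realised identity, and the realised value is exactly
recomputable from the emitted sequences.

Two placement rules keep truth-to-segment accounting one-to-one. First,
insertions keep ≥ word_size − 1 bases of separation so seeds cannot chain
across distinct truths. Second, each insertion is flanked by four guard
bases rewritten to mismatch the organellar residues that would continue the
alignment past the boundary — both in register and under ±1/±2 gap shifts.
Without the guards, a chance flank match (probability ≈ 1/4 per side, plus
rarer gap-shifted re-anchorings) extends a fraction of detected boundaries
a few bases past the truth, which would make exact-boundary recovery of
perfect-identity insertions untestable. Contaminant contigs are verbatim
organellar substrings appended as separate records.

Trees are pure-birth (Yule) with exponential waiting times; because the
process stops at the n-th birth, all terminal branches are extended by one
further exponential waiting time so no tip edge is zero (the tree stays
ultrametric). Traits are y = β₀ + β₁x + ε with ε ~ MVN(0, σ²·V(λ)) drawn
through the Cholesky factor of V(λ). Paired designs draw control values
i.i.d. (lognormal by default, matching the skew of abundance data) and add
a shift δ to independent draws for the tolerant side; δ = 0 is the null.

What the generator does **not** emulate: repeat landscapes and segmental
duplications (no post-insertion NUMT–NUMT duplication), sequencing error
and assembly artefacts other than verbatim contamination, indel divergence
(off by default), and realistic organellar gene content. Passing recovery
tests therefore demonstrates the correctness of the detection and counting
machinery under the stated divergence model, not detection power on real
genomes with repetitive or duplicated nuclear contexts.

## Problem sizes in the validation experiments

The acceptance script and end-to-end tests use: a 2 Mb nuclear genome with
50 planted insertions (25 mitochondrial from a 16 kb genome, 25 plastid
from a 120 kb genome; lengths 200–2000 bp; identities 85–100% with five
exact copies per organelle); 100 random hit sets of up to 500 intervals for
the dedup oracle; 100 seeded pairs for the aligner oracle; 200 replicates
on a 100-tip tree (λ = 0.8, slope = 1, σ² = 1) for PGLS recovery; 2000
replicates of the 24-pair null for Wilcoxon calibration; and 20 random
configurations for the contamination filter. These sizes give stable
estimates (e.g. binomial standard error ≈ 0.005 on the rejection rate) at
desk scale.

## Known limitations

- The aligner is a faithful but unoptimised re-implementation; it is meant
  for genomes up to a few tens of Mb, not mammalian-scale assemblies, where
  externally produced 12-column hit tables should be supplied instead
  (`--hits`).
- Gapped E-values reuse ungapped Karlin–Altschul parameters; absolute
  E-values differ from tools with empirically fitted gapped constants,
  though ordering and internal consistency are preserved.
- MINC/PLNC (organellar sequences of nuclear origin) are not discriminated
  from NUMTs/NUPTs; insertions are not dated; NUMT–NUMT post-insertion
  duplications are counted as separate segments.
- The λ profile can be flat on small trees; the reported λ is then
  grid-optimal but weakly identified, and the slope p-value does not
  account for λ estimation.
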