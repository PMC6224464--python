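# Methods

This note documents the models, conventions, and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the design decisions taken where more than one reading was
defensible.

## Coordinates, keys, and formats

All genomic coordinates are 1-based inclusive (the GFF3 convention), on the
forward strand of the reference; the only exception is the emitted BED file
of hypervariable regions, which follows the BED 0-based half-open standard
(the conversion is `start-1, end` and is unit-tested).  A mutation's
identity key is the triple *(position, ref, alt)* — lossless when several
alleles segregate at one site — with a position-collapsed mode available
where analyses want distinct mutated *locations*.  Insertions are recorded
as `ref="-"`, `alt=<inserted bases>` after `position`; deletions as
`ref=<deleted bases>` starting at `position`, `alt="-"`.  Standard formats
are used throughout: FASTA for the genome, a fixed GFF3 dialect for
annotations (CDS features with `ID`; tRNA features with `ID` and
`anticodon`), TSV for variant tables, time-courses, alignment records and
distance matrices, Newick for trees, JSON for reports.

## Variant filtering and annotation

Two technical sequencing libraries per evolved population are reconciled
under two filters, both applied **per library, before averaging**:

* frequency ≥ 1% (a 1.5%/0.6% pair is dropped even though its mean exceeds
  1% — the rule is membership in each library, not on the mean);
* strand-specific coverage ≥ 10 reads on *each* strand at the site, which
  guards against strand-biased artifacts.  `fwd_reads`/`rev_reads` are
  strand coverage at the variant site, not variant-supporting reads — a 1%
  variant cannot carry 10 supporting reads per strand at any realistic
  depth, so the coverage reading is the only satisfiable one.

A mutation failing either filter in a library counts as absent from that
library; only mutations present in both survive, at the mean of the two
frequencies.  When one library is unusable, the single-library calls pass
through with their own frequencies (the pipeline treats a missing
`*_lib2.tsv` as that case).  Disagreeing reference alleles at a shared
position abort reconciliation — they signal an inconsistent reference.

Annotation locates each SNP in its ORF's reading frame (minus-strand ORFs
via the reverse complement, amino-acid numbering from the ORF's own start),
classifying synonymous / nonsynonymous / nonsense; indels inside ORFs are
frameshift when the length is not divisible by 3, otherwise
`inframe_indel` (this keeps long in-frame deletions distinct from
frameshifts).  Codon optimization is judged with **strict Watson–Crick
pairing, no wobble**: a codon "pairs" with a tRNA iff it equals the reverse
complement of the anticodon at all three positions (anticodons are stored
as RNA-alphabet triplets, 5′→3′).  A synonymous change is *optimizing* for
a host iff the mutated codon pairs with at least one of that host's
anticodons while the ancestral codon pairs with none; both-pair and
neither-pair cases are *nonoptimizing*.  Whether wobble decoding should
soften the judgement of the ancestral codon is genuinely open; the strict
rule is one consistent reading and is applied symmetrically.

## Selection statistics

The neutral expectation for the nonsynonymous fraction of coding changes is
computed by exact enumeration over all sense codons × 9 single-nucleotide
changes, weighted by optional codon-usage weights and a 4×4 substitution
matrix (uniform defaults).  Changes to stop codons are excluded from both
numerator and denominator by default (include them and they count as
nonsynonymous); with the standard code and uniform weights the defaults
give 392/526 ≈ 74.5%.

The excess test takes observed counts *(n_nonsyn, n_syn)* against an
expected fraction *f*.  Two constructions are provided because the exact
2×2 used in this kind of analysis is typically not printed: the default
builds a pseudo-count expected column *(round(N·f), N − round(N·f))* at the
same total and applies one-sided Fisher; the alternative is the one-sided
exact binomial tail of *n_nonsyn* in *N* trials at *f*.  The Fisher
construction is the more conservative of the two (it treats the expected
column as a second sample of size N).

Mutation burdens across regimes use tie-corrected Kruskal–Wallis with the
chi-square approximation (the convention of standard stacks); an exact
permutation p is available for groups of ≤ 10.  Degenerate all-tied input
reports (H = 0, p = 1).  Region enrichment is the upper-tail hypergeometric
probability of the observed number of mutations falling in a region set,
drawing `n_mut_total` positions from the genome without replacement.  The
enrichment unit defaults to mutation records, with distinct positions
behind a flag — the two differ when several alleles segregate at a site.

## Phenotypic analysis

Infectivity of population *i* on host *j* at ratio VpC is the mean infected
fluorescence over the mean uninfected-control fluorescence at a fixed
readout day (default 10).  A missing readout day is a hard error — no
interpolation — because silent interpolation would mask config/data
mismatches.  No replicate-outlier handling is applied.  Profiles are
6-vectors in fixed host-major order (hosts sorted, ratios ascending),
compared with the Canberra distance Σ|xᵢ−yᵢ|/(|xᵢ|+|yᵢ|), where 0/0 terms
contribute 0 so that identical (including all-zero) profiles are at
distance zero.

## Neighbor joining

Saitou–Nei agglomeration with the standard Q criterion, shared by both
trees.  Two conventions are pinned for cross-platform determinism: Q ties
are broken by the lexicographically smallest pair of representative labels
(a cluster is represented by its smallest leaf), and negative branch
lengths are clamped to zero with the deficit transferred to the sibling
edge of the same join, preserving the joined pair's distance; clamp events
are counted on the tree object.  NJ recovers additive (tree-realizable)
matrices exactly — topology and all leaf-path lengths to 1e-9 — which the
suite verifies against randomly generated tree metrics and cross-checks
against an independent library implementation.  Outgroup rooting bisects
the edge leading to the outgroup leaf; the genotypic tree is rooted on the
ancestral population, whose vector is all zeros.

## Genotypic analysis

Frequency vectors over the sorted union of mutation keys, Euclidean
distances (well-defined at zero entries), NJ tree as above, and
within-regime dispersion as the mean pairwise distance inside each regime
(regimes with < 2 members excluded with a warning).  Frequencies are on the
[0,1] scale by default — the ancestral-distance-equals-L2-norm identity
then holds on the natural scale — with a percent scale available; topology
is scale-invariant, branch lengths are not.

## Hypervariable regions

Recruitment acceptance transcribes the two published rule sets verbatim,
including their boundary asymmetry: rule 1 requires aligned length > 300 bp
at identity ≥ 65% with < 25 unaligned bases at either end; rule 2 requires
> 100 bp at identity *strictly* > 65% with < 20 unaligned bases.  A
rejected read is rescued iff its mate is an accepted record aligned over
strictly more than 80% of its length.  Coverage is the count of accepted
records spanning each position; hypervariable regions are maximal runs of
≥ 500 bp strictly below 20% of the central coverage.  The central coverage
defaults to the **median**, with the mean available — the source
literature for this definition states both in different places, so the
choice is explicit, logged in the output metadata, and neither is asserted
as canonical.  The genome is treated as linear (no wrap-around), and
all-zero coverage is an error rather than a call of the whole genome.

## Fitness landscape

The 2-D "genomic space" embedding defaults to deterministic classical
metric scaling (double-centered squared distances, axes ordered by
eigenvalue, each axis's sign fixed so its largest-magnitude loading is
positive); it is exact for plane-realizable distance matrices, which makes
the exactness tests meaningful.  t-SNE (stochastic, seeded, perplexity
default 5) is available behind a flag for parity with practice, but a
stochastic default would make every downstream artifact seed-dependent.
Fitness on a host is the reciprocal of infectivity at the high
virus-per-cell ratio; zero infectivity is an error (the caller may cap).
Interpolation is inverse-distance weighting with exponent 2 over a regular
grid (default 50×50) spanning the bounding box of all population
coordinates: grid nodes coinciding with a data point take that point's
value exactly, and every IDW value is a convex combination of the data, so
the surface stays within [min Z, max Z].  "IDW" and "kriging" are
sometimes conflated in applied descriptions of this construction; IDW is
what the operational definition specifies, and variogram-based kriging is
deliberately out of scope.  An optional smoothing pass replaces the surface
with a thin-plate spline fitted to the points under a roughness penalty
(recording the residual sum of squares at the data points); it is off by
default and in all exactness tests because it destroys the
interpolation-exactness property.  One grid per host shares a single
identical GS1~GS2 plane; each host's on-surface point list is the ancestor
plus the populations evolved on that host, while all populations remain on
the plane.

## Synthetic data

The generator emulates the study design end to end: one ancestral
population and three regimes of 4–5 replicate populations evolved on hosts
of decreasing optimality, with regime mutation means 6 / 18 / 30 and
ancestral infectivities 0.25 / 0.5 / 0.8 (lower = better-infected host).
Each population draws Poisson-many mutations, filled first from a
regime-specific pool (host-specific adaptation; base frequencies 30–90%,
emulating high-frequency host-tailored sweeps), then from a global shared
pool of ~5 mutations common to all regimes (base frequencies 5–16%, the
range observed for host-independent parallel mutations in this kind of
experiment), the remainder private to the population (frequencies 2–30%;
~10% of privates are 1-bp frameshift indels, and the least-optimal regime
occasionally adds one long in-frame deletion).  Pool frequencies get
per-population Gaussian jitter (sd 0.02).  Per-regime ORF subsets host the
regime pools, emulating regime-specific mutated gene sets.

Sequencing libraries report Binomial(depth, true frequency)/depth per
library at depth 200 (zero-draw mutations are absent from that library's
table), strand coverage splits the depth binomially, and two sub-1%
single-library artifact calls per population exercise the reconciliation
filter.  Infection curves grow the control geometrically and decline the
infected/control ratio linearly to the configured infectivity by day 10,
with lognormal replicate noise (sd 0.02) on the infected series; evolved
populations improve 2%/mutation on their own host and degrade 1%/mutation
on the others (capped at 1 — no detectable killing — so complete host-range
loss is reachable).  Recruitment places reads (length ~N(1000, 150), as in
long-read environmental surveys) uniformly, discarding reads overlapping a
declared desert with high probability, plus a 5% admixture of
rule-violating records, half of them mate-rescuable.

Determinism: one global seed fans out to per-stage child generators via
fixed offsets (`default_rng([seed, stage, ...])`), so any stage can be
re-run in isolation and byte-identical outputs follow from identical
configs.

What the generator does **not** emulate: read-level sequences (no FASTQ),
linkage between mutations (frequencies are drawn independently; real
populations carry haplotype structure), recombination, coevolving hosts,
intra-infection-cycle dynamics (the day grid is fixed; real cycle lengths
vary), reference-mapping artifacts beyond the injected false positives, and
percent-identity structure along reads.  Passing tests therefore
demonstrate that the pipeline's inferences recover the regime structure the
generator encodes — not that they would be robust to mapping bias, linkage,
or contamination in real sequencing data.

## Problem sizes and calibration choices

The demo bundle is desk-scale by design: a 50 kb genome with 20 ORFs and 3
tRNA genes, 13 evolved populations plus the ancestor, depth-200 libraries,
12-day time-courses, and 10,000 recruitment reads — large enough for every
statistic to be well-posed, small enough that the full pipeline runs in
seconds.  The verification suite runs the regime-structure recovery across
100 seeds, hypervariable-region recovery (600 bp declared desert, interval
Jaccard ≥ 0.5) across 100 seeds, and NJ exactness on 200 random tree
metrics of up to 12 taxa.

Type-I-error calibration of the selection test simulates 1000 populations
at the neutral nonsynonymous fraction with Poisson-mean-150 coding SNP
counts and uses the exact binomial variant.  The count scale matters: a
one-sided exact test on discrete data can only realize p-values on a
lattice, so its attained size is strictly below the nominal level at small
counts (that conservatism is correct behavior, not miscalibration) and
approaches the nominal level as counts grow; calibration is therefore
checked in the large-count regime where the attainable levels are dense
near α.  The pseudo-count Fisher construction is markedly more conservative
at every scale, which is why the calibration check exercises the binomial
variant.

## Known limitations

* Annotation assumes non-overlapping ORFs (enforced by the genome
  container); overlapping reading frames would need per-frame annotation.
* Indel annotation classifies by length only; it does not recompute the
  downstream protein or detect restored frames from compound events.
* The mate-rescue pass recovers rejected records but does not re-estimate
  their alignment quality; rescued low-identity records enter coverage
  as-is.
* Canberra distance is a semimetric; the triangle inequality is verified
  empirically on random non-negative vectors but not relied on.
* t-SNE coordinates depend on seed and perplexity; only the classical
  scaling path is covered by exactness guarantees.
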