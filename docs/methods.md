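# Methods

This note records the models, conventions and design choices behind
`camlnc`, and what the synthetic cohorts do and do not demonstrate.

## Coordinates and formats

All genomic intervals are GTF-style 1-based inclusive. The only half-open
representation lives inside the interval index (`intervaltree` wants
half-open integers); the conversion `[s, e] -> [s, e+1)` happens in one
place and round-trips exactly. The gap between `[a, b]` and `[c, d]` with
`c > b` is `c − b − 1`, the count of intervening bases, so touching or
overlapping features are at distance 0. GTF and GFF3 are read through
`gffutils`; GTF output is written directly (transcript + exon lines with
`class_code` and `biotype` attributes, so an accepted set round-trips).
Expression tables are written with full float repr so write→read is exact.

FPKM is taken as given and never renormalized. Replicates are averaged
(not medianed) to one column per (tissue, time point); this is the
conventional reduction for FPKM time courses, and every downstream
correlation or maximum is taken over those condition means. Transcript
length is the mature length (sum of exon lengths), the standard basis for
the ">200 nt" lncRNA definition.

## Identification funnel

Steps run in a fixed order (class code, length, coding potential, protein
domain, strand, expression) and each records entrants, survivors and the
rejected ids, so counts are non-increasing by construction and audits are
cheap. Boundary conventions:

- class code: `u` requires zero overlapping bases with any reference gene
  locus; `x` requires ≥ 1 bp exonic overlap on the opposite strand; `i`
  requires full containment within one reference intron; any sense exonic
  overlap, or a partial structure matching none of these, is `other`.
  Sense overlap is tested before antisense so a transcript touching exons
  on both strands is conservatively dropped from the candidate classes.
- length is a strict bound: exactly 200 nt fails.
- a coding-potential score of exactly 0 fails (strict `< 0`): the
  enumerated definition of the filter is taken as normative over looser
  prose phrasings of the same rule.
- the expression criterion is the maximum over collapsed conditions ("in
  at least one sample"), with single-exon transcripts held to 2 FPKM
  versus 0.5 for spliced ones.

Intronic (`i`) transcripts are assigned lncNAT when their host gene is on
the opposite strand and lincRNA when on the same strand. The antisense
test is ≥ 1 bp of locus overlap with no minimum fraction. Candidates
failing only strand or expression form the low-confidence set; failures
at sequence-level criteria do not.

## Tissue specificity

Tau uses max-normalization: `τ = Σ(1 − x̂ᵢ)/(N − 1)`. Entropy uses the
Shannon form on the sum-normalized profile with `0·log 0 := 0`. Both are
scale-invariant; τ = 0 iff the profile is uniform and τ = 1 iff exactly
one tissue is nonzero. Rows with FPKM < 1 in every tissue are discarded
before scoring. The specificity call is strict (`τ > 0.8`). The argmax
tissue is left unassigned on exact ties rather than broken arbitrarily,
and "expressed in a tissue" for unique-expression counting reuses the
1-FPKM detection threshold so the module has a single notion of
"detected". Multi-stage tissues (the six fruit stages) are averaged into
one profile component before scoring.

## Co-expression

Pearson r is computed on z-scored rows over the shared condition columns
(vectorized as a matrix product, clipped to [−1, 1]); edges require
strictly |r| > 0.95. Correlations are taken on the 26 condition means, not
the 78 replicate columns, so replicate noise does not inflate the sample
size. Zero-variance profiles cannot be correlated; they are skipped and
counted rather than failing the run, since silent transcripts are normal
in both real and synthetic data.

## ceRNA pairing

Pair enumeration is exact: for every miRNA, every unordered pair of its
bound transcripts is a candidate pair, annotated with the full shared
miRNA set. Typing is by strongest evidence: any perfect-perfect shared
miRNA makes the pair target-target; otherwise any perfect-mimic link makes
it target-mimic. Pairs whose only shared links are mimic-mimic carry no
release-of-repression logic and are excluded by default
(`include_mimic_mimic=True` restores them). Binding prediction itself is
an input boundary: the table arrives with a mandatory mode per record.

## Diel cycling

The model library holds cosine, spike, box and sawtooth shapes at 2-h
phase offsets, evaluated at the actual (possibly uneven) clock hours of
the sampling grid; constant vectors are dropped. Scoring a profile takes
the maximum correlation over the library; fold change is
`(max + 1)/(min + 1)` (pseudocount 1 FPKM avoids division by zero) and
amplitude is `max − min` in FPKM, the only scale present in the data. The
p-value is a seeded permutation test: time labels are shuffled
`n_permutations` times (default 1000), the best-model correlation is
recomputed each time, and `p = (1 + #{r_perm ≥ r_obs}) / (n + 1)`. A call
requires all four criteria; the p criterion is a *significance* bound
(p < 0.05) — requiring an insignificant fit would contradict the notion
of an empirically defined cycling gene, so the package treats it as such.
A constant profile has undefined r and is reported non-cycling with reason
"zero variance".

One structural caveat is worth recording: a spike profile permuted in time
is still a spike, and the library contains spikes at every phase, so the
permutation p-value has no power against spike-shaped signals. The spike
model therefore stays in the scoring library (it can still win the
correlation), but the synthetic generator never plants spike cyclers —
a planted spike could never satisfy all four criteria.

## Synthetic cohorts and what they show

The generator emulates the study design end to end: two leaf tissues
sampled at 13 time points over 24 h in triplicate (the default grid is
18:00–16:00 at 2-h steps with the uneven daytime tail 12, 13, 15, 16 h),
a four-tissue panel with six fruit stages, coding genes with 4–8 exons,
and candidate transcripts planted per class (`u`/`x`/`i`) plus one planted
failure set per filter criterion, each violating exactly one criterion so
filter bugs localize. ceRNA triangles plant a focal coding transcript
perfectly bound by m miRNAs and k mimic-bound decoy lncRNAs jointly
covering them (defaults: one 2-miRNA/5-decoy and one 3-miRNA/8-decoy
triangle). Cycling plants add `baseline + amplitude · model` with the
model min-max normalized on the grid so the realized amplitude equals the
requested one; noise is additive Normal(0, `noise_sd`) at replicate level,
clipped at zero (default 0.2 FPKM, a modest measurement noise).
Co-expression partners are exact affine transforms of their lncRNA's
two-tissue profile (negative partners use a negative slope), so planted
edges have |r| = 1 before noise.

Truth labels are **realized**, not requested: the manifest stores class
codes from the deterministic geometry, filter fates from re-applying the
five criteria to the emitted numbers, τ recomputed from the written
matrix, cycling metrics (best r, amplitude, fold change) from the
replicate-averaged emitted profiles, and co-expression edges from an
independent all-pairs correlation scan. Recovery tests on noiseless data
are therefore exact. All structure is integer arithmetic and all noise
flows from one seed through named substreams, so outputs are byte-identical
per seed.

What passing tests do *not* show about real data: FPKM distributions here
are uniform blocks rather than heavy-tailed; transcripts are single-isoform;
chromosome structure is a gene-gap chain without overlapping loci, repeats
or assembly artifacts; binding tables contain no false-positive target
predictions; and diel noise is homoscedastic. Oracle-equality results
(funnel, pairing, networks) transfer directly to real inputs since they are
data-agnostic; detection *rates* (cycling, specificity) are
condition-dependent and should be read as behaviour under these planted
conditions only.

## Problem sizes

Defaults are desk-scale: 60 coding genes and 80 candidates in the demo
cohort, a ≥ 500-candidate cohort (250 genes, 3 chromosomes) for the
funnel-oracle checks, 1000 permutations per cycling call, and a
four-noise-level sweep (σ ∈ {0, 1, 5, 10} FPKM) with ~130 scored profiles
per level for the noise-monotonicity check. These sizes were chosen so
each property is exercised with comfortable margins while the whole suite
runs in a couple of minutes; all of them scale linearly through the
`SimulationConfig` counts.
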