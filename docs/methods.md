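# Methods

This note documents the models, conventions and numerical choices
behind `icshapemap`, in the order the pipeline runs them.

## Reactivity scoring from mutational profiles

Chemical acylation of flexible (single-stranded) 2'-OH groups leaves
mutations in the cDNA when reverse transcription reads through the
adduct.  The per-nucleotide reactivity is

    s_i = (r_nai_i − r_dmso_i) / f

where `r_*` are all-class mutation rates (events / aligned coverage) in
the reagent-treated and mock-treated libraries and `f` is a
per-transcript normalization factor.

**Mutation parsing.**  Each aligned read's CIGAR and bases are walked
against the reference.  Primitive events (mismatches, indels) separated
by ≤ 2 matched reference bases are merged: homogeneous groups become
`multi-*` classes, mixed groups are labelled by their net
reference-length change (net loss → `complex-deletion`, net gain →
`complex-insertion`, net zero → `multi-mismatch`).  Eight classes
result.  Every event is anchored at its 3'-most reference position —
the nucleotide the RT was traversing when it erred, since the enzyme
approaches the adduct from the 3' side.  Insertions, which consume no
reference, anchor at the base immediately 5' of the inserted bases.
Ambiguous deletions inside repeats are right-aligned to their 3'-most
equivalent placement before classification.  Reads that are unmapped,
secondary, supplementary or mapping-quality 0 are excluded; soft clips
contribute neither events nor coverage.  Because SAM files store read
bases in the DNA alphabet, the parser normalizes both strands to T ≡ U
before comparison.

The merge distance of 2 is a package choice: the class vocabulary
distinguishes single from multi/complex events but no public merge
distance accompanies it; 2 keeps SNV-like events separable while making
the complex classes reachable.  It is exposed as a parameter
(`merge_spacer`).

**Normalization (boxplot rule).**  Among usable (non-null) raw scores,
values above Q3 + 1.5·IQR are excluded as outliers, capping exclusions
at 10% of the usable positions; `f` is the mean of the top 10% of the
remainder.  The top decile of normalized scores therefore averages 1.
Profiles with fewer than 10 usable positions, or a non-positive factor
(e.g. an all-zero profile), are emitted fully null with a warning.

**Masking.**  Positions with coverage below `min_coverage` (default
1000×; 2000× gives very high-quality scores and is recommended when
depth allows) or with a DMSO mutation rate above `max_background`
(default 0.05, flagging endogenous-modification sites such as m1A) are
set to null.  Negative normalized scores are retained in output files
but treated as 0 by the folding constraints, preserving QC information
while keeping pseudo-energies defined.

**Replicates** are combined by summing event counts and coverage
*before* the rate computation, not by averaging scores afterwards.

## Replicate QC

Total coverages of two replicates are balanced by seeded down-sampling
(binomial thinning of coverage, hypergeometric thinning of events).
Bases are sorted by pairwise-minimum coverage, and for each coverage
cutoff (500/1000/2000/3000/4000/5000×) the qualifying bases are cut
into sliding windows (50 bases, step 10); Pearson r of the two
replicates' mutation rates is computed per window.  Zero-variance
windows are skipped and logged.  Because sampling noise shrinks with
coverage, the median window r is non-decreasing in the cutoff — a
property the acceptance suite checks on simulated replicate pairs.

## Structure AUC

Reactivity as a predictor of the unpaired state against a reference
structure, summarized as ROC AUC: higher score ⇒ unpaired, ties counted
half (trapezoidal ROC), null positions excluded.  A reference with only
one class among scored positions is rejected.

## Enrichment and cleavage scores

Per-transcript log2 ratios of within-library read proportions:
RIP vs input for binding enrichment, catalytic-dead vs wild-type for
cleavage.  A zero count in either condition yields a null score rather
than ±∞; classification as "enriched" requires a strictly positive
score.  No pseudocount is applied by default (an optional, explicitly
non-canonical `pseudocount` parameter exists for exploration), and no
dispersion modelling is done — the raw log-ratio is the statistic.
The normalizing totals are the supplied table's own totals.

Note that proportions are compositional: planting a log2 effect `e` on
a transcript changes every proportion through the renormalization
constant Z, so the recoverable score is `e − log2 Z`.  Recovery of
planted effects is therefore only exact in the small-share limit; the
generator records the planted truth so tests can account for this.

## SHAPE-constrained folding

A self-contained Zuker-style dynamic program over a simplified
nearest-neighbor model:

* Watson–Crick and GU wobble pairs; stack free energies from the
  standard published tables (wobble values declared constants);
* hairpin/bulge/internal-loop initiation by lookup tables with
  logarithmic extrapolation (`ΔG(n) = ΔG(n_max) + 1.078·ln(n/n_max)`
  kcal/mol, 37 °C);
* linear multiloop penalties (closing 3.4, per branch 0.4, per unpaired
  nt 0.0 kcal/mol); no dangles, no coaxial stacking, no terminal-pair
  penalties; interior loops capped at 30 unpaired nt; minimum hairpin
  loop 3 nt.

The reactivity constraint is the Deigan pseudo-energy, applied once per
paired nucleotide:

    ΔG_SHAPE(i) = m·ln(s_i + 1) + b,   m = 1.8, b = −0.6 kcal/mol

with negative scores clamped to 0 and null scores contributing 0.  With
no profile the fold reduces to the unconstrained MFE.  Ties in the DP
resolve to a fixed candidate order, making folds deterministic.

`score_structure` re-derives the energy of any given structure by loop
decomposition, independent of the DP recursions; the test suite uses it
with exhaustive enumeration (all pseudoknot-free structures of short
sequences) as an exact oracle for the DP optimum, and cross-checks the
unconstrained fold against an external engine (RNAfold) on unambiguous
perfect hairpins.  The model is intentionally small — it reproduces the
constraint mechanism faithfully at desk scale; it is not a replacement
for a full folding package on long or multi-domain RNAs.

## Structure features and comparison

The **terminal loop** is chosen by the central-loop rule: among all
hairpin loops, the one whose centre is nearest the sequence midpoint;
ties break toward the larger loop, then the 5'-most.  Loop centres of
even-sized loops use the floor midpoint.  Each maximal internal
unpaired run is classified terminal loop (its flanks pair with each
other), bulge (the flanking helices stack directly on the opposite
strand), or internal loop (everything else, including multiloop
junctions); exterior overhangs are not listed.  Runs are assigned to
the 5p arm, 3p arm, or loop relative to the terminal loop.

Structure comparison classifies each position as identical,
single-stranded in one model only (either direction), or paired in both
with different partners — a partition of the sequence.

## Profile clustering

Per-transcript reactivity profiles are aligned on the terminal-loop
centre; columns −30…−1 and +1…+30 (centre nucleotide excluded, exactly
60 dimensions) form the feature matrix.  Columns beyond a transcript's
ends are null; nulls are imputed by the transcript's mean score (zero
and column-mean imputation available behind a flag); transcripts with
more than 50% null columns, or without a hairpin, are dropped and
logged.  PCA mean-centres but does not variance-scale — reactivities
share a scale after normalization, and variance-scaling would inflate
flat flank positions.  Loadings are unit-norm with the sign convention
that each component's largest-magnitude entry is positive.  K-means
(K = 3, Lloyd, 10 restarts, best inertia, seeded) labels the 2-D
projections; labels are renumbered by descending cluster size.

## Dicer cleavage-site rules

Cleavage sites are the annotated 5' end of the 3p miRNA and 3' end of
the 5p miRNA.  Three rules are evaluated per pre-miRNA:

* **loop counting** — the 3p cleavage site sits exactly two paired
  nucleotides downstream of a single-stranded bulge/loop:  for p = the
  3p span's first nucleotide, p−1 and p−2 are paired and p−3 is
  single-stranded.  The 5p variant ("0 nt") asks for the position
  immediately 3' of the 5p span's last nucleotide to be
  single-stranded — the k = 0 member of the same family.  The exact
  off-by-one convention is this package's reading; a brute-force scan
  over single-stranded regions validates it on hand-built cases.
* **3' counting** — D_3p_miRNA, the spatial distance from the C5' atom
  of the 3p miRNA's first nucleotide to the O3' atom of the pre-miRNA's
  last nucleotide, lies within 59 ± 1 Å.  The target reflects the
  ~58 Å PAZ-to-catalytic-site span measured in the Dicer–TRBP–pre-let-7
  cryo-EM structure; both target and tolerance are parameters.
* **5' counting** — likewise for D_5p_miRNA (C5' of nucleotide 1 to O3'
  of the 5p span's last nucleotide).

Distances are medians over a coordinate-model ensemble; when more than
50 models are supplied, the 50 lowest-energy models are used (all
models, with a warning, when energies are absent).  Arm lengths
(D_5p_arm, D_3p_arm) use the nucleotides bordering the terminal loop.
Atom-name dialects `C5'`/`C5*` and `O3'`/`O3*` are both accepted.
Isoform comparison shifts the 3p 5' end by integer offsets and reports
each isoform's distance deviation and expression share, whether the
annotated isoform minimizes |D − 59|, and the total share within the
tolerance window.  Medians are used throughout the rule comparisons.

## Synthetic data

The generators define the study conditions and are first-class, tested
code:

* **Hairpin cohort** — 50 transcripts, 15-bp Watson–Crick stem, 9-nt
  loop (loop bases drawn from {A, C} so the loop cannot pair and the
  emitted dot-bracket is exact by construction).
* **MaP reads** — full-length reads (the library design amplifies only
  full-length molecules); per-position event probability
  `mod_rate + background` under NAI (0.02 single-stranded, 0.002
  paired) and `background` alone (0.002) under DMSO, at 2000× depth.
  Event types follow a fixed 70% mismatch / 15% 1-nt deletion / 15%
  1-nt insertion mixture; multi-nt and complex classes are exercised by
  hand-built reads rather than this model.  No quality model beyond a
  constant placeholder string, no RT-stop simulation (the scoring
  method discards stops by design).
* **Count tables** — condition-B proportions equal condition-A
  proportions scaled by `2^effect`, renormalized, then sampled
  multinomially (see the compositional caveat above).
* **Helix models** — one tracked point per residue per strand on a
  cylinder (rise 2.81 Å, twist 32.7°, radius 9.0 Å, A-form-like;
  strand-2 phase offset 150°, arbitrary and recorded).  C5' and O3' of
  a residue are coincident at the tracked point, so chord distances
  follow `d(n) = sqrt((n·rise)² + (2·radius·sin(n·twist/2))²)` exactly.
  These are fixture constants, not biological claims; model ensembles
  are Gaussian jitters of the ideal helix with synthetic energies.
* **Profile archetypes** — three loop-centred reactivity shapes
  (hairpin-like: high centre ± 5, low flanks; loose stem: moderate
  centre, loose flanks; chessboard alternation) with additive Gaussian
  noise, used to exercise the clustering stage with known labels.

What passing tests on these fixtures show — and what they do not:
recovery works when the signal model holds (structure-dependent
mutation rates, clean full-length alignments, hairpin topologies).
Real libraries add PCR duplicates, alignment artefacts, heterogeneous
modification chemistry, multi-domain structures and expression-coupled
coverage, none of which the generators emulate.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; the pipeline derives
per-stage, per-transcript seeds from the run seed, and reruns with the
same configuration and seed produce byte-identical tabular outputs
(output headers record tool version, a hash of the analysis parameters,
and the seed — never timestamps).  The test and acceptance fixtures use
the study conditions above for signal recovery (50 hairpins × 2000×),
200 random sequences of length ≤ 14 plus an exhaustive length-8 sweep
for the folding oracle, ~1200 simulated reads for the parser oracle,
10⁶-read multinomial tables for effect recovery, 50-model ensembles at
0.5 Å jitter for geometry, and a reduced pipeline configuration
(10 transcripts × 250×) for the byte-identity check, sizes chosen to
keep a full run in minutes on one core.

## Known limitations

* The energy model omits dangles, coaxial stacking, terminal-pair
  penalties and special hairpin sequences; predicted structures for
  natural RNAs will differ from full-parameter engines even
  unconstrained.
* Mixed merged events are labelled by net length change; the original
  upstream tool's tie-breaking between complex classes is not public,
  so agreement there is a convention, not a reproduction.
* Log-ratio scores are compositional (see above); comparisons across
  conditions with very different library compositions inherit that
  caveat.
* The loop-counting operationalization fixes one reading of "2 nt
  downstream"; alternative off-by-one conventions change individual
  rule calls but not the machinery.
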