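# Methods

This note documents the models, rules and numerical choices implemented in
`loxevo`, what the synthetic-data generator does and does not emulate, and
the known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Profile HMMs (`profile_hmm`)

**Model.** A Plan7-flavoured core: L match states with 20-residue emission
tables, insert states emitting at background, delete states, per-column
transitions (M→M/I/D, I→M/I, D→M/D). Local alignment uses uniform entry and
exit over the match columns (score contribution −log₂L each); there is no
multi-hit state loop — repeats are handled downstream (see scanning).

**Construction.** Columns with gap fraction < 0.5 become match columns.
Sequences get Henikoff position-based weights (mean 1). Weighted emission
counts are mixed with `pseudocount_weight × background` and normalized;
transition counts get a flat pseudocount split over the allowed targets.
Background frequencies are the Robinson & Robinson (1991) table. `X` carries
no count at build time and scores log-odds 0 (missing data) at search time.

**Scores.** Bits = log₂ of the ratio between the path probability of the
aligned subsequence and its i.i.d. background probability; flanking residues
cancel, so no N/C flank states are needed. Viterbi and forward share one DP
with the delete chain vectorized via prefix sums (max-accumulate for
Viterbi, `logaddexp2.accumulate` for forward). Both are verified against
explicit enumeration of all local paths on small instances (≤ 1e-12 bits).
Tie-breaks: end cell with the smallest sequence position then smallest
column; the traceback prefers continuing a match over re-entry, yielding the
leftmost, then shortest, envelope.

**E-values.** The null is empirical: forward scores of sequences drawn
i.i.d. from the profile background (default 200 draws of length 150),
fitted to a Gumbel law by method of moments; E = database_size × P(S > s).
Search space is rescaled linearly to each query's length. A fixed
Karlin–Altschul calibration would be meaningless for arbitrary toy profiles.
Note the E-value uses the Gumbel *survival* function; at the null mean the
exceedance is 1 − exp(−exp(−γ)) ≈ 0.430.

**Scanning.** Per protein and profile, the best Viterbi hit is extracted and
the flanks are recursively re-scanned (depth ≤ 12); hits from all profiles
are then accepted greedily in decreasing bit order, discarding any hit
overlapping an accepted one by more than 10 residues. Default inclusion
threshold E ≤ 1e-5 (configurable); the reporting threshold of the original
HMMER-based retrieval is not stated anywhere, so this is a package choice.

## 2. Feature annotation (`annotation`)

Documented rule-based stand-ins for dedicated predictors, all thresholds
exposed as keyword arguments:

* **TM helix**: Kyte–Doolittle window 19, mean ≥ 1.6, merged regions kept at
  ≥ 15 residues. A TM call overlapping the predicted signal peptide is
  suppressed — an N-terminal hydrophobic helix coinciding with a signal
  peptide *is* the signal peptide (the disambiguation every real TM
  predictor performs).
* **Signal peptide**: requires (a) an 8-residue window with mean KD ≥ 2.0
  starting within residues 1–12 and (b) an A-x-A-type cleavage motif
  `[AGSV].[AGS]` whose last residue falls in 15–35 (overlapping occurrences
  all considered; the first qualifying one sets the cleavage site).
* **Proline-rich**: window 25, Pro fraction ≥ 0.25, merged; regions fully
  inside an excluded region (signal peptide, domain hit) are dropped.
* **Propeptide**: the unannotated stretch between the last N-terminal
  feature (signal peptide or proline-rich region; residue 1 if none) and the
  first domain hit, labeled propeptide iff ≥ 50 residues and not
  proline-rich. The anchor is the *last* N-terminal feature rather than the
  signal peptide alone so that an architecture with both a proline-rich
  region and a downstream propeptide (the LOXL5 pattern) is representable.
* **Canonical strings**: tokens N→C, runs of identical adjacent tokens
  collapsed to `kxTOKEN` (`SP+4xSRCR+LOX`); a TM overlapping a domain is
  placed after the overlapped token.

These rules are approximations of SignalP/TMHMM/manual curation; output
tables carry the method name so scores are never mistaken for predictor
probabilities.

## 3. Catalytic competence (`catalytic`)

The reference motif `WEWHSCHQHYHSMD` (human LOX) is located in the reference
row of the alignment by the tolerant pattern `W.WH..H.H.H`; its histidines
sit at motif offsets 4, 7, 9, 11 (1-based). The first histidine is
dispensable (experimental mutagenesis showed its loss preserves copper
binding); the remaining three are the required core. The LTQ lysine and
tyrosine columns are located by reference positions (K320/Y355 for human
LOX; the generator's template positions for synthetic data), with a flagged
fallback scan within ±3 ungapped positions. Verdict: competent ⇔ core
histidines ∧ K ∧ Y. Gaps at located columns count as residue-absent
(conservative); a row entirely gapped across the motif span is reported
`unalignable` rather than classified.

## 4. Alignment (`msa`)

Needleman–Wunsch with affine gaps (BLOSUM62; gap of length L costs
`open + L·extend`, defaults 10/0.5; ties broken match > delete > insert),
Kimura-corrected distances d = −ln(1 − p − p²/5) capped at p = 0.85, UPGMA
guide tree (scipy average linkage), profile–profile merging with
mean-of-pairs column scores, and an optional leave-one-out refinement pass
accepted only when the affine sum-of-pairs score improves. Input order is
canonicalized (sort by id) so results are order-independent. This is a
deliberately simple progressive aligner, not a consistency-based one; the
output metadata says so.

## 5. Phylogenetics (`phylo`)

* **Models**: WAG, LG, JTT exchangeabilities and frequencies bundled as text
  data files with literature provenance; Poisson for tests. Q = S·diag(π)
  normalized to mean rate 1; P(t) via symmetric eigendecomposition.
* **Rate variation**: discrete gamma, 4 categories, mean-of-quantile rates
  renormalized to mean exactly 1; proportion of invariable sites mixed as
  (1−p_inv)·Γ-average + p_inv·(constant-pattern term). `+F` uses observed
  frequencies with a Laplace 1-pseudocount and counts 19 AIC parameters.
* **Likelihood**: Felsenstein pruning over unique site patterns; gaps/X are
  unit partial likelihoods. Verified against brute-force summation over all
  internal-state assignments (≤ 1e-10) and invariant under re-rooting.
* **Search**: neighbor joining (lowest-index tie-break, negative branches
  clamped to 0) for starting trees and bootstrap replicates; per-branch
  bounded scalar optimization (xatol 1e-6) cycled until the per-pass lnL
  gain < 1e-4; NNI hill-climbing with branch re-optimization per candidate,
  greedy first-improvement, optional random multi-start (default 1 start —
  desk-scale data; the production analyses this emulates used 100).
* **Model selection**: AIC on a fixed NJ topology, alpha optimized on a log
  grid up to 1e6 (so +Γ properly nests equal rates), p_inv on [0, 0.9].
* **Bootstrap**: column resampling, NJ per replicate (NNI optional), support
  = % of replicates containing the split.

## 6. Tree samples (`tree_support`)

Splits are canonicalized as the tip side not containing the lexicographically
smallest tip; trivial splits excluded. `maxdiff` is taken over the union of
splits observed in either sample (a split absent from one sample has
frequency 0 there — the usual bpcomp semantics). The convergence scan fixes
the ingested samples and scans burn-in 1–50% in 1% steps (the "generations
so far" dimension of an on-line scan collapses for finished samples),
choosing the minimizing burn-in, smallest on ties, and declaring convergence
iff min maxdiff ≤ 0.1. Majority-rule consensus inserts the (> 0.5,
necessarily pairwise-compatible) splits largest-first; supports are
100 × frequency exactly.

## 7. Reciprocal-hit network (`rbh_network`)

Smith–Waterman with affine gaps is the alignment kernel (verified against an
independent quadratic DP); Karlin–Altschul statistics with the gapped
BLOSUM62 convention λ = 0.267, K = 0.041 turn raw scores into bits and
E = m·n·2^(−bits), where m is the query length and n the total residue count
of the database — database-search semantics, so the two directions of a pair
differ when query lengths differ. An edge requires both directions to pass
the threshold ("reciprocal hits", any-hit semantics; a best-hit mode exists
for sensitivity analysis). The published threshold is printed as
"e-value <10^10", which can only be the typo for 1e-10 (10^10 would connect
everything); 1e-10 is the default and configurable.

Two thresholds play different roles: 1e-10 for HGT screening (clade-mixed
connected components), and a tight-cluster threshold of 1e-30 for *family
delineation* — in the presets within-family pairs sit near E ≈ 1e-50 and
cross-family pairs near 1e-11..1e-14, so the families are the tight
clusters by a wide margin.

## 8. Dollo events (`dollo_events`)

One gain per character at the MRCA of the presence tips (or at a constrained
ancestral node); losses are the roots of the maximal subtrees inside the
gain clade whose non-"?" tips are all absent — the unique minimum-cardinality
loss set given the gain node (oracle-checked by exhaustive enumeration).
"?" tips constrain nothing. Duplication-aware gain placement: a family's
gain node is the species-tree LCA of its own species united with the species
of its sister family clade in the gene tree, which moves a post-duplication
family's gain up to the duplication branch (e.g. a family lost in one early
lineage would otherwise be gained too shallowly).

## 9. Synthetic data (`synthetic_data`)

**What is emulated.** Multi-domain proteins evolve along a fixed,
preset-specific species tree by site-wise substitution under WAG with
4-category discrete-gamma rates (shape 1.0). Domain segments are drawn from
deterministic toy seed alignments (10 rows, 12% divergence from fixed
consensus templates — the same seeds the profiles are built from, so planted
domains are detectable). Signal peptides, TM regions, proline-rich and
propeptide segments are built by composition rules matching the annotation
detectors' definitions, and their defining composition is held fixed during
evolution (the hydrophobic character *is* the feature). Scheduled events
apply at the start of their branch: duplication (optionally with a founder
"burst" — a fraction of non-invariant sites randomized on the new copy,
emulating post-duplication divergence), gene loss, domain gain/loss, HGT
(the donor lineage's stem-node state is copied and evolved down the
recipient subtree, replacing any same-family gene), and catalytic knockouts
(scheduled residues to alanine).

**Purifying selection.** Exactly the six functional residues of the LOX
domain — the four motif histidines and the LTQ K/Y — are invariant unless
knocked out. The inter-motif scaffold drifts freely; this is what makes
planted families genuinely independent at the reciprocal-hit threshold
while keeping every evolved domain classifiable.

**Preset worlds** (counts fixed by the published repertoire):
`vertebrate_repertoire` — 7 families realizing exactly 5 architecture
classes (SP+PROPEP+LOX; SP+PRR+LOX; SP+PRR+PROPEP+LOX; SP+4xSRCR+LOX ×3
families; 4xSRCR+LOX+TM, the last a simulator convention for the
membrane-associated variant, not a literature claim);
`eumetazoa_duplication` — one duplication on the eumetazoan stem (burst
0.35) and loss of one paralog in cnidarians; `prokaryote_hgt` — two
independent bacteria→archaea transfers from different bacterial subclades
(founder divergence 0.55 between the two bacterial families);
`porifera_families` — three family-founding duplications (burst 0.5) on the
sponge stem with loss of the ancestral copy; `catalytic_panel` — wild type
plus first-histidine, histidine-core, LTQ-K and LTQ-Y knockouts (competence
flags 1,1,0,0,0 by construction).

**What is not emulated** — hence what a green test does not establish:
codon-level evolution, realistic indel processes (indels are optional,
geometric, confined to non-domain segments, off by default), rate variation
across branches, gene conversion, assembly/annotation noise in real
proteomes, and the database-scale search space of a real survey. Recovery
rates measured here are upper bounds on real-data performance.

**Reproducibility.** Every preset is a pure function of (name, seed):
bit-identical FASTA, tables and event logs per seed. Template and seed
alignments use a frozen internal seed and are independent of the user seed.

## 10. Pipeline (`pipeline_cli`)

Stage order: simulate/ingest → scan → annotate → align (scan envelopes where
found, whole single-domain sequences otherwise) → model selection → NJ tree
+ bootstrap ×2 seeds + convergence scan → catalytic assessment (a pristine
template reference row is added to the alignment) → RBH network at both
thresholds → Dollo events from family-cluster presence/absence → summary.
Per-stage seeds derive from the master seed with fixed offsets
(counter-based), so adding a stage never shifts another stage's randomness;
identical config + seed ⇒ byte-identical summary.

## Known limitations

* The progressive aligner does not implement consistency objectives; column
  counts on real LOX data will differ from MAFFT L-INS-i's.
* The profile HMM has no multi-hit state loop, no glocal mode, and no
  HMMER3 file-format compatibility; the greedy envelope decomposition can
  mis-handle overlapping repeats closer than 10 residues.
* E-value calibration is per-profile empirical; absolute E-values are not
  comparable to HMMER's or BLAST's.
* Tree search is NNI-only from an NJ start; likelihood surfaces with
  multiple optima need the multi-start option.
* Bayesian posterior probabilities are out of scope; the convergence scan
  applies to any ingested tree samples (here, bootstrap samples).
* Catalytic assessment is alignment-projected: heavily diverged rows can
  misalign at the reference columns and be scored non-competent even when
  the functional residues are present elsewhere in the row; on the
  deep-divergence presets this affects a sequence or two, exactly as it
  would on saturated real data.
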