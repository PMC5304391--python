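# Methods

## The inference problem

A stop-to-sense reassignment replaces a termination codon's meaning with an
amino acid in one lineage. In transcriptome data it appears as in-frame
occurrences of that codon (here UAG) inside otherwise conserved coding
regions, while translation termination falls exclusively to the remaining
stops (UAA/UGA). Two independent lines of evidence identify the amino acid
the reassigned codon encodes: the residues conserved at homologous
alignment positions in other species, and the fit of each candidate residue
to a phylogenetic substitution model. This package implements both, plus
the screening and bookkeeping around them.

## The likelihood scan

**Model.** Amino-acid substitution follows the LG empirical model: a
reversible CTMC with rate matrix Q_ij = R_ij·π_j (i ≠ j), R the published
symmetric exchangeabilities and π the stationary frequencies (shipped as
data in `_lg.py`). The diagonal is set to −(row sum) and Q is normalised so
−Σ_i π_i Q_ii = 1, making branch lengths expected substitutions per site.
Among-site rate variation uses k equal-probability discrete-gamma
categories with rates equal to the category means of Gamma(α, α) (computed
via the regularised incomplete gamma function), so rates are non-decreasing
and average exactly 1. Defaults: k = 4, LG's own frequencies; an empirical
(+F) mode counts frequencies from the alignment with add-one smoothing.
The mean-category discretisation (rather than median) is chosen because it
preserves the unit mean exactly and is the common default.

**Likelihood.** `tree_loglik` runs Felsenstein's pruning algorithm on a
fixed tree with fixed branch lengths: per-pattern partial likelihoods
propagate root-ward via P(r_c·t) = exp(Q r_c t), computed by symmetric
eigendecomposition of the π^(1/2)-similarity transform of Q (entries
clipped at 0 to absorb round-off; per-node rescaling guards against
underflow on deep trees). Gaps, X and ambiguous residues contribute
all-ones partials (missing data), so an all-missing column contributes
exactly 0. Identical site patterns are compressed first; this cannot change
the result and is verified by test.

**α estimation.** The gamma shape is fitted by bounded one-dimensional
maximisation over log α ∈ [log 0.02, log 100] (tolerance 1e−4) on the
alignment with all focal UAG cells masked as X, and then held fixed.
Estimates at the bounds are flagged: data with no detectable rate
heterogeneity drive α to the upper bound, which is reported rather than
silently accepted.

**The 20-hypothesis scan.** Conditional on "UAG codes for a single amino
acid at all positions", the focal row's UAG-backed cells are set to each
candidate a in turn and lnL_a computed with tree, branch lengths and α all
fixed — only the focal cells differ between evaluations, so the
log-likelihood splits into a background term (computed once) and a
focal-column term (recomputed 20 times). Branch lengths are deliberately
not re-optimised per hypothesis; holding everything but the focal cells
fixed makes the 20 scores directly comparable. Conditional probabilities
are the softmax of the log-likelihoods (log-sum-exp shifted by the
maximum), i.e. likelihood ratios against the sum of all 20 likelihoods —
interpreting "ratio of likelihood scores" on the likelihood, not the log,
scale; this interpretation exactly reproduces the published worked-example
probabilities at their printed precision (see `tests/test_acceptance.py`).
With zero UAG-backed columns the scan degenerates to 20 equal scores and
p = 0.05 each.

## Conservation voting

Candidate sites are focal-row columns backed by a codon of interest
(default UAG/TAG; canonical classes such as {CAA, CAG} give matched
controls). A site's flanks pass if each of the 5 columns on both sides has
no focal gap and reaches a configurable identity threshold (default 0.7 —
"well conserved" has no published quantitative definition, so the knob is
exposed). A column classifies to its most frequent residue iff that
residue's identity fraction reaches the threshold τ (0.9 hyperconserved,
0.5 permissive); a tied maximum yields NONE. This dominant-residue rule
makes the classified-site count monotone in τ. The focal cell is excluded
from the denominator (it is X or the codon under test by construction —
including it would make the threshold depth-dependent), as are gaps and X
in other rows; columns with fewer than `min_depth` (default 10) informative
residues never classify. Whether published analyses excluded the focal cell
from their denominator is not stated; the exclusion here is a documented
assumption.

## Stop scanning and codon usage

Internal stops are standard-code stop codons strictly before a 3' boundary
(the inferred termination codon, or the aligned-region end when homology
coordinates are supplied). The termination codon is the first in-frame stop
at or after the aligned region; with `uag_is_sense`, UAG is skipped and
scanning continues to the first UAA/UGA — the re-check applied to
transcripts whose first downstream stop is UAG. Transcripts without any
downstream stop are TRUNCATED; exactly one of the two outcomes is always
reported. Relative codon frequencies are percentages within meaning classes
(all codons coding the same amino acid under the supplied, possibly
non-canonical, code); termination codons count once per transcript, since
the stop class is per-gene termination, not UTR content. Ambiguous codons
(any non-ACGT base) translate to X, never count as stops, and are excluded
from frequency classes — conservative on all three counts.

## Screening

Filters over precomputed BLAST-style tabular hits (12 standard columns plus
query frame and subject taxonomic division; resolving division from subject
ids is the caller's job). A query passes if its five best hits (ranked by
e-value, bitscore tiebreak — the ranking key is a choice, as none is
published) are all eukaryotic and all hsps of the best hit share one frame;
queries whose top five are all archaeal/bacterial/viral are labelled
`contamination`. Homolog support requires ≥ 50 hits with e-value strictly
below 1e−30 (the boundary is strict: exactly 1e−30 fails). Alternative
transcripts deduplicate to the group member with the lowest best-hit
e-value (bitscore, then id, as tiebreaks). The two filters commute; every
failure carries machine-readable reasons. Coordinates convert from the
format's 1-based inclusive convention to 0-based half-open internally.

## Synthetic data

`synth.simulate_alignment` evolves alignments under the scan's own model
along a fixed tree, with per-site gamma categories. Reassigned columns are
simulated **conditional on the focal leaf carrying the true residue**:
because the model is reversible and at stationarity, this is implemented
exactly by evolving outward from the focal leaf (background columns start
from a draw from π, reassigned columns start from the true residue). The
conditioning is essential — overwriting the focal state after an
unconditional simulation would leave the other taxa uncorrelated with the
true residue, and no method could recover it; conditioning reproduces the
real situation of a UAG codon homologous to a conserved residue.
`emit_cds_fixture` reverse-translates gap-free alignments with weighted
synonymous codon choice (uniform by default; a skew preset makes TAG ~8% of
its family, mimicking the observed rarity of freshly reassigned codons),
writes TAG at focal reassigned columns, and appends a UAA/UGA terminator
with 56:15 odds, the proportion observed in the termination survey of the
rhizarian data. `emit_hit_fixture` builds hit tables whose screening
decisions equal planted pass/fail patterns. All routines take explicit
integer seeds (default 1337) and are deterministic given the seed.

What the generator does **not** emulate: alignment error, indels (a gap
knob exists but is off by default), lineage-specific composition, and codon
bias beyond the skew preset. Passing tests therefore demonstrate the
correctness of the algorithms under the model's assumptions, not robustness
to real-data artefacts such as misalignment or assembly chimeras.

## Problem sizes and numerical choices

Default test and verification scales: oracle equivalence on 4–5-taxon,
≤5-site instances (100 random draws, agreement to 10 decimals against
exhaustive enumeration with scipy's expm); α recovery on 12 taxa × 2000
sites (20 seeds); scan recovery on 50 replicates of 12 taxa × 550 sites
with 50 reassigned columns at α = 0.8, requiring the true residue at
p > 0.99 in ≥ 95% of replicates. Random trees use uniform branch lengths in
[0.02, 0.3]. Softmax conservation holds to 1e−12; discrete-gamma means to
1e−10. The simulation-derived observation that the runner-up hypothesis for
a true glutamine is leucine (driven by leucine's high stationary frequency
at divergent sites) is what the generator's conditions produce; real
datasets have shown chemically similar residues (e.g. glutamate) as
runner-up instead, which depends on the actual conservation structure.

## Known limitations

- Single-meaning hypothesis only: no per-site posterior decoding, no
  context-dependent dual-meaning (readthrough-style) codes.
- Trees, branch lengths and alignments are consumed as given; no topology
  search, no mixture models, no branch-length re-optimisation per
  hypothesis (an explicit design choice, see above).
- Reverse-strand transcripts are out of scope; inputs are assumed
  mRNA-sense.
- Alignment trimming is the caller's responsibility.
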