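# Methods

`dupreloc` implements an analysis of protein subcellular relocalization in
recently duplicated gene pairs: discovering candidate duplicate pairs from
gene-family trees, assigning outgroup orthologs, testing each pair for
asymmetric protein-sequence evolution and positive selection against the
outgroup, classifying localization divergence, and testing whether
relocalized pairs are enriched for asymmetric evolution and for
isoelectric-point shifts.  This note records the models, the numerical
choices, and what the synthetic data do and do not establish.

## Duplicate-pair discovery

Candidate pairs are the two-member monophyletic groups (cherries) of a
strict-majority consensus over a bootstrap tree set.  Trees are read as
rooted, as written in the Newick source; a clade is retained when it
appears in strictly more than 50% of trees (a clade in exactly half of the
trees is excluded).  Retained clades are mutually nested or disjoint by
construction, so the consensus always assembles into a tree; each
consensus node carries its support fraction.  Pairs already attributed to
the alpha whole-genome duplication (alpha-WGD) or to two-gene tandem
clusters are labelled from the supplied rosters, order-insensitively; a
pair in both rosters is an error.  The remaining "other" duplicates are
restricted to recent events with a pairwise dS cutoff of 1.0 —
approximately the mean age of the alpha-WGD duplicates — applied
inclusively (dS = 1.0 is kept; the boundary choice is configurable).

## Ortholog assignment and triangulation

Similarity hits (BLAST tabular, 12-column outfmt-6 dialect) are filtered
on e-value ≤ 1e-5 and coverage: the reported alignment length (column 4,
gaps included) must be ≥ 60% of the shorter protein's full length.
Orthologs are reciprocal best hits, where "best" means highest bit score,
ties broken by lowest e-value and then lexicographically smallest subject
id so the result is deterministic; a one-way best hit is an optional
fallback, recorded in the `provenance` field.  When several outgroup
species qualify, a configurable species-priority list (closest outgroup
first) picks one.  A candidate triplet (dup1, dup2, ortholog) is kept only
when dS(dup1, ortholog) > dS(dup1, dup2) and dS(dup2, ortholog) >
dS(dup1, dup2), both strictly — the duplication must postdate the
speciation.  Non-finite (saturated) dS estimates reject the triplet as
unestimable.

## Clock vs free-rate test

Each retained pair is analyzed on the unrooted star tree joining dup1,
dup2 and the ortholog.  Protein likelihoods use the Jones–Taylor–Thornton
empirical model with its published frequencies (an empirical +F mode is
available); the per-site likelihood marginalizes the internal node state,
and gapped or ambiguous residues are marginalized as missing data.  The
free model fits (b1, b2, b3); the clock model constrains b1 = b2 with b3
free.  Twice the log-likelihood difference is referred to chi-square with
one degree of freedom, and p-values are Benjamini–Hochberg adjusted across
the cohort.  When Q < 0.05, the duplicate with the longer fitted branch is
called the accelerated copy; otherwise no call is made.

Branch lengths are bounded in [1e-9, 50] and optimized by L-BFGS-B from a
deterministic grid of five starting scales around a mismatch-based
distance guess (relative lnL tolerance 1e-8 equivalent).  Because the
likelihood in three branch lengths is well behaved, bulk simulation loops
use two starts; single-pair analyses use the full five.

Calibration (reproduced by `scripts/acceptance.py` and the test suite):
on 500 clock-simulated triplets of 1,000 sites with b1 = b2 = 0.1 and
outgroup branch 0.3, the test rejects at alpha = 0.05 in about 5% of
replicates (the chi-square approximation is slightly anticonservative at a
few hundred substitutions per branch and converges with sequence length).
With b1 = 0.3 = 3·b2 at 2,000 sites, essentially all significant
replicates name the correct accelerated copy.

## Codon models, dN/dS and the branch-site test

The codon machinery is a Goldman–Yang-style model on the 61 sense codons
of the standard code: off-diagonal rates pi_j · kappa^[transition] ·
omega^[nonsynonymous] for single-nucleotide changes, scaled to one
expected substitution per codon per unit branch length, with F3x4
frequencies estimated from the alignment (a half-count is added to
per-position nucleotide counts so no sense codon has zero frequency).
Gapped or ambiguous codon columns are removed before fitting (complete
deletion); protein-level fits instead marginalize gaps.

Pairwise dN/dS fits (t, kappa, omega) by ML and decomposes t into dN and
dS through the synonymous/nonsynonymous flux shares of the fitted model,
divided by three times the corresponding site fractions (flux shares at
omega = 1), so dN/dS equals the fitted omega identically.  The
Nei–Gojobori (1986) counting method with Jukes–Cantor correction is
implemented as an independent cross-check (equal-weight averaging over
mutational pathways; changes to stop codons count as nonsynonymous sites,
the convention of standard implementations, against which the routine is
verified exactly).  The two routes agree within 20% for divergences up to
t = 0.3; the residual gap is the known transition/transversion bias of
equal-weight counting, not estimation noise.

Branch-specific asymmetry in dN or omega is tested by LRT on the triplet:
the alternative gives each branch its own length and omega; the null
constrains omega1 = omega2, or dN1 = dN2 by tying b2 to b1 through the
nonsynonymous flux ratio.

The branch-site test designates the accelerated duplicate as foreground
and mixes four site classes (0: omega0 < 1 everywhere; 1: neutral
everywhere; 2a/2b: omega2 on the foreground over an omega0 or neutral
background).  Site classes share one mutation process: a class's rate on
a branch is proportional to its expected flux (A + omega·B), normalized so
the branch length is the class-averaged substitution count.  The
alternative frees omega2 ≥ 1 (8 free parameters: three branch lengths,
kappa, two simplex coordinates for p0/p1, omega0, omega2); the null fixes
omega2 = 1 (7 parameters).  The LRT uses chi-square with df = 1 — the
simple reference rather than the 50:50 boundary mixture — which is
conservative under the null, as the null calibration shows (rejection
well below 5% on 60 null replicates of 200 codons).

## Bayes Empirical Bayes site detection

Positively selected sites are located by empirical-Bayes averaging over a
uniform prior grid: 10 points per direction on the (p0, p1) simplex
(pairs with p0 + p1 < 1), 10 points for omega0 in (0, 1), and 10 for
omega2 in (1, 11); grid density is configurable.  Branch lengths and
kappa are fixed at their MLEs, and the per-class rate normalizers are also
fixed at the MLE so the grid factorizes into reusable likelihood blocks
(a deliberate simplification; freeing the normalizers per grid point
changes posteriors negligibly at the divergences involved).  A site's
posterior probability of belonging to class 2a/2b is averaged over the
grid with weights proportional to each grid point's full-data likelihood;
only sites with posterior > 0.95 (strict) are reported, as position,
foreground residue and posterior.  Under null simulation BEB flags zero
sites in ≥ 95% of replicates; under simulated selection (omega2 = 6 on
10–20% of sites, ≥ 500 codons) flagged sites are ≥ 80% true positives.

## Localization classification and group statistics

Compartment annotations are sets of controlled-vocabulary tokens,
compared case-insensitively; "cyb" (cytosolic body) is distinct from "cy"
(cytosol).  A pair whose two GFP records come from different studies or
different conditions is excluded under the strict same-study rule.  Two
equal sets are "same"; disjoint sets are a complete change; any other
overlap (expansion, contraction, partial overlap) is a partial change.
Relocalized means complete or partial change.

Enrichment of asymmetric evolution among relocalized pairs uses the
one-tailed (enrichment-direction) Fisher exact test on the 2x2 table and
a Monte Carlo test of the DIF statistic, the absolute difference in
asymmetry frequency between groups.  Two null schemes are implemented and
reported: `resample` (default) redraws every pair's flag at the pooled
frequency with group sizes fixed; `permute` shuffles the observed flags,
whose tail coincides with the Fisher tail.  The Monte Carlo p is the
plain fraction of 10,000 simulated DIF values at least as large as the
observed one (a (k+1)/(n+1) estimator is exposed as an option), computed
from a seeded generator and bit-reproducible.  On the observed cohort
(8/19 vs 13/109) DIF_obs ≈ 0.302, the Fisher tail is 3.4e-3, and the
converged resample tail is 1.8e-3.

Isoelectric points use the Henderson–Hasselbalch net-charge function with
the EMBOSS pK set (N-terminus 8.6, C-terminus 3.6; side chains C 8.5,
D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1), solved by bisection on
[0, 14] to 1e-4 pH; the charge function is strictly decreasing, so the
root is unique.  Within-pair |ΔpI| values are compared between groups
with a Welch (unequal-variance) two-tailed t-test.

## Synthetic data: what it does and does not show

The simulators generate exactly the structures the analysis assumes:
stationary, reversible substitution along star-tree branches, i.i.d.
sites (discrete classes in the codon case), ungapped sequences, and
cohorts with Bernoulli or exact-count flags.  Default cohort parameters
reproduce the observed study: 128 pairs, 19 relocalized, asymmetry
frequencies 8/19 and 13/109.  Every stochastic operation takes an
explicit seed (documented default 0), with per-pair substreams derived
from (seed, pair index) so cohort order never changes draws.

Passing tests therefore demonstrate internal statistical correctness —
calibrated type-I error, consistent estimators, faithful reproduction of
the printed cohort statistics — not robustness to features of real data
the simulator omits: alignment error, indels and gap patterns,
among-site rate autocorrelation, codon-usage heterogeneity along genes,
or localization-annotation noise.  Gap handling is exercised with
fixtures, not the simulator.  The published per-gene branch-site numbers
(log-likelihoods near -6,307, omega2 = 6.229 and a specific BEB site
list) derive from the original multi-species alignments, which are not
distributable here; the package instead verifies the model's structure
(one extra free parameter in the alternative, omega2 pinned at 1.000 in
the null, 2dL = 9.58 from the published likelihood pair) and its
behaviour on data simulated under known truth.

## Reporting conventions and limitations

Fisher and Monte Carlo p-values are reported at full precision; note that
the exact Fisher tail for the observed table is 3.4e-3, which a
one-significant-figure report may print as either 3e-3 or 4e-3.  The
randomization scheme, replicate count and seed are embedded in every
result object.  Known limitations: the triplet machinery is restricted to
three taxa (no larger clock models); site-model families beyond what the
branch-site test requires are not implemented; pH-dependent corrections
beyond the fixed pK set are out of scope; and the dS age filter shares
one estimator with the pair tests rather than reproducing any particular
external tool's defaults.
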