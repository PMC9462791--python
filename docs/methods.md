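# Methods

`ctsevo` implements the computational toolkit behind comparative analyses
of cardiotonic-steroid (CTS) resistance evolution in the Na,K-ATPase
α-subunit (ATP1A) family: ancestral-state-based convergence counting,
correlated evolution of binary site states, dose-response statistics for
engineered enzymes, and the localization of background sites that make a
substitution's effect depend on the protein it lands in. This note
documents the models, the defaults, the numerical choices, and what the
synthetic data do and do not emulate.

## Ancestral state reconstruction

Marginal reconstruction uses Felsenstein's pruning algorithm on a fixed
rooted tree with branch lengths in expected substitutions/site. The
substitution process is an empirical exchangeability model (JTT shipped as
package data; the "+F" variant takes frequencies from the alignment) with
discrete-gamma rate heterogeneity: `n_categories` (default 4) categories
at the means of equal-probability quantile bins, rescaled to mean rate 1.
The generator is Q = S·diag(π) normalized to one expected substitution per
unit branch length; transition matrices come from the eigendecomposition
of the symmetrized generator diag(√π)·Q·diag(1/√π), which is exact and
cheap to reuse across branches and categories.

Posteriors combine an up-pass (partial likelihoods of the data below each
node) and a down-pass (outside likelihoods), each scaled per node and
site with log-scale bookkeeping so that rate categories combine with the
correct weights: P(state | data) = Σ_k w_k · up_k · out_k / Σ_k w_k · L_k.
The root prior is the equilibrium distribution. Gaps and unknown residues
are missing data (unit partial likelihoods); IUPAC ambiguity codes expand
to uniform support over their possibility set; a gap state is never called
at an ancestor. State calls require max posterior probability above a
threshold (default 0.8); everything below is treated as missing
downstream. The gamma shape can be estimated by 1-D bounded ML
(`fit_gamma_shape`, log-scale golden-section over [0.05, 20]); a fit
pinned at the upper bound is flagged as a flat likelihood.

Oracle: on trees of ≤6 tips, posteriors and log-likelihoods are tested
against exhaustive enumeration over all internal-state assignments at
tolerance 1e-8.

## Convergence counting

Substitution events are one per (branch, site) where the states at both
ends of the branch are called and differ. Site labels live in a reference
coordinate system (for ATP1A, the conventional sheep numbering: ungapped
position in the reference sequence plus a configurable offset, so other
numbering conventions are a parameter, not a code change). A putative
alternatively spliced region (sites 810–840) is excluded by default in the
pipeline configuration.

All unordered branch pairs are compared except sister branches and
ancestor–descendant pairs. At each shared substituted site: same derived
state → convergence (the ancestral states need not match); same ancestral
state with different derived states → divergence; different ancestral and
different derived states fall in neither class (the two quoted definitions
do not cover that cell, and we do not invent a third). The per-pair
summary is (C+1)/(D+1). Pair distance is the sum of branch lengths on the
path between the two branches' child nodes, excluding the two focal branch
lengths themselves — an explicit convention, since "distance between
branches" admits several endpoint choices. The distance trend is a running
mean with window 0.05 substitutions/site (step 0.01; the step is our
choice) and a percentile bootstrap band from 100 resamples of the pairs
within each window. Per-site convergence-vs-distance tests encode
convergence 1 / divergence 0 per pair and fit a logistic regression of
outcome on distance (statsmodels ML; complete separation and degenerate
outcomes are flagged rather than reported as trustworthy p-values).

Under our event model a branch carries at most one ancestral→derived call
per site, so multiple hits within a branch are invisible by construction.

## Correlated evolution (Pagel's discrete model)

Sites are recoded relative to the reconstructed most recent common
ancestor of the clade: 0 = ancestral state, 1 = anything else, gaps
missing. Singleton sites (fewer than two derived tips) and sites with more
than 80% missing entries are excluded (exactly 80% is kept). Branch
lengths are rescaled by a single constant to mean 0.1 before fitting.

A site pair evolves as a 4-state compound chain over (0,0), (0,1), (1,0),
(1,1) with double transitions forbidden. Two model families are fitted:

* base: independent null (4 rates: gain and loss per site, shared across
  the other site's states) vs dependent alternative (all 8 rates), LRT
  df = 4;
* restricted: all reversal rates to the ancestral state fixed at 0 —
  appropriate when branches are so short that revisiting a state is
  unlikely — with null q13 = q24 and q12 = q34 (2 rates) vs alternative
  with 4 free gain rates, LRT df = 2. (The source wording for the
  restricted family is ambiguous about which 4- and 2-parameter models are
  compared; we implement 2 vs 4 as the constraint quotes jointly imply.)

Because the coding makes the compound state (0,0) the ancestor by
construction, the root state is fixed at (0,0) by default (uniform and
stationary priors are available). Likelihoods use pruning with per-branch
transition matrices from a single eigendecomposition of the 4×4 generator,
with a scipy `expm` fallback when the eigenbasis is ill-conditioned
(defective generators occur when rates coincide under the restricted
constraints). Fitting is multi-start L-BFGS-B in log-rate space over
[1e-4, 1e3] (default 25 starts; per-site scans and simulation studies use
5–10, which suffices for the 2–4-parameter models). The LRT statistic is
floored at 0. Ranking takes the top 5% of sites by −log p with ties broken
by site label; multiple testing is deliberately left to this ranking step.

Oracles and calibration: pruning equals enumeration on ≤5-tip trees
(1e-8); the type-I error of the restricted LRT at α = 0.05, measured over
300 simulations of independent evolution on a 100-tip tree, falls within
the exact binomial 95% band around 0.05; power against 10× dependence
(q24/q13 = 10) is also reported by the acceptance script. The power and
type-I runs use 100-tip trees to keep the suite inside ordinary test
runtimes; power at 100 tips is a conservative stand-in for larger trees.

## Dose-response and activity statistics

Raw absorbances are calibrated against the fully inhibited background
well; percent non-inhibited activity is 100·(well − background)/(control −
background), with technical replicates averaged before any statistics.
Baseline activity converts the background-corrected control absorbance to
mM phosphate through a linear standard curve (seven standards, 0–1.2 mM)
and then to nmol Pi per mg protein per minute using the assay volume in
µL (1 mM = 1 nmol/µL). The default volume of 1 µL is a deliberate
"volume-free" convention — activity numerically equals mM Pi/(mg·min) —
because plate volume is an instrument detail; the synthetic plates use
50 µL so that phosphate concentrations land inside the standard range.
Defaults: 100 µg protein, 20 min incubation.

log10 IC50 comes from least squares on the logistic
y = 100/(1 + 10^(s·(x − m))) with asymptotes fixed at 100 and 0, slope
constrained positive, multi-start over s ∈ {0.5, 1, 2}, tolerances 1e-10.
Fits whose midpoint lands at or above the highest tested concentration
(10⁻³ M) are censored — the IC50 is unmeasurable in range — and any
censored replicate censors the construct summary. Replicates are fitted
separately; the summary is the mean ± SE of per-replicate log10 IC50.

Construct-level tests mirror the analysis conventions of this assay
family: paired t-tests with a Bonferroni multiplier (default 15 tests)
and zero-variance guards; a two-factor ANOVA (background × carries-state)
whose interaction term is the background-dependence (epistasis) test, with
reverse substitutions aligned to the forward direction by coding each
construct by whether it carries the focal derived state; an exact
two-sided binomial direction test (2 × the smaller tail, capped at 1); a
chi-squared uniformity test of p-values (default 5 equal-width bins for
panels of ~15 p-values — binning is configurable since the convention is
not standardized); and Spearman correlations with midrank ties and an
optional permutation p for small panels. Bonferroni is used throughout;
no FDR.

## Localizing background sites (epistasis)

The effect of introducing a derived state is E = (mut − wt)/wt·100 in
percent activity. For every unordered pair of backgrounds given the same
derived state at the same site, Δ = |E1 − E2| measures background
dependence (Δ is defined as an absolute difference; the signed version
appears only inside the comparison enumeration). Variant sites across the
wild-type panel are binarized per comparison (0 = same state in both
backgrounds, 1 = different; gap vs residue counts as different).

Because a small panel cannot separate collinear sites, sites are grouped
into connected components of the graph joining columns with |Pearson r|
above a threshold (default 0.8; zero-variance columns form their own
groups; representative = lowest site label). Nested linear models of Δ
then add groups in decreasing order of marginal variance explained (each
group's representative indicator plus the mutated-site covariate, which is
included in every model). Model selection offers an LRT walk (stop at the
first non-significant addition) and an information criterion; the
information criterion used for selection is the small-sample AICc, because
with ~11 comparisons plain AIC essentially always accepts the first
ascertained group even for pure-noise responses (the table reports both
AIC and AICc). Significance of the ascertained model is established by
permutation: Δ is permuted across comparisons (default 10,000 times), the
entire ascertainment — re-rank groups, take the best two — is repeated on
each permutation, and p = (1 + #{null R² ≥ observed})/(1 + n_perm); p = 0
is never reported. The association between Δ and divergence restricted to
a site set uses Pearson r with the same one-sided add-one permutation.

## Structure proximity and overlap tests

Distances are CA–CA in Å from a PDB chain (altlocs resolved to highest
occupancy). Alignment sites map to structure residues through an explicit
two-column table — no automatic sequence-to-structure alignment, to avoid
silent off-by-one errors. The proximity statistic is the median CA
distance from the focal site to the candidate set; the null resamples
equal-size sets from the universe of variable sites (default 1000 draws),
counting ties as ≤ observed (conservative). Set-overlap enrichment is the
exact hypergeometric upper tail P(X ≥ k); the universe size is always an
explicit argument because printed overlap p-values in this literature
rarely state it.

## Synthetic data

Every generator is seeded and returns the ground truth needed to score
the downstream module.

* Trees: pure-birth (Yule) with exponential waiting times, rescaled to a
  requested mean root-to-tip depth or mean branch length.
* Alignments: site-independent CTMC under the same JTT+gamma model, with
  optional planted convergence — at focal sites each branch independently
  adopts the target state with a fixed probability (default 0.15 toward
  arginine). Conversion probability rather than a selection model, because
  it gives exact, countable truth for convergence recovery.
* Binary pairs: exact Gillespie simulation of the 4-state compound chain;
  single-branch transition frequencies are tested against expm(Qt).
* Assay panels: 8 wild-type backgrounds, 113 variant sites, substitutions
  at loop sites 111 and 122 introduced on four backgrounds each (spread to
  cover the panel), 3 biological replicates, 6 ouabain concentrations,
  5-percentage-point Gaussian dose noise truncated at physical bounds,
  wild-type activities uniform on 3–18 nmol/(mg·min), wild-type log10 IC50
  uniform on [−7.5, −4.5] with ±1 log shifts from substitutions. These are
  the scales of the study this package is built around.

  Background divergence patterns are phylogenetic: the wild-type
  backgrounds are related by their own Yule tree and every variant site
  substitutes exactly once on one branch, so its derived set is a clade
  (an infinite-sites model). This reproduces the strong collinearity of
  real panels — many sites sharing a handful of clade patterns — which is
  what makes correlation grouping meaningful; independent per-site coin
  flips would instead produce dozens of distinct patterns and an
  unrealistically permissive ascertainment null. The planted causal sites
  form two collinear blocks on nested clades (default 3 + 2 sites), so
  causal divergence between any two backgrounds is direction-consistent
  and the expected Δ of a comparison is exactly (causal differences) ×
  (effect per difference). The default effect is 25% per causal-site
  difference against ~5-percentage-point effect noise after replicate
  averaging: signal-to-noise 5.

What the synthetic panels do not emulate: homoplasy in the background
sequences (each variant site changes once), measurement drift between
plates, correlated noise across replicates of one membrane preparation,
and any nonlinearity between enzyme activity and fitness. Passing
recovery tests therefore show that the inference machinery is correct and
calibrated under the stated model, not that real panels of eight
backgrounds always carry recoverable signal.

## Problem sizes in the test suite and acceptance script

Simulation studies run at sizes chosen to keep the full suite in ordinary
local-test runtimes while preserving the statistical point of each check:
300 null simulations on 100 tips for LRT calibration, 100 seeded panels
with 999 permutations each for localization recovery, 100 noisy curves for
IC50 error, 60 simulations for LRT power. The acceptance script
(`scripts/acceptance.py`) recomputes all of these from scratch under a
single seed.

## Known limitations

* Marginal ASR only; no joint reconstruction and no codon models.
* The Pagel fits are ML only (no MCMC) and do not attempt numerical
  parity with existing implementations; constraint sets, not numbers, are
  the contract.
* Convergence counting uses point calls above the posterior threshold;
  ancestral uncertainty is not integrated over.
* The localization analysis attributes variance to site groups, not to
  individual sites; with eight backgrounds, sites within a group are
  genuinely indistinguishable.
* The numbering map between alignment sites and structure residues is the
  user's responsibility (by design).
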