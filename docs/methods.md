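# Methods

## Data model

A tumour is a rooted clone tree: clones are nodes, and the branch entering
a clone carries the genes newly mutated there.  A clone's genotype is the
union of branch gene sets along its root path, so genotypes are monotone
along lineages.  A gene pair is *clonally exclusive* in a tree when no
clone's genotype carries both genes; this "no doubly-mutated clone"
definition equals branch incomparability when every gene sits on a single
branch, and extends naturally to parallel evolution (a gene on several
branches).  The complement — same branch or ancestor/descendant branches —
is clonal co-occurrence.

Per patient, the background exclusivity rate r is the fraction of unordered
gene pairs in the tree that are exclusive, averaged over the patient's tree
samples when phylogenetic uncertainty is represented by several trees.
Patients are classified by this averaged r: r = 0 (all-linear), r = 1
(all-star) or informative (0 < r < 1).  With posterior samples, a pair's
outcome O is the fraction of trees *containing both genes* in which the
pair is exclusive; trees lacking one of the genes are excluded from the
denominator.  This denominator convention (and the classification by
averaged r rather than by topology shape, which coincide for single-tree
patients) is a deliberate design choice, configurable at the API level
through the binarisation threshold.

Clone-frequency filtering (default threshold 1%) merges a low-frequency
clone into its parent: branch genes are re-attached, frequency mass added,
children re-parented.  Filtering therefore changes the clone partition but
never the gene content of a tree.  The root is never removed.

## Placement test

With informative patients i = 1..n carrying the pair, the null
log-likelihood is l0 = Σ O_i log r_i + (1 − O_i) log(1 − r_i).  The
alternative shifts every rate on the logit scale, logit(r′_i) = logit(r_i)
− Δ, and maximises l1(Δ) over Δ ∈ [−10, 10]; LLR = 2(l1 − l0) is referred
to χ²₁.  The sign convention makes Δ < 0 exclusivity enrichment.  The ±10
bound is numerical: beyond it the shifted rates saturate at 0/1 and the
likelihood is flat to machine precision; an optimum within 1e−6 of a bound
is reported as ±∞.  The objective is a sum of concave log-logistic terms,
so a vectorised golden-section search (interval tolerance 1e−8) finds the
global maximum deterministically.

**Exact version.**  For n ≤ 12 (configurable) all 2ⁿ binary outcome vectors
b are enumerated with null probability P(b) = Π[r_i b_i + (1−r_i)(1−b_i)];
the p-value sums P(b) over vectors with a larger LLR than observed plus
*half* the probability of vectors with an equal LLR.  This mid-p/half-tie
rule gives the p-value a null expectation of exactly one half, which the
Monte-Carlo smoothing argument justifies: adding vanishing beta noise to
the rates splits each tie group evenly into more and less extreme samples.
Ties are detected at a relative tolerance of 1e−9 on the LLR — enumerated
ties are exact in real arithmetic, and the tolerance only absorbs float
noise from the optimiser.  The exact test requires binary outcomes;
fractional posterior outcomes are binarised at 0.5 (the chi-squared
variant accepts fractions directly, since l0 and l1 are linear in O).

**Monte-Carlo smoothing.**  Each of M samples perturbs every rate with a
Beta(νr, ν(1−r)) draw (ν defaults to 10), draws outcomes at the perturbed
rates and recomputes the LLR at those rates; the p-value is the fraction of
samples with a strictly larger LLR.  ν → ∞ recovers the exact test.

**Alpha budgeting.**  Before testing, each pair's minimum achievable exact
p-value (over all 2ⁿ outcomes) is computed; pairs with a minimum above the
significance level can never become significant and are removed so they do
not dilute the Benjamini–Hochberg correction.

## Occurrence test

Under the null that gene pairs are interchangeable, a pair lands in patient
i with probability proportional to the number of pairs the patient
possesses, w_i = C(g_i, 2).  Conditioning on the carrier-set size, P0(S) =
Π_{i∈S} w_i / e_{|S|}(w) — the Fisher non-central hypergeometric form —
with the elementary symmetric polynomial e_k computed by the standard
O(N·k) dynamic programme on weights rescaled by their maximum (log-domain
assembly keeps cohort-scale normalisers finite).  The alternative tilts
weights by w′_i = 2 w_i [ρ(1−r_i) + (1−ρ)r_i], logit ρ = Δ, and the
maximised LLR is referred to χ²₁; the output flags this p-value as
approximate, since enumerating all C(N, |S|) sets for an exact version is
prohibitive.  The eligible cohort comprises patients with w ≥ 1 (patients
with fewer than two genes have zero selection probability; including them
is available as a switch and changes nothing).  The tilt objective is
maximised by a 41-point grid scan with bounded Brent refinement, which is
robust if the profile is not unimodal.

## Combined test

Setting Δ = Δ_placement = Δ_occurrence, the identities r′_i =
(1−ρ)r_i / D_i and 1−r′_i = ρ(1−r_i)/D_i with D_i = ρ(1−r_i) + (1−ρ)r_i
collapse the joint log-likelihood: per selected patient the terms reduce to
log 2 + log w_i + O_i log((1−ρ) r_i) + (1−O_i) log(ρ(1−r_i)), so the
selected patients' weights and rates cancel in the likelihood ratio and

LLR(m) = 2 max_ρ [ n_t log 2 + m log(1−ρ) + (n_t−m) log ρ + log e_{n_t}(w)
− log e_{n_t}(w′(ρ)) ],

where m counts carriers whose trees show the pair as exclusive — star trees
count as exclusive (O = 1 automatically) and linear trees as co-occurring
(O = 0); informative patients contribute their binarised outcome.  The
statistic depends on the data only through m ∈ {0..n_t}, so the exact
p-value enumerates m with the same half-tie rule.  The null P(m) is
computed by a bivariate dynamic programme over patients tracking (selected
count, exclusive count) with per-patient factors {unselected: 1, selected
co-occurring: w_i(1−r_i), selected exclusive: w_i r_i}, normalised by
e_{n_t}(w).  Both the reduced LLR and the DP are cross-validated in the
test suite against direct joint-likelihood optimisation and full
set-by-outcome enumeration (agreement to 1e−8 and 1e−12 respectively).
Note that when the carrier set is the whole cohort the occurrence component
degenerates but the placement component remains, so the combined LLR need
not vanish; it reduces exactly to the placement LLR in that case.
Fisher's-method combination of the two marginal p-values is provided as a
secondary summary only.

## Naive baselines

Each clone of each carrier tree contributes one unit to a 2×2 table by its
genotype; Fisher's exact test, the G-test (likelihood-ratio chi-squared,
1 df, no Williams correction) and the log odds ratio with the normal
approximation are applied.  The Haldane–Anscombe +0.5 correction is added
to all cells only when some cell is zero; degenerate margins yield p = 1.
Negative z means exclusivity.  Patients with several tree samples
contribute their first tree by default.  These tests exist to demonstrate
the confounding induced by ignoring clone ancestry.

## Synthetic data and study conditions

Background rates are drawn from Beta(2, 3) (mean 0.4), which mimics the
rate distribution of real single-cell AML cohorts; effects are planted by
the same logit shift the tests estimate.  The naive-comparison null draws
uniform random binary trees (Rémy-style uniform edge insertion; any
uniform-over-shapes scheme suffices because the downstream null needs only
mutation exchangeability) with 10 inner branches and 20 mutations placed
uniformly with replacement, one clone per inner branch, collated into 400
sets of 10 trees.

The full-cohort generator emits the clone-per-row TSV: roughly half linear
patients, a few star patients and a core of branched patients (default 30
patients: 10 informative carriers of the planted pair, 3 informative
non-carriers, 14 linear, 3 star; 10 background genes, 4–7 genes per
patient, 3–6 inner branches).  These proportions mirror the mostly-linear
composition reported for AML single-cell cohorts.  The planted pair's
exclusivity indicator is drawn as Bernoulli(shift_rate(r, Δ)) and realised
by placing the two genes on an incomparable or comparable branch pair
chosen uniformly.  What the generator does *not* emulate: sequencing noise
and tree-inference error (trees are taken as given), mutation hotspots,
clone-frequency structure, and correlated gene placement beyond the single
planted pair — so passing tests demonstrate correctness of the statistical
machinery under the stated model, not robustness to upstream inference
error.

Default study sizes: 10⁴ replicates for calibration, 10³ per power cell,
400 tree sets for the naive comparison and 200 cohorts for parameter
recovery; these match the reported experiments at sizes that keep a full
run in minutes on one core.

## Numerical choices and degenerate inputs

* Rates entering the placement likelihood must lie strictly in (0, 1);
  generators clip draws to [1e−12, 1 − 1e−12] and patient classification
  uses a 1e−12 tolerance on the averaged r.
* LLR values are clipped at zero (optimiser noise only; asserted
  non-negative within tolerance).
* Occurrence/combined: |S| = N or all-equal rates give a flat profile and
  llr = 0; selected patients with zero tilted weight give −∞ log-probability.
* The exact enumeration refuses n above the configured limit and fractional
  outcomes; the error directs callers to the chi-squared or Monte-Carlo
  variants.
* Pair ranking breaks p-value ties by larger LLR (stable sort).
* Self-pairs and always-co-placed gene pairs receive no special casing.

## Known limitations

* No exact occurrence-only test (combinatorially prohibitive by design).
* The combined test binarises fractional posterior outcomes; a fully
  fractional combined test would need a different null for m.
* Pathway-level analysis relabels genes before testing; overlapping
  pathway memberships (one gene in two pathways) are not supported.
* Higher-order (three or more genes) exclusivity patterns are out of scope.
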