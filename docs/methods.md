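# Methods

This note records the modelling conventions, default parameters and
design choices behind `kinassign`, and what the synthetic benchmarks do
and do not demonstrate.

## Sequence windows

Phosphosites are identified by protein accession, 1-based position and
acceptor residue (S, T or Y). Scoring operates on 15-residue windows
(±7 around the acceptor). Positions outside the protein are padded with
`'-'`; non-standard residues (U, B, Z, O, J) map to `'X'`. Both symbols
are excluded from the 20-letter counting alphabet but tracked: pad
counts at a column are converted into extra background-proportional
pseudocount mass, so terminal sites are neither rewarded nor punished.
Acceptor residues that mismatch the supplied sequence (isoform drift)
raise an error in strict mode and are flagged in permissive mode.

## Specificity matrices

*Sequence weighting.* Henikoff position-based weights down-weight
redundant windows: each column contributes 1/(r·s) to a window's weight
(r distinct symbols in the column, s the count of the window's own
symbol), summed over columns and normalized to sum to the number of
windows. Pad and unknown symbols participate as ordinary symbols.

*Counting and pseudocounts.* Weighted counts per column over the
20-letter alphabet receive background-proportional pseudocounts with
total mass B = √N_eff per column by default (N_eff the column's
weighted non-pad count). The mass is configurable; `"prop"` selects
B = 1 + 0.05·N_eff, which keeps smoothed minimum frequencies — and
hence theoretical score ranges — stable across training-set sizes.

*Column weights.* Each column is weighted by the relative entropy
(KL divergence, bits) of its frequency vector versus the background.
Relative entropy separates well-resolved from degenerate positions more
strongly than information content, which is why it is the weighting of
choice here. The plug-in KL estimate is biased upward by roughly
(k−1)/(2·N_eff·ln 2) bits for k=20 residue categories; this
Miller–Madow term is subtracted (floored at zero). Without the
correction, models trained on few substrates spuriously weight every
column, inflating their score ranges in a size-dependent way that
distorts cross-kinase score comparisons.

*Backgrounds.* Proteome backgrounds are global residue frequencies;
phosphoproteome backgrounds are position-specific frequencies of all
observed windows. All backgrounds are floored at 1e-6 and renormalized
before use. All logarithms are base 2.

*Scoring and normalization.* PSSMs (log2 odds versus background)
accumulate weighted log-odds per column; PFMs accumulate weighted log2
frequencies (a weighted product of frequencies in linear terms). Scores
are min-max normalized against the theoretical extremes (the sums of
weighted per-column minima/maxima) so every kinase shares the [0, 1]
range. PSSM scores are normalized linearly in the log-odds domain; PFM
scores are normalized in the **linear (probability) domain**,
s = (2^raw − 2^min)/(2^max − 2^min), so they behave as likelihoods.
This distinction matters: normalizing PFM log-scores linearly would
compress all typical windows near the top of the range and make the
Naive Bayes posterior degenerate. Pad positions contribute zero
log-odds (PSSM) or the column's expected background log-frequency
(PFM); pad-containing windows are clipped into [0, 1].

## Multi-label Naive Bayes

Each kinase gets an independent binary sub-model: a foreground PFM from
its substrates, a background PFM from all pool sites it did *not*
phosphorylate, and empirical priors (fraction of assayed sites
phosphorylated, smoothed off the boundary by 1e-6). The posterior is
P(K|S) = s_K·P(K) / (s_K·P(K) + s_K̄·P(K̄)) with s the min-max
normalized PFM scores — a score-as-likelihood convention, not a
calibrated density. Assignment is strict: P > 0.5.

Both likelihood terms are scored under the **foreground** model's
column weights. The background PFM barely diverges from the pool, so
its own relative-entropy weights are near zero; using per-model weights
would collapse the background score range and make the two normalized
scores incommensurable. Applying the foreground weights symmetrically
reads as: the positions that carry this kinase's specificity are
weighed identically in both hypotheses.

The "+" variant multiplies Bernoulli likelihoods for four binary
context features into both terms: interaction with the kinase (graph
distance ≤ 2, configurable — "indirect" is read as one shared
partner), carrying a domain enriched among the kinase's substrates,
carrying a domain enriched among its interactors, and the site lying
inside an annotated domain interval (1-based, inclusive ends).
Enrichment is a one-sided Fisher exact test per domain (presence/
absence per protein), Benjamini–Hochberg adjusted, tested at 0.05.
Bernoulli parameters are Laplace-smoothed ((k+1)/(n+2)) to avoid zero
likelihoods. Kinases with fewer than 20 substrates are modellable but
flagged; evaluation conventionally restricts to ≥ 20.

## In vivo layer

The in vivo classifier is one monolithic model over 8 features per
(kinase, site) pair (see README). Missing association scores are
imputed as 0 and flagged, so all-versus-all scoring never silently
shrinks; 0–1000 score dialects are rescaled to [0, 1]. GO semantic
similarities are ingested as precomputed per-pair tables; the pipeline
is agnostic to the measure that produced them. Dual-specificity kinases
are encoded by their dominant annotated class in the kinase registry.
Negative sets mirror the positive set exactly: same kinase multiset,
same per-kinase site-class counts (cross-type annotations mirrored in
proportion), substrate-kinase proportion maintained when the pool
records it, sampling without replacement per kinase, never colliding
with positives or held-out pairs, deterministic under seed. The default
classifier is a 500-tree Random Forest (Gini splitting, impurity
importances) behind a predict-probability contract; any learner with
that contract can be substituted. Probability exactly 0.5 is not
assigned.

## Evaluation

Macro metrics average per-kinase precision, recall, F1 (and FDR/TPR)
over the kinase set; any term undefined by division by zero is set to 0
first. Macro-TPR is by construction identical to macro-recall.
Constrained repeated k-fold CV co-assigns each kinase's shuffled
positive/negative couples to folds so that any test fold containing a
kinase holds at least one positive and one negative pair for it (the
constraint is enforced on test folds; with ≥ 2 folds per kinase the
training side follows). Cutoff curves recompute macro metrics on a
101-point grid by default; ROC curves use trapezoidal area over the
macro-averaged (FPR, TPR) staircase. Confidence intervals across folds
use the percentile bootstrap. The logistic calibration fits
posterior = 1/(1+exp(−slope·(score−inflection))) by least squares;
fits with fewer than 10 points are rejected, fits whose posteriors do
not span 0.5 or that fail to converge are flagged and excluded from
trend analyses.

## Activity inference

Quant tables are reduced to one complete peptide per site (peptides
missing any condition dropped first; greatest dynamic range wins; ties
break lexicographically and are logged). Activity is the one-sample
KSEA-style statistic Z = (x̄_sub − x̄_all)·√m / σ_all with a two-sided
normal p-value floored at 1e-300 and activity = −log10(p)·sgn(x̄_sub −
x̄_all). A two-sample variant is selectable. The reference distribution
is the condition's full fold-change vector including the kinase's own
substrates (exclusion mode available). A kinase with no quantified
substrates is reported as missing, never as 0. Kinases are tagged per
condition as direct target, activated downstream, inhibited downstream
(from a signed kinase–kinase regulatory edge list with consensus sign)
or other, with the expected activity sign derived from the tag.

## Synthetic data

The generator emulates a shared-pool in vitro assay at desk scale:
30 kinases (75% S/T, 25% Y; about 40% grouped into isozyme families of
2–3 with shared informative columns), a pool of 2000 sites, planted
priors of 0.005–0.05 (20–200 substrates per kinase — the reduced-scale
analogue of an assay spanning 1–1700 substrates). Motifs are 15×20
column-stochastic matrices: proteome-frequency columns plus 4
informative flank columns carrying `motif_sharpness` (default 0.8) mass
on a preferred residue; Y-kinase motifs put all center mass on Y, S/T
motifs split the center 0.7/0.3. Passing a `(lo, hi)` sharpness range
anti-correlates sharpness with the planted prior (permissive kinases
are promiscuous).

Labels are drawn per (kinase, site) with probability equal to the
*planted-motif Naive Bayes posterior* (planted motif as foreground,
pool background as background, planted prior). This well-specified
design has two consequences worth stating plainly: the expected
substrate count tracks prior × pool size, and the nominal 0.5 cutoff is
the Bayes rule for the simulated assay — which is precisely the regime
in which the model's universal-cutoff property can be tested.
`thin_detected_substrates` additionally emulates the stochastic-
detection limit of shotgun proteomics by randomly thinning a kinase's
detected substrate set to a target count.

Association channels are Beta-distributed with a single
`signal_strength` dial: at 0 every channel, the interaction graph and
the domain assignments are independent of the truth; at 1 true pairs
receive strongly elevated scores and planted feature propensities
(e.g. interactor: 0.55 for substrates vs 0.08 baseline). The quant
simulator shifts true substrates of each inhibited kinase by a stated
effect (default −1) on Gaussian noise (sd 0.5), emits a second noisier
peptide for 10% of sites and sprinkles 5% missing values on those
peptides (simple MCAR only — no realistic mass-spectrometry missingness
mechanisms).

What passing the synthetic benchmarks does *not* show: real substrate
windows share compositional structure (e.g. disorder-biased flanks)
that iid-background pools lack, so real PSSM score distributions have
more mid-range mass than synthetic ones; real association evidence is
not conditionally independent of sequence given the truth; and real
assays have batch structure the generator omits.

## Benchmark designs and their rationale

*Recovery and layering.* The layered comparison fits all models on a
random half of the pool sites and evaluates all-versus-all on the other
half (mirroring per-fold refitting), with sharp motifs (0.95), no
families and 150–250 substrates per kinase on a pool of 9000. Under
informative association signal the in vivo layer strictly improves on
Naive Bayes+; with the signal removed the two agree within a 0.1
macro-F1 band. Exact equality is structurally unattainable: a
classifier trained on balanced pairs always recalibrates the posterior
cutoff somewhat, and at the nominal 0.5 cutoff that recalibration alone
is worth a few points of macro-F1. The 0.1 band is the same tolerance
used for the classifier-swap robustness property.

*Calibration trend.* The score-calibration experiment uses a kinome of
equally promiscuous kinases whose detected substrates are thinned to a
log-spaced ladder of 20–500; logistic fits use probe windows sampled
from geometric motif–background interpolations, because a shared pool
contains almost no partially matched windows and the logistic
transition would otherwise be unsupported. Detection thinning isolates
the training-set-size mechanism: with counts planted independently of
detection, inter-kinase motif heterogeneity (and, on small pools, the
contribution of abundant kinases' substrates to the shared background)
obscures the trend.

*Activity.* Inhibition benchmarks simulate the fold-change model
directly (effect −1, sd 0.5, 40 repetitions) and separately run the
full pipeline on a simulated multi-inhibitor experiment. Diluting
assignments with 50% false positives attenuates |activity|, the
variance-dilution effect that motivates precise assignment for activity
inference.

## Numerical conventions and limitations

- Coordinates: 1-based positions in all tables and interfaces; 0-based
  half-open slices internally.
- All randomness flows through explicitly passed seeds; no global RNG
  state. Saving and reloading a model bundle reproduces scores
  bit-identically (backgrounds are not re-smoothed on load).
- Degenerate matrices (theoretical min = max) refuse to normalize
  rather than return arbitrary values.
- Benchmark problem sizes (pools of 1–12k sites, 10–30 kinases) are the
  package's desk-scale defaults; all reported quantities are computed
  at these scales.
- The paired rank-test comparison of activity distributions across
  assignment sources is left to example scripts; it is not a library
  guarantee.
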