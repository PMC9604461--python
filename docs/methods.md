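# Methods

This note records the models, parameter choices and numerical conventions
behind `diaphos`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Experimental design assumed

A stage-resolved relative quantification experiment: `n_stages` ordered
biological stages (default three, labelled D, PD, FPD for the diapause →
postdiapause → founder-postdiapause transition in overwintering insects),
`n_replicates` biological replicates per stage (default three), one
abundance column per sample. Two matrices share this design: proteins and
phosphosites, the latter annotated with parent protein, residue (S/T/Y),
1-based position and a 13-mer sequence window (centre = phosphosite,
terminal overhang padded with `_`; left pad count is max(0, 7 − position)).

## Normalization

1. **Total-abundance**: each sample column is multiplied by a scalar so
   all column sums equal the mean of the original column sums. This is
   idempotent, preserves within-column structure, and is invariant to
   rescaling any input column *up to a single global factor* (the mean
   target moves); since every downstream statistic is a within-matrix
   ratio, the global factor is irrelevant. A caveat worth knowing:
   sum-based normalization is sensitive to composition bias — when
   up- and down-regulation do not cancel on the *linear* scale, part of
   the real signal is absorbed into the scale factors. The synthetic
   experiments below quantify this (planted 1.00 log2 effects are
   measured at ≈ 0.95 after normalization at a 30% DE fraction).
2. **Protein adjustment**: each phosphosite with a quantified parent is
   divided, per sample, by the parent's abundance in that sample. Sites
   without a quantified parent pass through unchanged and are counted in
   the report — real phosphoproteomes routinely contain phosphoproteins
   missing from the global proteome, so dropping them would discard
   signal. Per-sample division (rather than one ratio per contrast) was
   chosen as the more granular reading; it also cancels any replicate
   noise shared between a site and its parent.

## Differential calling

Ratio = mean(linear B)/mean(linear A); p from a two-sided two-sample
t-test on log2 values; q by Benjamini–Hochberg within the contrast.
Classes use the raw p value (up: ratio > 1.3 and p < 0.05; down: ratio
< 0.77 and p < 0.05); a strict-FDR mode classifies on q instead. The
default test is the **pooled-variance (Student) t**: the two groups share
the noise model by design, and with three replicates per group the pooled
variance estimate (4 df) buys substantial power over Welch (down to 2 df);
on the recovery conditions below the difference is recall ≈ 0.92 versus
≈ 0.86. Welch remains available via `test="welch"` for designs where the
equal-variance assumption is doubtful. Contrasts for an ordered design
are the successive pairs plus the endpoints (PD/D, FPD/PD, FPD/D).

Extreme-feature lists cut at 5-fold (ratio > 5 or < 1/5), optionally
requiring p < α, sorted by |log2 ratio|. Over-representation of any
selected feature list in GMT annotation sets uses the hypergeometric
upper tail with BH correction across sets.

## Fuzzy trajectory clustering

Clustering operates on per-stage means of log2 abundance (3-point
profiles for the default design), not on all 9 samples — the trajectory
is the object of interest and replicate noise is already averaged.
Features whose profile SD (ddof = 1) is ≤ 0.4 are removed; survivors are
z-scored per feature. Fuzzy c-means (c = 6, m = 2, Euclidean distance)
alternates the closed-form membership and center updates until the
largest membership change is below 1e−6 (max 300 iterations); the
objective Σ u^m d² is recorded per iteration and is non-increasing by
construction. Initial memberships are symmetric-Dirichlet draws from a
seeded generator, so fits are exactly reproducible. A profile exactly on
a center receives membership 1 there (lowest index on ties). Cluster
labels are arbitrary; all evaluation uses label-invariant indices (ARI).
Hard assignments take the argmax membership when it reaches 0.5
(configurable); below that a feature is reported unassigned.

Six trajectory archetypes over three stages (early/late/sustained rises
and falls) are the planted templates of the generator. After per-feature
z-scoring, 3-point profiles live on a circle and the six archetypes are
exactly the vertices of a regular hexagon — c = 6 is therefore the
natural cluster count for this design, and recovery is a fair test of the
implementation rather than of model selection (estimating c is out of
scope).

## Motif extraction

Foreground = windows of regulated sites, background = windows of all
identified sites, split by central residue (S, T, Y analysed separately
by default; a pooled mode exists). Greedy extraction: for every
unconstrained (offset, residue) with foreground count k ≥ 20, the
binomial tail p = P(X ≥ k), X ~ Binom(n_fg, q_bg) with q_bg the residue's
current background frequency at that offset; the smallest p wins (ties:
larger k, then smaller offset, then alphabetical residue — this makes
extraction fully deterministic); acceptance requires p < 10⁻⁶. Both sets
are then reduced to matching windows and the search repeats; on
completion the motif's foreground matches are removed and extraction
restarts for further motifs. Motif score = Σ −log10 p over the accepted
steps; fold change = (fg matches / original fg size) / (bg matches /
original bg size). The 20-occurrence / 10⁻⁶ defaults are the customary
motif-x settings. Position heatmaps report log2 frequency ratios with a
0.5 pseudocount and mark cells passing a two-sided binomial test at
BH-corrected 0.05.

## Kinase activity

Sites are ranked by contrast log2 ratio (descending; ties broken by site
id). The enrichment score is the signed extremum of the weighted KS
running sum — hits add |metric|^p / Σ_hits |metric|^p (weight exponent
p = 1), misses subtract 1/(N − N_hits); an exact |max| = |min| tie
resolves to the positive deviation. Because three replicates per group
preclude sample permutation, the null is **substrate-set permutation**:
`n_perm` (default 1000) random same-size site sets from the same ranking.
NES divides ES by the mean |null ES| of the same sign (positive and
negative nulls normalized separately); p = (1 + #same-sign nulls at least
as extreme) / (1 + #same-sign nulls). Sets smaller than 3 after
restriction to the ranking are skipped. The kinase–substrate network
keeps kinases with p < α and links them to substrate sites classed
up/down, annotating activation state and site regulation.

Per-contrast ratio rankings are the default metric source; per-stage
abundance rankings are possible by ranking any single-stage summary, but
the contrast form is what the recovery experiments validate.

## PPI modules

Subnetworks keep edges whose two endpoints are both in the feature list
of interest and whose confidence is ≥ 0.7 (the customary high-confidence
cut for STRING-style combined scores, taken as given — no re-scoring).
MCODE vertex weight = k × density of the highest k-core of the node's
closed neighbourhood. Modules grow from the highest-weight unassigned
seed, admitting neighbours with weight ≥ (1 − vwp) × seed weight
(vwp = 0.2), followed by a haircut that iteratively removes members with
fewer than two in-module connections; modules need ≥ 3 members and are
ranked by density × size. Ties in seed order break on node id, making the
output independent of edge-list order. Fluff expansion is not
implemented (off in the reference parameterization).

## Synthetic data generator

Protein log2 abundance = baseline ~ N(20, 2) + per-stage template offset
+ replicate noise N(0, replicate_sd); matrices are linearized by 2^x.
A fraction `de_fraction` (default 0.3) of features receives one of the
six archetypes (unit log2 steps); the rest are flat. Phosphosite values
are tethered to the parent's *per-sample* value plus a constant site
offset ~ N(0, 1), a site-level stage effect (site templates drawn
independently of the parent) and the site's own replicate noise — so
protein adjustment exactly cancels the parent's contribution, which is
the property the normalization stage is meant to exploit. Kinase
regulons are disjoint sets of template-flat sites (so planted kinase
effects are not confounded with template effects); each kinase gets an
activation stage and sign (random, or fixed via `kinase_stages` /
`kinase_signs`) and its substrates shift by ±`kinase_shift` from that
stage onward. Regulon windows are serine-centred and carry the planted
motif (default D at +1, E at +3 — an acidic, casein-kinase-II-like
pattern); other windows draw flanks i.i.d. from a SwissProt-like residue
frequency table. PPI graphs plant cliques with confidence ~ U(0.7, 1.0)
over independent background edges (probability 0.01, confidence
~ U(0.15, 0.95)), so the 0.7 filter removes some background and keeps
some — the filter is exercised in both directions. One seed drives
everything; identical configurations are bit-identical.

Defaults: 400 proteins, Poisson(2.5) sites per protein, replicate_sd
0.25 (log2), de_fraction 0.3, 8 kinases × 10 substrates, kinase_shift
1.0. These are deliberate desk-scale stand-ins for a full experiment
(thousands of proteins, ~10⁴ sites): large enough for stable statistics,
small enough that the full validation battery runs in seconds. The
generator does **not** emulate missing values, isotopic impurity or
ratio compression, multi-plex batch structure, or peptide-level
ambiguity; conclusions from passing tests are about the correctness of
the algorithms under the stated noise model, not about robustness to
those real-data pathologies.

## Validation experiments (what the acceptance script measures)

- Reference-table filters: the bundled >5-fold tables reproduce the
  published counts (7 proteins in PD/D at p < 0.05; 19 and 9 phosphosites
  in PD/D and FPD/PD).
- Null calibration: with no planted effects (2000 features), the raw
  p < 0.05 rate of the differential test is 5% within binomial error;
  KSEA permutation p values for random sets on a null ranking are
  uniform.
- Recovery: planted +1 log2 site effects at replicate_sd 0.25 are called
  at the 1.3-fold/p < 0.05 thresholds with recall ≈ 0.90 and empirical
  FDR ≈ 0.03 (recall sits near the 0.9 boundary precisely because of the
  composition-bias shrinkage described under Normalization); fuzzy
  clustering recovers the six archetypes with ARI ≈ 0.75–0.87 over five
  seeds; planted motif constraints are recovered exactly; all planted
  kinase signs are recovered; planted cliques emerge as the top MCODE
  modules.
- Oracle equivalence: binomial tails, enrichment scores and MCODE
  weights match independent by-definition computations (exact rational
  binomial sums, brute-force running sums, iterated-removal k-cores).

## Known limitations

- Sum-based normalization absorbs asymmetric global shifts (above);
  median-ratio alternatives would be more robust but are not what the
  emulated workflow prescribes.
- Raw-p classification (the emulated convention) does not control FDR;
  the q column and strict-FDR mode exist for users who need control.
- Substrate-set permutation tests competitive enrichment against random
  site sets, not against sample relabelling; with correlated substrate
  sites its p values can be anti-conservative on real data.
- Module detection is deterministic but greedy; overlapping complexes
  are reported as disjoint modules.
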