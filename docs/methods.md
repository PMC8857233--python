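# Methods

This note documents the models implemented in `phyloturn`, the null-model
constructions and their numerical details, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Data model and assumptions

All analyses operate on a rooted phylogeny with branch lengths in expected
substitutions per site, an ASV × sample abundance table, and (optionally)
ASV sequences, a taxonomy table and a sample environment table. Presence is
defined as abundance > 0 throughout. Two assumptions underlie the
nearest-taxon machinery: (a) some historical migration connected the local
communities, so shared membership is informative; and (b) phylogenetic niche
conservatism holds at short phylogenetic distances — closely related taxa
occupy similar niches. The `niche` module tests (b) directly (see below);
the package does not attempt to verify (a).

Branch lengths are mandatory. A tree without them is rejected rather than
defaulted to unit lengths, because every statistic in the package is
substitution-scaled and silent defaults would corrupt the z-scores.
Multifurcations are accepted as-is: patristic distances and nearest taxon
distances are well defined on them.

## Community-level turnover (`turnover_null`)

Per sample pair:

* **βMNTD** — for each ASV present in exactly one of the two samples, its
  minimum patristic distance to the taxa present in the other sample, then
  the weighted mean of those distances. Abundance weighting uses the focal
  ASV's relative abundance in its own sample, renormalized over the
  contributing (uniquely present) ASVs; presence weighting (simple mean) is
  available as a cross-check. Identical membership gives βMNTD = 0 with a
  logged flag.
* **βNTI** — the z-score of the observed βMNTD against a null in which each
  sample's membership is re-assigned to random tree tips (a label
  permutation of the distance matrix, which preserves the phylogenetic
  distance pool). By default the two samples are permuted *independently*
  each replicate, so the null randomizes which taxa co-occur as well as
  where each sample sits on the tree; two identical samples then face a
  positive null and score far below −2 rather than hitting a degenerate
  (zero-spread) null. `shuffle="joint"` applies one permutation to both
  samples — the variant in which the shared/unique structure of the pair is
  preserved — and is provided for comparison; under it, identical samples
  yield a NaN sentinel. On membership-randomized data the default null is
  well calibrated (~95 % of pairs fall inside ±2).
* **Bray–Curtis** — computed on relative abundances,
  BC = 1 − 2 Σ min(x, y) / Σ (x + y).
* **RC_Bray** — Raup–Crick on Bray–Curtis. Each null replicate rebuilds both
  samples from the regional pool: membership of the observed richness drawn
  without replacement with probability proportional to each ASV's occupancy,
  then the observed total abundance filled by seeding one individual per
  chosen taxon and drawing the remainder with replacement proportional to
  regional relative abundance. If the table holds counts the observed totals
  are used; otherwise a fixed depth of 2000 individuals per sample.
  RC = 2·[(#null BC < obs) + ½(#ties)]/reps − 1 ∈ [−1, 1]; ties (at numpy's
  default `isclose` tolerance) counted at half weight keep an exactly
  null-typical pair at RC = 0.

Process assignment uses strict inequalities, in order: βNTI < −2 →
homogeneous selection; βNTI > +2 → variable selection; otherwise
RC_Bray < −0.95 → homogenizing dispersal; RC_Bray > +0.95 → dispersal
limitation; else undominated. Boundary values fall through to the next
stage. RC is only computed when |βNTI| ≤ 2. The default replicate count is
999 (enough resolution for the ±2 and ±0.95 cutoffs); the regional pool is
the whole table, with a `pool_samples` option for per-group pools.

## The phyloscore (`phyloscore_core`)

For ASV *i* present in donor sample *j* and absent from recipient *k*:
observed statistic d = min patristic distance from *i* to the taxa present
in *k*; null = nearest distance from *i* to a uniform random N_k-subset
(without replacement) of the pool, repeated M times (default M = 100);
z = (log d − mean log null) / sd log null, natural logarithms.

Numerical and implementation choices:

* **Null pool** — all ASVs in the validated dataset except *i* ("regional"),
  consistent with the tip-shuffle logic of the community framework. A
  per-pair pool (taxa of j ∪ k) is exposed as an option; under it z becomes
  donor-dependent.
* **Order-statistic sampling** — for a pool of P sorted distances, the
  minimum of a uniform random N-subset equals the r-th smallest with
  probability C(P−r, N−1)/C(P, N). The Monte-Carlo draw samples this rank
  distribution directly (distributionally identical to drawing the subset,
  O(P+M) instead of O(M·N)), and `exhaustive_null` evaluates the exact mean
  and (population) sd of the log minimum from the same pmf — exact for any
  pool size, no subset enumeration. The test suite checks both against a
  brute-force enumeration oracle.
* **(i, k) sufficiency** — d and the null depend only on (i, k), not on the
  donor j. Records are computed once per (i, recipient) and replicated over
  donors, sharing one Monte-Carlo null per (i, k) by default
  (`share_null_across_donors=False` redraws per donor). Each record's
  marginal distribution is unchanged; only the Monte-Carlo noise shared
  between same-(i,k) records is affected.
* **Zero distances** — observed or null distances of 0 (identical placements
  or zero-length branches) are floored at half the smallest positive
  patristic distance in the dataset before the log, with a logged count.
* **Degenerate nulls** — records whose log null distances have zero sd carry
  z = NaN, are excluded from aggregation, and are counted in the log.
* **Aggregation** — the per-ASV total (sum) of z is the default
  phylofactorization input; mean, median, record count and mean/sd are
  always emitted so the robustness of clade calls to the aggregation metric
  can be re-checked cheaply. ASVs never uniquely present get total 0 and
  n_pairs 0.
* A single seeded RNG stream with a fixed traversal order (recipients in
  column order, focal ASVs in row order) makes the full table
  bit-reproducible from one seed.

Because presence/absence alone enters, every z is invariant to rescaling
abundances (asserted in the tests). On membership-randomized matrices the z
distribution is centered on 0 (|grand mean| < 0.05 at ≥ 10⁴ records).

## Phylofactorization (`phylofactor`)

Candidate edges are evaluated within the current bins (connected components
of the tree after the previous cuts). For an edge, the objective is the
absolute equal-variance two-sample t-statistic between the scores of the
tips on its two sides within the bin; both sides need ≥ 2 scored tips. The
globally best edge is cut, splitting its bin; ties in |t| break on the
smallest preorder edge index (logged, deterministic — the module uses no
randomness). Clades whose mean score is below the complement's are labelled
HoS, otherwise HeS.

Stopping: the number of factors is a genuinely open choice; the default
stops when the best edge's p-value, Bonferroni-corrected by the number of
admissible edges tested in that iteration, exceeds α = 0.05, with
`max_factors` as a hard cap. On iid-normal scores this keeps the fraction of
runs producing any factor at or below ~5 % (the correlation among edge tests
makes Bonferroni conservative). Consensus taxonomy of a clade is the deepest
rank at which ≥ 95 % of the classified tips agree.

## Microdiversity screen (`microdiversity`)

Per clade, against the background (non-clade) tips:

* **NTD** — each tip's minimum patristic distance to any other tip;
  rerooting-invariant. Distributions compared by a two-sided Wilcoxon
  rank-sum test.
* **β-nearest similarity** — for each focal ASV and each sample lacking it,
  the nucleotide identity to the phylogenetically nearest ASV present there
  (ties on distance average their identities); per-ASV value = median over
  those samples; the >97 % "putative ecotype" fraction is computed on the
  per-replacement values, strict `> 97.0`. All samples lacking the focal ASV
  are used (restricting to phyloscore-style pairs is a documented
  alternative reading). Abundances never enter.
* **Aligner** — a built-in global pairwise aligner (Needleman–Wunsch with
  affine gaps via `Bio.Align.PairwiseAligner`: match +1, mismatch −1, gap
  open −2, gap extend −0.5) keeps the package self-contained; identity is
  counted over alignment columns excluding terminal gaps (end-gap-free
  semantics suit amplicons of unequal trimming). Parameters are
  configurable and a precomputed identity matrix can be supplied instead.
* **Rarefaction** — the clade's pooled counts are subsampled without
  replacement (multivariate hypergeometric); a saturating curve indicates
  the clade's presence/absence pattern is not an artifact of sampling
  effort. The closed-form expectation Σᵢ [1 − C(N−nᵢ, d)/C(N, d)] is the
  test oracle.
* **Depth vs NTD** — Spearman correlation between root distance and NTD.
  On uniform-attachment random trees this relationship is weak (|mean ρ|
  ≈ 0.03–0.06 across ensembles, and in our reproductions weakly positive
  rather than negative), so the optional linear detrending of log NTD on
  root distance is off by default.

## Niche conservatism (`niche`)

The niche optimum of an ASV for an environmental variable is the
abundance-weighted mean of that variable over the samples where the ASV
occurs (weighted median available as an option); niche distance is Euclidean
on per-variable z-scored optima, so it is invariant to affine transforms of
the inputs. The Mantel correlogram partitions the phylogenetic distance
range into classes (Sturges' rule on the pair count by default) and, per
class, computes the Pearson Mantel statistic between the niche distances and
the within-class indicator, sign-flipped so that positive r means pairs in
the class are more similar than average (the convention in which
conservatism appears as positive r at short classes; values match vegan's
`mantel.correlog`). p-values come from joint row/column permutations of the
niche matrix (two-sided, default 999) with a progressive Holm correction
from short to long classes; classes with < 20 pairs are flagged low-power.
The prerequisite for nearest-taxon null models is significant positive r in
the shortest class(es).

## Synthetic data (`simulate`)

The generator produces the study conditions the stack is validated under:

* **Trees** — sequential uniform attachment of tips to a uniformly chosen
  edge ("rtree-like"; a Yule option attaches to pendant edges only), iid
  exponential branch lengths with mean 0.05 substitutions/site.
* **Planted HoS clade** (`hos_dataset` composes the full recipe) — within a
  500-tip tree, a ~40-tip monophyletic clade has its internal branches
  scaled by 0.05 (giving within-clade distances around 0.02 subs/site and
  Jukes–Cantor identities above 97 %); every sample contains ≥ 1 clade
  member (clade-wise occupancy 1.0) while each member individually occupies
  only 0.3 of samples; background tips occur iid at occupancy 0.1.
  The sparse background is essential, not cosmetic: amplicon occupancy
  distributions are strongly right-skewed (most ASVs occupy a minority of
  samples), and if background occupancy matched the clade's per-ASV
  occupancy the observed membership rate would equal the null's uniform
  rate, making z = 0 in expectation — the planted matrix would not be an
  HoS clade at all. Abundances are lognormal(0, 1) per occurrence; the
  phyloscore is abundance-blind, so the abundance model only matters for
  βMNTD/RC checks.
* **Planted HeS clade** — clade members confined to one sample group;
  between-group phyloscores for the clade are positive on average.
* **Sequences** — Jukes–Cantor evolution along the tree (per site, stay
  probability ¼ + ¾e^(−4d/3)); the closed-form expected identity is the
  oracle for the generator itself.
* **Traits** — Brownian motion along branches (tip variance grows linearly
  with root distance); the sample environment value is the
  abundance-weighted mean of the present tips' traits plus Gaussian
  measurement noise (sd = 0.1 × trait sd), producing environment tables
  whose niche optima carry the tree's phylogenetic signal.

Every generator is bit-reproducible from (parameters, seed), and the
returned `SimTruth` records the planted clade and occupancy parameters.

What the generator does **not** emulate: sequencing error and chimeras
(upstream denoising is assumed), compositionality of counts, heterogeneous
per-taxon occupancy within the background, non-neutral abundance dynamics,
and spatial/geographic structure among samples. Passing the planted-clade
tests therefore demonstrates that the statistics detect the targeted
replacement structure under clean conditions, not that any particular real
dataset is free of the biases (sequencing error, undersampling) the
rarefaction screen is meant to catch.

## Problem sizes and runtime defaults

The validation suite runs at desk scale: planted-clade recovery uses 500
tips × 30 samples × M = 100 across 50 seeds (< 1 s per run thanks to the
order-statistic null); calibration uses ≥ 2 × 10⁴ records; turnover and
correlogram checks use 60–200 tips with 99–199 permutations. The same code
paths scale to amplicon datasets of 10³–10⁴ ASVs; `all_phyloscores` costs
roughly O(#ASVs × #samples) null evaluations of O(pool size) each.

## Known limitations

* The phyloscore null treats all pool members as exchangeable; strong
  occupancy heterogeneity in real data shifts the null's effective
  composition and is exactly what the membership-randomized calibration
  cannot rule out — inspect per-ASV record counts alongside totals.
* The total phyloscore weights high-occupancy ASVs' many records more than
  low-occupancy ASVs' few; the alternative aggregates are emitted for
  robustness checks.
* RC_Bray on relative-abundance tables uses an arbitrary fill depth (2000);
  supply counts when available.
* The equal-variance t objective is the only phylofactorization objective
  implemented (no ILR-balance or regression objectives).
* The microdiversity verdict is "putative": nucleotide similarity of 16S
  fragments cannot by itself demarcate ecotypes.
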