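# Methods

This note records the models, formulas, parameter choices and numerical
conventions behind `cofrac`, and what the synthetic benchmark does and does
not establish about real data.

## Synthetic co-elution model

The simulator emulates the statistical structure a multiplexed CF/MS
analysis relies on, not the physics of chromatography or mass
spectrometry.

**Planted truth.** `n_complexes` complexes draw sizes uniformly from
{3..12}; members are assigned disjointly, after which a fraction
(`multi_complex_fraction`, default 0.1) of complex proteins joins a second
complex, modelling moonlighting subunits. Remaining proteins are monomers.
A fraction of complexes (`condition_specific_fraction`, default 0.3) is
present only in a random proper subset of conditions; among fully shared
complexes, a fraction (default 0.2) carries an abundance multiplier
(default 3×) in one condition.

**Elution.** Per condition, each present complex draws one apex fraction
uniformly; each member elutes as a Gaussian peak (in fraction index)
centred at apex + jitter (sd `co_elution_jitter_sd`, default 0.5
fractions), scaled by the protein's log-normal base amplitude (sigma 0.5
around a 1e4 intensity scale) and the condition multiplier. Proteins in
several present complexes sum their peaks (intensities are additive).
Monomers draw independent apexes per condition. Peak shape is Gaussian —
the standard one-parameter chromatography approximation. Each assembly
(complex or monomer) has its own peak width, log-normal around
`peak_width_sd` (default 2.0 fractions) with coefficient of variation
`peak_width_cv` (default 0.3), shared by the subunits of a complex because
the intact assembly migrates as one species. Width heterogeneity matters:
with one global width, two distinct complexes that happen to elute at the
same fraction produce feature-identical profiles and become
indistinguishable from true co-complex pairs, an artifact real separations
do not have.

**Noise and missingness.** Replicate channels of a condition share all
apexes and differ by per-cell multiplicative log-normal noise with
coefficient of variation `replicate_noise_cv` (default 0.05, placing
replicate Pearson agreement in the ≥ 0.95 regime expected of a
well-behaved fractionation; a tunable, not a fit). Missing identifications
are drawn once per (protein, fraction) with probability `missing_rate`
(default 0.05) and shared across **all** channels of the multiplex: in an
isobaric design every channel of a fraction comes from the same pooled
LC/MS injection, so the identification event — and therefore a missing
value — is common to the plex. Intensities below a detection limit
(default 1.0, i.e. four orders below the amplitude scale) read as zero,
giving profiles a realistic finite support. A single seed fans out to
independent streams for truth generation and elution, so identical configs
are bit-identical.

**What the simulator does not model** — and hence what passing tests do
not show about real data: peptide-level identification and inference,
reporter-ion ratio compression and channel cross-talk, chromatographic
drift between replicates, correlated (abundance-dependent) missingness,
baseline signal, and complexes with condition-dependent subunit
composition (presence is all-or-none per condition; only abundance shifts
are graded).

## Preprocessing

Proteins detected in fewer than two fractions carry no co-elution evidence
and are removed (the filter is idempotent; removals are reported with a
reason). Normalization is column-then-row: fraction totals are equalized
to the mean column total (removing fraction/loading bias), then each
profile is scaled to unit sum so metrics compare shape independent of
abundance. The column step must precede the row step — loading bias is a
column effect and must be removed before shapes are fixed. The final
matrix is invariant under arbitrary positive per-column rescaling of the
input (property-tested).

Replicate agreement is per-protein Pearson *r* between replicate channels
of a condition, averaged over proteins with defined *r*; zero-variance
profiles are excluded and counted. Because "correlation (R²)" is ambiguous
in common usage, both the mean *r* and mean *r²* are reported.

Abundance comparisons use a separate normalization: per-fraction totals
summed over **all** channels are equalized with one shared factor per
fraction. Per-channel column normalization would rescale each channel's
fractions independently and destroy the cross-channel reporter ratios that
encode relative abundance — with co-eluting complexes dominating their own
elution columns, a planted 3× shift would be flattened far beyond any
useful tolerance. The shared-factor variant removes injection bias while
preserving channel ratios exactly; row-normalized matrices are never used
for abundance.

## Co-elution features

Five pairwise metrics, computed per condition on the concatenated
replicate profiles (384 points for a duplicate 192-fraction design; the
concatenated vector is rescaled to unit sum). Concatenation rather than
per-replicate averaging is a recorded choice: it lets reproducible signal
reinforce itself and treats replicate disagreement as dissimilarity.

* **Euclidean**: `1 − ‖a − b‖₂/√2`; √2 is the diameter of the simplex of
  nonnegative unit-sum vectors, so the score is in [0, 1].
* **Jaccard**: `|A∩B|/|A∪B|` on detection sets (intensity > 0); 0 when
  both sets are empty (flagged convention).
* **Apex**: 1 iff the argmax fractions coincide; plateau ties resolve to
  the lowest fraction index (deterministic and configurable in principle;
  recorded here as the frozen convention).
* **Mutual information**: discrete MI (natural log) after equal-width
  intensity binning with `⌈√n⌉` bins by default; zero intensities occupy a
  dedicated bin so detection pattern and level both contribute. Degenerate
  single-bin profiles score 0.
* **Bayes**: profiles are scaled to pseudo-counts (sum = n), a uniform
  Dirichlet pseudocount (default 1) is added, and the Pearson correlation
  of the posterior-mean profiles is mapped to [0, 1] via `(r+1)/2`.
  Because Pearson is affine-invariant, any finite pseudocount yields the
  plain Pearson score; the prior acts only through the degenerate
  (uniform-posterior / zero-variance) convention of 0.5. The formula is
  frozen as stated for reproducibility.

Candidate pairs require at least 2 co-detected points (configurable),
bounding the quadratic pair space. The vectorized all-pairs implementation
is tested to agree with the scalar reference definitions; all metrics are
symmetric and invariant under identical fraction permutations (except
apex, which depends on fraction order only through the tie-break).

## Classification

Positives are intra-complex pairs of detected reference proteins;
negatives are pairs of detected reference proteins never co-annotated,
sampled at 5:1 (class-imbalance realism). When the candidate-pair pool is
available, negatives are sampled from it — uniformly sampled protein pairs
often fail the co-detection filter and lose their feature rows, which
would silently collapse the intended ratio in the rows the forest actually
sees. The train/test split is complex-wise: whole complexes are held out,
and any test pair also implied by a training complex is removed, so train
and test positives are provably disjoint (audited in tests). The model is
a random forest with library-default hyperparameters and a fixed seed; no
functional-evidence features exist anywhere in the package — co-elution
alone carries the predictions. Calls use `score ≥ 0.625` (inclusive
boundary), per condition. Precision/FDR are computed on called pairs whose
both proteins occur in the reference universe (the standard co-complex
evaluation convention); an empty eligible set reports as not-applicable
rather than 0.

## Clustering

Cohesiveness `f(V) = w_in/(w_in + w_bound + p|V|)` with penalty `p = 2` by
default; edge weights are classifier scores (calls gate graph membership,
scores carry information). Growth seeds every vertex not yet claimed by an
earlier cluster, in descending weighted-degree order, and repeatedly
applies the single vertex addition or removal that most increases `f`
(strict improvement above 1e-12; ties prefer additions, then lexicographic
protein id), stopping at a local maximum — verified exhaustively against
single-move neighborhoods on random graphs in tests. Candidates with
overlap `ω(A,B) = |A∩B|²/(|A||B|) ≥ 0.8` merge transitively (union);
clusters with fewer than 3 members or weighted density below 0.3 are
discarded. All thresholds are exposed in config. Note that **global**
maximization of `f` is not the specification of the algorithm: for two
cliques joined by any positive-weight bridge the union scores at least as
high as either clique for every penalty, so separation is inherently a
property of greedy local search. No significance-based post-filter is
applied.

## Evaluation

With reference set R and predicted catalog P: MMR is the total weight of
the maximum one-to-one matching between R and P under ω (edges kept at
ω ≥ 0.25), divided by |R| (matching solved by linear assignment; tested
against exhaustive enumeration). Overlap is the fraction of references
with any match at ω ≥ 0.25. Accuracy is `√(Sn·PPV)` from the confusion
matrix `T(i,j) = |Rᵢ ∩ Pⱼ|`. The Composite Score is their unweighted sum.
The ω threshold 0.25 is the lineage standard and configurable. Simpson's
index `|A∩B|/min(|A|,|B|)` serves for annotation matching (significant at
≥ 0.45) and cross-condition comparison; it is undefined for empty sets and
always ≥ ω.

## Differential comparison

Interaction identity across conditions is the unordered protein pair
called in that condition. Complexes match across conditions by best SI
(ties: larger intersection, then lexicographic id); the conservation class
derives from the minimum best-SI over all other conditions: conserved at
≥ 0.8, differential strictly below 0.45, the unnamed middle band labelled
"intermediate". Complex abundance per condition is the mean over members
of total (fraction-summed) intensity, averaged over replicate channels, on
the jointly column-normalized matrices; absent members contribute zero and
are counted. The enrichment call — one condition at least `min_fold`
(default 2×) above every other, required positive and unique — is a
deliberately simple stand-in for a full statistical test and is flagged as
such in outputs.

## Pipeline, determinism and scale

A flat, versioned YAML config (unknown keys rejected) drives the pipeline;
one global seed derives per-stage seeds via SHA-256 (all below 2³¹), so
stages are independently reproducible and reruns are byte-identical. The
manifest records package version, full config and SHA-256 of every
artifact. The benchmark scale used by the test suite and the acceptance
script — 500 proteins, 50 complexes, 192 fractions, 6 channels — runs the
full chain in seconds on one CPU; the unit-test fixtures use a smaller
90-protein design with the same structure.

## Known limitations

* The five metrics cannot separate two distinct complexes whose apexes
  collide within the jitter scale and whose widths happen to agree; this
  bounds attainable precision on any co-elution-only analysis, synthetic
  or real.
* Negatives are sampled, not exhaustive; extreme negative ratios can be
  truncated when a split's protein universe is small (the sampler caps at
  availability).
* Conservation classes are driven entirely by membership (SI), not
  abundance; a complex present everywhere at very different levels is
  "conserved" with an abundance shift, matching the separation of the two
  readouts.
* The enrichment rule is a threshold heuristic, not an error-controlled
  test.
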