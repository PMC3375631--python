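# Methods

## Enrichment core

Genes are ranked by the two-class signal-to-noise ratio
`s = (μ₁ − μ₂)/(σ₁ + σ₂)` with sample standard deviations; class 1 is the
lexicographically smaller label unless overridden. Denominators are
floored at `0.2·|μ|` per class (0.2 absolute for all-zero genes), the
convention used by desktop GSEA implementations, so constant genes never
divide by zero. The ranking is deterministic: ties in the statistic break
by gene id ascending. Multiplying the expression matrix by a positive
constant leaves the ranking unchanged.

The running-sum enrichment score walks the ranked list; at a set member
("hit") it rises by `w(g)/W` with `W = Σ w` over the set members present
in the list, at a non-member it falls by `1/(N − N_h)`. Equal weights give
the classic unweighted statistic; the IDF weights give the AF variant.
Two conventions are exposed: `extreme` (default) reports the signed value
of largest magnitude so negative enrichment is representable in two-sided
tests; `max` reports the maximum of the running sum. The earliest peak
wins; because a perfectly symmetric walk can tie a negative and a positive
extreme exactly, ties are resolved to a tolerance of 1e−12 so floating-
point noise cannot flip the reported sign between equivalent
implementations. Weights are rescaled by their maximum before use — a
mathematical no-op under the `w/W` normalisation that makes constant
weights reduce to the equal-weight statistic bit-exactly.

Significance is by permutation: phenotype (label) permutation by default,
with a gene-set permutation fallback that the batch runner selects
automatically below 7 samples per class, where label permutations are too
few. p-values use the add-one estimator `(b + 1)/(B + 1)` and are never
zero. One shared null is computed per collection run, and per-set
standardisation of the observed ES against its own permutation null is
reported as a `z_score` column — a significance-scaled score used where a
single per-pathway number is needed (e.g. as a weight source). Multiple
testing uses plain Benjamini–Hochberg across pathways (via statsmodels),
which composes cleanly with the weighted adjustment below. Genes present
in a set but absent from the expression matrix are dropped from the set
with a log message.

## Appearance-frequency (IDF) weighting

`idf(g) = ln(N / n_g)` over a pathway collection of `N` sets, `n_g` the
number of sets containing `g`. The natural log is a free choice: changing
base rescales all weights by one constant, which the running-sum
normalisation cancels, so the ES is provably base-independent (and tested
as such). Term frequency is fixed at 1 — a gene rarely occurs more than
once within one pathway map, so a TF component carries no information.
IDF is computed over the full supplied collection (or an explicit
reference collection) rather than only scored pathways, keeping weights
stable under filtering. Members with `idf = 0` (genes in every pathway)
keep their list positions as zero-increment hits rather than being
removed, so the miss normalisation is untouched. A collection whose IDF
is constant — including the degenerate single-pathway case where every
idf is zero — falls back to equal weights, which the constant-weight
reduction property makes exactly equivalent.

## Density analysis

Pathway graphs are undirected with unit edges; direction and edge signs
are not used. All-pairs shortest paths are computed by Floyd–Warshall
(vectorised over one axis; Θ(n³), exact for these sizes); repeated BFS is
used only as an independent oracle in the tests. Unreachable pairs carry
an infinite distance and contribute nothing to any score; components are
not scored separately.

The per-gene score is `ds(g) = x(g) · Σ_{g'≠g} x(g') · penalty(d(g,g'))`
with `penalty = decay^d` (default, `decay = 0.5`) or `1/d`. The
multiplicative `x(g)` gate is essential: an ungated sum of neighbour
contributions is invariant between clustered and dispersed placements on
symmetric graphs (verifiable on the six-node path fixture), whereas the
gated form separates them. The pathway score averages `ds` over all graph
nodes — isolated and non-DE nodes stay in the denominator — so the score
rewards the DE fraction and the DE genes' mutual proximity jointly.
Exponential decay is the default penalty for its summability and tunable
locality; `decay` is exposed because the effective neighbourhood radius
it induces is a modelling choice, not a constant of nature.

DE intensities `x ∈ [0, 1]` come either from a supplied per-gene TSV or
from a ranked list via a two-sided threshold: binary mode flags the top
quantile of `|s|` (default 10%), continuous mode uses `|s|` scaled by its
maximum. Both are provided because "differentially expressed genes" is
binary language while expression evidence is continuous; binary is the
default for its robustness to the statistic's scale.

## Weighted p-value adjustment

Scores become weights by `w = (score − min(score) + floor)/mean(·)` with
`floor = 0.01`: strictly positive, exactly mean-one, and order-isomorphic
to the scores. Adjusted p-values are `min(1, p/w)`, after which BH
q-values and ranks are recomputed. With mean-one weights chosen
independently of the p-values this is the classical weighted-BH
construction with its FDR guarantee, verified empirically in the
acceptance suite (500 full-null replicates). Pathways missing from the
weight map are a hard error by default (`missing_weight=1.0` opts into
neutrality) so id mismatches between collections and graph directories
surface instead of silently passing through.

## Synthetic data

The generators are pure functions of a `FixtureSpec`; identical specs
produce byte-identical files. Collections realise a target appearance-
count profile (counts above the pathway count are clipped to it) by
assigning each gene's memberships greedily to the currently smallest
sets, which keeps realised set sizes balanced; infeasible profiles
(memberships outside what the size range allows) raise rather than warp
the request. Expression is standard normal background with a constant
class-mean shift planted in a chosen fraction of enriched-set members —
signal-to-noise is location-scale free, so richer noise families would
change nothing these tests measure; no platform realism (batch structure,
intensity-dependent variance) is claimed, and results on real microarray
data can differ accordingly. Graphs come from path, cycle, Erdős–Rényi
(regenerated until connected, with bridge edges as a last resort) and
Barabási–Albert models; clustered DE placement grows a breadth-first
neighbourhood, dispersed placement uses greedy farthest-point sampling
(exact max-min dispersal is NP-hard and unnecessary for property tests).

## Evaluation studies

`evaluation.py` holds the simulation experiments. Sizes were chosen to
give stable Monte-Carlo estimates at desk scale: 1,000 random instances
for the ES brute-force comparison, 200 random graphs (n ≤ 50) for the
shortest-path comparison, 500 synthetic pathways for null-p uniformity
(1,000 genes, 8 + 8 samples, 200 permutations), 500 replicates of 500
pathways for the weighted-BH null, and 100 replicates of the paired-
cohort study.

The paired-cohort study emulates two studies of one biological contrast
with unequal batch quality. Each replicate draws a 40-set collection over
700 specific and 15 ubiquitous genes: 6 planted sets (15 specific genes,
10 carrying a shared +1.2 SD case shift, plus 4 ubiquitous), 8
housekeeping decoys (17 specific + 13 ubiquitous), 26 background sets.
Each cohort shifts a random subset of the ubiquitous genes upward by
2.5–4 SD — 15 genes in the severe cohort, 3 in the mild one — so decoy
enrichment is strong but does not replicate across cohorts. Pathway
graphs are fixed per replicate (topology is a database object): planted
DE members occupy one graph neighbourhood, ubiquitous members are
dispersed. The base method is the equal-weight enrichment table (199
label permutations). The AF adjustment uses two-group weights — sets
whose AF-weighted `z_score` clears 1.2 form the prioritised group — the
grouped form of weighted BH, chosen because continuous per-cohort weight
estimates add noise that works against cross-cohort reproducibility; the
DS adjustment uses the continuous density scores (binary DE profile at
the top 15% of |signal-to-noise|, matching the planted DE plus drift
fraction of the universe). Reported are the fraction of replicates in
which each adjustment strictly improves the planted sets' mean rank and
the fraction in which the cross-cohort Spearman correlation of the
per-pathway p-values does not decrease.

## Numerical and interface conventions

Ranks are 1-based, most significant first, ties broken by pathway id.
Result TSVs use fixed 10-decimal formatting and round-trip through the
package's reader; rows are written in rank order. All randomness flows
through explicit integer seeds (default 0) via numpy Generators; CLI runs
write a sidecar JSON with resolved parameters, seed and input SHA-256
checksums sufficient to re-execute the run bit-identically.

## Known limitations

Graph semantics ignore edge direction, sign (activation vs inhibition)
and weights; sub-path extraction is out of scope. The enrichment core
deliberately omits the rank-weighted (|r|^p) running-sum variant, NES
normalisation of the classic FDR machinery, and leading-edge extraction.
Only two-class phenotypes are supported. Identifier namespaces are opaque
strings: callers must supply collections, graphs and expression data in
one consistent namespace.
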