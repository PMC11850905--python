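# Methods

`sacscreen` re-implements, as a tested pipeline over synthetic data, the
computational stages of a pooled CRISPR knockout resistance screen and the
cell-line-panel analytics used to connect a screen hit (a mitotic regulator
such as CDC20) to drug sensitivity: read-level sgRNA quantification,
guide-level differential enrichment, gene-level robust rank aggregation,
expression-quartile drug-association profiles with covariate
partialization, and a severity scoring scheme for mitotic aberrations.
Every input is produced by a seeded generator with a ground-truth ledger,
so each stage can be checked against what was planted.

## Read quantification

Reads follow the screen's amplicon layout: a 6-nt sample barcode at the
read start, a variable stuffer, the key sequence `CGAAACACC` immediately
upstream of the guide, then the 20-nt guide, sometimes preceded by one
extra template G. Demultiplexing is by exact barcode prefix. The key is
searched left to right with its first base constrained to 1-based read
positions 16–44 (configurable); the first in-window occurrence wins.
Position coordinates are 1-based because that is how molecular protocols
describe read layouts.

Two candidate 20-mers are extracted: the 20 bases after the key
(candidate A) and, when the base after the key is a G, the 20 bases after
that G (candidate B). Candidates are matched exactly (uppercase, `N` never
matches) against the library. Exactly one hit increments that guide's
count. When A and B hit two different guides — possible in principle,
never observed with random libraries — candidate A wins and the read is
tallied `ambiguous` in the per-sample report, keeping counting
deterministic. Column sums of the count matrix therefore equal
`n_assigned + n_ambiguous` per sample. No mismatch tolerance, quality use
or UMI logic: the counting contract is exact lookup.

## Normalization and the guide-level statistic

Size factors use median-of-ratios: guides positive in every sample form
the reference, each guide's count is divided by its geometric mean across
samples, and a sample's factor is the (arithmetic-interpolation) median of
those ratios. Scaling one sample by c rescales every geometric mean by
c^(1/m), so factors are meaningful only relative to each other — the
equivariance property holds for factor ratios. Guides with zero counts in
all samples are dropped before analysis.

The screen design is paired: each replicate contributes one control and
one treated sample. Per guide and replicate, d_i = log2(treated_i + c) −
log2(control_i + c) on normalized counts with pseudocount c = 0.5; the
log2 fold change is mean(d) and the test statistic mean(d)/(sd/√m).

With m = 2 replicates a per-guide sd has a single degree of freedom, and a
ranking built on the plain t is dominated by null guides that drew two
nearly identical log-ratios by chance. We therefore shrink the per-guide
variances toward a common prior by empirical Bayes (a scaled
inverse-chi-square prior fitted by moment matching on log s², the
moderated-t construction used throughout the microarray/RNA-seq
literature), and take p two-sided from t with m − 1 + d0 degrees of
freedom. This plays the same role as the dispersion sharing in
negative-binomial screen tools: information about noise is borrowed across
all guides, so the ranking reflects fold change against a stable noise
scale. `moderate=False` restores the plain per-guide t (with sd = 0
guides clamped to the smallest positive sd, or assigned stat 0/p 1 when
the fold change is also zero). In a planted-effect benchmark (500 genes ×
4 guides, one gene at log2 effect 2) moderation moves planted-gene
recovery from ~70% to 100% of seeds while leaving null p-values uniform.

## Gene scoring: alpha-RRA

Guides are ranked by the statistic (descending for enrichment, ascending
for depletion; ties broken by guide id) and assigned normalized ranks
r = rank/n. For a gene with sorted ranks r(1) ≤ … ≤ r(k), only ranks below
the cutoff alpha participate; the score is

    rho = min over j = 1..k_sel of P(Beta(j, k − j + 1) ≤ r(j)),

i.e. how improbably early the j-th of k uniform order statistics would
fall; rho = 1 when no rank clears alpha. Alpha defaults to the fraction of
guides on the tested side of zero, mirroring the "maximum percentile"
setting of the screen's rank-aggregation tool; the tool's reported
"p ≤ 0.25" screen setting is exposed as a post-hoc reporting filter (CLI
`--max-p`), not as part of rho. The permutation p draws k ranks without
replacement from the pooled rank list, n_perm times per distinct k, and
uses the add-one estimator (1 + #{null ≤ observed})/(n_perm + 1); BH
adjustment across genes gives the FDR. Default n_perm = 100 matches the
screen's setting; calibration tests raise it (see below).

Two discreteness effects matter when judging calibration. First, genes
with no guide below alpha have rho = 1 exactly — an atom of mass
(1 − alpha)^k, large for k = 2 but negligible at the ~10 guides/gene of a
genome-wide library. Second, all genes share one n_perm-draw null ECDF,
so its Monte-Carlo error (~0.09 in KS distance at n_perm = 100) propagates
to every p; at n_perm = 1000 the null p distribution is within KS 0.04 of
uniform at 1,000 genes. Neither effect biases the ranking of genes, which
is what the screen consumes.

Cross-screen concordance takes each screen's top fraction (default 25%) of
genes by permutation p and reports the intersection with both screens'
−log10 p. Pathway enrichment is a preranked weighted Kolmogorov–Smirnov
running sum: down the ranked list the sum rises by |score|^weight
(normalized over set members) at set genes and falls by 1/(n − set size)
elsewhere; the enrichment score is the signed maximum deviation, with a
set-membership permutation p.

Screen-design arithmetic: cells required for a target coverage are
⌈coverage × library size / surviving fraction⌉ — at 500× for a
188,509-guide library this is 94,254,500 cells to maintain and
377,018,000 to transduce when only 25% of cells survive infection at
MOI 0.3 plus selection.

## Panel association analytics

The panel bundle holds genes × lines expression, drugs × lines response
(**lower = more sensitive**, the log-fold-change viability convention of
public repurposing screens; stated in output headers), a per-line
aneuploidy score and per-drug class labels, inner-joined on line ids.

* **ssGSEA.** One line's genes are ranked by expression descending (ties
  by gene id); the score is the summed difference between the weighted
  in-set ECDF (weights = rank score^exponent, rank score n..1 from the
  top, default exponent 0.25) and the unweighted out-of-set ECDF. Using
  ranks rather than raw values makes the score invariant under strictly
  monotone transforms of the profile.
* **Quartile groups.** Bottom = values ≤ 25th percentile, top = values ≥
  75th percentile (linear-interpolation quantiles, boundary ties
  included); needs ≥ 8 non-missing values and a non-constant vector.
* **Quartile t test.** Welch by default (pooled via `equal_var=True`);
  delta and t are top − bottom. Degenerate groups with equal means give
  t = 0, p = 1.
* **Partialization.** OLS residuals of response on covariate with
  intercept; residuals are exactly orthogonal to both. The
  aneuploidy association runs the quartile test before and after
  partializing a candidate mediator gene's expression out of the response.
* **Genome-wide profile.** For every drug, every gene's quartile test runs
  via a vectorized path (group means/variances by matrix products,
  algebraically identical to the scalar test and tested against it);
  missing responses are deleted pairwise and pairs with under
  `min_group` (default 10) lines per quartile are skipped. Genes are
  ranked per drug by ascending p (ties by gene id); the target's
  percentile is 100 × (1 − (rank − 1)/n), so 100 = most significant.
  The direction is configurable (`high_is_significant=False` flips it)
  and recorded in outputs. Class-vs-rest comparison of percentiles is a
  two-sample t.

## Mitotic severity statistics

Events carry a category from a controlled vocabulary mapped to a 0–5
severity score: 0 correct segregation; 1 DNA bridge, micronucleus, or
lagging chromosome; 2 bridge/lagging with micronucleus, or metaphase
misalignment; 3 misalignment with micronucleus or with lagging/bridge;
4 metaphase skipping, cytokinesis failure, or misalignment with
lagging/bridge *and* micronuclei (the micronuclei clause is what separates
4 from 3 at that margin); 5 skipping with DNA bridging or with
micronucleus. Categories are normalized to lower-case canonical tokens
with an alias map. Events that fit no category ("other") keep their manual
1–5 score in exports but are excluded from the main statistics.

Severity distributions are compared with Kruskal–Wallis (mid-rank ties,
tie correction, upper-tail chi-square p — the KW statistic is inherently
one-sided, which is how we read a "one-sided" KW). Durations use a Welch
t for two groups and one-way ANOVA for more. Densitometry fold changes
double-normalize: target / (mitotic marker / loading control) per lane,
then treated over control.

## Synthetic data

The generators define the study conditions; they are deliberately minimal:

* **Library**: unique random 20-mers, guide ids encoding gene membership.
* **Counts**: gamma-Poisson (negative binomial) with variance μ + φμ²,
  φ = 0.1 by default; a shared per-replicate log-normal depth factor
  (sd 0.2) induces the pairing; planted genes scale treated means by
  2^effect; φ = 0 switches noise off and returns rounded means. Default
  depth 500 counts/guide and 2 replicates match the screen's design.
* **Reads**: exact per-guide read counts with the layout above, key offset
  uniform over the window, optional extra G, qualities constant 'I',
  default length 75. Flanking sequence is rejection-resampled (bounded
  retries, ~1e-4 trigger rate) so it never creates an earlier in-window
  key or an ambiguous library match — this is what makes the count
  round trip bit-exact, and is a property of the generator, not of real
  sequencing. No sequencing errors, PCR jackpotting or guide-efficiency
  heterogeneity are modeled: passing round-trip tests demonstrates the
  extraction logic, not robustness to noisy reads.
* **Panel**: expression standard normal; aneuploidy = coupling ×
  standardized target expression + orthogonal noise; drugs of a planted
  class respond as −effect × driver + noise where the driver is the
  target gene's expression by default. We chose the target gene (not
  aneuploidy) as the causal driver because only then does partializing
  the target out provably abolish the marginal aneuploidy–response
  association in a linear-Gaussian model — the structure the mediation
  analysis is meant to detect; `response_driver="aneuploidy"` provides
  the alternative. All other gene–drug pairs are null. Defaults: 200
  lines, 2,000 genes, 100 drugs with a 5-drug planted class.
* **Events**: severity scores drawn per-condition from stated
  probabilities, mapped to one canonical representative category per
  score; durations normal truncated at 0.

All generators take one seed and are bit-reproducible; ledgers record
planted effects, per-read assignments and per-condition histograms.

## Numerical and scale choices

Pseudocount 0.5 on log-ratios; ties broken lexicographically by identifier
everywhere; every stochastic step takes an explicit seed. Benchmarks run
at desk scale by choice: planted-screen recovery uses 500 genes × 4
guides × 2 replicates with n_perm = 1000 over 50 seeds (~1 minute);
null-calibration checks use 1,000 draws; the genome-wide gene × drug loop
(2,000 × 100 × 200) runs in about a second via the vectorized path.

## Limitations

The differential statistic is a moderated paired log-ratio t, not a full
negative-binomial GLM: it shares the ranking contract with such tools but
not their count-level likelihood, dispersion–mean trends or Cook's-style
outlier handling. Quantification is exact-match only. The panel generator
is linear-Gaussian with homoscedastic noise and no batch structure, so
panel results demonstrate the analytics' logic, not performance on real
dose–response data. Permutation p-values are floored at 1/(n_perm + 1),
which in turn floors the achievable FDR for top hits.
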