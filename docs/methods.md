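# Methods

This note records the model behind each stage, the conventions chosen
where the analysis design was genuinely open, and what the synthetic data
do and do not establish.

## Ranking and differential expression

Input matrices are log2-scale, gene-by-sample, complete (missing values
are rejected at load, because rank statistics and enrichment walks are
undefined on gaps). Two-class ranking uses the signal-to-noise metric
(μ₁ − μ₂)/(σ₁ + σ₂) with each class standard deviation floored at
0.2·|μ| and at an absolute 0.2 when μ = 0 — the standard guard against
near-constant genes blowing up the ratio. Ties are broken by
lexicographic gene id everywhere a deterministic order is needed
(rankings, within-sample expression ranks, probe collapsing), so reruns
are bit-identical.

Differential-expression gene sets use a strict linear fold-change cut
(default > 2, i.e. |log2FC| > 1 on log2 input; a gene at exactly 2 is
excluded). A Welch two-sample t-test p and its Benjamini–Hochberg
adjustment are reported per gene for context but never decide set
membership: the set-defining criterion is fold change alone. Moderated
(empirical-Bayes) variance modelling is deliberately out of scope; the
plain Welch test is reported as what it is.

## GSEA engine

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum with weight exponent p = 1 by default (p = 0 gives the unweighted
statistic). The extremum is the first position whose |running sum| is
within 1e-12 of the maximum — a float-tolerant earliest-position
tie-break that keeps the implementation and any independent enumeration
of the same walk in agreement.

The null distribution permutes gene labels: for a set of size k, ES of
n_perm (default 1000) uniformly drawn size-k subsets of the ranked list.
The p-value is sign-matched with the add-one rule,
p = (1 + #{same-sign null ES at least as extreme}) / (1 + #{same-sign
null ES}), which avoids p = 0 at finite n_perm at the price of a slight
conservatism of order 1/n_perm. NES divides ES by the mean magnitude of
same-sign null scores. The FDR q is the pooled-null ratio: each null ES
is normalized by its own set's same-sign null mean, the normalized nulls
of all tested sets are pooled, and q = (tail fraction of pooled null NES
beyond the observed NES) / (fraction of observed NES at least as
extreme), clipped to [0, 1]. With a single tested set the pooled ratio is
degenerate and q = p is reported with a log note. If a set has no
same-sign null scores, p and NES are reported as NaN and logged rather
than invented.

Set genes absent from the ranked list are dropped with a logged count; an
intersection below half the set size triggers a warning, because silent
gene loss is the chief failure mode of cross-species mapping.

A note on leading-edge contraction: removing the leading edge always
strictly shrinks the running-sum extremum *in the original ES direction*.
It does not always shrink the two-sided |ES| — when the remaining set
members happen to concentrate in the opposite tail, the recomputed score
can be a larger opposite-sign deviation. The test suite asserts the
direction-matched property, plus |ES| contraction whenever the recomputed
score keeps the original sign.

## ssGSEA and the fit score

Per sample, genes are ranked by that sample's expression (rank 1 =
highest; ties by gene id). With r = N − rank + 1, in-set positions carry
weights r^α normalized to sum 1 and out-of-set positions carry 1/(N − k);
the raw score is the sum over all positions of the in-set minus
out-of-set cumulative step difference (no division by N). α = 0.25, the
canonical single-sample exponent. The score depends on within-sample
ranks only, hence is invariant under any strictly increasing per-sample
transform.

Normalization divides every raw score by the pooled range (max − min)
over all samples *and both signature directions* of one dataset. The
pooling scope is a declared convention: it makes the up and down scores
commensurable, the fit thresholds scale-free, and each dataset
self-contained (cohorts on different platforms normalize independently).
The fit score is normalized up minus normalized down; classes are high
(fit > 0.40) and moderate (fit > 0.25), strict inequalities on both
boundaries (fit = 0.25 is none, fit = 0.40 is moderate).

Group-level assessment runs Bartlett's homogeneity test, one-way ANOVA,
and Tukey's HSD (studentized-range adjusted pairwise p) on the fit
scores; Bartlett and ANOVA are reported, the Tukey pairs drive the
decisions.

## Signature construction

Stage 1 tests study B's up and down DE sets against study A's ranking.
The up set must enrich at the top (ES > 0) and the down set at the bottom
(ES < 0); wrong-sign enrichment is an error naming the direction, not a
silent empty signature. The two leading edges, made disjoint by dropping
any gene occurring in both, form the shared signature, with the ES / NES
/ p / q of both runs recorded in its provenance string.

Stage 2 operationalizes "development-associated" as membership in the
same-direction leading edge of the shared sets' GSEA on an
undifferentiated-vs-differentiated healthy T-cell ranking (up genes
enriched toward the undifferentiated pole, down genes toward the
differentiated pole). Leading-edge membership is the construction's own
currency, so it is also the default removal criterion; an optional
`refine_q_max` switch additionally requires the development run to reach
a given FDR before any removal happens. Removed genes are logged and kept
in the provenance. The refinement can only shrink the signature, never
grow it.

## Correlation triage

Pairwise Pearson matrices over a small gene panel. Significance is exact:
|r| > r_c(n, α) with r_c = t_c/√(t_c² + n − 2) and t_c the two-sided t
quantile at n − 2 degrees of freedom — identical to p < α from the t
transform, and both are computed and cross-checked. The test is two-sided
(both enriched and depleted pairs matter) and per-pair without
multiple-testing correction by default, matching correlogram practice of
annotating each cell at α = 0.05; a BH option exists but defaults off.

The criterion-3 check in the triage restricts to a subtype's
signature-positive samples (fit class moderate or high) and requires a
significant *negative* VAV1–HES1 coefficient; fewer than 4 positive
samples makes the criterion not evaluable and the subtype cannot be a
candidate.

## Synthetic study design

All cohorts are simulated directly on the log2 scale: gene-specific
baselines uniform in [4, 12] log2 units, i.i.d. Gaussian noise (σ = 0.5)
around group means — matching the assumptions of RMA-scale array data and
keeping fold-change semantics exact. Defaults, chosen once as realistic
study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 1500 | genes per species |
| mouse groups | 3 / 3 / 3 | no-tumor, DN tumor, CD8⁺ tumor replicas |
| study B groups | 4 / 4 | control vs double-knockout |
| development contrast | 4 / 4 | undifferentiated vs differentiated |
| human cohorts | 64 / 52 / 124 | immature / TLX / TAL1 subtype splits |
| signature block | 60 up / 60 down | study A's common deregulated genes |
| overlap_fraction | 0.7 | fraction of the block also deregulated in B |
| n_dev_confounders | 12 | shared genes also tied to development |
| effect_log2fc | 2.0 | embedded group shift (linear 4-fold) |
| vav1_hes1_r | −0.8 | VAV1–HES1 correlation in the positive subtype |
| vav1_shift | 1.5 | VAV1 depression in the positive subtype |

Both tumor groups of study A shift the same common block (±2 log2);
study B shifts the 42-gene-per-direction overlap subset plus 18
study-B-only genes per direction, so the B-side DE sets contain genuine
shared genes, B-private genes, and a handful of noise false positives —
the mixture the leading edge must separate. The development contrast
shifts only the 6 + 6 confounder genes. Exactly one human subtype (TLX)
receives the ortholog images of the non-confounder shared genes, a 1.5
log2 VAV1 down-shift with the HES1 counter-shift, a bivariate-normal
VAV1/HES1 pair at ρ = −0.8, and TLX1-or-TLX3 marker elevation per sample
(the marker-based subtype-calling rule used when genomic annotation is
missing). The effect size (4-fold) reflects the strong deregulation
typical of tumor-vs-normal array contrasts; ρ = −0.8 encodes a strong
direct repressive relationship, consistent with an inverse pair that
reaches per-cohort significance thresholds of |r| ≈ 0.3–0.4 with margin.
The ortholog map is 1:1 Title-case → uppercase; many-to-many maps are
supported by the mapping code (expansion to all targets, cross-direction
conflicts dropped from both sides) but not exercised by the generator.

What the generator does *not* emulate: probe-level artifacts, batch or
platform effects, correlated gene-gene background structure, heavy-tailed
noise, or subtype heterogeneity within cohorts. Passing recovery tests
therefore shows the pipeline's statistical machinery is correct and
calibrated under its stated assumptions — not that it is robust to the
full messiness of real microarray data.

## Numerical choices and problem sizes

* One `numpy.random.Generator` per entry point, seeded from config; every
  stochastic result records its seed. Null ES computation is vectorized
  in blocks of 512 permutations.
* The permutation count defaults to 1000; calibration tests use 500 and
  recovery runs use the default.
* Acceptance-style checks run at desk scale chosen for tight feedback
  loops: exhaustive ES enumeration up to N = 12 and set size 3,
  permutation calibration over 300–500 null replicates, signature
  recovery over 20 seeds, triage recovery over 100 seeds, correlation
  null over 500–1000 replicate panels.
* `fold_change_filter` returns `None` for a direction with no passing
  genes (gene sets are non-empty by construction); pipeline stages treat
  that as an error naming the stage.

## Known limitations

* The pooled-range ssGSEA normalization makes fit scores comparable only
  within one dataset; cross-dataset fit values share thresholds but not a
  scale.
* The FDR q is the GSEA-style pooled-null ratio, which is noisy for very
  small set counts; with one set it degenerates to q = p.
* Tukey HSD assumes homoscedastic groups; Bartlett's test is reported so
  users can judge that assumption, but the pipeline does not switch
  procedures automatically.
* The triage's criterion 2 is the fit-score group test (highest mean fit
  and Tukey significance against every other subtype). Requiring an
  additional cohort-level GSEA of the signature against a
  subtype-vs-rest ranking would be a stricter reading; the per-sample
  fit evidence was chosen as the primary criterion because it is the
  quantity the thresholds (0.25 / 0.40) are defined on.
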