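# Methods

## The inference problem

Single-nucleus ATAC-seq measures, per nucleus, fragment counts in a fixed set
of open-chromatin peaks. Given cell-type labels (obtained upstream by label
transfer from matched scRNA-seq; that step is outside this package's scope),
the pipeline identifies peaks specifically accessible in one invasive cell
population at two developmental stages, keeps the peaks shared by both
stages, asks which of them are conserved in a reference species, finds the
transcription-factor motifs over-represented in them, and assembles a
bipartite TF-family → target-gene network over the conserved elements.

## Differential accessibility model

Membership in the target population is modeled per peak as

    logit P(nucleus ∈ target) = β₀ + β₁·a + β₂·log d

with `a = log(1 + 10⁴·count/d)` the depth-normalized log accessibility and
`d` the nucleus's total fragments in peaks. The test is the likelihood-ratio
χ² (df = 1) against the model without β₁. Modeling membership as the outcome
with depth as a covariate is the explicit-model restatement of the
"logistic regression with a latent depth variable" framework popularized by
Seurat's `FindMarkers(test.use = "LR")`; the normalization scale (10⁴) and
the link-scale predictor are fixed here because the framework's published
description leaves them open.

Numerical details:

- The null model does not involve the peak, so it is fitted once per
  comparison and reused across peaks.
- Fits use Newton iterations with step halving, converging on the
  log-likelihood (relative change < 1e-10). Under quasi-complete separation
  the coefficients diverge while the likelihood approaches its supremum;
  converging on the likelihood keeps the LRT statistic well defined instead
  of reporting a spurious failure. A fit that genuinely fails to stabilize
  within 100 iterations is reported with p = 1 and `converged = False`,
  never silently.
- A peak with a constant predictor (e.g. all-zero counts) gets statistic 0,
  p = 1, log₂FC = 0 without fitting.
- Effect size: `log2((mean_target(a′)+1)/(mean_other(a′)+1))` with
  `a′ = 10⁴·count/d`. The pseudocount 1 on this scale is fixed and documented
  so that the log₂ 1.5 specificity threshold is meaningful.
- Specific peak: BH-adjusted P ≤ 0.05 and log₂FC ≥ log₂ 1.5 (both
  inclusive).

The test suite verifies the p-values against an independent statsmodels
logistic GLM (≤ 1e-6 relative) and checks calibration under the null
generator (fraction of p < 0.05 within [0.03, 0.07] and the ECDF inside the
95% Kolmogorov band at 2000 peaks).

## Statistical conventions

- Over-representation tails are P(X ≥ k) — R's
  `phyper(k−1, …, lower.tail=FALSE)`. The off-by-one is fixed once in
  `stats_core.hypergeom_overlap`; callers choose the tail explicitly.
- `two_proportion_greater` transcribes R `prop.test`'s contract: Yates
  continuity correction capped at the smallest |observed − expected| cell,
  one-sided p from the signed square root of the χ² statistic. Frozen
  reference values in the tests were computed with R 4.3.
- Wilcoxon rank-sum uses exact enumeration when n₁+n₂ ≤ 20 without ties,
  otherwise the normal approximation with tie and continuity corrections.
- BH adjustment is the plain step-up, order-preserving and clipped to 1.

## Interval logic

All internal coordinates are 0-based half-open; GTF input is shifted on read.
The common-peak rule keeps a query peak when a partner covers ≥ 50% of the
query's length (query frame, bedtools `-f 0.5`; a reciprocal mode is
provided). Conservation requires ≥ 1 bp overlap between the mapped image and
any reference peak; adjacent half-open intervals do not overlap. Cross-species
projection uses a deliberately simplified 7-column mapping dialect (source
block → equal-length target block, optional strand flip): a peak maps iff it
lies entirely within one source block. Real UCSC chain parsing, and therefore
real liftOver edge cases (split blocks, partial matches), are out of scope.

Nearest-gene distance is measured from the peak edge to the strand-aware TSS
(start on +, end−1 on −), zero when the TSS falls inside the peak, with the
gap counted from the peak's end coordinate on the downstream side; distance
ties break toward the lexicographically smaller gene id and are flagged. A
flag allows measuring to the annotated start regardless of strand, since
"start position" is ambiguous in common usage.

## Motif scanning

PWMs are probability matrices obtained from counts with a pseudocount of 0.8
distributed by background frequency (the TFBSTools/JASPAR convention).
Scanning scores log₂-odds against the background composition, discretized to
1e-3 granularity. The hit threshold is the smallest *achievable* window score
whose exact null tail probability under iid background bases is ≤ the p-value
cutoff (default 5e-5, the motifmatchr convention); the null distribution is
computed by dynamic programming — one sparse convolution (four shifted adds)
per motif position. The DP threshold is verified against exhaustive
enumeration of all 4^L words for L ≤ 8. Scanning evaluates both strands; the
reverse-complement score matrix is obtained by flipping the integer matrix, so
strand symmetry is exact by construction. Windows containing non-ACGT
characters carry a sentinel score and can never match; sequences are scanned
as one concatenated array with single-N separators.

Backgrounds are sampled with replacement from the non-foreground peak pool,
allocated over the foreground's joint (GC decile × length decile) histogram
(50,000 draws by default). A foreground bin with no pool members falls back
to the nearest populated bin with a warning. Enrichment per motif is the
hypergeometric upper tail on pooled foreground+background hits, BH-corrected
across motifs; fold change is the ratio of hit fractions, with an infinity
sentinel when the background fraction is zero.

Filtering and grouping follow the order: per-motif enrichment thresholds
(adj P ≤ 0.05, fold ≥ 1.5) → TF-expression filter (≥ 0.5 at both stages, one
passing subunit suffices for dimer motifs) → family grouping. A family hits a
peak iff any member motif does (union), its adjusted p is the best member's,
and its representative motifs are the best-fold-change motifs of the two most
highly expressed member TFs. Whether fold-change filtering happens before or
after family grouping was an open choice; filtering per motif first was
chosen because family-level fractions are unions and would dilute the
threshold's meaning.

## Network

Edges require the conjunction: peak ∈ conserved common set, family motif hit
on the peak, nearest gene of the peak, gene ∈ conserved-marker list (markers
at both stages *and* conserved, supplied as explicit inputs because marker
calling from scRNA-seq is out of scope). Duplicate (family, gene) pairs merge
with all mediating peaks recorded. In-degree centrality counts distinct
regulating families per gene. Exports: lossless edge TSV, SIF ("regulates"),
GraphML.

## Synthetic study design

The generator emulates the study structure end to end; its defaults are the
standing conditions for every calibration and recovery figure:

| parameter | default | rationale |
|---|---|---|
| cell types × nuclei | 5 × 200 per stage | the five labeled populations of a uterine–placental interface at a desk-scale nucleus count |
| peaks | 2000 over a 4 Mb two-chromosome genome | grid-spaced ~2 kb apart, lengths 300–500 bp |
| depths | lognormal(meanlog 7.5, sdlog 0.4) | median ≈ 1800 fragments in peaks, spanning the 1000–20000 QC window; 5% junk nuclei (depth ≈ 400, low FRiP/TSS) exercise QC |
| counts | Poisson(depth × weight), weights ~ Gamma(2) normalized | simplest depth-scaled model that exercises the LR test; no zero inflation |
| specific peaks | 50 per type per stage, planted as runs of 1–4 adjacent peaks | clustered accessibility around regulated genes, so peaks-per-gene histograms have mass at ≥ 3; 80% of the target's peaks (whole runs) shared between stages |
| effect | +10 on the 10⁴-normalized scale | ≈ 3× the mean baseline: clearly detectable at 200 vs 800 nuclei yet not separable |
| sequences | iid with per-peak GC ~ clipped N(0.45, 0.07) | heterogeneous GC for the matched-background machinery |
| motifs | 6 near-deterministic 12-mers in 5 families, planted into 30% of the target's common peaks; 50 decoys | recovery and false-positive control for the enrichment stage |
| conservation | mapping records for 60% of peaks (identity + 1 Mb offset); reference ATAC covers 85% of mappable common peaks | conservation is a genuine second filter beyond mappability, keeping the H3K27ac and proportion tests non-degenerate |
| expression | 5 + z(promoter accessibility) + N(0, 1.7), floored at 0 | the noise scale places the expression–accessibility Spearman ρ in the documented 0.4–0.6 band (a generator property chosen to echo the moderate coupling seen in real tissue, not a reproduction of any measured value) |

Gene placement: each specific-peak run's middle peak hosts a gene (TSS at the
peak midpoint ± 100 bp); remaining genes go to peaks outside a two-cell
margin around the runs, so a run member's nearest gene is its own run's host.
TF expression for planted motifs is drawn ≥ 1 at both stages; half the decoy
TFs are drawn below the 0.5 filter to exercise expression filtering. The
orthology table is one-to-one for most genes with a few deliberate
one-to-many rows (which downstream analyses must drop).

The *null* bundle forces effect 0 and no motif planting and empties the
ground truth; it is the calibration condition. The *noiseless* configuration
(effect +150, exhaustive consensus planting, no expression noise, no junk
nuclei, scan cutoff 1e-7 so only consensus-grade matches count) is the
end-to-end condition under which the recovered network must equal the planted
edge set exactly. The effect size is large because the fold-change threshold
is evaluated against heterogeneous baselines: a +40 shift on a high-baseline
peak (Gamma weight tail) can fail log₂FC ≥ log₂ 1.5 even when the planting is
real.

What the generator does **not** emulate — and what passing tests therefore do
not show about real data: Tn5 insertion bias and fragment-length structure,
zero inflation and overdispersion beyond Poisson, peaks distal to their
target genes (planted genes sit on their runs, so distal fractions are near
zero, unlike real tissue where most specific peaks are > 5 kb from the TSS),
correlated motif co-occurrence, real liftover breakpoints, and
one-to-many regulatory relationships.

## Problem sizes

Calibration and recovery run at the defaults above (2000 peaks, 400–1000
nuclei per comparison); the oracle-equivalence checks run on universes ≤ 12
where exhaustive enumeration is feasible; the end-to-end noiseless chain runs
at 1000 peaks × 3 cell types × 150 nuclei. These sizes were chosen so each
property is measured on the same conditions the generator documents while the
whole suite stays fast enough to run routinely.

## Known limitations

- The LR test's asymptotic χ² is slightly anticonservative at very low
  per-peak counts; the null calibration band [0.03, 0.07] reflects this.
- Family-level adjusted p (best member) is a reporting convenience, not a
  family-level test; co-occurrence matrices are the inferential layer at
  family resolution.
- The hypergeometric enrichment treats background draws as exchangeable with
  foreground peaks; with-replacement sampling makes the background
  pseudo-replicated, which is the standard practice this stage mirrors.
- `sample_matched_background` matches marginal deciles jointly but not the
  full copula of (GC, length).
- The marker-overlap test defaults to the over-representation tail
  (P(X ≥ k)); the depletion tail is available via the `tail` parameter.
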