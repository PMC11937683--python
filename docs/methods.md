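# Methods

This package re-implements, as a tested pipeline on synthetic data, the
computational core of a skeletal-muscle DNA-methylome aging study: the
whole-genome bisulfite (PBAT-style) descriptive layer, de-novo DMR
calling with published post-filters, the aging/genotype sensitivity
contrast, the two-enzyme (HpaII/MspI) microarray methylation
classification, and the spreadsheet-defined Tissue Elasticity Score for
fasting–refeeding experiments. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Methylome model and simulation

Per-CpG data are methylated/unmethylated read counts. The generator
(`synthetic_data`) draws, for CpG *i*, a baseline level
πᵢ ~ Beta(a, b) shared by all samples, with default (a, b) = (6, 6):
a unimodal distribution centred at 0.5 with sd ≈ 0.14, leaving headroom
for the planted shifts on both sides. Real methylomes are strongly
bimodal (most CpGs near 0 or 1); the unimodal baseline is a deliberate
simplification — it makes every planted shift estimable without
boundary censoring, at the cost of not exercising the caller on
near-saturated CpGs. Passing tests therefore demonstrate correctness of
the procedures, not calibration on real bimodal methylomes.

Group expectations add, on the proportion scale and clipped to [0, 1]:

* a global aging gain `age_effect_background` (default **0.02**) in old
  samples — aging muscle methylomes drift upward genome-wide, and the
  boxplot-median contrast between old and young is driven by exactly
  this term (the planted hyper/hypo regions cancel in a genome-wide
  median);
* ± `age_effect` (default **0.30**) in old samples inside planted
  age-hyper / age-hypo regions;
* genotype (transgene) shifts in Tg samples: `tg_effect_in_hyper` =
  **0.15** inside age-hyper regions, `tg_effect_in_hypo` = **0.03**
  inside age-hypo regions, 0 elsewhere — encoding the hypothesis that
  the age-gaining compartment is the genotype-sensitive one.

Counts are beta-binomial: total ~ Poisson(coverage, default 20); meth ~
BetaBinomial(total, μ, ρ) with intra-class correlation ρ
(`overdispersion`, default **0.05**, a typical WGBS value); ρ = 0
reduces exactly to the binomial, which the tests exploit as an analytic
limit. One global seed feeds per-(sample, chromosome, stage) sub-streams
(CRC-keyed `SeedSequence`s), so adding samples or groups never perturbs
existing ones.

Planted regions span a fixed number of consecutive CpGs (default 15) so
recall is independent of local CpG density, and are placed only on runs
whose internal gaps are ≤ 300 bp. The density restriction is not
cosmetic: any metilene-style caller pre-segments at large CpG gaps, so a
"region" straddling a 300-bp gap is two regions to every caller of this
family; dense placement also mirrors real DMRs, which concentrate in
CpG-dense sequence. Default scenario: one 2-Mb chromosome, ~20,000
CpGs (mean spacing 100 bp), 25 + 25 planted regions, n = 4 per group —
sized so a full multi-replicate sweep runs in minutes on one CPU while
keeping Monte-Carlo error an order of magnitude below the planted
effects.

## Descriptive layer

Coverage filtering keeps CpGs with ≥ `min_reads` total reads (inclusive
bound; 10 for tibialis-anterior-type data, 5 for gastrocnemius-type).
Windows tile each non-sex chromosome from 0 with step = size by default
(the window step was not published; disjoint tiling keeps window values
independent, and a `step` parameter provides true sliding windows).
Region values are **unweighted** means of per-site levels — "averaging
the methylation levels of CG sites" — not coverage-weighted means;
`min_sites` (default 1) controls missingness. PCA uses complete-case
regions (rows with any missing value dropped — imputation is out of
scope), centred, via SVD. Hierarchical clustering is complete-linkage
on euclidean or correlation distances (scipy); ties follow scipy's
deterministic input ordering. Row z-scores use the sample (n − 1)
standard deviation so heat-map matrices are exactly reproducible.

## DMR calling

The caller follows the metilene recipe with its default parameters
(min 10 CpGs, 300-bp maximum gap):

1. **Pre-segmentation** at inter-CpG gaps > 300 bp (and chromosome
   boundaries), on sites with a defined level in all samples of both
   groups (`min_present` relaxes this; metilene's internal imputation is
   not reproduced).
2. **Recursive binary segmentation** within each pre-segment on the
   per-site group mean difference dᵢ: the contiguous block of ≥ 10
   sites maximising the scan statistic |Σdᵢ| / √length is extracted and
   the flanks are searched recursively. The √length (CUSUM)
   normalisation is the standard binary-segmentation scoring; scoring
   blocks by the raw |mean| instead biases the search toward a short,
   noise-inflated core of a true region (a 15-CpG signal is routinely
   truncated to its best 10 CpGs, and boundary recovery degrades
   measurably), so the scan form is used. Ties break to the leftmost,
   then longest, block.
3. **Testing**: a two-sample Kolmogorov–Smirnov test on the pooled
   per-site per-sample levels of the two groups, and a Mann–Whitney U
   test on per-site group means. Exact small-sample methods are used
   when feasible (the exact KS/MWU p-values match exhaustive
   permutation enumeration to < 1e-12 on tie-free data), asymptotic
   otherwise. This KS construction is an auditable stand-in for
   metilene's "2D KS" statistic, which is not fully specified in public
   descriptions; the *filtering semantics* are preserved exactly, the
   statistic is not bit-compatible with metilene. This is a deliberate,
   documented divergence.
4. **Filters**: p_KS < p_threshold AND |mean diff| > diff_threshold,
   both strict, with the two published presets (0.01 / 0.20 and
   0.05 / 0.10; thresholds live on the proportion scale, 20% ⇔ 0.20,
   and the difference is taken as an absolute value since both
   directions are reported). No multiple-testing correction is applied
   in this mode — the published filter acts on raw p — but
   Benjamini–Hochberg q-values over all candidates are attached for
   transparency and can be switched on (`adjust="BH"`).

Called DMRs are disjoint, sorted, and annotated with their nearest
gene (distance 0 on overlap, else interval gap; ties to the smaller
gene start, then lexicographic id).

## Aging contrasts

Age DMRs come from the old-WT vs young-WT contrast and are partitioned
by sign into hyper/hypo sets. The genotype-sensitivity statistic is
computed on the methylation-proportion scale (the same scale as the
published heat maps; no logit transform, keeping deltas in [−1, 1]):
per region, delta = mean(young Tg) − mean(young WT); the hyper-set and
hypo-set delta distributions are compared with a two-sided Mann–Whitney
U test (deltas are bounded and need not be normal — the rank test is an
implementation choice, not a published fact). Old-Tg samples appear in
matrices and z-scored heat-map copies but not in the sensitivity
statistic (the claim under test concerns young ages). Gene-set overlaps
are exact set partitions; differential-expression lists are consumed as
plain tables (gene_id, log2fc), never computed here.

Observed calibration: the replicate-mean estimate of delta_hyper runs
~0.01 above the planted 0.15. The bias is a selection effect — called
region boundaries are chosen partly on the young-WT samples, which also
enter the delta — and stays well inside the ±0.03 recovery band.

## MIAMI classification

The classified value per probe is the HpaII/MspI between-sample signal
ratio: normalising the methylation-sensitive channel by the
methylation-insensitive one cancels probe-level copy/amplification
variation common to both digests (the simulator plants exactly such a
shared component). Thresholds are the published linear-scale cut-offs,
< 0.714 hypomethylated and > 1.3 hypermethylated (strict inequalities;
the asymmetry is reproduced verbatim, unexplained in the source). An
optional `mspi_band` forces probes with extreme MspI ratios to
"unchanged" as a copy-number guard; it is off by default because no such
gate is published.

## Tissue Elasticity Score

Weights are normalised within genotype to the fasted-group mean
(X = fed/mean(fasted)·100 − 100 per fed mouse, Y analogous per refed
mouse), and the published spreadsheet formula is evaluated **verbatim**,
with y = Y − 100 and A = mean over fed mice of (X − 100):

    Value1 = (y + A) · min(y, A) / max(y, A)
    Value2 = Value1 if y > 0 else −Value1
    ElaS   = −Value2 if (|y| > A and y < 0) else Value2

Two oddities are retained deliberately, because the published figures
were produced by this exact function: (i) X and Y are already
percent-change values, yet the formula subtracts a further 100 from
each; (ii) the final condition applies ABS() to y but not to A. A is
computed once per genotype × tissue, so per-mouse scores vary only
through Y. When max(y, A) = 0 the division is undefined; the score is
reported as 0 with a degenerate flag (excluded from group summaries)
so batch runs complete. Group comparisons use mean ± SE and Student's
two-tailed unpaired t test, the published statistic.

A consequence of the double subtraction: ElaS is monotone in the true
restoration fraction ρ (refed mean = fasted + ρ·(fed − fasted)) only
while the fed/fasted mean ratio is below 2 (equivalently A < 0). The
feeding simulator's defaults — liver 1300/900 mg, gastrocnemius
150/130 mg, lognormal noise cv = 0.05, n = 8 per state — sit in this
physiological regime, where monotonicity holds analytically and is
verified empirically across ρ ∈ {0, 0.25, 0.5, 0.75, 1}. At ratios ≥ 2
the verbatim score becomes V-shaped in ρ; users scoring quantities with
large fed/fasted contrast should treat ElaS comparisons with care.
Within the monotone regime the score is also invariant to rescaling all
weights of a genotype × tissue cell (units cancel in the fasted-mean
normalisation), which the tests verify.

Gene responsiveness uses two plain summaries per gene × genotype:
induction = mean(fasted)/mean(fed), and restoration =
1 − |mean(refed) − mean(fed)| / |mean(fasted) − mean(fed)| (1 = full
return to the fed level, 0 = still at the fasted level; undefined and
flagged when fasting did not move the gene).

## Numerical and degenerate-input policy

* All internal coordinates are 0-based half-open; 1-based coverage
  input is converted only in `io_formats` readers/writers. The meth%
  column of coverage files is never trusted; counts are authoritative.
* Zero-coverage CpGs are retained with an undefined (NaN) level.
* Constant rows: z-scoring raises by default (or drops with a warning,
  for heat maps); correlation-distance clustering raises naming the
  offending row.
* p-values are clipped into (0, 1]; identical groups give p = 1.
* Determinism: every stochastic function takes a seed; the pipeline
  manifest records sha256 checksums, and reruns with the same config +
  seed are byte-identical.

## Known limitations

* The KS statistic is not metilene's exact "2D KS"; DMR lists from this
  caller and metilene will differ in detail even at identical filters.
* The generator's unimodal baseline, single-chromosome default, and
  absence of read-level artefacts (bisulfite conversion error, mapping
  bias, CNVs/SNPs) mean the simulations validate procedure, not
  genome-scale performance claims.
* No microarray normalisation or dye-bias correction for MIAMI inputs;
  probe ratios are taken as given.
* Differential-expression calling, GO/KEGG enrichment and epigenetic
  clocks are out of scope; their outputs are consumed as plain tables
  where needed.
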