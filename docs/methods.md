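# Methods

This note documents the models, estimators and design choices behind
`beprog`, in the order the funnel runs them, followed by the synthetic-data
model and known limitations.

## Frozen-quantile normalization

Each sample's values are replaced by the frozen reference quantiles of
equal rank: the sorted sample values are assigned the reference quantile
function evaluated at plotting positions (i − ½)/n, and tied input values
receive the mean of their assigned quantiles. Mapping is independent per
sample, preserves within-sample ranks exactly, and is idempotent. Pooling
intersects gene sets and sorts genes lexicographically, so results do not
depend on dataset or gene order.

This is a deliberate, loudly documented simplification of frozen RMA:
the original method freezes *probe-level* effects learned from a large
reference corpus; here a gene-level frozen quantile vector plus per-gene
unexpressed location/scale parameters stand in, because every downstream
stage consumes gene-level values and frozen cutoffs only. Nothing is refit
on the incoming data, which is the property that matters for cross-dataset
comparability. Probe-level processing, and learning the reference from an
external corpus, are out of scope; when multiple matrix rows share a gene
id, the row with the highest mean intensity is kept (deterministic
conventional collapse).

Note that a gene-wise batch shift is *not* fully removed by any rank-based
per-sample mapping — only its global component is. This residual is
intentional in the synthetic model (below): it is what makes the
negative-control calibration of the DE threshold meaningful.

## Moderated differential expression

Per gene, with groups A and B of sizes n_A, n_B:

- log2 ratio = x̄_A − x̄_B (difference of group means of log2 values —
  the natural reading of a log2-ratio threshold);
- pooled residual variance s²_g with d_g = n_A + n_B − 2 df;
- hyperparameters by moment matching on z = log s²_g: with
  e_g = z_g − ψ(d_g/2) + log(d_g/2), the excess of var(e) over ψ′(d_g/2)
  determines d₀ via the inverse trigamma (Newton iteration), and
  s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the observed spread does
  not exceed sampling noise the prior df are infinite and the shrinkage
  target is the arithmetic mean of the s²_g — chosen so that in the
  degenerate case where all sample variances coincide, the moderated t
  reduces *exactly* to the ordinary pooled t (a test oracle);
- posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g); moderated
  t̃_g = log2 ratio / (s̃_g √(1/n_A + 1/n_B)); two-sided p from t with
  d₀ + d_g df (normal when infinite); Benjamini–Hochberg adjustment.

The Lods (B-statistic) score is the log posterior odds that a gene is
differential, given a prior proportion p_de of changed genes (default
0.01, the conventional choice; Lods shifts by a constant in logit(p_de),
so the default only anchors the scale). With v the unscaled coefficient
variance (1/n_A + 1/n_B) and v₀ the variance prior of true effects,
r = (v + v₀)/v and

    Lods = logit(p_de) − ½ log r + (1 + df)/2 · log[(t̃² + df)/(t̃²/r + df)].

v₀ is estimated from the top p_de/2 fraction of |t̃| (the excess of each
observed top statistic over the null tail quantile it would occupy),
clipped to [0.1², 4²]·v and floored at a tiny positive value so Lods is
strictly increasing in |t̃| at fixed df. Lods is clipped below at −10⁶;
zero-variance genes get a machine-epsilon variance floor and a flag, never
silent removal.

Selection is inclusive at both bounds (Lods ≥ 5, |log2 ratio| ≥ 0.58
defaults). Both directions are kept by default — the exclusivity step of
the barcode imposes directionality — with an `up_only` option. The
contrast pools all datasets after frozen normalization into a single
two-group design. The Lods ≥ 5 default is the threshold that survives
negative-control calibration: `calibrate_null` refits the model with
dataset-of-origin as the contrast on two sample sets where no real
differences are expected and reports how many genes exceed the cutoff (a
threshold passes when none do).

## Expression barcode

A gene is expressed in a sample iff (value − μ_g)/σ_g ≥ z_cut, with μ_g,
σ_g the frozen unexpressed location and scale. z_cut defaults to 5.0: the
barcode literature uses a conservative sd-threshold against the
unexpressed distribution, and 5 sd makes false "expressed" calls
negligible; it is exposed in config. All boundaries are inclusive.
Dataset rules default to 1.00 (P-BE) and 0.75 (nonP-BE and EA); group
barcodes are intersections over datasets; the exclusivity step is the set
difference P-BE − nonP-BE. An EA barcode, when EA datasets are provided,
is computed and reported but subtracted only on request
(`subtract_ea`) — the default funnel reads exclusivity as
progressor-minus-non-progressor.

## Enrichment and network prioritization

Over-representation is one-sided: p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n), BH-adjusted across sets; the universe
defaults to all genes of the pooled matrix. Guilt-by-association ranking
is regularized label propagation: f = (I + λL)⁻¹y with L the
symmetric-normalized Laplacian of a user-supplied weighted network and y
the seed indicator. λ defaults to 1; scores are non-negative (the
resolvent of a substochastic non-negative matrix) and zero on components
without seeds. Neighbor expansion keeps the seeds plus the top-k
reachable non-seeds (k = 100 by default), ties broken by gene id. The
multi-network weighting of interactive network tools is out of scope; a
single pre-combined network is the input, which keeps the ranking step
testable offline against a dense linear solve.

## qPCR and clinical statistics

2^−ΔΔCt: replicate Ct values are averaged *before* any subtraction; ΔCt =
Ct_target − Ct_calibrator per patient and timepoint; ΔΔCt subtracts the
control group's mean ΔCt within the same timepoint; the per-patient fold
change is 2^−ΔΔCt. Group fold changes are summarized by the geometric
mean (primary — fold changes are ratios) with the arithmetic mean also
reported. The construction is invariant to any per-patient constant added
to both genes (loading differences), which is the point of the calibrator.

Standard curves regress Ct on log10(input ng) by least squares over the
seven-point dilution grid 100 … 0.0001 ng; efficiency = 10^(−1/slope) − 1,
so −3.32 cycles per decade is perfect doubling.

The Wilcoxon rank-sum test enumerates the exact null distribution of the
Mann–Whitney U (dynamic program over rank configurations) when
n + m ≤ 20 and there are no ties — the validation cohort's 9-vs-10
comparison lands in the exact regime — and otherwise uses the normal
approximation with continuity and tie correction; two-sided p is twice
the smaller tail, capped at 1. Pearson's chi-squared test applies the
Yates continuity correction on 2×2 tables by default (the convention of
the statistical environments this field uses), with a flag to disable.
Follow-up summaries report per-group mean (one decimal), min and max of
integer follow-up years. Ordinal score tables retain zero-count
categories; the IHC alphabets differ per antibody ({−, +, ++, +++} for
CYR61, {−, +, ++} for TAZ) and are validated at parse time.

## Synthetic-data model

Intensities are a two-component normal mixture on the log2 scale:
unexpressed N(4, 0.5²) and expressed N(9, 1²) by default — typical
microarray magnitudes, and any parameters with μ_expr − μ_unexpr > 4σ
behave equivalently. A gene's baseline expressed state is drawn once per
gene (probability 0.35) and shared by all samples, so baseline bimodality
carries no group signal. Planted progression genes are exclusively
expressed in P-BE samples (off elsewhere) and additionally mean-shifted
(+2.0 log2 in the standard runs). Each dataset adds a gene-wise batch
shift N(0, 0.5²); because the only P-BE dataset is then confounded with
its batch, naïve pooling produces false DE calls — the failure mode the
barcode-exclusivity filter and the calibrated threshold are there to
absorb. The default cohort is one P-BE dataset of 8 samples and nonP-BE
datasets of 7 and 18. All generators are pure functions of (config, seed);
there is no hidden global random state.

What the simulator does *not* model: probe-level effects and annotation
ambiguity, intensity-dependent (non-additive) batch distortions,
correlated gene modules, mixed dysplasia grades within a dataset, and
dropout/degradation patterns of FFPE-derived RNA. Passing tests therefore
demonstrate that the computation is correct and that the funnel's logic
recovers planted signal under its own model assumptions — not that the
thresholds are optimal for any particular real cohort.

Standard problem sizes used by the test suite and the acceptance script:
2000 genes, the 8/7/18 cohort, 20 planted genes, 20 negative-control
replicates, 10-vs-10 qPCR patients — small enough to run in seconds while
keeping the group sizes and rules of the study design.

## Numerical choices and degenerate inputs

- Quantile-mapping ties: averaged, deterministically.
- Inverse trigamma by Newton iteration (relative tolerance 1e−10).
- Lods floor −10⁶; v₀ floored at 1e−8·v; BH capped at 1.
- Zero-variance genes flagged, variance floored at machine epsilon.
- Exact-vs-approximate Wilcoxon switch at n + m = 20; ties always route
  to the corrected approximation.
- Candidate ordering: descending Lods, ties by gene id; all set-valued
  outputs are written sorted so reruns are byte-identical.
- Derived child seeds stay below 2³¹.

## Known limitations

The normalization is a gene-level surrogate and cannot undo gene-wise
batch effects (only calibration + exclusivity absorb them). The
hyperparameter estimator assumes a common residual df across genes (true
for the complete two-group design it serves). The label-propagation
ranking treats the input network as given and correct. The clinical table
module validates schema and alphabets but performs no survival analysis;
follow-up is summarized, not modeled.
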