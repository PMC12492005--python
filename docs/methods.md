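# Methods

This note documents the statistical procedures implemented in `imodkit`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that make runs exactly
reproducible.

## Expression input and centering

The unit of analysis is a genes × samples matrix of log-transformed TPM
values with unique identifiers and no missing entries (loading fails loudly
otherwise). Before decomposition the matrix is centered to a *reference
condition*: for each gene, the mean over the reference samples is
subtracted, so reference samples read as zero and every other entry is a
log fold change against the reference state. Centering is idempotent for a
fixed reference set. Matrix-level QC covers two of the checks a compendium
pipeline applies after alignment: the Pearson correlation between
biological replicates (pairs below r = 0.95 flag both samples;
replicate-singleton groups are skipped with a logged note; a zero-variance
sample has undefined r and fails with a reason) and outlier detection by
average-linkage hierarchical clustering on the distance 1 − r, cutting the
dendrogram at a configurable height (default 0.3) and flagging samples
outside the largest cluster. The clustering cut is not a published
constant; it is exposed in the config rather than presented as canonical.
Genes constant across all samples are kept in the matrix but excluded from
correlation computations, unless that would leave fewer than two genes (a
degenerate matrix), in which case all genes are used.

## Robust ICA

A single run treats genes as observations: the centered matrix is projected
onto its top-`dim` principal directions by SVD (explicit whitening — no
extra mean removal, so a noiseless rank-`dim` matrix is decomposed inside
its exact column span) and FastICA with the logcosh contrast pursues
non-Gaussian gene-weight vectors. Each recovered column is scaled to unit
L2 norm and oriented so its largest-|weight| entry is positive. Runs are
deterministic given their seed; run *i* of a decomposition uses
`base_seed + i`, and every seed is recorded in the run manifest.

Robustness comes from consensus over `n_runs` (default 100) runs: all
pooled columns are clustered with DBSCAN under d(u, v) = 1 − |ρ(u, v)|
(sign-invariant by construction, so a component and its negation
coincide), with radius eps = 0.1. A cluster becomes a robust component if
at least `min_support` distinct runs contribute to it — default
⌈n_runs/2⌉ + 1, i.e. *more than half* the runs; duplicated columns within
one run count once, so a single pathological run cannot manufacture
support. The component is the unit-norm mean of its sign-aligned members.

The final activity matrix is recomputed by least squares, A = M⁺X, rather
than averaged from per-run mixing matrices, making M·A the best Frobenius
reconstruction for the chosen M and keeping the explained-variance
definition consistent.

### Dimensionality selection

Too low a dimensionality merges regulatory signals; too high a
dimensionality starts producing components that fail to define a module —
a single outlier gene or, in data whose noise is not heavy-tailed
per gene, no outlier genes at all. The scan runs the full
pool-and-cluster procedure at each candidate dimensionality and selects the
largest one whose fraction of such ≤1-member robust components is at most
`single_gene_fraction_max` (default 0.10). If no candidate qualifies the
smallest dimensionality is returned with an explicit warning flag. The
per-dimensionality component and single-gene counts are written to
`diagnostics.tsv`.

## Membership thresholding

An iModulon's gene weights are modeled as a normal background plus a few
outlier member genes. Membership is decided by iterative outlier removal
against the D'Agostino–Pearson omnibus statistic
K² = Z₁(skewness)² + Z₂(kurtosis)², implemented from the published
closed-form transforms (K² ~ χ²₂ under normality; at least 20 values and
nonzero variance required). The gene with the largest remaining |weight| is
removed one at a time — ties broken by gene order for determinism — and K²
recomputed; removal stops as soon as K² < 550. Removed genes are the
members, so member |weights| always dominate non-member |weights| exactly,
and the member set shrinks monotonically as the threshold rises. A column
already normal at the outset yields an empty member set flagged degenerate.

Two scale effects of K² are worth knowing. The statistic grows roughly
linearly with the number of genes, so the same threshold is more permissive
on small gene sets than at genome scale. And its two terms are not
symmetric in power: a *sign-balanced* set of outliers contributes only
through the kurtosis term Z₂, which saturates (cube-root transform) near
K² ≈ 375 for ~1% contamination of a 1,000-gene vector — below a threshold
of 550 — whereas sign-imbalanced outliers also drive the skewness term and
are detected easily. Modules whose members all move one way (the common
regulon case) therefore threshold crisply; perfectly symmetric mixed-sign
modules can be missed at fixed thresholds on small gene universes.

Regulon annotation uses the one-sided Fisher exact test (hypergeometric
upper tail) per regulator on the member × regulon contingency within the
gene universe, with Benjamini–Hochberg q-values across regulators. The
choice of test is a package decision; it is the conventional, auditable
option for set enrichment.

## Differential iModulon activity (DiMA)

The null model asks: how different do a component's activities look between
samples that are biologically identical? For each iModulon the absolute
activity differences over all within-replicate-group sample pairs are
collected and a log-normal is fitted by maximum likelihood to
log(|d| + ε), ε = 10⁻⁶ guarding exact zeros (ε and the pair count are
recorded in the fitted null). All-zero differences cannot calibrate a test
and raise. By default pairs are pooled from the whole provided compendium;
the pair scope is configurable.

A comparison of groups G₁, G₂ uses the absolute difference of group mean
activities as its observed statistic (a single-sample group is allowed —
its mean is that sample — with a logged warning, since ancestor-vs-evolved
comparisons often have n = 1 on one side). The p-value is the fitted
log-normal's survival at the observed statistic; q-values are BH across
iModulons; a call is significant iff q < 0.1 **and** |Δ| > 5 activity
units. Note the null describes single replicate pairs while the statistic
averages groups, so for multi-sample groups the test is conservative by
construction — appropriate for a screen whose hits are inspected
individually.

## Explained variance

For a subset S of iModulons and T of samples,
EV = 1 − ‖X_T − M_S·A_{S,T}‖²_F / ‖X_T‖²_F. Singleton EVs use the given
activities (each component's own contribution, which can be slightly
negative for a badly mismatched component; a clamped value can be
requested). Cumulative curves over the EV-ranked components instead
re-estimate activities per prefix (A_S = M_S⁺·X_T), i.e. they project X
onto the prefix's column span — this makes the cumulative sequence
nondecreasing, bounded by 1, and invariant to duplicated components even
though iModulons are not orthogonal. For mutually orthogonal equal-power
components both definitions coincide and each singleton carries exactly
1/k of the variance.

## Trendlines and phase planes

Phase-plane analysis scatters one iModulon's activity against another
across samples and fits a background trend to a chosen sample set
(`fit_mask`): ordinary least squares of y on x, or on ln(x − min(x) + 1)
for saturating relationships (the +1 shift makes the transform defined at
the fit minimum; the shift is stored with the fit). At least 3 fit points
and a non-constant abscissa are required. Samples are then scored by their
signed vertical residual y − ŷ(x) (above the line positive); by the normal
equations the fit set's residuals average to zero.

## Physiology

Growth rate is the slope of an ordinary least-squares fit of ln(OD600)
versus time over a user-chosen window (≥3 points, all OD > 0), reported
with R²; it is invariant to rescaling OD by a positive constant. The
exponential window is chosen by the analyst — no automatic changepoint
detection is attempted. Specific exchange rates are the best-fit slope of
metabolite concentration (mmol/L) against cell dry weight (gDW/L)
multiplied by the growth rate (1/h): consumption negative, production
positive, linear in the growth rate. The OD-to-dry-weight factor is an
instrument-specific config constant (default 0.4 gDW/L per OD unit).

## The synthetic generator

`generate_truth` plants k components in G genes: each column has exactly
m member genes of magnitude ≈ `member_weight` over a
Normal(0, `background_sigma`) background, renormalized to unit L2. Member
sets are disjoint by default (`overlap_fraction` shares a chosen fraction
of members with earlier components, since real iModulons overlap). Member
signs follow `positive_member_fraction` (default 1.0: single-direction
modules, the textbook regulon; the component as a whole then receives a
random global sign, so no code may assume orientation). As discussed under
membership, symmetric mixed-sign modules (fraction near 0.5) are partially
invisible to fixed K² thresholds at the ~1,000-gene scale; that is a
property of the statistic, and the generator lets you reproduce it.

`generate_activities` draws per-sample activities as per-condition offsets
plus Normal(0, `replicate_sigma`) replicate noise, with the reference
condition pinned at zero offset. `synthesize_compendium` forms
X = M·A + Normal(0, `noise_sigma`) elementwise. Identical seeds give
bit-identical output everywhere.

`generate_paired_activities` serves differential-activity studies: each
replicate group is a pair at center ± d/2 with |d| drawn exactly
LogNormal(μ = ln 2, σ = 0.3) — tight replicates whose activity differences
concentrate around 2 units with ~±35% log-spread — plus
Normal(0, 0.5) pair-baseline (batch-like) variation that, unlike the
antisymmetric pair noise, does not cancel in group means. The σ = 0.3
tightness is the regime in which a biologically modest shift of 3× the
null median is unambiguously detectable at the default thresholds; under
purely Gaussian replicate noise the log-magnitude spread is fixed at
π/(2√2) ≈ 1.11 and such a shift would sit near p ≈ 0.16 for any sample
size — a useful reminder that DiMA's resolution is set by replicate
quality, not replication depth.

What the generator does **not** emulate: library-size and compositional
effects upstream of log-TPM, gene–gene correlation in the background
(noise is i.i.d. normal — the marginal distribution of real log-TPM
residuals is unknown and heavier-tailed), heteroskedasticity across
expression levels, and batch structure beyond the pair-baseline term.
Passing tests on synthetic data therefore demonstrate correctness of the
algorithms under the stated model, not performance guarantees on real
compendia.

## Problem sizes and reproducibility

The reference recovery study used in tests and in `scripts/acceptance.py`
is 1,000 genes × 150 samples (75 conditions × 2 replicates), 8 planted
components of 15 members at member/background weight ratio 20, expression
noise at 25% of the signal scale, decomposed with 20 ICA runs over
candidate dimensionalities {4, 6, 8, 10, 12} — small enough to run in
seconds yet large enough that every stage (whitening, consensus,
dimensionality scan, K² thresholding, DiMA) operates away from its
degenerate corners. The full pipeline is a pure function of (inputs,
config): every stochastic stage derives its seed from the config, the
manifest records config, seeds and artifact checksums, parallel ICA
execution is bit-identical to serial, and all TSVs are written at fixed
6-significant-digit precision so reruns diff clean.

## Known limitations

- ICA identifiability rests on non-Gaussian gene-weight structure; the
  activity profiles themselves may be Gaussian (they are, in the
  generator) without harming recovery, but components whose gene weights
  are near-normal cannot be separated.
- The K² membership threshold (550) is calibrated to genome-scale weight
  vectors; on much smaller universes it is conservative (see above).
- The DiMA null pools replicate pairs regardless of condition; strong
  condition-dependent replicate variability would miscalibrate it.
- QC clustering assumes one dominant sample cluster; a compendium that is
  half-and-half two deep batches will flag the smaller half.
- Enrichment treats regulons as flat gene sets; no effect direction or
  regulator hierarchy is used.
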