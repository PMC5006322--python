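# Methods

## The atlas design and what the generator emulates

The default study design is a rat body atlas: 23 tissues from 14 organs
(brain contributes cerebrum, cerebellum, hippocampus and brainstem;
kidney three tissues; intestine three; muscle and stomach two each; nine
organs one each), sampled in 5 male and 5 female animals. Testis is
male-only and ovary/uterus female-only, so the full panel is 215
samples. The tissue→organ map beyond the brain grouping is a
reconstruction — it is the unique natural grouping giving 23 tissues and
14 organs from this tissue list — and is user-overridable everywhere it
is consumed (YAML config or an explicit dict).

`miratlas.synthetic` draws counts from the same two-component model the
classifiers assume: a miRNA's count in (animal, tissue) is
Poisson(λ_high·s) in its enriched tissues and Poisson(λ_low·s) elsewhere,
with s a per-sample depth factor. Defaults are λ_high = 500, λ_low = 1 —
a strong planted signal (ratio 500) representative of genuinely
tissue-restricted miRNAs, with a background low enough that the
raw-count > 1 expression rule is meaningful. Sex-specific patterns emit
exact zeros in the opposite sex inside their tissue, mirroring a truly
silent locus. An `overdispersion` knob gamma-mixes the rate
(variance = μ + φμ²) for quasi-Poisson power studies, because the
one-vs-rest test presumes overdispersion exists even though the
generator's default is pure Poisson.

What the generator does **not** emulate: sequencing-error substitutions,
ligase/adapter bias (a known quantitative distortion of small-RNA
libraries), inter-animal biological variance beyond Poisson, and batch
structure. Passing tests therefore demonstrate correctness of the
*computations* under the stated model, not robustness of the biology to
those artifacts.

Planted "enriched" miRNAs occupy 2–4 tissues **within a single
multi-tissue organ**. This is deliberate: the three institutional
definitions of enrichment only describe the same object when the signal
is concentrated in one tissue group — a miRNA spread evenly over three
tissues of different organs carries ~33 % of reads per tissue and is
invisible to the read-share rule at its 50 % cut, while still being
trivially enriched to the quorum rule and the one-vs-rest test.

## Read processing

Trimming truncates a read at the first perfect occurrence of the
adapter's prefix (8 bases by default; the shipped `lilly` profile uses a
10-base probe, minimum 17 nt and drop-N; `maastricht` 16–35 nt;
`niehs` 14–24 nt). Reads with no adapter occurrence are kept when inside
the length window — the trimmer cannot prove adapter read-through — with
a strict mode to discard them. Quality cutoffs are configuration only
and a no-op on FASTA input. Every discard is itemized by reason so
read-count conservation is auditable at each stage.

Mapping is exact substring search (no mismatches or gaps), reporting all
occurrences over all precursors with 1-based inclusive coordinates; U is
normalized to T on input. The mature-association rule is the one place
the naming semantics needed operationalizing: a locus is associated with
an annotated mature arm when its start is within ±3 nt of the window
start **and** it covers ≥ 75 % of the window. This matches typical
isomiR end-variation tolerance and is configurable
(`start_tol`, `min_overlap`). The arm of a hairpin-only ("-pre") hit is
assigned by the hairpin midpoint. Composite names are the
lexicographically sorted, deduplicated union of per-locus identities, so
they are invariant to precursor input order. Multi-locus division
assigns count/n_loci to each locus; sums restore the original integers
exactly (fractions are kept as floats).

## Normalization conventions

**TMM.** M-values are per-gene log2 ratios of raw counts
sample/reference and A-values their log2 geometric-mean relative
abundance; genes zero in either sample are excluded; the extreme 30 % of
M and 5 % of A are trimmed from both tails; the factor is the
precision-weighted (delta-method) mean of the surviving M. Because M is
computed on raw counts, the reported factor captures depth *and*
composition relative to the reference — a library scaled by c gets
factor c — and normalized counts (count/factor) stay on the reference's
count scale, which is what the "≥ 10 normalized reads in ≥ 1 sample"
retention filter expects. Scale-consistency holds exactly up to the
precision weights (which depend on library depth); the package tests it
at 1 %.

**TPM.** Zeros are imputed at 1.0 before scaling, columns scaled to 1e6,
values ceiled to integers for count models downstream. Without
imputation and ceiling, columns sum to exactly 1e6.

All percentile computations (Q3 offsets, TMM trims) use linear
interpolation (NumPy default, R type 7).

## The three classifiers

**Animal-quorum rule.** Expressed = raw count > 1 in ≥ ⌈0.8·n⌉ animals
(8/10 mixed-sex; proportionally 4/5 for the 5-animal single-sex
tissues). Exactly one expressed tissue ⇒ specific; 2–5 ⇒ enriched (the
upper bound is deliberately loose and configurable); the sex rule (≥ 4/5
of one sex, 0/5 of the other, in exactly one mixed-sex tissue, nothing
expressed by the plain rule) ⇒ sex-specific. Precedence: specific >
sex_specific > enriched. Classification runs on raw counts by default; a
normalized matrix can be substituted. Known behavior worth stating: at
background λ_low = 1 the 4-of-5 quorum on a 5-animal tissue fires by
chance for ≈ 2 % of null miRNAs per tissue, so the *specific* and
*sex-specific* call sets carry a visible false-positive floor on noisy
toy data. The *enriched* set (≥ 2 tissues must fire jointly) does not.

**NMF + Poisson mixture.** The organ-level matrix (max over member
tissues of the animal-summed counts) is factorized by multiplicative-
update NMF minimizing generalized KL divergence — the natural objective
for counts — at rank k = 14 (one factor per organ), 10 seeded random
restarts keeping the best objective, convergence at relative objective
change < 1e-6 or 500 iterations. The objective trace is exposed and
non-increasing by construction. A miRNA joins the factor maximizing its
W row; a factor nominates its H-argmax organ only when that organ holds
> 50 % of the factor's H mass. Candidates are refined by a two-component
Poisson mixture (EM, tolerance 1e-8, ≤ 1000 iterations) over the
candidate's 215 animal-level counts: a tissue is "high" when a majority
of its animals have posterior(high) ≥ 0.5; one high tissue ⇒ specific,
2–5 ⇒ enriched. Degenerate data collapse to one component when BIC
prefers it (penalty 3 log n vs log n), and collapsed candidates are not
called — this is what keeps flat-background miRNAs out of the call set.

**Read-share percentage.** share = 100·tissue/total per miRNA; > 90 %
⇒ specific, > 50 % ⇒ enriched; zero-total miRNAs are flagged, not called.
With an organ map the shares are evaluated per tissue group and calls
carry the group's member tissues — the mode used for cross-method
comparisons, for the reason given above.

**One-vs-rest quasi-Poisson (DEMiR).** For each (miRNA, tissue): counts
follow a log-link Poisson model with intercept + tissue indicator and a
per-sample offset log(Q3 of that sample's counts) (fallback: mean count
when Q3 = 0). A two-group log-link Poisson GLM with offsets has a
closed-form MLE — each group's rate is its count total over its summed
exposure — so the fit is exact and vectorized across miRNAs (an
independent statsmodels IRLS fit reproduces it to 1e-8 in the tests).
Per-miRNA Pearson dispersion (df = n−2) is shrunk toward the 10 %-trimmed
mean across miRNAs with prior weight d0 = 10:
φ̃ = (d0·φ̄ + df·φ)/(d0 + df). The test is the quasi-likelihood F test on
the deviance drop of the tissue term, F = Δdev/φ̃ against F(1, df + d0).
The deviance form was chosen over a Wald square because the Wald
statistic is anti-conservative in the far tail at low counts (its
claimed p can run ~4× below the exact Poisson tail at λ = 1), which
matters when the significant set feeds a set-level comparison.
Significance is a *nominal* p < 0.01 by default — the screening
convention — with a Benjamini–Hochberg mode available. For planted-truth
set comparisons the BH mode is the right tool: at a calibrated per-test
1 % level, 23 nominal tests per miRNA give every null miRNA a ≈ 20 %
familywise chance of entering the enriched set, so set-level precision
is only meaningful with multiplicity control.

Measured behavior (recomputed by `scripts/acceptance.py`): type-I
fraction ≈ 0.010 at nominal 0.01 on 2000 null miRNAs × 14 tissues;
power 1.0 for 10-fold enrichment at λ = 20 with 10 animals/tissue.

## Serum qPCR analysis

**QC.** A Ct is accepted iff it lies ≥ 10 cycles (configurable) below
every *detected* negative control (NTC, each no-RT replicate); undetected
controls impose no bound; multi-peak melt curves reject the assay; an
undetected target is rejected as non-amplifying.

**Fold changes.** ΔCt = Ct_target − Ct_spike per (animal, timepoint);
ΔΔCt subtracts the mean reference ΔCt (vehicle group at matched time, or
the earliest timepoint pooled over groups in pre-dose mode);
FC = 2^(−ΔΔCt). The computation is exactly invariant to any per-sample
constant added to both Ct values, and observations lacking a spike-in
well are excluded and counted, not imputed. Undetected Cts are excluded
throughout (never imputed at 40).

**Repeated-measures ANOVA.** log2 fold changes are fit to group × time
cell means by generalized least squares with an AR(1) within-animal
working correlation (compound symmetry available). ρ is a lag-1 moment
estimate from OLS residuals using matched-pair denominators — the naive
ACF's (T−1)/T attenuation is material at T = 5 — then the data are
whitened per animal (innovations transform, time-ordered) and refit.
AR(1) is indexed by measurement order, not clock hours. Each
non-reference cell is reported as a *contrast* against its reference
cell with a t-based 95 % CI (df = N − p); the reference cell itself is
fixed at FC = 1 with no interval. The contrast formulation is essential:
it cancels the shared ΔΔCt normalizer exactly, whereas an interval on
the cell mean alone would ignore reference-estimate noise and
undercover. Simulated coverage at the study's scale (2 groups, 5
timepoints, 6 animals, σ = 0.5) is 0.94–0.95 across ρ ∈ {0, 0.5, 0.9}.

**Validation correlation.** Ct is correlated with log10(count+1) across
tissues (Pearson, with Spearman co-reported so the transform choice is
auditable); a perfect qPCR/sequencing agreement is −1. Fewer than three
accepted pairs, or a constant series, is reported undefined.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and acceptance script are the
package's verification scale: 200 observations per mixture fit (5
replicate fits when estimating recovery error), 2000 null + 500 planted
miRNAs for DEMiR calibration, a 300-miRNA atlas with 30 planted enriched
miRNAs for the cross-method comparison, and 500 (tests) / 200
(acceptance script) replicates per ρ for interval coverage. EM tolerance
1e-8; NMF tolerance 1e-6 with ε = 1e-12 floors in the multiplicative
updates; zero group totals in DEMiR get a 0.5 continuity floor and a
flag; ties in the mixture are broken by BIC collapse.

## Known limitations

- Exact matching only: a single sequencing error unmaps a read; the
  upstream error rate must be handled by trimming/quality profiles.
- The "-pre" class is not sub-classified (offset RNAs, incompletely
  processed sequence and unannotated arms all land in it).
- The quorum rule's specific/sex-specific labels are noisy at very low
  background (documented above); its enriched label is robust.
- The NMF route reports candidates and refined calls; any manual
  curation step between them is out of scope.
- GLS assumes a common σ and ρ across groups and animals; heavily
  unbalanced or missing-cell designs are rejected rather than patched.
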