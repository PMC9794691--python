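# Methods

This note documents the models, defaults, and numerical choices behind
`persisterlab`, and what the synthetic data can and cannot show.

## Growth model and screen simulator

Each well holds two pools: sensitive cells S and persisters P, with total
confluence N = S + P capped at carrying capacity K (percent confluence).

* Vehicle (DMSO): logistic growth of both pools at rate `r`.
* Under osimertinib: dS/dt = −d·S (first-order kill), dP/dt =
  r_p·P·(1 − N/K) (slow persister expansion).
* Test compound: kills the persister pool at rate `e_drug·d` whenever it
  is present (arm A alone, arm C during co-dose, arm D after crossover).
  `e_drug` is the planted effect size; `e_drug = 0` reproduces the
  osimertinib-only trajectory exactly.
* Washout: arms A–C lose drug at `washout_day`; after a regrowth lag
  (`lag` hours, during which the pools hold) both pools grow at `r`.
  Arm D crosses over at `dtp_day` (osimertinib off, test compound on);
  its persisters likewise revert to growth at `r` after the lag, which is
  what makes an inert sequential compound regrow *earlier* than the
  osimertinib control and prevents trivial sequential hits.

Observed confluence is N·exp(ε), ε ~ N(0, σ²), clipped to [0, K].

Defaults (exposed in `SimParams`/`RegimenSpec`): r = 0.03 h⁻¹,
r_p = 0.002 h⁻¹, K = 100, c0 = 10, persister fraction f = 0.05,
d = 0.05 h⁻¹, lag = 24 h, σ = 0.03, sampling every 6 h, horizon 35 days,
DTP day 14, washout day 24. These put the osimertinib arm at a persister
plateau of 1–2 % confluence around the DTP stage and full regrowth within
the horizon. The 6 h sampling interval is a conventional live-imaging
cadence, not an inferred value. Media-change dips are not modelled; they
would perturb the AUC only marginally and no magnitudes are available.

Integration is fixed-step RK4 with 5 substeps per sampling interval —
fixed-step for bit reproducibility, substepped so the noise-free DMSO
trace matches the closed-form logistic solution to 1e-6. Child well seeds
are derived from the master seed via `numpy.random.SeedSequence` spawn
keys (deterministic, collision-free, < 2³¹).

The default panel plants 5 strong persister killers (e_drug ~ U(2, 4))
among 15 decoys (e_drug ~ U(0, 0.02)). The decoy ceiling is deliberately
below r_p/d: a compound whose kill rate on persisters exceeds their net
growth rate for the whole co-dose window eliminates regrowth entirely, so
"weakly active" decoys would be genuine hits by the assay's own logic,
not false positives. The ground-truth label threshold is e_drug ≥ 0.5.

## Screen scoring

AUC is the trapezoidal integral of percent confluence over the full
observed window, no baseline subtraction, units percent·hours. The
assay's thresholds (upfront > 10,000; sequential > 7,500; activity > 2×
monotherapy; common hit in ≥ 3 models) are configuration with those
defaults. Replicates are summarised by the median AUC (mean of the
central pair when even). Endpoint significance (replicate combination
AUCs vs osimertinib control) is available via `study_stats.endpoint_test`
(Welch two-sided t).

## Count simulation

RNA counts are negative binomial with variance μ + φμ² (φ = 0 degenerates
to Poisson), mean = baseline × cell-line offset × 2^lfc × size factor.
Baselines are lognormal (log-mean 5, log-sd 1.2 — detected-gene coverage
of order 10²–10³ counts); per-(gene, line) offsets are lognormal with
log-sd 1.0 so that cell line dominates overall expression variance, as it
does in real cell-line panels; size factors are lognormal(0, 0.1) to
exercise normalisation. Four temporal archetypes (down-acute-recovering,
up-acute-transient, up-in-DTP-persisting, down-in-DTP-persisting) define
the planted per-treatment log2 fold changes; a `concordant` subset of the
DTP-responsive genes is earmarked for same-direction chromatin effects.

ATAC peaks: true summits shared across samples with N(0, 20 bp) per-sample
summit jitter, MACS2-like scores increasing with abundance, a 97 % call
rate for covered peaks, and NB counts with the planted DTP effect (80 %
of it retained in short washout, mirroring persistent chromatin change).
Gained/lost peaks are placed within 5 kb of their linked concordant
gene's TSS so the nearest-TSS annotation recovers the intended link at
synthetic gene densities.

## Differential model

Per-feature OLS on log₂ CPM under `~0 + treatment + cell_line` (one
indicator per treatment; line offsets relative to the first line). For
model fits the library size is the composition-robust effective size
(median-of-ratios over features positive everywhere, scaled to geometric
mean 1); plain library-size CPM (prior count 0.5, doubled in the
denominator) is used for the peak abundance filter, where the published
rule is defined on raw CPM. Without the robust correction, planting a
one-sided block of two-fold changes inflates treated libraries by ~20 %
and biases fold-change estimates down by ~0.2–0.3 log₂ units.

Moderation follows the standard empirical-Bayes scheme: the prior
variance s²₀ and prior degrees of freedom d₀ are fitted by method of
moments on log residual variances (digamma/trigamma matching, trigamma
inverse by Newton iteration); posteriors are the precision-weighted blend
above; t and F statistics use d_res + d₀ degrees of freedom (normal/χ²
limits when d₀ = ∞). `d_prior` can be forced to 0 or ∞, which reproduces
the ordinary-t and pooled-z limits exactly and is verified to 1e-10 in
tests. Precision weights (voom-style mean-variance weighting) are *not*
implemented: at the simulated depths and dispersions the moderated fit on
log-CPM recovers planted effects well within tolerance, and the weighting
would obscure the closed-form limit checks.

BH adjustment is the step-up procedure with enforced monotonicity, capped
at 1, order-preserving (cross-checked against statsmodels). K-means
clustering of per-line Z-scores uses scikit-learn (k-means++, 25
restarts, fixed seed, clusters relabelled by descending size); features
within a cluster are displayed in complete-linkage Euclidean dendrogram
leaf order. Whether clustering should run on all samples or group means
is exposed as `average_replicates` without asserting either convention.

Signature scores are the per-sample mean of feature Z-scores over the
set (primary), with a rank-based alternative (mean set rank minus its
expectation, scaled to [−1, 1]); both are labelled in output. These are
deliberately simple single-sample statistics, not a KS-kernel GSVA.

## Consensus peaks and annotation

Summits are expanded to summit ± 250 bp; windows are retained greedily in
descending score order, discarding any window overlapping a retained one;
score ties break leftmost (chrom, then start) for determinism. The
procedure is idempotent and matches a naive O(n²) re-implementation on
1,000 random fixtures. Windows are clipped at chromosome ends but still
treated as nominal 500 bp. A sample "calls" a consensus peak when any of
its windows overlaps it.

Peak filtering keeps peaks with (max over groups of group-mean log₂ CPM)
≥ 2 *and* full-replicate calls in ≥ 1 group. Annotation assigns the
nearest TSS by distance from peak center, only within 100 kb; feature
classes are promoter (TSS ± 2 kb — a conventional window, configurable),
gene body (within a gene's extent), else distal intergenic. Signed
distances flip for minus-strand genes so positive is downstream.
Regulatory-element deltas report, per element class (PLS/pELS/dELS),
percent of peaks overlapping ≥ 1 element, minus the same percentage in
the all-peaks reference.

## Motifs

PFMs are normalised with pseudocount 1e-3 and scored as log₂-odds against
the background base composition at every offset on both strands; N bases
contribute 0 bits. Enrichment treats a peak as a hit at ≥ 1 occurrence
above threshold and tests gained vs background peaks with the one-sided
hypergeometric upper tail, BH-adjusted across motifs (enrichment only —
depletion is not scored, matching the gained-peak framing). Random test
motifs peak one base per column (Dirichlet, sharpness 25) with threshold
at 75 % of their own maximum score, giving low but nonzero background hit
rates.

## Meta-analysis, concordance, merged enrichment

Cross-line intersection anchors on the first line's intervals and
requires a reciprocal overlap of ≥ 50 % of both window widths in every
other line (best-overlap match when several qualify). Records are
summarised by the arithmetic mean log2 fold change and Fisher's method on
the per-line **adjusted** p-values — combining adjusted values is
conservative relative to combining raw p-values and is the deliberate
primary behaviour here, matching how such meta-tables are usually
reported; the function accepts raw p-values unchanged if callers prefer.
Inconsistent-direction records are retained but flagged.

Concordance classes (concordant up/down, discordant, RNA-only,
ATAC-only, not significant) partition the RNA gene list. A gene's ATAC
effect is the mean log2 fold change of its significant linked peaks
(`strongest` peak available as an alternative; the two differ only for
multi-peak genes). Cutoffs default to FDR < 0.005 and ≥ 2-fold.

Merged enrichment filters both assays at ≥ 2-fold and adjusted p < 0.005,
takes the union of passing genes (ATAC via peak→gene links), and tests
each gene set with the hypergeometric upper tail against the RNA-tested
universe. This is a single merged-list test; staged multi-omics p-value
merging (Brown's method with ranking refinement) is out of scope and the
per-gene evidence labels (rna/atac/both) are reported instead.

## Causal regulators

One network level only: regulator R under hypothesis h predicts direction
h·s for each signed edge (R→g, s). Among signature genes, matches and
mismatches are counted; both hypotheses are scored (they exactly swap the
counts). The analytic p is the binomial upper tail of the match count at
the signature's background match probability (the signature's up-fraction,
per edge sign, averaged over the regulator's observed edges) — a
documented stand-in for proprietary causal-reasoning scores, labelled as
such. The permutation p reassigns observed directions over signature
genes: exhaustive enumeration of direction assignments when a regulator
has ≤ 12 observed targets (each target up with the signature's
up-fraction), Monte Carlo with the +1/(B+1) floor otherwise. Both-sign
duplicate edges are ambiguous and excluded with a warning. Ties rank by
analytic then permutation p, then identifier.

In the network generator, a planted target disagreeing with the expected
direction keeps a *random* direction rather than the opposite one — a
concordance of 0.7 therefore yields a ~0.85 per-target match rate, which
is what partial regulation of an otherwise noisy signature looks like.

## Figure-level statistics

Tumor volume is π/6 × width² × length (smaller measurement taken as
width). Nuclear fraction is 100·nuclear/(nuclear+cytoplasmic), zero-total
cells dropped with a warning. The localization comparison defaults to the
unpaired two-sided Wilcoxon rank-sum test — the paired signed-rank
variant is available behind a flag, but per-cell measurements from
independently imaged wells are structurally unpaired, so the unpaired
test is primary. Endpoint comparisons use Welch's t (unequal variances)
rather than the pooled test, as replicate variances under different drug
regimens have no reason to agree.

## Problem sizes and determinism

Default synthetic studies are desk-scale: 20-compound × 3-line × 3-replicate
screens, 2-chromosome 4 Mb genomes with 200 genes, 500 true peaks,
2,000-feature calibration matrices, 20-regulator networks. Every
generator and every CLI stage is deterministic given its seed; TSV floats
are written at fixed precision so reruns are byte-identical.

## Limitations

The simulators emulate the *structure* of the real inputs, not their
biology: no pharmacokinetics, resistance mutations, single-cell
stochasticity, fragment-level ATAC artefacts, read-level data, or real
motif databases. Passing planted-truth recovery therefore demonstrates
that the statistical machinery is correct and calibrated, not that the
thresholds are optimal for any particular dataset. The analytic causal
p-value and the mean-Z signature score are simple documented statistics,
not re-implementations of proprietary or kernel-based originals, and no
claim is made of reproducing any published p-values that depend on
deposited data or curated knowledgebases.
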