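# Methods

## Problem and model

`epivar` screens methylation-array beta-values for *rare, individual-specific*
methylation defects: events present in one (or a few) case samples and
essentially absent from controls. Group-wise case–control contrasts have no
power for such events; instead each case sample is tested on its own against a
matched control group, probe by probe.

At probe $g$ with control values $x_{g1},\dots,x_{gn}$ and case value $y_g$,
the statistic is a moderated one-versus-group t:

$$ t_g = \frac{y_g - \bar{x}_g}{\tilde{s}_g\sqrt{1 + 1/n}},\qquad
   \tilde{s}_g^2 = \frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},\qquad d_g = n-1 $$

where $(d_0, s_0^2)$ is an empirical-Bayes prior over per-probe variances,
estimated once from the control group by moment-matching the log variances to
a scaled-F distribution: under $s_g^2 \sim s_0^2 F(d_g, d_0)$,
$\operatorname{Var}[\log s_g^2] = \psi_1(d_g/2) + \psi_1(d_0/2)$ plus a known
mean shift, so the excess spread of the observed log variances determines
$d_0$ through a trigamma inversion (Newton iteration). Two-sided p-values use
$d_0 + d_g$ degrees of freedom ($d_0=\infty$ degenerates to a normal tail,
$d_0=0$ to the ordinary t-test). The moderation matters because $n=10$
controls estimate each probe variance with only 9 df; borrowing strength
across ~10^4–10^5 probes stabilises the denominator exactly where outlier
calling needs it.

A retained differentially methylated CpG (DMCpG) call must clear, in order:

1. **q < 0.01** — Benjamini–Hochberg step-up within the sample's probe set;
2. **|Δβ| ≥ 0.18** — effect size versus the control mean (0.15 in the optional
   second pass against an extended control set);
3. **status change** — the call must cross a methylation-status bin
   (hypo: β < 0.3, hyper: β > 0.7, intermediate: the closed interval
   [0.3, 0.7]);
4. **no altered control** — no matched-control sample shows the same
   delta-and-status event against the leave-one-out mean of the others;
5. **panel frequency ≤ 0.005** — the same directional event must be rare in a
   large reference panel (e.g. 757 samples), screening out common epigenetic
   polymorphisms.

Every filter only removes candidates, never adds; the per-filter flags of all
q-significant candidates are kept so the funnel is auditable.

## Regions

Two region detectors. **Strict DMRs** cluster a sample's retained calls:
maximal same-chromosome runs of ≥ 2 calls with consecutive gaps ≤ 1 kb
(`max_gap_bp`, configurable; promoter CpG clusters have ~50–150 bp spacing,
so 1 kb comfortably joins a cluster without bridging unrelated loci).
**comb-p-style scan** for subtler signal: per-probe p-values are converted to
z-scores, their autocorrelation is estimated in 50 bp distance bins up to the
window width, each probe's p is smoothed by a correlation-adjusted
Stouffer–Liptak combination over its ± 1 kb neighbourhood, regions are seeded
and extended where smoothed p < 0.01, each region's raw p-values are combined
(again Stouffer–Liptak with the distance-binned correlations), and the region
p is Šidák-corrected for the number of independent windows of that size in the
scanned span. The Stouffer–Liptak combination is

$$ z_c = \frac{\sum_i w_i z_i}{\sqrt{w^\top \Sigma w}},\qquad
   z_i = \Phi^{-1}(1-p_i), $$

which reduces to classic Stouffer for $\Sigma = I$ and returns the common p
under perfect correlation. Negative estimated correlations are clipped to 0
before use (a negative off-diagonal can make $w^\top\Sigma w$ collapse and
manufacture significance from noise); if the quadratic form is still
non-positive, a 0.05 diagonal jitter is applied. p-values are truncated to
$[10^{-15}, 1-10^{-15}]$ before the normal quantile.

## Classification, expression, association

A retained call with a catalogued variant on the CG dinucleotide (offset 0 or
1 from the cytosine) at MAF < 0.005 is a known meSNP; a call inside a DMR with
no underlying variant defaults to epimutation; everything else is a meSNV
candidate awaiting sequencing. A CG variant with MAF ≥ 0.005 contradicts the
upstream QC (which removes probes with common SNPs within ±5 nt) and raises a
consistency warning rather than silently classifying.

Cis-expression integration scores, for each call, every gene whose annotated
span intersects ±50 kb of the CpG and that is expressed (nonzero in ≥ 50% of
cohort samples): $z = (x - \bar{x})/s$ over the expression cohort, with the
calling sample included in the moments (with a cohort of ~29 the inclusion
bias is small; a leave-one-out mode is a flag). A locus is altered when one
gene has |z| > 2, or ≥ 2 genes in the same window each have |z| > 1.5. The
altered-locus fraction is reported under both defensible denominators (loci
with ≥ 1 expressed cis gene, and all tested calls).

Association uses the 2×2 allele table per variant: two-sided Fisher exact
p-value under the minimum-likelihood definition (the definition R's
`fisher.test` uses — other two-sided conventions, e.g. tail doubling, give
different numbers), the unconditional sample OR $ad/bc$ (the conditional MLE
is emitted in a secondary column), and a conditional exact CI obtained by
inverting the Fisher noncentral hypergeometric tails at α/2. Zero cells yield
0/∞ OR endpoints, or a Haldane +0.5 correction on request. Allele counts can
be reconstructed from printed cohort sizes and MAFs by nearest-integer
rounding (ties up) of MAF·2n — this reproduces the published odds ratios of
four genotyped loci (USP24 3.64, DBT 6.07, METTL21C 3.56, PDE10A 6.11) at two
decimals. FDR control is BH by default; Storey q-values (λ-grid π₀ with a
cubic smoother evaluated at λ = 0.95, q = π₀·BH) by flag. The gene-burden
comparison is the same exact test on carrier counts per cohort.

## Synthetic-data generator

The generator emulates the statistical structure the screen assumes, not the
array chemistry. Per-probe control betas are Beta-distributed in three
archetypes:

| archetype    | mean β | concentration | cross-sample sd |
|--------------|--------|---------------|-----------------|
| hypo         | 0.10   | 300           | ~0.017          |
| intermediate | 0.50   | 40            | ~0.078          |
| hyper        | 0.85   | 300           | ~0.021          |

The concentrations encode a deliberate, realistic feature of 450K data:
probes at the extremes are tight (sd ≈ 0.02 across individuals) while
intermediate probes are noisy. That tightness is what makes per-individual
outlier calling feasible at all — a Δβ ≈ 0.4 event against 10 controls is a
|t| in the teens at sd 0.02, but only ~7 at sd 0.05, which cannot clear a
per-sample BH(0.01) threshold over 10^4 probes. The defaults also keep
unspiked probes essentially inside their status bin. All archetype parameters
are exposed in `StudyConfig`.

Spiked signals, each recorded in a `TruthRecord` (with original values, so
spikes revert exactly):

* **meSNV (het)** — measured β modelled as the mean of two allele betas with
  the mutant allele at the array background (0.05): a het on a hyper probe
  lands near (0.9 + 0.05)/2 ≈ 0.47, i.e. the intermediate 0.3–0.6 band; a
  homozygote reads < 0.15. Noise is Beta around the shifted mean with the
  probe's concentration.
* **clustered epimutation** — a run of ≥ 2 consecutive probes shifted by a
  signed delta (default +0.30 over 13 tightly spaced probes in one sample),
  clipped to [0,1]; a mean clipped to the boundary stays exactly there.
* **expression effects** — log-normal per-gene baselines with per-sample CV
  0.2; carriers multiplied by $2^{\mathrm{lfc}}$ (default lfc = 2).
* **allele counts** — Binomial(2n, MAF) per cohort.

The default study is 29 cases + 10 matched controls + a 757-sample panel over
10,000 probes on 4 chromosomes (inter-probe gaps uniform in 200–2000 bp, the
epimutation cluster at 100 bp spacing), 20 het meSNVs on hypermethylated
probes spread over 8 carrier samples, one 13-probe cluster, and three
rare-variant allele tables at MAFs of the order seen in genotyped loci. The
panel shares the per-probe archetype assignment with the cohort matrix —
otherwise the panel-frequency filter would compare a probe against a
different probe population. Spiked probes are kept apart (≥ 10 index steps,
hence > 1 kb) so meSNVs never cluster into spurious regions, and
detection-failure/cross-reactive/SNP flags are placed off the spiked probes
so QC measures the flags, not the spikes.

**Not emulated:** raw IDAT intensities, bisulfite-conversion efficiency,
chip/batch effects, age-related drift, probe-type (I/II) chemistry, genomic
correlation of methylation beyond the spiked clusters, and linkage between
the SNP catalogue and the beta values (the catalogue is planted to match a
chosen fraction of spikes). Passing recovery tests therefore demonstrate the
*pipeline logic* — filter semantics, thresholds, bookkeeping — under the
stated noise model, not robustness to real-array artefacts.

## Numerical choices and degenerate inputs

* Status bins: boundaries 0.3 and 0.7 belong to *intermediate* (closed
  interval), so 0.30 and 0.70 are not status changes.
* All QC thresholds are strict inequalities (> 0.01, > 5%, > 0.005); a probe
  is attributed to the first rule that removes it (detection →
  cross-reactive → SNP), making the funnel counts additive.
* BH ties are handled by the standard step-up on a stable sort (via
  statsmodels).
* `fit_ebayes_prior`: all-zero variances raise; exactly equal variances give
  $d_0 = \infty$ with $s_0^2$ the common value (the zero-spread limit);
  otherwise non-positive excess spread gives $d_0=\infty$ with the log-scale
  bias-corrected $s_0^2 = e^{\bar e}$.
* Zero expression variance makes the Z-score undefined: the gene is skipped
  with a log entry rather than propagating an infinity.
* Interval conventions: internal and BED output are 0-based half-open; the
  DMR TSV is 1-based inclusive and its column names say so; probe positions
  are 1-based C coordinates and the CpG occupies (pos, pos+1).
* Monte-Carlo scales were chosen to keep the default suite and the
  reproduction script compact: recovery properties use 20 seeds of the
  10,000-probe default study (3 seeds at reduced scale in unit tests), the
  exact-test equivalence suite enumerates all tables with total ≤ 20 plus 600
  random tables with total ≤ 60, and prior-recovery simulations use 10^4
  probes.

## Known limitations

* The one-versus-group contrast assumes the matched controls are exchangeable
  with the case apart from the tested defect; batch or age structure would
  inflate calls (the real analysis mitigated this with a wide-age panel, which
  the panel-frequency filter represents here).
* The second-pass (extended-control, |Δβ| ≥ 0.15) path is implemented but the
  default synthetic study does not exercise it; which cohort the relaxed
  threshold applied to is a documented reading, configurable.
* "Altered in a control" has no published operational definition; the
  symmetric leave-one-out rule used here is one defensible choice.
* The comb-p-style scan implements seed–extend–combine–Šidák only; peak
  trimming and annotation stages of the original tool are out of scope.
* Beta-values are treated as given (normalisation, IDAT processing and
  RNA-seq quantification are upstream of this package).
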