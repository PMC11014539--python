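# Methods

This note records the models implemented in `apobec_smoke`, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests do
and do not establish about real data.

## Context annotation and motif counting

Every SNV is annotated with a 5-base reference window centered on the mutated
base, reverse-complemented into the pyrimidine frame whenever the reference
base is a purine (the universal strand convention of SBS signature analysis,
so `pyr_ref` is always C or T). Coordinates are 1-based at file interfaces
(VCF/MAF) and 0-based half-open internally. Windows containing N are kept but
flagged and excluded from all motif statistics; `genome_length` likewise
excludes N bases.

Motif inventories (C, TCW, TCA, YTCA, RTCA) are counted on both strands: a
motif counts once per strand on which it matches, so a sequence and its
reverse complement give identical counts. One deliberate edge rule: a TCA
occurrence whose 5' flanking base is absent (contig edge) or N contributes to
`n_TCA` but to neither YTCA nor RTCA, so `n_YTCA + n_RTCA ≤ n_TCA` with
equality everywhere away from contig edges — at genome scale the difference
is at most one count per contig end.

Two denominator scopes are exposed: whole-genome (default in the pipeline
driver) and merged ±20-base windows around mutated cytosines (the windowed
convention of motif-enrichment tooling; half-width configurable, recorded in
output metadata). Overlapping windows are merged before counting so no base
is counted twice.

Following the standard IUPAC codes, Y = C/T and R = A/G throughout: YTCA
excess is read as A3A-like, RTCA excess as A3B-like.

## Enrichment and the minimum load

`E_TCW = (mut_TCW/ctx_TCW)/(mut_C/ctx_C)`, defined as 0 for empty catalogs.
Only pyrimidine-frame C>T and C>G substitutions count as APOBEC-type (the
SBS2+SBS13 chemistry); C>A is excluded, which keeps the smoking-dominated
background out of the numerator and denominator alike. The Fisher test is
one-sided (greater) because the screen is for enrichment only; depletion has
no biological reading here. BH correction runs across the cohort with
Q < 0.05 by default. The minimum load `mut_TCW·(E−1)/E` subtracts the number
of TCW mutations expected if mutations fell on cytosines at random — it is a
lower bound on the APOBEC burden by construction, which the simulation tests
confirm (median load/truth ratio ≈ 0.8 under the default genome's
TCW-fraction of cytosines). The load is reported raw and half-even rounded.

## Clusters, kataegis, scssDNA

Candidate clusters are maximal same-chromosome runs with inter-mutation gaps
≤ 1000 bp (`d_max`); the binding criterion is the P-value, the gap threshold
only bounds the search. Members < 10 bp apart are collapsed into one event
(complex events from a single lesion), keeping the first coordinate. The
cluster P-value is the negative-binomial tail `Pr(NB(k−1, π) ≤ span)` under a
uniform per-base rate π = SNVs / non-N genome length; clusters are retained
at P ≤ 10⁻⁴ with k ≥ 2 after collapsing. Regional rate variation is
deliberately ignored — a constant-rate null is conservative for a genome-wide
screen and is the assumption the detection tests calibrate against.

Retained clusters with k in {2,3} are omikli, k ≥ 4 kataegis. Coordination is
judged on the reference-strand mutated base: all-C or all-G kataegis proxy
strand-coordinated ssDNA, and the scssDNA percentage is 100 × (summed spans
of proxy clusters) / genome length, the span being the distance between the
bordering mutations of the cluster.

A note on scale: cluster detection is only meaningful when π is small. A
desk-scale genome must be sparse (the tests use 400 SNVs on 2 Mb, π = 2×10⁻⁴,
comparable per-base rates to real WGS) — compressing a real mutation burden
onto a 50 kb toy genome makes every gap "clustered" and the NB filter then
correctly rejects everything.

## Subtype and phenotype rules

Signature evidence: SBS2+SBS13 ≥ 5% of the sample's mutations AND ≥ 50
mutations. Motif evidence: BH-significant TCW enrichment. HAS requires both;
motif-only (or neither) is LAS/no-APOBEC; the signature-only corner is
unobserved in practice and maps conservatively to LAS with a logged warning.

Phenotype: observed YTCA/RTCA counts among APOBEC-type TCA-context mutations
are tested against the genomic motif fractions by a 1-df χ² without Yates
correction (counts are large in the regime where the call is made), BH across
the cohort; the call is gated on TCA-mutation enrichment, computed with the
same one-sided Fisher machinery as TCW with TCA in its place. Samples failing
the gate, or without a significant deviation, are NA.

The association stage is plain ML logistic regression (statsmodels) of a
binary feature on the HAS indicator with age/sex/TMB/purity/histology
covariates; sex and histology are indicator-encoded and TMB is
log10-transformed (a transform choice of this package). Complete separation
is reported as non-converged, never silently dropped; a two-sided Fisher
exact test on the unadjusted 2×2 table is always reported alongside.

## Tumor timing

Clock mutations are pyrimidine-frame C>T with a 3' G neighbor (NpCpG, SBS1).
Clonality comes from CCF with a 0.8 threshold (configurable; the clonal peak
sits at CCF ≈ 1). Counts are normalized to a diploid genome by ploidy/2;
purity enters through the upstream CCF call and the >0.3 quality gate
(together with NRPCC > 10), not as a second divisor, to avoid double
correction.

The rate model is hierarchical: `n_clonal_i ~ Poisson(r_i · age_i ·
ploidy_i/2)`, `log r_i ~ N(μ, σ²)`. (μ, σ) maximize the marginal likelihood
via 40-node Gauss–Hermite quadrature and Nelder–Mead; per-sample posteriors
are computed on a fine log-rate grid and marginalized over a 7×7
likelihood-weighted hyperparameter grid spanning ±3.5 SE (from a
finite-difference Hessian, clamped when a noiseless cohort degenerates
σ → 0). This keeps the right-skewed σ uncertainty that a plug-in empirical
Bayes interval would clip; simulation shows mean 90%-interval coverage ≈ 0.90
with cohort-level fluctuation of a few percent, which is intrinsic to judging
coverage on a single 60-sample cohort.

Latency converts the subclonal clock burden at an accelerated rate:
`latency = (n_subclonal/(ploidy/2)) / (r_i · A)`, A = 5 by default, exactly
homogeneous of degree −1 in A. MRCA age = age at diagnosis − latency, floored
at zero with a flag. Only subclonal *clock* mutations are used (the
alternative — all subclonal mutations scaled by a clock fraction — is not
implemented; clock-only is the direct reading of the clonal-side model).
The clonal burden is modeled against age at diagnosis rather than MRCA age;
in the latency ≪ age regime the distinction is below the Poisson noise floor,
and the simulator generates data under the same convention so the recovery
tests measure estimation error, not convention mismatch.

## Cell of origin

Per-bin SNV counts are regressed on one cell type's expression centroid plus
replication timing, GC fraction, mean expression across centroids, and log
intronic/exonic fractions, under an NB2 Gamma-Poisson likelihood (variance
μ + φμ², φ estimated jointly by ML via statsmodels). The relative risk is
exp(β₁) with Wald 95% CI on the log scale. The COO call is the argmin of RR
across cell types — mutation density is *depleted* in regions expressed in
the cell of origin (transcription-coupled repair, early replication); the
convention is invertible by flag since the upstream method literature is
unsettled. Ties break toward the narrower CI. Cell types map to proximal
(basal, neuroendocrine, goblet, ciliated, club) or distal (AT1, AT2) airway
classes; cohort comparisons report the proximal/distal × subtype Fisher test
and per-cell-type median RR by subtype.

## Synthetic cohorts

The generator emulates the generative structure the analyses assume:

- **smoking-like**: C>A at random cytosines (both strands) — the dominant
  process in smokers' lung genomes; default weight 0.6.
- **APOBEC**: C>T/C>G (1:1) at TCW sites; among TCA-context events the
  YTCA-vs-RTCA target is chosen with probability `ytca_bias` (default 0.5,
  i.e., no A3A/A3B skew). Default weight 0.2, matching a moderate APOBEC
  component.
- **flat**: uniform background over all bases, weight 0.2. Weights are
  normalized among these three for the non-clock budget of `total_mutations`
  (default 2000, a desk-scale stand-in for a WGS burden).
- **clock**: C>T at NpCpG with clonal count ~ Poisson(rate·age·ploidy/2) and
  subclonal count ~ Poisson(rate·A·latency·ploidy/2); default rate 1.5/yr,
  A = 5, latency uniform on 2–10 years.
- **kataegis**: Poisson(λ = 2) events per sample, each k ≥ 6 strand-coordinated
  APOBEC-type mutations at same-strand TCW sites with ~100 bp geometric gaps;
  kataegis mutations are labeled APOBEC and drawn from the APOBEC budget.
- **CCF**: clonal (1.0) with probability 0.8, else uniform 0.2–0.5 — enough
  structure to exercise the clonal/subclonal threshold, not a subclone model.
- **COO tables**: per-bin centroids ~ N(0,1) for seven lung cell types,
  covariates with fixed small effects, counts ~ NB2 with β₀ = 3, β₁ = −0.5
  toward the sample's target cell type, φ = 0.3, 500 bins.

Signature attributions are derived from truth labels (SBS2+SBS13 = APOBEC,
SBS4 = smoking, SBS1 = clock, SBS5 = flat), so subtype tests isolate the
decision rule from extraction noise; a multiplicative `attribution_noise`
knob exists to stress the 5%/50 thresholds. Everything is byte-deterministic
under (config, seed) via spawned seed sequences.

What the simulator does **not** emulate: real trinucleotide background
composition, regional mutation-rate covariates (replication timing,
chromatin), copy-number structure, subclone trees, or NMF extraction noise.
Passing recovery tests therefore demonstrates correctness of the statistics
under their stated assumptions, not robustness to the full heterogeneity of
real tumor genomes.

## Problem sizes in the test suite

Chosen as the smallest scales at which each statistic is in its intended
regime: 50 kb references for motif/enrichment work (motif inventories of
thousands), 2 Mb sparse genomes for cluster detection (π ≈ 2×10⁻⁴), cohorts
of 20–200 samples for calibration and recall properties, 60 samples for the
clock model, 500 bins × 50 seeds for the COO regression.

## Known limitations

- The enrichment load is a minimum estimate; it systematically undershoots
  the injected truth by roughly the genomic TCW-per-C fraction.
- The cluster null ignores regional rate variation; on real genomes hotspots
  can inflate cluster calls, which the P ≤ 10⁻⁴ threshold only partly absorbs.
- The clock model assumes a shared log-normal rate family and CCF-resolved
  clonality; misassigned clonality propagates directly into latency.
- COO inference identifies the depletion-convention argmin; with correlated
  centroids the margin between cell types can be small, and only converged
  fits enter the call.
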