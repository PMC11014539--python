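# apobec-smoke

Characterization of APOBEC mutagenesis in whole-genome somatic mutation
catalogs from smoking-associated lung cancer, built for analysts who have SNV
calls (VCF/MAF), a reference genome, and per-sample signature attributions,
and who want the downstream APOBEC phenotyping that those inputs support:

- **TCW motif enrichment** per sample, with a one-sided Fisher exact test,
  Benjamini–Hochberg correction across the cohort, and the minimum APOBEC
  mutation-load estimate,
- **clustered mutation analysis**: complex events, omikli, kataegis, C/G
  strand-coordinated clusters as a proxy for long-lived single-stranded DNA
  (scssDNA), and the 96-channel spectrum of kataegis mutations,
- **A3A-like vs A3B-like phenotyping** from the YTCA/RTCA tetranucleotide
  split of TCA-context mutations (χ² goodness of fit against motif
  availability),
- the **two-evidence subtype rule**: High APOBEC Subtype (HAS) when both the
  signature attribution (SBS2+SBS13 ≥ 5% of mutations and ≥ 50 mutations) and
  the motif enrichment agree, Low APOBEC Subtype (LAS) otherwise,
- **tumor timing**: clock-like CpG>TpG (SBS1) mutation counting, a partially
  pooled Poisson rate model against age, and MRCA age / latency under a 5×
  accelerated subclonal expansion,
- **cell-of-origin inference** by Gamma-Poisson regression of binned mutation
  density on cell-type expression centroids,
- a **synthetic cohort generator** with full ground-truth labels, so every
  stage is testable without any data download.

## The statistics

For a sample with `mut_TCW` APOBEC-type mutations (pyrimidine-frame C>T/C>G)
at TCW motifs (W = A/T) out of `mut_C` at any cytosine, against genomic motif
inventories `ctx_TCW` and `ctx_C`:

```
E_TCW = (mut_TCW / ctx_TCW) / (mut_C / ctx_C)
APOBEC_MutLoad_MinEstimate = mut_TCW · (E_TCW − 1) / E_TCW   (E_TCW > 1)
```

with significance from a one-sided Fisher exact test on
`[[mut_TCW, mut_C − mut_TCW], [ctx_TCW, ctx_C − ctx_TCW]]`, Q < 0.05 after BH.

A run of k mutations spanning x bases is a bona fide cluster when the
negative-binomial tail `Pr(NB(k−1, π) ≤ x) ≤ 10⁻⁴`, where π is the sample's
per-base mutation probability; members < 10 bp apart collapse to one event
first. Clusters of ≥ 4 events are kataegis; kataegis with all mutated bases at
reference-strand C (or all G) proxy scssDNA tracts.

The clock model treats the diploid-normalized clonal CpG>TpG burden as
Poisson with mean `r_i · age_i`, `log r_i ~ N(μ, σ²)` partially pooled across
the cohort; tumor latency is `subclonal burden / (r_i · A)` with acceleration
A = 5 by default, and MRCA age is age at diagnosis minus latency.

## Worked example

```python
import numpy as np
from apobec_smoke import (SimulationConfig, SiteInventory, simulate_reference,
                          simulate_sample, count_motifs, tcw_enrichment,
                          cohort_adjust)
from apobec_smoke.simulate import records_to_catalog

# a 50 kb reference and three tumors with increasing APOBEC activity
seq = simulate_reference(50_000, gc=0.45, seed=1)
sites = SiteInventory(seq)
motifs = count_motifs({"chr1": seq}, scope="genome")

results = []
for i, w_apobec in enumerate([0.0, 0.15, 0.4]):
    cfg = SimulationConfig(w_apobec=w_apobec, w_smoking=0.8 - w_apobec,
                           w_flat=0.2, total_mutations=1500)
    records, truth = simulate_sample(seq, sites, cfg,
                                     np.random.default_rng(10 + i),
                                     age=62, ploidy=2.0, latency=5.0)
    catalog = records_to_catalog(records, f"tumor_{i}", seq)
    results.append(tcw_enrichment(catalog, motifs))
cohort_adjust(results, alpha=0.05)

for r in results:
    print(f"{r.sample_id}: E_TCW={r.e_tcw:.2f}  q={r.q_bh:.2e}  "
          f"enriched={r.enriched_flag}  APOBEC_MutLoad_MinEstimate={r.apobec_load_min_rounded}")
```

prints

```
tumor_0: E_TCW=0.77  q=9.52e-01  enriched=False  APOBEC_MutLoad_MinEstimate=0
tumor_1: E_TCW=3.63  q=7.49e-86  enriched=True  APOBEC_MutLoad_MinEstimate=185
tumor_2: E_TCW=4.71  q=4.15e-289  enriched=True  APOBEC_MutLoad_MinEstimate=488
```

The APOBEC-free tumor shows enrichment below 1 (its C>A-dominated smoking
background contributes nothing to the APOBEC-type numerator) and a zero load;
the two APOBEC-positive tumors are flagged with loads that track — and, as
minimum estimates, slightly undershoot — the number of injected APOBEC
mutations (225 and 600 expected).

The same analyses are available from a shell via the `apobec-smoke` CLI
(`simulate`, `annotate`, `enrich`, `clusters`, `subtype`, `timing`, `coo`);
each subcommand is a thin wrapper over the functions used above.

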