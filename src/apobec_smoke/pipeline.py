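"""End-to-end cohort analysis over a directory of per-sample VCFs.

Thin orchestration over the library modules: read + annotate catalogs, genome
motif counts, per-sample enrichment with cohort BH, cluster/kataegis detection,
subtype and phenotype calls, clock timing and (when the COO tables are present)
cell-of-origin inference. Used by both the CLI and the reproduction script.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import catalog as cat
from . import clusters as clu
from . import coo as coo_mod
from . import enrichment as enr
from . import subtypes as sub
from . import timing as tim


def load_cohort(simdir, clonal_threshold: float = 0.8):
    """Read reference, metadata and every sample VCF from a cohort directory."""
    simdir = Path(simdir)
    import pyfaidx

    reference = pyfaidx.Fasta(str(simdir / "reference.fa"))
    meta = pd.read_csv(simdir / "metadata.tsv", sep="\t").set_index("sample_id")
    glen = cat.genome_length(reference)
    catalogs = {}
    for vcf in sorted(simdir.glob("sample_*.vcf")):
        sid = vcf.stem
        c = cat.read_mutations(vcf, "vcf", sid)
        c.genome_length = glen
        if sid in meta.index:
            c.metadata = meta.loc[sid].to_dict()
        cat.annotate_context(c, reference)
        cat.resolve_clonality(c, threshold=clonal_threshold)
        catalogs[sid] = c
    return reference, catalogs, meta


def run_enrichment(catalogs: Dict[str, cat.MutationCatalog], reference,
                   scope: str = "genome", window: int = 20,
                   alpha: float = 0.05) -> List[enr.EnrichmentResult]:
    results = []
    genome_motifs = cat.count_motifs(reference, scope="genome") if scope == "genome" else None
    for sid, c in catalogs.items():
        motifs = genome_motifs if scope == "genome" else \
            cat.count_motifs(reference, c, window=window, scope="windows")
        results.append(enr.tcw_enrichment(c, motifs, alpha=alpha))
    return enr.cohort_adjust(results, alpha=alpha)


def run_clusters(catalogs: Dict[str, cat.MutationCatalog],
                 d_max: int = 1000) -> Dict[str, clu.ClusterSet]:
    return {sid: clu.detect_clusters(c, d_max=d_max) for sid, c in catalogs.items()}


def run_subtypes(catalogs, reference, enrichments, signatures: pd.DataFrame,
                 alpha: float = 0.05) -> List[sub.SubtypeCall]:
    motifs = cat.count_motifs(reference, scope="genome")
    pheno = [sub.ytca_rtca_counts(catalogs[e.sample_id], motifs) for e in enrichments]
    pheno = sub.classify_phenotypes(pheno, enrichments, alpha=alpha)
    attrs = []
    for sid, grp in signatures.groupby("sample_id"):
        attrs.append(sub.SignatureAttribution(
            sample_id=sid,
            counts=dict(zip(grp["signature"], grp["count"])),
            total=int(grp["total"].iloc[0]),
        ))
    attrs.sort(key=lambda a: [e.sample_id for e in enrichments].index(a.sample_id))
    return sub.call_subtypes(attrs, enrichments, phenotype_calls=pheno)


def run_timing(catalogs, acceleration: float = 5.0,
               purity_min: float = 0.3, nrpcc_min: float = 10.0):
    counts = [tim.count_clock_mutations(c) for c in catalogs.values()]
    model = tim.fit_clock_model(counts, purity_min=purity_min, nrpcc_min=nrpcc_min)
    estimates = []
    for c in model.samples_:
        post = model.sample_rates_.loc[c.sample_id]
        estimates.append(tim.estimate_mrca(
            c, rate=post["rate_mean"], acceleration=acceleration,
            rate_lo=post["rate_lo"], rate_hi=post["rate_hi"]))
    return model, estimates


def run_coo(simdir, sample_ids: Optional[List[str]] = None) -> List[coo_mod.COOResult]:
    """Cell-of-origin fits from the cohort's binned count and centroid tables."""
    simdir = Path(simdir)
    bins = pd.read_csv(simdir / "bins.bed", sep="\t",
                       names=["chrom", "start", "end"])
    cov = pd.read_csv(simdir / "covariates.tsv", sep="\t")
    centroids = pd.read_csv(simdir / "centroids.tsv", sep="\t")
    counts = pd.read_csv(simdir / "bin_counts.tsv", sep="\t")
    results = []
    for sid in sample_ids or list(counts.columns):
        matrix = coo_mod.BinMatrix(sample_id=sid, bins=bins,
                                   counts=counts[sid].values,
                                   covariates=cov, centroids=centroids)
        results.append(coo_mod.assign_coo(matrix))
    return results
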