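"""Clustered-mutation detection: complex events, omikli, kataegis, scssDNA proxy.

Candidate clusters are maximal same-chromosome runs of mutations with consecutive
gaps <= ``d_max``. Within a candidate, members closer than 10 bp are collapsed into
a single event (a complex event arising from one lesion, not independent damage).
A candidate is retained as a bona fide cluster when its negative-binomial P-value
under a uniform per-base mutation rate is <= 1e-4 and it still has >= 2 events
after collapsing. Clusters of 2-3 events are omikli, >= 4 are kataegis; kataegis
whose members all mutate reference-strand C (or all G) proxy long-lived
strand-coordinated ssDNA tracts, and the summed spans of those clusters give the
scssDNA percentage of the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Mutation, MutationCatalog

COMPLEX_GAP_BP = 10        # < 10 bp apart -> one mutagenic event
P_CLUSTER_THRESHOLD = 1e-4
KATAEGIS_MIN_K = 4         # >3 events


@dataclass
class MutationCluster:
    chrom: str
    members: list                 # collapsed representative events, coordinate order
    raw_members: list             # all mutations in the candidate run
    span_bp: int = 0
    k: int = 0
    p_cluster: float = 1.0
    klass: str = "complex"        # {complex, omikli, kataegis}
    coordination: str = "mixed"   # {C, G, mixed}
    is_scssdna_proxy: bool = False

    @property
    def start(self) -> int:
        return self.members[0].pos

    @property
    def end(self) -> int:
        return self.members[-1].pos


@dataclass
class ClusterSet:
    sample_id: str
    clusters: List[MutationCluster] = field(default_factory=list)
    pi: float = 0.0
    genome_length: int = 0
    scssdna_percent: float = 0.0
    kataegis_count: int = 0
    kataegis_mutation_count: int = 0


def cluster_pvalue(k: int, span_bp: int, pi: float) -> float:
    """P-value of observing k mutations within span_bp under a uniform rate pi.

    The span is the sum of k-1 independent inter-mutation gaps, each geometric
    with success probability pi (counting failures), so the P-value is the
    negative-binomial CDF Pr(NB(r=k-1, p=pi) <= span_bp). Monotone decreasing in
    k at fixed span, increasing in span at fixed k.
    """
    if not (0 < pi < 1):
        raise ValueError(f"per-base mutation probability pi={pi} outside (0, 1)")
    if k < 2:
        raise ValueError("cluster P-value needs k >= 2")
    if span_bp < 0:
        raise ValueError("span_bp must be >= 0")
    return float(stats.nbinom.cdf(span_bp, k - 1, pi))


def _collapse(run: List[Mutation]) -> List[Mutation]:
    """Merge members <10 bp apart into one event, keeping the first coordinate."""
    events = [run[0]]
    for m in run[1:]:
        if m.pos - events[-1].pos < COMPLEX_GAP_BP:
            continue
        events.append(m)
    return events


def detect_clusters(catalog: MutationCatalog, d_max: int = 1000,
                    p_threshold: float = P_CLUSTER_THRESHOLD) -> ClusterSet:
    """Find clusters as runs with gaps <= d_max, collapse complex events, filter by P.

    ``pi`` is estimated per sample as total SNVs / non-N genome length (constant-rate
    null). Fully collapsed candidates (one event) are complex events and never
    reported as clusters.
    """
    if not catalog.genome_length:
        raise ValueError("catalog.genome_length must be set to estimate the null rate")
    cset = ClusterSet(sample_id=catalog.sample_id, genome_length=catalog.genome_length)
    n = len(catalog)
    if n == 0:
        return cset
    cset.pi = n / catalog.genome_length
    if not (0 < cset.pi < 1):
        raise ValueError(f"degenerate per-base rate pi={cset.pi}")

    run: List[Mutation] = []
    for m in catalog:
        if run and m.chrom == run[-1].chrom and m.pos - run[-1].pos <= d_max:
            run.append(m)
        else:
            _finish_run(run, cset, p_threshold)
            run = [m]
    _finish_run(run, cset, p_threshold)
    return classify_clusters(cset)


def _finish_run(run, cset, p_threshold):
    if len(run) < 2:
        return
    events = _collapse(run)
    if len(events) < 2:
        return  # complex event: counted as one mutation, not a cluster
    span = events[-1].pos - events[0].pos
    p = cluster_pvalue(len(events), span, cset.pi)
    if p <= p_threshold:
        cset.clusters.append(
            MutationCluster(chrom=run[0].chrom, members=events, raw_members=list(run),
                            span_bp=span, k=len(events), p_cluster=p)
        )


def classify_clusters(cset: ClusterSet) -> ClusterSet:
    """Assign omikli/kataegis class, C/G coordination, scssDNA proxy and summaries."""
    kat_muts = 0
    scss_span = 0
    n_kat = 0
    for cl in cset.clusters:
        refs = {m.ref for m in cl.raw_members}
        cl.coordination = "C" if refs == {"C"} else "G" if refs == {"G"} else "mixed"
        cl.klass = "kataegis" if cl.k >= KATAEGIS_MIN_K else "omikli"
        cl.is_scssdna_proxy = cl.k >= KATAEGIS_MIN_K and cl.coordination in ("C", "G")
        if cl.klass == "kataegis":
            n_kat += 1
            kat_muts += len(cl.raw_members)
        if cl.is_scssdna_proxy:
            # ssDNA tract length: distance between the bordering mutations
            scss_span += cl.span_bp
    cset.kataegis_count = n_kat
    cset.kataegis_mutation_count = kat_muts
    cset.scssdna_percent = 100.0 * scss_span / cset.genome_length if cset.genome_length else 0.0
    return cset


# 96-channel SBS ordering: substitution major, 5' flank, 3' flank
_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_FLANKS = ["A", "C", "G", "T"]
SPECTRUM_CHANNELS = [
    f"{f5}[{sub}]{f3}" for sub in _SUBS for f5 in _FLANKS for f3 in _FLANKS
]


def kataegis_spectrum(cset: ClusterSet) -> dict:
    """96-channel trinucleotide spectrum of kataegis members + APOBEC fraction.

    The APOBEC fraction is the share of kataegis mutations that are pyrimidine-frame
    C>T/C>G at a TCW motif. With zero kataegis mutations the spectrum is empty and
    the fraction undefined (NaN, flagged).
    """
    members = [m for cl in cset.clusters if cl.klass == "kataegis" for m in cl.raw_members
               if m.context5 and m.context_ok]
    spectrum = pd.Series(0.0, index=SPECTRUM_CHANNELS)
    if not members:
        return {"spectrum": spectrum, "apobec_fraction": math.nan,
                "n_mutations": 0, "defined": False}
    for m in members:
        channel = f"{m.context5[1]}[{m.pyr_ref}>{m.pyr_alt}]{m.context5[3]}"
        spectrum[channel] += 1
    spectrum /= spectrum.sum()
    apo = sum(1 for m in members if m.is_apobec_type and m.at_tcw)
    return {"spectrum": spectrum, "apobec_fraction": apo / len(members),
            "n_mutations": len(members), "defined": True}


def clusters_to_frame(cset: ClusterSet) -> pd.DataFrame:
    rows = [
        {"sample_id": cset.sample_id, "chrom": cl.chrom, "start": cl.start,
         "end": cl.end, "k": cl.k, "n_raw": len(cl.raw_members), "span_bp": cl.span_bp,
         "p_cluster": cl.p_cluster, "klass": cl.klass, "coordination": cl.coordination,
         "is_scssdna_proxy": cl.is_scssdna_proxy}
        for cl in cset.clusters
    ]
    cols = ["sample_id", "chrom", "start", "end", "k", "n_raw", "span_bp",
            "p_cluster", "klass", "coordination", "is_scssdna_proxy"]
    return pd.DataFrame(rows, columns=cols)
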