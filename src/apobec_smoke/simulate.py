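"""Synthetic tumor cohorts with known mutational-process composition.

The generator emulates the generative structure the analyses assume, at desk
scale: a smoking-like process (C>A at cytosines, the SBS4-like chemistry that
dominates smokers' lung genomes), an APOBEC process (C>T/C>G 1:1 at TCW motifs,
with a tunable probability that TCA-context events land at YTCA vs RTCA), a
clock-like process (C>T at NpCpG accumulating with age), a uniform background,
kataegis events (strand-coordinated runs of APOBEC-type mutations with geometric
gaps), a clonal/subclonal CCF structure, and per-sample binned mutation counts
log-linearly coupled to one cell-type expression centroid through a
Gamma-Poisson model. Every emitted mutation carries exactly one process label in
the machine-readable truth record, and the whole cohort is byte-deterministic
under (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._seq import revcomp, seq_to_array, A, C, G, T

DEFAULT_CELL_TYPES = ["basal", "neuroendocrine", "goblet", "ciliated", "club", "AT1", "AT2"]

#: fixed covariate effects used when generating binned counts
COVARIATE_EFFECTS = {
    "replication_timing": 0.10,
    "gc_fraction": 0.30,
    "mean_expression": -0.10,
    "log_intronic_fraction": 0.05,
    "log_exonic_fraction": 0.05,
}


@dataclass
class SimulationConfig:
    """Study conditions for a simulated smoking-lung-cancer cohort.

    Defaults describe a desk-scale analogue of a deeply sequenced smoker cohort:
    2000 SNVs per sample dominated by smoking-like mutagenesis with a moderate
    APOBEC component, ~1.5 diploid-normalized clock mutations per year of life,
    a 5x accelerated subclonal expansion lasting 2-10 years, and occasional
    kataegis storms of >= 6 strand-coordinated mutations with ~100 bp gaps.
    """

    seed: int = 0
    genome_length: int = 200_000
    gc_fraction: float = 0.45
    chrom: str = "chr1"
    n_samples: int = 12
    total_mutations: int = 2000
    w_smoking: float = 0.6
    w_apobec: float = 0.2
    w_flat: float = 0.2
    ytca_bias: float = 0.5
    clock_rate: float = 1.5
    acceleration: float = 5.0
    subclonal_fraction: float = 0.2
    latency_range: Tuple[float, float] = (2.0, 10.0)
    age_range: Tuple[int, int] = (45, 78)
    purity_range: Tuple[float, float] = (0.4, 0.95)
    ploidy_range: Tuple[float, float] = (1.8, 3.4)
    nrpcc_range: Tuple[float, float] = (11.0, 35.0)
    kataegis_lambda: float = 2.0
    kataegis_k_min: int = 6
    kataegis_k_extra_mean: float = 2.0
    kataegis_gap_mean: float = 100.0
    attribution_noise: float = 0.0
    # cell-of-origin coupling
    coo_n_bins: int = 500
    coo_beta0: float = 3.0
    coo_beta1: float = -0.5
    coo_phi: float = 0.3
    coo_target: str = "AT2"
    coo_targets: Optional[List[str]] = None   # per-sample override
    cell_types: List[str] = field(default_factory=lambda: list(DEFAULT_CELL_TYPES))

    def validate(self):
        for w in (self.w_smoking, self.w_apobec, self.w_flat):
            if w < 0:
                raise ValueError("process weights must be non-negative")
        if self.w_smoking + self.w_apobec + self.w_flat <= 0:
            raise ValueError("at least one process weight must be positive")
        if not 0 <= self.ytca_bias <= 1:
            raise ValueError("ytca_bias must lie in [0, 1]")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if not 0 <= self.subclonal_fraction <= 1:
            raise ValueError("subclonal_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def simulate_reference(length: int, gc: float, seed: int) -> str:
    """I.i.d. reference sequence with P(G)+P(C)=gc; deterministic under seed."""
    if not 0 <= gc <= 1:
        raise ValueError("gc fraction must lie in [0, 1]")
    if length < 10_000:
        raise ValueError("reference length must be >= 10 kb for stable motif statistics")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def write_fasta(seq: str, path, chrom: str = "chr1", width: int = 60) -> None:
    """Write a single-contig FASTA plus its .fai index."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")
    import pyfaidx
    pyfaidx.Faidx(str(path))


# ---------------------------------------------------------------------------
# site inventories
# ---------------------------------------------------------------------------

class SiteInventory:
    """Positions (0-based, plus-strand mutated base) of each process's target motifs.

    Sites within 2 bp of a contig edge are excluded so every simulated mutation
    has a full 5-base context window.
    """

    def __init__(self, seq: str):
        a = seq_to_array(seq)
        L = a.size
        interior = np.zeros(L, dtype=bool)
        interior[2:L - 2] = True
        isC, isG, isT, isA = a == C, a == G, a == T, a == A

        def pat(*offsets_masks):
            m = interior.copy()
            for off, mask in offsets_masks:
                shifted = np.zeros(L, dtype=bool)
                if off == 0:
                    shifted = mask
                elif off > 0:
                    shifted[:-off] = mask[off:]
                else:
                    shifted[-off:] = mask[:off]
                m &= shifted
            return np.flatnonzero(m)

        isW = isA | isT
        isY = isC | isT
        isR = isA | isG
        # mutated-base inventories; "minus" = motif on the reverse strand
        self.tca_plus = pat((-1, isT), (0, isC), (1, isA))
        self.tct_plus = pat((-1, isT), (0, isC), (1, isT))
        self.tca_minus = pat((-1, isT), (0, isG), (1, isA))   # plus TGA
        self.tct_minus = pat((-1, isA), (0, isG), (1, isA))   # plus AGA
        self.ytca_plus = pat((-2, isY), (-1, isT), (0, isC), (1, isA))
        self.rtca_plus = pat((-2, isR), (-1, isT), (0, isC), (1, isA))
        self.ytca_minus = pat((-1, isT), (0, isG), (1, isA), (2, isR))  # plus TGA[AG]
        self.rtca_minus = pat((-1, isT), (0, isG), (1, isA), (2, isY))  # plus TGA[CT]
        self.clock_plus = pat((0, isC), (1, isG))    # CpG, plus C
        self.clock_minus = pat((-1, isC), (0, isG))  # CpG, plus G
        self.c_pos = pat((0, isC))
        self.g_pos = pat((0, isG))
        self.any_pos = pat((0, isC | isG | isT | isA))
        self.ytca = np.sort(np.concatenate([self.ytca_plus, self.ytca_minus]))
        self.rtca = np.sort(np.concatenate([self.rtca_plus, self.rtca_minus]))
        self.tct = np.sort(np.concatenate([self.tct_plus, self.tct_minus]))
        self.tca = np.sort(np.concatenate([self.tca_plus, self.tca_minus]))
        self.cg_pos = np.sort(np.concatenate([self.c_pos, self.g_pos]))
        self.clock = np.sort(np.concatenate([self.clock_plus, self.clock_minus]))
        # strand-specific TCW inventories for strand-coordinated kataegis runs
        self.tcw_plus = np.sort(np.concatenate([self.tca_plus, self.tct_plus]))
        self.tcw_minus = np.sort(np.concatenate([self.tca_minus, self.tct_minus]))


# ---------------------------------------------------------------------------
# per-sample simulation
# ---------------------------------------------------------------------------

def _draw_sites(inventory: np.ndarray, n: int, used: set, rng) -> np.ndarray:
    """Sample n unused positions uniformly without replacement."""
    if n == 0:
        return np.empty(0, dtype=int)
    free = inventory[~np.isin(inventory, np.fromiter(used, dtype=int, count=len(used)))] \
        if used else inventory
    if len(free) < n:
        raise ValueError(
            f"requested {n} mutations but only {len(free)} free motif sites remain"
        )
    picked = rng.choice(free, size=n, replace=False)
    used.update(int(p) for p in picked)
    return picked


def _apobec_alt(seq: str, pos: int, rng) -> str:
    """C>T or C>G (1:1) in pyrimidine frame at a plus-strand C or G site."""
    pyr_alt = "T" if rng.random() < 0.5 else "G"
    return pyr_alt if seq[pos] == "C" else revcomp(pyr_alt)


def _assign_ccf(rng, subclonal_fraction: float) -> float:
    if rng.random() < 1 - subclonal_fraction:
        return 1.0
    return float(rng.uniform(0.2, 0.5))


def simulate_sample(seq: str, sites: SiteInventory, cfg: SimulationConfig,
                    rng: np.random.Generator, age: float, ploidy: float,
                    latency: float) -> Tuple[List[dict], dict]:
    """Simulate one tumor's SNV records plus its ground-truth labels.

    Returns ``(records, truth)`` where each record is a dict with chrom, pos
    (1-based), ref, alt, ccf and a single process label, and the truth dict
    summarizes counts, kataegis event intervals and the timing parameters.
    """
    cfg.validate()
    used: set = set()
    records: List[dict] = []

    def emit(pos0: int, alt: str, label: str, ccf: float):
        records.append({
            "chrom": cfg.chrom, "pos": int(pos0) + 1, "ref": seq[pos0], "alt": alt,
            "ccf": ccf, "label": label,
        })

    # ---- process budgets -------------------------------------------------
    w = np.array([cfg.w_smoking, cfg.w_apobec, cfg.w_flat], dtype=float)
    n_smoke, n_apo, n_flat = rng.multinomial(cfg.total_mutations, w / w.sum())

    # ---- kataegis (APOBEC-labeled, drawn from the APOBEC budget) ---------
    n_events = rng.poisson(cfg.kataegis_lambda)
    kat_events = []
    n_kat_total = 0
    for _ in range(n_events):
        strand = "C" if rng.random() < 0.5 else "G"
        # APOBEC deaminates the exposed ssDNA strand: same-strand TCW targets
        inv = sites.tcw_plus if strand == "C" else sites.tcw_minus
        k = cfg.kataegis_k_min + int(rng.poisson(cfg.kataegis_k_extra_mean))
        origin = int(rng.integers(2, len(seq) - 2000))
        target = origin
        placed = []
        for _ in range(k):
            j = np.searchsorted(inv, target)
            while j < len(inv) and int(inv[j]) in used:
                j += 1
            if j >= len(inv):
                break
            p = int(inv[j])
            used.add(p)
            placed.append(p)
            target = p + 1 + int(rng.geometric(1.0 / cfg.kataegis_gap_mean))
        if len(placed) >= 2:
            for p in placed:
                emit(p, _apobec_alt(seq, p, rng), "apobec_kataegis",
                     _assign_ccf(rng, cfg.subclonal_fraction))
            kat_events.append({"start": placed[0] + 1, "end": placed[-1] + 1,
                               "strand": strand, "k": len(placed)})
            n_kat_total += len(placed)
    n_apo_dispersed = max(int(n_apo) - n_kat_total, 0)

    # ---- dispersed APOBEC at TCW, with the YTCA/RTCA bias at TCA ---------
    n_tcw_sites = len(sites.tca) + len(sites.tct)
    p_tca = len(sites.tca) / n_tcw_sites if n_tcw_sites else 0.0
    n_at_tca = rng.binomial(n_apo_dispersed, p_tca)
    n_at_ytca = rng.binomial(n_at_tca, cfg.ytca_bias)
    n_at_rtca = n_at_tca - n_at_ytca
    n_at_tct = n_apo_dispersed - n_at_tca
    for inv, count in ((sites.ytca, n_at_ytca), (sites.rtca, n_at_rtca),
                       (sites.tct, n_at_tct)):
        for p in _draw_sites(inv, int(count), used, rng):
            emit(int(p), _apobec_alt(seq, int(p), rng), "apobec",
                 _assign_ccf(rng, cfg.subclonal_fraction))

    # ---- smoking-like: C>A in pyrimidine frame at any cytosine ----------
    for p in _draw_sites(sites.cg_pos, int(n_smoke), used, rng):
        p = int(p)
        emit(p, "A" if seq[p] == "C" else "T", "smoking",
             _assign_ccf(rng, cfg.subclonal_fraction))

    # ---- flat background -------------------------------------------------
    alt_choices = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    for p in _draw_sites(sites.any_pos, int(n_flat), used, rng):
        p = int(p)
        emit(p, alt_choices[seq[p]][rng.integers(3)], "flat",
             _assign_ccf(rng, cfg.subclonal_fraction))

    # ---- clock-like: C>T at NpCpG, clonal burden ∝ age, subclonal ∝ A·latency
    n_clock_clonal = rng.poisson(cfg.clock_rate * age * ploidy / 2.0)
    n_clock_sub = rng.poisson(cfg.clock_rate * cfg.acceleration * latency * ploidy / 2.0)
    for p in _draw_sites(sites.clock, int(n_clock_clonal), used, rng):
        p = int(p)
        emit(p, "T" if seq[p] == "C" else "A", "clock_clonal", 1.0)
    for p in _draw_sites(sites.clock, int(n_clock_sub), used, rng):
        p = int(p)
        emit(p, "T" if seq[p] == "C" else "A", "clock_subclonal",
             float(rng.uniform(0.2, 0.5)))

    records.sort(key=lambda r: (r["chrom"], r["pos"]))
    labels = {}
    counts: Dict[str, int] = {}
    for r in records:
        labels[f"{r['chrom']}:{r['pos']}:{r['alt']}"] = r["label"]
        counts[r["label"]] = counts.get(r["label"], 0) + 1
    truth = {
        "process_counts": counts,
        "labels": labels,
        "n_apobec_total": counts.get("apobec", 0) + counts.get("apobec_kataegis", 0),
        "n_apobec_ytca": int(n_at_ytca),
        "n_apobec_rtca": int(n_at_rtca),
        "kataegis_events": kat_events,
        "n_clock_clonal": int(n_clock_clonal),
        "n_clock_subclonal": int(n_clock_sub),
        "age": float(age),
        "ploidy": float(ploidy),
        "true_latency": float(latency),
        "true_mrca_age": float(age - latency),
        "clock_rate": cfg.clock_rate,
        "acceleration": cfg.acceleration,
        "ytca_bias": cfg.ytca_bias,
    }
    return records, truth


def records_to_catalog(records: List[dict], sample_id: str, seq: str,
                       chrom: str = "chr1", metadata: Optional[dict] = None,
                       clonal_threshold: float = 0.8):
    """Build an annotated, clonality-resolved catalog directly from simulated records."""
    from .catalog import Mutation, MutationCatalog, annotate_context, resolve_clonality

    muts = [Mutation(r["chrom"], r["pos"], r["ref"], r["alt"], ccf=r["ccf"])
            for r in records]
    cat = MutationCatalog(sample_id, muts, genome_length=len(seq),
                          metadata=metadata or {})
    annotate_context(cat, {chrom: seq})
    return resolve_clonality(cat, threshold=clonal_threshold)


def write_vcf(records: List[dict], path, chrom: str, contig_length: int) -> None:
    """Write simulated records as a plain-text VCF with CCF and PROC INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={contig_length}>\n")
        fh.write('##INFO=<ID=CCF,Number=1,Type=Float,Description="Cancer cell fraction">\n')
        fh.write('##INFO=<ID=PROC,Number=1,Type=String,Description="Simulated process label">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            info = f"CCF={r['ccf']:.4f};PROC={r['label']}"
            fh.write(f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# cell-of-origin tables
# ---------------------------------------------------------------------------

def simulate_coo_tables(cfg: SimulationConfig, rng: np.random.Generator,
                        targets: List[str]):
    """Centroids, bin covariates, and per-sample NB bin counts coupled to targets.

    Counts for sample i follow NB2 with log-mean
    beta0 + beta1 * centroid[target_i] + sum(gamma_j * covariate_j) and
    dispersion phi (variance mu + phi mu^2).
    """
    nb = cfg.coo_n_bins
    centroids = pd.DataFrame(
        {ct: rng.normal(0.0, 1.0, nb) for ct in cfg.cell_types})
    cov = pd.DataFrame({
        "replication_timing": rng.normal(0.0, 1.0, nb),
        "gc_fraction": rng.uniform(0.3, 0.6, nb),
        "log_intronic_fraction": np.log(rng.uniform(0.05, 0.6, nb)),
        "log_exonic_fraction": np.log(rng.uniform(0.01, 0.2, nb)),
    })
    cov.insert(2, "mean_expression", centroids.mean(axis=1))
    lin = sum(COVARIATE_EFFECTS[c] * cov[c].values for c in COVARIATE_EFFECTS)
    counts = {}
    for i, target in enumerate(targets):
        mu = np.exp(cfg.coo_beta0 + cfg.coo_beta1 * centroids[target].values + lin)
        counts[f"sample_{i + 1:03d}"] = sample_gamma_poisson(mu, cfg.coo_phi, rng)
    bins = pd.DataFrame({
        "chrom": "bins", "start": np.arange(nb) * 1000, "end": (np.arange(nb) + 1) * 1000})
    return bins, cov, centroids, pd.DataFrame(counts)


def sample_gamma_poisson(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Draw NB2 counts (variance mu + phi mu^2) via the Gamma-Poisson mixture."""
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimulationConfig, outdir) -> dict:
    """Simulate a full cohort and write every file the pipeline consumes.

    Emits reference FASTA (+ .fai), one VCF per sample, metadata TSV, truth-based
    signature-attribution TSV (SBS2+SBS13 = APOBEC labels, SBS4 = smoking,
    SBS1 = clock, SBS5 = flat), COO bin/covariate/centroid/count TSVs, a truth
    JSON and a manifest. Byte-deterministic under (config, seed).
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(cfg.n_samples + 3)
    ref_rng, meta_rng, coo_rng = (np.random.default_rng(c) for c in child[:3])

    seq = simulate_reference(cfg.genome_length, cfg.gc_fraction, cfg.seed)
    write_fasta(seq, outdir / "reference.fa", cfg.chrom)
    sites = SiteInventory(seq)

    sample_ids = [f"sample_{i + 1:03d}" for i in range(cfg.n_samples)]
    meta_rows, sig_rows, truths = [], [], {}
    targets = list(cfg.coo_targets) if cfg.coo_targets else [cfg.coo_target] * cfg.n_samples
    if len(targets) != cfg.n_samples:
        raise ValueError("coo_targets must have one entry per sample")

    for i, sid in enumerate(sample_ids):
        rng = np.random.default_rng(child[i + 3])
        age = float(meta_rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        purity = round(float(meta_rng.uniform(*cfg.purity_range)), 3)
        ploidy = round(float(meta_rng.uniform(*cfg.ploidy_range)), 2)
        nrpcc = round(float(meta_rng.uniform(*cfg.nrpcc_range)), 1)
        latency = round(float(meta_rng.uniform(*cfg.latency_range)), 2)
        sex = "F" if meta_rng.random() < 0.5 else "M"
        hist = "adenocarcinoma" if meta_rng.random() < 0.6 else "squamous"

        records, truth = simulate_sample(seq, sites, cfg, rng, age, ploidy, latency)
        write_vcf(records, outdir / f"{sid}.vcf", cfg.chrom, cfg.genome_length)
        truth["coo_target"] = targets[i]
        truths[sid] = truth
        meta_rows.append({"sample_id": sid, "age": age, "sex": sex, "histology": hist,
                          "purity": purity, "ploidy": ploidy, "nrpcc": nrpcc})

        pc = truth["process_counts"]
        apo = truth["n_apobec_total"]
        noise = (lambda x: max(0, int(round(x * math.exp(
            rng.normal(0.0, cfg.attribution_noise)))))) if cfg.attribution_noise > 0 \
            else (lambda x: int(x))
        total = len(records)
        for sig, count in (("SBS2", apo // 2), ("SBS13", apo - apo // 2),
                           ("SBS4", pc.get("smoking", 0)),
                           ("SBS1", pc.get("clock_clonal", 0) + pc.get("clock_subclonal", 0)),
                           ("SBS5", pc.get("flat", 0))):
            sig_rows.append({"sample_id": sid, "signature": sig,
                             "count": noise(count), "total": total})

    bins, cov, centroids, bin_counts = simulate_coo_tables(cfg, coo_rng, targets)

    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(sig_rows).to_csv(outdir / "signatures.tsv", sep="\t", index=False)
    bins.to_csv(outdir / "bins.bed", sep="\t", index=False, header=False)
    cov.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    centroids.to_csv(outdir / "centroids.tsv", sep="\t", index=False)
    bin_counts.to_csv(outdir / "bin_counts.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "samples": sample_ids,
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
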