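"""Somatic SNV catalogs: parsing, pyrimidine-frame context annotation, motif counting.

Coordinates are 1-based inclusive at every file interface (VCF/MAF convention) and
0-based half-open internally. All context annotation follows the universal pyrimidine
strand convention of SBS signature analysis: a mutation at a purine reference base is
reported as the reverse complement event, so ``pyr_ref`` is always C or T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._seq import A, C, G, N, T, fetch, revcomp, seq_to_array

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: columns a minimal MAF-like TSV must provide
MAF_REQUIRED = (
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
)


class CatalogError(ValueError):
    """Malformed catalog record or coordinate."""


class ReferenceMismatchError(CatalogError):
    """Catalog REF base disagrees with the reference sequence."""


@dataclass
class Mutation:
    """One somatic single-nucleotide variant.

    ``pos`` is 1-based. ``context5`` is the 5-base reference window centered on the
    mutated base, reverse-complemented together with ``pyr_ref``/``pyr_alt`` whenever
    the plus-strand reference base is a purine.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ccf: Optional[float] = None
    clonal_flag: str = "unknown"  # {clonal, subclonal, unknown}
    pyr_ref: Optional[str] = None
    pyr_alt: Optional[str] = None
    context5: Optional[str] = None
    context_ok: bool = True

    @property
    def trinucleotide(self) -> Optional[str]:
        return self.context5[1:4] if self.context5 else None

    @property
    def is_apobec_type(self) -> bool:
        """C>T or C>G in pyrimidine frame (SBS2+SBS13 chemistry)."""
        return self.pyr_ref == "C" and self.pyr_alt in ("T", "G")

    @property
    def at_tcw(self) -> bool:
        tri = self.trinucleotide
        return tri is not None and tri[0] == "T" and tri[1] == "C" and tri[2] in "AT"

    @property
    def at_tca(self) -> bool:
        return self.trinucleotide == "TCA"


@dataclass
class MutationCatalog:
    """One sample's SNVs, sorted by (chrom, pos), with genome size and metadata."""

    sample_id: str
    mutations: list = field(default_factory=list)
    genome_length: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mutations = _sort_dedup(self.mutations)

    def __len__(self):
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)


def _sort_dedup(muts: Iterable[Mutation]) -> list:
    seen = set()
    out = []
    for m in sorted(muts, key=lambda m: (m.chrom, m.pos, m.alt)):
        key = (m.chrom, m.pos, m.alt)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def resolve_clonality(catalog: MutationCatalog, threshold: float = 0.8) -> MutationCatalog:
    """Set clonal_flag from CCF: clonal iff ccf >= threshold; missing CCF -> unknown."""
    for m in catalog.mutations:
        if m.ccf is None:
            m.clonal_flag = "unknown"
        else:
            m.clonal_flag = "clonal" if m.ccf >= threshold else "subclonal"
    return catalog


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def read_mutations(path, format: str, sample_id: str) -> MutationCatalog:
    """Read a somatic SNV catalog from a VCF or MAF-like TSV.

    Only biallelic SNVs are retained; indels, MNVs and multi-allelic ALTs are
    dropped with a logged count, and duplicate (chrom, pos, alt) records are
    deduplicated. A CCF INFO field (VCF) or CCF column (MAF) is carried through
    when present.
    """
    if format == "vcf":
        muts, n_dropped = _read_vcf(path)
    elif format == "maf":
        muts, n_dropped = _read_maf(path, sample_id)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'maf'")

    n_raw = len(muts)
    catalog = MutationCatalog(sample_id=sample_id, mutations=muts)
    n_dedup = n_raw - len(catalog)
    if n_dropped or n_dedup:
        logger.info(
            "%s: dropped %d non-SNV records, deduplicated %d", sample_id, n_dropped, n_dedup
        )
    if len(catalog) == 0:
        logger.warning("%s: empty catalog after SNV filtering", sample_id)
    return catalog


def _read_vcf(path):
    import pysam

    muts, n_dropped = [], 0
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            if rec.alts is None or len(rec.alts) != 1:
                n_dropped += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                n_dropped += 1
                continue
            if ref == alt:
                raise CatalogError(f"{path}: record {i + 1} has REF == ALT ({ref})")
            ccf = rec.info.get("CCF")
            if isinstance(ccf, tuple):
                ccf = ccf[0]
            muts.append(
                Mutation(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    ccf=float(ccf) if ccf is not None else None,
                )
            )
    return muts, n_dropped


def _read_maf(path, sample_id):
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: MAF missing required columns {missing}")
    df = df[df["Tumor_Sample_Barcode"] == sample_id]
    muts, n_dropped = [], 0
    for idx, row in df.iterrows():
        ref = str(row["Reference_Allele"]).upper()
        alt = str(row["Tumor_Seq_Allele2"]).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            n_dropped += 1
            continue
        try:
            pos = int(row["Start_Position"])
        except ValueError as exc:
            raise CatalogError(f"{path}: line {idx + 2}: bad Start_Position") from exc
        if ref == alt:
            raise CatalogError(f"{path}: line {idx + 2} has identical ref/alt")
        ccf = row.get("CCF")
        ccf = float(ccf) if ccf is not None and not pd.isna(ccf) else None
        muts.append(Mutation(chrom=str(row["Chromosome"]), pos=pos, ref=ref, alt=alt, ccf=ccf))
    return muts, n_dropped


# ---------------------------------------------------------------------------
# context annotation
# ---------------------------------------------------------------------------

def annotate_context(catalog: MutationCatalog, reference) -> MutationCatalog:
    """Fill pyrimidine-normalized 5-base contexts for every mutation.

    ``reference`` may be a ``pyfaidx.Fasta`` handle or a dict of chromosome name to
    plain sequence string. Mutations whose 5-base window contains an N keep their
    context but are flagged ``context_ok=False`` and are excluded from motif
    statistics downstream. Idempotent: annotation is computed from the stored
    plus-strand ref/alt, never from a previous annotation.
    """
    for m in catalog.mutations:
        contig = reference[m.chrom]
        clen = len(contig)
        if m.pos < 1 or m.pos > clen:
            raise CatalogError(f"{m.chrom}:{m.pos} beyond contig end ({clen} bp)")
        if m.pos < 3 or m.pos > clen - 2:
            raise CatalogError(f"{m.chrom}:{m.pos} lacks 2 flanking bases for context")
        window = fetch(reference, m.chrom, m.pos - 3, m.pos + 2)
        if window[2] != m.ref:
            raise ReferenceMismatchError(
                f"{m.chrom}:{m.pos} catalog ref {m.ref} != reference base {window[2]}"
            )
        if m.ref in ("G", "A"):
            m.pyr_ref = revcomp(m.ref)
            m.pyr_alt = revcomp(m.alt)
            m.context5 = revcomp(window)
        else:
            m.pyr_ref, m.pyr_alt, m.context5 = m.ref, m.alt, window
        m.context_ok = "N" not in m.context5
    n_flagged = sum(1 for m in catalog.mutations if not m.context_ok)
    if n_flagged:
        logger.info("%s: %d mutations with N in context window flagged", catalog.sample_id, n_flagged)
    return catalog


# ---------------------------------------------------------------------------
# motif counting
# ---------------------------------------------------------------------------

@dataclass
class MotifCounts:
    """Double-stranded motif inventory of the evaluated sequence space.

    ``n_C`` counts cytosine positions on both strands (C plus G on the plus strand).
    A trinucleotide motif is counted once per strand on which it matches, so a
    sequence and its reverse complement give identical counts. YTCA/RTCA require the
    5' flanking base of the TCA to exist and be non-N; TCA occurrences at contig
    edges therefore contribute to ``n_TCA`` but to neither tetranucleotide class.
    """

    n_C: int = 0
    n_TCW: int = 0
    n_TCA: int = 0
    n_YTCA: int = 0
    n_RTCA: int = 0
    scope: str = "genome"

    def __add__(self, other: "MotifCounts") -> "MotifCounts":
        if other.scope != self.scope:
            raise ValueError("cannot combine MotifCounts with different scopes")
        return MotifCounts(
            self.n_C + other.n_C,
            self.n_TCW + other.n_TCW,
            self.n_TCA + other.n_TCA,
            self.n_YTCA + other.n_YTCA,
            self.n_RTCA + other.n_RTCA,
            self.scope,
        )


def _count_segment(seq: str, scope: str) -> MotifCounts:
    a = seq_to_array(seq)
    out = MotifCounts(scope=scope)
    if a.size == 0:
        return out
    out.n_C = int(((a == C) | (a == G)).sum())
    if a.size >= 3:
        t0, t1, t2 = a[:-2], a[1:-1], a[2:]
        tca_p = (t0 == T) & (t1 == C) & (t2 == A)
        tct_p = (t0 == T) & (t1 == C) & (t2 == T)
        tga_m = (t0 == T) & (t1 == G) & (t2 == A)  # minus-strand TCA
        aga_m = (t0 == A) & (t1 == G) & (t2 == A)  # minus-strand TCT
        out.n_TCA = int(tca_p.sum() + tga_m.sum())
        out.n_TCW = out.n_TCA + int(tct_p.sum() + aga_m.sum())
    if a.size >= 4:
        f0, f1, f2, f3 = a[:-3], a[1:-2], a[2:-1], a[3:]
        tca4_p = (f1 == T) & (f2 == C) & (f3 == A)
        out.n_YTCA = int((((f0 == C) | (f0 == T)) & tca4_p).sum())
        out.n_RTCA = int((((f0 == A) | (f0 == G)) & tca4_p).sum())
        tga4_m = (f0 == T) & (f1 == G) & (f2 == A)
        out.n_YTCA += int((tga4_m & ((f3 == A) | (f3 == G))).sum())  # revcomp YTCA
        out.n_RTCA += int((tga4_m & ((f3 == C) | (f3 == T))).sum())  # revcomp RTCA
    return out


def _merged_windows(catalog: MutationCatalog, window: int, contig_lengths: dict) -> dict:
    intervals = {}
    for m in catalog.mutations:
        lo = max(0, m.pos - 1 - window)
        hi = min(contig_lengths[m.chrom], m.pos + window)
        intervals.setdefault(m.chrom, []).append((lo, hi))
    merged = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        acc = [list(ivs[0])]
        for lo, hi in ivs[1:]:
            if lo <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], hi)
            else:
                acc.append([lo, hi])
        merged[chrom] = [tuple(iv) for iv in acc]
    return merged


def count_motifs(reference, catalog: Optional[MutationCatalog] = None,
                 window: int = 20, scope: str = "genome") -> MotifCounts:
    """Count C/TCW/TCA/YTCA/RTCA motifs on both strands of the evaluated space.

    ``scope='genome'`` scans every contig; ``scope='windows'`` scans the union of
    ±``window``-base intervals around each mutated position (overlaps merged so no
    base is double-counted). Motifs containing N are never counted.
    """
    if scope not in ("genome", "windows"):
        raise ValueError(f"unknown scope {scope!r}")
    total = MotifCounts(scope=scope)
    if scope == "genome":
        for chrom in list(reference.keys()):
            total = total + _count_segment(fetch(reference, chrom, 0, len(reference[chrom])), scope)
        return total
    if window < 2:
        raise ValueError("window half-width must be >= 2")
    if catalog is None or len(catalog) == 0:
        logger.warning("count_motifs: empty catalog with scope='windows' -> zero counts")
        return total
    lengths = {c: len(reference[c]) for c in list(reference.keys())}
    for chrom, ivs in _merged_windows(catalog, window, lengths).items():
        for lo, hi in ivs:
            total = total + _count_segment(fetch(reference, chrom, lo, hi), scope)
    return total


def genome_length(reference) -> int:
    """Count of non-N bases across all contigs."""
    n = 0
    for chrom in list(reference.keys()):
        a = seq_to_array(fetch(reference, chrom, 0, len(reference[chrom])))
        n += int((a != N).sum())
    return n


def catalog_to_frame(catalog: MutationCatalog) -> pd.DataFrame:
    """Annotated catalog as a TSV-ready DataFrame with stable column order."""
    rows = [
        {
            "sample_id": catalog.sample_id,
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
            "ccf": m.ccf,
            "clonal_flag": m.clonal_flag,
            "pyr_ref": m.pyr_ref,
            "pyr_alt": m.pyr_alt,
            "context5": m.context5,
            "context_ok": m.context_ok,
        }
        for m in catalog.mutations
    ]
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "ccf", "clonal_flag",
            "pyr_ref", "pyr_alt", "context5", "context_ok"]
    return pd.DataFrame(rows, columns=cols)
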