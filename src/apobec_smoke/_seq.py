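"""Low-level sequence helpers shared by catalog annotation and the simulator."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte codes for vectorized scans
A, C, G, T, N = (ord(b) for b in "ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Uppercase DNA string -> uint8 array of ASCII codes."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def fetch(handle, chrom: str, start: int, end: int) -> str:
    """0-based half-open fetch working for both pyfaidx.Fasta and dict-of-str."""
    return str(handle[chrom][start:end]).upper()


def contig_names(handle) -> list:
    return list(handle.keys())
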