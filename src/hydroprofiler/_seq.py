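"""Shared sequence encodings: nucleotide/amino-acid codes, codon table, BLOSUM62.

Nucleotides are coded A=0, C=1, G=2, T=3, N(or anything else)=4.  Amino acids
use a 22-symbol alphabet: the 20 canonical residues, X (unknown, index 20) and
'*' (stop, index 21).  The genetic code and the BLOSUM62 matrix come from
Biopython; stops are rescored to the matrix minimum against every symbol so a
translated stop codon can never support an alignment.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

# --- nucleotides -----------------------------------------------------------

NT_A, NT_C, NT_G, NT_T, NT_N = 0, 1, 2, 3, 4

_NT_LUT = np.full(256, NT_N, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _NT_LUT[ord(_c)] = _i
    _NT_LUT[ord(_c.lower())] = _i

_NT_CHARS = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_dna(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (non-ACGT -> N)."""
    return _NT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode_dna(codes: np.ndarray) -> str:
    return _NT_CHARS[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; N stays N."""
    rc = codes[::-1].copy()
    acgt = rc < 4
    rc[acgt] = 3 - rc[acgt]
    return rc


def encode_many(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode a list of sequences into one concatenated code array + offsets.

    ``offsets`` has length ``len(seqs) + 1``; sequence i occupies
    ``concat[offsets[i]:offsets[i + 1]]``.
    """
    joined = "".join(seqs).encode("ascii")
    concat = _NT_LUT[np.frombuffer(joined, dtype=np.uint8)]
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    return concat, offsets


# --- amino acids -----------------------------------------------------------

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"
AA_X = 20
AA_STOP = 21
N_AA = len(AA_ALPHABET)  # 22
AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}

_AA_LUT = np.full(256, AA_X, dtype=np.int8)
for _i, _c in enumerate(AA_ALPHABET):
    _AA_LUT[ord(_c)] = _i

_AA_CHARS = np.frombuffer(AA_ALPHABET.encode("ascii"), dtype=np.uint8)


def encode_protein(seq: str) -> np.ndarray:
    return _AA_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode_protein(codes: np.ndarray) -> str:
    return _AA_CHARS[codes].tobytes().decode("ascii")


# --- genetic code ----------------------------------------------------------

def _build_codon_table() -> np.ndarray:
    """125-entry map from codon index (n0*25 + n1*5 + n2) to amino-acid code.

    Codons containing N translate to X; stop codons to '*'.
    """
    table = CodonTable.unambiguous_dna_by_name["Standard"]
    out = np.full(125, AA_X, dtype=np.int8)
    nt_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    for codon, aa in table.forward_table.items():
        idx = nt_of[codon[0]] * 25 + nt_of[codon[1]] * 5 + nt_of[codon[2]]
        out[idx] = AA_INDEX[aa]
    for codon in table.stop_codons:
        idx = nt_of[codon[0]] * 25 + nt_of[codon[1]] * 5 + nt_of[codon[2]]
        out[idx] = AA_STOP
    return out


CODON_AA = _build_codon_table()

#: Synonymous codons per amino-acid letter, for seeded reverse translation.
def _build_back_table() -> dict[str, tuple[str, ...]]:
    table = CodonTable.unambiguous_dna_by_name["Standard"]
    back: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        back.setdefault(aa, []).append(codon)
    return {aa: tuple(codons) for aa, codons in back.items()}


BACK_CODONS = _build_back_table()


def translate_codes(codes: np.ndarray) -> np.ndarray:
    """Translate nucleotide codes (frame +1, trailing partial codon dropped)."""
    n = (len(codes) // 3) * 3
    c = codes[:n].reshape(-1, 3).astype(np.int64)
    return CODON_AA[c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]]


# --- scoring ---------------------------------------------------------------

def _build_blosum62() -> np.ndarray:
    """BLOSUM62 over the 22-symbol alphabet, stops at the matrix minimum."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((N_AA, N_AA), dtype=np.int8)
    for i, a in enumerate(AA_ALPHABET[:21]):  # 20 aa + X are in BLOSUM62
        for j, b in enumerate(AA_ALPHABET[:21]):
            out[i, j] = int(m[a, b])
    lowest = int(out[:21, :21].min())
    out[AA_STOP, :] = lowest
    out[:, AA_STOP] = lowest
    return out


BLOSUM62 = _build_blosum62()
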