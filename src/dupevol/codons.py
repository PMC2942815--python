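"""Standard genetic code tables and NG86 lookup structures.

Everything downstream (the counting estimator and the simulator) works on
integer codon indices: ``index = 16*nt[0] + 4*nt[1] + nt[2]`` with the
nucleotide order A=0, C=1, G=2, T=3.  Only the standard code (NCBI table 1)
is supported.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: All 64 codons in index order.
CODONS = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

#: One-letter amino acid per codon index, '*' for stops.
AMINO_ACIDS = np.array(
    ["*" if c in _TABLE.stop_codons else _TABLE.forward_table[c] for c in CODONS]
)
IS_STOP = AMINO_ACIDS == "*"
SENSE_CODONS = [i for i in range(64) if not IS_STOP[i]]


def codon_index(codon: str) -> int:
    """Map a 3-mer over ACGT to its integer index."""
    try:
        return CODON_INDEX[codon.upper()]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


def is_stop(codon: str) -> bool:
    return bool(IS_STOP[codon_index(codon)])


def translate_codon(codon: str) -> str:
    return str(AMINO_ACIDS[codon_index(codon)])


# --- single-nucleotide mutation tables ------------------------------------
#
# For codon index c, position p (0..2) and alternative rank a (0..2), the
# mutated codon replaces the base at p with the a-th *other* nucleotide
# (in A<C<G<T order).  MUT_TARGET holds the mutated codon index, MUT_CLASS
# the change class: 0 = synonymous, 1 = non-synonymous, 2 = creates a stop.

MUT_TARGET = np.zeros((64, 3, 3), dtype=np.int64)
MUT_CLASS = np.zeros((64, 3, 3), dtype=np.int64)

for _c in range(64):
    _nts = [(_c >> (2 * (2 - p))) & 3 for p in range(3)]
    for _p in range(3):
        _alts = [n for n in range(4) if n != _nts[_p]]
        for _a, _n in enumerate(_alts):
            _t = _c + (_n - _nts[_p]) * 4 ** (2 - _p)
            MUT_TARGET[_c, _p, _a] = _t
            if IS_STOP[_t]:
                MUT_CLASS[_c, _p, _a] = 2
            elif AMINO_ACIDS[_t] == AMINO_ACIDS[_c]:
                MUT_CLASS[_c, _p, _a] = 0
            else:
                MUT_CLASS[_c, _p, _a] = 1

#: Raw counts of synonymous / non-stop single-nucleotide changes per codon,
#: used by the simulator's rate calibration.
SYN_CHANGE_COUNT = (MUT_CLASS == 0).sum(axis=(1, 2)).astype(np.float64)
NONSYN_CHANGE_COUNT = (MUT_CLASS == 1).sum(axis=(1, 2)).astype(np.float64)

# --- NG86 site counts ------------------------------------------------------
#
# Synonymous sites per codon: at each position, the fraction of the (up to 3)
# non-stop single-nucleotide changes that are synonymous; positions whose
# changes are all stop-producing contribute 0.  Non-synonymous sites are the
# complement to 3.  Stop codons get NaN.

SYN_SITES = np.full(64, np.nan)
for _c in SENSE_CODONS:
    _s = 0.0
    for _p in range(3):
        cls = MUT_CLASS[_c, _p]
        nonstop = (cls != 2).sum()
        if nonstop:
            _s += (cls == 0).sum() / nonstop
    SYN_SITES[_c] = _s
NONSYN_SITES = 3.0 - SYN_SITES


def encode(seq: str) -> np.ndarray:
    """Nucleotide string -> int array (A=0,C=1,G=2,T=3)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for nt, i in NT_INDEX.items():
        out[arr == ord(nt)] = i
    if (out < 0).any():
        bad = seq[int(np.argmin(out >= 0))]
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return out


def decode(nts: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[i] for i in nts)


def codon_indices(seq: str) -> np.ndarray:
    """Nucleotide string (length multiple of 3) -> codon index array."""
    nts = encode(seq)
    if nts.size % 3:
        raise ValueError("sequence length is not a multiple of 3")
    nts = nts.reshape(-1, 3)
    return nts[:, 0] * 16 + nts[:, 1] * 4 + nts[:, 2]


def codons_to_seq(codons: np.ndarray) -> str:
    return "".join(CODONS[i] for i in codons)
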