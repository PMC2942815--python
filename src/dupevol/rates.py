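"""Pairwise dN/dS estimation by Nei–Gojobori (1986) counting.

The estimator replaces maximum-likelihood pairwise runs (PAML codeml) with
the classic counting method: fractional synonymous/non-synonymous site
counts per codon, pathway-averaged difference counts for codons differing
at more than one position, and the Jukes–Cantor multiple-hit correction

    d = -(3/4) * ln(1 - (4/3) * p).

Counts are exact by enumeration (see :func:`count_sites`,
:func:`count_diffs`); orderings of mutational steps that pass through a
stop codon are discarded and the remainder renormalized.  Pairs whose
proportion of differences reaches the Jukes–Cantor pole (p >= 3/4) are
returned flagged as saturated rather than raising; downstream selection
skips them.

An adapter (:func:`import_rates`) accepts an externally computed pairwise
table (e.g. codeml output) in place of the internal estimator.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import codons as cd

logger = logging.getLogger(__name__)

SATURATION_P = 0.75  # Jukes-Cantor pole: d undefined for p >= 3/4


@dataclass(frozen=True)
class CodonSequence:
    """An in-frame coding nucleotide sequence.

    Length must be a multiple of 3, alphabet ACGT, no internal stop codon.
    A single terminal stop codon is tolerated and trimmed at load.
    """

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("empty sequence id")
        seq = self.seq.upper()
        if len(seq) % 3:
            raise ValueError(f"{self.id}: length {len(seq)} not a multiple of 3")
        if not set(seq) <= set("ACGT"):
            raise ValueError(f"{self.id}: non-ACGT characters present")
        idx = cd.codon_indices(seq)
        if cd.IS_STOP[idx[-1]]:
            idx = idx[:-1]
            seq = seq[:-3]
            if not len(seq):
                raise ValueError(f"{self.id}: sequence is a lone stop codon")
        if cd.IS_STOP[idx].any():
            pos = int(np.argmax(cd.IS_STOP[idx]))
            raise ValueError(f"{self.id}: internal stop codon at codon {pos}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def translate(self) -> str:
        return "".join(cd.AMINO_ACIDS[i] for i in cd.codon_indices(self.seq))


def count_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous and non-synonymous site counts for one sense codon.

    At each of the three positions the synonymous fraction is taken among
    the single-nucleotide changes that do not create a stop codon (the
    denominator is reduced by stop-producing changes).  The two counts sum
    to 3 exactly.
    """
    i = cd.codon_index(codon)
    if cd.IS_STOP[i]:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    s = float(cd.SYN_SITES[i])
    return s, 3.0 - s


def _enumerate_diffs(ia: int, ib: int) -> tuple[float, float, bool]:
    """Pathway-averaged (syn, nonsyn) difference counts between two sense
    codons; third value flags the all-paths-blocked degenerate case."""
    nts_a = [(ia >> (2 * (2 - p))) & 3 for p in range(3)]
    nts_b = [(ib >> (2 * (2 - p))) & 3 for p in range(3)]
    positions = [p for p in range(3) if nts_a[p] != nts_b[p]]
    d = len(positions)
    if d == 0:
        return 0.0, 0.0, False
    syn_total = 0.0
    nonsyn_total = 0.0
    n_valid = 0
    for order in itertools.permutations(positions):
        cur = list(nts_a)
        syn = nonsyn = 0
        blocked = False
        for p in order:
            before = cur[0] * 16 + cur[1] * 4 + cur[2]
            cur[p] = nts_b[p]
            after = cur[0] * 16 + cur[1] * 4 + cur[2]
            if cd.IS_STOP[after]:
                blocked = True
                break
            if cd.AMINO_ACIDS[before] == cd.AMINO_ACIDS[after]:
                syn += 1
            else:
                nonsyn += 1
        if blocked:
            continue
        syn_total += syn
        nonsyn_total += nonsyn
        n_valid += 1
    if n_valid == 0:
        # Convention: unreachable via stop-free paths -> all differences
        # treated as non-synonymous.
        return 0.0, float(d), True
    return syn_total / n_valid, nonsyn_total / n_valid, False


# Precomputed 64x64 pathway-averaged difference tables (NaN rows/cols for
# stop codons).
_SYN_DIFFS = np.full((64, 64), np.nan)
_NONSYN_DIFFS = np.full((64, 64), np.nan)
_ALL_BLOCKED = np.zeros((64, 64), dtype=bool)
for _ia in cd.SENSE_CODONS:
    for _ib in cd.SENSE_CODONS:
        _s, _n, _blk = _enumerate_diffs(_ia, _ib)
        _SYN_DIFFS[_ia, _ib] = _s
        _NONSYN_DIFFS[_ia, _ib] = _n
        _ALL_BLOCKED[_ia, _ib] = _blk


def count_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/non-synonymous differences between two
    sense codons.

    All orderings of the single-nucleotide steps are averaged with equal
    weight; orderings passing through a stop codon are discarded and the
    average renormalized over the rest.  The two counts sum to the Hamming
    distance of the codons.
    """
    ia, ib = cd.codon_index(codon_a), cd.codon_index(codon_b)
    if cd.IS_STOP[ia] or cd.IS_STOP[ib]:
        raise ValueError("stop codons have no difference counts")
    if _ALL_BLOCKED[ia, ib]:
        logger.warning(
            "all mutational orderings between %s and %s pass through a stop; "
            "treating the %d differences as non-synonymous",
            codon_a, codon_b, int(_NONSYN_DIFFS[ia, ib]),
        )
    return float(_SYN_DIFFS[ia, ib]), float(_NONSYN_DIFFS[ia, ib])


def jukes_cantor(p: float) -> float:
    """JC69 distance for a proportion of differences p < 3/4."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= SATURATION_P:
        raise ValueError("proportion at or beyond the Jukes-Cantor pole")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass(frozen=True)
class PairwiseRates:
    """NG86 counts and corrected distances for one unordered gene pair.

    ``saturated`` is set when pS or pN reaches 3/4, in which case dS/dN are
    NaN and downstream selection must skip the pair (treated as dS > 3).
    """

    id_a: str
    id_b: str
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons_compared: int
    pS: float
    pN: float
    dS: float
    dN: float
    saturated: bool = False

    @property
    def omega(self) -> float:
        if self.saturated or self.dS <= 0:
            return float("nan")
        return self.dN / self.dS


def pairwise_rates(a: CodonSequence | str, b: CodonSequence | str,
                   id_a: str = "a", id_b: str = "b") -> PairwiseRates:
    """NG86 pairwise dN and dS for two codon-aligned sequences.

    Accepts :class:`CodonSequence` objects (gap-free) or raw aligned strings
    that may contain gaps ("-") or ambiguity characters; codon columns
    containing either are skipped and excluded from ``n_codons_compared``.
    Site counts are averaged over the two sequences, difference counts are
    pathway-averaged; the Jukes–Cantor correction is applied to both
    proportions.  Symmetric in its arguments.
    """
    if isinstance(a, CodonSequence):
        id_a, seq_a = a.id, a.seq
    else:
        seq_a = a.upper()
    if isinstance(b, CodonSequence):
        id_b, seq_b = b.id, b.seq
    else:
        seq_b = b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    if len(seq_a) % 3:
        raise ValueError("aligned length is not a multiple of 3")

    syn_sites = nonsyn_sites = syn_diffs = nonsyn_diffs = 0.0
    n_used = 0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k:k + 3], seq_b[k:k + 3]
        if not (set(ca) <= set("ACGT") and set(cb) <= set("ACGT")):
            continue  # gap or ambiguity column: dropped pairwise
        ia, ib = cd.CODON_INDEX[ca], cd.CODON_INDEX[cb]
        if cd.IS_STOP[ia] or cd.IS_STOP[ib]:
            raise ValueError(f"stop codon in aligned column {k // 3}")
        syn_sites += 0.5 * (cd.SYN_SITES[ia] + cd.SYN_SITES[ib])
        nonsyn_sites += 0.5 * (cd.NONSYN_SITES[ia] + cd.NONSYN_SITES[ib])
        syn_diffs += _SYN_DIFFS[ia, ib]
        nonsyn_diffs += _NONSYN_DIFFS[ia, ib]
        n_used += 1

    pS = syn_diffs / syn_sites if syn_sites > 0 else 0.0
    pN = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else 0.0
    saturated = pS >= SATURATION_P or pN >= SATURATION_P
    dS = float("nan") if saturated else jukes_cantor(pS)
    dN = float("nan") if saturated else jukes_cantor(pN)
    if saturated:
        logger.info("pair (%s, %s) saturated: pS=%.3f pN=%.3f", id_a, id_b, pS, pN)
    return PairwiseRates(id_a, id_b, syn_sites, nonsyn_sites, syn_diffs,
                         nonsyn_diffs, n_used, pS, pN, dS, dN, saturated)


def amino_acid_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical amino acids over comparable aligned codons."""
    same = total = 0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k:k + 3].upper(), seq_b[k:k + 3].upper()
        if not (set(ca) <= set("ACGT") and set(cb) <= set("ACGT")):
            continue
        total += 1
        if cd.AMINO_ACIDS[cd.CODON_INDEX[ca]] == cd.AMINO_ACIDS[cd.CODON_INDEX[cb]]:
            same += 1
    return same / total if total else float("nan")


class RateMatrix:
    """Symmetric all-pairs dS/dN (and amino-acid identity) for one family."""

    def __init__(self, family_id: str, ids: Sequence[str],
                 pairs: Mapping[frozenset, PairwiseRates],
                 aa_identity: Mapping[frozenset, float] | None = None,
                 provenance: str = "internal-ng86"):
        self.family_id = family_id
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate gene ids")
        self._pairs = dict(pairs)
        self._aa = dict(aa_identity or {})
        self.provenance = provenance
        for a, b in itertools.combinations(self.ids, 2):
            if frozenset((a, b)) not in self._pairs:
                raise ValueError(f"missing pair ({a}, {b})")

    def pair(self, a: str, b: str) -> PairwiseRates:
        return self._pairs[frozenset((a, b))]

    def ds(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self._pairs[frozenset((a, b))].dS

    def dn(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self._pairs[frozenset((a, b))].dN

    def saturated(self, a: str, b: str) -> bool:
        if a == b:
            return False
        return self._pairs[frozenset((a, b))].saturated

    def aa_identity(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._aa.get(frozenset((a, b)), float("nan"))

    def iter_pairs(self) -> Iterable[PairwiseRates]:
        for a, b in itertools.combinations(self.ids, 2):
            yield self.pair(a, b)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pr in self.iter_pairs():
            rows.append({
                "family": self.family_id, "id_a": pr.id_a, "id_b": pr.id_b,
                "syn_sites": pr.syn_sites, "nonsyn_sites": pr.nonsyn_sites,
                "syn_diffs": pr.syn_diffs, "nonsyn_diffs": pr.nonsyn_diffs,
                "dS": pr.dS, "dN": pr.dN,
                "flags": "saturated" if pr.saturated else "",
            })
        return pd.DataFrame(rows)


def rate_matrix(family: Sequence[CodonSequence] | Mapping[str, str],
                family_id: str = "family") -> RateMatrix:
    """All-pairs NG86 rates from one shared (codon-aware) alignment.

    ``family`` is either a list of gap-free :class:`CodonSequence` of equal
    length or a mapping id -> aligned sequence (gaps allowed).
    """
    if isinstance(family, Mapping):
        aligned = {k: v.upper() for k, v in family.items()}
    else:
        aligned = {s.id: s.seq for s in family}
    ids = list(aligned)
    if len(ids) < 2:
        raise ValueError("family must contain at least 2 sequences")
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    pairs = {}
    aa = {}
    for a, b in itertools.combinations(ids, 2):
        pairs[frozenset((a, b))] = pairwise_rates(aligned[a], aligned[b], a, b)
        aa[frozenset((a, b))] = amino_acid_identity(aligned[a], aligned[b])
    return RateMatrix(family_id, ids, pairs, aa)


def import_rates(table: pd.DataFrame | str, ids: Sequence[str],
                 family_id: str = "family", atol: float = 1e-9) -> RateMatrix:
    """Build a :class:`RateMatrix` from an external pairwise table.

    The table (DataFrame or TSV path) must carry columns id_a, id_b, dN, dS
    and cover every unordered pair of ``ids``.  Duplicate (a,b)/(b,a) rows
    must agree within ``atol``.  Pairs with dS > 3 are flagged saturated so
    downstream window rules treat them exactly like internally flagged
    pairs.  Count columns are unavailable externally and set to NaN.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = {"id_a", "id_b", "dN", "dS"}
    if not required <= set(table.columns):
        raise ValueError(f"table missing columns: {sorted(required - set(table.columns))}")
    seen: dict[frozenset, tuple[float, float]] = {}
    for row in table.itertuples(index=False):
        key = frozenset((row.id_a, row.id_b))
        val = (float(row.dN), float(row.dS))
        if key in seen:
            prev = seen[key]
            if abs(prev[0] - val[0]) > atol or abs(prev[1] - val[1]) > atol:
                raise ValueError(f"conflicting duplicate entries for pair {sorted(key)}")
        seen[key] = val
    pairs = {}
    for a, b in itertools.combinations(ids, 2):
        key = frozenset((a, b))
        if key not in seen:
            raise ValueError(f"pair ({a}, {b}) missing from imported table")
        dn_v, ds_v = seen[key]
        saturated = ds_v > 3.0
        pairs[key] = PairwiseRates(
            a, b, float("nan"), float("nan"), float("nan"), float("nan"), 0,
            float("nan"), float("nan"), ds_v, dn_v, saturated)
    return RateMatrix(family_id, ids, pairs, provenance="imported")
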