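"""Asymmetry screen: outgroup-parsimony substitution assignment between
bidirectional best paralogs and exact binomial statistics.

Under symmetric evolution the substitution counts of the two copies are
independent Poisson with a common rate, so conditional on the total
Y = X1 + X2 the count in one copy is Binomial(Y, 1/2).  Each pair is
tested with the exact symmetric binomial test; the genome-scale excess of
significant pairs is then itself tested against Binomial(n_pairs, alpha)
(the meta-test), which is the screen's answer to multiple testing — no
per-pair correction is applied.

Substitutions are assigned by parsimony against the pair's closest cousin:
at a column where the two copies differ, the copy disagreeing with the
outgroup acquired the change; columns where all three differ are excluded
(unresolvable), as are columns with a gap in any of the three.

Two channels are available: ``aa`` compares the encoded proteins
(non-synonymous asymmetry); ``syn`` counts nucleotide changes inside
codons whose amino acid is identical across the triplet, so every
assigned change is synonymous by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

from . import codons as cd
from .rates import RateMatrix
from .triplets import SISTER_DS_MAX, find_sister

__all__ = [
    "BestPair", "SubstitutionAssignment", "AsymmetryResult", "MetaTestResult",
    "bidirectional_best_pairs", "assign_substitutions", "binom_symmetry_test",
    "meta_test", "run_asymmetry_screen",
]


@dataclass(frozen=True)
class BestPair:
    """Mutual-sister pair with its closest valid cousin (outgroup)."""

    family_id: str
    gene_a: str
    gene_b: str
    cousin_c: str
    dS_ab: float
    dS_ac: float
    dS_bc: float

    def __post_init__(self):
        if not (self.dS_ac > self.dS_ab and self.dS_bc > self.dS_ab):
            raise ValueError("cousin does not satisfy the outgroup inequalities")


@dataclass(frozen=True)
class SubstitutionAssignment:
    """Parsimony-assigned substitution counts for one pair.

    x1/x2 are the counts assigned to gene_a/gene_b; ``excluded_all_differ``
    counts columns where all three sequences disagree, ``excluded_gap``
    columns with a gap in any of the three.
    """

    x1: int
    x2: int
    excluded_all_differ: int
    excluded_gap: int
    channel: str

    def __post_init__(self):
        if min(self.x1, self.x2, self.excluded_all_differ, self.excluded_gap) < 0:
            raise ValueError("negative count")

    @property
    def y(self) -> int:
        return self.x1 + self.x2


@dataclass(frozen=True)
class AsymmetryResult:
    pair: BestPair
    assignment: SubstitutionAssignment
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class MetaTestResult:
    n_pairs: int
    n_asymmetric: int
    p_asym: float
    p_value: float


def bidirectional_best_pairs(matrix: RateMatrix,
                             ds_min: float = 0.01,
                             ds_max: float = SISTER_DS_MAX) -> list[BestPair]:
    """All mutual-sister pairs of one family with their closest cousin.

    The cousin minimizes dS(a,c) + dS(b,c) subject to both outgroup
    inequalities (and dS <= ds_max, unsaturated); equal sums break toward
    the lexicographically smaller id.  Pairs without any valid cousin are
    dropped.  A gene's sister is unique, so each gene appears in at most
    one pair.
    """
    pairs = []
    for a in matrix.ids:
        b = find_sister(a, matrix, ds_min, ds_max)
        if b is None or b <= a:
            continue  # emit each unordered pair once, from its smaller id
        if find_sister(b, matrix, ds_min, ds_max) != a:
            continue
        ds_ab = matrix.ds(a, b)
        best = None
        for k in matrix.ids:
            if k in (a, b):
                continue
            if matrix.saturated(a, k) or matrix.saturated(b, k):
                continue
            ds_ac, ds_bc = matrix.ds(a, k), matrix.ds(b, k)
            if ds_ac > ds_max or ds_bc > ds_max:
                continue
            if ds_ac > ds_ab and ds_bc > ds_ab:
                key = (ds_ac + ds_bc, k)
                if best is None or key < best:
                    best = key
        if best is None:
            continue
        c = best[1]
        pairs.append(BestPair(matrix.family_id, a, b, c, ds_ab,
                              matrix.ds(a, c), matrix.ds(b, c)))
    return pairs


def _aa_columns(seq: str) -> list[str]:
    """Aligned nucleotide row -> aligned aa row (gap codon -> '-',
    part-gap or ambiguous codon -> '?')."""
    out = []
    for k in range(0, len(seq), 3):
        codon = seq[k:k + 3].upper()
        if codon == "---":
            out.append("-")
        elif set(codon) <= set("ACGT"):
            out.append(str(cd.AMINO_ACIDS[cd.CODON_INDEX[codon]]))
        else:
            out.append("?")
    return out


def assign_substitutions(seq_a: str, seq_b: str, seq_c: str,
                         channel: str = "aa") -> SubstitutionAssignment:
    """Outgroup-parsimony substitution counts for an aligned triplet.

    Per divergent column: a != b with b == c assigns the change to a
    (x1 += 1); a != b with a == c assigns it to b (x2 += 1); a, b, c all
    distinct is excluded as unresolvable; a == b contributes nothing.
    Columns with a gap in any sequence are excluded and tallied
    separately.

    ``channel='aa'`` applies the rule to translated columns.
    ``channel='syn'`` applies it to nucleotide columns restricted to
    codons whose translations are identical across the triplet.
    """
    if not len(seq_a) == len(seq_b) == len(seq_c):
        raise ValueError("aligned triplet rows differ in length")
    if channel not in ("aa", "syn"):
        raise ValueError(f"unknown channel {channel!r}")
    if len(seq_a) % 3:
        raise ValueError("aligned length is not a multiple of 3")

    x1 = x2 = all_differ = gap = 0

    def classify(a: str, b: str, c: str):
        nonlocal x1, x2, all_differ
        if a == b:
            return
        if b == c:
            x1 += 1
        elif a == c:
            x2 += 1
        else:
            all_differ += 1

    aas = [_aa_columns(s) for s in (seq_a, seq_b, seq_c)]
    if channel == "aa":
        for a, b, c in zip(*aas):
            if "-" in (a, b, c) or "?" in (a, b, c):
                gap += 1
                continue
            classify(a, b, c)
    else:
        for k, (a, b, c) in enumerate(zip(*aas)):
            if "-" in (a, b, c) or "?" in (a, b, c):
                gap += 3
                continue
            if not a == b == c:
                continue  # aa not conserved: outside the synonymous channel
            for off in range(3):
                pos = 3 * k + off
                classify(seq_a[pos], seq_b[pos], seq_c[pos])
    return SubstitutionAssignment(x1, x2, all_differ, gap, channel)


def binom_symmetry_test(x1: int, x2: int, sided: str = "two") -> float:
    """Exact binomial test of x1 successes in x1+x2 trials at p = 1/2.

    Two-sided doubles the smaller tail (capped at 1); ``sided='one'``
    returns the smaller tail.  p = 1 when there are no substitutions.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("negative substitution counts")
    if sided not in ("two", "one"):
        raise ValueError(f"unknown sidedness {sided!r}")
    n = x1 + x2
    if n == 0:
        return 1.0
    lower = float(binom.cdf(min(x1, x2), n, 0.5))
    if sided == "one":
        return lower
    return min(1.0, 2.0 * lower)


def meta_test(n_asymmetric: int, n_pairs: int, p_asym: float = 0.05) -> float:
    """Exact upper tail P(X >= n_asymmetric | n_pairs, p_asym).

    Direct log-space summation of binomial terms (no normal
    approximation); numerically exact far into the tail.
    """
    if not 0 < p_asym < 1:
        raise ValueError("p_asym must lie strictly inside (0, 1)")
    if not 0 <= n_asymmetric <= n_pairs:
        raise ValueError("need 0 <= n_asymmetric <= n_pairs")
    if n_asymmetric == 0:
        return 1.0
    k = np.arange(n_asymmetric, n_pairs + 1)
    log_terms = (gammaln(n_pairs + 1) - gammaln(k + 1) - gammaln(n_pairs - k + 1)
                 + k * math.log(p_asym) + (n_pairs - k) * math.log1p(-p_asym))
    m = log_terms.max()
    return float(min(1.0, math.exp(m) * np.exp(log_terms - m).sum()))


def run_asymmetry_screen(matrices: Sequence[RateMatrix],
                         alignments: Mapping[str, Mapping[str, str]],
                         alpha: float = 0.05, channel: str = "aa",
                         sided: str = "two", p_asym: float = 0.05
                         ) -> tuple[list[AsymmetryResult], MetaTestResult]:
    """Screen every family: best pairs -> assignment -> per-pair exact test
    -> genome-scale meta-test.

    ``alignments`` maps family_id -> {gene id -> aligned sequence}.
    """
    results: list[AsymmetryResult] = []
    for matrix in matrices:
        aln = alignments[matrix.family_id]
        for pair in bidirectional_best_pairs(matrix):
            assignment = assign_substitutions(
                aln[pair.gene_a], aln[pair.gene_b], aln[pair.cousin_c], channel)
            p = binom_symmetry_test(assignment.x1, assignment.x2, sided)
            results.append(AsymmetryResult(pair, assignment, p, alpha))
    n_sig = sum(r.significant for r in results)
    meta = MetaTestResult(len(results), n_sig, p_asym,
                          meta_test(n_sig, len(results), p_asym)
                          if results else 1.0)
    return results, meta


def results_frame(results: Sequence[AsymmetryResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "family": r.pair.family_id, "gene_a": r.pair.gene_a,
            "gene_b": r.pair.gene_b, "cousin": r.pair.cousin_c,
            "dS_ab": r.pair.dS_ab, "x1": r.assignment.x1, "x2": r.assignment.x2,
            "excluded_all_differ": r.assignment.excluded_all_differ,
            "excluded_gap": r.assignment.excluded_gap,
            "channel": r.assignment.channel, "p_value": r.p_value,
            "significant": r.significant,
        })
    return pd.DataFrame(rows)
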