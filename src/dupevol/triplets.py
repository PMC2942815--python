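"""Sister/cousin selection and individual per-gene dN/dS rates.

For a gene i, its *sister* j is the closest family member by dS within the
comparison window 0.01 <= dS <= 3 (closer neighbours are skipped as likely
alleles/identical duplicates); a *cousin* k is a valid outgroup when
dS(i,k) > dS(i,j) and dS(j,k) > dS(i,j).  With those three pairwise
distances the substitutions on i's own post-duplication branch follow from
the additive three-point decomposition

    dX_I(i) = (dX(i,j) + dX(i,k) - dX(j,k)) / 2,      X in {N, S}

so dX_I(i) + dX_I(j) = dX(i,j) holds exactly whenever i and j are each
other's sisters sharing a cousin.  Negative individual rates (noise makes
the triangle non-additive) are kept but flagged; the downstream window
filter 0.005 <= dS_I <= 0.6 removes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .rates import RateMatrix

__all__ = ["TripletRates", "find_sister", "find_cousin", "individual_rates",
           "build_triplets", "rate_window_filter"]

SISTER_DS_MIN = 0.01
SISTER_DS_MAX = 3.0
WINDOW_LO = 0.005
WINDOW_HI = 0.6


@dataclass(frozen=True)
class TripletRates:
    """One gene with its sister, cousin, the six pairwise distances and the
    derived individual rates."""

    family_id: str
    gene_i: str
    sister_j: str
    cousin_k: str
    dS_ij: float
    dS_ik: float
    dS_jk: float
    dN_ij: float
    dN_ik: float
    dN_jk: float
    dS_I: float
    dN_I: float
    nonadditive: bool

    @property
    def omega_I(self) -> float:
        """dN_I / dS_I; NaN when dS_I <= 0."""
        if self.dS_I <= 0:
            return float("nan")
        return self.dN_I / self.dS_I


def find_sister(gene_i: str, matrix: RateMatrix,
                ds_min: float = SISTER_DS_MIN,
                ds_max: float = SISTER_DS_MAX) -> str | None:
    """Closest family member by dS within [ds_min, ds_max].

    Saturated pairs are excluded (treated as dS > 3); neighbours closer
    than ds_min are skipped — by taking the minimum over the in-window
    candidates, arbitrarily many too-close neighbours are passed over.
    Ties break toward the lexicographically smaller id.
    """
    best = None
    for g in matrix.ids:
        if g == gene_i or matrix.saturated(gene_i, g):
            continue
        ds = matrix.ds(gene_i, g)
        if not ds_min <= ds <= ds_max:
            continue
        if best is None or (ds, g) < best:
            best = (ds, g)
    return best[1] if best else None


def find_cousin(gene_i: str, sister_j: str, matrix: RateMatrix,
                ds_max: float = SISTER_DS_MAX) -> str | None:
    """Closest valid outgroup for the pair (i, j).

    Candidates must satisfy dS(i,k) > dS(i,j) and dS(j,k) > dS(i,j) with
    both distances unsaturated and <= ds_max; the candidate minimizing
    dS(i,k) wins, ties toward the smaller id.
    """
    ds_ij = matrix.ds(gene_i, sister_j)
    best = None
    for k in matrix.ids:
        if k in (gene_i, sister_j):
            continue
        if matrix.saturated(gene_i, k) or matrix.saturated(sister_j, k):
            continue
        ds_ik, ds_jk = matrix.ds(gene_i, k), matrix.ds(sister_j, k)
        if ds_ik > ds_max or ds_jk > ds_max:
            continue
        if ds_ik > ds_ij and ds_jk > ds_ij:
            if best is None or (ds_ik, k) < best:
                best = (ds_ik, k)
    return best[1] if best else None


def individual_rates(d_ij: float, d_ik: float, d_jk: float) -> float:
    """Three-point decomposition: the distance on i's own branch."""
    return (d_ik + d_ij - d_jk) / 2.0


def build_triplets(matrix: RateMatrix,
                   ds_min: float = SISTER_DS_MIN,
                   ds_max: float = SISTER_DS_MAX) -> list[TripletRates]:
    """Per-gene triplets for one family; genes without an in-window sister
    or a valid cousin are silently not emitted."""
    out = []
    for gene in matrix.ids:
        sister = find_sister(gene, matrix, ds_min, ds_max)
        if sister is None:
            continue
        cousin = find_cousin(gene, sister, matrix, ds_max)
        if cousin is None:
            continue
        ds_ij, ds_ik, ds_jk = (matrix.ds(gene, sister), matrix.ds(gene, cousin),
                               matrix.ds(sister, cousin))
        dn_ij, dn_ik, dn_jk = (matrix.dn(gene, sister), matrix.dn(gene, cousin),
                               matrix.dn(sister, cousin))
        ds_i = individual_rates(ds_ij, ds_ik, ds_jk)
        dn_i = individual_rates(dn_ij, dn_ik, dn_jk)
        assert ds_ik > ds_ij and ds_jk > ds_ij, "cousin inequalities violated"
        out.append(TripletRates(matrix.family_id, gene, sister, cousin,
                                ds_ij, ds_ik, ds_jk, dn_ij, dn_ik, dn_jk,
                                ds_i, dn_i,
                                nonadditive=ds_i < 0 or dn_i < 0))
    return out


def rate_window_filter(triplets: Sequence[TripletRates],
                       lo: float = WINDOW_LO, hi: float = WINDOW_HI
                       ) -> tuple[list[TripletRates], int]:
    """Keep triplets with lo <= dS_I <= hi (both ends inclusive); returns
    (kept, n_dropped).  Negative/nonadditive dS_I fall below lo and drop."""
    kept = [t for t in triplets if lo <= t.dS_I <= hi]
    return kept, len(triplets) - len(kept)


def triplets_frame(triplets: Sequence[TripletRates]) -> pd.DataFrame:
    rows = []
    for t in triplets:
        rows.append({
            "family": t.family_id, "gene": t.gene_i, "sister": t.sister_j,
            "cousin": t.cousin_k, "dS_ij": t.dS_ij, "dS_ik": t.dS_ik,
            "dS_jk": t.dS_jk, "dN_ij": t.dN_ij, "dN_ik": t.dN_ik,
            "dN_jk": t.dN_jk, "dS_I": t.dS_I, "dN_I": t.dN_I,
            "omega_I": t.omega_I,
            "flags": "nonadditive" if t.nonadditive else "",
        })
    return pd.DataFrame(rows)
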