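"""dN/dS-versus-dS trend quantification.

The strength of purifying selection (ω = dN/dS) is regressed on dS — a
proxy for time since the duplication — by ordinary least squares, with the
95% slope confidence interval from the t distribution.  A declining slope
means young duplicates evolve under relaxed constraint that tightens with
age.  Supporting operations: the >=100-substitution robustness control
(discrete-count artifacts) and per-family averages of pairwise rates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rates import RateMatrix
from .triplets import TripletRates

__all__ = ["TrendFit", "FamilySummary", "fit_trend",
           "substitution_floor_filter", "family_summaries"]


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of ω on dS with the 95% slope CI."""

    slope: float
    intercept: float
    ci95_lo: float
    ci95_hi: float
    n: int
    subset_label: str = ""
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate and not (self.ci95_lo <= self.slope <= self.ci95_hi):
            raise ValueError("slope outside its own confidence interval")

    def covers(self, slope: float) -> bool:
        return self.ci95_lo <= slope <= self.ci95_hi

    def summary(self) -> str:
        if self.degenerate:
            return f"TrendFit[{self.subset_label}]: degenerate (all dS identical), n={self.n}"
        return (f"TrendFit[{self.subset_label}]: slope={self.slope:.4g} "
                f"(95% CI {self.ci95_lo:.4g}..{self.ci95_hi:.4g}), "
                f"intercept={self.intercept:.4g}, n={self.n}")


@dataclass(frozen=True)
class FamilySummary:
    """Average pairwise dN and dS over all member pairs of one family."""

    family_id: str
    n_genes: int
    n_pairs: int
    mean_dN: float
    mean_dS: float
    any_saturated: bool

    @property
    def family_omega(self) -> float:
        """Ratio of averages (mean dN over mean dS)."""
        if not self.mean_dS > 0:
            return float("nan")
        return self.mean_dN / self.mean_dS


def fit_trend(points: Sequence[tuple[float, float]],
              subset_label: str = "") -> TrendFit:
    """OLS of ω (second coordinate) on dS (first coordinate).

    Needs >= 3 finite points; if all dS coincide the slope is undefined and
    a degenerate fit is returned flagged.  Exactly collinear points yield
    the exact slope with a zero-width interval.
    """
    pts = [(x, y) for x, y in points if math.isfinite(x) and math.isfinite(y)]
    if len(pts) < 3:
        raise ValueError("need at least 3 finite (dS, omega) points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        return TrendFit(float("nan"), float("nan"), float("nan"), float("nan"),
                        len(pts), subset_label, degenerate=True)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = model.conf_int(alpha=0.05)[1]
    return TrendFit(float(model.params[1]), float(model.params[0]),
                    float(lo), float(hi), len(pts), subset_label)


def substitution_floor_filter(triplets: Sequence[TripletRates],
                              alignments: Mapping[str, Mapping[str, str]],
                              min_subs: int = 100
                              ) -> tuple[list[TripletRates], int]:
    """Keep genes with >= min_subs nucleotide differences to their sister
    (counted over gap-free aligned columns); inclusive at the floor."""
    kept = []
    for t in triplets:
        aln = alignments[t.family_id]
        a, b = aln[t.gene_i], aln[t.sister_j]
        subs = sum(1 for x, y in zip(a, b)
                   if x != y and x in "ACGT" and y in "ACGT")
        if subs >= min_subs:
            kept.append(t)
    return kept, len(triplets) - len(kept)


def family_summaries(matrices: Sequence[RateMatrix]) -> list[FamilySummary]:
    """Mean pairwise dN and dS per family over all unordered pairs.

    Families containing any saturated pair are flagged; their means are
    computed over the unsaturated pairs only.
    """
    out = []
    for m in matrices:
        dn, ds = [], []
        any_sat = False
        for pr in m.iter_pairs():
            if pr.saturated:
                any_sat = True
                continue
            dn.append(pr.dN)
            ds.append(pr.dS)
        out.append(FamilySummary(
            m.family_id, len(m.ids), len(dn),
            float(np.mean(dn)) if dn else float("nan"),
            float(np.mean(ds)) if ds else float("nan"),
            any_sat))
    return out


def summaries_frame(summaries: Sequence[FamilySummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "family": s.family_id, "n_genes": s.n_genes, "n_pairs": s.n_pairs,
        "mean_dN": s.mean_dN, "mean_dS": s.mean_dS,
        "family_omega": s.family_omega, "any_saturated": s.any_saturated,
    } for s in summaries])


def mean_of_ratios(matrix: RateMatrix) -> float:
    """Alternative family ω: average of per-pair dN/dS (behind a flag; the
    default family ω is the ratio of averages)."""
    vals = [pr.dN / pr.dS for pr in matrix.iter_pairs()
            if not pr.saturated and pr.dS > 0]
    return float(np.mean(vals)) if vals else float("nan")
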