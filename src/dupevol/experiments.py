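"""Monte-Carlo calibration experiments on the simulator.

These drive the full analysis machinery (simulate -> NG86 rate matrix ->
best-pair selection -> parsimony assignment -> exact test / triplet
decomposition / trend fit) over replicate simulated families, and back the
package's statistical validation: type-I calibration and power of the
asymmetry screen, unbiasedness of the individual-rate decomposition, and
confidence-interval coverage of the trend fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import asymmetry as asym
from . import trends
from . import triplets as trip
from .rates import rate_matrix
from .simulate import duplication_scenario
from .trends import fit_trend


def screen_simulated_pair(pair_depth: float = 0.05, outgroup_depth: float = 0.5,
                          omega: float = 0.3, accel_factor: float = 1.0,
                          n_codons: int = 1000, seed: int = 0,
                          channel: str = "aa", alpha: float = 0.05
                          ) -> asym.AsymmetryResult | None:
    """One simulated duplication put through the complete asymmetry path.

    Returns None when the realized distances yield no bidirectional best
    pair with a valid cousin (rare at the default depths).
    """
    truth = duplication_scenario(pair_depth, outgroup_depth, omega,
                                 accel_factor, n_codons, seed)
    matrix = rate_matrix(truth.alignment, f"sim{seed}")
    pairs = asym.bidirectional_best_pairs(matrix)
    if not pairs:
        return None
    pair = pairs[0]
    aln = truth.alignment
    assignment = asym.assign_substitutions(aln[pair.gene_a], aln[pair.gene_b],
                                           aln[pair.cousin_c], channel)
    p = asym.binom_symmetry_test(assignment.x1, assignment.x2)
    return asym.AsymmetryResult(pair, assignment, p, alpha)


def rejection_rate(n_reps: int, accel_factor: float = 1.0, seed0: int = 0,
                   alpha: float = 0.05, **kwargs) -> tuple[float, int]:
    """Fraction of simulated pairs flagged asymmetric at ``alpha``.

    Returns (rate, n_tested); replicates without a testable pair are
    excluded from the denominator.
    """
    hits = tested = 0
    for r in range(n_reps):
        res = screen_simulated_pair(accel_factor=accel_factor,
                                    seed=seed0 + r, alpha=alpha, **kwargs)
        if res is None:
            continue
        tested += 1
        hits += res.significant
    return (hits / tested if tested else float("nan")), tested


def triplet_recovery(n_reps: int = 200, pair_depth: float = 0.05,
                     outgroup_depth: float = 0.5, omega: float = 0.3,
                     n_codons: int = 1000, seed0: int = 0) -> np.ndarray:
    """Individual dS_I estimates of gene i over replicates (truth:
    ``pair_depth``)."""
    out = []
    for r in range(n_reps):
        truth = duplication_scenario(pair_depth, outgroup_depth, omega,
                                     1.0, n_codons, seed0 + r)
        matrix = rate_matrix(truth.alignment, f"rep{r}")
        for t in trip.build_triplets(matrix):
            if t.gene_i == "i":
                out.append(t.dS_I)
    return np.array(out)


@dataclass(frozen=True)
class TrendReplicate:
    fit: trends.TrendFit
    true_slope: float
    true_intercept: float

    @property
    def covered(self) -> bool:
        return self.fit.covers(self.true_slope)


def trend_replicate(seed: int, depths: np.ndarray | None = None,
                    slope: float = -0.6, intercept: float = 0.5,
                    outgroup_extra: float = 0.4,
                    n_codons: int = 1500) -> TrendReplicate:
    """One replicate of the trend-recovery experiment.

    Families are simulated on a depth grid with the linear selection rule
    ω(depth) = intercept + slope * depth; the OLS fit of the realized
    (dS_I, ω_I) points is returned with the generating truth.
    """
    if depths is None:
        depths = np.linspace(0.05, 0.5, 12)
    points = []
    for k, d in enumerate(depths):
        omega = intercept + slope * d
        if omega <= 0:
            raise ValueError("selection rule leaves omega non-positive")
        truth = duplication_scenario(float(d), float(d) + outgroup_extra,
                                     omega, 1.0, n_codons,
                                     seed=seed * 1000 + k)
        matrix = rate_matrix(truth.alignment, f"d{k}")
        triplets, _ = trip.rate_window_filter(trip.build_triplets(matrix))
        for t in triplets:
            if t.gene_i == "i" and t.dS_I > 0:
                points.append((t.dS_I, t.omega_I))
    fit = fit_trend(points, subset_label=f"rep{seed}")
    return TrendReplicate(fit, slope, intercept)
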