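"""Simulator: determinism, invariants, and Monte-Carlo calibration.

The generator is calibrated in *true* substitutions: expected accepted
synonymous changes per NG86 synonymous site equal the branch length.  The
truth-level check asserts that directly from the recorded branch counts.
The estimator-level checks (mean NG86 dS across replicates) additionally
tolerate the small multiple-hit bias of the counting estimator at
moderate divergence (|bias| ~1-2% at dS 0.2-0.4), so their band is
max(3 SE, 5% of the target).
"""

import numpy as np
import pytest

from dupevol import codons as cd
from dupevol.rates import pairwise_rates, rate_matrix
from dupevol.simulate import (FamilyTruth, SimConfig, duplication_scenario,
                              simulate_family)

TREE3 = "((A:0.1,B:0.1)n1:0.3,C:0.4);"


def test_reproducible_given_seed():
    cfg = SimConfig(tree=TREE3, omega=0.2, n_codons=300, seed=7)
    t1, t2 = simulate_family(cfg), simulate_family(cfg)
    assert t1.alignment == t2.alignment
    assert t1.branch_counts == t2.branch_counts
    assert t1.root_seq == t2.root_seq
    t3 = simulate_family(SimConfig(tree=TREE3, omega=0.2, n_codons=300, seed=8))
    assert t3.alignment != t1.alignment


def test_omega_zero_forbids_amino_acid_change():
    truth = simulate_family(SimConfig(tree=TREE3, omega=0.0, n_codons=500, seed=1))
    assert all(n == 0 for _, n in truth.branch_counts.values())
    prots = {cd.AMINO_ACIDS[cd.codon_indices(s)].tobytes()
             for s in truth.alignment.values()}
    assert len(prots) == 1  # all leaves encode the root protein


def test_zero_branch_lengths_copy_root():
    truth = simulate_family(SimConfig(tree="((A:0,B:0)n1:0,C:0);",
                                      omega=0.5, n_codons=200, seed=3))
    assert all(s == truth.root_seq for s in truth.alignment.values())
    assert all(c == (0, 0) for c in truth.branch_counts.values())


def test_no_stop_codons_anywhere():
    for seed in range(5):
        truth = simulate_family(SimConfig(tree=TREE3, omega=1.0,
                                          n_codons=300, seed=seed))
        for seq in list(truth.alignment.values()) + [truth.root_seq]:
            assert not cd.IS_STOP[cd.codon_indices(seq)].any()


def test_conservation_diffs_bounded_by_path_substitutions():
    truth = simulate_family(SimConfig(tree=TREE3, omega=0.6, n_codons=400, seed=11))
    root = np.array(list(truth.root_seq))
    for leaf, seq in truth.alignment.items():
        diffs = int((np.array(list(seq)) != root).sum())
        assert diffs <= truth.root_path_substitutions(leaf)


def test_explicit_root_sequence_used_and_validated():
    root = "ATGGCTAAAGTTCCAGAT"
    truth = simulate_family(SimConfig(tree="(A:0,B:0);", omega=0.3,
                                      n_codons=6, root_seq=root, seed=0))
    assert truth.alignment["A"] == root
    with pytest.raises(ValueError, match="stop"):
        SimConfig(tree="(A:0,B:0);", n_codons=2, root_seq="ATGTAA", seed=0)
    with pytest.raises(ValueError, match="length"):
        SimConfig(tree="(A:0,B:0);", n_codons=3, root_seq="ATG", seed=0)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(tree=TREE3, n_codons=0)
    with pytest.raises(ValueError):
        SimConfig(tree=TREE3, accel_factor=0.5)
    with pytest.raises(ValueError):
        simulate_family(SimConfig(tree=TREE3, omega=-0.1, n_codons=10))
    with pytest.raises(ValueError, match="accel_branch"):
        simulate_family(SimConfig(tree=TREE3, accel_branch="nope", n_codons=10))
    with pytest.raises(ValueError, match="negative"):
        simulate_family(SimConfig(tree="(A:-0.1,B:0.1);", n_codons=10))


def test_duplication_scenario_validation():
    with pytest.raises(ValueError, match="outgroup"):
        duplication_scenario(0.5, 0.5)
    truth = duplication_scenario(0.05, 0.5, seed=2)
    assert set(truth.alignment) == {"i", "j", "k"}
    assert truth.branch_lengths["i"] == 0.05
    assert truth.branch_lengths["k"] == 0.5


def test_truth_level_synonymous_calibration():
    """Realized syn substitutions per entry syn site match branch length."""
    ratios = []
    for seed in range(60):
        truth = simulate_family(SimConfig(tree=TREE3, omega=0.2,
                                          n_codons=2000, seed=seed))
        for b, t in truth.branch_lengths.items():
            syn, _ = truth.branch_counts[b]
            ratios.append(syn / truth.branch_syn_sites[b] / t)
    ratios = np.array(ratios)
    se = ratios.std(ddof=1) / np.sqrt(len(ratios))
    assert abs(ratios.mean() - 1.0) < max(3 * se, 0.01)


def test_mean_ng86_ds_matches_tree_distance():
    """A/B are 0.2 apart on the tree; the replicate-mean NG86 dS agrees
    within max(3 SE, 5%) (the slack covers known estimator bias)."""
    ds = []
    for seed in range(200):
        truth = simulate_family(SimConfig(tree=TREE3, omega=0.2,
                                          n_codons=2000, seed=seed))
        ds.append(pairwise_rates(truth.alignment["A"], truth.alignment["B"]).dS)
    ds = np.array(ds)
    se = ds.std(ddof=1) / np.sqrt(len(ds))
    assert abs(ds.mean() - 0.2) < max(3 * se, 0.05 * 0.2)


def test_mean_pairwise_ds_of_duplication_pair():
    """pair_depth 0.2 on both branches -> dS(i,j) targets 0.4."""
    ds = []
    for seed in range(200):
        truth = duplication_scenario(0.2, 0.8, omega=0.25, n_codons=5000,
                                     seed=seed)
        ds.append(pairwise_rates(truth.alignment["i"], truth.alignment["j"]).dS)
    ds = np.array(ds)
    se = ds.std(ddof=1) / np.sqrt(len(ds))
    assert abs(ds.mean() - 0.4) < max(3 * se, 0.05 * 0.4)


def test_neutral_ratio_approaches_one():
    """omega=1: realized per-site non-synonymous rate matches synonymous."""
    ratios = []
    for seed in range(30):
        truth = simulate_family(SimConfig(tree="(A:0.4,B:0.4);", omega=1.0,
                                          n_codons=3000, seed=seed))
        for b in ("A", "B"):
            syn, nonsyn = truth.branch_counts[b]
            entry = truth.branch_syn_sites[b]
            n_sites = 3 * 3000 - entry
            ratios.append((nonsyn / n_sites) / (syn / entry))
    ratios = np.array(ratios)
    se = ratios.std(ddof=1) / np.sqrt(len(ratios))
    assert abs(ratios.mean() - 1.0) < max(3 * se, 0.03)


def test_omega_above_one_supported():
    """The thinning scheme keeps the synonymous clock while dN/dS > 1."""
    ratios = []
    for seed in range(25):
        truth = simulate_family(SimConfig(tree="(A:0.25,B:0.25);", omega=2.0,
                                          n_codons=3000, seed=seed))
        for b in ("A", "B"):
            syn, nonsyn = truth.branch_counts[b]
            entry = truth.branch_syn_sites[b]
            n_sites = 3 * 3000 - entry
            ratios.append((nonsyn / n_sites) / (syn / entry))
    ratios = np.array(ratios)
    se = ratios.std(ddof=1) / np.sqrt(len(ratios))
    assert abs(ratios.mean() - 2.0) < max(3 * se, 0.1)


def test_symmetric_scenario_counts_exchangeable():
    """accel=1: substitution totals of i and j have a common mean."""
    deltas = []
    for seed in range(80):
        truth = duplication_scenario(0.1, 0.5, omega=0.4, n_codons=500,
                                     seed=seed)
        ci, cj = truth.branch_counts["i"], truth.branch_counts["j"]
        deltas.append(sum(ci) - sum(cj))
    deltas = np.array(deltas)
    se = deltas.std(ddof=1) / np.sqrt(len(deltas))
    assert abs(deltas.mean()) < 3 * se + 1e-9


def test_accelerated_branch_recorded_in_truth(small_truth):
    assert isinstance(small_truth, FamilyTruth)
    accel = duplication_scenario(0.1, 0.5, omega=0.3, accel_factor=5.0,
                                 n_codons=600, seed=42)
    assert accel.branch_omegas["i"] == pytest.approx(1.5)
    assert accel.branch_omegas["j"] == pytest.approx(0.3)
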