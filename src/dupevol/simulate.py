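"""Codon-level gene-family simulator with truth-labelled branch counts.

The generator evolves an in-frame coding sequence down a rooted tree whose
branch lengths are expressed in expected synonymous substitutions per
synonymous site (the dS scale used throughout the package).  Selection is
implemented by acceptance–rejection: candidate single-nucleotide changes
arise uniformly over the sequence; synonymous candidates are always
accepted, non-synonymous candidates are accepted with probability ω for
the branch (times an optional acceleration factor on exactly one branch —
the planted asymmetry signal), and candidates creating a stop codon are
rejected without consuming branch length.  The candidate rate is
recalibrated every 0.05 substitution units from the current sequence so
that the expected number of accepted synonymous changes per NG86
synonymous site equals the branch length.

ω (or ω·accel) above 1 is supported by boosting the candidate rate and
thinning synonymous acceptances, so the synonymous clock stays calibrated
while the non-synonymous rate exceeds it.

The mutation process is deliberately minimal: uniform base exchange (no
transition/transversion bias), no indels, no site-to-site rate
heterogeneity, standard genetic code only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np

from . import codons as cd

__all__ = ["SimConfig", "FamilyTruth", "simulate_family", "duplication_scenario"]

_SEGMENT = 0.05  # recalibration interval, substitutions per synonymous site


def _branch_events_py(codons, pc, pw, pa, u, omega_eff, inv_m,
                      mut_target, mut_class):
    syn = 0
    nonsyn = 0
    thr_nonsyn = omega_eff * inv_m
    for i in range(pc.shape[0]):
        c = codons[pc[i]]
        cls = mut_class[c, pw[i], pa[i]]
        if cls == 2:
            continue  # would create a stop: rejected, branch length intact
        if cls == 0:
            if u[i] < inv_m:
                codons[pc[i]] = mut_target[c, pw[i], pa[i]]
                syn += 1
        else:
            if u[i] < thr_nonsyn:
                codons[pc[i]] = mut_target[c, pw[i], pa[i]]
                nonsyn += 1
    return syn, nonsyn


try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _branch_events = njit(cache=False)(_branch_events_py)
except Exception:  # pragma: no cover
    _branch_events = _branch_events_py


@dataclass(frozen=True)
class SimConfig:
    """Stated world for one simulated family.

    Parameters
    ----------
    tree : str
        Rooted newick with named leaves and branch lengths in expected
        synonymous substitutions per synonymous site.  Branches are
        identified by their child node: leaf labels for terminal branches,
        internal-node labels (or auto-assigned ``n1, n2, ...`` in preorder)
        for internal ones.
    omega : float or mapping
        dN/dS target; a scalar applies to every branch, a mapping must
        name every branch.
    accel_branch, accel_factor :
        Optional branch whose non-synonymous acceptance rate is multiplied
        by ``accel_factor`` (>= 1).
    n_codons : int
        Root sequence length in codons.
    root_seq : str or None
        Explicit root coding sequence (no stops, length ``3 * n_codons``);
        default draws codons uniformly from the 61 sense codons.
    seed : int
        Single seeded stream for the family; recorded in the truth object.
    """

    tree: str
    omega: float | Mapping[str, float] = 0.3
    accel_branch: str | None = None
    accel_factor: float = 1.0
    n_codons: int = 1000
    root_seq: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.accel_factor < 1.0:
            raise ValueError("accel_factor must be >= 1")
        if isinstance(self.omega, (int, float)) and self.omega < 0:
            raise ValueError("omega must be non-negative")
        if self.root_seq is not None:
            idx = cd.codon_indices(self.root_seq)
            if idx.size != self.n_codons:
                raise ValueError("root_seq length must equal 3 * n_codons")
            if cd.IS_STOP[idx].any():
                raise ValueError("root_seq contains a stop codon")


@dataclass(frozen=True)
class FamilyTruth:
    """Simulator output: alignment plus per-branch ground truth.

    ``branch_counts`` maps branch name -> (synonymous, non-synonymous)
    realized accepted substitution counts; ``branch_syn_sites`` records the
    NG86 synonymous site count of the sequence entering each branch (the
    denominator of the calibration), so realized per-site synonymous
    divergence of a branch is ``counts[0] / branch_syn_sites``.
    """

    alignment: dict[str, str]
    tree: str
    branch_lengths: dict[str, float]
    branch_omegas: dict[str, float]
    branch_counts: dict[str, tuple[int, int]]
    branch_syn_sites: dict[str, float]
    root_seq: str
    config: SimConfig

    def sequences(self):
        from .rates import CodonSequence

        return [CodonSequence(name, seq) for name, seq in self.alignment.items()]

    def root_path_substitutions(self, leaf: str, tree_obj=None) -> int:
        """Total accepted substitutions on the root-to-leaf path."""
        tree = tree_obj or _parse_tree(self.tree)
        for node in tree.leaf_node_iter():
            if node.taxon.label == leaf:
                total = 0
                while node.parent_node is not None:
                    name = node._dupevol_name
                    s, n = self.branch_counts[name]
                    total += s + n
                    node = node.parent_node
                return total
        raise KeyError(leaf)


def _parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=False)
    counter = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._dupevol_name = "root"
            continue
        if node.is_leaf():
            name = node.taxon.label if node.taxon else None
        else:
            name = node.taxon.label if node.taxon else node.label
        if not name:
            counter += 1
            name = f"n{counter}"
        node._dupevol_name = name
        if node.edge.length is None:
            raise ValueError(f"branch to {name!r} has no length")
        if node.edge.length < 0:
            raise ValueError(f"branch to {name!r} has negative length")
    names = [n._dupevol_name for n in tree.preorder_node_iter()
             if n.parent_node is not None]
    if len(set(names)) != len(names):
        raise ValueError("branch names are not unique")
    return tree


def _evolve_branch(codons: np.ndarray, t: float, omega_eff: float,
                   rng: np.random.Generator) -> tuple[int, int, float]:
    """Evolve ``codons`` in place for branch length t; return realized
    (syn, nonsyn) counts and the syn-site count at branch entry."""
    L = codons.size
    entry_sites = float(cd.SYN_SITES[codons].sum())
    syn_total = nonsyn_total = 0
    remaining = t
    while remaining > 1e-12:
        dt = min(_SEGMENT, remaining)
        remaining -= dt
        s_sites = float(cd.SYN_SITES[codons].sum())
        s_changes = float(cd.SYN_CHANGE_COUNT[codons].sum())
        if s_changes <= 0:
            raise ValueError("sequence has no synonymous mutational "
                             "opportunity; branch length is uncalibratable")
        m = max(1.0, omega_eff)
        lam = 9.0 * L * dt * s_sites / s_changes * m
        n_events = int(rng.poisson(lam))
        if n_events == 0:
            continue
        pc = rng.integers(0, L, n_events)
        pw = rng.integers(0, 3, n_events)
        pa = rng.integers(0, 3, n_events)
        u = rng.random(n_events)
        syn, nonsyn = _branch_events(codons, pc, pw, pa, u, omega_eff,
                                     1.0 / m, cd.MUT_TARGET, cd.MUT_CLASS)
        syn_total += int(syn)
        nonsyn_total += int(nonsyn)
    return syn_total, nonsyn_total, entry_sites


def simulate_family(config: SimConfig) -> FamilyTruth:
    """Evolve one family root-to-leaves under ``config``.

    Deterministic given the seed.  Every accepted change increments the
    (syn, nonsyn) bucket of its branch; rejected stop-producing candidates
    consume nothing.  No intermediate or leaf sequence ever contains a
    stop codon.
    """
    tree = _parse_tree(config.tree)
    rng = np.random.default_rng(config.seed)

    branch_names = [n._dupevol_name for n in tree.preorder_node_iter()
                    if n.parent_node is not None]
    if config.accel_branch is not None and config.accel_branch not in branch_names:
        raise ValueError(f"accel_branch {config.accel_branch!r} not in tree "
                         f"(branches: {branch_names})")

    if isinstance(config.omega, Mapping):
        missing = set(branch_names) - set(config.omega)
        if missing:
            raise ValueError(f"omega mapping missing branches: {sorted(missing)}")
        omegas = {b: float(config.omega[b]) for b in branch_names}
    else:
        omegas = {b: float(config.omega) for b in branch_names}
    if any(w < 0 for w in omegas.values()):
        raise ValueError("omega must be non-negative")
    eff_omegas = dict(omegas)
    if config.accel_branch is not None:
        eff_omegas[config.accel_branch] *= config.accel_factor

    if config.root_seq is not None:
        root = cd.codon_indices(config.root_seq)
    else:
        root = rng.choice(np.array(cd.SENSE_CODONS), size=config.n_codons)
    root = root.astype(np.int64)

    alignment: dict[str, str] = {}
    branch_counts: dict[str, tuple[int, int]] = {}
    branch_sites: dict[str, float] = {}
    seqs = {id(tree.seed_node): root}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        name = node._dupevol_name
        seq = seqs[id(node.parent_node)].copy()
        syn, nonsyn, entry = _evolve_branch(seq, node.edge.length,
                                            eff_omegas[name], rng)
        branch_counts[name] = (syn, nonsyn)
        branch_sites[name] = entry
        if node.is_leaf():
            alignment[name] = cd.codons_to_seq(seq)
        else:
            seqs[id(node)] = seq

    if any(cd.IS_STOP[cd.codon_indices(s)].any() for s in alignment.values()):
        raise AssertionError("stop codon leaked into a leaf sequence")

    lengths = {n._dupevol_name: n.edge.length for n in tree.preorder_node_iter()
               if n.parent_node is not None}
    return FamilyTruth(alignment=alignment, tree=config.tree,
                       branch_lengths=lengths, branch_omegas=eff_omegas,
                       branch_counts=branch_counts, branch_syn_sites=branch_sites,
                       root_seq=cd.codons_to_seq(root), config=config)


def duplication_scenario(pair_depth: float, outgroup_depth: float,
                         omega: float = 0.3, accel_factor: float = 1.0,
                         n_codons: int = 1000, seed: int = 0) -> FamilyTruth:
    """Three-gene family: a recent duplication pair (i, j) plus an
    outgroup paralog k.

    ``pair_depth`` is the post-duplication branch length of i and j,
    ``outgroup_depth`` the depth of the split from k (both on the dS
    scale, from the root).  ``accel_factor`` multiplies the
    non-synonymous rate of i's post-duplication branch only — with
    ``accel_factor == 1`` the two copies are exchangeable in distribution.
    """
    if not 0 < pair_depth < outgroup_depth:
        raise ValueError("need 0 < pair_depth < outgroup_depth for the "
                         "cousin to be a valid outgroup")
    newick = (f"((i:{pair_depth},j:{pair_depth})anc:"
              f"{outgroup_depth - pair_depth},k:{outgroup_depth});")
    config = SimConfig(tree=newick, omega=omega, accel_branch="i",
                       accel_factor=accel_factor, n_codons=n_codons, seed=seed)
    return simulate_family(config)
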