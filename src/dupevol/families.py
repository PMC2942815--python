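"""Paralogous-family construction: identity linking, single-linkage
clustering, codon-aware alignment and the family QC filters.

The original genome-scale discovery stack (repeat masking + discontiguous
megablast) is replaced by direct global protein alignment of the provided
coding sequences; the linking thresholds (>=75% identity over >20% of the
average length), single-linkage clustering, the 25–98% family identity
window, the 80% single-gene divergence cut and the >=3-member rule are
applied exactly.

Alignment is center-star progressive alignment on amino-acid translations,
back-projected to codons — adequate for the recently duplicated, largely
colinear families this package targets; it does not attempt the quality of
a general-purpose MSA tool on deeply diverged or shuffled inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import codons as cd
from .rates import CodonSequence

__all__ = [
    "SimilarityLink", "GeneFamily", "pairwise_similarity",
    "single_linkage_cluster", "align_family", "filter_family",
    "build_families",
]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


@dataclass(frozen=True)
class SimilarityLink:
    """Identity/coverage of one unordered gene pair, from a global protein
    alignment back-projected to nucleotides."""

    id_a: str
    id_b: str
    identity_fraction: float
    coverage_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction outside [0, 1]")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction outside [0, 1]")


@dataclass(frozen=True)
class GeneFamily:
    """An accepted family: >= 3 members plus their codon alignment and QC."""

    family_id: str
    members: tuple[str, ...]
    alignment: Mapping[str, str]
    qc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.members) < 3:
            raise ValueError("gene family needs >= 3 members")
        if set(self.members) != set(self.alignment):
            raise ValueError("alignment rows do not match the member list")


def _backproject(aln, seq_a: CodonSequence, seq_b: CodonSequence):
    """Expand an aa pairwise alignment to nucleotide strings with '-' gaps."""
    aa_a, aa_b = str(aln[0]), str(aln[1])
    nt_a, nt_b = [], []
    ia = ib = 0
    for ca, cb in zip(aa_a, aa_b):
        nt_a.append("---" if ca == "-" else seq_a.seq[3 * ia:3 * ia + 3])
        nt_b.append("---" if cb == "-" else seq_b.seq[3 * ib:3 * ib + 3])
        ia += ca != "-"
        ib += cb != "-"
    return "".join(nt_a), "".join(nt_b)


def pairwise_similarity(a: CodonSequence, b: CodonSequence) -> SimilarityLink:
    """Nucleotide identity and coverage of one gene pair.

    Identity is computed over nucleotide columns where neither sequence is
    gapped, after back-projecting the first optimal global BLOSUM62 protein
    alignment; coverage is the gapless aligned span divided by the average
    sequence length.  Deterministic and symmetric (ids are ordered
    lexicographically before aligning).
    """
    if a.id > b.id:
        a, b = b, a
    aln = _aligner().align(a.translate(), b.translate())[0]
    nt_a, nt_b = _backproject(aln, a, b)
    same = span = 0
    for x, y in zip(nt_a, nt_b):
        if x != "-" and y != "-":
            span += 1
            same += x == y
    avg_len = 0.5 * (len(a.seq) + len(b.seq))
    identity = same / span if span else 0.0
    coverage = min(span / avg_len, 1.0) if avg_len else 0.0
    return SimilarityLink(a.id, b.id, identity, coverage)


def single_linkage_cluster(links: Sequence[SimilarityLink],
                           ids: Sequence[str] | None = None,
                           min_identity: float = 0.75,
                           min_coverage: float = 0.20) -> list[set[str]]:
    """Connected components of the thresholded link graph.

    A pair is linked when identity >= ``min_identity`` over coverage
    > ``min_coverage`` of the average length.  Every gene lands in exactly
    one group; singletons are returned too (and dropped later by the
    family-size rule).  Components are returned sorted by (size desc,
    smallest member id) so output is input-order free.
    """
    graph = nx.Graph()
    if ids is not None:
        graph.add_nodes_from(ids)
    for link in links:
        graph.add_nodes_from([link.id_a, link.id_b])
        if (link.identity_fraction >= min_identity
                and link.coverage_fraction > min_coverage):
            graph.add_edge(link.id_a, link.id_b)
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def align_family(seqs: Sequence[CodonSequence]) -> dict[str, str]:
    """Center-star codon-aware multiple alignment.

    The center is the sequence with the highest total pairwise protein
    alignment score; all others are aligned to it and merged on center
    coordinates (gaps in the center accumulate as union columns).  Input
    that is already of equal length is returned as-is (gap-free columns),
    which is the common case for simulated families.
    """
    if len({len(s.seq) for s in seqs}) == 1:
        return {s.id: s.seq for s in seqs}

    aligner = _aligner()
    prots = {s.id: s.translate() for s in seqs}
    score = {s.id: 0.0 for s in seqs}
    for a, b in itertools.combinations(seqs, 2):
        sc = aligner.score(prots[a.id], prots[b.id])
        score[a.id] += sc
        score[b.id] += sc
    center = max(seqs, key=lambda s: (score[s.id], s.id))
    others = [s for s in seqs if s.id != center.id]

    # per-center-residue insertion widths (in codons), position -1 = leading
    insert = {i: 0 for i in range(-1, center.n_codons)}
    rows = {}
    for s in sorted(others, key=lambda x: x.id):
        aln = aligner.align(prots[center.id], prots[s.id])[0]
        aa_c, aa_s = str(aln[0]), str(aln[1])
        cells: list[tuple[int, list[str]]] = []  # (center codon idx | -1 block)
        ic = js = 0
        pend: list[str] = []
        placed: list[tuple[int, str, list[str]]] = []
        for x, y in zip(aa_c, aa_s):
            codon = "---" if y == "-" else s.seq[3 * js:3 * js + 3]
            js += y != "-"
            if x == "-":
                pend.append(codon)
            else:
                placed.append((ic, codon, pend))
                pend = []
                ic += 1
        rows[s.id] = (placed, pend)
        # insertions hanging before center residue ic2 belong to slot ic2-1
        for ic2, _codon, pre in placed:
            if pre:
                insert[ic2 - 1] = max(insert[ic2 - 1], len(pre))
        if pend:
            insert[center.n_codons - 1] = max(insert[center.n_codons - 1], len(pend))

    def build(placed, trailing, center_row=False):
        out = []
        pre_map = {ic2: pre for ic2, _c, pre in placed}
        codon_map = {ic2: c for ic2, c, _p in placed}
        for i in range(center.n_codons):
            if i == 0:
                pre = pre_map.get(0, [])
                out.append("---" * (insert[-1] - len(pre)) + "".join(pre))
            if center_row:
                out.append(center.seq[3 * i:3 * i + 3])
            else:
                out.append(codon_map.get(i, "---"))
            if i < center.n_codons - 1:
                pre = pre_map.get(i + 1, [])
                out.append("---" * (insert[i] - len(pre)) + "".join(pre))
        tail = trailing or []
        out.append("".join(tail) + "---" * (insert[center.n_codons - 1] - len(tail)))
        return "".join(out)

    result = {center.id: build([(i, None, []) for i in range(center.n_codons)],
                               [], center_row=True)}
    for sid, (placed, pend) in rows.items():
        result[sid] = build(placed, pend)
    lengths = {len(v) for v in result.values()}
    assert len(lengths) == 1, "center-star merge produced ragged rows"
    return result


def _drop_gap_columns(alignment: Mapping[str, str]) -> dict[str, str]:
    ids = list(alignment)
    rows = [alignment[i] for i in ids]
    keep = [k for k in range(len(rows[0])) if all(r[k] != "-" for r in rows)]
    return {i: "".join(r[k] for k in keep) for i, r in zip(ids, rows)}


def _identity_stats(alignment: Mapping[str, str]):
    """(unanimous-column fraction, per-gene mean pairwise divergence) after
    gap-column removal."""
    nogap = _drop_gap_columns(alignment)
    ids = list(nogap)
    rows = [nogap[i] for i in ids]
    ncol = len(rows[0])
    if ncol == 0:
        return float("nan"), {i: float("nan") for i in ids}, 0
    arr = np.array([list(r) for r in rows])
    unanimous = float(((arr == arr[0]).all(axis=0)).mean())
    div = {}
    for i, gid in enumerate(ids):
        ds = [np.mean(arr[i] != arr[j]) for j in range(len(ids)) if j != i]
        div[gid] = float(np.mean(ds)) if ds else float("nan")
    return unanimous, div, ncol


def filter_family(group: Sequence[str], alignment: Mapping[str, str],
                  family_id: str = "family",
                  min_identity: float = 0.25, max_identity: float = 0.98,
                  max_divergence: float = 0.80, min_size: int = 3
                  ) -> GeneFamily | None:
    """Apply the family QC rules; return the accepted family or None.

    After removing gap columns: genes whose mean pairwise nucleotide
    divergence exceeds ``max_divergence`` are removed one at a time (most
    divergent first, statistics recomputed after each removal); the family
    is rejected if fewer than ``min_size`` members remain or if the
    fraction of unanimous nucleotide columns falls outside
    [``min_identity``, ``max_identity``].
    """
    if set(group) != set(alignment):
        raise ValueError("alignment rows do not match the group")
    current = {g: alignment[g] for g in sorted(group)}
    while True:
        if len(current) < min_size:
            return None
        unanimous, div, ncol = _identity_stats(current)
        worst = max(div, key=lambda g: (div[g], g))
        if div[worst] > max_divergence:
            del current[worst]
            continue
        break
    if not (min_identity <= unanimous <= max_identity):
        return None
    qc = {"identical_column_fraction": unanimous,
          "columns_after_gap_removal": float(ncol),
          "mean_pairwise_divergence": float(np.mean(list(div.values())))}
    return GeneFamily(family_id, tuple(sorted(current)), dict(current), qc)


def build_families(seqs: Sequence[CodonSequence],
                   min_link_identity: float = 0.75,
                   min_link_coverage: float = 0.20,
                   min_identity: float = 0.25, max_identity: float = 0.98,
                   max_divergence: float = 0.80, min_size: int = 3
                   ) -> tuple[list[GeneFamily], list[dict]]:
    """Full family stage: link -> cluster -> align -> filter.

    Returns accepted families plus a rejection log (one dict per dropped
    preliminary group with the rule that removed it).
    """
    by_id = {s.id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise ValueError("duplicate sequence ids in input")
    links = [pairwise_similarity(a, b)
             for a, b in itertools.combinations(sorted(seqs, key=lambda s: s.id), 2)]
    groups = single_linkage_cluster(links, ids=list(by_id),
                                    min_identity=min_link_identity,
                                    min_coverage=min_link_coverage)
    families: list[GeneFamily] = []
    rejects: list[dict] = []
    k = 0
    for group in groups:
        if len(group) < min_size:
            rejects.append({"members": sorted(group), "reason": "fewer_than_min_size"})
            continue
        k += 1
        fid = f"fam{k:04d}"
        aln = align_family([by_id[g] for g in sorted(group)])
        fam = filter_family(sorted(group), aln, family_id=fid,
                            min_identity=min_identity, max_identity=max_identity,
                            max_divergence=max_divergence, min_size=min_size)
        if fam is None:
            rejects.append({"members": sorted(group),
                            "reason": "identity_window_or_size_after_divergence_cut"})
        else:
            families.append(fam)
    return families, rejects
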