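"""Haplotype collapsing and randomized-minimum-spanning-tree networks.

Sequences (identified or cf., >= 600 unambiguous bp) are collapsed to
haplotypes: two sequences belong to one haplotype when they agree at every
jointly unambiguous site.  Because ambiguity codes make that relation
non-transitive, collapsing is greedy in a fixed order — descending effective
length, ties by specimen id — and each sequence joins the first existing
haplotype compatible with its representative.  The representative is the
longest-coverage member.

The network is the union of minimum spanning trees over the complete
haplotype graph weighted by Hamming distance (number of mutations).  MSTs are
recomputed under randomized tie-breaking until no new edge has been added for
``stable_iter`` consecutive rounds, so alternative equally parsimonious
connections all appear.  Edges carry the mutation count between their
endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .records import AlignedSeq, ValidationError

__all__ = [
    "Haplotype",
    "HaplotypeSet",
    "HaplotypeNetwork",
    "collapse_haplotypes",
    "hamming",
    "rmst_network",
]

_UNAMBIGUOUS = set("ACGT")


@dataclass
class Haplotype:
    hap_id: str
    representative: AlignedSeq
    members: list[str] = field(default_factory=list)

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeSet:
    haplotypes: list[Haplotype]

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def total_frequency(self) -> int:
        return sum(h.frequency for h in self.haplotypes)

    def member_map(self) -> dict[str, str]:
        return {m: h.hap_id for h in self.haplotypes for m in h.members}


@dataclass
class HaplotypeNetwork:
    haplotypes: HaplotypeSet
    edges: list[tuple[str, str, int]]  # (hapA, hapB, n_mutations), hapA < hapB
    n_iterations: int

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["hapA", "hapB", "n_mutations"])

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "haplotype": h.hap_id,
                    "frequency": h.frequency,
                    "members": ";".join(h.members),
                }
                for h in self.haplotypes.haplotypes
            ]
        )


def _compatible(a: str, b: str) -> bool:
    """Zero mismatches at jointly unambiguous sites."""
    for x, y in zip(a, b):
        if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS and x != y:
            return False
    return True


def hamming(a: AlignedSeq | str, b: AlignedSeq | str) -> int:
    """Number of mutations: mismatches over jointly unambiguous sites."""
    ra = a.residues if isinstance(a, AlignedSeq) else a.upper()
    rb = b.residues if isinstance(b, AlignedSeq) else b.upper()
    if len(ra) != len(rb):
        raise ValidationError("unequal column counts in hamming()")
    return sum(
        1
        for x, y in zip(ra, rb)
        if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS and x != y
    )


def collapse_haplotypes(seqs: Sequence[AlignedSeq]) -> HaplotypeSet:
    """Greedy haplotype collapse in descending-coverage order."""
    if not seqs:
        return HaplotypeSet([])
    ordered = sorted(seqs, key=lambda s: (-s.effective_length, s.specimen_id))
    haps: list[Haplotype] = []
    for s in ordered:
        for h in haps:
            if _compatible(s.residues, h.representative.residues):
                h.members.append(s.specimen_id)
                break
        else:
            haps.append(
                Haplotype(f"H{len(haps) + 1:02d}", s, [s.specimen_id])
            )
    return HaplotypeSet(haps)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _kruskal(
    n: int, edges: list[tuple[int, int, int]], order: np.ndarray
) -> set[tuple[int, int]]:
    """One MST under a given tie-breaking permutation of the edge list."""
    ranked = sorted(range(len(edges)), key=lambda k: (edges[k][2], order[k]))
    uf = _UnionFind(n)
    chosen: set[tuple[int, int]] = set()
    for k in ranked:
        i, j, _ = edges[k]
        if uf.union(i, j):
            chosen.add((min(i, j), max(i, j)))
            if len(chosen) == n - 1:
                break
    return chosen


def rmst_network(
    haps: HaplotypeSet,
    seed: int = 0,
    max_iter: int = 2000,
    stable_iter: int = 50,
) -> HaplotypeNetwork | None:
    """Randomized-MST union network; None when fewer than three haplotypes.

    Repeatedly builds an MST with ties broken by a random permutation drawn
    from the seeded generator, accumulating the union of edges; stops when
    ``stable_iter`` consecutive rounds add nothing or at ``max_iter``.
    """
    n = len(haps)
    if n < 3:
        return None
    reps = [h.representative for h in haps.haplotypes]
    edges: list[tuple[int, int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            edges.append((i, j, hamming(reps[i], reps[j])))

    rng = np.random.default_rng(seed)
    union: set[tuple[int, int]] = set()
    stable = 0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        order = rng.permutation(len(edges))
        mst = _kruskal(n, edges, order)
        before = len(union)
        union |= mst
        stable = stable + 1 if len(union) == before else 0
        if stable >= stable_iter:
            break

    dist = {(i, j): w for i, j, w in edges}
    ids = [h.hap_id for h in haps.haplotypes]
    out_edges = sorted(
        (ids[i], ids[j], dist[(i, j)]) for i, j in union
    )
    return HaplotypeNetwork(haps, out_edges, iterations)
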