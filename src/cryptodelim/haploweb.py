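"""Haploweb construction and delimitation of fields for recombination (FFRs).

A haploweb is a haplotype network augmented with connections between
haplotypes observed together in heterozygous individuals.  Because such a
co-occurrence is direct evidence of contemporaneous mating, the connected
components of the co-occurrence graph — the fields for recombination —
partition the sample into groups within which gene flow demonstrably
occurs.  Distinct FFRs in sympatry indicate reproductive isolation, i.e.
candidate cryptic species, without requiring monophyly of either group.

Identity of haplotypes treats the alignment gap ``-`` as a fifth character
state, so length variants are distinct haplotypes.  Haplotypes carried only
by homozygotes form their own components; they are reported as separate
FFRs flagged "unconnected", since co-occurrence data are simply silent
about them.

A minimum spanning network over pairwise Hamming distances is provided as a
layout backbone for visualisation; it plays no role in delimitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .geno_io import PhasedHaplotypeSet, ValidationError

__all__ = [
    "HaplotypeRecord",
    "Haploweb",
    "FFR",
    "FFRPartition",
    "catalog_haplotypes",
    "build_haploweb",
    "find_ffrs",
    "msn_edges",
    "hamming",
]


@dataclass(frozen=True)
class HaplotypeRecord:
    hap_id: str
    sequence: str
    multiplicity: int


@dataclass
class Haploweb:
    """Haplotype co-occurrence graph.

    ``graph`` nodes are haplotype IDs (attribute ``multiplicity``); an edge
    ``(h_i, h_j)`` is weighted by the number of individuals heterozygous for
    exactly that pair.  ``individual_haplotypes`` maps each individual to
    its (ordered) pair of haplotype IDs.
    """

    catalog: list[HaplotypeRecord]
    graph: nx.Graph
    individual_haplotypes: dict[str, tuple[str, str]]

    @property
    def n_heterozygotes(self) -> int:
        return sum(1 for a, b in self.individual_haplotypes.values() if a != b)


@dataclass
class FFR:
    ffr_id: str
    haplotypes: frozenset[str]
    individuals: frozenset[str]
    connected: bool  # False for homozygote-only components


@dataclass
class FFRPartition:
    ffrs: list[FFR]
    singleton_policy: str = (
        "homozygote-only haplotype groups are separate FFRs flagged unconnected"
    )

    @property
    def n_ffrs(self) -> int:
        return len(self.ffrs)

    def ffr_of_individual(self) -> dict[str, str]:
        return {
            ind: f.ffr_id for f in self.ffrs for ind in f.individuals
        }


def catalog_haplotypes(h: PhasedHaplotypeSet) -> list[HaplotypeRecord]:
    """Collapse identical sequences; IDs ``H_1, H_2, ...`` ordered by
    decreasing multiplicity, then first occurrence in the sample."""
    first_seen: dict[str, int] = {}
    order = 0
    for ind in h.individuals:
        for seq in h.sequences[ind]:
            if seq not in first_seen:
                first_seen[seq] = order
            order += 1
    mult = h.haplotype_multiplicities()
    ranked = sorted(mult, key=lambda s: (-mult[s], first_seen[s]))
    return [
        HaplotypeRecord(f"H_{i + 1}", seq, mult[seq]) for i, seq in enumerate(ranked)
    ]


def build_haploweb(h: PhasedHaplotypeSet) -> Haploweb:
    """Connect haplotypes that co-occur within heterozygous individuals."""
    catalog = catalog_haplotypes(h)
    by_seq = {rec.sequence: rec.hap_id for rec in catalog}
    graph = nx.Graph()
    for rec in catalog:
        graph.add_node(rec.hap_id, multiplicity=rec.multiplicity)
    ind_haps: dict[str, tuple[str, str]] = {}
    for ind in h.individuals:
        a, b = (by_seq[s] for s in h.sequences[ind])
        ind_haps[ind] = (a, b)
        if a != b:
            if graph.has_edge(a, b):
                graph.edges[a, b]["weight"] += 1
            else:
                graph.add_edge(a, b, weight=1)
    return Haploweb(catalog, graph, ind_haps)


def find_ffrs(w: Haploweb) -> FFRPartition:
    """Fields for recombination = connected components of the co-occurrence
    graph.  Every individual's two haplotypes lie in one component by
    construction (they are either identical or joined by that individual's
    own heterozygosity), so the individual partition is well defined."""
    components = [set(c) for c in nx.connected_components(w.graph)]
    hap_to_comp: dict[str, int] = {}
    for idx, comp in enumerate(components):
        for hap in comp:
            hap_to_comp[hap] = idx
    inds_per_comp: dict[int, set[str]] = {i: set() for i in range(len(components))}
    for ind, (a, b) in w.individual_haplotypes.items():
        ca, cb = hap_to_comp[a], hap_to_comp[b]
        assert ca == cb, "haplotype pair split across FFRs (structurally impossible)"
        inds_per_comp[ca].add(ind)

    def hap_rank(hap_id: str) -> int:
        return int(hap_id.split("_")[1])

    ordered = sorted(range(len(components)), key=lambda i: min(hap_rank(h) for h in components[i]))
    ffrs = []
    for new_id, idx in enumerate(ordered, start=1):
        comp = components[idx]
        connected = any(w.graph.degree(h) > 0 for h in comp)
        ffrs.append(
            FFR(
                f"FFR{new_id}",
                frozenset(comp),
                frozenset(inds_per_comp[idx]),
                connected,
            )
        )
    # exhaustiveness / disjointness assertions on every output
    all_haps = [h for f in ffrs for h in f.haplotypes]
    assert len(all_haps) == len(set(all_haps)) == w.graph.number_of_nodes()
    all_inds = [i for f in ffrs for i in f.individuals]
    assert len(all_inds) == len(set(all_inds)) == len(w.individual_haplotypes)
    return FFRPartition(ffrs)


def hamming(a: str, b: str) -> int:
    """Hamming distance with the gap character as a fifth state."""
    if len(a) != len(b):
        raise ValidationError("hamming: sequences must have equal aligned length")
    return sum(x != y for x, y in zip(a, b))


def msn_edges(catalog: list[HaplotypeRecord]) -> list[tuple[str, str, int]]:
    """Minimum spanning network on pairwise Hamming distances.

    Edges are processed in increasing weight classes; within a class every
    edge joining components (as they stood when the class opened) is kept,
    so all ties at the accepted weight are retained.
    """
    if len(catalog) < 2:
        raise ValidationError("msn_edges: need at least 2 haplotypes")
    ids = [rec.hap_id for rec in catalog]
    seqs = {rec.hap_id: rec.sequence for rec in catalog}
    edges = sorted(
        (hamming(seqs[a], seqs[b]), a, b)
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    )
    parent = {h: h for h in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kept: list[tuple[str, str, int]] = []
    i = 0
    while i < len(edges):
        w = edges[i][0]
        cls = []
        while i < len(edges) and edges[i][0] == w:
            cls.append(edges[i])
            i += 1
        # membership frozen at the start of the weight class
        snapshot = {h: find(h) for h in ids}
        accepted = [(a, b, w) for w, a, b in cls if snapshot[a] != snapshot[b]]
        kept.extend(accepted)
        for a, b, _ in accepted:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        if len({find(h) for h in ids}) == 1:
            break
    return kept
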