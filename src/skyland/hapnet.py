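"""Statistical-parsimony style haplotype networks for aligned mtDNA.

Sequences are screened for completeness, collapsed to unique haplotypes
(N is a wildcard; the gap character '-' is a real fifth state), and joined
into a minimum-spanning network whose edges carry substitution-step counts.
Edges longer than the parsimony connection limit are not drawn, so deeply
divergent groups can remain as separate subnetworks — exactly the situation
the limit is meant to flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import HaplotypeAlignment

__all__ = [
    "Haplotype",
    "HaplotypeNetwork",
    "completeness_screen",
    "collapse_haplotypes",
    "step_matrix",
    "build_network",
    "parsimony_limit",
    "parsimony_probability",
    "min_steps_between",
]


@dataclass
class Haplotype:
    hap_id: str
    sequence: np.ndarray  # representative (fewest Ns among members)
    members: list[str]
    pop_counts: dict[str, int]

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    haplotypes: list[Haplotype]
    graph: nx.Graph  # nodes = hap ids; edge attr "steps"
    connection_limit: int

    def table(self) -> pd.DataFrame:
        pops = sorted({p for h in self.haplotypes for p in h.pop_counts})
        rows = []
        for h in self.haplotypes:
            row = {"haplotype": h.hap_id, "frequency": h.frequency}
            for p in pops:
                row[f"n_{p}"] = h.pop_counts.get(p, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"hap_a": a, "hap_b": b, "steps": d["steps"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["hap_a", "hap_b", "steps"])


def completeness_screen(
    aln: HaplotypeAlignment, max_missing_frac: float = 0.10
) -> tuple[HaplotypeAlignment, list[str]]:
    """Drop sequences whose fraction of N strictly exceeds the threshold."""
    frac = aln.missing_fraction()
    keep = frac <= max_missing_frac
    if not keep.any():
        raise ValueError("completeness screen removed every sequence")
    dropped = [str(s) for s in aln.sample_ids[~keep]]
    return aln.take(keep), dropped


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    """Identical wherever both are called (N wildcard; '-' is a real state)."""
    defined = (a != "N") & (b != "N")
    return bool(np.all(a[defined] == b[defined]))


def collapse_haplotypes(aln: HaplotypeAlignment) -> list[Haplotype]:
    """Merge sequences into unique haplotypes.

    Sequences are processed from fewest to most Ns; each joins the first
    compatible haplotype with the fewest Ns in its representative, or founds
    a new one. Every sample lands in exactly one haplotype.
    """
    order = np.argsort(aln.missing_fraction(), kind="stable")
    haps: list[Haplotype] = []
    for i in order:
        seq = aln.sequences[i]
        candidates = [h for h in haps if _compatible(seq, h.sequence)]
        if candidates:
            target = min(candidates, key=lambda h: int((h.sequence == "N").sum()))
            target.members.append(str(aln.sample_ids[i]))
            pop = str(aln.populations[i])
            target.pop_counts[pop] = target.pop_counts.get(pop, 0) + 1
        else:
            haps.append(
                Haplotype(
                    hap_id=f"H{len(haps) + 1}",
                    sequence=seq.copy(),
                    members=[str(aln.sample_ids[i])],
                    pop_counts={str(aln.populations[i]): 1},
                )
            )
    return haps


def step_matrix(haps: list[Haplotype]) -> np.ndarray:
    """Pairwise substitution steps between haplotype representatives.

    Hamming distance over sites where neither sequence is N; the gap
    character counts as a fifth state, so base-vs-gap is one step.
    """
    k = len(haps)
    seqs = np.array([h.sequence for h in haps])
    d = np.zeros((k, k), dtype=int)
    for i in range(k):
        defined_i = seqs[i] != "N"
        for j in range(i + 1, k):
            both = defined_i & (seqs[j] != "N")
            d[i, j] = d[j, i] = int(np.sum(seqs[i][both] != seqs[j][both]))
    return d


def build_network(
    haps: list[Haplotype], dists: np.ndarray, connection_limit: int
) -> HaplotypeNetwork:
    """Minimum-spanning network under a step limit.

    Pairs are taken in order of increasing steps; an edge is added when its
    steps are within the limit and its endpoints are in components that were
    not yet connected at any strictly smaller distance. All ties at the
    joining distance are included, so the result can contain cycles
    (reticulations) among equally parsimonious connections.
    """
    if connection_limit < 1:
        raise ValueError("connection limit must be >= 1")
    g = nx.Graph()
    for h in haps:
        g.add_node(h.hap_id, frequency=h.frequency, **{
            f"n_{p}": c for p, c in h.pop_counts.items()
        })
    k = len(haps)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = [(dists[i, j], i, j) for i in range(k) for j in range(i + 1, k)]
    pairs.sort()
    levels: dict[int, list[tuple[int, int]]] = {}
    for d, i, j in pairs:
        if d <= connection_limit:
            levels.setdefault(int(d), []).append((i, j))
    for d in sorted(levels):
        added = []
        for i, j in levels[d]:
            if find(i) != find(j):
                added.append((i, j))
                g.add_edge(haps[i].hap_id, haps[j].hap_id, steps=int(d))
        for i, j in added:
            parent[find(i)] = find(j)
    return HaplotypeNetwork(haps, g, connection_limit)


def parsimony_probability(j: int, seq_length: int) -> float:
    """Probability that j observed differences are all single substitutions.

    Model: per-site substitution counts are Poisson under a Jukes-Cantor
    process whose rate is set so the expected visible-difference fraction
    matches j / seq_length. A pair of haplotypes is parsimoniously connected
    when every differing site was hit exactly once and every identical site
    not at all (no hidden multiple hits).
    """
    if j == 0:
        return 1.0
    m = seq_length
    prop = j / m
    if prop >= 0.7499:
        return 0.0
    lam = -0.75 * math.log1p(-4.0 * prop / 3.0)
    d = prop  # visible-difference probability, by construction
    p_same = 1.0 - d
    log_p = j * (math.log(lam) - lam - math.log(d)) + (m - j) * (
        -lam - math.log(p_same)
    )
    return math.exp(log_p)


def parsimony_limit(seq_length: int, alpha: float = 0.95) -> int:
    """Largest step count with parsimonious-connection probability >= alpha.

    This is the statistical-parsimony connection limit: haplotype pairs more
    steps apart than this are not joined (at confidence ``alpha``). Always
    at least 1.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    j = 0
    while parsimony_probability(j + 1, seq_length) >= alpha:
        j += 1
        if j >= seq_length:
            break
    return max(j, 1)


def min_steps_between(
    net: HaplotypeNetwork, pop_a: str, pop_b: str
) -> float:
    """Minimum step count linking a haplotype carrying pop_a to one carrying pop_b.

    Uses shortest paths (summed edge steps) through the network; if no pair
    is connected within the network, falls back to the direct pairwise step
    distance between representatives.
    """
    nodes_a = [h.hap_id for h in net.haplotypes if h.pop_counts.get(pop_a, 0) > 0]
    nodes_b = [h.hap_id for h in net.haplotypes if h.pop_counts.get(pop_b, 0) > 0]
    if not nodes_a or not nodes_b:
        raise ValueError(f"no haplotypes for {pop_a!r} or {pop_b!r}")
    best = np.inf
    lengths = {}
    for a in nodes_a:
        lengths[a] = nx.single_source_dijkstra_path_length(
            net.graph, a, weight="steps"
        )
    for a in nodes_a:
        for b in nodes_b:
            if a == b:
                return 0.0
            if b in lengths[a]:
                best = min(best, lengths[a][b])
    if np.isinf(best):
        d = step_matrix(net.haplotypes)
        index = {h.hap_id: i for i, h in enumerate(net.haplotypes)}
        for a in nodes_a:
            for b in nodes_b:
                best = min(best, d[index[a], index[b]])
    return float(best)
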