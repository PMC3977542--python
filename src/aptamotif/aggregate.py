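"""Grouping of motif hits and the substring-relation digraph.

An exhaustive degenerate search emits clouds of highly similar motifs that
vacillate around a few true motifs.  Each hit is reduced to its consensus
(per-column majority base of the PSSM); hits sharing a consensus form one
group.  The groups are then arranged in a directed graph whose edges point
from a consensus to every other consensus that is a proper substring of it —
the sources of that graph are the maximal motifs, the natural focus of a
SELEX analysis.

Two maximal consensi that overlap without one containing the other (e.g. a
shared core extended on different sides) are reported as fusion candidates
but never merged automatically; that judgement is left to the analyst.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .search import MotifHit, PSSM


def consensus_of(pssm: PSSM) -> str:
    """Per-column majority base; ties resolved by the fixed order A<C<G<T."""
    if len(pssm) == 0:
        raise ValueError("empty PSSM")
    return "".join("ACGT"[int(np.argmax(col))] for col in pssm.columns)


@dataclass
class ConsensusGroup:
    consensus: str
    hits: list[MotifHit]

    @property
    def size(self) -> int:
        return len(self.hits)

    @property
    def best_coverage(self) -> float:
        return max(h.coverage for h in self.hits)

    @property
    def best_loop_propensity(self):
        vals = [h.loop_propensity for h in self.hits if h.loop_propensity is not None]
        return max(vals) if vals else None


def group_hits(hits: list[MotifHit]) -> list[ConsensusGroup]:
    """Partition hits by consensus; groups sorted by length desc, then lex."""
    groups: dict[str, list[MotifHit]] = {}
    for h in hits:
        groups.setdefault(consensus_of(h.pssm), []).append(h)
    return [
        ConsensusGroup(c, hs)
        for c, hs in sorted(groups.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    ]


def build_substring_graph(groups: list[ConsensusGroup]) -> nx.DiGraph:
    """Directed graph: edge a -> b iff consensus b is a proper substring of a.

    The full (transitive) relation is stored; rendering may reduce it.
    """
    g = nx.DiGraph()
    consensi = [grp.consensus for grp in groups]
    g.add_nodes_from(consensi)
    for a in consensi:
        for b in consensi:
            if a != b and b in a:
                g.add_edge(a, b)
    return g


def graph_sources(graph: nx.DiGraph) -> list[str]:
    """Maximal consensi: nodes with no incoming edge (longest first)."""
    sources = [n for n in graph.nodes if graph.in_degree(n) == 0]
    return sorted(sources, key=lambda s: (-len(s), s))


def suggest_overlaps(
    consensi: list[str], min_overlap: int = 4
) -> list[tuple[str, str, str]]:
    """Suffix-prefix fusion candidates among maximal consensi.

    For each ordered pair (a, b) with neither a substring of the other, the
    longest suffix of a equal to a prefix of b with length >= ``min_overlap``
    yields a candidate merged string a + b[overlap:].
    """
    out = []
    for a in consensi:
        for b in consensi:
            if a == b or a in b or b in a:
                continue
            best = 0
            for k in range(min(len(a), len(b)) - 1, min_overlap - 1, -1):
                if a.endswith(b[:k]):
                    best = k
                    break
            if best:
                out.append((a, b, a + b[best:]))
    out.sort(key=lambda t: (-len(t[2]), t[2]))
    return out


def graph_to_dot(graph: nx.DiGraph, path=None) -> str:
    lines = ["digraph motifs {", "  rankdir=TB;"]
    for n in sorted(graph.nodes, key=lambda s: (-len(s), s)):
        lines.append(f'  "{n}";')
    for a, b in sorted(graph.edges):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def groups_to_tsv(groups: list[ConsensusGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("consensus\tsize\tbest_coverage\tbest_loop_propensity\n")
        for g in groups:
            lp = g.best_loop_propensity
            fh.write(
                f"{g.consensus}\t{g.size}\t{g.best_coverage:.4f}\t"
                f"{'' if lp is None else f'{lp:.4f}'}\n"
            )
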