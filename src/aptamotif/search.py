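"""Exhaustive degenerate-motif search by progressive node merging.

The search walks the composite alphabet Sigma* depth-first, starting from
{root}.  Extending the current pattern by one composite character means
collecting, over all nodes of the current node set, the children whose edge
base belongs to the character, and merging their member lists (deduplicated
via the serial numbers).  The merged list is exactly the set of sequences
containing the extended pattern, so no string scan is ever repeated.

Branches terminate when

* the maximal motif length is reached,
* the (read-count weighted) coverage of the merged members drops below the
  threshold — coverage is anti-monotone in pattern extension, so nothing
  below the threshold can recover, or
* the pattern loses *formal integrity*: some base of a degenerate position
  is not actually observed among the occurrences, i.e. a stricter pattern
  covers the same branch.  Occurrence support only shrinks along a branch,
  so this cut is also safe.

Surviving patterns of sufficient length are emitted as :class:`MotifHit`
objects when the occurrence-derived PSSM passes the information-content
filters: per-position total information E = 2 - H(column) bits (optionally
with low-information gap positions exempted, as long as the motif neither
starts nor ends with a gap) and a minimal average information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabet import (
    Pattern,
    make_composite_alphabet,
    pattern_to_brackets,
    pattern_to_iupac,
)
from .suffixtree import LOOP, SuffixTree, TreeNode

READS = "READS"
DISTINCT = "DISTINCT"

_PAD = 4  # sentinel code for positions past a sequence's end


@dataclass
class PSSM:
    """Per-position relative base frequencies of a motif's occurrences."""

    columns: np.ndarray  # shape (L, 4), rows sum to 1
    support: list[frozenset]  # per column: bases with frequency > 0

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class SearchParams:
    min_len: int = 7
    max_len: int = 11
    min_coverage: float = 0.95
    coverage_basis: str = READS
    min_pos_info: float = 1.8
    min_avg_info: float = 0.0
    gap_max_info: Optional[float] = None
    max_degeneracy: int = 2

    def __post_init__(self):
        if self.min_len < 1 or self.min_len > self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.coverage_basis not in (READS, DISTINCT):
            raise ValueError(f"unknown coverage_basis {self.coverage_basis!r}")


@dataclass
class MotifHit:
    pattern: Pattern
    pssm: PSSM
    matched_serials: np.ndarray
    coverage: float
    per_pos_info: list[float]
    avg_info: float
    loop_propensity: Optional[float] = None

    @property
    def iupac(self) -> str:
        return pattern_to_iupac(self.pattern)

    @property
    def brackets(self) -> str:
        return pattern_to_brackets(self.pattern)


@dataclass
class MergedNode:
    """Pseudo-node produced by one merge step: node set + merged members."""

    nodes: list[TreeNode]
    members: np.ndarray
    weights: Optional[dict[int, float]] = None


def merge_step(nodes: list[TreeNode], cc: frozenset) -> MergedNode:
    """Aggregate the children of ``nodes`` under composite character ``cc``.

    Member lists are unioned without duplicates; in LOOP mode the merged
    per-serial weight is the maximum over the contributing nodes (the best
    loop support among the concrete strings the pattern subsumes).
    """
    from .alphabet import BASE_INDEX

    children = [
        child
        for node in nodes
        for b in cc
        if (child := node.children[BASE_INDEX[b]]) is not None
    ]
    if not children:
        return MergedNode([], np.empty(0, dtype=np.int32))
    if len(children) == 1:
        members = children[0].members
    else:
        members = np.unique(np.concatenate([c.members for c in children]))
    weights = None
    if children[0].weights is not None:
        weights = {}
        for c in children:
            for s, w in c.weights.items():
                if w > weights.get(s, 0.0):
                    weights[s] = w
    return MergedNode(children, members, weights)


def total_information(column) -> float:
    """Total information E = log2(4) - H of one PSSM column, in bits."""
    col = np.asarray(column, dtype=float)
    if (col < 0).any():
        raise ValueError("negative frequency in PSSM column")
    nz = col[col > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return 2.0 - h


def check_integrity(pattern: Pattern, pssm: PSSM) -> bool:
    """PASS iff at every position the observed support equals the pattern set."""
    if len(pattern) != len(pssm):
        raise ValueError("pattern and PSSM length differ")
    return all(sup == cs for sup, cs in zip(pssm.support, pattern))


class _SeqMatrix:
    """Inserts encoded as a padded (n, Lmax) uint8 matrix for fast PSSM tallies."""

    def __init__(self, tree: SuffixTree):
        from .alphabet import BASE_INDEX

        records = tree.records
        n = len(tree.counts)
        lmax = max((len(r.insert) for r in records), default=0)
        self.enc = np.full((n, lmax), _PAD, dtype=np.uint8)
        self.lengths = np.zeros(n, dtype=np.int64)
        for r in records:
            self.enc[r.serial, : len(r.insert)] = [
                BASE_INDEX[c] for c in r.insert
            ]
            self.lengths[r.serial] = len(r.insert)
        self.counts = tree.counts


# base-code membership lookup tables per composite character (index 4 = pad)
_LUTS: dict[frozenset, np.ndarray] = {}


def _lut(cs: frozenset) -> np.ndarray:
    lut = _LUTS.get(cs)
    if lut is None:
        lut = np.zeros(5, dtype=bool)
        lut[[_code(b) for b in cs]] = True
        _LUTS[cs] = lut
    return lut


def column_information(columns: np.ndarray) -> np.ndarray:
    """Total information E = 2 - H for every PSSM column at once, in bits."""
    cols = np.asarray(columns, dtype=float)
    if (cols < 0).any():
        raise ValueError("negative frequency in PSSM column")
    logs = np.zeros_like(cols)
    np.log2(cols, out=logs, where=cols > 0)
    return 2.0 + (cols * logs).sum(axis=1)


def _weights_vector(matrix: _SeqMatrix, basis: str) -> np.ndarray:
    if basis == READS:
        return matrix.counts.astype(float)
    return (matrix.counts > 0).astype(float)


def build_pssm(
    pattern: Pattern,
    serials: np.ndarray,
    matrix: _SeqMatrix,
    weights: np.ndarray,
) -> Optional[PSSM]:
    """Tally all occurrences of ``pattern`` in the inserts of ``serials``.

    Every occurrence counts once (multiple occurrences within one insert
    each count), weighted by the record weight.  Returns None when no
    occurrence exists.
    """
    L = len(pattern)
    if len(serials) == 0:
        return None
    sub = matrix.enc[serials]
    lens = matrix.lengths[serials]
    wmax = sub.shape[1] - L + 1
    if wmax <= 0:
        return None
    offsets = np.arange(wmax)
    match = offsets[None, :] <= (lens[:, None] - L)
    for j, cs in enumerate(pattern):
        match &= _lut(cs)[sub[:, j : j + wmax]]
    occw = np.where(match, weights[serials][:, None], 0.0)
    if not occw.any():
        return None
    flatw = occw.ravel()
    cols = np.empty((L, 4))
    for j in range(L):
        cols[j] = np.bincount(
            sub[:, j : j + wmax].ravel(), weights=flatw, minlength=5
        )[:4]
    cols /= cols.sum(axis=1, keepdims=True)
    support = [
        frozenset("ACGT"[b] for b in range(4) if cols[j, b] > 0) for j in range(L)
    ]
    return PSSM(cols, support)


from .alphabet import BASE_INDEX as _CODE


def _code(base: str) -> int:
    return _CODE[base]


def find_members(tree: SuffixTree, pattern: Pattern) -> np.ndarray:
    """Serials of sequences matching a degenerate pattern, via node merging."""
    nodes = [tree.root]
    for cc in pattern:
        merged = merge_step(nodes, cc)
        nodes = merged.nodes
        if not nodes:
            return np.empty(0, dtype=np.int32)
    return merged.members


def loop_propensity(
    merged: MergedNode, tree: SuffixTree, basis: str = READS
) -> float:
    """Count-weighted mean loop weight of the matched serials, in [0, 1]."""
    if tree.mode != LOOP:
        raise ValueError("loop_propensity requires a LOOP-mode tree")
    if merged.weights is None or len(merged.members) == 0:
        raise ValueError("merged node carries no loop weights")
    if basis == READS:
        w = tree.counts[merged.members].astype(float)
    else:
        w = np.ones(len(merged.members))
    loops = np.array([merged.weights[int(s)] for s in merged.members])
    return float((w * loops).sum() / w.sum())


def search_motifs(tree: SuffixTree, params: Optional[SearchParams] = None) -> list[MotifHit]:
    """Depth-first exhaustive search over the composite alphabet.

    Returns the hits sorted by (length desc, coverage desc, consensus lex).
    """
    params = params or SearchParams()
    if params.max_len > tree.max_depth:
        raise ValueError(
            f"max_len {params.max_len} exceeds tree depth {tree.max_depth}"
        )
    alphabet = make_composite_alphabet(params.max_degeneracy)
    matrix = _SeqMatrix(tree)
    weights = _weights_vector(matrix, params.coverage_basis)
    root_members = tree.root.members
    total = weights[root_members].sum()
    if total == 0:
        return []
    use_gaps = params.gap_max_info is not None
    hits: list[MotifHit] = []
    char_mask = {cs: sum(1 << _code(b) for b in cs) for cs in alphabet}
    _w_cache: dict[int, float] = {}  # per-node weighted occurrence totals

    def emit(
        pattern: Pattern,
        merged: MergedNode,
        paths: list[tuple[int, ...]],
        coverage: float,
    ) -> None:
        # Every merged node is one concrete occurring string; its weighted
        # occurrence total contributes to each column's base tally.  In LOOP
        # mode occ is 1 per (string, sequence): each loop-located string
        # counts once per sequence it occurs in.
        L = len(pattern)
        cols = np.zeros((L, 4))
        for node, path in zip(merged.nodes, paths):
            nid = id(node)
            nw = _w_cache.get(nid)
            if nw is None:
                nw = float((weights[node.members] * node.occ).sum())
                _w_cache[nid] = nw
            for j, code in enumerate(path):
                cols[j, code] += nw
        totals = cols.sum(axis=1, keepdims=True)
        if totals[0, 0] == 0:
            return
        cols /= totals
        support = [
            frozenset("ACGT"[b] for b in range(4) if cols[j, b] > 0)
            for j in range(L)
        ]
        pssm = PSSM(cols, support)
        if tree.mode == LOOP:
            w: dict[int, float] = {}
            for node in merged.nodes:
                for s, wt in node.weights.items():
                    if wt > w.get(s, 0.0):
                        w[s] = wt
            merged.weights = w
        info = column_information(pssm.columns).tolist()
        gap_flags = [False] * len(pattern)
        if use_gaps:
            gap_flags = [
                e < params.min_pos_info and e <= params.gap_max_info for e in info
            ]
            if gap_flags[0] or gap_flags[-1]:
                return
            # a gap position is treated as the full alphabet for integrity
            ok = all(
                gap or sup == cs
                for gap, sup, cs in zip(gap_flags, pssm.support, pattern)
            )
            if not ok:
                return
        if any(
            e < params.min_pos_info and not gap for e, gap in zip(info, gap_flags)
        ):
            return
        avg = float(np.mean(info))
        if avg < params.min_avg_info:
            return
        hit = MotifHit(
            pattern=pattern,
            pssm=pssm,
            matched_serials=merged.members,
            coverage=coverage,
            per_pos_info=info,
            avg_info=avg,
        )
        if tree.mode == LOOP:
            hit.loop_propensity = loop_propensity(
                merged, tree, params.coverage_basis
            )
        hits.append(hit)

    def dfs(
        nodes: list[TreeNode],
        paths: list[tuple[int, ...]],
        pattern: tuple,
        pattern_masks: tuple,
        cov_prev: float,
    ) -> None:
        depth = len(pattern) + 1
        for cc in alphabet:
            child_nodes: list[TreeNode] = []
            child_paths: list[tuple[int, ...]] = []
            for node, path in zip(nodes, paths):
                for b in cc:
                    code = _CODE[b]
                    child = node.children[code]
                    if child is not None:
                        child_nodes.append(child)
                        child_paths.append(path + (code,))
            if not child_nodes:
                continue
            merged = merge_step_from(child_nodes)
            coverage = float(weights[merged.members].sum() / total)
            # anti-monotonicity: an extension can never gain coverage
            assert coverage <= cov_prev + 1e-9
            if coverage < params.min_coverage:
                continue
            new_pattern = pattern + (cc,)
            new_masks = pattern_masks + (char_mask[cc],)
            if not use_gaps:
                # formal integrity on the occurring strings: the bases seen
                # at every position must be exactly the pattern's sets
                support = [0] * depth
                for p in child_paths:
                    for i, code in enumerate(p):
                        support[i] |= 1 << code
                if support != list(new_masks):
                    continue  # a stricter pattern covers this branch: cut
            if depth >= params.min_len:
                emit(new_pattern, merged, child_paths, coverage)
            if depth < params.max_len:
                dfs(child_nodes, child_paths, new_pattern, new_masks, coverage)

    def merge_step_from(children: list[TreeNode]) -> MergedNode:
        # weight merging is deferred to emission; only members matter here
        if len(children) == 1:
            members = children[0].members
        else:
            members = np.unique(np.concatenate([c.members for c in children]))
        return MergedNode(children, members)

    dfs([tree.root], [()], (), (), 1.0)
    hits.sort(key=lambda h: (-len(h.pattern), -h.coverage, _consensus(h.pssm)))
    return hits


def _consensus(pssm: PSSM) -> str:
    return "".join("ACGT"[int(np.argmax(col))] for col in pssm.columns)


# ---------------------------------------------------------------------------
# exports

def hits_to_tsv(hits: list[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "consensus\tiupac\tlength\tcoverage\tavg_info\tloop_propensity\n"
        )
        for h in hits:
            lp = "" if h.loop_propensity is None else f"{h.loop_propensity:.4f}"
            fh.write(
                f"{_consensus(h.pssm)}\t{h.iupac}\t{len(h.pattern)}\t"
                f"{h.coverage:.4f}\t{h.avg_info:.4f}\t{lp}\n"
            )


def hits_to_json(hits: list[MotifHit], path) -> None:
    import json

    payload = []
    for h in hits:
        payload.append(
            {
                "iupac": h.iupac,
                "brackets": h.brackets,
                "consensus": _consensus(h.pssm),
                "coverage": h.coverage,
                "avg_info": h.avg_info,
                "per_pos_info": h.per_pos_info,
                "loop_propensity": h.loop_propensity,
                "matched_serials": [int(s) for s in h.matched_serials],
                "pssm": h.pssm.columns.tolist(),
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def hits_to_meme(hits: list[MotifHit], path, background=None) -> None:
    """MEME minimal motif format, for downstream logo/scan tools."""
    bg = background or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[b]:.3f}" for b in "ACGT") + "\n\n")
        for h in hits:
            fh.write(f"MOTIF {h.iupac}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(h.pattern)}\n"
            )
            for col in h.pssm.columns:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")
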