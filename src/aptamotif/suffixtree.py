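"""Depth-limited generalized suffix tree over SELEX inserts.

Every suffix of every insert is walked into a trie, truncated at the maximal
allowed motif length r.  A node reached by the path string p stores the set
of sequence serials whose insert contains p as a substring — duplicate
entries are avoided, so the member list of a node answers "which sequences
contain p" in O(1) after an O(|p|) walk.  Construction is O(n * l * r).

Two construction modes exist:

* FULL — every suffix of every insert is inserted (weight implicitly 1).
* LOOP — only subsequences lying on unpaired (loop) regions of predicted
  secondary structures are inserted.  Each node additionally stores, per
  serial, the total Boltzmann probability of the structures that routed at
  least one loop suffix through the node; a structure contributes to a node
  at most once, so no weight can exceed the structure's own probability
  mass and every weight stays in (0, 1].

Children are kept in fixed 4-slot arrays indexed by the base code
(A=0, C=1, G=2, T=3) for direct access.  After construction the tree is
frozen: member sets become sorted numpy arrays, which the node-merging
search unions at C speed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabet import BASE_INDEX, BASES
from .preprocess import SequenceRecord
from .structures import (
    BoltzmannConfig,
    StructureEnsemble,
    boltzmann_weights,
    clip_runs,
    extract_unpaired_runs,
    insert_window,
)

FULL = "FULL"
LOOP = "LOOP"


class TreeNode:
    """One trie node: 4-slot child array, member serials, optional weights.

    ``occ`` is aligned with ``members`` and counts, per member, how many
    times the node's path string occurs in that member's insert (FULL mode
    only) — it lets the search tally a PSSM without rescanning sequences.
    """

    __slots__ = ("children", "members", "weights", "occ", "_member_occ")

    def __init__(self, with_weights: bool = False):
        self.children: list[Optional[TreeNode]] = [None, None, None, None]
        self._member_occ: dict[int, int] = {}
        self.members: np.ndarray = _EMPTY
        self.occ: np.ndarray = _EMPTY
        self.weights: Optional[dict[int, float]] = {} if with_weights else None

    def child(self, base: str) -> Optional["TreeNode"]:
        return self.children[BASE_INDEX[base]]


_EMPTY = np.empty(0, dtype=np.int32)


@dataclass
class SuffixTree:
    root: TreeNode
    max_depth: int
    mode: str
    n_sequences: int
    total_count: int
    records: list[SequenceRecord] = field(repr=False, default_factory=list)
    counts: np.ndarray = field(repr=False, default_factory=lambda: _EMPTY)

    def lookup(self, pattern: str) -> Optional[TreeNode]:
        """Node whose path spells ``pattern`` (plain ACGT), or None."""
        if len(pattern) > self.max_depth:
            raise ValueError(
                f"pattern length {len(pattern)} exceeds tree depth {self.max_depth}"
            )
        node = self.root
        for ch in pattern:
            if ch not in BASE_INDEX:
                raise ValueError(f"non-ACGT character {ch!r} in pattern")
            node = node.children[BASE_INDEX[ch]]
            if node is None:
                return None
        return node

    def node_count(self) -> int:
        n, stack = 0, [self.root]
        while stack:
            node = stack.pop()
            n += 1
            stack.extend(c for c in node.children if c is not None)
        return n

    def dump(self) -> dict:
        """Debug dump: path -> (members, weights), for golden tests."""
        out: dict[str, dict] = {}
        stack: list[tuple[str, TreeNode]] = [("", self.root)]
        while stack:
            path, node = stack.pop()
            entry: dict = {"members": [int(s) for s in node.members]}
            if node.weights is not None:
                entry["weights"] = {
                    str(s): round(w, 12) for s, w in sorted(node.weights.items())
                }
            out[path] = entry
            for i, child in enumerate(node.children):
                if child is not None:
                    stack.append((path + BASES[i], child))
        return out

    def dump_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.dump(), fh, indent=2, sort_keys=True)


def _encode(insert: str) -> list[int]:
    try:
        return [BASE_INDEX[ch] for ch in insert]
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in insert") from None


def _freeze(root: TreeNode) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        serials = sorted(node._member_occ)
        node.members = np.fromiter(serials, dtype=np.int32, count=len(serials))
        node.occ = np.fromiter(
            (node._member_occ[s] for s in serials),
            dtype=np.int32,
            count=len(serials),
        )
        node._member_occ = {}
        stack.extend(c for c in node.children if c is not None)


def _finish(
    root: TreeNode, records: list[SequenceRecord], max_depth: int, mode: str
) -> SuffixTree:
    _freeze(root)
    max_serial = max((r.serial for r in records), default=-1)
    counts = np.zeros(max_serial + 1, dtype=np.int64)
    for r in records:
        counts[r.serial] = r.count
    inserted = root.members
    return SuffixTree(
        root=root,
        max_depth=max_depth,
        mode=mode,
        n_sequences=len(inserted),
        total_count=int(counts[inserted].sum()),
        records=records,
        counts=counts,
    )


def build_tree(records: list[SequenceRecord], max_depth: int) -> SuffixTree:
    """FULL-mode tree: insert every suffix of every insert, depth-limited."""
    if not records:
        raise ValueError("no records to insert")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    root = TreeNode()
    for rec in records:
        codes = _encode(rec.insert)
        serial = rec.serial
        root._member_occ[serial] = 1
        for start in range(len(codes)):
            node = root
            for code in codes[start : start + max_depth]:
                nxt = node.children[code]
                if nxt is None:
                    nxt = TreeNode()
                    node.children[code] = nxt
                node = nxt
                node._member_occ[serial] = node._member_occ.get(serial, 0) + 1
    return _finish(root, records, max_depth, FULL)


def build_loop_tree(
    records: list[SequenceRecord],
    ensembles: dict[int, StructureEnsemble],
    cfg: Optional[BoltzmannConfig] = None,
    max_depth: int = 11,
) -> SuffixTree:
    """LOOP-mode tree from Boltzmann-weighted unpaired runs.

    ``ensembles`` maps record serial -> StructureEnsemble (probabilities are
    computed here if absent, using ``cfg``).  For every structure x of a
    record, every maximal unpaired run — clipped to the insert window when
    the fold covers the primer-flanked sequence — is inserted with all its
    suffixes; every node touched by x gains P(x) of weight for that serial,
    once per structure.  Records whose ensembles have no unpaired run inside
    the insert are skipped with a warning.
    """
    if not records:
        raise ValueError("no records to insert")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    cfg = cfg or BoltzmannConfig()
    root = TreeNode(with_weights=True)
    for rec in records:
        ens = ensembles.get(rec.serial)
        if ens is None:
            raise ValueError(f"no structure ensemble for serial {rec.serial}")
        if ens.probabilities is None:
            boltzmann_weights(ens, cfg)
        win = insert_window(ens, rec.insert)
        codes = _encode(rec.insert)
        serial = rec.serial
        touched_any = False
        for (db, _), p in zip(ens.structures, ens.probabilities):
            runs = clip_runs(extract_unpaired_runs(db), *win)
            if not runs:
                continue
            visited: set[int] = set()
            for rs, re_ in runs:
                for start in range(rs, re_):
                    node = root
                    for code in codes[start : min(re_, start + max_depth)]:
                        nxt = node.children[code]
                        if nxt is None:
                            nxt = TreeNode(with_weights=True)
                            node.children[code] = nxt
                        node = nxt
                        if id(node) not in visited:
                            visited.add(id(node))
                            node._member_occ[serial] = 1
                            node.weights[serial] = node.weights.get(serial, 0.0) + p
            if visited:
                touched_any = True
                root._member_occ[serial] = 1
                root.weights[serial] = root.weights.get(serial, 0.0) + p
        if not touched_any:
            warnings.warn(
                f"record serial {rec.serial} has no unpaired run; "
                "absent from the loop tree",
                stacklevel=2,
            )
    return _finish(root, records, max_depth, LOOP)
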