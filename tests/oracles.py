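"""Independent brute-force oracles for the motif search.

Everything here works directly on the raw insert strings — no suffix tree,
no node merging — so agreement with the package's tree-based search is a
meaningful cross-check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np

from aptamotif.alphabet import make_composite_alphabet
from aptamotif.preprocess import SequenceRecord
from aptamotif.search import DISTINCT, READS, SearchParams


def substring_members(records: list[SequenceRecord], pattern) -> set[int]:
    """Serials whose insert contains the degenerate pattern (direct scan)."""
    out = set()
    for rec in records:
        s = rec.insert
        L = len(pattern)
        for off in range(len(s) - L + 1):
            if all(s[off + j] in pattern[j] for j in range(L)):
                out.add(rec.serial)
                break
    return out


def occurrences(records, pattern) -> list[tuple[int, int]]:
    """All (serial, offset) occurrence positions of the pattern."""
    occs = []
    L = len(pattern)
    for rec in records:
        s = rec.insert
        for off in range(len(s) - L + 1):
            if all(s[off + j] in pattern[j] for j in range(L)):
                occs.append((rec.serial, off))
    return occs


def tally_pssm(records, pattern, occs, basis=READS):
    """Occurrence-weighted per-column base frequencies (columns, support)."""
    by_serial = {r.serial: r for r in records}
    L = len(pattern)
    cols = np.zeros((L, 4))
    for serial, off in occs:
        rec = by_serial[serial]
        w = rec.count if basis == READS else 1
        for j in range(L):
            cols[j, "ACGT".index(rec.insert[off + j])] += w
    cols /= cols.sum(axis=1, keepdims=True)
    support = [
        frozenset("ACGT"[b] for b in range(4) if cols[j, b] > 0) for j in range(L)
    ]
    return cols, support


def column_entropy_information(cols) -> list[float]:
    out = []
    for col in cols:
        h = -sum(p * math.log2(p) for p in col if p > 0)
        out.append(2.0 - h)
    return out


def brute_force_search(
    records: list[SequenceRecord], params: SearchParams
) -> dict[tuple, dict]:
    """Enumerate every composite pattern up to max_len by occurrence extension.

    A pattern branch is abandoned only when it has no occurrence at all;
    coverage, integrity and information filters are applied as emission
    filters exactly as specified, never as search-space pruning, so the
    result is independent of the anti-monotonicity arguments the tree search
    relies on.

    Returns pattern -> {members, coverage, columns, info}.
    """
    alphabet = make_composite_alphabet(params.max_degeneracy)
    weights = {
        r.serial: (r.count if params.coverage_basis == READS else 1)
        for r in records
    }
    total = sum(weights.values())
    by_serial = {r.serial: r for r in records}
    use_gaps = params.gap_max_info is not None
    results: dict[tuple, dict] = {}

    def consider(pattern, occs):
        if len(pattern) < params.min_len:
            return
        members = sorted({s for s, _ in occs})
        coverage = sum(weights[s] for s in members) / total
        if coverage < params.min_coverage:
            return
        cols, support = tally_pssm(records, pattern, occs, params.coverage_basis)
        info = column_entropy_information(cols)
        gap_flags = [False] * len(pattern)
        if use_gaps:
            gap_flags = [
                e < params.min_pos_info and e <= params.gap_max_info for e in info
            ]
            if gap_flags[0] or gap_flags[-1]:
                return
        if any(
            not gap and sup != cs
            for gap, sup, cs in zip(gap_flags, support, pattern)
        ):
            return
        if any(
            e < params.min_pos_info and not gap for e, gap in zip(info, gap_flags)
        ):
            return
        if sum(info) / len(info) < params.min_avg_info:
            return
        results[pattern] = {
            "members": members,
            "coverage": coverage,
            "columns": cols,
            "info": info,
        }

    def extend(pattern, occs):
        depth = len(pattern) + 1
        for cc in alphabet:
            new_occs = [
                (s, off)
                for s, off in occs
                if off + depth <= len(by_serial[s].insert)
                and by_serial[s].insert[off + depth - 1] in cc
            ]
            if not new_occs:
                continue
            new_pattern = pattern + (cc,)
            consider(new_pattern, new_occs)
            if depth < params.max_len:
                extend(new_pattern, new_occs)

    seeds = [
        (r.serial, off) for r in records for off in range(len(r.insert))
    ]
    extend((), seeds)
    return results
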