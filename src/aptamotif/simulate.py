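"""Synthetic SELEX round generator.

The sequencing data of a real SELEX experiment is modelled as a *clone
pool*: a round contains a limited number of distinct aptamer candidates,
and reads sample that pool with a heavily skewed (Zipf-like) multiplicity
distribution — an enriched late round has far fewer distinct sequences than
reads.  A configurable fraction of the clones carries one instance of a
planted degenerate motif at a uniform random offset within the 49-nt random
region; the remainder is fully random.  Reads are the primer-flanked
inserts with i.i.d. substitution errors and clipped-normal Phred scores,
written as Phred+33 FASTQ.

Across rounds, enrichment is emulated by (a) a planted-motif fraction that
rises geometrically towards its final value and (b) a clone pool that
shrinks geometrically towards its final size, so diversity indices fall
round by round.

A companion generator fabricates RNAsubopt-style suboptimal-structure
ensembles for preprocessed records: random, properly nested helices with
uniform free energies in [-10, -1] kcal/mol, where the minimum-energy
structure keeps the planted-motif window unpaired.  This emulates the
folding behaviour the loop-mode search relies on; it is a synthetic
stand-in for a thermodynamic folding tool, not a fold prediction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .alphabet import parse_pattern, Pattern
from .preprocess import DEFAULT_PRIMER3, DEFAULT_PRIMER5, SequenceRecord

DEFAULT_PLANTED = "[AG]G[AG]TGGTCCGGG"


@dataclass
class RoundSimSpec:
    n_reads: int = 2000
    insert_len: int = 49
    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    planted_pattern: str = DEFAULT_PLANTED
    planted_fraction: float = 0.97
    phred_mean: float = 35.0
    phred_sd: float = 4.0
    error_rate: float = 0.005
    pool_size: int = 200
    pool_growth: float = 2.0  # pool size multiplier per round going backwards
    n_rounds: int = 1
    enrichment_schedule: Optional[list[float]] = None
    enrichment_growth: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(parse_pattern(self.planted_pattern)) > self.insert_len:
            raise ValueError("planted pattern longer than the insert")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")

    def round_fraction(self, round_index: int) -> float:
        """Planted-clone fraction of a round (0-based; last = planted_fraction)."""
        if self.enrichment_schedule is not None:
            return self.enrichment_schedule[round_index]
        back = self.n_rounds - 1 - round_index
        return self.planted_fraction * self.enrichment_growth**back

    def round_pool_size(self, round_index: int) -> int:
        back = self.n_rounds - 1 - round_index
        return max(2, round(self.pool_size * self.pool_growth**back))


def _sample_instance(pattern: Pattern, rng: np.random.Generator) -> str:
    return "".join(sorted(cs)[rng.integers(0, len(cs))] for cs in pattern)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


def simulate_pool(
    spec: RoundSimSpec, round_index: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """The round's clone pool: (insert, read count) pairs, counts Zipf-skewed."""
    pool_n = spec.round_pool_size(round_index)
    fraction = spec.round_fraction(round_index)
    pattern = parse_pattern(spec.planted_pattern)
    plen = len(pattern)
    n_motif = round(fraction * pool_n)
    motif_flags = np.zeros(pool_n, dtype=bool)
    motif_flags[rng.permutation(pool_n)[:n_motif]] = True
    inserts = []
    for flag in motif_flags:
        ins = _random_seq(spec.insert_len, rng)
        if flag:
            off = int(rng.integers(0, spec.insert_len - plen + 1))
            ins = ins[:off] + _sample_instance(pattern, rng) + ins[off + plen :]
        inserts.append(ins)
    ranks = np.arange(1, pool_n + 1, dtype=float)
    probs = (1.0 / ranks) / (1.0 / ranks).sum()
    counts = rng.multinomial(spec.n_reads, probs)
    return [(ins, int(c)) for ins, c in zip(inserts, counts)]


def simulate_round(
    spec: RoundSimSpec, round_index: int = 0, path=None
) -> str:
    """Generate one round's FASTQ; returns the text (and writes it if ``path``).

    Deterministic for a fixed (seed, round_index) pair.
    """
    rng = np.random.default_rng([spec.seed, round_index])
    pool = simulate_pool(spec, round_index, rng)
    lines: list[str] = []
    ridx = 0
    for clone_idx, (ins, count) in enumerate(pool):
        full = spec.primer5 + ins + spec.primer3
        for _ in range(count):
            bases = list(full)
            errs = rng.random(len(bases)) < spec.error_rate
            for i in np.flatnonzero(errs):
                alt = [b for b in "ACGT" if b != bases[i]]
                bases[i] = alt[int(rng.integers(0, 3))]
            phred = np.clip(
                np.rint(rng.normal(spec.phred_mean, spec.phred_sd, len(bases))),
                2,
                41,
            ).astype(int)
            lines.append(f"@sim_r{round_index}_c{clone_idx}_{ridx}")
            lines.append("".join(bases))
            lines.append("+")
            lines.append("".join(chr(q + 33) for q in phred))
            ridx += 1
    text = "\n".join(lines) + "\n" if lines else ""
    if path is not None:
        Path(path).write_text(text)
    return text


def simulate_rounds(spec: RoundSimSpec, out_dir) -> list[Path]:
    """All rounds of a run, one FASTQ per round."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in range(spec.n_rounds):
        p = out_dir / f"round_{r}.fastq"
        simulate_round(spec, r, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# synthetic structure ensembles


def _place_helices(
    length: int,
    rng: np.random.Generator,
    protect: Optional[tuple[int, int]] = None,
) -> str:
    """A random valid dot-bracket: disjoint hairpin helices, never crossing.

    ``protect`` is a window kept unpaired.
    """
    db = ["."] * length
    used = np.zeros(length, dtype=bool)
    if protect is not None:
        used[protect[0] : protect[1]] = True
    n_helices = int(rng.integers(1, 4))
    for _ in range(n_helices):
        for _attempt in range(20):
            span = int(rng.integers(9, 19))
            if span >= length:
                continue
            a = int(rng.integers(0, length - span))
            b = a + span - 1
            if used[a : b + 1].any():
                continue
            h = min(4, (span - 3) // 2)
            if h < 2:
                continue
            for k in range(h):
                db[a + k] = "("
                db[b - k] = ")"
            used[a : b + 1] = True
            break
    return "".join(db)


def find_planted_window(
    insert: str, planted_pattern: str = DEFAULT_PLANTED
) -> Optional[tuple[int, int]]:
    """First occurrence window of the planted degenerate pattern, or None."""
    pattern = parse_pattern(planted_pattern)
    regex = re.compile(
        "".join("[" + "".join(sorted(cs)) + "]" for cs in pattern)
    )
    m = regex.search(insert)
    return (m.start(), m.end()) if m else None


def simulate_ensembles(
    records: list[SequenceRecord],
    seed: int = 0,
    planted_pattern: str = DEFAULT_PLANTED,
    primer5: str = DEFAULT_PRIMER5,
    primer3: str = DEFAULT_PRIMER3,
    path=None,
) -> str:
    """RNAsubopt-style ensembles for preprocessed records.

    Per record: 1–5 structures over the primer-flanked sequence, energies
    uniform in [-10, -1] kcal/mol.  When the insert carries the planted
    motif, the minimum-energy structure keeps that window (plus one base of
    margin) unpaired, so the motif sits on a loop of the most stable fold.
    """
    if not records:
        raise ValueError("no records")
    rng = np.random.default_rng([seed, 20177])
    lines: list[str] = []
    for rec in records:
        full = primer5 + rec.insert + primer3
        win = find_planted_window(rec.insert, planted_pattern)
        protect = None
        if win is not None:
            lo = max(0, len(primer5) + win[0] - 1)
            hi = min(len(full), len(primer5) + win[1] + 1)
            protect = (lo, hi)
        k = int(rng.integers(1, 6))
        energies = np.sort(rng.uniform(-10.0, -1.0, size=k))
        structs = []
        for j in range(k):
            structs.append(
                _place_helices(len(full), rng, protect if j == 0 else None)
            )
        lines.append(full)
        for db, en in zip(structs, energies):
            lines.append(f"{db} {en:6.2f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
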