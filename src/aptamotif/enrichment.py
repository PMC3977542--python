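"""Per-round diversity indices and motif-enriched library generation.

A SELEX run converges: read mass concentrates on fewer distinct sequences
round by round.  Two classical indices quantify this over the distinct-insert
count vector of a round:

* Gini–Simpson index  D = 1 - sum(p_i^2)   (0 for a single species,
  1 - 1/k for k uniform species; higher = more diverse),
* Shannon–Weaver index H = -sum(p_i * ln p_i)  (natural log; ln k for k
  uniform species).

Both classical variants (raw Simpson sum(p^2), log2 Shannon) are selectable.

The discovered motif PSSM can seed a new starting library: a chosen fraction
of the generated sequences carries one motif instance sampled column-wise
from the PSSM at a uniform random offset, either verbatim
(CONSTRAINED_RANDOM) or post-randomized with per-base mutations
(POST_RANDOMIZE), filling the conformation space with varied motif
configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .preprocess import SequenceRecord
from .search import PSSM

POST_RANDOMIZE = "POST_RANDOMIZE"
CONSTRAINED_RANDOM = "CONSTRAINED_RANDOM"


def _proportions(counts: Sequence[float]) -> list[float]:
    if len(counts) == 0:
        raise ValueError("empty count vector")
    if any(c <= 0 for c in counts):
        raise ValueError("counts must be positive")
    total = float(sum(counts))
    return [c / total for c in counts]


def simpson_index(counts: Sequence[float], variant: str = "gini") -> float:
    """Simpson diversity of a count vector.

    ``variant="gini"`` (default) returns 1 - sum(p^2); ``variant="raw"``
    returns sum(p^2) itself.
    """
    p = _proportions(counts)
    s = sum(x * x for x in p)
    if variant == "gini":
        return 1.0 - s
    if variant == "raw":
        return s
    raise ValueError(f"unknown Simpson variant {variant!r}")


def shannon_weaver_index(counts: Sequence[float], base: str = "e") -> float:
    """Shannon–Weaver diversity: -sum(p ln p) (or log2 with ``base='2'``)."""
    p = _proportions(counts)
    log = math.log if base == "e" else math.log2
    if base not in ("e", "2"):
        raise ValueError(f"unknown log base {base!r}")
    return -sum(x * log(x) for x in p if x > 0)


@dataclass
class RoundDiversity:
    round_id: str
    n_reads: int
    n_distinct: int
    simpson: float
    shannon_weaver: float


def round_diversity(
    records: list[SequenceRecord], round_id: str = ""
) -> RoundDiversity:
    """Diversity of one preprocessed round (counts = read multiplicities)."""
    counts = [r.count for r in records]
    return RoundDiversity(
        round_id=round_id,
        n_reads=sum(counts),
        n_distinct=len(records),
        simpson=simpson_index(counts),
        shannon_weaver=shannon_weaver_index(counts),
    )


def diversity_to_tsv(rows: list[RoundDiversity], path) -> None:
    with open(path, "w") as fh:
        fh.write("round\tn_reads\tn_distinct\tsimpson\tshannon_weaver\n")
        for r in rows:
            fh.write(
                f"{r.round_id}\t{r.n_reads}\t{r.n_distinct}\t"
                f"{r.simpson:.6f}\t{r.shannon_weaver:.6f}\n"
            )


@dataclass
class LibrarySpec:
    motif_pssm: PSSM
    random_len: int = 49
    n_sequences: int = 1000
    enriched_fraction: float = 1.0
    strategy: str = CONSTRAINED_RANDOM
    mutation_rate: float = 0.0
    template_5p: str = ""
    template_3p: str = ""
    seed: int = 0

    def __post_init__(self):
        if self.random_len < len(self.motif_pssm):
            raise ValueError("motif longer than the random region")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not 0 <= self.enriched_fraction <= 1:
            raise ValueError("enriched_fraction must be in [0, 1]")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.strategy not in (POST_RANDOMIZE, CONSTRAINED_RANDOM):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def generate_library(spec: LibrarySpec) -> list[str]:
    """Generate a motif-enriched starting library (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    cols = spec.motif_pssm.columns
    L = len(cols)
    out: list[str] = []
    for _ in range(spec.n_sequences):
        seq = list("ACGT"[b] for b in rng.integers(0, 4, size=spec.random_len))
        if rng.random() < spec.enriched_fraction:
            offset = int(rng.integers(0, spec.random_len - L + 1))
            instance = [
                "ACGT"[int(rng.choice(4, p=col / col.sum()))] for col in cols
            ]
            if spec.strategy == POST_RANDOMIZE and spec.mutation_rate > 0:
                for i in range(L):
                    if rng.random() < spec.mutation_rate:
                        alt = [b for b in "ACGT" if b != instance[i]]
                        instance[i] = alt[int(rng.integers(0, 3))]
            seq[offset : offset + L] = instance
        out.append(spec.template_5p + "".join(seq) + spec.template_3p)
    return out


def write_fasta(sequences: list[str], path, prefix: str = "lib") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">{prefix}{i}\n{seq}\n")
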