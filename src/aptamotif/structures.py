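"""Secondary-structure ensembles and Boltzmann loop weighting.

Aptamer binding sites sit preferentially on unpaired (loop) nucleotides, so
the structure-aware tree is built from loop subsequences only.  Folding
itself is delegated to an external suboptimal-structure predictor (RNAsubopt
or an equivalent DNA-parameterized tool); this module consumes its text
output: per sequence, a set of dot-bracket structures with free energies in
kcal/mol.

Each structure x of an ensemble X receives a Boltzmann probability

    P(x) = exp(-beta * E(x) / (kB * T)) / Z,
    Z    = sum over x' in X of exp(-beta * E(x') / (kB * T)),

where kB is the Boltzmann constant in kcal/(mol*K), T the absolute
temperature, and beta a shape parameter: beta = 0 weights all structures
equally, larger beta concentrates mass on low-energy structures.

Because the constant primers fold together with the insert, predictions are
made on the primer-flanked sequence; loop runs are afterwards clipped to the
insert window and shifted to insert coordinates.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Optional

_RUN_RE = re.compile(r"\.+")
_SEQ_RE = re.compile(r"^[ACGTUNacgtun]+$")
_STRUCT_RE = re.compile(r"^([.()]+)\s+\(?\s*(-?\d+(?:\.\d+)?)\s*\)?$")


@dataclass
class BoltzmannConfig:
    temperature_K: float = 310.0
    beta: float = 1.0
    kB: float = 0.0019872  # kcal / (mol * K)

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")
        if self.kB <= 0:
            raise ValueError("kB must be > 0")


@dataclass
class StructureEnsemble:
    """A sequence with its suboptimal structures and (optional) probabilities."""

    sequence: str
    structures: list[tuple[str, float]]
    probabilities: Optional[list[float]] = None


def _check_dotbracket(db: str, seqlen: int, where: str = "") -> None:
    depth = 0
    for ch in db:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced dot-bracket{where}")
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}{where}")
    if depth != 0:
        raise ValueError(f"unbalanced dot-bracket{where}")
    if len(db) != seqlen:
        raise ValueError(
            f"dot-bracket length {len(db)} != sequence length {seqlen}{where}"
        )


def parse_subopt_output(path) -> list[StructureEnsemble]:
    """Parse RNAsubopt-style text: a sequence line, then 'dotbracket energy' lines.

    U is normalized to T (the tool reports RNA letters even for DNA folds).
    Structural problems are hard errors carrying the offending line number.
    """
    ensembles: list[StructureEnsemble] = []
    current: Optional[StructureEnsemble] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(">"):
                continue
            if _SEQ_RE.match(line):
                current = StructureEnsemble(
                    line.upper().replace("U", "T"), []
                )
                ensembles.append(current)
                continue
            m = _STRUCT_RE.match(line)
            if m is None:
                raise ValueError(f"line {lineno}: cannot parse {line!r}")
            if current is None:
                raise ValueError(f"line {lineno}: structure before any sequence")
            db, energy = m.group(1), float(m.group(2))
            _check_dotbracket(db, len(current.sequence), f" at line {lineno}")
            current.structures.append((db, energy))
    for ens in ensembles:
        if not ens.structures:
            raise ValueError(
                f"sequence {ens.sequence[:20]}... has no structure lines"
            )
    return ensembles


def boltzmann_weights(
    ensemble: StructureEnsemble, cfg: Optional[BoltzmannConfig] = None
) -> StructureEnsemble:
    """Attach normalized Boltzmann probabilities to an ensemble (in place).

    Computed with the maximum factor subtracted before exponentiation, so
    large |E|/(kB*T) ratios cannot overflow.
    """
    cfg = cfg or BoltzmannConfig()
    if not ensemble.structures:
        raise ValueError("cannot weight an empty ensemble")
    scale = -cfg.beta / (cfg.kB * cfg.temperature_K)
    exponents = [scale * e for _, e in ensemble.structures]
    m = max(exponents)
    factors = [math.exp(x - m) for x in exponents]
    z = sum(factors)
    ensemble.probabilities = [f / z for f in factors]
    return ensemble


def extract_unpaired_runs(dotbracket: str) -> list[tuple[int, int]]:
    """Maximal runs of unpaired bases as 0-based half-open intervals."""
    _check_dotbracket(dotbracket, len(dotbracket))
    return [(m.start(), m.end()) for m in _RUN_RE.finditer(dotbracket)]


def clip_runs(
    runs: list[tuple[int, int]], window_start: int, window_end: int
) -> list[tuple[int, int]]:
    """Intersect runs with [window_start, window_end) and shift to window coords."""
    out = []
    for s, e in runs:
        s2, e2 = max(s, window_start), min(e, window_end)
        if s2 < e2:
            out.append((s2 - window_start, e2 - window_start))
    return out


def insert_window(ensemble: StructureEnsemble, insert: str) -> tuple[int, int]:
    """Locate the insert inside the (possibly primer-flanked) folded sequence."""
    if ensemble.sequence == insert:
        return 0, len(insert)
    i = ensemble.sequence.find(insert)
    if i < 0:
        raise ValueError("insert not found in the folded sequence")
    return i, i + len(insert)


@dataclass
class LoopRun:
    start: int
    end: int
    weight: float = field(default=1.0)


def loop_weight_map(ensemble: StructureEnsemble) -> dict[tuple[int, int], float]:
    """Weight of every maximal unpaired run appearing in the ensemble.

    The weight of a run is the total probability of the structures in which
    that run is unpaired, i.e. lies fully inside one of the structure's
    maximal '.'-runs.  A run present in every structure therefore gets
    weight 1; nested sub-runs accumulate weight only via their own interval
    (suffix insertion covers shorter runs at the tree level).
    """
    if ensemble.probabilities is None:
        raise ValueError("probabilities not computed; call boltzmann_weights first")
    per_structure = [
        extract_unpaired_runs(db) for db, _ in ensemble.structures
    ]
    candidates = sorted({r for runs in per_structure for r in runs})
    weights: dict[tuple[int, int], float] = {}
    for run in candidates:
        w = 0.0
        for runs, p in zip(per_structure, ensemble.probabilities):
            if any(s <= run[0] and run[1] <= e for s, e in runs):
                w += p
        weights[run] = w
    return weights


def ensembles_to_json(ensembles: list[StructureEnsemble], path) -> None:
    payload = [
        {
            "sequence": e.sequence,
            "structures": [
                {"dotbracket": db, "energy": en} for db, en in e.structures
            ],
            "probabilities": e.probabilities,
        }
        for e in ensembles
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
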