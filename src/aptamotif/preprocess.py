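"""Raw-read preparation for SELEX NGS rounds.

Sequenced reads carry the aptamer insert flanked by the constant library
primers, possibly truncated at either end of the read.  This module strips
the primers (exact full match, or an end-anchored fragment of configurable
minimum length), applies quality and abundance filters, and collapses the
surviving inserts into distinct :class:`SequenceRecord` objects carrying a
read count and a dense serial number.  The serial numbers are what the
suffix tree stores in its node member lists.

All coordinates are 0-based half-open; FASTQ input is Phred+33 only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: Library template constant regions (5' and 3' primers) used as defaults.
DEFAULT_PRIMER5 = "GCCTCTTGTGAGCCTCCTAAC"
DEFAULT_PRIMER3 = "CATGCTTATTCTTGTCTCCC"

_MAX_PHRED = 60


@dataclass(frozen=True)
class RawRead:
    """One FASTQ record: id, base calls, and per-base Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self):
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.quals)} quality values "
                f"for {len(self.bases)} bases"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """A distinct post-preprocessing insert with its read multiplicity."""

    serial: int
    insert: str
    count: int = 1


@dataclass
class PreprocessConfig:
    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    min_fragment_len: int = 8
    min_mean_phred: float = 20.0
    min_count: int = 2
    expected_insert_len: Optional[int] = None

    def __post_init__(self):
        if self.min_fragment_len < 1:
            raise ValueError("min_fragment_len must be >= 1")
        if self.min_mean_phred < 0:
            raise ValueError("min_mean_phred must be >= 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not self.primer5 or not self.primer3:
            raise ValueError("both primers must be non-empty")


@dataclass
class PreprocessReport:
    """Per-stage accounting of where reads were lost."""

    reads_in: int = 0
    primer_rejected: int = 0
    quality_failed: int = 0
    abundance_dropped: int = 0
    distinct_out: int = 0
    counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_fastq(path) -> Iterator[RawRead]:
    """Stream RawRead objects from a Phred+33 FASTQ file.

    Malformed records (base/quality length mismatch, out-of-range scores
    suggesting a different encoding) raise ``ValueError`` naming the record
    index.
    """
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index}: {exc}") from exc
            if len(qual) != len(seq):
                raise ValueError(
                    f"malformed FASTQ record {index} ({title.split()[0]}): "
                    f"{len(qual)} quality characters for {len(seq)} bases"
                )
            quals = tuple(ord(c) - 33 for c in qual)
            if any(q < 0 or q > _MAX_PHRED for q in quals):
                raise ValueError(
                    f"FASTQ record {index}: Phred score outside [0, {_MAX_PHRED}] "
                    "— only Phred+33 encoding is supported"
                )
            yield RawRead(title.split()[0], seq.upper(), quals)
            index += 1


def trim_primers(
    read: RawRead, cfg: PreprocessConfig
) -> Optional[tuple[str, tuple[int, ...]]]:
    """Strip the flanking primers from a read; ``None`` means REJECTED.

    The 5' primer is accepted as a full exact occurrence anywhere in the
    read, or as any of its suffix fragments (length >= ``min_fragment_len``)
    anchored at the read start.  Symmetrically the 3' primer matches in full,
    or as a prefix fragment anchored at the read end.  The enclosed insert
    and its quality slice are returned; an empty insert is rejected.
    """
    seq, p5, p3 = read.bases, cfg.primer5, cfg.primer3
    end5: Optional[int] = None
    i = seq.find(p5)
    if i >= 0:
        end5 = i + len(p5)
    else:
        limit = min(len(p5) - 1, len(seq))
        for flen in range(limit, cfg.min_fragment_len - 1, -1):
            if seq.startswith(p5[-flen:]):
                end5 = flen
                break
    if end5 is None:
        return None

    start3: Optional[int] = None
    j = seq.find(p3, end5)
    if j >= 0:
        start3 = j
    else:
        limit = min(len(p3) - 1, len(seq) - end5)
        for flen in range(limit, cfg.min_fragment_len - 1, -1):
            if seq.endswith(p3[:flen]):
                start3 = len(seq) - flen
                break
    if start3 is None or start3 <= end5:
        return None
    return seq[end5:start3], read.quals[end5:start3]


def filter_read(insert: str, quals: Iterable[int], cfg: PreprocessConfig) -> bool:
    """True (PASS) iff the insert survives the quality filters.

    Fails on: mean Phred below threshold, any non-ACGT character (ambiguous
    base calls cannot be placed in the tree), or — when configured — an
    insert length differing from ``expected_insert_len``.
    """
    quals = list(quals)
    if len(quals) != len(insert):
        raise ValueError("insert and quality slice differ in length")
    if not insert:
        return False
    if any(b not in "ACGT" for b in insert):
        return False
    if sum(quals) / len(quals) < cfg.min_mean_phred:
        return False
    if cfg.expected_insert_len is not None and len(insert) != cfg.expected_insert_len:
        return False
    return True


def dedupe_and_count(
    inserts: Iterable[str], cfg: PreprocessConfig
) -> list[SequenceRecord]:
    """Collapse inserts to distinct records with counts; drop rare ones.

    Records below ``min_count`` are discarded (a sequence seen only a handful
    of times in an enriched round is treated as a sequencing artefact).
    Serials are assigned 0..n-1 in descending-count order with lexicographic
    tie-break, so every downstream step is deterministic.
    """
    tally: dict[str, int] = {}
    for ins in inserts:
        tally[ins] = tally.get(ins, 0) + 1
    kept = [(ins, c) for ins, c in tally.items() if c >= cfg.min_count]
    kept.sort(key=lambda t: (-t[1], t[0]))
    return [SequenceRecord(i, ins, c) for i, (ins, c) in enumerate(kept)]


def select_top_k(records: list[SequenceRecord], k: int) -> list[SequenceRecord]:
    """The k highest-count records (count-desc, insert-lex tie-break), re-serialed."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(records, key=lambda r: (-r.count, r.insert))
    return [
        SequenceRecord(i, r.insert, r.count) for i, r in enumerate(ordered[:k])
    ]


def preprocess_fastq(
    path, cfg: Optional[PreprocessConfig] = None
) -> tuple[list[SequenceRecord], PreprocessReport]:
    """Full pipeline: FASTQ -> primer strip -> quality filter -> dedupe."""
    cfg = cfg or PreprocessConfig()
    report = PreprocessReport()
    passed: list[str] = []
    for read in read_fastq(path):
        report.reads_in += 1
        trimmed = trim_primers(read, cfg)
        if trimmed is None:
            report.primer_rejected += 1
            continue
        insert, quals = trimmed
        if not filter_read(insert, quals, cfg):
            report.quality_failed += 1
            continue
        passed.append(insert)
    records = dedupe_and_count(passed, cfg)
    report.distinct_out = len(records)
    report.abundance_dropped = len(passed) - sum(r.count for r in records)
    report.counts = {
        "passed_reads": len(passed),
        "retained_reads": sum(r.count for r in records),
    }
    return records, report


def write_records_tsv(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("serial\tinsert\tcount\n")
        for r in records:
            fh.write(f"{r.serial}\t{r.insert}\t{r.count}\n")


def read_records_tsv(path) -> list[SequenceRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("serial"):
            raise ValueError(f"{path}: expected 'serial\\tinsert\\tcount' header")
        for line in fh:
            serial, insert, count = line.rstrip("\n").split("\t")
            records.append(SequenceRecord(int(serial), insert, int(count)))
    return records
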