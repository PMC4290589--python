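"""Per-assembly quality metrics computed directly from FASTA files.

The metrics follow the reference-free draft-genome assessment convention:

* goodness metrics — largest contig, N50, L50 — describe the contiguity of
  the bulk of the assembly;
* problem metrics — chaff-bases percentage and the number of uncalled
  bases (N's) — describe fragmentation debris and gaps.

A *chaff* contig is any record shorter than ``min_len`` (200 bp by
default, strict ``<``). The chaff percentage is measured against the full,
unfiltered assembly; every other metric (largest contig, N50, L50, N
count) is computed after chaff contigs have been removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

DEFAULT_CHAFF_MIN_LEN = 200


class Level(str, Enum):
    """Assembly level: contigs or scaffolds (a label; processing is identical)."""

    CONTIGS = "contigs"
    SCAFFOLDS = "scaffolds"


@dataclass(frozen=True)
class Assembly:
    """A named set of sequence records from one FASTA file.

    Attributes
    ----------
    name : str
        Free-text label (typically the assembler name).
    level : Level
        Whether the file holds contigs or scaffolds. Label only; scaffold
        records are not split at N runs.
    records : tuple[tuple[str, str], ...]
        Ordered ``(id, sequence)`` pairs. Case is preserved.
    """

    name: str
    level: Level
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rid, seq in self.records:
            if len(seq) == 0:
                raise ValueError(
                    f"assembly {self.name!r}: record {rid!r} has zero length"
                )
            if rid in seen:
                raise ValueError(
                    f"assembly {self.name!r}: duplicate record id {rid!r}"
                )
            seen.add(rid)

    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class MetricSet:
    """Measured metric values for one assembly.

    ``largest_contig``/``n50``/``l50``/``n_count`` refer to the post-chaff
    record set; ``chaff_pct`` to the full set.
    """

    name: str
    level: Level
    largest_contig: int
    n50: int
    l50: int
    chaff_pct: float
    n_count: int
    total_len_all: int
    total_len_kept: int
    num_contigs_all: int
    num_contigs_kept: int


def read_assembly(path: str | Path, name: str, level: Level | str) -> Assembly:
    """Read a (possibly wrapped, CRLF-tolerant) multi-FASTA file.

    Raises
    ------
    ValueError
        If the file contains no records, a zero-length record, or is not
        FASTA-formatted.
    """
    path = Path(path)
    level = Level(level)
    records: list[tuple[str, str]] = []
    with open(path, "r", newline=None) as handle:
        first = handle.read(1)
        if first == "":
            raise ValueError(f"{path}: empty file, no FASTA records")
        if first != ">":
            raise ValueError(f"{path}: line 1: not FASTA (expected '>')")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if len(seq) == 0:
                raise ValueError(f"{path}: record {rec.id!r} has zero length")
            records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return Assembly(name=name, level=level, records=tuple(records))


def partition_chaff(
    assembly: Assembly, min_len: int = DEFAULT_CHAFF_MIN_LEN
) -> tuple[Assembly, Assembly]:
    """Split an assembly into (kept, chaff) at the chaff length threshold.

    Records strictly shorter than ``min_len`` are chaff; ties at the
    threshold are kept. The two parts partition the input.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = tuple(r for r in assembly.records if len(r[1]) >= min_len)
    chaff = tuple(r for r in assembly.records if len(r[1]) < min_len)
    return (
        Assembly(assembly.name, assembly.level, kept),
        Assembly(assembly.name, assembly.level, chaff),
    )


def contiguity_stats(lengths: Sequence[int]) -> tuple[int, int, int]:
    """Largest contig, N50 and L50 of a length multiset.

    N50 is the length of the record at which the descending-sorted
    cumulative length first reaches at least half the total; L50 is the
    size of that minimal covering prefix. Callers are expected to pass
    post-chaff lengths.
    """
    if not lengths:
        raise ValueError("no contigs after filtering")
    if any(x < 1 for x in lengths):
        raise ValueError("contig lengths must be >= 1")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    cum = 0
    for i, x in enumerate(ordered, start=1):
        cum += x
        if cum >= half:
            return ordered[0], x, i
    raise AssertionError("unreachable: prefix must reach half the total")


def l50_at_least_n50(lengths: Sequence[int]) -> int:
    """L50 counted as the number of records with length >= N50.

    Alternative convention; differs from the minimal-prefix count only
    when several records tie at the N50 length.
    """
    _, n50, _ = contiguity_stats(lengths)
    return sum(1 for x in lengths if x >= n50)


def chaff_percent(
    assembly: Assembly, min_len: int = DEFAULT_CHAFF_MIN_LEN
) -> float:
    """Chaff bases as a percentage of the total (pre-filter) assembly length."""
    if len(assembly) == 0:
        raise ValueError(f"assembly {assembly.name!r} is empty")
    lengths = assembly.lengths()
    chaff_len = sum(x for x in lengths if x < min_len)
    return 100.0 * chaff_len / sum(lengths)


def count_uncalled(assembly: Assembly) -> int:
    """Number of uncalled bases (N or n) across all records.

    Other IUPAC ambiguity codes are partial calls, not gaps, and are not
    counted. Pass the post-chaff assembly to match the metric definition.
    """
    return sum(seq.count("N") + seq.count("n") for _, seq in assembly.records)


def compute_metric_set(
    assembly: Assembly, min_len: int = DEFAULT_CHAFF_MIN_LEN
) -> MetricSet:
    """Compute the full goodness/problems metric set for one assembly.

    Chaff percentage uses the full record set; contiguity statistics and
    the N count use the post-chaff set.

    Raises
    ------
    ValueError
        If the assembly is empty or every record is chaff.
    """
    if len(assembly) == 0:
        raise ValueError(f"assembly {assembly.name!r} is empty")
    pct = chaff_percent(assembly, min_len)
    kept, _ = partition_chaff(assembly, min_len)
    if len(kept) == 0:
        raise ValueError(
            f"assembly {assembly.name!r}: no contigs after chaff filtering"
            f" at min_len={min_len}"
        )
    kept_lengths = kept.lengths()
    largest, n50, l50 = contiguity_stats(kept_lengths)
    return MetricSet(
        name=assembly.name,
        level=assembly.level,
        largest_contig=largest,
        n50=n50,
        l50=l50,
        chaff_pct=pct,
        n_count=count_uncalled(kept),
        total_len_all=sum(assembly.lengths()),
        total_len_kept=sum(kept_lengths),
        num_contigs_all=len(assembly),
        num_contigs_kept=len(kept),
    )
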