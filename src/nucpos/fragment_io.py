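"""Reading mapped nucleosome fragments, length filtering and dyad tables.

Coordinates are 0-based half-open internally.  Fragment sequences are stored
in reference-forward orientation regardless of mapping strand; the "leading
strand" of a nucleosome is taken to be the reference-forward strand of its
fragment.  Fragments containing ``N`` are retained here and excluded
position-wise from profile denominators downstream.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


@dataclass(slots=True)
class Fragment:
    """One mapped nucleosome-sized DNA interval with oriented sequence.

    ``start``/``end`` are 0-based half-open reference coordinates.  ``sequence``
    (if present) is given in reference-forward orientation, uppercase, over
    the alphabet {A, C, G, T, N}.
    """

    contig: str
    start: int
    end: int
    strand: str = "+"
    sequence: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise DataError(f"fragment start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise DataError(
                f"fragment end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise DataError(
                    f"sequence length {len(self.sequence)} does not match "
                    f"interval length {self.length}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class LengthFilter:
    """Inclusive fragment-length window in bp (e.g. 147-149 or 146-148)."""

    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.min_len <= 0 or self.max_len <= 0:
            raise ConfigurationError("length bounds must be positive")
        if self.min_len > self.max_len:
            raise ConfigurationError(
                f"min_len {self.min_len} exceeds max_len {self.max_len}"
            )

    def __contains__(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


@dataclass
class DyadTable:
    """Per-position dyad occurrence counts for one nucleosome population.

    ``counts`` maps contig -> {dyad position (0-based) -> occurrence}.
    Multiple fragments at the same dyad are counted multiply.
    """

    counts: dict[str, dict[int, int]] = field(default_factory=dict)

    @property
    def total_occurrence(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    @property
    def contigs(self) -> list[str]:
        return sorted(self.counts)

    def add(self, contig: str, position: int, occurrence: int = 1) -> None:
        if occurrence < 0:
            raise DataError("occurrence must be non-negative")
        self.counts.setdefault(contig, defaultdict(int))[position] += occurrence

    def to_tsv(self, path: str | Path) -> None:
        """Write a BED-like TSV: contig, position, position+1, occurrence."""
        with open(path, "w") as fh:
            for contig in self.contigs:
                for pos in sorted(self.counts[contig]):
                    occ = self.counts[contig][pos]
                    fh.write(f"{contig}\t{pos}\t{pos + 1}\t{occ}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DyadTable":
        table = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise DataError(f"{path}:{lineno}: expected 4 columns")
                table.add(fields[0], int(fields[1]), int(fields[3]))
        return table


def dyad_position(fragment: Fragment) -> int:
    """Reference coordinate of the fragment's dyad.

    Defined as ``start + floor((length - 1) / 2)``: the central base for
    odd lengths, the 5'-of-center base (reference-forward) for even lengths.
    """
    return fragment.start + (fragment.length - 1) // 2


def filter_by_length(
    fragments: Iterable[Fragment], length_filter: LengthFilter
) -> list[Fragment]:
    """Keep fragments with min_len <= length <= max_len, order preserved."""
    fragments = list(fragments)
    kept = [f for f in fragments if f.length in length_filter]
    logger.info(
        "length filter %d-%d: %d in, %d kept",
        length_filter.min_len,
        length_filter.max_len,
        len(fragments),
        len(kept),
    )
    return kept


def build_dyad_table(fragments: Iterable[Fragment]) -> DyadTable:
    """Tally fragments per dyad position per contig (duplicates counted multiply)."""
    table = DyadTable()
    n = 0
    for frag in fragments:
        table.add(frag.contig, dyad_position(frag))
        n += 1
    assert table.total_occurrence == n
    return table


# ---------------------------------------------------------------------------
# readers


def read_fragments(
    path: str | Path,
    format: str,
    reference: str | Path | None = None,
) -> list[Fragment]:
    """Read fragments from BED, BAM or FASTA.

    BED requires ``reference`` (a FASTA path) so sequences can be filled in.
    FASTA input yields coordinate-less fragments (contig = record id,
    start = 0).  Records whose sequence cannot be resolved are dropped and
    the count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    fmt = format.upper()
    if fmt == "BED":
        return _read_bed(path, reference)
    if fmt == "BAM":
        return _read_bam(path)
    if fmt == "FASTA":
        return _read_fasta(path)
    raise ConfigurationError(f"unknown format {format!r}; expected BED, BAM or FASTA")


def _read_bed(path: Path, reference: str | Path | None) -> list[Fragment]:
    if reference is None:
        raise ConfigurationError("BED input requires a reference FASTA")
    from pyfaidx import Fasta

    ref = Fasta(str(reference), sequence_always_upper=True)
    fragments: list[Fragment] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: BED line has <3 columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            if contig not in ref or end > len(ref[contig]):
                dropped += 1
                continue
            seq = ref[contig][start:end].seq
            fragments.append(
                Fragment(contig, start, end, strand=strand, sequence=seq, name=name)
            )
    if dropped:
        logger.warning("%s: dropped %d records with unresolvable sequence", path, dropped)
    logger.info("%s: read %d fragments (BED)", path, len(fragments))
    return fragments


def _read_bam(path: Path) -> list[Fragment]:
    """Aligned record span per fragment; skips unmapped/secondary records."""
    import pysam

    fragments: list[Fragment] = []
    dropped = 0
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for rec in bam:
            # samtools flag 260 semantics: unmapped or not primary
            if rec.is_unmapped or rec.is_secondary:
                skipped += 1
                continue
            seq = rec.query_sequence
            if seq is None or rec.reference_name is None:
                dropped += 1
                continue
            fragments.append(
                Fragment(
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    # query_sequence is already reference-forward in SAM/BAM
                    sequence=seq if len(seq) == rec.reference_end - rec.reference_start else None,
                    name=rec.query_name,
                )
            )
    if skipped:
        logger.info("%s: skipped %d unmapped/secondary records", path, skipped)
    if dropped:
        logger.warning("%s: dropped %d records without sequence", path, dropped)
    logger.info("%s: read %d fragments (BAM)", path, len(fragments))
    return fragments


def _read_fasta(path: Path) -> list[Fragment]:
    from Bio import SeqIO

    fragments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            continue
        fragments.append(
            Fragment(rec.id, 0, len(seq), strand="+", sequence=seq, name=rec.id)
        )
    logger.info("%s: read %d fragments (FASTA)", path, len(fragments))
    return fragments


def write_fragments_fasta(fragments: Sequence[Fragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, frag in enumerate(fragments):
            name = frag.name or f"frag{i}"
            fh.write(f">{name} {frag.contig}:{frag.start}-{frag.end}({frag.strand})\n")
            fh.write((frag.sequence or "") + "\n")


def write_fragments_bed(fragments: Sequence[Fragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, frag in enumerate(fragments):
            name = frag.name or f"frag{i}"
            fh.write(
                f"{frag.contig}\t{frag.start}\t{frag.end}\t{name}\t0\t{frag.strand}\n"
            )
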