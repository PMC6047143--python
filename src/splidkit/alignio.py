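"""Reading, masking, filtering and concatenation of alignment blocks.

Alignment blocks are the unit of processing: a gapped alignment over a
subset of the taxon universe, read either from an aligned FASTA file
(one block per file) or from a MAF file (one block per ``a`` paragraph).
Columns are indexed 0-based with half-open intervals throughout the
library; human-readable reports use 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import AlignIO, SeqIO

from .errors import FormatError, TaxonMismatchError

log = logging.getLogger(__name__)

#: Residue characters that carry sequence state (upper-case; N is an
#: unresolved residue, *not* missing data).
RESIDUES = frozenset("ACGTN")
GAP = "-"
MISSING = "?"

_ALPHABET = frozenset("ACGTNacgtn-?")

_LEADING_GAPS = re.compile(r"^-+")
_TRAILING_GAPS = re.compile(r"-+$")


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapped alignment over a subset of taxa.

    Rows are stored upper-cased.  The constructor enforces rectangularity
    and taxon uniqueness; rejection of pure-gap rows is the readers' job
    (synthetic pipelines may legitimately produce them, e.g. when a long
    simulated alignment is cut into blocks).
    """

    block_id: str
    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must be parallel")
        if not self.rows:
            raise ValueError(f"block {self.block_id!r} has no rows")
        length = len(self.rows[0])
        if length < 1:
            raise ValueError(f"block {self.block_id!r} has zero columns")
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != length:
                raise FormatError(
                    f"block {self.block_id!r}: row for {taxon!r} has length "
                    f"{len(row)}, expected {length}"
                )
            bad = set(row) - _ALPHABET
            if bad:
                raise FormatError(
                    f"block {self.block_id!r}: row for {taxon!r} contains "
                    f"illegal characters {sorted(bad)!r}"
                )
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError(f"block {self.block_id!r}: duplicate taxon identifiers")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.taxa


@dataclass(frozen=True)
class ConcatenatedAlignment:
    """Concatenation of blocks over a common taxon universe.

    Taxa absent from a member block are padded with ``?`` across that
    block's columns.  ``block_boundaries[i]`` is the half-open column
    interval of block ``block_ids[i]``; boundaries are hard breaks for
    gap runs downstream.
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    block_boundaries: tuple[tuple[int, int], ...]
    block_ids: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def block_view(self, index: int) -> AlignmentBlock:
        """Materialize member block ``index`` with its present taxa only.

        A taxon counts as absent from the block when its characters over
        the block's columns are all ``?``.
        """
        start, end = self.block_boundaries[index]
        taxa, rows = [], []
        for taxon, row in zip(self.taxa, self.rows):
            piece = row[start:end]
            if set(piece) == {MISSING}:
                continue
            taxa.append(taxon)
            rows.append(piece)
        return AlignmentBlock(
            block_id=self.block_ids[index],
            taxa=tuple(taxa),
            rows=tuple(rows),
            source=f"concat[{index}]",
        )


def _check_read_rows(block: AlignmentBlock) -> AlignmentBlock:
    for taxon, row in zip(block.taxa, block.rows):
        if set(row) <= {GAP}:
            raise FormatError(
                f"block {block.block_id!r}: row for {taxon!r} consists only of gaps"
            )
    return block


def read_fasta_alignment(path: str | Path, block_id: Optional[str] = None) -> AlignmentBlock:
    """Read one aligned FASTA file as a single block.

    Identifiers are taken from the header up to the first whitespace and
    sequences are upper-cased.  Unequal record lengths, duplicate
    identifiers and empty files are format errors.
    """
    path = Path(path)
    taxa: list[str] = []
    rows: list[str] = []
    length: Optional[int] = None
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise FormatError(
                f"{path}: record {record.id!r} has length {len(seq)}, "
                f"expected {length}"
            )
        if record.id in taxa:
            raise FormatError(f"{path}: duplicate identifier {record.id!r}")
        taxa.append(record.id)
        rows.append(seq)
    if not taxa:
        raise FormatError(f"{path}: no FASTA records found")
    block = AlignmentBlock(
        block_id=block_id or path.stem,
        taxa=tuple(taxa),
        rows=tuple(rows),
        source=str(path),
    )
    return _check_read_rows(block)


def read_maf(path: str | Path, split_names: bool = True) -> list[AlignmentBlock]:
    """Read a MAF file as a list of blocks, one per ``a`` paragraph.

    ``split_names`` truncates the ``s``-line source name at the first
    ``.`` (the species part of ``species.chromosome``); set it to False
    to keep the full source string.  ``i``/``e``/``q`` and comment lines
    are ignored.  A duplicate species within one paragraph keeps the
    first row and logs a warning.
    """
    path = Path(path)
    blocks: list[AlignmentBlock] = []
    for index, msa in enumerate(AlignIO.parse(str(path), "maf")):
        taxa: list[str] = []
        rows: list[str] = []
        for record in msa:
            name = record.id.split(".", 1)[0] if split_names else record.id
            if name in taxa:
                log.warning(
                    "%s block %d: duplicate species %r, keeping first row",
                    path, index, name,
                )
                continue
            taxa.append(name)
            rows.append(str(record.seq).upper())
        block = AlignmentBlock(
            block_id=f"{path.stem}.{index}",
            taxa=tuple(taxa),
            rows=tuple(rows),
            source=f"{path}#{index}",
        )
        blocks.append(_check_read_rows(block))
    if not blocks:
        raise FormatError(f"{path}: no MAF alignment blocks found")
    return blocks


def write_fasta_alignment(block: AlignmentBlock | ConcatenatedAlignment,
                          path: str | Path) -> None:
    """Write a block or concatenation as aligned FASTA (round-trip format)."""
    with open(path, "w") as handle:
        for taxon, row in zip(block.taxa, block.rows):
            handle.write(f">{taxon}\n{row}\n")


def mask_terminal_gaps(block: AlignmentBlock) -> AlignmentBlock:
    """Replace leading and trailing gap runs of every row by ``?``.

    Terminal gaps are alignment artifacts rather than evidence of
    deletion, so they are coded as missing data.  Interior gaps are
    untouched; the operation is idempotent.
    """
    rows = []
    for row in block.rows:
        row = _LEADING_GAPS.sub(lambda m: MISSING * len(m.group()), row)
        row = _TRAILING_GAPS.sub(lambda m: MISSING * len(m.group()), row)
        rows.append(row)
    return AlignmentBlock(block.block_id, block.taxa, tuple(rows), block.source)


def filter_blocks(blocks: Iterable[AlignmentBlock], min_taxa: int = 2,
                  require_gap: bool = True) -> list[AlignmentBlock]:
    """Keep blocks with at least ``min_taxa`` rows and, if ``require_gap``,
    at least one interior gap character (i.e. one surviving terminal-gap
    masking).  Order is preserved; blocks are returned unmodified."""
    kept = []
    for block in blocks:
        if len(block.taxa) < min_taxa:
            continue
        if require_gap and GAP not in "".join(mask_terminal_gaps(block).rows):
            continue
        kept.append(block)
    return kept


def concatenate(blocks: Sequence[AlignmentBlock],
                taxon_universe: Optional[Sequence[str]] = None) -> ConcatenatedAlignment:
    """Concatenate blocks over a taxon universe with ``?`` padding.

    The universe defaults to the union of block taxa in first-seen
    order.  A taxon present in a block but missing from an explicit
    universe is an error.
    """
    if not blocks:
        raise ValueError("cannot concatenate an empty list of blocks")
    if taxon_universe is None:
        universe: list[str] = []
        for block in blocks:
            for taxon in block.taxa:
                if taxon not in universe:
                    universe.append(taxon)
    else:
        universe = list(taxon_universe)
        for block in blocks:
            for taxon in block.taxa:
                if taxon not in universe:
                    raise TaxonMismatchError(
                        f"taxon {taxon!r} of block {block.block_id!r} is not "
                        f"in the supplied taxon universe"
                    )
    parts: dict[str, list[str]] = {taxon: [] for taxon in universe}
    boundaries: list[tuple[int, int]] = []
    offset = 0
    for block in blocks:
        for taxon in universe:
            if taxon in block:
                parts[taxon].append(block.row(taxon))
            else:
                parts[taxon].append(MISSING * block.length)
        boundaries.append((offset, offset + block.length))
        offset += block.length
    return ConcatenatedAlignment(
        taxa=tuple(universe),
        rows=tuple("".join(parts[taxon]) for taxon in universe),
        block_boundaries=tuple(boundaries),
        block_ids=tuple(block.block_id for block in blocks),
    )
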