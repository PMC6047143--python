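"""Binary character matrices: construction, invariant-site removal and
serialization to FASTA, relaxed PHYLIP and NEXUS, plus the TSV summary."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .engine import Splid, SummaryStats
from .errors import FormatError, TaxonMismatchError

_SYMBOLS = frozenset("01?")


@dataclass(frozen=True)
class BinaryMatrix:
    """Taxon-by-character matrix over the symbols 0/1/?."""

    taxa: tuple[str, ...]
    splids: tuple[Splid, ...]
    cells: tuple[str, ...]  # one row string per taxon

    def __post_init__(self) -> None:
        for row in self.cells:
            if len(row) != self.n_characters:
                raise ValueError("matrix is not rectangular")
            if set(row) - _SYMBOLS:
                raise ValueError("matrix cells must be 0, 1 or ?")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.splids) if self.splids else (len(self.cells[0]) if self.cells else 0)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.cells)


def build_matrix(splids: Sequence[Splid], taxa: Sequence[str]) -> BinaryMatrix:
    """One column per splid, in splid order; rows follow ``taxa``."""
    taxa = tuple(taxa)
    universe = set(taxa)
    for splid in splids:
        members = splid.presence | splid.absence | splid.missing
        if members != universe:
            raise TaxonMismatchError(
                f"splid taxon set {sorted(members)} does not match matrix taxa"
            )
    cells = tuple(
        "".join(splid.symbol(taxon) for splid in splids) for taxon in taxa
    )
    return BinaryMatrix(taxa=taxa, splids=tuple(splids), cells=cells)


def drop_invariant(matrix: BinaryMatrix) -> tuple[BinaryMatrix, int]:
    """Remove columns whose non-``?`` cells are all equal.

    Ascertainment-bias-corrected likelihoods require variable characters
    only, so constant columns (including all-missing ones) are dropped.
    Returns the filtered matrix and the number of removed columns.
    """
    keep = []
    for j in range(matrix.n_characters):
        states = set(matrix.column(j)) - {"?"}
        if len(states) >= 2:
            keep.append(j)
    removed = matrix.n_characters - len(keep)
    cells = tuple("".join(row[j] for j in keep) for row in matrix.cells)
    splids = tuple(matrix.splids[j] for j in keep) if matrix.splids else ()
    return BinaryMatrix(taxa=matrix.taxa, splids=splids, cells=cells), removed


def _sanitize_phylip(name: str, truncate: bool) -> str:
    clean = re.sub(r"\s", "_", name)
    return clean[:10] if truncate else clean


def write_matrix(matrix: BinaryMatrix, fmt: str, path: str | Path,
                 truncate_names: bool = False) -> None:
    """Serialize the matrix as ``fasta``, ``phylip`` (relaxed) or ``nexus``.

    The NEXUS output carries a comment block with each character's source
    block and 1-based coordinates for provenance.
    """
    path = Path(path)
    if fmt == "fasta":
        with open(path, "w") as fh:
            for taxon, row in zip(matrix.taxa, matrix.cells):
                fh.write(f">{taxon}\n{row}\n")
    elif fmt == "phylip":
        names = [_sanitize_phylip(t, truncate_names) for t in matrix.taxa]
        if len(set(names)) != len(names):
            raise FormatError("PHYLIP name sanitization produced collisions")
        pad = max((len(n) for n in names), default=1) + 2
        with open(path, "w") as fh:
            fh.write(f"{matrix.n_taxa} {matrix.n_characters}\n")
            for name, row in zip(names, matrix.cells):
                fh.write(f"{name.ljust(pad)}{row}\n")
    elif fmt == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n")
            if matrix.splids:
                fh.write("[characters: block, 1-based start-end, size]\n")
                for j, splid in enumerate(matrix.splids, start=1):
                    start, end = splid.indel.cols
                    fh.write(f"[{j}: {splid.indel.block_id} "
                             f"{start + 1}-{end} size={splid.size}]\n")
            fh.write("BEGIN DATA;\n")
            fh.write(f"    DIMENSIONS NTAX={matrix.n_taxa} "
                     f"NCHAR={matrix.n_characters};\n")
            fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" '
                     "MISSING=? GAP=-;\n")
            fh.write("    MATRIX\n")
            pad = max((len(t) for t in matrix.taxa), default=1) + 2
            for taxon, row in zip(matrix.taxa, matrix.cells):
                fh.write(f"    {taxon.ljust(pad)}{row}\n")
            fh.write("    ;\nEND;\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path: str | Path, fmt: str) -> BinaryMatrix:
    """Read back a matrix written by :func:`write_matrix` (round-trip
    checks; splid provenance is not reconstructed)."""
    path = Path(path)
    taxa: list[str] = []
    rows: list[str] = []
    if fmt == "fasta":
        name = None
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                taxa.append(line[1:].split()[0])
                rows.append("")
            elif line.strip():
                rows[-1] += line.strip()
    elif fmt == "phylip":
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        ntax, nchar = map(int, lines[0].split())
        for line in lines[1:1 + ntax]:
            name, symbols = line.split(None, 1)
            taxa.append(name)
            rows.append(symbols.replace(" ", ""))
        if any(len(r) != nchar for r in rows):
            raise FormatError(f"{path}: PHYLIP row length disagrees with header")
    elif fmt == "nexus":
        in_matrix = False
        for raw in path.read_text().splitlines():
            line = re.sub(r"\[[^\]]*\]", "", raw).strip()
            if not line:
                continue
            upper = line.upper()
            if upper == "MATRIX":
                in_matrix = True
                continue
            if in_matrix:
                if line == ";" or upper.startswith("END"):
                    break
                name, symbols = line.split(None, 1)
                taxa.append(name)
                rows.append(symbols.replace(" ", "").rstrip(";"))
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    if not taxa:
        raise FormatError(f"{path}: no matrix rows found")
    return BinaryMatrix(taxa=tuple(taxa), splids=(), cells=tuple(rows))


def write_summary(stats: SummaryStats, path: str | Path) -> None:
    """Tab-separated extraction report: totals, size histogram, per-block
    counts and one row per accepted splid (1-based coordinates)."""
    with open(path, "w") as fh:
        fh.write("# splid extraction summary\n")
        fh.write(f"total_splids\t{stats.n_splids}\n")
        fh.write(f"total_loci\t{stats.n_loci}\n")
        fh.write("\n# size histogram\nsize\tcount\n")
        for size in sorted(stats.size_histogram):
            fh.write(f"{size}\t{stats.size_histogram[size]}\n")
        fh.write("\n# per-block counts\nblock\tcount\n")
        for block_id in sorted(stats.per_block):
            fh.write(f"{block_id}\t{stats.per_block[block_id]}\n")
        fh.write("\n# splids\nblock\tstart\tend\tsize\tpresence\tabsence\tmissing\n")
        for rec in stats.records:
            fh.write(
                f"{rec.block_id}\t{rec.start}\t{rec.end}\t{rec.size}\t"
                f"{','.join(rec.presence)}\t{','.join(rec.absence)}\t"
                f"{','.join(rec.missing)}\n"
            )
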