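"""Core algorithm: from gap runs to binary-coded split-inducing indels.

An *indel* is a maximal run of gap characters with identical start and
stop columns shared by one or more taxa.  Overlapping indels chain into
*indel loci*, which are independent units of inference.  Within each
locus an indel is accepted as a split-inducing indel when

1. it is present in at least two taxa and its size lies within the
   configured bounds (default: size >= 2, no upper bound);
2. it does not overlap another indel satisfying rule 1 (both members of
   an overlapping candidate pair are discarded);
3. in *strict* mode it does not overlap a single-residue indel that
   occurs in at least two taxa (*fuzzy* mode skips this filter).

Each accepted indel is coded as one binary character: ``1`` for taxa
carrying a gap run with exactly the indel's boundaries, ``0`` for taxa
with residues across its columns, ``?`` for taxa with no sequence data
there or with a conflicting gap pattern.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .alignio import GAP, MISSING, RESIDUES, AlignmentBlock, ConcatenatedAlignment

_GAP_RUN = re.compile(r"-+")


@dataclass(frozen=True)
class GapRun:
    """A maximal run of ``-`` in one row, delimited by residues, ``?`` or
    the row ends.  ``cols`` is 0-based half-open."""

    taxon: str
    cols: tuple[int, int]
    block_id: str

    @property
    def size(self) -> int:
        return self.cols[1] - self.cols[0]


@dataclass(frozen=True)
class Indel:
    """A set of taxa sharing a gap run with identical boundaries."""

    cols: tuple[int, int]
    taxa: frozenset[str]
    block_id: str

    @property
    def size(self) -> int:
        return self.cols[1] - self.cols[0]

    def overlaps(self, other: "Indel") -> bool:
        return self.cols[0] < other.cols[1] and other.cols[0] < self.cols[1]


@dataclass(frozen=True)
class IndelLocus:
    """A maximal chain of mutually/transitively overlapping indels."""

    span: tuple[int, int]
    indels: tuple[Indel, ...]


@dataclass(frozen=True)
class Splid:
    """An accepted split-inducing indel with its taxon partition."""

    indel: Indel
    presence: frozenset[str]
    absence: frozenset[str]
    missing: frozenset[str]
    block_index: int = 0
    global_cols: tuple[int, int] | None = None

    @property
    def size(self) -> int:
        return self.indel.size

    def symbol(self, taxon: str) -> str:
        if taxon in self.presence:
            return "1"
        if taxon in self.absence:
            return "0"
        return MISSING

    def split_key(self) -> tuple[frozenset[str], int]:
        """Order-independent identity used in permutation-invariance checks."""
        return (self.presence, self.size)


@dataclass(frozen=True)
class SplidConfig:
    min_size: int = 2
    max_size: int | None = None
    mode: str = "strict"

    def __post_init__(self) -> None:
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.max_size is not None and self.max_size < self.min_size:
            raise ValueError("min_size must not exceed max_size")
        if self.mode not in ("strict", "fuzzy"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SplidRecord:
    """Human-readable provenance of one accepted splid (1-based inclusive)."""

    block_id: str
    start: int
    end: int
    size: int
    presence: tuple[str, ...]
    absence: tuple[str, ...]
    missing: tuple[str, ...]


@dataclass
class SummaryStats:
    n_splids: int = 0
    n_loci: int = 0
    size_histogram: Counter = field(default_factory=Counter)
    per_block: Counter = field(default_factory=Counter)
    records: list[SplidRecord] = field(default_factory=list)


def find_gap_runs(block: AlignmentBlock) -> list[GapRun]:
    """Maximal ``-`` runs per row, sorted by (start, taxon).

    ``?`` delimits runs: a gap run never extends through missing data.
    """
    runs = []
    for taxon, row in zip(block.taxa, block.rows):
        for match in _GAP_RUN.finditer(row):
            runs.append(GapRun(taxon, (match.start(), match.end()), block.block_id))
    runs.sort(key=lambda r: (r.cols[0], r.taxon))
    return runs


def group_indels(runs: Iterable[GapRun]) -> list[Indel]:
    """Partition runs by exact (block, start, end); one indel per class."""
    classes: dict[tuple[str, int, int], set[str]] = defaultdict(set)
    for run in runs:
        classes[(run.block_id, *run.cols)].add(run.taxon)
    indels = [
        Indel(cols=(start, end), taxa=frozenset(taxa), block_id=block_id)
        for (block_id, start, end), taxa in classes.items()
    ]
    indels.sort(key=lambda i: i.cols)
    return indels


def find_loci(indels: Sequence[Indel]) -> list[IndelLocus]:
    """Connected components of the column-overlap graph, by span start.

    Because members are intervals, a sweep over start-sorted indels
    finds the components: a new locus starts whenever the next indel
    begins at or after the running span end (half-open intervals, so
    abutting indels share no column and fall into separate loci).
    """
    ordered = sorted(indels, key=lambda i: i.cols)
    loci: list[IndelLocus] = []
    current: list[Indel] = []
    span_end = -1
    for indel in ordered:
        if current and indel.cols[0] < span_end:
            current.append(indel)
            span_end = max(span_end, indel.cols[1])
        else:
            if current:
                loci.append(IndelLocus((current[0].cols[0], span_end), tuple(current)))
            current = [indel]
            span_end = indel.cols[1]
    if current:
        loci.append(IndelLocus((current[0].cols[0], span_end), tuple(current)))
    return loci


def candidate_splids(locus: IndelLocus, config: SplidConfig) -> list[Indel]:
    """Rule 1: at least two taxa and size within the configured bounds."""
    return [
        indel for indel in locus.indels
        if len(indel.taxa) >= 2 and config.min_size <= indel.size
        and (config.max_size is None or indel.size <= config.max_size)
    ]


def exclude_mutual_overlaps(candidates: Sequence[Indel]) -> list[Indel]:
    """Rule 2: discard every candidate overlapping another candidate.

    Both members of an overlapping pair are removed; candidates that
    overlap only non-candidate indels survive.
    """
    kept = []
    for i, indel in enumerate(candidates):
        if any(i != j and indel.overlaps(other) for j, other in enumerate(candidates)):
            continue
        kept.append(indel)
    return kept


def strict_filter(candidates: Sequence[Indel], locus: IndelLocus) -> list[Indel]:
    """Rule 3 (strict mode): discard candidates overlapping a
    single-residue indel that occurs in at least two taxa."""
    triggers = [i for i in locus.indels if i.size == 1 and len(i.taxa) >= 2]
    if not triggers:
        return list(candidates)
    return [c for c in candidates if not any(c.overlaps(t) for t in triggers)]


def code_splid(indel: Indel, block: AlignmentBlock,
               taxon_universe: Sequence[str]) -> Splid:
    """Binary-code one accepted indel over the taxon universe.

    ``1``: the taxon's gap run matches the indel's boundaries exactly.
    ``0``: the taxon has residues (A/C/G/T/N) across all indel columns.
    ``?``: the taxon is absent from the block, has missing data in the
    indel's columns, or carries gaps with non-matching run boundaries.
    """
    start, end = indel.cols
    presence, absence, missing = set(), set(), set()
    for taxon in taxon_universe:
        if taxon not in block:
            missing.add(taxon)
            continue
        row = block.row(taxon)
        segment = row[start:end]
        if set(segment) <= RESIDUES:
            absence.add(taxon)
        elif (set(segment) == {GAP}
              and (start == 0 or row[start - 1] != GAP)
              and (end == len(row) or row[end] != GAP)):
            presence.add(taxon)
        else:
            missing.add(taxon)
    return Splid(
        indel=indel,
        presence=frozenset(presence),
        absence=frozenset(absence),
        missing=frozenset(missing),
    )


def _extract_from_block(block: AlignmentBlock, config: SplidConfig,
                        taxon_universe: Sequence[str]) -> tuple[list[Splid], int]:
    runs = find_gap_runs(block)
    indels = group_indels(runs)
    loci = find_loci(indels)
    splids: list[Splid] = []
    for locus in loci:
        accepted = exclude_mutual_overlaps(candidate_splids(locus, config))
        if config.mode == "strict":
            accepted = strict_filter(accepted, locus)
        for indel in sorted(accepted, key=lambda i: i.cols):
            splids.append(code_splid(indel, block, taxon_universe))
    return splids, len(loci)


def extract_splids(
    alignment: Union[AlignmentBlock, ConcatenatedAlignment],
    config: SplidConfig = SplidConfig(),
) -> tuple[list[Splid], SummaryStats]:
    """Run the full pipeline on a block or a concatenation.

    Concatenations are processed block by block (block boundaries are
    hard breaks for gap runs); splids are ordered by (block index,
    start column).  Summary coordinates are 1-based inclusive.
    """
    stats = SummaryStats()
    splids: list[Splid] = []
    if isinstance(alignment, ConcatenatedAlignment):
        universe = alignment.taxa
        for index in range(len(alignment.block_ids)):
            block = alignment.block_view(index)
            offset = alignment.block_boundaries[index][0]
            block_splids, n_loci = _extract_from_block(block, config, universe)
            stats.n_loci += n_loci
            for splid in block_splids:
                start, end = splid.indel.cols
                splids.append(Splid(
                    indel=splid.indel,
                    presence=splid.presence,
                    absence=splid.absence,
                    missing=splid.missing,
                    block_index=index,
                    global_cols=(offset + start, offset + end),
                ))
    else:
        universe = alignment.taxa
        block_splids, n_loci = _extract_from_block(alignment, config, universe)
        stats.n_loci = n_loci
        splids = [
            Splid(indel=s.indel, presence=s.presence, absence=s.absence,
                  missing=s.missing, block_index=0, global_cols=s.indel.cols)
            for s in block_splids
        ]
    stats.n_splids = len(splids)
    for splid in splids:
        stats.size_histogram[splid.size] += 1
        stats.per_block[splid.indel.block_id] += 1
        start, end = splid.indel.cols
        stats.records.append(SplidRecord(
            block_id=splid.indel.block_id,
            start=start + 1,
            end=end,
            size=splid.size,
            presence=tuple(sorted(splid.presence)),
            absence=tuple(sorted(splid.absence)),
            missing=tuple(sorted(splid.missing)),
        ))
    return splids, stats
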