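from __future__ import annotations

import numpy as np
import pytest

from splidkit.alignio import AlignmentBlock, concatenate


def _punch(row: list[str], start: int, end: int) -> None:
    row[start:end] = ["-"] * (end - start)


def make_block(block_id: str, gaps: dict[str, list[tuple[int, int]]],
               length: int, taxa: list[str]) -> AlignmentBlock:
    """Residue-filled block with gap runs punched at given intervals."""
    rows = []
    for i, taxon in enumerate(taxa):
        row = list("ACGT"[(i + j) % 4] for j in range(length))
        for start, end in gaps.get(taxon, []):
            _punch(row, start, end)
        rows.append("".join(row))
    return AlignmentBlock(block_id, tuple(taxa), tuple(rows))


@pytest.fixture
def caption_blocks():
    """Two-block fixture realizing the reference caption's 13 indels.

    Block A (taxa a..g, 20 columns) holds three loci:
      locus I  ([1,10)): e[1,2), c[1,4), d[2,4), e[3,9),
                         {a,b}[5,8) and {f,g}[8,10)  (the two splids),
      locus II ([11,13)): e[11,13) and the size-1 pair {c,d}[12,13),
      locus III ([14,18)): overlapping candidates {a,b}[14,17) and
                           {c,d}[15,18) (mutually excluded).
    Block B (taxa a..f, 10 columns; g absent) holds locus IV:
      candidate {a,b}[2,6), its strict-mode trigger {c,d}[3,4),
      and the single-taxon e[5,8).
    """
    block_a = make_block(
        "A",
        {
            "a": [(5, 8), (14, 17)],
            "b": [(5, 8), (14, 17)],
            "c": [(1, 4), (12, 13), (15, 18)],
            "d": [(2, 4), (12, 13), (15, 18)],
            "e": [(1, 2), (3, 9), (11, 13)],
            "f": [(8, 10)],
            "g": [(8, 10)],
        },
        length=20,
        taxa=list("abcdefg"),
    )
    block_b = make_block(
        "B",
        {
            "a": [(2, 6)],
            "b": [(2, 6)],
            "c": [(3, 4)],
            "d": [(3, 4)],
            "e": [(5, 8)],
        },
        length=10,
        taxa=list("abcdef"),
    )
    return [block_a, block_b]


@pytest.fixture
def caption_alignment(caption_blocks):
    return concatenate(caption_blocks, taxon_universe=list("abcdefg"))


def random_alignment(rng: np.random.Generator, max_taxa: int = 6,
                     max_cols: int = 30, alphabet: str = "AC-?",
                     weights=(0.35, 0.2, 0.35, 0.1)) -> AlignmentBlock:
    """Gap-rich random block for oracle-equivalence and property tests."""
    n_taxa = int(rng.integers(2, max_taxa + 1))
    n_cols = int(rng.integers(2, max_cols + 1))
    taxa = tuple(f"t{i}" for i in range(n_taxa))
    chars = np.array(list(alphabet))
    rows = tuple(
        "".join(rng.choice(chars, size=n_cols, p=weights))
        for _ in range(n_taxa)
    )
    return AlignmentBlock("rand", taxa, rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
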