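"""Dual-granularity one-hot encodings of DNA contigs.

A contig is represented at two granularities:

* **base level** — an ``L x 4`` binary matrix, one row per nucleotide, with
  column order (A, C, G, T).  Characters outside {A, C, G, T} (N and IUPAC
  ambiguity codes alike) become an all-zero row.
* **codon level** — the three forward-strand reading frames are read as
  codons and encoded into a ``R x 64`` binary matrix, where
  ``R = sum_f floor((L - f) / 3)`` and the rows of the three frames are
  stacked in frame order 0, 1, 2.  Codon columns are ordered
  lexicographically over the (A, C, G, T) alphabet, so AAA is column 0 and
  TTT is column 63.  A codon window containing any non-ACGT character maps
  to an all-zero row.

The codon matrix can be produced two ways: directly (:func:`encode_codons_direct`)
or by convolving the base matrix with 64 fixed codon-template kernels and a
thresholded rectification (:func:`apply_codon_transformer`).  The two routes
are bit-identical by construction; the fixed convolution is what lets a
network compute codon identity from base input without trainable parameters.

Sequences are uppercased before encoding; only the forward strand is read.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Dict, List, Tuple, Union

import numpy as np

__all__ = [
    "Role",
    "ContigRecord",
    "BaseOneHot",
    "CodonOneHot",
    "CodonFilter",
    "CODON_ORDER",
    "CODON_INDEX",
    "encode_bases",
    "enumerate_frames",
    "encode_codons_direct",
    "build_codon_filter",
    "apply_codon_transformer",
]


class Role(str, Enum):
    """Which side of an association pair a contig belongs to."""

    PHAGE = "phage"
    HOST = "host"


@dataclass(frozen=True)
class ContigRecord:
    """An identified DNA sequence with its role and genome of origin."""

    id: str
    sequence: str
    role: Role
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"contig {self.id!r}: sequence must be non-empty")
        object.__setattr__(self, "role", Role(self.role))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, eq=False)
class BaseOneHot:
    """``L x 4`` binary matrix over column order (A, C, G, T)."""

    matrix: np.ndarray

    @property
    def L(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True, eq=False)
class CodonOneHot:
    """``R x 64`` binary matrix; frames 0,1,2 stacked along the row axis."""

    matrix: np.ndarray
    frame_offsets: Tuple[Tuple[int, int], ...]

    @property
    def R(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True, eq=False)
class CodonFilter:
    """64 codon-template kernels of shape 3x4 plus the codon->index bijection."""

    kernels: np.ndarray  # (64, 3, 4), uint8
    codon_index: Dict[str, int]


#: All 64 codons in lexicographic (A, C, G, T) order.
CODON_ORDER: Tuple[str, ...] = tuple(
    "".join(c) for c in product("ACGT", repeat=3)
)
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CODON_ORDER)}

# byte -> base code lookup: A,C,G,T (upper or lower) -> 0..3, anything else -> 4
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

# row templates: codes 0..3 -> unit rows, code 4 -> zero row
_BASE_ROWS = np.vstack([np.eye(4, dtype=np.uint8), np.zeros((1, 4), dtype=np.uint8)])


def _codes(sequence: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def _as_sequence(contig: Union[ContigRecord, str]) -> str:
    return contig.sequence if isinstance(contig, ContigRecord) else contig


def encode_bases(contig: Union[ContigRecord, str]) -> BaseOneHot:
    """Encode a contig as its base-level one-hot matrix.

    Each of A, C, G, T maps to the corresponding unit row vector; any other
    character maps to the all-zero row.  Case-insensitive.

    Raises
    ------
    ValueError
        If the sequence is empty.
    """
    seq = _as_sequence(contig)
    if len(seq) == 0:
        raise ValueError("cannot encode an empty sequence")
    return BaseOneHot(matrix=_BASE_ROWS[_codes(seq)])


def enumerate_frames(sequence: str) -> Tuple[List[str], List[str], List[str]]:
    """Read the three forward reading frames as codon lists.

    Frame ``f`` starts at offset ``f`` and contains ``floor((L - f) / 3)``
    codons; trailing bases that do not fill a codon are dropped.
    """
    seq = sequence.upper()
    frames: List[List[str]] = []
    for f in range(3):
        n = max(0, (len(seq) - f) // 3)
        frames.append([seq[f + 3 * i : f + 3 * i + 3] for i in range(n)])
    return frames[0], frames[1], frames[2]


def _codon_rows_per_frame(codes: np.ndarray) -> List[np.ndarray]:
    """Per-frame codon one-hot blocks (each n_f x 64, uint8)."""
    L = codes.shape[0]
    blocks: List[np.ndarray] = []
    for f in range(3):
        n = max(0, (L - f) // 3)
        block = np.zeros((n, 64), dtype=np.uint8)
        if n:
            tri = codes[f : f + 3 * n].reshape(n, 3)
            valid = (tri < 4).all(axis=1)
            idx = tri[:, 0].astype(np.intp) * 16 + tri[:, 1] * 4 + tri[:, 2]
            rows = np.nonzero(valid)[0]
            block[rows, idx[rows]] = 1
        blocks.append(block)
    return blocks


def _frame_offsets(lengths: List[int]) -> Tuple[Tuple[int, int], ...]:
    out, start = [], 0
    for n in lengths:
        out.append((start, start + n))
        start += n
    return tuple(out)


def encode_codons_direct(contig: Union[ContigRecord, str]) -> CodonOneHot:
    """Encode a contig's three reading frames as a stacked codon one-hot matrix.

    Rows are the frame-0, frame-1, frame-2 codon one-hots concatenated along
    the row axis.  A codon containing any non-ACGT character yields an
    all-zero row.
    """
    codes = _codes(_as_sequence(contig))
    blocks = _codon_rows_per_frame(codes)
    matrix = (
        np.concatenate(blocks, axis=0)
        if any(b.shape[0] for b in blocks)
        else np.zeros((0, 64), dtype=np.uint8)
    )
    return CodonOneHot(
        matrix=matrix, frame_offsets=_frame_offsets([b.shape[0] for b in blocks])
    )


def build_codon_filter() -> CodonFilter:
    """Construct the 64 fixed codon-template kernels.

    Kernel ``i`` is the base one-hot matrix of codon ``CODON_ORDER[i]``; its
    inner product with the base one-hot of a 3-mer equals the number of
    positions where the 3-mer matches the codon, so only the matching codon
    reaches the maximum of 3.
    """
    kernels = np.zeros((64, 3, 4), dtype=np.uint8)
    for i, codon in enumerate(CODON_ORDER):
        kernels[i] = _BASE_ROWS[_codes(codon)]
    return CodonFilter(kernels=kernels, codon_index=dict(CODON_INDEX))


_FILTER = build_codon_filter()


def apply_codon_transformer(base: BaseOneHot) -> CodonOneHot:
    """Convert a base one-hot matrix into the codon one-hot matrix.

    Implements ``f(M) = ReLU(F * M - 2)`` over every 3-row window of the base
    matrix: the per-kernel inner sum is 3 only for the window's own codon
    (rectifying ``3 - 2`` to 1) and at most 2 otherwise (rectified to 0).  A
    window overlapping a zero row can reach at most 2, so it yields an
    all-zero output row — exactly the non-ACGT rule of the direct encoder.

    Output rows are regrouped by frame (offsets 0, 1, 2 stacked in order) and
    are bit-identical to :func:`encode_codons_direct` on the same contig.
    An input with fewer than 3 rows yields an empty codon matrix.
    """
    M = base.matrix
    L = M.shape[0]
    if L < 3:
        return CodonOneHot(
            matrix=np.zeros((0, 64), dtype=np.uint8),
            frame_offsets=_frame_offsets([0, 0, 0]),
        )
    # windows: (L-2, 3, 4); scores: (L-2, 64) integer inner sums
    windows = np.lib.stride_tricks.sliding_window_view(M, (3, 4)).reshape(L - 2, 3, 4)
    scores = np.tensordot(
        windows.astype(np.int16), _FILTER.kernels.astype(np.int16), axes=([1, 2], [1, 2])
    )
    rectified = np.maximum(scores - 2, 0).astype(np.uint8)
    blocks = [rectified[f::3] for f in range(3)]
    return CodonOneHot(
        matrix=np.concatenate(blocks, axis=0),
        frame_offsets=_frame_offsets([b.shape[0] for b in blocks]),
    )
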