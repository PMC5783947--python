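"""Aptamer constructs and their extension-aware coordinate system.

An aptamer construct is the full synthesized strand: the consensus aptamer
sequence, optionally preceded by a 5' extension and/or followed by a 3'
extension.  Bases are addressed with 1-based *aptamer coordinates*: the first
consensus base is coordinate 1, 5'-extension bases count backwards from -1,
and there is no coordinate 0.  An ATP-aptamer construct with a 5-base 5'
extension therefore spans coordinates -5..-1, 1..27.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick complement of an aptamer base, written in the DNA alphabet
#: (microarray probes are DNA regardless of the aptamer chemistry).
DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


class CoordinateError(ValueError):
    """An aptamer coordinate is 0 or outside the construct."""


@dataclass(frozen=True)
class AptamerConstruct:
    """A 5'->3' aptamer sequence with extension-aware coordinates.

    Parameters
    ----------
    id : str
        Identifier used to tie designs, probes and spot tables together.
    sequence : str
        Full construct sequence, 5'->3', pure DNA ({A,C,G,T}) or pure RNA
        ({A,C,G,U}).
    consensus_start : int
        1-based position *within the sequence string* of the first consensus
        base (coordinate 1).  ``consensus_start=6`` means a 5-base 5'
        extension occupying coordinates -5..-1.
    description : str
        Free-text provenance.
    """

    id: str
    sequence: str
    consensus_start: int = 1
    description: str = ""
    alphabet: str = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("aptamer sequence must be non-empty")
        bases = set(seq)
        if bases <= DNA_ALPHABET:
            alphabet = "DNA"
        elif bases <= RNA_ALPHABET:
            alphabet = "RNA"
        else:
            raise ValueError(
                f"sequence of {self.id!r} is neither pure DNA nor pure RNA: "
                f"unexpected characters {sorted(bases - (DNA_ALPHABET | RNA_ALPHABET))}"
            )
        object.__setattr__(self, "alphabet", alphabet)
        if not 1 <= self.consensus_start <= len(seq):
            raise ValueError(
                f"consensus_start {self.consensus_start} outside sequence of "
                f"length {len(seq)}"
            )

    # -- coordinate arithmetic -------------------------------------------

    @property
    def n_5prime_ext(self) -> int:
        """Number of 5'-extension bases (coordinates -n..-1)."""
        return self.consensus_start - 1

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def first_coord(self) -> int:
        return -self.n_5prime_ext if self.n_5prime_ext else 1

    @property
    def last_coord(self) -> int:
        return len(self.sequence) - self.n_5prime_ext

    def index(self, coord: int) -> int:
        """0-based string index of an aptamer coordinate."""
        if coord == 0:
            raise CoordinateError("aptamer coordinates have no position 0")
        i = self.n_5prime_ext + coord - (0 if coord < 0 else 1)
        if not 0 <= i < len(self.sequence):
            raise CoordinateError(
                f"coordinate {coord} outside construct {self.id!r} "
                f"({self.first_coord}..{self.last_coord})"
            )
        return i

    def coord(self, index: int) -> int:
        """Aptamer coordinate of a 0-based string index."""
        if not 0 <= index < len(self.sequence):
            raise CoordinateError(f"index {index} outside sequence")
        c = index - self.n_5prime_ext
        return c if c < 0 else c + 1

    def shift(self, coord: int, delta: int) -> int:
        """The coordinate ``delta`` bases 3' of ``coord`` (skipping 0)."""
        return self.coord(self.index(coord) + delta)

    def base(self, coord: int) -> str:
        return self.sequence[self.index(coord)]

    def coords(self) -> list[int]:
        """All coordinates, 5'->3'."""
        return [self.coord(i) for i in range(len(self.sequence))]

    def window_coords(self, start5: int, length: int) -> list[int]:
        """Coordinates of the ``length``-base window beginning at ``start5``."""
        i0 = self.index(start5)
        if i0 + length > len(self.sequence):
            raise CoordinateError(
                f"window start {start5} length {length} runs past the 3' end "
                f"of {self.id!r}"
            )
        return [self.coord(i0 + k) for k in range(length)]

    def window_sequence(self, start5: int, length: int) -> str:
        i0 = self.index(start5)
        if i0 + length > len(self.sequence):
            raise CoordinateError(
                f"window start {start5} length {length} runs past the 3' end "
                f"of {self.id!r}"
            )
        return self.sequence[i0 : i0 + length]
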