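"""ACE library design: enumeration, counting, naming, probes, layout.

An ACE (aptamer-complementary element) is a short DNA oligo complementary to
one window of an aptamer.  A library tiles the aptamer with every window of
every requested length, optionally adding single-mismatch variants, and lays
the probes out on identical randomized microarray sub-arrays.

Naming convention
-----------------
A design is written ``5ʹ_{N}{b}:{L}`` — an ACE of length L whose duplex
starts at aptamer coordinate N (5'-most duplexed aptamer base), with ``b``
the aptamer base at N.  The equivalent 3'-anchored name uses the 3'-most
duplexed coordinate, ``N3 = N5 + L - 1`` counted in aptamer coordinates
(which skip 0 across the consensus boundary).  Mismatched designs append
``:{MM}{b}`` with the aptamer coordinate and base of the mismatched pair,
e.g. ``5ʹ_4T:12:6G``.

Mismatch rule
-------------
Mismatches are introduced in the *probe*: a perfect-match probe base G, C or
T is replaced by A (giving A·C, A·G and A·A probe-aptamer mismatches), and a
probe base A is replaced by T (giving T·T).  Adenosine mismatches keep the
destabilization roughly uniform across positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aptamer import DNA_COMPLEMENT, AptamerConstruct, CoordinateError

PRIME = "ʹ"  # modifier letter prime, as printed in design names

#: probe-side single-mismatch substitution (see module docstring)
MISMATCH_SUBSTITUTION = {"G": "A", "C": "A", "T": "A", "A": "T"}


class DesignError(ValueError):
    """A design request violates the aptamer geometry or grid capacity."""


@dataclass(frozen=True)
class AceDesign:
    """One ACE: a duplex window on an aptamer plus synthesis decorations.

    ``start5`` and ``mismatch_pos`` are aptamer coordinates; ``length`` is
    the duplexed length.  ``spacer3_len`` poly-T bases separate the duplex
    from the slide surface (3' light-directed synthesis); ``linker5_len``
    optionally extends the spacer at the probe 5' end.
    """

    aptamer_id: str
    start5: int
    length: int
    mismatch_pos: int | None = None
    spacer3_len: int = 25
    linker5_len: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise DesignError(f"ACE length must be >= 1, got {self.length}")
        if self.spacer3_len < 0 or self.linker5_len < 0:
            raise DesignError("spacer/linker lengths must be >= 0")

    @property
    def key(self) -> tuple[int, int, int | None]:
        return (self.start5, self.length, self.mismatch_pos)


def validate_design(ace: AceDesign, aptamer: AptamerConstruct) -> list[int]:
    """Check a design against its aptamer; return the window coordinates."""
    if ace.aptamer_id != aptamer.id:
        raise DesignError(
            f"design references aptamer {ace.aptamer_id!r}, got {aptamer.id!r}"
        )
    try:
        coords = aptamer.window_coords(ace.start5, ace.length)
    except CoordinateError as exc:
        raise DesignError(str(exc)) from exc
    if ace.mismatch_pos is not None and ace.mismatch_pos not in coords:
        raise DesignError(
            f"mismatch coordinate {ace.mismatch_pos} outside duplex window "
            f"{coords[0]}..{coords[-1]}"
        )
    return coords


def end3(ace: AceDesign, aptamer: AptamerConstruct) -> int:
    """3'-most duplexed aptamer coordinate (N3 = N5 + L - 1, skipping 0)."""
    return aptamer.shift(ace.start5, ace.length - 1)


# ---------------------------------------------------------------------------
# enumeration


def enumerate_perfect_match(
    aptamer: AptamerConstruct,
    min_len: int,
    max_len: int,
    *,
    spacer3_len: int = 25,
    linker5_len: int = 0,
) -> list[AceDesign]:
    """All perfect-match windows of every length in ``[min_len, max_len]``.

    For a length-``L`` aptamer there are ``L - N + 1`` windows of length
    ``N``; designs are returned 5'->3' within each length, lengths ascending.
    """
    L = len(aptamer)
    if not 1 <= min_len <= max_len:
        raise DesignError(f"invalid length range {min_len}..{max_len}")
    if max_len > L:
        raise DesignError(
            f"ACE length {max_len} exceeds aptamer length {L} of {aptamer.id!r}"
        )
    out: list[AceDesign] = []
    for n in range(min_len, max_len + 1):
        for i0 in range(L - n + 1):
            out.append(
                AceDesign(
                    aptamer_id=aptamer.id,
                    start5=aptamer.coord(i0),
                    length=n,
                    spacer3_len=spacer3_len,
                    linker5_len=linker5_len,
                )
            )
    return out


def enumerate_single_mismatch(
    aptamer: AptamerConstruct,
    lengths: "int | list[int] | set[int]",
    *,
    spacer3_len: int = 25,
    linker5_len: int = 0,
) -> list[AceDesign]:
    """All single-mismatch variants: one design per window per position.

    Every position of every window is mismatched, termini included, so a
    length-``N`` window contributes ``N`` designs and a length-``L`` aptamer
    ``N * (L - N + 1)`` designs per requested length.
    """
    if isinstance(lengths, int):
        lengths = [lengths]
    L = len(aptamer)
    out: list[AceDesign] = []
    for n in sorted(set(lengths)):
        if not 1 <= n <= L:
            raise DesignError(
                f"ACE length {n} exceeds aptamer length {L} of {aptamer.id!r}"
            )
        for i0 in range(L - n + 1):
            start5 = aptamer.coord(i0)
            for k in range(n):
                out.append(
                    AceDesign(
                        aptamer_id=aptamer.id,
                        start5=start5,
                        length=n,
                        mismatch_pos=aptamer.coord(i0 + k),
                        spacer3_len=spacer3_len,
                        linker5_len=linker5_len,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# closed-form counts
#
# In these two functions only, symbols follow the combinatorial convention:
# L is the aptamer length and X..Y the range of ACE lengths.


def _check_bounds(L: int, X: int, Y: int) -> None:
    if not 1 <= X <= Y <= L:
        raise DesignError(f"require 1 <= X <= Y <= L, got X={X}, Y={Y}, L={L}")


def count_perfect_match(L: int, X: int, Y: int) -> int:
    """Number of perfect-match ACEs of lengths X..Y on a length-L aptamer.

    Closed form ``[(Y-X+1)(2L+1) - Y^2 + (X-1)^2] / 2``; equals
    ``sum_{N=X..Y} (L - N + 1)``.
    """
    _check_bounds(L, X, Y)
    num = (Y - X + 1) * (2 * L + 1) - Y * Y + (X - 1) * (X - 1)
    assert num % 2 == 0
    return num // 2


def count_single_mismatch(L: int, X: int, Y: int) -> int:
    """Number of single-mismatch ACEs of lengths X..Y on a length-L aptamer.

    Closed form ``[Y(Y+1)(3L-2Y+2) - X(X-1)(3L-2X+4)] / 6``; equals
    ``sum_{N=X..Y} N (L - N + 1)``.
    """
    _check_bounds(L, X, Y)
    num = Y * (Y + 1) * (3 * L - 2 * Y + 2) - X * (X - 1) * (3 * L - 2 * X + 4)
    assert num % 6 == 0
    return num // 6


# ---------------------------------------------------------------------------
# probe sequences


def duplex_probe_core(ace: AceDesign, aptamer: AptamerConstruct) -> str:
    """The duplex-forming part of the probe, 5'->3', mismatch applied."""
    coords = validate_design(ace, aptamer)
    window = aptamer.window_sequence(ace.start5, ace.length)
    # reverse complement in the DNA alphabet; probe base j pairs window base
    # length-1-j
    probe = [DNA_COMPLEMENT[b] for b in reversed(window)]
    if ace.mismatch_pos is not None:
        j = ace.length - 1 - coords.index(ace.mismatch_pos)
        probe[j] = MISMATCH_SUBSTITUTION[probe[j]]
    return "".join(probe)


def is_degenerate(ace: AceDesign, aptamer: AptamerConstruct) -> bool:
    """True when the mismatch substitution is a fixed point.

    A degenerate design is sequence-identical to its perfect-match
    counterpart.  Under the A/T substitution rule this cannot happen for
    valid inputs, but the flag is kept so enumerated counts always match the
    closed forms even if the substitution table is customized downstream.
    """
    if ace.mismatch_pos is None:
        return False
    pm = AceDesign(
        aptamer_id=ace.aptamer_id,
        start5=ace.start5,
        length=ace.length,
        spacer3_len=ace.spacer3_len,
        linker5_len=ace.linker5_len,
    )
    return duplex_probe_core(ace, aptamer) == duplex_probe_core(pm, aptamer)


def probe_sequence(ace: AceDesign, aptamer: AptamerConstruct) -> str:
    """Full synthesized probe: 5' T-linker + duplex core + 3' T-spacer."""
    core = duplex_probe_core(ace, aptamer)
    return "T" * ace.linker5_len + core + "T" * ace.spacer3_len


# ---------------------------------------------------------------------------
# names


def format_name(
    ace: AceDesign, aptamer: AptamerConstruct, anchor: str = "5p"
) -> str:
    """Canonical design name, 5'- or 3'-anchored (see module docstring)."""
    validate_design(ace, aptamer)
    if anchor == "5p":
        n = ace.start5
    elif anchor == "3p":
        n = end3(ace, aptamer)
    else:
        raise ValueError(f"anchor must be '5p' or '3p', got {anchor!r}")
    name = f"{anchor[0]}{PRIME}_{n}{aptamer.base(n)}:{ace.length}"
    if ace.mismatch_pos is not None:
        name += f":{ace.mismatch_pos}{aptamer.base(ace.mismatch_pos)}"
    return name


_NAME_RE = re.compile(
    r"^([53])[ʹ′']?Q?_(-?\d+)([ACGTU])"
    r":(\d+)"
    r"(?::(-?\d+)([ACGTU]))?$"
)


def parse_name(
    name: str,
    aptamer: AptamerConstruct,
    *,
    spacer3_len: int = 25,
    linker5_len: int = 0,
) -> AceDesign:
    """Inverse of :func:`format_name`; accepts either anchor and ``ʹ``/``′``/``'``.

    The embedded base letters are validated against the aptamer, catching a
    name paired with the wrong construct.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise DesignError(f"malformed design name {name!r}")
    anchor, n, base, length, mm, mm_base = m.groups()
    n, length = int(n), int(length)
    if aptamer.base(n) != base:
        raise DesignError(
            f"{name!r}: aptamer {aptamer.id!r} has {aptamer.base(n)!r} at "
            f"coordinate {n}, name says {base!r}"
        )
    start5 = n if anchor == "5" else aptamer.shift(n, -(length - 1))
    mismatch_pos = None
    if mm is not None:
        mismatch_pos = int(mm)
        if aptamer.base(mismatch_pos) != mm_base:
            raise DesignError(
                f"{name!r}: aptamer base at {mismatch_pos} is "
                f"{aptamer.base(mismatch_pos)!r}, name says {mm_base!r}"
            )
    ace = AceDesign(
        aptamer_id=aptamer.id,
        start5=start5,
        length=length,
        mismatch_pos=mismatch_pos,
        spacer3_len=spacer3_len,
        linker5_len=linker5_len,
    )
    validate_design(ace, aptamer)
    return ace


# ---------------------------------------------------------------------------
# array layout


@dataclass
class ArrayLayout:
    """Spot-grid assignment, identical across all sub-arrays.

    ``assignment`` has one row per spot of one sub-array with columns
    ``ace_id, replicate, grid_row, grid_col``; every sub-array replicates it.
    """

    n_subarrays: int
    replicates_per_ace: int
    n_rows: int
    n_cols: int
    seed: int
    assignment: pd.DataFrame

    @property
    def ace_ids(self) -> list[str]:
        return sorted(self.assignment["ace_id"].unique())

    def subarray_ids(self, slide_id: str = "slide1") -> list[str]:
        return [f"{slide_id}.sa{i + 1}" for i in range(self.n_subarrays)]


def assign_layout(
    designs: list[AceDesign],
    aptamer: AptamerConstruct,
    n_subarrays: int,
    replicates: int,
    seed: int,
    *,
    grid: tuple[int, int] | None = None,
) -> ArrayLayout:
    """Randomize ``replicates`` spots per design onto one sub-array grid.

    The seeded permutation is shared by every sub-array (identical layouts);
    the default grid is the smallest near-square holding all spots.
    """
    if not designs:
        raise DesignError("cannot lay out an empty design list")
    if replicates < 1:
        raise DesignError("replicates must be >= 1")
    names = [format_name(d, aptamer) for d in designs]
    if len(set(names)) != len(names):
        raise DesignError("duplicate designs in layout request")
    spots = [(nm, r) for nm in names for r in range(1, replicates + 1)]
    need = len(spots)
    if grid is None:
        n_cols = int(np.ceil(np.sqrt(need)))
        n_rows = int(np.ceil(need / n_cols))
    else:
        n_rows, n_cols = grid
        if n_rows * n_cols < need:
            raise DesignError(
                f"sub-array grid {n_rows}x{n_cols} holds {n_rows * n_cols} "
                f"spots but {need} are required "
                f"({len(designs)} designs x {replicates} replicates)"
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(need)
    rows = [
        (spots[j][0], spots[j][1], int(pos // n_cols), int(pos % n_cols))
        for pos, j in enumerate(order)
    ]
    assignment = pd.DataFrame(
        rows, columns=["ace_id", "replicate", "grid_row", "grid_col"]
    )
    return ArrayLayout(
        n_subarrays=n_subarrays,
        replicates_per_ace=replicates,
        n_rows=n_rows,
        n_cols=n_cols,
        seed=seed,
        assignment=assignment,
    )


# ---------------------------------------------------------------------------
# manifest export


def probe_manifest(
    designs: list[AceDesign], aptamer: AptamerConstruct
) -> pd.DataFrame:
    """Tabular description of a probe library (one row per design)."""
    rows = []
    for d in designs:
        rows.append(
            {
                "ace_name_5p": format_name(d, aptamer, "5p"),
                "ace_name_3p": format_name(d, aptamer, "3p"),
                "aptamer_id": aptamer.id,
                "start5": d.start5,
                "length": d.length,
                "mismatch_pos": d.mismatch_pos,
                "probe_sequence": probe_sequence(d, aptamer),
                "flags": "degenerate" if is_degenerate(d, aptamer) else "",
            }
        )
    df = pd.DataFrame(rows)
    df["mismatch_pos"] = df["mismatch_pos"].astype("Int64")
    return df


def write_manifest(
    designs: list[AceDesign], aptamer: AptamerConstruct, path
) -> None:
    probe_manifest(designs, aptamer).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def write_probe_fasta(
    designs: list[AceDesign], aptamer: AptamerConstruct, path
) -> None:
    """FASTA of full probe sequences, record id = 5'-anchored name."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(probe_sequence(d, aptamer)),
            id=format_name(d, aptamer),
            description="",
        )
        for d in designs
    ]
    seqio_write(records, path, "fasta")
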