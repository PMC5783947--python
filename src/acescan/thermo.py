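"""Nearest-neighbor duplex and self-structure free energies.

Duplex stability is estimated with the unified DNA/DNA nearest-neighbor
parameter set (stacking ΔH/ΔS for Watson–Crick steps, internal and terminal
single-mismatch steps, and duplex initiation terms), evaluated at the assay
temperature with an entropic monovalent/divalent salt correction.  RNA
aptamer strands are modeled in the DNA alphabet (probes are DNA; mixed
DNA:RNA duplexes are approximated as DNA:DNA, which biases purine-rich
hybrids slightly).

Parameter provenance: the tables shipped with Biopython's
``Bio.SeqUtils.MeltingTemp`` (``DNA_NN3`` unified Watson–Crick set,
``DNA_IMM1`` internal mismatches, ``DNA_TMM1`` terminal mismatches).
Absolute agreement with partition-function servers is not claimed; the
estimates are for rank-order comparison against measured landscapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt
from scipy import stats

from .aptamer import DNA_COMPLEMENT, AptamerConstruct
from .design import AceDesign, duplex_probe_core, validate_design

R_KCAL = 1.987204e-3  # kcal / (mol K)

#: hairpin loop closure penalties, kcal/mol (approximate unified values)
HAIRPIN_LOOP_DG = {3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.9}


class ThermoError(ValueError):
    pass


@dataclass(frozen=True)
class ThermoConditions:
    """Assay temperature and cation concentrations for ΔG evaluation."""

    temperature_c: float = 23.0
    monovalent_m: float = 1.0
    divalent_m: float = 0.0

    def __post_init__(self) -> None:
        if not -10.0 <= self.temperature_c <= 100.0:
            raise ThermoError("temperature outside parameter validity range")
        if self.monovalent_m < 0 or self.divalent_m < 0:
            raise ThermoError("salt concentrations must be >= 0")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15

    @property
    def sodium_equivalent(self) -> float:
        """Monovalent-equivalent cation concentration (M).

        Divalent cations enter as ``3.795 * sqrt([Mg2+])`` (the 120*sqrt(mM)
        equivalence expressed in molar units).
        """
        return self.monovalent_m + 3.795 * math.sqrt(self.divalent_m)


def _stack_params(top2: str, bot2: str) -> tuple[float, float] | None:
    """(dH, dS) of one stack; tries WC, internal- and terminal-mismatch tables."""
    key = f"{top2}/{bot2}"
    rkey = f"{bot2[::-1]}/{top2[::-1]}"
    for table in (mt.DNA_NN3, mt.DNA_IMM1, mt.DNA_TMM1):
        for k in (key, rkey):
            if k in table:
                dh, ds = table[k]
                return float(dh), float(ds)
    return None


def _init_params(pair_top: str) -> tuple[float, float]:
    key = "init_A/T" if pair_top in "AT" else "init_G/C"
    dh, ds = mt.DNA_NN3[key]
    return float(dh), float(ds)


def _dg(dh: float, ds_cal: float, cond: ThermoConditions, n_stacks: int) -> float:
    """ΔG (kcal/mol) at temperature with entropic salt correction.

    ΔS gains ``0.368 * n_stacks * ln([Na+]_eq)`` cal/(mol K); at the 1 M
    monovalent reference the correction vanishes.
    """
    na_eq = cond.sodium_equivalent
    ds = ds_cal + (0.368 * n_stacks * math.log(na_eq) if na_eq > 0 else 0.0)
    return dh - cond.temperature_k * ds / 1000.0


def duplex_dG_sequences(top: str, bottom: str, cond: ThermoConditions) -> float:
    """ΔG of a duplex given the top strand 5'->3' and the base paired under
    each top base, listed 5'->3' of the *top* strand (i.e. bottom read
    3'->5').  Mismatch steps fall back to the IMM/TMM tables; steps missing
    from every table contribute nothing."""
    if len(top) != len(bottom) or len(top) < 2:
        raise ThermoError("duplex needs two aligned strands of length >= 2")
    dh_tot, ds_tot = 0.0, 0.0
    for i in range(len(top) - 1):
        p = _stack_params(top[i : i + 2], bottom[i : i + 2])
        if p is not None:
            dh_tot += p[0]
            ds_tot += p[1]
    for end in (0, -1):
        if DNA_COMPLEMENT.get(top[end]) == bottom[end]:  # matched terminus
            dh, ds = _init_params(top[end])
            dh_tot += dh
            ds_tot += ds
    return _dg(dh_tot, ds_tot, cond, n_stacks=len(top) - 1)


def duplex_dG(
    ace: AceDesign, aptamer: AptamerConstruct, cond: ThermoConditions
) -> float:
    """Nearest-neighbor ΔG (kcal/mol) of the ACE:aptamer duplex window."""
    validate_design(ace, aptamer)
    if ace.length < 2:
        raise ThermoError("duplex window shorter than 2 has no defined stack")
    top = aptamer.window_sequence(ace.start5, ace.length).replace("U", "T")
    # probe core is 5'->3'; reversed it lists the base paired under each top
    # base in top-strand order
    bottom = duplex_probe_core(ace, aptamer)[::-1]
    return duplex_dG_sequences(top, bottom, cond)


# ---------------------------------------------------------------------------
# self structure


def _loop_penalty(n: int, cond: ThermoConditions) -> float:
    if n <= 10:
        return HAIRPIN_LOOP_DG[max(n, 3)]
    return HAIRPIN_LOOP_DG[10] + 1.75 * R_KCAL * cond.temperature_k * math.log(n / 10)


def _stem_dG(stem_top: str, stem_bot: str, cond: ThermoConditions) -> tuple[float, float]:
    dh, ds = 0.0, 0.0
    for i in range(len(stem_top) - 1):
        p = _stack_params(stem_top[i : i + 2], stem_bot[i : i + 2])
        if p is not None:
            dh += p[0]
            ds += p[1]
    return dh, ds


def self_dG(
    sequence: str, cond: ThermoConditions = ThermoConditions(), *,
    min_stem: int = 3, min_loop: int = 3,
) -> float:
    """Minimum free energy over simple self-structure candidates, capped at 0.

    Candidates: hairpins with a perfectly paired stem of >= ``min_stem`` bp
    and a loop of >= ``min_loop`` nt (stem stacks + loop closure penalty),
    and perfect contiguous self-dimer duplexes of >= ``min_stem`` bp (stacks
    + initiation + homodimer symmetry entropy).  This is an exhaustive
    search over those candidates, not a partition-function fold.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    comp = DNA_COMPLEMENT
    best = 0.0

    # hairpins: pairs (i+k, j-k), loop j-i+1-2s >= min_loop
    for i in range(n):
        for j in range(i + 2 * min_stem + min_loop - 1, n):
            s = 0
            while (
                i + s < j - s
                and (j - s) - (i + s) - 1 >= min_loop
                and comp[seq[i + s]] == seq[j - s]
            ):
                s += 1
            for stem in range(min_stem, s + 1):
                top = seq[i : i + stem]
                bot = "".join(seq[j - k] for k in range(stem))
                dh, ds = _stem_dG(top, bot, cond)
                loop_n = (j - (stem - 1)) - (i + (stem - 1)) - 1
                dg = _dg(dh, ds, cond, stem - 1) + _loop_penalty(loop_n, cond)
                best = min(best, dg)

    # perfect self-dimers: seq vs seq antiparallel at every offset
    sym_dh, sym_ds = mt.DNA_NN3["sym"]
    for offset in range(-(n - min_stem), n - min_stem + 1):
        # position i of strand A pairs position (n-1) - (i + offset) of strand B
        run = 0
        for i in range(n):
            jb = n - 1 - (i + offset)
            paired = 0 <= jb < n and comp[seq[i]] == seq[jb]
            run = run + 1 if paired else 0
            if run >= min_stem:
                top = seq[i - run + 1 : i + 1]
                bot = "".join(
                    seq[n - 1 - (k + offset)] for k in range(i - run + 1, i + 1)
                )
                dh, ds = _stem_dG(top, bot, cond)
                for end in (top[0], top[-1]):
                    idh, ids = _init_params(end)
                    dh += idh
                    ds += ids
                dh += sym_dh
                ds += sym_ds
                best = min(best, _dg(dh, ds, cond, run - 1))
    return best


def landscape_correlation(values, predictor) -> tuple[float, float, int]:
    """Pairwise-complete (Pearson r, Spearman rho, n) between a landscape's
    values and a per-design predictor; n < 3 -> (nan, nan, n)."""
    x = np.asarray(values, float)
    y = np.asarray(predictor, float)
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < 3:
        return (float("nan"), float("nan"), n)
    r = stats.pearsonr(x[keep], y[keep]).statistic
    rho = stats.spearmanr(x[keep], y[keep]).statistic
    return (float(r), float(rho), n)
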