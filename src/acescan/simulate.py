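"""Synthetic slide generator with known ground truth.

The generator emulates the observable structure of an ACE-scanning
experiment so the whole pipeline is testable end to end:

* hybridization signals follow a Langmuir-like occupancy in the predicted
  duplex free energy: ``F_hyb = F_max / (1 + exp((dG - dG_mid)/slope))``;
* fluorescence decays first order over the incubation interval at
  ``k = k_off + k*_max [L] / (K_Fit + [L])`` (``[L] = 0`` for BufferOnly;
  no decay on the unincubated Calibration sub-array), on top of a shared
  handling-loss fraction ``phi``;
* replicate noise is multiplicative lognormal per spot per imaging round;
* rare planted spot failures inflate the pixel SD (morphology) or the local
  background tenfold at configured rates.

The generative decay model deliberately matches the analysis model, so a
zero-noise dataset is recovered exactly — the standard simulation-based
calibration posture.  What this does *not* emulate: scanner optics, spatial
gradients, aptamer tertiary structure, or any misspecified decay law (a
biphasic stress scenario can be built by hand and is not canonical).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aptamer import AptamerConstruct
from .arrayio import CONDITION_COLUMNS, SlideDataset
from .design import (
    AceDesign,
    ArrayLayout,
    assign_layout,
    enumerate_perfect_match,
    enumerate_single_mismatch,
    format_name,
    validate_design,
)
from .thermo import ThermoConditions, duplex_dG

# --- built-in aptamer constructs -------------------------------------------
# The ATP construct carries the classical 27-base DNA ATP aptamer consensus
# with a synthetic 5-base 5' extension (chosen so the extension coordinates
# carry C at -5 and T at -2, matching the printed design names used in the
# tests).  The cocaine- and null-like constructs are synthetic stand-ins.

ATP_DNA_APTAMER = AptamerConstruct(
    id="atp_dna",
    sequence="CGATC" + "ACCTGGGGGAGTATTGCGGAGGAAGGT",
    consensus_start=6,
    description="DNA ATP aptamer consensus with synthetic 5-base 5' extension",
)

COCAINE_DNA_APTAMER = AptamerConstruct(
    id="cocaine_dna",
    sequence="GGA" + "GACAAGGAAAATCCTTCAACGAAGTGGGTC" + "TCC",
    consensus_start=4,
    description="cocaine-aptamer-like synthetic stand-in with 3-base extensions",
)

NULL_APTAMER = AptamerConstruct(
    id="flat_null",
    sequence="ACGTACGTAGCTAGCTACGT",
    description="structureless synthetic stand-in",
)


@dataclass
class Scenario:
    """Ground truth + noise model for one synthetic experiment."""

    name: str
    aptamer: AptamerConstruct
    designs: list[AceDesign]
    truth: pd.DataFrame  # ace_id, k_off, k_star_max, K_fit, hot
    seed: int
    thermo: ThermoConditions = ThermoConditions(23.0, 0.3, 0.005)
    f_max: float = 30000.0  # RFU at full occupancy
    dg_mid: float = -11.0  # kcal/mol at half occupancy
    dg_slope: float = 2.5  # kcal/mol per e-fold of occupancy odds
    noise_sigma: float = 0.10  # lognormal sigma per spot per round
    background_mean: float = 80.0
    background_sd: float = 15.0
    pixel_cv: float = 0.08
    morphology_failure_rate: float = 0.002
    background_failure_rate: float = 0.002
    calibration_loss_fraction: float = 0.15
    concentrations: tuple = ()
    ligand_name: str = "ligand"
    delta_t: float = 1.0  # hours
    replicates: int = 5
    n_subarrays: int = 6

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, float)
        if len(c) and (np.any(c <= 0) or len(np.unique(c)) != len(c)):
            raise ValueError("concentrations must be positive and distinct")
        t = self.truth
        if (t["k_off"] < 0).any() or (t["k_star_max"] < 0).any():
            raise ValueError("planted rates must be >= 0")

    def noiseless(self) -> "Scenario":
        return replace(
            self,
            noise_sigma=0.0,
            background_sd=0.0,
            morphology_failure_rate=0.0,
            background_failure_rate=0.0,
        )


def dilution_series(low: float, high: float, n: int) -> np.ndarray:
    """``n`` log-spaced concentrations with both endpoints exact."""
    if low <= 0 or high <= 0 or n < 1:
        raise ValueError("need positive endpoints and n >= 1")
    if n == 1:
        if low != high:
            raise ValueError("a single-point series needs low == high")
        return np.array([low])
    out = np.geomspace(low, high, n)
    out[0], out[-1] = low, high
    return out


DEFAULT_CONCENTRATIONS = tuple(dilution_series(0.124e-6, 10e-3, 8))


def _window_overlap(
    ace: AceDesign, aptamer: AptamerConstruct, region: set[int]
) -> float:
    coords = validate_design(ace, aptamer)
    return len(set(coords) & region) / max(len(region), 1)


def _atp_truth(
    aptamer: AptamerConstruct, designs: list[AceDesign]
) -> pd.DataFrame:
    # planted induced-fit hotspot: the G-rich core of the consensus
    # (coordinates 4..12); planted high-k_off "stem": the 5' extension plus
    # the 3' closing stem of the construct
    site = set(range(4, 13))
    stem = set(range(-5, 0)) | set(range(18, 28))
    rows = []
    for d in designs:
        site_frac = _window_overlap(d, aptamer, site)
        stem_frac = _window_overlap(d, aptamer, stem)
        k_off = 0.05 + 0.30 * stem_frac
        hot = 7 <= d.length <= 12 and site_frac > 0
        kmax = 0.5 + site_frac if hot else 0.0
        if hot and d.mismatch_pos is not None:
            kmax *= 1.5  # mismatched variants of hot designs respond harder
        rows.append(
            {
                "ace_id": format_name(d, aptamer),
                "k_off": k_off,
                "k_star_max": kmax,
                "K_fit": 200e-6 if hot else np.nan,
                "hot": hot,
            }
        )
    return pd.DataFrame(rows)


def _cocaine_truth(
    aptamer: AptamerConstruct, designs: list[AceDesign]
) -> pd.DataFrame:
    # three planted stems drive heterogeneous k_off; no induced fit anywhere
    stems = set(range(1, 7)) | set(range(13, 19)) | set(range(25, 31))
    rows = []
    for d in designs:
        stem_frac = _window_overlap(d, aptamer, stems)
        rows.append(
            {
                "ace_id": format_name(d, aptamer),
                "k_off": 0.08 + 0.40 * stem_frac,
                "k_star_max": 0.0,
                "K_fit": np.nan,
                "hot": False,
            }
        )
    return pd.DataFrame(rows)


def make_scenario(preset: str, seed: int, **overrides) -> Scenario:
    """Built-in study conditions.

    ``atp_dna_like``
        7-32-mer perfect-match tiling plus single-mismatch 12-mers on the
        extended ATP DNA construct; induced fit (K_Fit = 200 uM,
        k*_max 0.5-1.5 1/h, mismatched hot variants boosted 1.5x) planted
        exactly on 7-12-mers overlapping the binding-site coordinates.
    ``cocaine_like``
        8-15-mer tiling of a structured construct; heterogeneous
        hybridization and stem-dependent k_off but zero induced fit.
    ``flat_null``
        unstructured 20-mer, uniform k_off, zero induced fit.
    """
    if preset == "atp_dna_like":
        apt = ATP_DNA_APTAMER
        designs = enumerate_perfect_match(apt, 7, 32) + enumerate_single_mismatch(
            apt, [12]
        )
        truth = _atp_truth(apt, designs)
        ligand = "ATP"
    elif preset == "cocaine_like":
        apt = COCAINE_DNA_APTAMER
        designs = enumerate_perfect_match(apt, 8, 15)
        truth = _cocaine_truth(apt, designs)
        ligand = "cocaine"
    elif preset == "flat_null":
        apt = NULL_APTAMER
        designs = enumerate_perfect_match(apt, 7, 12)
        truth = pd.DataFrame(
            {
                "ace_id": [format_name(d, apt) for d in designs],
                "k_off": 0.10,
                "k_star_max": 0.0,
                "K_fit": np.nan,
                "hot": False,
            }
        )
        ligand = "none"
    else:
        raise ValueError(f"unknown preset {preset!r}")
    sc = Scenario(
        name=preset,
        aptamer=apt,
        designs=designs,
        truth=truth,
        seed=seed,
        concentrations=DEFAULT_CONCENTRATIONS,
        ligand_name=ligand,
    )
    return replace(sc, **overrides) if overrides else sc


def standard_condition_table(
    scenario: Scenario, slide_id: str, concentrations
) -> pd.DataFrame:
    """One Calibration, one BufferOnly, then one Ligand sub-array per
    concentration — the standard slide partition."""
    rows = [
        {
            "subarray_id": f"{slide_id}.sa1",
            "condition": "Calibration",
            "ligand_name": "",
            "concentration": 0.0,
        },
        {
            "subarray_id": f"{slide_id}.sa2",
            "condition": "BufferOnly",
            "ligand_name": "",
            "concentration": 0.0,
        },
    ]
    for i, c in enumerate(concentrations):
        rows.append(
            {
                "subarray_id": f"{slide_id}.sa{3 + i}",
                "condition": "Ligand",
                "ligand_name": scenario.ligand_name,
                "concentration": float(c),
            }
        )
    df = pd.DataFrame(rows)
    df["slide_id"] = slide_id
    df["temperature"] = scenario.thermo.temperature_c
    df["delta_t"] = scenario.delta_t
    df["buffer_label"] = "assay"
    return df[CONDITION_COLUMNS]


def _stream(seed: int, slide_id: str, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [seed, zlib.crc32(slide_id.encode()), zlib.crc32(label.encode())]
        )
    )


def clean_hybridization_signal(scenario: Scenario) -> pd.Series:
    """Noise-free F_hyb per design from duplex ΔG occupancy."""
    vals = {}
    for d in scenario.designs:
        dg = duplex_dG(d, scenario.aptamer, scenario.thermo)
        occ = 1.0 / (1.0 + np.exp((dg - scenario.dg_mid) / scenario.dg_slope))
        vals[format_name(d, scenario.aptamer)] = scenario.f_max * occ
    return pd.Series(vals, name="f_hyb")


def simulate_slide(
    scenario: Scenario,
    layout: ArrayLayout | None = None,
    conditions: pd.DataFrame | None = None,
    slide_id: str = "slide1",
) -> SlideDataset:
    """Generate the green-channel spot table for one slide.

    Fully deterministic given (scenario, layout, conditions, slide_id); all
    draws come from seed-derived independent streams.
    """
    if layout is None:
        layout = assign_layout(
            scenario.designs,
            scenario.aptamer,
            n_subarrays=scenario.n_subarrays,
            replicates=scenario.replicates,
            seed=scenario.seed,
        )
    if conditions is None:
        conditions = standard_condition_table(
            scenario, slide_id, scenario.concentrations[: layout.n_subarrays - 2]
        )
    truth = scenario.truth.set_index("ace_id")
    missing = set(layout.assignment["ace_id"]) - set(truth.index)
    if missing:
        raise ValueError(
            f"layout contains designs absent from the scenario truth, e.g. "
            f"{sorted(missing)[:3]}"
        )
    f_hyb_clean = clean_hybridization_signal(scenario)

    assign = layout.assignment
    n_spots = len(assign)
    sigma = scenario.noise_sigma
    phi = scenario.calibration_loss_fraction
    rng_hyb = _stream(scenario.seed, slide_id, "hyb_noise")
    rng_post = _stream(scenario.seed, slide_id, "post_noise")
    rng_bg = _stream(scenario.seed, slide_id, "background")
    rng_fail = _stream(scenario.seed, slide_id, "failures")

    frames = []
    planted = []
    for _, cond in conditions.iterrows():
        sub = cond["subarray_id"]
        conc = cond["concentration"] if cond["condition"] == "Ligand" else 0.0
        k = truth.loc[assign["ace_id"], "k_off"].to_numpy(float).copy()
        kmax = truth.loc[assign["ace_id"], "k_star_max"].to_numpy(float)
        kfit = truth.loc[assign["ace_id"], "K_fit"].to_numpy(float)
        if conc > 0:
            lig = np.where(kmax > 0, kmax * conc / (np.where(kmax > 0, kfit, 1.0) + conc), 0.0)
            k = k + lig
        decay = (
            np.ones(n_spots)
            if cond["condition"] == "Calibration"
            else np.exp(-k * cond["delta_t"])
        )
        eps_h = np.exp(rng_hyb.normal(0.0, sigma, n_spots)) if sigma > 0 else 1.0
        eps_p = np.exp(rng_post.normal(0.0, sigma, n_spots)) if sigma > 0 else 1.0
        f_hyb = f_hyb_clean.loc[assign["ace_id"]].to_numpy(float) * eps_h
        f_post = f_hyb * (1.0 - phi) * decay * eps_p

        morph_fail = rng_fail.random(n_spots) < scenario.morphology_failure_rate
        bg_fail = rng_fail.random(n_spots) < scenario.background_failure_rate
        for rnd, sig in (("post_hyb", f_hyb), ("post_incubation", f_post)):
            bg = rng_bg.normal(scenario.background_mean, scenario.background_sd, n_spots)
            bg = np.clip(bg, 0.0, None)
            pixel_sd = scenario.pixel_cv * sig
            if rnd == "post_hyb":
                pixel_sd = np.where(morph_fail, pixel_sd * 10.0, pixel_sd)
                bg = np.where(bg_fail, bg * 10.0 + 10.0 * scenario.background_mean, bg)
            frames.append(
                pd.DataFrame(
                    {
                        "subarray_id": sub,
                        "ace_id": assign["ace_id"].to_numpy(),
                        "replicate": assign["replicate"].to_numpy(),
                        "round": rnd,
                        "channel": "green",
                        "grid_row": assign["grid_row"].to_numpy(),
                        "grid_col": assign["grid_col"].to_numpy(),
                        "median_signal": sig,
                        "pixel_sd": pixel_sd,
                        "background_mean": bg,
                    }
                )
            )
        planted.append(
            pd.DataFrame(
                {
                    "subarray_id": sub,
                    "ace_id": assign["ace_id"].to_numpy(),
                    "replicate": assign["replicate"].to_numpy(),
                    "morphology": morph_fail,
                    "background": bg_fail,
                }
            )
        )
    ds = SlideDataset(
        layout=layout,
        conditions=conditions,
        spots=pd.concat(frames, ignore_index=True),
        provenance=f"synthetic scenario {scenario.name!r} seed {scenario.seed}",
        truth=scenario.truth,
        planted_failures=pd.concat(planted, ignore_index=True),
    )
    ds.validate()
    return ds


def simulate_experiment(
    scenario: Scenario, n_slides: int = 2
) -> list[SlideDataset]:
    """Split the dilution series across slides (4 ligand sub-arrays each)."""
    layout = assign_layout(
        scenario.designs,
        scenario.aptamer,
        n_subarrays=scenario.n_subarrays,
        replicates=scenario.replicates,
        seed=scenario.seed,
    )
    per_slide = scenario.n_subarrays - 2
    conc = list(scenario.concentrations)
    if len(conc) > n_slides * per_slide:
        raise ValueError("more concentrations than ligand sub-arrays")
    out = []
    for s in range(n_slides):
        chunk = conc[s * per_slide : (s + 1) * per_slide]
        slide_id = f"slide{s + 1}"
        conditions = standard_condition_table(scenario, slide_id, chunk)
        out.append(simulate_slide(scenario, layout, conditions, slide_id))
    return out
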