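"""Spot tables, condition tables and landscape tables (native TSV + GPR).

Native files are UTF-8 TSV with a versioned ``#`` header comment and ``NA``
for missing.  Spot tables carry one row per spot per imaging round per
channel; condition tables describe what each sub-array was incubated with.
A GenePix-results (GPR) dialect reader is provided as a best-effort
convenience for externally extracted intensity tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SPOTS_HEADER = "# acescan spots v1"
CONDITIONS_HEADER = "# acescan conditions v1"
LANDSCAPE_HEADER = "# acescan landscape v1"

ROUNDS = ("post_hyb", "post_incubation")
CHANNELS = ("green", "red")
CONDITION_KINDS = ("Calibration", "BufferOnly", "Ligand")

SPOT_COLUMNS = [
    "subarray_id",
    "ace_id",
    "replicate",
    "round",
    "channel",
    "grid_row",
    "grid_col",
    "median_signal",
    "pixel_sd",
    "background_mean",
]

CONDITION_COLUMNS = [
    "subarray_id",
    "slide_id",
    "condition",
    "ligand_name",
    "concentration",
    "temperature",
    "delta_t",
    "buffer_label",
]

#: GenePix column names -> native schema.  Round/replicate do not exist in
#: stock GPR output and must be supplied as extra columns.
GPR_COLUMN_MAP = {
    "Block": "subarray_id",
    "ID": "ace_id",
    "Rep": "replicate",
    "Round": "round",
    "Row": "grid_row",
    "Column": "grid_col",
}
GPR_CHANNEL_COLUMNS = {
    "green": ("F532 Median", "F532 SD", "B532 Mean"),
    "red": ("F635 Median", "F635 SD", "B635 Mean"),
}


class SchemaError(ValueError):
    """An input table violates the expected schema."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def validate_spot_table(spots: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    _require_columns(spots, SPOT_COLUMNS, source)
    spots = spots.copy()
    for col in ("median_signal", "pixel_sd", "background_mean"):
        vals = pd.to_numeric(spots[col], errors="coerce")
        bad = vals.isna() & spots[col].notna()
        if bad.any():
            raise SchemaError(
                f"{source}: non-numeric {col} at row(s) {list(spots.index[bad][:5])}"
            )
        neg = vals < 0
        if neg.any():
            raise SchemaError(
                f"{source}: negative {col} at row(s) {list(spots.index[neg][:5])}"
            )
        spots[col] = vals
    bad_round = ~spots["round"].isin(ROUNDS)
    if bad_round.any():
        raise SchemaError(f"{source}: unknown round value(s) "
                          f"{sorted(spots.loc[bad_round, 'round'].unique())}")
    bad_chan = ~spots["channel"].isin(CHANNELS)
    if bad_chan.any():
        raise SchemaError(f"{source}: unknown channel value(s) "
                          f"{sorted(spots.loc[bad_chan, 'channel'].unique())}")
    key = ["subarray_id", "grid_row", "grid_col", "round", "channel"]
    dup = spots.duplicated(key)
    if dup.any():
        raise SchemaError(
            f"{source}: duplicate spot key(s) "
            f"{spots.loc[dup, key].head(3).to_dict('records')}"
        )
    return spots


def read_spot_table(path, dialect: str = "native") -> pd.DataFrame:
    """Read a spot-intensity table into the native schema.

    ``dialect='native'`` expects the native columns; ``dialect='genepix_gpr'``
    maps GenePix result columns (F532/F635 Median, SD, B Mean) onto them,
    emitting one row per channel present.  Unknown columns are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native":
        return validate_spot_table(_read_tsv(path), str(path))
    if dialect != "genepix_gpr":
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    _require_columns(raw, list(GPR_COLUMN_MAP), path)
    frames = []
    for channel, (f_med, f_sd, b_mean) in GPR_CHANNEL_COLUMNS.items():
        if f_med not in raw.columns:
            continue
        df = raw[list(GPR_COLUMN_MAP)].rename(columns=GPR_COLUMN_MAP).copy()
        df["channel"] = channel
        df["median_signal"] = raw[f_med]
        df["pixel_sd"] = raw[f_sd] if f_sd in raw.columns else 0.0
        df["background_mean"] = raw[b_mean] if b_mean in raw.columns else 0.0
        frames.append(df)
    if not frames:
        raise SchemaError(f"{path}: no GPR channel columns found")
    spots = pd.concat(frames, ignore_index=True)[SPOT_COLUMNS]
    return validate_spot_table(spots, str(path))


def write_spot_table(spots: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SPOTS_HEADER + "\n")
        spots[SPOT_COLUMNS].to_csv(fh, sep="\t", index=False, na_rep="NA")


def validate_condition_table(
    cond: pd.DataFrame, source: str = "<table>"
) -> pd.DataFrame:
    _require_columns(cond, CONDITION_COLUMNS, source)
    cond = cond.copy()
    bad = ~cond["condition"].isin(CONDITION_KINDS)
    if bad.any():
        raise SchemaError(
            f"{source}: unknown condition(s) "
            f"{sorted(cond.loc[bad, 'condition'].unique())}"
        )
    for col in ("concentration", "temperature", "delta_t"):
        cond[col] = pd.to_numeric(cond[col], errors="raise")
    if cond["subarray_id"].duplicated().any():
        raise SchemaError(f"{source}: duplicate subarray_id")
    for slide, grp in cond.groupby("slide_id"):
        n_cal = (grp["condition"] == "Calibration").sum()
        if n_cal != 1:
            raise SchemaError(
                f"{source}: slide {slide!r} has {n_cal} Calibration "
                f"sub-arrays; exactly one is required"
            )
    lig = cond["condition"] == "Ligand"
    if (cond.loc[lig, "concentration"] <= 0).any():
        raise SchemaError(f"{source}: Ligand rows must carry concentration > 0")
    if (cond["delta_t"] <= 0).any():
        raise SchemaError(f"{source}: delta_t must be > 0")
    return cond


def read_condition_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_condition_table(_read_tsv(path), str(path))


def write_condition_table(cond: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(CONDITIONS_HEADER + "\n")
        cond[CONDITION_COLUMNS].to_csv(fh, sep="\t", index=False, na_rep="NA")


LANDSCAPE_COLUMNS = [
    "start5",
    "length",
    "mismatch_pos",
    "value",
    "n_replicates",
    "qc_flag",
]


def write_landscape_table(values: pd.DataFrame, path) -> None:
    """Long-form landscape TSV; NaN serialized as NA; lossless round trip."""
    df = values.copy()
    for col in LANDSCAPE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df["mismatch_pos"] = df["mismatch_pos"].astype("Int64")
    df["n_replicates"] = df["n_replicates"].astype("Int64")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(LANDSCAPE_HEADER + "\n")
        df[LANDSCAPE_COLUMNS].to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_landscape_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, LANDSCAPE_COLUMNS, path)
    df["mismatch_pos"] = df["mismatch_pos"].astype("Int64")
    df["n_replicates"] = df["n_replicates"].astype("Int64")
    df["qc_flag"] = df["qc_flag"].fillna("").astype(str).replace("nan", "")
    return df


@dataclass
class SlideDataset:
    """Everything measured on one slide (or a pooled set of slides)."""

    layout: "object"  # ArrayLayout; avoid import cycle in type checking
    conditions: pd.DataFrame
    spots: pd.DataFrame
    provenance: str = ""
    truth: pd.DataFrame | None = None
    planted_failures: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        validate_spot_table(self.spots, "spots")
        validate_condition_table(self.conditions, "conditions")
        known = set(self.conditions["subarray_id"])
        orphan = set(self.spots["subarray_id"]) - known
        if orphan:
            raise SchemaError(f"spots reference unknown sub-array(s) {sorted(orphan)}")
        layout_aces = set(self.layout.assignment["ace_id"])
        orphan_ace = set(self.spots["ace_id"]) - layout_aces
        if orphan_ace:
            raise SchemaError(
                f"spots reference ACEs absent from layout, e.g. "
                f"{sorted(orphan_ace)[:3]}"
            )


def pool_slides(datasets: list[SlideDataset]) -> SlideDataset:
    """Concatenate slides into one dataset (sub-array ids stay distinct).

    Calibration/BufferOnly averaging across slides happens downstream in the
    analysis, keyed on ace_id; pooling here only merges the tables.
    """
    if not datasets:
        raise ValueError("nothing to pool")
    spots = pd.concat([d.spots for d in datasets], ignore_index=True)
    conds = pd.concat([d.conditions for d in datasets], ignore_index=True)
    truth = datasets[0].truth
    planted = pd.concat(
        [d.planted_failures for d in datasets], ignore_index=True
    )
    ds = SlideDataset(
        layout=datasets[0].layout,
        conditions=conds,
        spots=spots,
        provenance="; ".join(filter(None, (d.provenance for d in datasets))),
        truth=truth,
        planted_failures=planted,
    )
    ds.validate()
    return ds
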