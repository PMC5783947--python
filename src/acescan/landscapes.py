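"""Per-ACE scalars assembled into heat-map matrices and per-base linear maps.

The canonical landscape container is a long-form table keyed by
``(start5, length, mismatch_pos)``; matrix views are derived from it:

* 5'-anchored map: rows = duplex start coordinate N5, columns = ACE length;
* 3'-anchored map: rows = duplex end coordinate N3 = N5 + L - 1;
* enantio view: both anchors side by side (diagonals of the 5' map share a
  3' duplex start site);
* mismatch map: rows = L-mer windows, columns = mismatch coordinate, with a
  leading perfect-match column holding the (L-1)-mer sharing each window's
  3' end (a 5'-terminally mismatched L-mer is structurally that (L-1)-mer).

Missing values (QC-excluded designs) stay NaN everywhere and render as
blank tiles; means skip missing contributors and a cell with no
contributors is missing, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aptamer import AptamerConstruct
from .design import AceDesign, end3, validate_design

KINDS = (
    "hybridization",
    "relative_loss",
    "k_off",
    "k_star_off",
    "K_fit",
    "k_star_max",
    "two_color_ratio",
)


@dataclass
class Landscape:
    """Map from (start5, length, mismatch_pos-or-NA) to a scalar."""

    aptamer_id: str
    kind: str
    values: pd.DataFrame  # start5, length, mismatch_pos, value[, n_replicates, qc_flag]
    ligand_name: str = ""
    concentration: float = float("nan")

    def __post_init__(self) -> None:
        df = self.values.copy()
        for col, default in (("n_replicates", pd.NA), ("qc_flag", "")):
            if col not in df.columns:
                df[col] = default
        df["mismatch_pos"] = df["mismatch_pos"].astype("Int64")
        df["n_replicates"] = df["n_replicates"].astype("Int64")
        if df.duplicated(["start5", "length", "mismatch_pos"]).any():
            raise ValueError("duplicate design keys in landscape")
        self.values = df

    @classmethod
    def from_mapping(
        cls, aptamer_id: str, kind: str, mapping: dict, **kw
    ) -> "Landscape":
        """Build from ``{(start5, length, mismatch_pos-or-None): value}``."""
        rows = [
            {"start5": s, "length": l, "mismatch_pos": m, "value": v}
            for (s, l, m), v in mapping.items()
        ]
        return cls(aptamer_id, kind, pd.DataFrame(rows), **kw)

    def perfect_match(self) -> pd.DataFrame:
        return self.values[self.values["mismatch_pos"].isna()]

    def mismatched(self, length: int | None = None) -> pd.DataFrame:
        df = self.values[self.values["mismatch_pos"].notna()]
        if length is not None:
            df = df[df["length"] == length]
        return df


def _coord_sort_key(coords) -> np.ndarray:
    # aptamer coordinates skip 0, so plain numeric order is 5'->3'
    return np.argsort(np.asarray(coords))


def build_heatmap_5p(landscape: Landscape) -> pd.DataFrame:
    """Perfect-match matrix: rows start5 ascending, columns length ascending."""
    pm = landscape.perfect_match()
    mat = pm.pivot(index="start5", columns="length", values="value")
    return mat.sort_index().sort_index(axis=1)


def build_heatmap_3p(
    landscape: Landscape, aptamer: AptamerConstruct
) -> pd.DataFrame:
    """Perfect-match matrix anchored at the 3' duplex end (rows = N3)."""
    pm = landscape.perfect_match().copy()
    pm["end3"] = [
        aptamer.shift(int(s), int(l) - 1)
        for s, l in zip(pm["start5"], pm["length"])
    ]
    mat = pm.pivot(index="end3", columns="length", values="value")
    return mat.sort_index().sort_index(axis=1)


def build_enantio(
    landscape: Landscape, aptamer: AptamerConstruct
) -> pd.DataFrame:
    """Fused 5'/3'-anchored view: columns are a (anchor, length) MultiIndex.

    Each design appears exactly once under each anchor; the two single-anchor
    matrices are recoverable as ``enantio['5p']`` and ``enantio['3p']``.
    """
    m5 = build_heatmap_5p(landscape)
    m3 = build_heatmap_3p(landscape, aptamer)
    fused = pd.concat({"5p": m5, "3p": m3}, axis=1)
    fused.index.name = "anchor_coord"
    return fused


def build_mismatch_map(
    landscape: Landscape, length: int, aptamer: AptamerConstruct
) -> pd.DataFrame:
    """Mismatch matrix for one ACE length: rows = windows, cols = MM coord.

    The leftmost column (labelled ``PM``) holds the perfect-match
    (L-1)-mer starting one base 3' of each row's window — the design that a
    5'-terminally mismatched L-mer structurally resembles.  Only coordinates
    inside each row's window are populated.
    """
    mm = landscape.mismatched(length)
    mat = mm.pivot(index="start5", columns="mismatch_pos", values="value")
    mat = mat.sort_index().sort_index(axis=1)
    mat.columns = [int(c) for c in mat.columns]
    pm = landscape.perfect_match()
    pm_short = pm[pm["length"] == length - 1].set_index("start5")["value"]
    pm_col = []
    for n in mat.index:
        try:
            nxt = aptamer.shift(int(n), 1)
            pm_col.append(pm_short.get(nxt, np.nan))
        except Exception:
            pm_col.append(np.nan)
    mat.insert(0, "PM", pm_col)
    return mat


def forward_linear_map(
    landscape: Landscape,
    aptamer: AptamerConstruct,
    mode: str = "covers_base",
) -> pd.Series:
    """Project a landscape onto the aptamer sequence, one value per base.

    ``covers_base``: each base averages all designs whose duplex window
    covers it.  ``mismatch_at_base``: each base averages all designs whose
    mismatch coordinate is that base.  Bases without contributors are NaN.
    """
    if mode not in ("covers_base", "mismatch_at_base"):
        raise ValueError(f"unknown mode {mode!r}")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for row in landscape.values.itertuples(index=False):
        v = row.value
        if not np.isfinite(v):
            continue
        if mode == "mismatch_at_base":
            if pd.isna(row.mismatch_pos):
                continue
            targets = [int(row.mismatch_pos)]
        else:
            targets = aptamer.window_coords(int(row.start5), int(row.length))
        for c in targets:
            sums[c] = sums.get(c, 0.0) + v
            counts[c] = counts.get(c, 0) + 1
    coords = aptamer.coords()
    vals = [sums[c] / counts[c] if c in counts else np.nan for c in coords]
    return pd.Series(vals, index=pd.Index(coords, name="coord"), name=landscape.kind)


def reverse_linear_map(
    per_base_scores: pd.Series,
    designs: list[AceDesign],
    aptamer: AptamerConstruct,
) -> pd.Series:
    """Score each design with the mean per-base score over its window."""
    from .design import format_name

    out = {}
    for d in designs:
        coords = validate_design(d, aptamer)
        vals = per_base_scores.reindex(coords).to_numpy(float)
        out[format_name(d, aptamer)] = (
            float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
        )
    return pd.Series(out, name="reverse_linear_map")


def two_color_normalize(red_post, green_post):
    """Per-DA red/green post-incubation ratio; green <= 0 -> NaN."""
    red = np.asarray(red_post, float)
    green = np.asarray(green_post, float)
    out = np.where(green > 0, red / np.where(green > 0, green, 1.0), np.nan)
    return out.item() if out.ndim == 0 else out


def plot_heatmap(matrix: pd.DataFrame, ax=None, cmap="viridis", **kw):
    """Optional rendering convenience; the matrices are the canonical output."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = np.ma.masked_invalid(matrix.to_numpy(float))
    im = ax.pcolormesh(data, cmap=cmap, **kw)
    ax.set_xticks(np.arange(matrix.shape[1]) + 0.5, matrix.columns, rotation=90)
    ax.set_yticks(np.arange(matrix.shape[0]) + 0.5, matrix.index)
    ax.invert_yaxis()
    return im
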