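"""End-to-end analysis: QC -> calibration -> rates -> dose-response -> maps.

``analyze`` consumes one or more slides sharing a layout.  Per the pooling
convention, Calibration and BufferOnly per-DA values are averaged across
slides before any rate is computed; each Ligand sub-array then borrows the
pooled per-DA calibration loss fraction (layouts are identical, so the
matched spot exists on every sub-array).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinetics, qc
from .aptamer import AptamerConstruct
from .arrayio import SlideDataset, pool_slides
from .design import parse_name
from .kinetics import DoseResponseModel
from .landscapes import Landscape


class AnalysisError(ValueError):
    pass


@dataclass
class AnalysisResult:
    """Tables produced by one analysis run.

    ``da``       aggregated replicate means per (ace, sub-array, round, channel);
    ``rates``    one row per (ace, incubated sub-array): relative loss (%),
                 corrected survival, total rate, and for Ligand rows the
                 concentration and the induced-fit component ``k_star``;
    ``kinetics`` one row per ace: pooled ``k_off`` plus calibration phi;
    ``fits``     one row per fitted ace: ``K_fit``, ``k_star_max``, standard
                 errors, RSS, convergence flag.
    """

    aptamer: AptamerConstruct
    da: pd.DataFrame
    rates: pd.DataFrame
    kin: pd.DataFrame
    fits: pd.DataFrame
    flags: pd.DataFrame

    def _keyed(self, series: pd.Series) -> pd.DataFrame:
        rows = []
        for ace_id, value in series.items():
            d = parse_name(ace_id, self.aptamer)
            rows.append(
                {
                    "start5": d.start5,
                    "length": d.length,
                    "mismatch_pos": d.mismatch_pos,
                    "value": value,
                }
            )
        return pd.DataFrame(rows)

    def landscape(
        self,
        kind: str,
        concentration: float | None = None,
        *,
        floor: bool = True,
    ) -> Landscape:
        """Assemble a landscape of one scalar per design.

        ``k_star_off`` requires ``concentration``; displayed induced-fit
        rates are floored at 0 unless ``floor=False`` (fits always use raw
        values).
        """
        if kind == "hybridization":
            s = self.rates.groupby("ace_id")["f_hyb"].mean()
        elif kind == "k_off":
            s = self.kin.set_index("ace_id")["k_off"]
        elif kind == "relative_loss":
            sel = self.rates[self.rates["condition"] == "BufferOnly"]
            if concentration is not None:
                sel = self.rates[
                    np.isclose(self.rates["concentration"], concentration)
                ]
            s = sel.groupby("ace_id")["relative_loss"].mean()
        elif kind == "k_star_off":
            if concentration is None:
                raise AnalysisError("k_star_off landscape needs a concentration")
            sel = self.rates[
                np.isclose(self.rates["concentration"], concentration)
            ]
            if sel.empty:
                raise AnalysisError(
                    f"no Ligand sub-array at concentration {concentration}"
                )
            s = sel.groupby("ace_id")["k_star"].mean()
            if floor:
                s = s.clip(lower=0.0)
        elif kind in ("K_fit", "k_star_max"):
            s = self.fits.set_index("ace_id")[kind]
        else:
            raise AnalysisError(f"unknown landscape kind {kind!r}")
        values = self._keyed(s)
        return Landscape(
            self.aptamer.id,
            kind,
            values,
            concentration=concentration if concentration is not None else float("nan"),
        )


def analyze(
    datasets: "SlideDataset | list[SlideDataset]",
    aptamer: AptamerConstruct,
    *,
    signal_threshold: float = qc.LOW_SIGNAL_THRESHOLD,
    min_pass: int = 3,
    fit: bool = True,
) -> AnalysisResult:
    """Run the full analysis chain on one or more slides."""
    if isinstance(datasets, SlideDataset):
        dataset = datasets
    else:
        dataset = pool_slides(list(datasets))

    flags = qc.flag_spots(dataset.spots, threshold=signal_threshold)
    da = qc.aggregate_replicates(dataset.spots, flags, min_pass=min_pass)

    green = da[da["channel"] == "green"]
    wide = green.pivot_table(
        index=["ace_id", "subarray_id"],
        columns="round",
        values="mean_signal",
        dropna=False,
    ).reset_index()
    for col in ("post_hyb", "post_incubation"):
        if col not in wide.columns:
            raise AnalysisError(f"dataset lacks {col} measurements")
    wide = wide.rename(columns={"post_hyb": "f_hyb", "post_incubation": "f_post"})
    wide = wide.merge(dataset.conditions, on="subarray_id", how="left")
    if wide["condition"].isna().any():
        raise AnalysisError("spots reference sub-arrays missing from conditions")

    # pooled per-DA Calibration and BufferOnly means (across slides)
    cal = (
        wide[wide["condition"] == "Calibration"]
        .groupby("ace_id")[["f_hyb", "f_post"]]
        .mean()
    )
    if cal.empty:
        raise AnalysisError("no Calibration sub-array in dataset")
    phi = pd.Series(
        kinetics.calibration_loss_fraction(cal["f_hyb"], cal["f_post"]),
        index=cal.index,
        name="phi",
    )
    cal_loss = (cal["f_hyb"] - cal["f_post"]).rename("cal_loss")

    incub = wide[wide["condition"].isin(["BufferOnly", "Ligand"])].copy()
    incub = incub.join(phi, on="ace_id").join(cal_loss, on="ace_id")
    with np.errstate(invalid="ignore", divide="ignore"):
        incub["relative_loss"] = np.where(
            incub["cal_loss"] > 0,
            100.0 * (incub["f_hyb"] - incub["f_post"]) / incub["cal_loss"],
            np.nan,
        )
        s, clipped, uncal = kinetics.corrected_survival(
            incub["f_hyb"].to_numpy(),
            incub["f_post"].to_numpy(),
            incub["phi"].to_numpy(),
            return_flags=True,
        )
    incub["survival"] = s
    incub["clipped"] = clipped
    incub["uncalibratable"] = uncal
    with np.errstate(invalid="ignore", divide="ignore"):
        incub["k_total"] = -np.log(incub["survival"]) / incub["delta_t"]

    # pooled BufferOnly -> per-DA spontaneous rate.  Per the pooling rule the
    # BufferOnly fluorescences are averaged across slides before the rate is
    # taken.
    buf = incub[incub["condition"] == "BufferOnly"]
    buf_mean = buf.groupby("ace_id")[["f_hyb", "f_post", "phi"]].mean()
    s_buf = kinetics.corrected_survival(
        buf_mean["f_hyb"].to_numpy(),
        buf_mean["f_post"].to_numpy(),
        buf_mean["phi"].to_numpy(),
    )
    dt = float(buf["delta_t"].iloc[0]) if len(buf) else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        k_off = pd.Series(
            -np.log(np.asarray(s_buf, float)) / dt, index=buf_mean.index, name="k_off"
        )
    kin = pd.concat([k_off, phi], axis=1).reset_index().rename(columns={"index": "ace_id"})

    incub = incub.join(k_off, on="ace_id", rsuffix="_pooled")
    incub["k_star"] = np.where(
        incub["condition"] == "Ligand",
        incub["k_total"] - incub["k_off"],
        np.nan,
    )

    fits = pd.DataFrame(
        columns=[
            "ace_id",
            "K_fit",
            "k_star_max",
            "se_K_fit",
            "se_k_star_max",
            "rss",
            "nobs",
            "converged",
            "flags",
        ]
    )
    if fit:
        rows = []
        lig = incub[incub["condition"] == "Ligand"]
        for ace_id, grp in lig.groupby("ace_id"):
            ok = grp["k_star"].notna() & (grp["concentration"] > 0)
            if grp.loc[ok, "concentration"].nunique() < 3:
                continue
            res = DoseResponseModel(
                grp.loc[ok, "concentration"], grp.loc[ok, "k_star"]
            ).fit()
            rows.append(
                {
                    "ace_id": ace_id,
                    "K_fit": res.K_fit,
                    "k_star_max": res.k_star_max,
                    "se_K_fit": res.se_K_fit,
                    "se_k_star_max": res.se_k_star_max,
                    "rss": res.rss,
                    "nobs": res.nobs,
                    "converged": res.converged,
                    "flags": ",".join(res.flags),
                }
            )
        if rows:
            fits = pd.DataFrame(rows)

    rates = incub[
        [
            "ace_id",
            "subarray_id",
            "slide_id",
            "condition",
            "concentration",
            "delta_t",
            "f_hyb",
            "f_post",
            "relative_loss",
            "survival",
            "clipped",
            "uncalibratable",
            "k_total",
            "k_star",
        ]
    ].reset_index(drop=True)
    return AnalysisResult(
        aptamer=aptamer, da=da, rates=rates, kin=kin, fits=fits, flags=flags
    )


def robust_noise_floor(values) -> float:
    """Robust sigma of a rate landscape: 1.4826 * median absolute deviation."""
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return float("nan")
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def empirical_kstar_floor(result: AnalysisResult) -> float:
    """Measurement-noise floor of the induced-fit rate landscape, in 1/h.

    Estimated without ground truth from replicated BufferOnly sub-arrays:
    the per-DA difference of k_total between two BufferOnly sub-arrays is a
    pure noise contrast with variance ``4 sigma_F^2 / dt^2`` (four
    independent aggregated fluorescences; the shared calibration term
    cancels), while ``k* = k_total(Ligand) - k_off(pooled BufferOnly)``
    carries ``3 sigma_F^2 / dt^2``.  The floor is therefore
    ``sqrt(3)/2`` times the robust sd of the BufferOnly difference.

    Falls back to the robust sd of the k* landscape itself when only one
    BufferOnly sub-array exists.
    """
    buf = result.rates[result.rates["condition"] == "BufferOnly"]
    subs = sorted(buf["subarray_id"].unique())
    if len(subs) >= 2:
        a = buf[buf["subarray_id"] == subs[0]].set_index("ace_id")["k_total"]
        b = buf[buf["subarray_id"] == subs[1]].set_index("ace_id")["k_total"]
        diff = (a - b).dropna()
        if len(diff) >= 10:
            return float(np.sqrt(3.0) / 2.0 * robust_noise_floor(diff))
    return robust_noise_floor(result.rates["k_star"])


def exceedances(values, floor: float | None = None, n_sigma: float = 3.0):
    """Designs whose |value| exceeds ``n_sigma`` times the noise floor.

    ``floor`` defaults to the robust sd of ``values`` itself (appropriate
    for a null landscape); pass :func:`empirical_kstar_floor` output when
    the landscape carries real signal.  Returns (mask, floor); NaNs never
    exceed.
    """
    x = np.asarray(values, float)
    if floor is None:
        floor = robust_noise_floor(x)
    with np.errstate(invalid="ignore"):
        mask = np.abs(x) > n_sigma * floor
    return np.where(np.isfinite(x), mask, False), floor
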