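"""Spot quality control and replicate aggregation.

Three per-spot rejection rules are applied to the post-hybridization green
image of each sub-array:

1. low signal      — spot signal < 200 RFU (strict);
2. bad morphology  — pixel CV (sd/signal) above the sub-array mean CV plus
   3 sample standard deviations (strict);
3. high background — local background above the sub-array mean background
   plus 3 sample standard deviations (strict).

A spot failing any rule is dropped from *all* rounds and channels.  An ACE
with fewer than ``min_pass`` surviving replicates in any sub-array is
excluded from the whole dataset and propagates downstream as missing.

The native tables carry one central statistic per spot (the median pixel
signal); rule 1's spot mean is approximated by it, a documented divergence
from pixel-level data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LOW_SIGNAL_THRESHOLD = 200.0  # RFU


class QcError(ValueError):
    pass


def _outlier_cut(values: np.ndarray) -> float:
    """mean + 3 * sample sd (ddof=1); +inf when the spread is undefined."""
    if len(values) < 2:
        return np.inf
    return float(np.mean(values) + 3.0 * np.std(values, ddof=1))


def flag_spots(
    spots: pd.DataFrame, threshold: float = LOW_SIGNAL_THRESHOLD
) -> pd.DataFrame:
    """Apply the three rejection rules to post-hybridization green spots.

    Returns one row per (subarray_id, ace_id, replicate) with boolean
    columns ``low_signal, bad_morphology, high_background, pass``.
    """
    ph = spots[(spots["round"] == "post_hyb") & (spots["channel"] == "green")]
    if ph.empty:
        raise QcError("no post-hybridization green spots to QC")
    out = []
    for subarray, grp in ph.groupby("subarray_id", sort=False):
        sig = grp["median_signal"].to_numpy(float)
        sd = grp["pixel_sd"].to_numpy(float)
        bg = grp["background_mean"].to_numpy(float)
        low = sig < threshold
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(sig > 0, sd / np.where(sig > 0, sig, 1.0), np.inf)
        finite = np.isfinite(cv)
        if finite.sum() < 2:
            raise QcError(
                f"sub-array {subarray!r}: fewer than 2 spots with positive "
                f"signal; pixel CV undefined"
            )
        morph = cv > _outlier_cut(cv[finite])
        morph |= ~finite  # zero-signal spots cannot have a defined CV
        high_bg = bg > _outlier_cut(bg)
        out.append(
            pd.DataFrame(
                {
                    "subarray_id": subarray,
                    "ace_id": grp["ace_id"].to_numpy(),
                    "replicate": grp["replicate"].to_numpy(),
                    "low_signal": low,
                    "bad_morphology": morph,
                    "high_background": high_bg,
                }
            )
        )
    flags = pd.concat(out, ignore_index=True)
    flags["pass"] = ~(
        flags["low_signal"] | flags["bad_morphology"] | flags["high_background"]
    )
    return flags


def aggregate_replicates(
    spots: pd.DataFrame, flags: pd.DataFrame, min_pass: int = 3
) -> pd.DataFrame:
    """Mean passing-replicate signal per (ace, sub-array, round, channel).

    Columns: ``ace_id, subarray_id, round, channel, mean_signal, n_pass,
    excluded``.  ``excluded`` is dataset-wide: true for every row of an ACE
    that has < ``min_pass`` passing replicates in *any* sub-array; its
    ``mean_signal`` is set to NaN.
    """
    key = ["subarray_id", "ace_id", "replicate"]
    merged = spots.merge(flags[key + ["pass"]], on=key, how="left")
    if merged["pass"].isna().any():
        # spots in rounds/channels without a post-hyb flag row (e.g. an ACE
        # absent from the hybridization image) fail closed
        merged["pass"] = merged["pass"].fillna(False).astype(bool)

    passing = merged[merged["pass"]]
    agg = (
        passing.groupby(["ace_id", "subarray_id", "round", "channel"])
        .agg(mean_signal=("median_signal", "mean"), n_pass=("median_signal", "size"))
        .reset_index()
    )
    # reinstate fully-failed groups with n_pass = 0 so exclusion sees them
    all_groups = merged[
        ["ace_id", "subarray_id", "round", "channel"]
    ].drop_duplicates()
    agg = all_groups.merge(
        agg, on=["ace_id", "subarray_id", "round", "channel"], how="left"
    )
    agg["n_pass"] = agg["n_pass"].fillna(0).astype(int)

    per_sub = agg[(agg["round"] == "post_hyb") & (agg["channel"] == "green")]
    worst = per_sub.groupby("ace_id")["n_pass"].min()
    excluded_aces = set(worst.index[worst < min_pass])
    agg["excluded"] = agg["ace_id"].isin(excluded_aces)
    agg.loc[agg["excluded"], "mean_signal"] = np.nan
    return agg
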