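"""Plate normalization, replicate-adjusted Z'-factor QC, and hit calling.

Normalization follows the screen's two-step scheme: features are z-scored to
the plate median first, then either z-scored to the unstimulated-control
median or rescaled linearly to percent inhibition (unstimulated-control
median -> 100%, forskolin-stimulated-control median -> 0%).  The default
z-score denominator is the normal-consistent MAD (1.4826 * MAD); classical
SD scaling is selectable.

The assay-quality statistic is the replicate-adjusted Z'-factor

    Z' = [(AVG_max - 3*SD_max/sqrt(n)) - (AVG_min + 3*SD_min/sqrt(n))]
         / (AVG_max - AVG_min)

where AVG/SD describe the stimulated (max) and unstimulated (min) control
groups and n is the number of technical replicates.  At n = 1 this is the
classical Z'-factor; dividing the 3-SD bands by sqrt(n) credits the assay
for averaging over replicate wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import feature_columns

__all__ = [
    "NormalizedTable", "ZPrimeInputs", "zprime", "zprime_from_groups",
    "zscore_to_plate_median", "zscore_to_control", "percent_inhibition",
    "percent_inhibition_table", "select_hits", "NormalizationError",
]


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedTable:
    """Well x feature matrix under a named normalization.

    ``provenance`` records the medians and scale constants used, plus any
    features flagged constant (zero spread -> values set missing).
    """

    data: pd.DataFrame
    normalization: str
    provenance: dict = field(default_factory=dict)


def _as_frame(table) -> pd.DataFrame:
    return table.data if isinstance(table, NormalizedTable) else table


def _scale(values: np.ndarray, policy: str) -> float:
    if policy == "mad":
        med = np.nanmedian(values)
        return float(1.4826 * np.nanmedian(np.abs(values - med)))
    if policy == "sd":
        return float(np.nanstd(values, ddof=1))
    raise NormalizationError(f"unknown scale policy {policy!r}")


def zscore_to_plate_median(table, scale_policy: str = "mad") -> NormalizedTable:
    """Per plate and feature: (x - plate median) / robust scale.

    Features with zero spread on a plate are flagged constant and set
    missing.  A single-well plate is an error naming the plate.
    """
    df = _as_frame(table).copy()
    for col in feature_columns(df):
        df[col] = df[col].astype(float)
    plates = df["plate"] if "plate" in df.columns else pd.Series("P1", index=df.index)
    prov: dict = {"scale_policy": scale_policy, "constant_features": [],
                  "plate_medians": {}, "plate_scales": {}}
    for plate, idx in df.groupby(plates).groups.items():
        if len(idx) < 2:
            raise NormalizationError(f"plate {plate!r} has fewer than 2 wells")
        for col in feature_columns(df):
            vals = df.loc[idx, col].to_numpy(dtype=float)
            if np.all(np.isnan(vals)):
                continue
            med = float(np.nanmedian(vals))
            s = _scale(vals, scale_policy)
            prov["plate_medians"].setdefault(plate, {})[col] = med
            prov["plate_scales"].setdefault(plate, {})[col] = s
            if s == 0 or not np.isfinite(s):
                prov["constant_features"].append((plate, col))
                df.loc[idx, col] = np.nan
            else:
                df.loc[idx, col] = (vals - med) / s
    return NormalizedTable(df, "plate_z", prov)


def zscore_to_control(table, control_role: str = "unstimulated",
                      scale_policy: str = "mad") -> NormalizedTable:
    """Per plate and feature: (x - control median) / control scale.

    The named control group's median maps to 0 for every feature.
    """
    df = _as_frame(table).copy()
    for col in feature_columns(df):
        df[col] = df[col].astype(float)
    if "role" not in df.columns:
        raise NormalizationError("table has no 'role' column")
    plates = df["plate"] if "plate" in df.columns else pd.Series("P1", index=df.index)
    prov: dict = {"scale_policy": scale_policy, "control_role": control_role,
                  "constant_features": [], "control_medians": {},
                  "control_scales": {}}
    for plate, idx in df.groupby(plates).groups.items():
        ctrl = df.loc[idx][df.loc[idx, "role"] == control_role]
        if len(ctrl) < 2:
            raise NormalizationError(
                f"plate {plate!r} has fewer than 2 {control_role!r} control wells")
        for col in feature_columns(df):
            cvals = ctrl[col].to_numpy(dtype=float)
            if np.all(np.isnan(cvals)):
                continue
            med = float(np.nanmedian(cvals))
            s = _scale(cvals, scale_policy)
            prov["control_medians"].setdefault(plate, {})[col] = med
            prov["control_scales"].setdefault(plate, {})[col] = s
            vals = df.loc[idx, col].to_numpy(dtype=float)
            if s == 0 or not np.isfinite(s):
                prov["constant_features"].append((plate, col))
                df.loc[idx, col] = np.nan
            else:
                df.loc[idx, col] = (vals - med) / s
    return NormalizedTable(df, "control_z", prov)


def percent_inhibition(values, unstim_median: float, stim_median: float):
    """Linear map: stimulated-control median -> 0, unstimulated -> 100.

    Values beyond the anchors are NOT clamped; over-inhibition (> 100%) is a
    meaningful phenotype signal.
    """
    if unstim_median == stim_median:
        raise NormalizationError("percent inhibition undefined: control medians "
                                 "are equal")
    values = np.asarray(values, dtype=float)
    out = 100.0 * (values - stim_median) / (unstim_median - stim_median)
    return float(out) if out.ndim == 0 else out


def percent_inhibition_table(table, feature: str) -> NormalizedTable:
    """Percent-inhibition scaling of one feature, anchored per plate."""
    df = _as_frame(table).copy()
    plates = df["plate"] if "plate" in df.columns else pd.Series("P1", index=df.index)
    prov: dict = {"feature": feature, "anchors": {}}
    col = f"{feature}_percent_inhibition"
    df[col] = np.nan
    for plate, idx in df.groupby(plates).groups.items():
        sub = df.loc[idx]
        unstim = sub[sub["role"] == "unstimulated"][feature].to_numpy(dtype=float)
        stim = sub[sub["role"] == "stimulated"][feature].to_numpy(dtype=float)
        if unstim.size == 0 or stim.size == 0:
            raise NormalizationError(f"plate {plate!r} lacks control wells")
        um, sm = float(np.nanmedian(unstim)), float(np.nanmedian(stim))
        prov["anchors"][plate] = {"unstim_median": um, "stim_median": sm}
        df.loc[idx, col] = percent_inhibition(sub[feature].to_numpy(dtype=float),
                                              um, sm)
    return NormalizedTable(df, "percent_inhibition", prov)


@dataclass(frozen=True)
class ZPrimeInputs:
    """Control-group summaries entering the replicate-adjusted Z'-factor."""

    avg_max: float
    sd_max: float
    avg_min: float
    sd_min: float
    n: int = 1

    def __post_init__(self) -> None:
        if self.sd_max < 0 or self.sd_min < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.avg_max == self.avg_min:
            raise ValueError("Z' undefined: control means are equal")


def zprime(inputs: ZPrimeInputs) -> float:
    """Replicate-adjusted Z'-factor; equals the classical Z' at n = 1."""
    band = 3.0 * (inputs.sd_max + inputs.sd_min) / np.sqrt(inputs.n)
    return float(1.0 - band / (inputs.avg_max - inputs.avg_min))


def zprime_from_groups(max_values, min_values, n: int | None = None) -> float:
    """Z' from raw control-group values; ``n`` defaults to the smaller group."""
    mx = np.asarray(max_values, dtype=float)
    mn = np.asarray(min_values, dtype=float)
    mx, mn = mx[np.isfinite(mx)], mn[np.isfinite(mn)]
    if n is None:
        n = int(min(mx.size, mn.size))
    return zprime(ZPrimeInputs(
        avg_max=float(mx.mean()), sd_max=float(mx.std(ddof=1)) if mx.size > 1 else 0.0,
        avg_min=float(mn.mean()), sd_min=float(mn.std(ddof=1)) if mn.size > 1 else 0.0,
        n=n))


def select_hits(table, size_feature: str = "area_px_median",
                threshold: float = 0.0, doses=None,
                min_replicates: int = 2) -> pd.DataFrame:
    """Call hit compounds by the cyst-size rule.

    A compound is a hit iff the replicate-mean control-z of the size feature
    is <= ``threshold`` at ANY tested dose.  Expects a table normalized by
    :func:`zscore_to_control` (unstimulated-control median at 0).  Compounds
    whose size values are all missing are flagged unevaluable, never hits.

    Returns one row per compound x dose with the replicate mean, the per-dose
    flag and the compound-level hit flag.
    """
    df = _as_frame(table)
    tests = df[df["role"] == "test"]
    if doses is not None:
        tests = tests[tests["concentration_um"].isin(doses)]
    rows = []
    for (treat, dose), grp in tests.groupby(["treatment", "concentration_um"],
                                            sort=True):
        vals = grp[size_feature].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        mean_z = float(vals.mean()) if vals.size >= min_replicates else np.nan
        rows.append({"treatment": treat, "concentration_um": dose,
                     "n_wells": int(len(grp)), "n_evaluable": int(vals.size),
                     "mean_size_z": mean_z,
                     "dose_hit": bool(np.isfinite(mean_z) and mean_z <= threshold)})
    out = pd.DataFrame(rows)
    if len(out) == 0:
        out["hit"] = pd.Series(dtype=bool)
        out["unevaluable"] = pd.Series(dtype=bool)
        return out
    comp_hit = out.groupby("treatment")["dose_hit"].any()
    comp_eval = out.groupby("treatment")["mean_size_z"] \
                   .apply(lambda s: bool(np.isfinite(s).any()))
    out["hit"] = out["treatment"].map(comp_hit)
    out["unevaluable"] = ~out["treatment"].map(comp_eval)
    out.loc[out["unevaluable"], "hit"] = False
    return out.sort_values(["treatment", "concentration_um"]).reset_index(drop=True)
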