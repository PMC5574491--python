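"""Bliss-independence synergy analysis of two-compound dose grids.

Single-agent inhibition is scaled to an effect in [0, 1] (0 = stimulated-
control size, 1 = unstimulated-control size, clamped — Bliss treats effects
as probabilities).  The Bliss null for the combination is

    E = E_A + E_B - E_A * E_B  =  1 - (1 - E_A)(1 - E_B)

and the combination index compares prediction with observation,

    CI = (E_A + E_B - E_A * E_B) / E_AB,

so CI < 1 means the observed combination outperforms independence (synergy)
and CI > 1 underperforms it (antagonism).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalization import percent_inhibition

__all__ = ["SynergyGrid", "scale_effect", "bliss_predicted",
           "combination_index", "classify_interaction", "build_synergy_grid"]


def scale_effect(raw_size, unstim_median: float, stim_median: float):
    """Scale a raw cyst-size readout to an inhibition effect in [0, 1].

    Percent inhibition divided by 100, clamped to [0, 1]; over-inhibited
    wells saturate at 1.
    """
    eff = np.asarray(percent_inhibition(raw_size, unstim_median, stim_median),
                     dtype=float) / 100.0
    out = np.clip(eff, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _check_unit(name, value):
    arr = np.asarray(value, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def bliss_predicted(e_a, e_b):
    """Bliss-independent combined effect E = E_A + E_B - E_A*E_B."""
    a = _check_unit("E_A", e_a)
    b = _check_unit("E_B", e_b)
    out = a + b - a * b
    return float(out) if out.ndim == 0 else out


def combination_index(e_a, e_b, e_ab):
    """CI = (E_A + E_B - E_A*E_B) / E_AB; NaN where E_AB = 0 (flagged, not inf)."""
    pred = np.asarray(bliss_predicted(e_a, e_b), dtype=float)
    obs = np.asarray(e_ab, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(obs > 0, pred / obs, np.nan)
    return float(ci) if ci.ndim == 0 else ci


def classify_interaction(ci, tolerance: float = 0.05):
    """synergistic (CI < 1-tol), antagonistic (CI > 1+tol), else additive."""
    def one(c):
        if not np.isfinite(c):
            return "undefined"
        if c < 1.0 - tolerance:
            return "synergistic"
        if c > 1.0 + tolerance:
            return "antagonistic"
        return "additive"
    arr = np.asarray(ci, dtype=float)
    if arr.ndim == 0:
        return one(float(arr))
    return np.array([one(c) for c in arr.ravel()]).reshape(arr.shape)


@dataclass
class SynergyGrid:
    """Dose x dose grid of scaled effects, Bliss predictions and CIs."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    effect_a: np.ndarray  # per dose of A alone
    effect_b: np.ndarray  # per dose of B alone
    effect_ab: np.ndarray  # observed, shape (len(doses_a), len(doses_b))
    predicted: np.ndarray
    ci: np.ndarray
    labels: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, da in enumerate(self.doses_a):
            for j, db in enumerate(self.doses_b):
                rows.append({
                    "dose_a_um": float(da), "dose_b_um": float(db),
                    "effect_a": float(self.effect_a[i]),
                    "effect_b": float(self.effect_b[j]),
                    "effect_ab": float(self.effect_ab[i, j]),
                    "predicted": float(self.predicted[i, j]),
                    "ci": float(self.ci[i, j]),
                    "label": str(self.labels[i, j]),
                })
        return pd.DataFrame(rows)


def build_synergy_grid(data: pd.DataFrame, unstim_median: float,
                       stim_median: float, tolerance: float = 0.05,
                       value_column: str = "size") -> SynergyGrid:
    """Assemble a Bliss grid from a long-format combination experiment.

    ``data`` needs columns ``dose_a_um``, ``dose_b_um`` and the raw size
    readout (one row per replicate well).  Rows with one zero dose provide
    the single-agent effects; rows with both doses positive provide the
    observed combination effects.  Effects are replicate means of the scaled
    size readout.
    """
    req = {"dose_a_um", "dose_b_um", value_column}
    if not req.issubset(data.columns):
        raise ValueError(f"long table needs columns {sorted(req)}")
    eff = scale_effect(data[value_column].to_numpy(dtype=float),
                       unstim_median, stim_median)
    d = data.assign(_effect=eff)
    doses_a = np.array(sorted(d.loc[d["dose_a_um"] > 0, "dose_a_um"].unique()))
    doses_b = np.array(sorted(d.loc[d["dose_b_um"] > 0, "dose_b_um"].unique()))

    def mono_effect(col, other, dose):
        sub = d[(d[col] == dose) & (d[other] == 0)]
        if len(sub) == 0:
            raise ValueError(f"no single-agent wells at {col}={dose}")
        return float(sub["_effect"].mean())

    e_a = np.array([mono_effect("dose_a_um", "dose_b_um", da) for da in doses_a])
    e_b = np.array([mono_effect("dose_b_um", "dose_a_um", db) for db in doses_b])
    e_ab = np.full((len(doses_a), len(doses_b)), np.nan)
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            sub = d[(d["dose_a_um"] == da) & (d["dose_b_um"] == db)]
            if len(sub):
                e_ab[i, j] = float(sub["_effect"].mean())
    pred = bliss_predicted(e_a[:, None], e_b[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(e_ab > 0, pred / e_ab, np.nan)
    labels = classify_interaction(ci, tolerance)
    return SynergyGrid(doses_a=doses_a, doses_b=doses_b, effect_a=e_a,
                       effect_b=e_b, effect_ab=e_ab, predicted=pred, ci=ci,
                       labels=labels)
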