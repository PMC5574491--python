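"""Per-cyst phenotypic descriptors and their aggregation to well records.

The default descriptor set covers the size / shape / wall / intensity
families: pixel area, perimeter, circularity (4*pi*A/P^2), wall thickness and
wall-area fraction, a wall-to-size ratio, and actin intensity statistics read
from the maximum intensity projection under the object mask.  Wells are
summarised robustly (median and normal-consistent MAD) because per-well cyst
populations carry outliers; the mean area is kept alongside since the screen
reports mean cyst size per well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import CystObject

DESCRIPTORS = (
    "area_px", "perimeter_px", "circularity", "wall_mean_thickness_px",
    "wall_area_fraction", "wall_size_ratio", "actin_mean", "actin_max",
)

ANNOTATION_COLUMNS = ("well_id", "plate", "treatment", "concentration_um",
                      "role", "stimulated")


def compute_object_features(obj: CystObject, actin_projection: np.ndarray) -> dict:
    """Descriptor vector for one segmented cyst.

    ``circularity`` is undefined (NaN) for a zero perimeter; the wall-to-size
    ratio relates the wall thickness to the equivalent circular radius.
    Intensity statistics are taken over the object mask in the projection.
    """
    area = float(obj.area_px)
    perim = float(obj.perimeter_px)
    circ = np.nan
    if perim > 0:
        circ = min(1.0, 4.0 * np.pi * area / perim ** 2)
    r_eq = np.sqrt(area / np.pi) if area > 0 else np.nan
    vals = actin_projection[obj.pixels]
    return {
        "area_px": area,
        "perimeter_px": perim,
        "circularity": circ,
        "wall_mean_thickness_px": float(obj.wall_mean_thickness_px),
        "wall_area_fraction": min(1.0, obj.wall_area_px / area) if area > 0 else np.nan,
        "wall_size_ratio": float(obj.wall_mean_thickness_px / r_eq)
        if r_eq and np.isfinite(r_eq) and r_eq > 0 else np.nan,
        "actin_mean": float(vals.mean()) if vals.size else np.nan,
        "actin_max": float(vals.max()) if vals.size else np.nan,
    }


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


@dataclass
class AggregationPolicy:
    """Which statistics summarise each descriptor across a well's cysts."""

    descriptors: tuple[str, ...] = DESCRIPTORS
    spread_descriptors: tuple[str, ...] = ("area_px",)
    mean_descriptors: tuple[str, ...] = ("area_px",)
    exclude_border: bool = True


@dataclass
class WellFeatureRecord:
    well_id: str
    annotations: dict
    object_count: int
    nuclei_count: int
    features: dict

    def to_row(self) -> dict:
        row = {"well_id": self.well_id, **self.annotations,
               "object_count": self.object_count,
               "nuclei_count": self.nuclei_count}
        row.update(self.features)
        return row


def aggregate_well(object_features: list[dict], nuclei_count: int,
                   annotations: dict,
                   policy: AggregationPolicy | None = None,
                   border_flags: list[bool] | None = None) -> WellFeatureRecord:
    """Collapse a well's per-object descriptor vectors into one record.

    Border-flagged objects are excluded (configurable).  A well with zero
    remaining objects is retained with all aggregates missing — an empty well
    is a cytotoxicity signal, not a data error.
    """
    policy = policy or AggregationPolicy()
    if border_flags is not None and policy.exclude_border:
        object_features = [f for f, b in zip(object_features, border_flags) if not b]
    feats: dict[str, float] = {}
    for name in policy.descriptors:
        vals = np.array([f[name] for f in object_features
                         if np.isfinite(f.get(name, np.nan))], dtype=float)
        feats[f"{name}_median"] = float(np.median(vals)) if vals.size else np.nan
        if name in policy.spread_descriptors:
            feats[f"{name}_mad"] = _mad(vals) if vals.size else np.nan
        if name in policy.mean_descriptors:
            feats[f"{name}_mean"] = float(vals.mean()) if vals.size else np.nan
    well_id = annotations.get("well_id", "")
    ann = {k: v for k, v in annotations.items() if k != "well_id"}
    return WellFeatureRecord(well_id=well_id, annotations=ann,
                             object_count=len(object_features),
                             nuclei_count=int(nuclei_count), features=feats)


def records_to_frame(records: list[WellFeatureRecord]) -> pd.DataFrame:
    """Well x feature table, annotation columns first, sorted by well id."""
    df = pd.DataFrame([r.to_row() for r in records])
    lead = [c for c in ANNOTATION_COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    return df[lead + rest].sort_values("well_id").reset_index(drop=True)


def aggregate_objects_table(objects_df: pd.DataFrame, counts_df: pd.DataFrame,
                            platemap: pd.DataFrame,
                            policy: AggregationPolicy | None = None) -> pd.DataFrame:
    """File-based variant: aggregate a per-object table to a well table.

    ``objects_df`` must carry one row per object with the descriptor columns
    of :data:`DESCRIPTORS` plus ``well_id`` and ``touches_border``;
    ``counts_df`` supplies ``nuclei_count`` per well; ``platemap`` the
    annotations.  Wells present in the platemap but absent from the object
    table yield empty records.
    """
    policy = policy or AggregationPolicy()
    records = []
    counts = counts_df.set_index("well_id")["nuclei_count"] if len(counts_df) else {}
    for _, ann in platemap.iterrows():
        wid = ann["well_id"]
        sub = objects_df[objects_df["well_id"] == wid] if len(objects_df) else \
            pd.DataFrame()
        feats = sub.to_dict("records") if len(sub) else []
        flags = [bool(r.get("touches_border", False)) for r in feats]
        nuc = int(counts.get(wid, 0)) if len(counts_df) else 0
        records.append(aggregate_well(feats, nuc, ann.to_dict(), policy, flags))
    return records_to_frame(records)


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Numeric feature columns of a well table (annotations excluded)."""
    skip = set(ANNOTATION_COLUMNS)
    return [c for c in df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(df[c])]
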