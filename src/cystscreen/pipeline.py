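"""End-to-end orchestration: simulate -> segment -> featurize -> normalize ->
QC -> hits -> profile, driven by one structured config with deterministic
re-runs.

Every stage is a pure function of its declared file inputs, so stages can be
re-run in isolation; the run manifest records the config snapshot, output
checksums, per-plate Z' QC and per-stage timings.  All tabular interchange is
CSV; images are multi-page TIFFs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import AggregationPolicy, aggregate_objects_table, feature_columns
from .normalization import (NormalizationError, select_hits, zprime_from_groups,
                            zscore_to_control, zscore_to_plate_median,
                            percent_inhibition_table)
from .profiling import (ProfilingParams, classify_phenotype, fit_phenotype_space,
                        project, rank_features_by_zprime)
from .segmentation import (NucleiParams, SegmentationParams, count_nuclei,
                           detect_cysts, max_projection)
from .features import compute_object_features
from .simulate import CompoundSpec, ScreenConfig, simulate_screen
from .stacks import read_stack

log = logging.getLogger("cystscreen")

ALL_STAGES = ("simulate", "segment", "featurize", "normalize", "qc", "hits",
              "profile")


class ConfigError(ValueError):
    """The run configuration violates the documented schema."""


class MissingChannelError(FileNotFoundError):
    pass


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages_run: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # stage -> {path: sha256}
    qc: dict = field(default_factory=dict)  # per-plate Z' block
    timings_s: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)  # diagnostic counters

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _screen_config(cfg: dict, seed: int) -> ScreenConfig:
    sc = dict(cfg.get("screen", {}))
    for key in ("plate_shape", "image_size", "cysts_per_well", "nuclei_per_cyst",
                "doses_um"):
        if key in sc:
            sc[key] = tuple(sc[key])
    sc["seed"] = seed
    sc.setdefault("plate_name", cfg.get("plate_name", "P1"))
    try:
        return ScreenConfig(**sc)
    except TypeError as exc:
        raise ConfigError(f"bad screen config: {exc}") from None


def _compounds(cfg: dict) -> list[CompoundSpec]:
    comps = cfg.get("compounds", [])
    if not comps:
        raise ConfigError("config lists no compounds")
    try:
        return [CompoundSpec(**c) for c in comps]
    except TypeError as exc:
        raise ConfigError(f"bad compound spec: {exc}") from None


def _seg_params(cfg: dict) -> SegmentationParams:
    return SegmentationParams(**cfg.get("segmentation", {}))


def _nuc_params(cfg: dict) -> NucleiParams:
    return NucleiParams(**cfg.get("nuclei", {}))


def _prof_params(cfg: dict) -> ProfilingParams:
    return ProfilingParams(**cfg.get("profiling", {}))


def validate_config(cfg: dict) -> None:
    """Fail fast, naming the offending key, before any computation."""
    _compounds(cfg)
    sc = cfg.get("screen", {})
    if sc.get("n_unstim_controls", 8) < 2:
        raise ConfigError("screen.n_unstim_controls must be >= 2 "
                          "(unstimulated controls anchor the normalization)")
    if sc.get("n_stim_controls", 8) < 2:
        raise ConfigError("screen.n_stim_controls must be >= 2")
    norm = cfg.get("normalization", {})
    if norm.get("scale_policy", "mad") not in ("mad", "sd"):
        raise ConfigError("normalization.scale_policy must be 'mad' or 'sd'")


# ---------------------------------------------------------------------------
# per-well segmentation + featurization (shared by file and in-memory paths)


def segment_well_stacks(actin, nuclei, seg: SegmentationParams,
                        nuc: NucleiParams):
    """Detect cysts in a well, featurize each object, count nuclei.

    Returns ``(object_rows, nuclei_count)`` where each object row carries the
    descriptor vector plus bookkeeping columns.
    """
    objects = detect_cysts(actin, seg)
    projection = max_projection(actin)
    rows = []
    for obj in objects:
        row = {"well_id": actin.well_id, "object_id": obj.object_id,
               "plane_index": obj.plane_index,
               "centroid_y": obj.centroid[0], "centroid_x": obj.centroid[1],
               "n_planes_spanned": obj.n_planes_spanned,
               "touches_border": obj.touches_border,
               "degenerate": obj.degenerate}
        row.update(compute_object_features(obj, projection))
        rows.append(row)
    return rows, count_nuclei(nuclei, nuc)


# ---------------------------------------------------------------------------
# file-based stages


def stage_simulate(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    screen = _screen_config(cfg, seed)
    simulate_screen(screen, _compounds(cfg), outdir=outdir)
    return [outdir / "platemap.csv", outdir / "truth_wells.csv",
            outdir / "truth_cysts.csv"]


def stage_segment(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    platemap = pd.read_csv(outdir / "platemap.csv")
    seg, nuc = _seg_params(cfg), _nuc_params(cfg)
    screen = _screen_config(cfg, seed)
    all_rows, counts = [], []
    for _, ann in platemap.sort_values("well_id").iterrows():
        base = outdir / "images" / f"{ann['plate']}_{ann['well_id']}"
        for ch in ("actin", "nuclei"):
            if not (base.parent / f"{base.name}_{ch}.tif").exists():
                raise MissingChannelError(
                    f"missing {ch} stack for well {ann['well_id']}: "
                    f"{base.name}_{ch}.tif")
        actin = read_stack(f"{base}_actin.tif", screen.z_interval_um, "actin",
                           ann["well_id"])
        nuclei = read_stack(f"{base}_nuclei.tif", screen.z_interval_um,
                            "nuclei", ann["well_id"])
        rows, n_nuc = segment_well_stacks(actin, nuclei, seg, nuc)
        all_rows.extend(rows)
        counts.append({"well_id": ann["well_id"], "nuclei_count": n_nuc,
                       "objects_total": len(rows),
                       "objects_border": int(sum(r["touches_border"]
                                                 for r in rows))})
    objects_df = pd.DataFrame(all_rows)
    counts_df = pd.DataFrame(counts)
    objects_df.to_csv(outdir / "objects.csv", index=False)
    counts_df.to_csv(outdir / "well_counts.csv", index=False)
    log.info("segment: %d objects in %d wells", len(objects_df), len(counts_df))
    return [outdir / "objects.csv", outdir / "well_counts.csv"]


def stage_featurize(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    objects_df = pd.read_csv(outdir / "objects.csv")
    counts_df = pd.read_csv(outdir / "well_counts.csv")
    platemap = pd.read_csv(outdir / "platemap.csv")
    feats = aggregate_objects_table(objects_df, counts_df, platemap,
                                    AggregationPolicy())
    feats.to_csv(outdir / "well_features.csv", index=False)
    return [outdir / "well_features.csv"]


def _load_features(outdir: Path) -> pd.DataFrame:
    path = outdir / "well_features.csv"
    if not path.exists():
        raise ConfigError("well_features.csv not found; run the featurize "
                          "stage first")
    return pd.read_csv(path)


def stage_normalize(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    feats = _load_features(outdir)
    norm = cfg.get("normalization", {})
    policy = norm.get("scale_policy", "mad")
    size_feature = norm.get("size_feature", "area_px_median")
    plate_z = zscore_to_plate_median(feats, policy)
    control_z = zscore_to_control(plate_z, "unstimulated", policy)
    pct = percent_inhibition_table(feats, size_feature)
    plate_z.data.to_csv(outdir / "normalized_plate_z.csv", index=False)
    control_z.data.to_csv(outdir / "normalized_control_z.csv", index=False)
    pct.data.to_csv(outdir / "percent_inhibition.csv", index=False)
    return [outdir / "normalized_plate_z.csv",
            outdir / "normalized_control_z.csv",
            outdir / "percent_inhibition.csv"]


def stage_qc(cfg: dict, outdir: Path, seed: int, manifest: RunManifest
             ) -> list[Path]:
    feats = _load_features(outdir)
    size_feature = cfg.get("normalization", {}).get("size_feature",
                                                    "area_px_median")
    qc = {}
    plates = feats["plate"] if "plate" in feats.columns else \
        pd.Series("P1", index=feats.index)
    for plate, sub in feats.groupby(plates):
        stim = sub[sub["role"] == "stimulated"][size_feature]
        unstim = sub[sub["role"] == "unstimulated"][size_feature]
        if len(stim) < 2 or len(unstim) < 2:
            raise NormalizationError(f"plate {plate!r} lacks control wells for QC")
        qc[str(plate)] = {
            "zprime_replicate_adjusted": zprime_from_groups(stim, unstim),
            "zprime_classical": zprime_from_groups(stim, unstim, n=1),
            "n_stimulated": int(len(stim)), "n_unstimulated": int(len(unstim)),
            "feature": size_feature,
        }
    manifest.qc = qc
    with open(outdir / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
    return [outdir / "qc.json"]


def stage_hits(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    control_z = pd.read_csv(outdir / "normalized_control_z.csv")
    norm = cfg.get("normalization", {})
    hits = select_hits(control_z,
                       size_feature=norm.get("size_feature", "area_px_median"),
                       threshold=norm.get("hit_threshold", 0.0),
                       min_replicates=norm.get("min_replicates", 2))
    hits.to_csv(outdir / "hits.csv", index=False)
    return [outdir / "hits.csv"]


def _usable_features(df: pd.DataFrame) -> list[str]:
    """Feature columns with enough finite, non-constant values to enter a PCA."""
    out = []
    for col in feature_columns(df):
        vals = df[col].dropna()
        if len(vals) >= 4 and vals.nunique() > 1:
            out.append(col)
    return out


def stage_profile(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    control_z = pd.read_csv(outdir / "normalized_control_z.csv")
    feats = _load_features(outdir)
    params = _prof_params(cfg)
    if (control_z["role"] == params.group_b_role).sum() >= 2:
        selected, ranking = rank_features_by_zprime(control_z, params)
    else:
        # no reference-inhibitor wells on the plate: profile on all features
        selected = _usable_features(control_z)
        ranking = pd.DataFrame({"feature": selected, "zprime": np.nan,
                                "selected": True})
    space = fit_phenotype_space(control_z, selected, params)
    scores = project(space, control_z)
    labels = classify_phenotype(scores, space,
                                feats[["well_id", "nuclei_count"]], params)
    ranking.to_csv(outdir / "feature_ranking.csv", index=False)
    space.loadings.rename_axis("feature").reset_index().to_csv(
        outdir / "pca_loadings.csv", index=False)
    pd.DataFrame({"component": list(space.loadings.columns),
                  "explained_variance_fraction":
                      space.explained_variance_fraction}).to_csv(
        outdir / "pca_explained_variance.csv", index=False)
    scores.to_csv(outdir / "pca_scores.csv", index=False)
    labels.to_csv(outdir / "phenotype_labels.csv", index=False)
    return [outdir / "feature_ranking.csv", outdir / "pca_loadings.csv",
            outdir / "pca_explained_variance.csv", outdir / "pca_scores.csv",
            outdir / "phenotype_labels.csv"]


def run_pipeline(config, stages=None, outdir=None, seed=None) -> RunManifest:
    """Run the requested stages in order and write the run manifest.

    ``config`` is a YAML path or a dict.  ``seed`` and ``outdir`` override
    the config keys of the same name.  Fails fast with the offending stage
    named.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    validate_config(cfg)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    outdir = Path(cfg.get("outdir", "cystscreen_run") if outdir is None else outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or cfg.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")

    manifest = RunManifest(config=cfg, seed=seed)
    runners = {
        "simulate": stage_simulate, "segment": stage_segment,
        "featurize": stage_featurize, "normalize": stage_normalize,
        "hits": stage_hits, "profile": stage_profile,
    }
    for stage in [s for s in ALL_STAGES if s in stages]:
        t0 = time.perf_counter()
        try:
            if stage == "qc":
                paths = stage_qc(cfg, outdir, seed, manifest)
            else:
                paths = runners[stage](cfg, outdir, seed)
        except Exception as exc:
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        manifest.stages_run.append(stage)
        manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)
        manifest.outputs[stage] = {str(p): _sha256(p) for p in paths}
        log.info("stage %s done in %.2fs", stage, manifest.timings_s[stage])
    manifest.save(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# in-memory screen analysis (no file round-trips; used for experiments)


@dataclass
class ScreenAnalysis:
    wells: list
    truth: pd.DataFrame
    features: pd.DataFrame
    control_z: pd.DataFrame
    zprime: float
    hits: pd.DataFrame
    labels: pd.DataFrame
    explained_variance_fraction: np.ndarray


def analyze_screen(screen: ScreenConfig, compounds: list[CompoundSpec],
                   seg: SegmentationParams | None = None,
                   nuc: NucleiParams | None = None,
                   prof: ProfilingParams | None = None,
                   scale_policy: str = "mad",
                   size_feature: str = "area_px_median") -> ScreenAnalysis:
    """Simulate a screen and run the full analysis in memory."""
    from .simulate import iter_simulated_wells, truth_tables, platemap_table

    seg = seg or SegmentationParams()
    nuc = nuc or NucleiParams()
    prof = prof or ProfilingParams()
    wells, rows, counts = [], [], []
    for well, actin, nuclei in iter_simulated_wells(screen, compounds):
        wells.append(well)
        wrows, n_nuc = segment_well_stacks(actin, nuclei, seg, nuc)
        rows.extend(wrows)
        counts.append({"well_id": well.well_id, "nuclei_count": n_nuc})
    truth, _ = truth_tables(wells)
    pm = platemap_table(wells)
    pm["plate"] = screen.plate_name
    feats = aggregate_objects_table(pd.DataFrame(rows), pd.DataFrame(counts), pm)
    plate_z = zscore_to_plate_median(feats, scale_policy)
    control_z = zscore_to_control(plate_z, "unstimulated", scale_policy)
    zp = zprime_from_groups(
        feats[feats["role"] == "stimulated"][size_feature],
        feats[feats["role"] == "unstimulated"][size_feature])
    hits = select_hits(control_z, size_feature=size_feature)
    if (control_z.data["role"] == prof.group_b_role).sum() >= 2:
        selected, _ = rank_features_by_zprime(control_z, prof)
    else:
        selected = _usable_features(control_z.data)
    space = fit_phenotype_space(control_z, selected, prof)
    scores = project(space, control_z)
    labels = classify_phenotype(scores, space,
                                feats[["well_id", "nuclei_count"]], prof)
    return ScreenAnalysis(wells=wells, truth=truth, features=feats,
                          control_z=control_z.data, zprime=zp, hits=hits,
                          labels=labels,
                          explained_variance_fraction=
                          space.explained_variance_fraction)
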