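"""Synthetic two-channel cyst screens with exhaustive ground truth.

This module emulates the statistical structure of a 384-well 3D cyst-swelling
screen: renal epithelial cysts grow as hollow spheres in a gel, imaged as
z-stacks of an actin channel (bright wall ring around a dim lumen) and a
nuclei channel (point-like spots near the wall).  Forskolin stimulation
swells cysts by a multiplicative radius factor; test compounds inhibit that
swelling with Hill-type dose dependence; cytotoxic compounds additionally
shrink cysts, fragment the actin wall and reduce nuclei counts ("novel
phenotype" wells).

Everything is reproducible from a single master seed.  Substreams are derived
with a fixed counter scheme (see :func:`substream`), so the plate layout and
every individual well render are independently reproducible.

Active compounds slightly inhibit basal (unstimulated-equivalent) cyst growth
in addition to abolishing the forskolin response.  This reproduces the
screen-level behaviour that full actives land *at or below* the unstimulated
control median — which is what makes a "size z-score <= 0" hit rule
informative rather than a coin flip.  Set ``basal_inhibition=0`` for
generators in which a full-effect well is distribution-identical to an
unstimulated well (same substream => identical draws).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stacks import ImageStack, write_stack

CONTROL_ROLES = ("unstimulated", "stimulated", "reference_inhibitor", "test")

# substream purposes (counter scheme: SeedSequence(master, spawn_key=(purpose, index)))
_STREAM_LAYOUT = 0
_STREAM_CYSTS = 1
_STREAM_RENDER = 2
_STREAM_NOISE = 3


class LayoutError(ValueError):
    """More wells requested than the plate can hold, or controls missing."""


@dataclass(frozen=True)
class CystSpec:
    """Ground truth for one cyst: a sphere with an actin-dense wall.

    ``center_zyx`` holds (z in plane index, y, x) in pixel coordinates; the z
    component is a plane index on the acquisition grid.  ``integrity`` < 1
    removes arc segments of the wall ring (fragmented, toxic phenotype).
    """

    center_zyx: tuple[float, float, float]
    radius: float
    wall_thickness: float
    wall_intensity: float
    lumen_intensity: float
    n_nuclei: int
    integrity: float = 1.0

    def __post_init__(self) -> None:
        if not (self.radius > self.wall_thickness >= 1):
            raise ValueError("need radius > wall_thickness >= 1")
        if not (0.0 <= self.integrity <= 1.0):
            raise ValueError("integrity must lie in [0, 1]")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")


@dataclass
class WellTruth:
    """One well's annotations and (once populated) its cysts."""

    well_id: str
    role: str
    treatment: str
    concentration: float  # µM; 0 for controls
    stimulated: bool
    true_effect: float  # fraction of forskolin swelling inhibited, in [0, 1]
    toxic: bool = False
    tox_level: float = 0.0  # graded toxicity in [0, 1]
    cysts: list[CystSpec] = field(default_factory=list)
    well_index: int = 0  # row-major position on the plate; substream counter

    def __post_init__(self) -> None:
        if self.role not in CONTROL_ROLES:
            raise ValueError(f"unknown control role {self.role!r}")
        if not (0.0 <= self.true_effect <= 1.0):
            raise ValueError("true_effect must lie in [0, 1]")


@dataclass(frozen=True)
class CompoundSpec:
    """Dose-response description of a test compound.

    ``max_inhibition`` is the saturating fraction of forskolin-induced
    swelling that the compound blocks.  Toxic compounds get a separate Hill
    curve (``tox_ec50_um``, defaulting to ``ec50_um``) controlling wall
    fragmentation, cyst shrinkage and nuclei loss.
    """

    name: str
    ec50_um: float = 0.01
    hill_slope: float = 2.0
    max_inhibition: float = 1.0
    toxic: bool = False
    tox_ec50_um: float | None = None


@dataclass
class ScreenConfig:
    """Everything the generator needs to lay out, populate and render a screen."""

    plate_shape: tuple[int, int] = (16, 24)
    n_planes: int = 25
    z_interval_um: float = 50.0
    image_size: tuple[int, int] = (1024, 1024)
    noise_sd: float = 40.0
    background: float = 200.0
    dynamic_range: float = 65535.0
    # morphology
    cysts_per_well: tuple[int, int] = (100, 150)
    base_radius_px: float = 10.0
    radius_cv: float = 0.2
    wall_thickness_px: float = 3.0
    wall_intensity: float = 3000.0
    lumen_intensity: float = 800.0
    nuclei_per_cyst: tuple[int, int] = (4, 8)
    nucleus_sigma_px: float = 2.0
    nucleus_intensity: float = 2500.0
    # z geometry: xy-equivalent pixels per plane step; with 50 µm plane spacing
    # and ~2 µm pixels most cysts intersect 1-3 planes
    z_scale_px: float = 15.0
    # pharmacology
    swelling_factor: float = 1.6
    basal_inhibition: float = 0.05
    toxic_radius_factor: float = 0.5
    toxic_nuclei_factor: float = 0.35
    toxic_integrity: float = 0.4
    reference_effect: float = 1.0
    # layout
    doses_um: tuple[float, ...] = (0.1, 1.0)
    replicates: int = 4
    n_unstim_controls: int = 8
    n_stim_controls: int = 8
    n_reference_controls: int = 0
    plate_name: str = "P1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if min(self.image_size) <= 0:
            raise ValueError("image_size must be positive")


def desk_screen_config(seed: int, **overrides) -> ScreenConfig:
    """Desk-scale study conditions: a 32-well mini-screen.

    3 compounds x 2 doses (0.1 and 1 µM) x 4 replicate wells plus 4 + 4
    controls on a 4 x 8 plate region; 5 focal planes, 256 px images, 10-14
    cysts per well.  These are the full screen conditions scaled down so a
    whole-screen recovery experiment runs in seconds on one CPU.
    """
    kw = dict(plate_shape=(4, 8), n_planes=5, image_size=(256, 256),
              cysts_per_well=(10, 14), base_radius_px=10.0, noise_sd=40.0,
              n_unstim_controls=4, n_stim_controls=4, replicates=4, seed=seed)
    kw.update(overrides)
    return ScreenConfig(**kw)


def desk_compounds() -> list[CompoundSpec]:
    """One full-effect active, one inert and one cytotoxic compound."""
    return [
        CompoundSpec("active", ec50_um=0.01, hill_slope=2.0, max_inhibition=1.0),
        CompoundSpec("inert", max_inhibition=0.0),
        CompoundSpec("toxicant", ec50_um=0.02, hill_slope=2.0, toxic=True),
    ]


def substream(seed: int, purpose: int, index: int = 0) -> np.random.Generator:
    """Deterministic child RNG: ``SeedSequence(seed, spawn_key=(purpose, index))``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(purpose, index)))


def hill(concentration_um: float, ec50_um: float, slope: float, emax: float) -> float:
    """Hill inhibition curve; 0 at zero dose, ``emax`` at saturation."""
    if concentration_um <= 0:
        return 0.0
    return float(emax / (1.0 + (ec50_um / concentration_um) ** slope))


def well_name(row: int, col: int) -> str:
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


# ---------------------------------------------------------------------------
# layout


def generate_plate_layout(config: ScreenConfig,
                          compounds: list[CompoundSpec]) -> list[WellTruth]:
    """Assign control and compound wells to plate positions (annotations only).

    Controls and every compound x dose x replicate combination are scattered
    over the plate by a seed-derived permutation; the returned list is sorted
    by well id.  Raises :class:`LayoutError` if the request exceeds the plate
    capacity or no stimulated/unstimulated controls are requested.
    """
    if config.n_unstim_controls < 1 or config.n_stim_controls < 1:
        raise LayoutError("at least one unstimulated and one stimulated control "
                          "group is required")
    requests: list[tuple[str, str, float, bool, float, float]] = []
    # (role, treatment, conc, stimulated, effect, tox_level)
    for _ in range(config.n_unstim_controls):
        requests.append(("unstimulated", "solvent", 0.0, False, 0.0, 0.0))
    for _ in range(config.n_stim_controls):
        requests.append(("stimulated", "forskolin", 0.0, True, 0.0, 0.0))
    for _ in range(config.n_reference_controls):
        requests.append(("reference_inhibitor", "reference_inhibitor", 0.0, True,
                         config.reference_effect, 0.0))
    for comp in compounds:
        for dose in config.doses_um:
            effect = hill(dose, comp.ec50_um, comp.hill_slope, comp.max_inhibition)
            tox = 0.0
            if comp.toxic:
                tox = hill(dose, comp.tox_ec50_um or comp.ec50_um, comp.hill_slope, 1.0)
            for _ in range(config.replicates):
                requests.append(("test", comp.name, dose, True, effect, tox))

    rows, cols = config.plate_shape
    capacity = rows * cols
    if len(requests) > capacity:
        raise LayoutError(f"{len(requests)} wells requested but the plate holds "
                          f"only {capacity}")

    rng = substream(config.seed, _STREAM_LAYOUT)
    positions = rng.permutation(capacity)[: len(requests)]
    wells = []
    for pos, (role, treat, conc, stim, eff, tox) in zip(positions, requests):
        r, c = divmod(int(pos), cols)
        wells.append(WellTruth(well_id=well_name(r, c), role=role, treatment=treat,
                               concentration=conc, stimulated=stim, true_effect=eff,
                               toxic=tox >= 0.5, tox_level=tox, well_index=int(pos)))
    wells.sort(key=lambda w: w.well_id)
    return wells


# ---------------------------------------------------------------------------
# cyst population


def _radius_multiplier(well: WellTruth, config: ScreenConfig) -> float:
    m = 1.0
    if well.stimulated:
        m *= 1.0 + (config.swelling_factor - 1.0) * (1.0 - well.true_effect)
    if well.role in ("test", "reference_inhibitor"):
        m *= 1.0 - config.basal_inhibition * well.true_effect
        m *= 1.0 - (1.0 - config.toxic_radius_factor) * well.tox_level
    return m


def populate_cysts(well: WellTruth, config: ScreenConfig) -> WellTruth:
    """Draw the well's cysts from its substream and apply treatment effects.

    Base radii, z positions and nuclei counts are drawn in a treatment-
    independent order, then scaled by the treatment multipliers; a well with
    ``true_effect = 1`` (and no basal inhibition or toxicity) therefore
    receives *exactly* the cysts of an unstimulated well with the same
    substream.
    """
    rng = substream(config.seed, _STREAM_CYSTS, well.well_index)
    lo, hi = config.cysts_per_well
    n = int(rng.integers(lo, hi + 1))
    sigma = np.sqrt(np.log1p(config.radius_cv ** 2))
    base_radii = config.base_radius_px * np.exp(rng.normal(0.0, sigma, size=n))
    z_centers = rng.integers(0, config.n_planes, size=n)
    nlo, nhi = config.nuclei_per_cyst
    nuclei = rng.integers(nlo, nhi + 1, size=n)

    mult = _radius_multiplier(well, config)
    nuc_mult = 1.0 - (1.0 - config.toxic_nuclei_factor) * well.tox_level \
        if well.role in ("test", "reference_inhibitor") else 1.0
    integrity = 1.0 - (1.0 - config.toxic_integrity) * well.tox_level \
        if well.role in ("test", "reference_inhibitor") else 1.0

    h, w = config.image_size
    placed: list[tuple[float, float, float, float]] = []  # z, y, x, r
    cysts = []
    for i in range(n):
        r = float(base_radii[i] * mult)
        r = max(r, config.wall_thickness_px + 1.0)
        margin = r + 3.0
        if 2 * margin >= min(h, w):
            r = min(h, w) / 2.0 - 4.0
            margin = r + 3.0
        z = float(z_centers[i])
        y = x = None
        for _ in range(200):
            yy = float(rng.uniform(margin, h - margin))
            xx = float(rng.uniform(margin, w - margin))
            ok = all(abs(z - pz) > 2.0 or (yy - py) ** 2 + (xx - px) ** 2
                     > (1.1 * (r + pr) + 4.0) ** 2
                     for pz, py, px, pr in placed)
            if ok:
                y, x = yy, xx
                break
        if y is None:  # crowded well: accept the last draw
            y, x = yy, xx
        placed.append((z, y, x, r))
        cysts.append(CystSpec(center_zyx=(z, y, x), radius=r,
                              wall_thickness=config.wall_thickness_px,
                              wall_intensity=config.wall_intensity,
                              lumen_intensity=config.lumen_intensity,
                              n_nuclei=int(round(int(nuclei[i]) * nuc_mult)),
                              integrity=float(integrity)))
    well.cysts = cysts
    return well


# ---------------------------------------------------------------------------
# rendering


def rasterized_disc_area(radius: float) -> int:
    """Pixel count of a rasterized disc (pixel centers within ``radius``)."""
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return int(np.count_nonzero(yy ** 2 + xx ** 2 <= radius ** 2))


def _disc_radius_at_plane(cyst: CystSpec, plane: int, z_scale: float) -> float:
    dz = (plane - cyst.center_zyx[0]) * z_scale
    if abs(dz) >= cyst.radius:
        return 0.0
    return float(np.sqrt(cyst.radius ** 2 - dz ** 2))


def render_well(well: WellTruth, config: ScreenConfig,
                add_noise: bool = True) -> tuple[ImageStack, ImageStack]:
    """Rasterize a well's cysts into (actin, nuclei) z-stacks.

    Each cyst sphere is drawn plane-by-plane as a bright annulus of its wall
    thickness around a dim lumen; fragmented walls (integrity < 1) lose arc
    segments.  Nuclei are Gaussian spots placed near the wall on the cyst's
    central plane.  Additive Gaussian noise with sd ``config.noise_sd`` is
    applied and intensities are clipped to ``[0, dynamic_range]``.
    """
    h, w = config.image_size
    if h <= 0 or w <= 0 or config.n_planes < 1:
        raise ValueError("image size and plane count must be positive")
    for c in well.cysts:
        _, cy, cx = c.center_zyx
        if not (0 <= c.center_zyx[0] < config.n_planes and 0 <= cy < h and 0 <= cx < w):
            raise ValueError(f"cyst center {c.center_zyx} outside the image volume "
                             f"in well {well.well_id}")

    rng = substream(config.seed, _STREAM_RENDER, well.well_index)
    actin = np.zeros((config.n_planes, h, w), dtype=np.float64)
    nuclei = np.zeros_like(actin)

    for cyst in well.cysts:
        cz, cy, cx = cyst.center_zyx
        # wall-gap arcs for fragmented rings; drawn per cyst, used on all planes
        gap_arcs: list[tuple[float, float]] = []
        if cyst.integrity < 1.0:
            n_gaps = 3
            gap_total = (1.0 - cyst.integrity) * 2 * np.pi
            width = gap_total / n_gaps
            for k in range(n_gaps):
                start = float(rng.uniform(0, 2 * np.pi))
                gap_arcs.append((start, width))
        pmin = max(0, int(np.ceil(cz - cyst.radius / config.z_scale_px)))
        pmax = min(config.n_planes - 1,
                   int(np.floor(cz + cyst.radius / config.z_scale_px)))
        for p in range(pmin, pmax + 1):
            rp = _disc_radius_at_plane(cyst, p, config.z_scale_px)
            if rp <= 0:
                continue
            rint = int(np.ceil(rp)) + 1
            y0, y1 = max(0, int(cy) - rint), min(h, int(cy) + rint + 1)
            x0, x1 = max(0, int(cx) - rint), min(w, int(cx) + rint + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            disc = d2 <= rp ** 2
            inner = max(rp - cyst.wall_thickness, 0.0)
            ring = disc & (d2 > inner ** 2)
            if gap_arcs:
                theta = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
                keep = np.ones_like(ring)
                for start, width in gap_arcs:
                    in_gap = np.mod(theta - start, 2 * np.pi) < width
                    keep &= ~in_gap
                ring = ring & keep
            patch = actin[p, y0:y1, x0:x1]
            np.maximum(patch, np.where(ring, cyst.wall_intensity,
                                       np.where(disc, cyst.lumen_intensity, 0.0)),
                       out=patch)
        # nuclei: spots near the wall on the central plane, spread angularly so
        # that individual nuclei stay resolvable (nuclei are solid bodies)
        if cyst.n_nuclei > 0:
            p = int(round(cz))
            angle0 = float(rng.uniform(0, 2 * np.pi))
            for k in range(cyst.n_nuclei):
                ang = angle0 + 2 * np.pi * (k + float(rng.uniform(-0.25, 0.25))) \
                    / cyst.n_nuclei
                rad = cyst.radius * float(rng.uniform(0.75, 1.0))
                ny, nx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
                s = config.nucleus_sigma_px
                ext = int(np.ceil(4 * s))
                y0, y1 = max(0, int(ny) - ext), min(h, int(ny) + ext + 1)
                x0, x1 = max(0, int(nx) - ext), min(w, int(nx) + ext + 1)
                if y0 >= y1 or x0 >= x1:
                    continue
                yy, xx = np.mgrid[y0:y1, x0:x1]
                blob = config.nucleus_intensity * np.exp(
                    -((yy - ny) ** 2 + (xx - nx) ** 2) / (2 * s ** 2))
                np.maximum(nuclei[p, y0:y1, x0:x1], blob,
                           out=nuclei[p, y0:y1, x0:x1])

    actin += config.background
    nuclei += config.background
    if add_noise and config.noise_sd > 0:
        noise_rng = substream(config.seed, _STREAM_NOISE, well.well_index)
        actin += noise_rng.normal(0.0, config.noise_sd, size=actin.shape)
        nuclei += noise_rng.normal(0.0, config.noise_sd, size=nuclei.shape)
    np.clip(actin, 0.0, config.dynamic_range, out=actin)
    np.clip(nuclei, 0.0, config.dynamic_range, out=nuclei)

    mk = lambda a, ch: ImageStack(a, z_interval_um=config.z_interval_um,
                                  channel=ch, well_id=well.well_id)
    return mk(actin, "actin"), mk(nuclei, "nuclei")


# ---------------------------------------------------------------------------
# whole screens


def iter_simulated_wells(config: ScreenConfig, compounds: list[CompoundSpec],
                         add_noise: bool = True):
    """Yield ``(WellTruth, actin_stack, nuclei_stack)`` for a whole screen."""
    for well in generate_plate_layout(config, compounds):
        populate_cysts(well, config)
        actin, nuc = render_well(well, config, add_noise=add_noise)
        yield well, actin, nuc


def truth_tables(wells: list[WellTruth]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Well-level and cyst-level ground-truth tables."""
    wrows, crows = [], []
    for wt in wells:
        wrows.append({
            "well_id": wt.well_id, "role": wt.role, "treatment": wt.treatment,
            "concentration_um": wt.concentration, "stimulated": wt.stimulated,
            "true_effect": wt.true_effect, "toxic": wt.toxic,
            "tox_level": wt.tox_level, "n_cysts": len(wt.cysts),
            "mean_radius_px": float(np.mean([c.radius for c in wt.cysts]))
            if wt.cysts else np.nan,
            "total_nuclei": int(sum(c.n_nuclei for c in wt.cysts)),
        })
        for c in wt.cysts:
            crows.append({
                "well_id": wt.well_id, "z_plane": c.center_zyx[0],
                "y_px": c.center_zyx[1], "x_px": c.center_zyx[2],
                "radius_px": c.radius, "wall_thickness_px": c.wall_thickness,
                "n_nuclei": c.n_nuclei, "integrity": c.integrity,
                "area_px_truth": rasterized_disc_area(c.radius),
            })
    return pd.DataFrame(wrows), pd.DataFrame(crows)


def platemap_table(wells: list[WellTruth]) -> pd.DataFrame:
    """The annotation table an analyst would have: no hidden truth columns."""
    return pd.DataFrame([{
        "well_id": w.well_id, "plate": "", "treatment": w.treatment,
        "concentration_um": w.concentration, "role": w.role,
        "stimulated": w.stimulated} for w in wells])


def simulate_screen(config: ScreenConfig, compounds: list[CompoundSpec],
                    outdir=None, add_noise: bool = True):
    """Simulate a full screen; optionally write TIFFs and truth CSVs.

    Returns ``(wells, truth_wells_df, truth_cysts_df)``.  With ``outdir`` set,
    per-well multi-page TIFFs are written as
    ``<plate>_<well>_<channel>.tif`` under ``outdir/images`` together with
    ``platemap.csv``, ``truth_wells.csv`` and ``truth_cysts.csv``.
    """
    wells = []
    if outdir is not None:
        from pathlib import Path
        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)
    for well, actin, nuc in iter_simulated_wells(config, compounds, add_noise):
        wells.append(well)
        if outdir is not None:
            base = outdir / "images" / f"{config.plate_name}_{well.well_id}"
            write_stack(f"{base}_actin.tif", actin)
            write_stack(f"{base}_nuclei.tif", nuc)
    wdf, cdf = truth_tables(wells)
    if outdir is not None:
        pm = platemap_table(wells)
        pm["plate"] = config.plate_name
        pm.to_csv(outdir / "platemap.csv", index=False)
        wdf.to_csv(outdir / "truth_wells.csv", index=False)
        cdf.to_csv(outdir / "truth_cysts.csv", index=False)
    return wells, wdf, cdf
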