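"""Generator contracts: layout arithmetic, determinism, rendering geometry."""

import numpy as np
import pandas as pd
import pytest

import cystscreen as cs
from conftest import mini_compounds, mini_screen_config, render_single_cyst


def small_config(**kw):
    base = dict(plate_shape=(8, 6), n_planes=5, image_size=(192, 192),
                cysts_per_well=(6, 9), noise_sd=0.0, n_unstim_controls=8,
                n_stim_controls=8, replicates=4, seed=3)
    base.update(kw)
    return cs.ScreenConfig(**base)


class TestLayout:
    def test_well_arithmetic(self):
        cfg = small_config()
        comps = [cs.CompoundSpec("a"), cs.CompoundSpec("b")]
        wells = cs.generate_plate_layout(cfg, comps)
        assert len(wells) == 2 * 2 * 4 + 8 + 8
        controls = [w for w in wells if w.role in ("unstimulated", "stimulated")]
        assert len(controls) == 16
        for comp in comps:
            for dose in cfg.doses_um:
                reps = [w for w in wells if w.treatment == comp.name
                        and w.concentration == dose]
                assert len(reps) == cfg.replicates

    def test_same_seed_same_layout(self):
        cfg = small_config()
        comps = [cs.CompoundSpec("a")]
        a = cs.generate_plate_layout(cfg, comps)
        b = cs.generate_plate_layout(cfg, comps)
        assert [(w.well_id, w.treatment, w.concentration) for w in a] == \
               [(w.well_id, w.treatment, w.concentration) for w in b]

    def test_layout_overflow_raises(self):
        cfg = cs.ScreenConfig(plate_shape=(16, 24), replicates=8)
        comps = [cs.CompoundSpec(f"c{i}") for i in range(24)]
        # 24 compounds x 2 doses x 8 replicates + 16 controls = 400 > 384
        with pytest.raises(cs.LayoutError):
            cs.generate_plate_layout(cfg, comps)

    def test_missing_controls_raises(self):
        with pytest.raises(cs.LayoutError):
            cs.generate_plate_layout(small_config(n_stim_controls=0), [])


class TestRender:
    def test_midplane_annulus_area_matches_disc(self):
        _, actin, _, cfg = render_single_cyst(radius=20, wall=3, noise_sd=0)
        mask = actin.planes[1] > cfg.background
        assert mask.sum() == pytest.approx(np.pi * 20 ** 2, rel=0.05)

    def test_empty_scene_is_constant_background(self):
        well = cs.WellTruth(well_id="A01", role="unstimulated",
                            treatment="solvent", concentration=0.0,
                            stimulated=False, true_effect=0.0, cysts=[])
        cfg = small_config()
        actin, nuclei = cs.render_well(well, cfg, add_noise=False)
        assert np.all(actin.planes == cfg.background)
        assert np.all(nuclei.planes == cfg.background)

    def test_vertically_separated_cysts_share_no_plane(self):
        cfg = cs.ScreenConfig(plate_shape=(1, 1), n_planes=14,
                              image_size=(128, 128), noise_sd=0.0,
                              n_unstim_controls=1, n_stim_controls=1)
        mk = lambda z: cs.CystSpec(center_zyx=(z, 64, 64), radius=20,
                                   wall_thickness=3, wall_intensity=3000,
                                   lumen_intensity=800, n_nuclei=0)
        well = cs.WellTruth(well_id="A01", role="unstimulated",
                            treatment="solvent", concentration=0.0,
                            stimulated=False, true_effect=0.0,
                            cysts=[mk(2), mk(12)])
        actin, _ = cs.render_well(well, cfg, add_noise=False)
        occupied = [p for p in range(cfg.n_planes)
                    if (actin.planes[p] > cfg.background).any()]
        # r=20 px at 15 px/plane: each sphere spans center +/- 1 plane
        assert set(occupied) == {1, 2, 3, 11, 12, 13}

    def test_cyst_outside_volume_raises(self):
        cfg = small_config()
        spec = cs.CystSpec(center_zyx=(99, 50, 50), radius=10,
                           wall_thickness=3, wall_intensity=3000,
                           lumen_intensity=800, n_nuclei=0)
        well = cs.WellTruth(well_id="A01", role="test", treatment="x",
                            concentration=1.0, stimulated=True,
                            true_effect=0.0, cysts=[spec])
        with pytest.raises(ValueError, match="outside"):
            cs.render_well(well, cfg)

    @pytest.mark.parametrize("radius", [5, 8, 12, 20, 40])
    def test_truth_area_matches_rendered_mask(self, radius):
        """Analytic, rasterized and rendered (noise-free) areas agree to 5%."""
        _, actin, _, cfg = render_single_cyst(radius=radius, wall=3,
                                              image=(160, 160), noise_sd=0)
        rendered = int((actin.planes[1] > cfg.background).sum())
        raster = cs.rasterized_disc_area(radius)
        assert rendered == pytest.approx(raster, rel=0.02)
        assert raster == pytest.approx(np.pi * radius ** 2, rel=0.05)


class TestEffects:
    def _populated(self, role, effect, cfg, tox_level=0.0, index=5):
        well = cs.WellTruth(well_id="A01", role=role,
                            treatment="x" if role == "test" else "solvent",
                            concentration=1.0 if role == "test" else 0.0,
                            stimulated=role != "unstimulated",
                            true_effect=effect, tox_level=tox_level,
                            toxic=tox_level >= 0.5, well_index=index)
        return cs.populate_cysts(well, cfg)

    def test_full_inhibition_equals_unstimulated_stream(self):
        cfg = small_config(basal_inhibition=0.0)
        treated = self._populated("test", 1.0, cfg)
        unstim = self._populated("unstimulated", 0.0, cfg)
        assert [c.radius for c in treated.cysts] == \
               [c.radius for c in unstim.cysts]

    def test_no_swelling_null_effect(self):
        cfg = small_config(swelling_factor=1.0, basal_inhibition=0.0)
        stim = self._populated("stimulated", 0.0, cfg)
        unstim = self._populated("unstimulated", 0.0, cfg)
        assert [c.radius for c in stim.cysts] == [c.radius for c in unstim.cysts]

    def test_stimulation_swells_radii(self):
        cfg = small_config()
        stim = self._populated("stimulated", 0.0, cfg)
        unstim = self._populated("unstimulated", 0.0, cfg)
        assert np.mean([c.radius for c in stim.cysts]) == pytest.approx(
            cfg.swelling_factor * np.mean([c.radius for c in unstim.cysts]),
            rel=1e-9)

    def test_toxicity_reduces_nuclei_and_integrity(self):
        cfg = small_config()
        toxic = self._populated("test", 1.0, cfg, tox_level=1.0)
        clean = self._populated("test", 1.0, cfg, tox_level=0.0)
        assert sum(c.n_nuclei for c in toxic.cysts) < \
            sum(c.n_nuclei for c in clean.cysts)
        assert all(c.integrity == cfg.toxic_integrity for c in toxic.cysts)


class TestScreenFiles:
    def test_truth_rows_match_files_and_rerun_is_bit_identical(self, tmp_path):
        cfg = mini_screen_config(11, cysts_per_well=(4, 6),
                                 image_size=(128, 128))
        comps = mini_compounds()
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        wells, wdf, cdf = cs.simulate_screen(cfg, comps, outdir=out1)
        cs.simulate_screen(cfg, comps, outdir=out2)
        assert len(wdf) == len(wells)
        assert len(cdf) == sum(len(w.cysts) for w in wells)
        for w in wells:
            for ch in ("actin", "nuclei"):
                assert (out1 / "images" / f"P1_{w.well_id}_{ch}.tif").exists()
        for rel in ["platemap.csv", "truth_wells.csv", "truth_cysts.csv",
                    f"images/P1_{wells[0].well_id}_actin.tif"]:
            assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes()


def test_hill_limits():
    assert cs.hill(0.0, 0.01, 2.0, 1.0) == 0.0
    assert cs.hill(0.01, 0.01, 2.0, 1.0) == pytest.approx(0.5)
    assert cs.hill(10.0, 0.01, 2.0, 0.8) == pytest.approx(0.8, abs=1e-4)


def test_cyst_spec_invariants():
    with pytest.raises(ValueError):
        cs.CystSpec(center_zyx=(0, 0, 0), radius=2, wall_thickness=3,
                    wall_intensity=1, lumen_intensity=1, n_nuclei=0)
    with pytest.raises(ValueError):
        cs.CystSpec(center_zyx=(0, 0, 0), radius=5, wall_thickness=3,
                    wall_intensity=1, lumen_intensity=1, n_nuclei=0,
                    integrity=1.5)
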