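import numpy as np
import pytest
from hypothesis import settings

import cystscreen as cs

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


mini_screen_config = cs.desk_screen_config
mini_compounds = cs.desk_compounds


def render_single_cyst(radius=20.0, wall=3.0, integrity=1.0, noise_sd=0.0,
                       n_planes=3, image=(128, 128), n_nuclei=0, seed=0):
    """One cyst centred on the middle plane; returns (well, actin, nuclei, cfg)."""
    cfg = cs.ScreenConfig(plate_shape=(1, 1), n_planes=n_planes,
                          image_size=image, noise_sd=noise_sd,
                          n_unstim_controls=1, n_stim_controls=1, seed=seed)
    spec = cs.CystSpec(center_zyx=(n_planes // 2, image[0] / 2, image[1] / 2),
                       radius=radius, wall_thickness=wall,
                       wall_intensity=cfg.wall_intensity,
                       lumen_intensity=cfg.lumen_intensity,
                       n_nuclei=n_nuclei, integrity=integrity)
    well = cs.WellTruth(well_id="A01", role="unstimulated", treatment="solvent",
                        concentration=0.0, stimulated=False, true_effect=0.0,
                        cysts=[spec])
    actin, nuclei = cs.render_well(well, cfg, add_noise=noise_sd > 0)
    return well, actin, nuclei, cfg


@pytest.fixture(scope="session")
def mini_analysis():
    """One fully analysed mini-screen, shared across tests."""
    return cs.analyze_screen(mini_screen_config(7), mini_compounds())
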