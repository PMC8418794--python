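import numpy as np
import pandas as pd
import pytest

import multidsm as m


@pytest.fixture(scope="session")
def fulmar_survey():
    """Two simultaneous platforms (binned line transect + strip), seed 7."""
    design = m.simulator._profile_design("fulmar_like", 7)
    seg, obs, truth = m.simulate_survey(design)
    return design, seg, obs, truth


@pytest.fixture(scope="session")
def fulmar_fits(fulmar_survey):
    design, seg, obs, _ = fulmar_survey
    fits = {}
    for sp in design.platforms:
        pl = sp.platform
        sub = obs[obs["platform_id"] == pl.platform_id].reset_index(drop=True)
        fits[pl.platform_id] = m.fit_detection(sub, pl, seg)
    return fits


@pytest.fixture(scope="session")
def fulmar_fit_A(fulmar_survey, fulmar_fits):
    _, seg, _, _ = fulmar_survey
    spec = m.DsmSpec(variant="A_common",
                     terms=[m.SmoothSpec(("x", "y"), k=20)], family="poisson")
    return m.fit_dsm(spec, seg, fulmar_fits)


@pytest.fixture(scope="session")
def minimal_fit():
    """One-platform line transect survey with a propagated intercept-only DSM."""
    design = m.simulator._profile_design("minimal", 5)
    seg, obs, truth = m.simulate_survey(design)
    pl = design.platforms[0].platform
    det = m.fit_detection(obs, pl, seg)
    fit = m.fit_dsm(m.DsmSpec(variant="A_common", terms=[], family="poisson"),
                    seg, {pl.platform_id: det})
    V, order = m.assemble_v_theta({pl.platform_id: det})
    m.propagate_variance(fit, V, order)
    grid = m.prediction_grid(design)
    return design, seg, obs, truth, det, fit, grid


def make_line_obs(distances, segment_id="s1"):
    return pd.DataFrame({"object_id": np.arange(len(distances)),
                         "segment_id": segment_id,
                         "distance": np.asarray(distances, dtype=float),
                         "size": 1})


def single_segment(platform_id="p", area=6.0):
    return pd.DataFrame({"segment_id": ["s1"], "platform_id": [platform_id],
                         "effort": [1.0], "area": [area], "count": [0]})
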