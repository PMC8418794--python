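import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import multidsm as m
from multidsm.detection import average_p_quad
from multidsm.survey_io import ValidationError

from conftest import make_line_obs, single_segment


# ---------------------------------------------------------------------------
# key functions and average detection probability
# ---------------------------------------------------------------------------

def test_key_function_closed_forms():
    assert m.g("half_normal", 0.0, 1.0) == 1.0
    assert np.isclose(m.g("half_normal", 1.0, 1.0), np.exp(-0.5))
    for b in (1.5, 2.0, 5.0):  # (x/sigma)^(-b) = 1 at x = sigma, any shape
        assert np.isclose(m.g("hazard_rate", 2.0, 2.0, b), 1 - np.exp(-1))
    with pytest.raises(ValidationError):
        m.g("half_normal", 1.0, -1.0)
    with pytest.raises(ValidationError):
        m.g("hazard_rate", 1.0, 1.0, 0.9)


def test_average_p_closed_forms():
    # line: (1/w) int_0^w exp(-x^2/2) dx = sqrt(pi/2) erf(1/sqrt(2))
    assert np.isclose(m.average_p_line("half_normal", 1.0, 1.0), 0.855624,
                      atol=1e-6)
    # point: 2 (1 - e^-0.5)
    assert np.isclose(m.average_p_point("half_normal", 1.0, 1.0), 0.786939,
                      atol=1e-6)


def test_average_p_limits():
    assert np.isclose(m.average_p_line("half_normal", 1.0, 1e-8), 1.0)
    assert np.isclose(m.average_p_point("half_normal", 1.0, 1e-8), 1.0)
    assert np.isclose(m.average_p_point("half_normal", 1e8, 1.0), 1.0)
    assert m.average_p_line("strip", 1.0, 1.0) == 1.0


@pytest.mark.parametrize("key,shape", [("half_normal", None),
                                       ("hazard_rate", 2.5),
                                       ("hazard_rate", 1.3)])
@pytest.mark.parametrize("point", [False, True])
def test_quadrature_agrees_with_fast_path(key, shape, point):
    """Closed forms / fixed-rule quadrature vs adaptive quadrature to 1e-8."""
    for sigma, w in [(0.5, 1.0), (1.0, 1.0), (2.0, 3.0)]:
        fast = (m.average_p_point if point else m.average_p_line)(
            key, sigma, w, shape)
        ref = average_p_quad(key, sigma, w, shape, point=point)
        assert abs(fast - ref) < 1e-8


@settings(deadline=None, derandomize=True, max_examples=30)
@given(sigma=st.floats(0.2, 5.0), w1=st.floats(0.1, 4.0),
       w2=st.floats(0.1, 4.0))
def test_average_p_monotone_in_truncation(sigma, w1, w2):
    """Widening the strip never increases average detectability."""
    lo, hi = sorted((w1, w2))
    for key, shape in (("half_normal", None), ("hazard_rate", 2.0)):
        assert m.average_p_line(key, sigma, hi, shape) \
            <= m.average_p_line(key, sigma, lo, shape) + 1e-12


# ---------------------------------------------------------------------------
# maximum likelihood fitting
# ---------------------------------------------------------------------------

def _hn_sample(rng, sigma, w, n):
    d = np.abs(rng.normal(0, sigma, int(n * 4 / 0.6)))
    return d[d <= w][:n]


def test_fit_halfnormal_exact_recovery():
    """Mean of sigma_hat over seeded replicates is unbiased within 3 MC SE."""
    pl = m.Platform("p", "line_cds", truncation_w=3.0)
    sighats = []
    for s in range(20):
        rng = np.random.default_rng(1 + s)
        d = _hn_sample(rng, 1.0, 3.0, 500)
        fit = m.fit_detection(make_line_obs(d), pl, single_segment())
        sighats.append(np.exp(fit.theta_hat[0]))
        assert fit.n_params == 1
        assert 0 < fit.p_by_segment["s1"] <= 1
    sighats = np.array(sighats)
    mcse = sighats.std(ddof=1) / np.sqrt(len(sighats))
    assert abs(sighats.mean() - 1.0) < 3 * mcse


def test_fit_matches_grid_search_oracle():
    """ML estimate agrees with a brute-force likelihood grid search."""
    rng = np.random.default_rng(3)
    d = _hn_sample(rng, 1.0, 3.0, 200)
    pl = m.Platform("p", "line_cds", truncation_w=3.0)
    fit = m.fit_detection(make_line_obs(d), pl, single_segment())

    from scipy.special import erf
    def nll(sigma):
        denom = sigma * np.sqrt(np.pi / 2) * erf(3.0 / (sigma * np.sqrt(2)))
        return -np.sum(-d ** 2 / (2 * sigma ** 2) - np.log(denom))
    grid = np.linspace(0.5, 2.0, 4001)
    sigma_grid = grid[np.argmin([nll(s) for s in grid])]
    assert abs(np.exp(fit.theta_hat[0]) - sigma_grid) < 1e-3


def test_binned_fit_and_bin_probabilities():
    """Multinomial bin shares match the quadrature oracle at the truth."""
    # expected share of bin [0,1) among detections within [0,2), sigma = 1
    from scipy.integrate import quad
    i1 = quad(lambda x: np.exp(-x ** 2 / 2), 0, 1)[0]
    i2 = quad(lambda x: np.exp(-x ** 2 / 2), 0, 2)[0]
    assert np.isclose(i1 / i2, 0.71524, atol=1e-5)

    rng = np.random.default_rng(4)
    d = _hn_sample(rng, 1.0, 2.0, 800)
    pl = m.Platform("p", "line_cds", truncation_w=2.0,
                    bin_cutpoints=np.array([0.0, 1.0, 2.0]))
    obs = make_line_obs(d)
    fit = m.fit_detection(obs, pl, single_segment())
    sigma_hat = np.exp(fit.theta_hat[0])
    share = np.mean(d < 1.0)
    assert abs(share - i1 / i2) < 0.05         # sampled share near oracle
    assert abs(sigma_hat - 1.0) < 0.15         # binned ML recovers the scale


def test_fulmar_style_binned_design_accepted(fulmar_survey, fulmar_fits):
    design, seg, obs, _ = fulmar_survey
    fit = fulmar_fits["water"]
    assert fit.key == "half_normal" and fit.n_obs > 50
    sigma_hat = np.exp(fit.theta_hat[0])
    assert abs(sigma_hat - 0.15) < 0.05        # true scale of the profile


def test_strip_fit_is_certain_detection(fulmar_fits):
    fit = fulmar_fits["flying"]
    assert fit.key == "strip"
    assert all(p == 1.0 for p in fit.p_by_segment.values())
    assert fit.theta_hat.size == 0 and fit.V_theta.size == 0


def test_scale_invariance_of_likelihood():
    """Rescaling distances and w by c rescales sigma_hat by c, p unchanged."""
    rng = np.random.default_rng(9)
    d = _hn_sample(rng, 1.0, 3.0, 300)
    c = 1000.0  # e.g. km -> m
    f1 = m.fit_detection(make_line_obs(d),
                         m.Platform("p", "line_cds", truncation_w=3.0),
                         single_segment())
    f2 = m.fit_detection(make_line_obs(d * c),
                         m.Platform("p", "line_cds", truncation_w=3.0 * c),
                         single_segment())
    assert np.isclose(np.exp(f2.theta_hat[0]), c * np.exp(f1.theta_hat[0]),
                      rtol=1e-4)
    assert np.isclose(f2.p_by_segment["s1"], f1.p_by_segment["s1"], rtol=1e-5)


def test_covariate_on_scale_recovery():
    rng = np.random.default_rng(11)
    nseg = 40
    seg = pd.DataFrame({"segment_id": [f"s{i}" for i in range(nseg)],
                        "platform_id": "p", "effort": 1.0, "area": 6.0,
                        "count": 0, "beaufort": rng.normal(0, 1, nseg)})
    rows = []
    w = 3.0
    for _, r in seg.iterrows():
        sigma = np.exp(0.0 + 0.3 * r["beaufort"])
        d = np.abs(rng.normal(0, sigma, 60))
        d = d[d <= w][:25]
        for j, x in enumerate(d):
            rows.append({"object_id": f"{r.segment_id}o{j}",
                         "segment_id": r.segment_id, "distance": x, "size": 1})
    obs = pd.DataFrame(rows)
    pl = m.Platform("p", "line_cds", truncation_w=w,
                    scale_covariates=("beaufort",))
    fit = m.fit_detection(obs, pl, seg)
    se = np.sqrt(np.diag(fit.V_theta))
    assert abs(fit.theta_hat[1] - 0.3) < 3 * se[1]
    assert len(fit.p_by_segment) == nseg


def test_observation_level_covariate_rejected():
    obs = make_line_obs([0.1, 0.2, 0.3])
    obs["beaufort"] = [1.0, 2.0, 3.0]      # varies within the segment
    seg = single_segment()
    seg["beaufort"] = 2.0
    pl = m.Platform("p", "line_cds", truncation_w=1.0,
                    scale_covariates=("beaufort",))
    with pytest.raises(ValidationError, match="segment level"):
        m.fit_detection(obs, pl, seg)


def test_point_transect_fit():
    rng = np.random.default_rng(13)
    w, sigma = 2.0, 1.0
    r = w * np.sqrt(rng.uniform(size=4000))          # triangular density
    keep = rng.uniform(size=r.size) < np.exp(-r ** 2 / (2 * sigma ** 2))
    d = r[keep][:400]
    pl = m.Platform("p", "point", truncation_w=w)
    fit = m.fit_detection(make_line_obs(d), pl, single_segment())
    sigma_hat = np.exp(fit.theta_hat[0])
    assert abs(sigma_hat - sigma) < 0.15
    assert fit.transect == "point"


def test_detection_aic_table():
    rng = np.random.default_rng(17)
    d = _hn_sample(rng, 1.0, 3.0, 300)
    nseg = 10
    seg = pd.DataFrame({"segment_id": [f"s{i}" for i in range(nseg)],
                        "platform_id": "p", "effort": 1.0, "area": 6.0,
                        "count": 0, "junk": rng.normal(0, 1, nseg)})
    obs = make_line_obs(d)
    obs["segment_id"] = np.repeat([f"s{i}" for i in range(nseg)], 30)
    pl0 = m.Platform("p", "line_cds", truncation_w=3.0)
    pl1 = m.Platform("p", "line_cds", truncation_w=3.0,
                     scale_covariates=("junk",))
    f0 = m.fit_detection(obs, pl0, seg)
    f1 = m.fit_detection(obs, pl1, seg)
    tab = m.detection_aic([f0, f1])
    assert np.isclose(tab["delta_aic"].iloc[0], 0.0)
    # pure-noise covariate should not win by more than chance
    assert tab.loc[tab.n_params == 2, "aic"].iloc[0] >= f0.aic - 2.0
    # single fit
    tab1 = m.detection_aic([f0])
    assert tab1["delta_aic"].tolist() == [0.0]
    # strip fits carry no likelihood
    strip = m.fit_detection(obs.iloc[0:0], m.Platform("q", "strip",
                                                      truncation_w=1.0))
    with pytest.warns(UserWarning, match="strip"):
        tab2 = m.detection_aic([f0, strip])
    assert "q" not in set(tab2["platform_id"])
    with pytest.raises(ValidationError):
        m.detection_aic([f0, m.fit_detection(obs.iloc[:100], pl0, seg)])


def test_detection_report_text():
    rng = np.random.default_rng(19)
    d = _hn_sample(rng, 1.0, 3.0, 100)
    pl = m.Platform("p", "line_cds", truncation_w=3.0)
    fit = m.fit_detection(make_line_obs(d), pl, single_segment())
    txt = m.detection_report(fit)
    assert "log_sigma" in txt and "AIC" in txt
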