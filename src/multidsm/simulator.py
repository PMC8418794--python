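"""Synthetic multi-platform surveys with known truth.

Generates line/strip/point/double-observer surveys over a rectangular region
so that every stage of the pipeline — detection fitting, the model variants,
variance propagation, interval coverage — is testable end to end without any
external data.  Animals arise from an inhomogeneous intensity surface,
segment counts are thinned by the true detection curve, availability and
trackline-detection probability, and per-detection distances follow the
within-strip distance density (uniform for lines, triangular for points),
optionally binned.

RNG contract: one root seed; independent child streams are spawned in a
documented order (one per platform, in list order, after one stream for
shared segment covariates), so ports can match distributions without
matching bit streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detection import g as detection_g
from .survey_io import Platform, ValidationError, assign_bins

_expit = lambda x: 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimPlatform:
    """True observation process for one simulated platform."""

    platform: Platform
    sigma: float | None = None        # detection scale at covariate 0
    shape: float | None = None        # hazard-rate exponent b (> 1)
    scale_coefs: dict = field(default_factory=dict)  # covariate -> coef on log sigma
    #: per-observer logistic detection (intercept, distance slope) — MRDS only
    observer_logits: tuple = ((1.5, -0.8), (1.5, -0.8))
    availability: float = 1.0
    density_multiplier: float = 1.0

    @property
    def true_g0(self) -> float:
        if self.platform.protocol != "mrds_io":
            return 1.0
        p1 = _expit(self.observer_logits[0][0])
        p2 = _expit(self.observer_logits[1][0])
        return p1 + p2 - p1 * p2


@dataclass
class SimDesign:
    """A simulated survey design over the rectangle [0, Lx] x [0, Ly].

    ``density`` names the intensity surface (animals per unit area):
    ``("constant", D)``, ``("loglinear", D0, bx, by)`` with
    ``D(x, y) = D0 exp(bx (x/Lx - 1/2) + by (y/Ly - 1/2))``, or
    ``("logsmooth", D0, amp)`` with
    ``D = D0 exp(amp sin(2 pi x / Lx) cos(pi y / Ly))``.
    ``family`` is the count noise: ``("poisson",)``, ``("negbin", theta)``
    or ``("tweedie", p, phi)``.  When ``simultaneous`` the platforms share
    one physical segment set (seabirds-at-sea style, segments duplicated);
    otherwise transects alternate between platforms.
    """

    region: tuple[float, float] = (10.0, 10.0)
    density: tuple = ("constant", 5.0)
    platforms: list[SimPlatform] = field(default_factory=list)
    n_transects: int = 6
    segments_per_transect: int = 5
    family: tuple = ("poisson",)
    simultaneous: bool = False
    seed: int = 0

    def density_at(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        kind = self.density[0]
        Lx, Ly = self.region
        if kind == "constant":
            return np.full(np.broadcast(x, y).shape, float(self.density[1]))
        if kind == "loglinear":
            D0, bx, by = self.density[1:]
            return D0 * np.exp(bx * (x / Lx - 0.5) + by * (y / Ly - 0.5))
        if kind == "logsmooth":
            D0, amp = self.density[1:]
            return D0 * np.exp(amp * np.sin(2 * np.pi * x / Lx)
                               * np.cos(np.pi * y / Ly))
        raise ValidationError(f"unknown density surface {kind!r}")


def _count_noise(rng, mu, family):
    kind = family[0]
    if kind == "poisson":
        return rng.poisson(mu)
    if kind == "negbin":
        theta = family[1]
        lam = rng.gamma(theta, mu / theta) if mu > 0 else 0.0
        return rng.poisson(lam)
    if kind == "tweedie":
        p, phi = family[1:]
        if mu <= 0:
            return 0.0
        lam = mu ** (2 - p) / (phi * (2 - p))
        n = rng.poisson(lam)
        if n == 0:
            return 0.0
        alpha = (2 - p) / (p - 1)
        gam_scale = phi * (p - 1) * mu ** (p - 1)
        return float(rng.gamma(n * alpha, gam_scale))
    raise ValidationError(f"unknown count family {kind!r}")


def _segment_frame(design: SimDesign) -> pd.DataFrame:
    """Physical segment layout: parallel vertical transects, equal segments."""
    Lx, Ly = design.region
    xs = (np.arange(design.n_transects) + 0.5) * Lx / design.n_transects
    seg_len = Ly / design.segments_per_transect
    ys = (np.arange(design.segments_per_transect) + 0.5) * seg_len
    rows = []
    for t, x in enumerate(xs):
        for s, y in enumerate(ys):
            rows.append({"segment_id": f"t{t}s{s}", "transect": t,
                         "x": float(x), "y": float(y), "effort": seg_len})
    return pd.DataFrame(rows)


def simulate_survey(design: SimDesign,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the survey; returns (segments, observations, truth record).

    Animal counts available in each covered strip are drawn from the design's
    count family around ``density * multiplier * area * availability``, then
    thinned by the true detection process.  The truth record stores the
    design's expected abundance over the region, per platform.
    """
    if not design.platforms:
        raise ValidationError("design has no platforms")
    root = np.random.SeedSequence(design.seed)
    streams = root.spawn(1 + len(design.platforms))
    cov_rng = np.random.default_rng(streams[0])
    phys = _segment_frame(design)
    # shared segment-level detection covariates (standard normal)
    covnames = sorted({c for sp in design.platforms for c in sp.scale_coefs})
    for c in covnames:
        phys[c] = cov_rng.normal(0.0, 1.0, size=len(phys))

    if design.simultaneous:
        assign = {sp.platform.platform_id: phys for sp in design.platforms}
    else:
        assign = {}
        for i, sp in enumerate(design.platforms):
            mask = phys["transect"] % len(design.platforms) == i
            assign[sp.platform.platform_id] = phys.loc[mask].reset_index(drop=True)

    seg_rows, obs_rows = [], []
    expected_detections = 0.0
    for i, sp in enumerate(design.platforms):
        rng = np.random.default_rng(streams[1 + i])
        pl = sp.platform
        w = pl.truncation_w
        base = assign[pl.platform_id]
        suffix = f":{pl.platform_id}" if design.simultaneous else ""
        for _, row in base.iterrows():
            sid = f"{row['segment_id']}{suffix}"
            area = pl.n_sides * w * row["effort"]
            mu = (design.density_at(row["x"], row["y"]) * sp.density_multiplier
                  * area * sp.availability)
            m = _count_noise(rng, mu, design.family)
            m_int = int(np.round(m)) if not float(m).is_integer() else int(m)
            count = 0.0
            log_sigma = (np.log(sp.sigma) if sp.sigma else 0.0) + sum(
                coef * row[c] for c, coef in sp.scale_coefs.items())
            sigma = float(np.exp(log_sigma))
            for a_i in range(m_int):
                if pl.protocol == "point":
                    dist = w * np.sqrt(rng.uniform())
                else:
                    dist = rng.uniform(0.0, w)
                det1 = det2 = None
                if pl.protocol == "strip":
                    detected = True
                elif pl.protocol == "mrds_io":
                    # two-part process: a distance-driven cue (the platform's
                    # key detection curve), then each observer independently
                    # detects a cued animal with its conditional (logistic)
                    # probability — so pooled distances follow the key curve
                    # and g(0) = p1 + p2 - p1 p2 at distance zero
                    cued = rng.uniform() < float(
                        detection_g(pl.key, dist, sp.sigma, sp.shape))
                    if not cued:
                        continue
                    (a1, g1), (a2, g2) = sp.observer_logits
                    det1 = rng.uniform() < _expit(a1 + g1 * dist)
                    det2 = rng.uniform() < _expit(a2 + g2 * dist)
                    detected = det1 or det2
                else:
                    pdet = float(detection_g(pl.key, dist, sigma, sp.shape))
                    detected = rng.uniform() < pdet
                if not detected:
                    continue
                count += 1
                obs = {"object_id": f"{sid}o{a_i}", "segment_id": sid,
                       "platform_id": pl.platform_id, "size": 1,
                       "distance": float(dist)}
                if pl.is_binned:
                    obs["bin"] = int(assign_bins(np.array([dist]),
                                                 pl.bin_cutpoints)[0])
                if pl.protocol == "mrds_io":
                    obs["detected_by_1"] = int(det1)
                    obs["detected_by_2"] = int(det2)
                obs_rows.append(obs)
            seg = {"segment_id": sid, "platform_id": pl.platform_id,
                   "effort": row["effort"], "area": area, "count": count,
                   "availability": sp.availability,
                   "x": row["x"], "y": row["y"]}
            for c in covnames:
                seg[c] = row[c]
            seg_rows.append(seg)
            expected_detections += mu
    segments = pd.DataFrame(seg_rows)
    observations = pd.DataFrame(obs_rows)
    if expected_detections < 5:
        import warnings
        warnings.warn("expected detections < 5: fits will be unstable")
    truth = {
        "seed": design.seed,
        "total_abundance": true_abundance(design),
        "per_platform_abundance": {
            sp.platform.platform_id: true_abundance(design, platform=sp)
            for sp in design.platforms},
        "true_g0": {sp.platform.platform_id: sp.true_g0
                    for sp in design.platforms},
    }
    return segments, observations, truth


def true_abundance(design: SimDesign, platform: SimPlatform | None = None,
                   nx: int = 80, ny: int = 80) -> float:
    """Expected number of animals in the region under the design's surface.

    With ``platform`` given, the platform's density multiplier is applied
    (distinct behavioural populations in simultaneous designs); otherwise
    the bare surface integral is returned.
    """
    Lx, Ly = design.region
    xs = (np.arange(nx) + 0.5) * Lx / nx
    ys = (np.arange(ny) + 0.5) * Ly / ny
    X, Y = np.meshgrid(xs, ys)
    dens = design.density_at(X, Y)
    mult = platform.density_multiplier if platform is not None else 1.0
    return float(dens.sum() * (Lx / nx) * (Ly / ny) * mult)


def prediction_grid(design: SimDesign, nx: int = 10, ny: int = 10) -> pd.DataFrame:
    Lx, Ly = design.region
    xs = (np.arange(nx) + 0.5) * Lx / nx
    ys = (np.arange(ny) + 0.5) * Ly / ny
    X, Y = np.meshgrid(xs, ys)
    return pd.DataFrame({"cell_id": np.arange(X.size),
                         "x": X.ravel(), "y": Y.ravel(),
                         "area": np.full(X.size, (Lx / nx) * (Ly / ny))})


# ---------------------------------------------------------------------------
# ready-made fixture profiles
# ---------------------------------------------------------------------------

def _profile_design(profile: str, seed: int) -> SimDesign:
    if profile == "minimal":
        return SimDesign(
            region=(8.0, 10.0), density=("constant", 6.0),
            platforms=[SimPlatform(
                Platform("boat", "line_cds", truncation_w=0.5, key="half_normal"),
                sigma=0.25)],
            n_transects=4, segments_per_transect=5, seed=seed)
    if profile == "fulmar_like":
        # seabirds-at-sea: one-sided 300 m strip; birds on the water in four
        # distance bins (0, 50, 100, 200, 300 m), flying birds by strip
        water = Platform("water", "line_mcds", truncation_w=0.3,
                         bin_cutpoints=np.array([0.0, 0.05, 0.1, 0.2, 0.3]),
                         sides="one", simultaneous_with="flying",
                         key="half_normal")
        flying = Platform("flying", "strip", truncation_w=0.3, sides="one",
                          simultaneous_with="water")
        return SimDesign(
            region=(30.0, 40.0), density=("logsmooth", 8.0, 0.8),
            platforms=[SimPlatform(water, sigma=0.15, density_multiplier=1.0),
                       SimPlatform(flying, density_multiplier=1.2)],
            n_transects=8, segments_per_transect=8,
            simultaneous=True, seed=seed)
    if profile == "finwhale_like":
        # shipboard double-observer MRDS (hazard-rate, distance-only g(0))
        # plus aerial survey with fixed external g0 = 0.67 and u = 0.37
        ship = Platform("ship", "mrds_io", truncation_w=6.0, key="hazard_rate")
        aerial = Platform("aerial", "line_mcds", truncation_w=0.9,
                          key="hazard_rate", fixed_g0=0.67, fixed_g0_cv=0.15,
                          availability_cv=0.10)
        return SimDesign(
            region=(60.0, 60.0), density=("loglinear", 0.3, 1.0, -0.5),
            platforms=[SimPlatform(ship, sigma=2.0, shape=2.5,
                                   observer_logits=((1.2, -0.3), (1.0, -0.25))),
                       SimPlatform(aerial, sigma=0.35, shape=2.5,
                                   availability=0.37)],
            n_transects=10, segments_per_transect=6, seed=seed)
    raise ValidationError(f"unknown fixture profile {profile!r}")


def make_fixtures(profile: str, outdir: str | Path, seed: int = 1,
                  ) -> dict[str, Path]:
    """Write a deterministic CSV/YAML fixture set for a named profile.

    Profiles: ``minimal`` (one line-transect platform, smoke scale),
    ``fulmar_like`` (water line transect with four distance bins + flying
    strip on duplicated segments), ``finwhale_like`` (ship MRDS hazard-rate
    with distance-only g(0) + aerial platform taking fixed multipliers
    g0 = 0.67 and availability u = 0.37).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = _profile_design(profile, seed)
    segments, observations, truth = simulate_survey(design)
    grid = prediction_grid(design)
    paths = {"segments": outdir / "segments.csv",
             "observations": outdir / "observations.csv",
             "grid": outdir / "grid.csv",
             "platforms": outdir / "platforms.yaml",
             "truth": outdir / "truth.json"}
    segments.to_csv(paths["segments"], index=False)
    observations.to_csv(paths["observations"], index=False)
    grid.to_csv(paths["grid"], index=False)
    reg = {}
    for sp in design.platforms:
        pl = sp.platform
        entry = {"protocol": pl.protocol, "truncation": float(pl.truncation_w),
                 "sides": pl.sides, "key": pl.key}
        if pl.bin_cutpoints is not None:
            entry["cutpoints"] = [float(c) for c in pl.bin_cutpoints]
        if pl.simultaneous_with:
            entry["simultaneous_with"] = pl.simultaneous_with
        if pl.fixed_g0 is not None:
            entry["g0"] = float(pl.fixed_g0)
            entry["g0_cv"] = float(pl.fixed_g0_cv)
        if pl.availability_cv:
            entry["availability_cv"] = float(pl.availability_cv)
        if sp.scale_coefs:
            entry["scale_covariates"] = sorted(sp.scale_coefs)
        reg[pl.platform_id] = entry
    with open(paths["platforms"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(reg, fh, sort_keys=True)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    return paths
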