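"""Single-platform detection functions.

Models the fall-off of detection probability with distance from the transect
line (or point) with the two standard key functions,

* half-normal: ``g(x) = exp(-x^2 / (2 sigma^2))``
* hazard-rate: ``g(x) = 1 - exp(-(x / sigma)^-b)``, shape ``b > 1``

optionally with segment-level covariates on the scale parameter via a log
link, ``sigma = exp(z' theta_sigma)`` (the multiple-covariate distance
sampling convention).  Maximum likelihood is used for exact distances (the
per-detection distance density) or binned distances (a multinomial over the
bin cutpoints, conditional on detection).  The fitted object carries the
parameter covariance and, for every segment of the platform, the average
detection probability

* lines:  ``p = (1/w) int_0^w g(x) dx``
* points: ``p = (2/w^2) int_0^w r g(r) dr``

together with the gradient of ``log p`` with respect to theta, which is what
the spatial model needs for its offset and for variance propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special

from .survey_io import Platform, ValidationError, assign_bins

QUAD_EPSABS = 1e-10
FD_STEP = 1e-5  # relative central-difference step for gradients/Hessians


class FitError(RuntimeError):
    """Detection-function optimisation failed to converge."""


# ---------------------------------------------------------------------------
# key functions and average detection probability
# ---------------------------------------------------------------------------

def g(key: str, x, sigma, shape: float | None = None):
    """Detection probability at distance ``x``; ``g(0) = 1`` by construction."""
    x = np.asarray(x, dtype=float)
    if key == "strip":
        return np.ones_like(x)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValidationError("sigma must be > 0")
    if key == "half_normal":
        return np.exp(-x ** 2 / (2.0 * sigma ** 2))
    if key == "hazard_rate":
        if shape is None or shape <= 1:
            raise ValidationError("hazard-rate shape b must be > 1")
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(x > 0, x / sigma, np.inf)  # placeholder at 0
            val = 1.0 - np.exp(-ratio ** (-shape))
        return np.where(x > 0, val, 1.0)
    raise ValidationError(f"unknown key {key!r}")


def average_p_line(key: str, sigma, w: float, shape: float | None = None):
    """Mean detection probability over a strip of half-width ``w`` (lines).

    Distances of available animals are uniform on ``[0, w]``, so
    ``p = (1/w) int_0^w g``.  Half-normal has the erf closed form; hazard-rate
    is integrated by adaptive Gauss–Kronrod quadrature.
    """
    if w <= 0:
        raise ValidationError("truncation w must be > 0")
    if key == "strip":
        return np.ones_like(np.asarray(sigma, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    out = _integrated_g_line(key, sigma, shape, w) / w
    return out if out.size > 1 else float(out[0])


def average_p_point(key: str, sigma, w: float, shape: float | None = None):
    """Mean detection probability within radius ``w`` of a point.

    Available animals are uniform in the disc, so distance has the triangular
    density ``2r/w^2`` and ``p = (2/w^2) int_0^w r g(r) dr``.
    """
    if w <= 0:
        raise ValidationError("truncation w must be > 0")
    if key == "strip":
        return np.ones_like(np.asarray(sigma, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    out = 2.0 * _integrated_rg_point(key, sigma, shape, w) / w ** 2
    return out if out.size > 1 else float(out[0])


def _quad_p(key, sigma, shape, w, point):
    if point:
        val, err = integrate.quad(lambda r: r * g(key, r, sigma, shape), 0, w,
                                  epsabs=QUAD_EPSABS, limit=200)
        val *= 2.0 / w ** 2
    else:
        val, err = integrate.quad(lambda x: g(key, x, sigma, shape), 0, w,
                                  epsabs=QUAD_EPSABS, limit=200)
        val /= w
    if not np.isfinite(val):
        raise FitError(f"quadrature failed (key={key}, sigma={sigma}, w={w})")
    return float(val)


def average_p_quad(key: str, sigma: float, w: float,
                   shape: float | None = None, point: bool = False) -> float:
    """Average detection probability by adaptive Gauss–Kronrod quadrature.

    Slow, tight-tolerance reference path used to cross-check the closed
    forms and the fixed-rule quadrature the fitting code relies on.
    """
    return _quad_p(key, sigma, shape, w, point)


_GL_NODES = np.polynomial.legendre.leggauss(100)


def _gl_integral(fn, upper):
    """Fixed 100-point Gauss–Legendre integral of fn over [0, upper];
    fn maps (npts,) distances to (..., npts) values."""
    gx, gw = _GL_NODES
    x = 0.5 * upper * (gx + 1.0)
    wts = 0.5 * upper * gw
    return fn(x) @ wts


def _integrated_g_line(key, sigma, shape, upper):
    """``int_0^upper g(x) dx`` for each sigma (vectorized)."""
    sigma = np.atleast_1d(sigma)
    if key == "half_normal":
        return sigma * np.sqrt(np.pi / 2.0) * special.erf(upper / (sigma * np.sqrt(2.0)))
    return _gl_integral(lambda x: g(key, x[None, :], sigma[:, None], shape), upper)


def _integrated_rg_point(key, sigma, shape, upper):
    """``int_0^upper r g(r) dr`` for each sigma (vectorized)."""
    sigma = np.atleast_1d(sigma)
    if key == "half_normal":
        return sigma ** 2 * (-np.expm1(-upper ** 2 / (2.0 * sigma ** 2)))
    return _gl_integral(
        lambda r: r[None, :] * g(key, r[None, :], sigma[:, None], shape), upper)


# ---------------------------------------------------------------------------
# maximum likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class DetectionFit:
    """A fitted detection model for one platform."""

    platform_id: str
    key: str                       # half_normal | hazard_rate | strip
    theta_hat: np.ndarray          # log-scale coefs (+ hazard shape param phi)
    V_theta: np.ndarray            # covariance of theta_hat
    loglik: float
    n_params: int
    n_obs: int
    p_by_segment: dict = field(default_factory=dict)
    dp_dtheta_by_segment: dict = field(default_factory=dict)
    scale_covariates: tuple = ()
    truncation_w: float = np.nan
    transect: str = "line"
    hessian_pd: bool = True
    #: optional g(0) multiplier (from an MRDS conditional model or fixed)
    g0: float = 1.0

    @property
    def aic(self) -> float:
        if self.key == "strip":
            raise ValidationError("strip protocol has no likelihood, hence no AIC")
        return -2.0 * self.loglik + 2.0 * self.n_params

    def average_p(self, z: np.ndarray | None = None):
        theta = self.theta_hat
        n_scale = 1 + len(self.scale_covariates)
        sigma = np.exp(_scale_eta(theta[:n_scale], z, len(self.scale_covariates)))
        shape = _shape_from_theta(self.key, theta)
        fn = average_p_point if self.transect == "point" else average_p_line
        return fn(self.key, sigma, self.truncation_w, shape)


def _scale_eta(theta_sigma, z, n_cov):
    if n_cov == 0:
        return np.asarray(theta_sigma[0])
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return theta_sigma[0] + z @ np.asarray(theta_sigma[1:])


def _shape_from_theta(key, theta):
    # hazard-rate shape b = 1 + exp(phi) keeps b > 1; phi clipped for safety
    return 1.0 + np.exp(np.clip(theta[-1], -20.0, 20.0)) if key == "hazard_rate" else None


def _neg_loglik(theta, key, transect, dists, bins, Z, w, cutpoints):
    n_cov = 0 if Z is None else Z.shape[1]
    sigma = np.exp(np.atleast_1d(_scale_eta(theta[:n_cov + 1], Z, n_cov)))
    if sigma.size == 1:
        sigma = np.full(len(dists) if dists is not None else len(bins), sigma[0])
    shape = _shape_from_theta(key, theta)
    if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
        return 1e10
    try:
        if bins is not None:
            # multinomial over bins, conditional on detection within w
            usig, inv = np.unique(sigma, return_inverse=True)
            cum = np.stack([_integrated_g_line(key, usig, shape, c)
                            for c in cutpoints], axis=1)  # (nsig, nbins+1)
            probs = np.diff(cum, axis=1) / cum[:, -1:][..., 0][:, None]
            pi = probs[inv, bins]
            if np.any(pi <= 0):
                return 1e10
            return -float(np.sum(np.log(pi)))
        gx = g(key, dists, sigma, shape)
        usig, inv = np.unique(sigma, return_inverse=True)
        if transect == "point":
            den = _integrated_rg_point(key, usig, shape, w)[inv]
            ll = np.log(np.maximum(dists, 1e-300)) + np.log(gx) - np.log(den)
        else:
            den = _integrated_g_line(key, usig, shape, w)[inv]
            ll = np.log(gx) - np.log(den)
        if not np.all(np.isfinite(ll)):
            return 1e10
        return -float(np.sum(ll))
    except (FitError, ValidationError, FloatingPointError):
        return 1e10


def _fd_hessian(fun, x, step=FD_STEP):
    x = np.asarray(x, dtype=float)
    p = len(x)
    h = step * (1.0 + np.abs(x))
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def fit_detection(observations: pd.DataFrame, platform: Platform,
                  segments: pd.DataFrame | None = None,
                  scale_covariates: tuple[str, ...] | None = None,
                  ) -> DetectionFit:
    """Fit the platform's detection function by maximum likelihood.

    ``scale_covariates`` (default: the platform registry entry) name
    segment-level columns of ``segments`` entering log sigma linearly.  The
    count-model formulation requires detection covariates constant within a
    segment, so covariate values are looked up from the segment table via each
    observation's ``segment_id``; observation-level covariates are not
    accepted (bin the covariate and duplicate segments instead).

    Returns a :class:`DetectionFit` with the ML estimate, its covariance
    (inverse observed information; pseudo-inverse with a warning when the
    Hessian is not positive definite), AIC ingredients, and per-segment
    average detection probabilities with gradients of ``log p``.
    """
    if scale_covariates is None:
        scale_covariates = platform.scale_covariates
    scale_covariates = tuple(scale_covariates)
    transect = "point" if platform.protocol == "point" else "line"

    if platform.protocol == "strip":
        fit = DetectionFit(platform.platform_id, "strip", np.empty(0),
                           np.empty((0, 0)), np.nan, 0, len(observations),
                           truncation_w=platform.truncation_w, transect=transect)
        if segments is not None:
            for sid in _platform_segment_ids(segments, platform):
                fit.p_by_segment[sid] = 1.0
                fit.dp_dtheta_by_segment[sid] = np.empty(0)
        return fit

    obs = observations
    if len(obs) < 1:
        raise FitError(f"platform {platform.platform_id!r}: no observations to fit")
    key = platform.key
    w = platform.truncation_w

    Z = None
    if scale_covariates:
        if segments is None:
            raise ValidationError("segments table required for scale covariates")
        lut = segments.set_index("segment_id")[list(scale_covariates)]
        try:
            Z = lut.loc[obs["segment_id"]].to_numpy(dtype=float)
        except KeyError as e:
            raise ValidationError(f"observation references unknown segment {e}")
        if np.isnan(Z).any():
            raise ValidationError("missing detection covariate values")
        for c in scale_covariates:
            if c in obs.columns and segments is not None:
                seg_vals = lut[c].reindex(obs["segment_id"]).to_numpy(dtype=float)
                if not np.allclose(seg_vals, obs[c].to_numpy(dtype=float),
                                   equal_nan=True):
                    raise ValidationError(
                        f"detection covariate {c!r} varies within segments; "
                        "covariates may only vary at the segment level — bin "
                        "the covariate and duplicate segments instead")

    dists = bins = cutpoints = None
    if platform.is_binned:
        cutpoints = platform.bin_cutpoints
        if "bin" in obs.columns and obs["bin"].notna().all():
            bins = obs["bin"].to_numpy(dtype=int)
        else:
            bins = assign_bins(obs["distance"].to_numpy(dtype=float), cutpoints)
        if bins.min() < 0 or bins.max() > len(cutpoints) - 2:
            raise ValidationError("bin index outside cutpoint range")
    else:
        dists = obs["distance"].to_numpy(dtype=float)
        if (dists < 0).any():
            raise ValidationError("negative distances")
        if (dists > w).any():
            raise ValidationError("distances beyond truncation; truncate() first")

    n_theta = 1 + len(scale_covariates) + (1 if key == "hazard_rate" else 0)
    ref = dists if dists is not None else cutpoints[1:][bins]
    x0 = np.zeros(n_theta)
    x0[0] = np.log(max(np.std(ref), 0.5 * np.mean(ref), 1e-3))
    nll = lambda th: _neg_loglik(th, key, transect, dists, bins, Z, w, cutpoints)
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 4000})
    res = optimize.minimize(nll, res.x, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    if not np.all(np.isfinite(res.x)) or nll(res.x) >= 1e10:
        raise FitError(f"platform {platform.platform_id!r}: detection fit "
                       f"diverged ({res.message})")
    theta = res.x
    H = _fd_hessian(nll, theta)
    hessian_pd = True
    try:
        np.linalg.cholesky(H)
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        hessian_pd = False
        warnings.warn(f"platform {platform.platform_id!r}: detection Hessian "
                      "not positive definite; using pseudo-inverse")
        V = np.linalg.pinv(H)
    V = 0.5 * (V + V.T)

    fit = DetectionFit(platform.platform_id, key, theta, V, -res.fun, n_theta,
                       len(obs), scale_covariates=scale_covariates,
                       truncation_w=w, transect=transect, hessian_pd=hessian_pd)
    if segments is not None:
        _populate_segment_p(fit, segments, platform)
    return fit


def _platform_segment_ids(segments, platform):
    mask = segments["platform_id"].astype(str) == platform.platform_id
    return list(segments.loc[mask, "segment_id"])


def _populate_segment_p(fit: DetectionFit, segments: pd.DataFrame,
                        platform: Platform) -> None:
    """Fill per-segment p and d log p / d theta (central finite differences)."""
    mask = segments["platform_id"].astype(str) == platform.platform_id
    sub = segments.loc[mask]
    Z = (sub[list(fit.scale_covariates)].to_numpy(dtype=float)
         if fit.scale_covariates else None)

    def logp(theta):
        n_cov = len(fit.scale_covariates)
        sigma = np.exp(np.atleast_1d(_scale_eta(theta[:n_cov + 1], Z, n_cov)))
        if sigma.size == 1 and len(sub) > 1:
            sigma = np.full(len(sub), sigma[0])
        shape = _shape_from_theta(fit.key, theta)
        fn = average_p_point if fit.transect == "point" else average_p_line
        return np.log(np.atleast_1d(fn(fit.key, sigma, fit.truncation_w, shape)))

    theta = fit.theta_hat
    base = logp(theta)
    grads = np.zeros((len(sub), len(theta)))
    for i in range(len(theta)):
        h = FD_STEP * (1.0 + abs(theta[i]))
        e = np.zeros_like(theta); e[i] = h
        grads[:, i] = (logp(theta + e) - logp(theta - e)) / (2 * h)
    p = np.exp(base)
    if np.any(p <= 0) or np.any(p > 1 + 1e-9):
        raise FitError("average detection probability outside (0, 1]")
    for sid, pj, gj in zip(sub["segment_id"], p, grads):
        fit.p_by_segment[sid] = float(min(pj, 1.0))
        fit.dp_dtheta_by_segment[sid] = gj


def detection_aic(fits: list[DetectionFit]) -> pd.DataFrame:
    """Compare detection fits on the same data by AIC (delta to the best).

    Strip fits carry no likelihood and are excluded with a note; fits on
    different datasets (different n) are an error.
    """
    rows, excluded = [], []
    for f in fits:
        if f.key == "strip":
            excluded.append(f.platform_id)
            continue
        rows.append({"platform_id": f.platform_id, "key": f.key,
                     "n_params": f.n_params, "n_obs": f.n_obs,
                     "loglik": f.loglik, "aic": f.aic})
    if excluded:
        warnings.warn(f"excluded strip fit(s) with no likelihood: {excluded}")
    if not rows:
        return pd.DataFrame(columns=["platform_id", "key", "n_params", "n_obs",
                                     "loglik", "aic", "delta_aic"])
    tab = pd.DataFrame(rows)
    if tab["n_obs"].nunique() > 1:
        raise ValidationError("AIC comparison requires fits on identical data")
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    return tab.sort_values("delta_aic").reset_index(drop=True)


def detection_report(fit: DetectionFit) -> str:
    """Plain-text summary of a fitted detection function."""
    lines = [f"Detection function — platform {fit.platform_id}",
             f"  key: {fit.key}   transect: {fit.transect}   "
             f"truncation: {fit.truncation_w}"]
    if fit.key == "strip":
        lines.append("  detection certain within the strip (p = 1)")
        return "\n".join(lines)
    se = np.sqrt(np.maximum(np.diag(fit.V_theta), 0.0))
    names = ["log_sigma(intercept)"] + [f"log_sigma({c})" for c in fit.scale_covariates]
    if fit.key == "hazard_rate":
        names.append("log(shape-1)")
    for nm, est, s in zip(names, fit.theta_hat, se):
        lines.append(f"  {nm:24s} {est: .5f}  (se {s:.5f})")
    lines.append(f"  loglik: {fit.loglik:.4f}   AIC: {fit.aic:.4f}   n: {fit.n_obs}")
    if fit.p_by_segment:
        pv = np.array(list(fit.p_by_segment.values()))
        lines.append(f"  average p over segments: mean {pv.mean():.4f} "
                     f"range [{pv.min():.4f}, {pv.max():.4f}]")
    if not fit.hessian_pd:
        lines.append("  WARNING: Hessian not positive definite (pseudo-inverse used)")
    return "\n".join(lines)
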