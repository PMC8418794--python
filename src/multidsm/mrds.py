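"""Independent-observer mark–recapture distance sampling (MRDS).

Conventional distance sampling assumes certain detection on the trackline,
``g(0) = 1``.  When two observers search independently, each observer's
detections form capture–recapture trials for the other: an object seen by
observer 2 either is or is not also seen by observer 1 (a duplicate).  A
logistic model for the conditional detection probabilities
``p_{1|2}(x, z)`` and ``p_{2|1}(x, z)`` — with distance and optional
segment-level covariates — then yields the trackline detection probability
under full independence,

    g(0) = p_1(0) + p_2(0) - p_1(0) p_2(0),

which multiplies the distance-sampling average detection probability in the
spatial model's offset.  Uncertainty in the conditional model is carried as a
covariance block alongside the distance model's, so it propagates into the
final abundance variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .detection import FD_STEP, DetectionFit
from .survey_io import ValidationError


class MrdsError(RuntimeError):
    pass


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class ConditionalFit:
    """Logistic conditional-detection models for an observer pair.

    ``params[j]`` are the coefficients of observer ``j+1``'s conditional
    detection probability (intercept, distance, extra covariates);
    ``cov[j]`` the corresponding covariance.  ``theta`` / ``V_theta`` stack
    the two observers' blocks (block-diagonal: trials are disjoint objects
    handled as independent).
    """

    covariates: tuple[str, ...]
    params: list[np.ndarray]
    cov: list[np.ndarray]
    loglik: float
    n_trials: int
    n_duplicates: int
    separation_warning: bool = False

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate(self.params)

    @property
    def V_theta(self) -> np.ndarray:
        k0, k1 = len(self.params[0]), len(self.params[1])
        V = np.zeros((k0 + k1, k0 + k1))
        V[:k0, :k0] = self.cov[0]
        V[k0:, k0:] = self.cov[1]
        return V

    def conditional_p(self, observer: int, distance, z=None) -> np.ndarray:
        """p(observer detects | the other observer detected) at the given
        distance(s) and covariates (extra covariates default to 0)."""
        beta = self.params[observer - 1]
        d = np.atleast_1d(np.asarray(distance, dtype=float))
        X = np.column_stack([np.ones_like(d), d])
        if len(self.covariates) > 1:
            extra = (np.zeros((len(d), len(self.covariates) - 1)) if z is None
                     else np.atleast_2d(np.asarray(z, dtype=float)))
            X = np.column_stack([X, extra])
        return _expit(X @ beta)


def build_trials(observations: pd.DataFrame) -> pd.DataFrame:
    """Construct capture–recapture trials from duplicate-flagged observations.

    Every object seen by observer 2 is a Bernoulli trial for observer 1
    (success when observer 1 also saw it) and vice versa.  Duplicates
    therefore contribute one trial to each observer.
    """
    for c in ("detected_by_1", "detected_by_2"):
        if c not in observations.columns:
            raise ValidationError(f"observations missing {c!r} column")
    d1 = observations["detected_by_1"].astype(int).to_numpy()
    d2 = observations["detected_by_2"].astype(int).to_numpy()
    if np.any(d1 + d2 < 1):
        raise ValidationError("MRDS rows must be detected by at least one observer")
    rows = []
    for obs_j, trial_mask, resp in ((1, d2 == 1, d1), (2, d1 == 1, d2)):
        sub = observations.loc[trial_mask].copy()
        sub["observer"] = obs_j
        sub["detected"] = resp[trial_mask]
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def fit_conditional(observations: pd.DataFrame,
                    covariates: tuple[str, ...] = ("distance",),
                    ) -> ConditionalFit:
    """Fit per-observer logistic conditional-detection models.

    ``covariates`` name the linear predictors after the intercept; the first
    is conventionally ``distance`` (a distance-only model is the common
    specification).  Raises when there are no duplicates — g(0) is then
    inestimable.  Complete or quasi-complete separation triggers a warning
    and a weakly penalised (ridge 1e-4) refit.
    """
    trials = build_trials(observations)
    n_dup = int(((observations["detected_by_1"] == 1)
                 & (observations["detected_by_2"] == 1)).sum())
    if n_dup == 0:
        raise MrdsError("no duplicate detections: g(0) is inestimable")
    params, covs, ll = [], [], 0.0
    separation = False
    for j in (1, 2):
        sub = trials[trials["observer"] == j]
        y = sub["detected"].to_numpy(dtype=float)
        X = sm.add_constant(sub[list(covariates)].to_numpy(dtype=float),
                            has_constant="add")
        if y.min() == y.max():
            # all trials successes (or failures): push the intercept via ridge
            separation = True
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = model.fit(maxiter=200, tol=1e-10)
            beta = np.asarray(res.params)
            if np.max(np.abs(beta)) > 15:
                raise RuntimeWarning("separation")
            V = np.asarray(res.cov_params())
            ll += float(res.llf)
        except (RuntimeWarning, np.linalg.LinAlgError, ValueError):
            separation = True
            res = model.fit_regularized(alpha=1e-4, L1_wt=0.0, maxiter=500)
            beta = np.asarray(res.params)
            mu = _expit(X @ beta)
            W = mu * (1 - mu)
            H = X.T @ (X * W[:, None]) + 2e-4 * np.eye(X.shape[1])
            V = np.linalg.inv(H)
            ll += float(np.sum(y * np.log(np.clip(mu, 1e-12, 1))
                               + (1 - y) * np.log(np.clip(1 - mu, 1e-12, 1))))
        params.append(beta)
        covs.append(0.5 * (V + V.T))
    if separation:
        warnings.warn("conditional detection model showed (quasi-)separation; "
                      "a weak ridge penalty was applied")
    return ConditionalFit(tuple(covariates), params, covs, ll,
                          len(trials), n_dup, separation)


def combined_g0(fit: ConditionalFit, z=None) -> tuple[float, np.ndarray]:
    """Trackline detection probability under full independence.

    ``g(0) = p1(0) + p2(0) - p1(0) p2(0)`` evaluated at distance 0 (extra
    covariates at 0 unless supplied).  Returns ``(g0_hat, grad)`` where
    ``grad`` is d log g0 / d theta over the stacked conditional coefficients,
    by central finite differences, for variance propagation.
    """
    theta0 = fit.theta
    k0 = len(fit.params[0])

    def g0_of(theta):
        f = ConditionalFit(fit.covariates, [theta[:k0], theta[k0:]],
                           fit.cov, fit.loglik, fit.n_trials, fit.n_duplicates)
        p1 = float(f.conditional_p(1, 0.0, z)[0])
        p2 = float(f.conditional_p(2, 0.0, z)[0])
        return p1 + p2 - p1 * p2

    g0 = g0_of(theta0)
    if not 0 < g0 <= 1:
        raise MrdsError(f"g(0) estimate {g0} outside (0, 1]")
    grad = np.zeros_like(theta0)
    for i in range(len(theta0)):
        h = FD_STEP * (1.0 + abs(theta0[i]))
        e = np.zeros_like(theta0); e[i] = h
        grad[i] = (np.log(g0_of(theta0 + e)) - np.log(g0_of(theta0 - e))) / (2 * h)
    return g0, grad


@dataclass
class MrdsFit:
    """Distance model x conditional g(0) model for one MRDS platform."""

    distance_fit: DetectionFit
    conditional_fit: ConditionalFit
    g0_hat: float = field(init=False)
    g0_grad: np.ndarray = field(init=False)

    def __post_init__(self):
        self.g0_hat, self.g0_grad = combined_g0(self.conditional_fit)

    def combined_detection_fit(self) -> DetectionFit:
        """Detectability multiplier ``g(0) * p(theta; z)`` per segment.

        theta stacks (distance-model theta, conditional-model theta); the
        covariance is block-diagonal across the two independently-estimated
        parts, and the per-segment gradient of ``log(g0 * p)`` concatenates
        the distance-model gradient with the (segment-constant) g(0)
        gradient.
        """
        d = self.distance_fit
        q1, q2 = len(d.theta_hat), len(self.conditional_fit.theta)
        V = np.zeros((q1 + q2, q1 + q2))
        V[:q1, :q1] = d.V_theta
        V[q1:, q1:] = self.conditional_fit.V_theta
        out = DetectionFit(
            d.platform_id, d.key,
            np.concatenate([d.theta_hat, self.conditional_fit.theta]),
            V, d.loglik + self.conditional_fit.loglik,
            q1 + q2, d.n_obs, scale_covariates=d.scale_covariates,
            truncation_w=d.truncation_w, transect=d.transect,
            hessian_pd=d.hessian_pd, g0=self.g0_hat)
        for sid, p in d.p_by_segment.items():
            out.p_by_segment[sid] = float(p * self.g0_hat)
            out.dp_dtheta_by_segment[sid] = np.concatenate(
                [d.dp_dtheta_by_segment[sid], self.g0_grad])
        return out


def apply_fixed_multipliers(segments: pd.DataFrame,
                            multipliers: dict[str, dict],
                            ) -> pd.DataFrame:
    """Attach fixed detectability multipliers (g(0), availability) to segments.

    ``multipliers`` maps platform_id to ``{"g0": float, "g0_cv": float}``;
    availability ``u`` is read from the segment table (default 1).  Adds the
    columns ``g0``, ``g0_cv`` and ``multiplier`` = ``g0 * u``.  The CVs of
    fixed multipliers never enter the variance-propagation refit; they are
    combined into the final abundance CV by squared-CV addition.
    """
    seg = segments.copy()
    if "availability" not in seg.columns:
        seg["availability"] = 1.0
    seg["g0"] = 1.0
    seg["g0_cv"] = 0.0
    for pid, spec in multipliers.items():
        g0 = float(spec.get("g0", 1.0))
        cv = float(spec.get("g0_cv", 0.0))
        if not 0 < g0 <= 1:
            raise ValidationError(f"platform {pid!r}: g0 {g0} outside (0, 1]")
        if cv < 0:
            raise ValidationError(f"platform {pid!r}: negative g0 CV")
        mask = seg["platform_id"].astype(str) == pid
        seg.loc[mask, "g0"] = g0
        seg.loc[mask, "g0_cv"] = cv
    u = seg["availability"].astype(float)
    if not ((u > 0) & (u <= 1)).all():
        raise ValidationError("availability outside (0, 1]")
    seg["multiplier"] = seg["g0"] * u
    return seg
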