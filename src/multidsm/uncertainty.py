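"""Detection-uncertainty propagation, posterior sampling and abundance.

The DSM is a two-stage model: detection-function parameters ``theta`` are
estimated first and enter the count model only through the offset, so a
naive spatial-model covariance understates the uncertainty of abundance.
Propagation refits the count model with extra columns holding, for each
platform, the derivative of the segment's log detectability with respect to
that platform's ``theta`` — treated as a zero-mean random effect whose
*fixed* prior covariance is the detection models' block-diagonal covariance
``V_theta``.  Fixing the prior is what makes this propagation rather than
re-estimation; the resulting joint posterior covariance ``V_{beta,theta}``
carries the detection uncertainty (including beta–theta covariance) into
everything derived from the coefficients.

Abundance over a prediction grid is ``N_hat = a exp(X_p beta)``; its
uncertainty comes from posterior draws of the coefficients (multivariate
normal, or Metropolis–Hastings on the model posterior), summarised as an
empirical CV.  Independent external multipliers (a fixed g(0), an
availability estimate) contribute by squared-CV addition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .detection import DetectionFit
from .dsm_core import DsmFit
from .gam_engine import GamError, _assemble_S, _irls, _quasi_loglik_core
from .survey_io import ValidationError


def assemble_v_theta(detection_fits: dict[str, DetectionFit] | list[DetectionFit],
                     ) -> tuple[np.ndarray, list[str]]:
    """Joint detection-parameter covariance, block diagonal over platforms.

    Returns ``(V_theta, order)`` where ``order`` lists the platform ids in
    block order (sorted).  Strip platforms have no theta and contribute no
    block; an empty result (0 x 0) makes propagation a no-op.
    """
    if isinstance(detection_fits, dict):
        fits = [detection_fits[k] for k in sorted(detection_fits)]
    else:
        fits = sorted(detection_fits, key=lambda f: f.platform_id)
    blocks, order = [], []
    for f in fits:
        if f.key == "strip" or f.V_theta.size == 0:
            continue
        V = np.asarray(f.V_theta, dtype=float)
        vals = np.linalg.eigvalsh(0.5 * (V + V.T))
        if vals.min() < -1e-8 * max(vals.max(), 1.0):
            raise ValidationError(
                f"platform {f.platform_id!r}: V_theta not positive semi-definite")
        blocks.append(V)
        order.append(f.platform_id)
    if not blocks:
        return np.empty((0, 0)), order
    return linalg.block_diag(*blocks), order


def _derivative_columns(fit: DsmFit, order: list[str]) -> np.ndarray:
    """Rows: segments; columns: stacked d log p / d theta_k per platform."""
    sizes = [len(fit.detection_fits[k].theta_hat) for k in order]
    q = sum(sizes)
    D = np.zeros((len(fit.segments), q))
    col0 = 0
    for k, sz in zip(order, sizes):
        df_k = fit.detection_fits[k]
        mask = fit.segments["platform_id"].astype(str).to_numpy() == k
        for row in np.where(mask)[0]:
            sid = fit.segments["segment_id"].iloc[row]
            if sid not in df_k.dp_dtheta_by_segment:
                raise ValidationError(f"segment {sid!r}: missing detection "
                                      "derivative for propagation")
            D[row, col0:col0 + sz] = df_k.dp_dtheta_by_segment[sid]
        col0 += sz
    return D


def propagate_variance(fit: DsmFit, V_theta: np.ndarray | None = None,
                       order: list[str] | None = None) -> DsmFit:
    """Refit with detection-derivative random-effect columns; update V.

    With a zero (or empty) ``V_theta`` the coefficient covariance is returned
    unchanged (no detection uncertainty to propagate).  On refit failure the
    procedure falls back to the unpropagated covariance with a prominent
    warning (the caller can then combine detection CVs by the delta method).
    """
    if V_theta is None:
        V_theta, order = assemble_v_theta(fit.detection_fits)
    V_theta = np.asarray(V_theta, dtype=float)
    P = fit.design.X.shape[1]
    if V_theta.size == 0 or not np.any(V_theta):
        fit.V_beta_theta = fit.pfit.V_beta.copy()
        fit.propagated = True
        return fit
    if order is None:
        raise ValidationError("platform block order required with V_theta")
    D = _derivative_columns(fit, order)
    q = D.shape[1]
    if q != V_theta.shape[0]:
        raise ValidationError("V_theta dimension does not match derivative columns")
    X_aug = np.column_stack([fit.design.X, D])
    S_beta = _assemble_S(fit.design.penalties, np.log(fit.pfit.lambda_hat), P)
    try:
        prec_theta = np.linalg.inv(V_theta)
    except np.linalg.LinAlgError:
        warnings.warn("V_theta is singular (a detection fit is degenerate); "
                      "using its pseudo-inverse as the random-effect precision")
        prec_theta = np.linalg.pinv(V_theta)
    S_aug = linalg.block_diag(S_beta, prec_theta)
    p = fit.pfit
    beta0 = np.concatenate([p.beta_hat, np.zeros(q)])
    try:
        beta_full, mu, XtWX = _irls(p.y, X_aug, S_aug, p.offset, p.family,
                                    p.power, p.theta, beta0=beta0)
        A = XtWX + S_aug
        V_full = p.scale * np.linalg.inv(A)
    except (GamError, np.linalg.LinAlgError) as e:
        warnings.warn("variance propagation refit failed "
                      f"({e}); FALLING BACK to the unpropagated covariance — "
                      "combine detection CVs by the delta method instead")
        fit.V_beta_theta = p.V_beta.copy()
        fit.propagated = False
        return fit
    V_full = 0.5 * (V_full + V_full.T)
    fit.V_beta_theta = V_full
    fit.propagated = True
    # refitted coefficients (theta adjustment absorbed into beta block)
    fit.pfit.beta_hat = beta_full[:P]
    fit.pfit.fitted = np.exp(np.clip(fit.design.X @ beta_full[:P]
                                     + D @ beta_full[P:] + p.offset, -300, 300))
    fit.theta_adjust = beta_full[P:]
    # kept for samplers that target the augmented (propagated) posterior
    fit._prop_D = D
    fit._prop_prec = prec_theta
    return fit


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------

def _coef_cov(fit: DsmFit) -> np.ndarray:
    P = fit.design.X.shape[1]
    if fit.V_beta_theta is not None:
        return fit.V_beta_theta[:P, :P]
    return fit.pfit.V_beta


def posterior_sample(fit: DsmFit, B: int = 1000, sampler: str = "mvn",
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw B coefficient vectors from the (approximate) model posterior.

    ``mvn`` samples the multivariate-normal approximation N(beta_hat,
    V_{beta,theta}); ``mh`` runs an adaptive random-walk Metropolis–Hastings
    sampler on the penalized-likelihood posterior (proposal covariance
    ``c * V``, c tuned to 0.2–0.4 acceptance during a burn-in of B/5,
    thinning 1).  Both are reproducible given the seed.
    """
    if B < 100:
        raise ValidationError("B must be >= 100")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    beta = fit.pfit.beta_hat
    V = _coef_cov(fit)
    P = len(beta)
    jitter = 1e-12 * max(np.trace(V) / max(P, 1), 1e-300)
    L = np.linalg.cholesky(V + jitter * np.eye(P))
    if sampler == "mvn":
        return beta[None, :] + rng.standard_normal((B, P)) @ L.T
    if sampler != "mh":
        raise ValidationError(f"unknown sampler {sampler!r}")

    p = fit.pfit
    X, y, off = fit.design.X, p.y, p.offset
    S = _assemble_S(fit.design.penalties, np.log(p.lambda_hat), P)
    phi = p.scale if p.scale > 0 else 1.0
    D = getattr(fit, "_prop_D", None)
    if fit.propagated and D is not None:
        # target the augmented posterior (beta, delta) with the fixed
        # detection-precision prior; only the beta block is returned
        X = np.column_stack([X, D])
        S = linalg.block_diag(S, getattr(fit, "_prop_prec"))
        mean_full = np.concatenate([beta, fit.theta_adjust])
        Pfull = len(mean_full)
        Vfull = fit.V_beta_theta
        jit = 1e-12 * max(np.trace(Vfull) / Pfull, 1e-300)
        Lfull = np.linalg.cholesky(Vfull + jit * np.eye(Pfull))
        beta, L, P = mean_full, Lfull, Pfull

    def logpost(b):
        mu = np.exp(np.clip(X @ b + off, -300, 300))
        return (_quasi_loglik_core(p.family, y, mu, p.power, p.theta) / phi
                - 0.5 * b @ S @ b / phi)

    c = 2.38 ** 2 / P
    burn = max(B // 5, 50)
    cur = beta.copy()
    lp = logpost(cur)
    acc_window = []
    draws = np.empty((B, P))
    accepted = 0
    for it in range(burn + B):
        prop = cur + np.sqrt(c) * (L @ rng.standard_normal(P))
        lp_prop = logpost(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            cur, lp = prop, lp_prop
            acc_window.append(1)
            if it >= burn:
                accepted += 1
        else:
            acc_window.append(0)
        if it < burn and (it + 1) % 50 == 0:
            rate = np.mean(acc_window[-50:])
            if rate < 0.2:
                c *= 0.6
            elif rate > 0.4:
                c *= 1.6
        if it >= burn:
            draws[it - burn] = cur
    rate = accepted / B
    if not 0.1 <= rate <= 0.6:
        warnings.warn(f"MH acceptance rate {rate:.2f} outside [0.1, 0.6] "
                      "after adaptation")
    nbeta = fit.design.X.shape[1]
    return draws[:, :nbeta]


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

@dataclass
class AbundanceEstimate:
    """Total abundance with posterior uncertainty."""

    N_hat: float
    draws: np.ndarray                    # B posterior N values
    cv_posterior: float
    cv_total: float
    cell_table: pd.DataFrame             # cell_id, area, density, cv
    per_platform: dict = field(default_factory=dict)
    extra_cv_components: dict = field(default_factory=dict)

    def summary(self) -> str:
        lo, hi = np.percentile(self.draws, [2.5, 97.5])
        lines = [f"Abundance: N_hat = {self.N_hat:.1f}",
                 f"  posterior CV = {self.cv_posterior:.4f}"
                 + (f"; total CV (with "
                    f"{', '.join(self.extra_cv_components)}) = "
                    f"{self.cv_total:.4f}" if self.extra_cv_components else ""),
                 f"  95% interval from draws: [{lo:.1f}, {hi:.1f}]"]
        for k, v in self.per_platform.items():
            lines.append(f"  platform {k}: N_hat = {v:.1f}")
        return "\n".join(lines)


def _grid_design(fit: DsmFit, grid: pd.DataFrame) -> list[tuple[str, np.ndarray]]:
    """Per-platform prediction design matrices.

    Variant A predicts one shared density surface; variants B and C replicate
    the grid per platform (the platform densities are distinct and summed).
    """
    if fit.spec.variant == "A_common":
        g = grid.copy()
        g["platform_id"] = fit.platform_ids[0]
        return [("(all)", fit.design.transform(g))]
    out = []
    for k in fit.platform_ids:
        g = grid.copy()
        g["platform_id"] = k
        out.append((k, fit.design.transform(g)))
    return out


def _check_extrapolation(fit: DsmFit, grid: pd.DataFrame) -> None:
    cols = set()
    for t in fit.design.terms:
        cols.update(getattr(t, "columns", ()) or
                    ([t.column] if hasattr(t, "column") else []))
        base = getattr(t, "base", None)
        if base is not None:
            cols.update(getattr(base, "columns", ()) or
                        ([base.column] if hasattr(base, "column") else []))
    for c in cols & set(grid.columns):
        lo, hi = fit.segments[c].min(), fit.segments[c].max()
        frac = float(np.mean((grid[c] < lo) | (grid[c] > hi)))
        if frac > 0:
            warnings.warn(f"{frac:.1%} of grid values for {c!r} lie outside "
                          "the training range (extrapolation)")


def abundance(fit: DsmFit, grid: pd.DataFrame,
              coef_draws: np.ndarray | None = None, B: int = 1000,
              sampler: str = "mvn", seed: int | np.random.Generator = 0,
              extra_cv_components: dict | None = None) -> AbundanceEstimate:
    """Predict total abundance over a grid with posterior uncertainty.

    ``N_hat = sum_cells a_c exp(x_c' beta_hat)`` (summed over platforms for
    variants B/C).  Uncertainty comes from coefficient draws (supplied, or
    generated by :func:`posterior_sample`); external independent CVs are
    folded in by squared-CV addition.
    """
    if "area" not in grid.columns:
        raise ValidationError("grid needs an 'area' column")
    a = grid["area"].to_numpy(dtype=float)
    if np.any(a <= 0):
        raise ValidationError("grid areas must be > 0")
    _check_extrapolation(fit, grid)
    designs = _grid_design(fit, grid)
    beta = fit.pfit.beta_hat
    if coef_draws is None:
        coef_draws = posterior_sample(fit, B=B, sampler=sampler, seed=seed)
    Bn = coef_draws.shape[0]

    cell_mu = np.zeros(len(grid))
    per_platform = {}
    cell_draws = np.zeros((Bn, len(grid)))
    for name, Xp in designs:
        mu_k = a * np.exp(np.clip(Xp @ beta, -300, 300))
        cell_mu += mu_k
        per_platform[name] = float(mu_k.sum())
        cell_draws += a[None, :] * np.exp(np.clip(coef_draws @ Xp.T, -300, 300))
    N_hat = float(cell_mu.sum())
    if not N_hat > 0:
        raise ValidationError("non-positive abundance estimate")
    N_draws = cell_draws.sum(axis=1)
    cv_post = float(N_draws.std(ddof=1) / N_draws.mean())
    extra = dict(extra_cv_components or {})
    cv_total = combine_cv({"posterior": cv_post, **extra})
    cell_sd = cell_draws.std(axis=0, ddof=1)
    cell_mean = cell_draws.mean(axis=0)
    cell_table = pd.DataFrame({
        "cell_id": grid["cell_id"] if "cell_id" in grid.columns
        else np.arange(len(grid)),
        "area": a,
        "abundance": cell_mu,
        "density": cell_mu / a,
        "cv": np.where(cell_mean > 0, cell_sd / cell_mean, np.nan),
    })
    return AbundanceEstimate(N_hat=N_hat, draws=N_draws, cv_posterior=cv_post,
                             cv_total=cv_total, cell_table=cell_table,
                             per_platform=per_platform,
                             extra_cv_components=extra)


def combine_cv(components: dict[str, float]) -> float:
    """Total CV of a product of independent factors: sqrt(sum of squared CVs)."""
    vals = np.asarray(list(components.values()), dtype=float)
    if np.any(vals < 0):
        raise ValidationError("negative CV component")
    return float(np.sqrt(np.sum(vals ** 2)))


def delta_method_total_cv(cv_gam: float, cv_detection: float) -> float:
    """Delta-method alternative to propagation: independence of the spatial
    model and detection model is assumed and squared CVs add."""
    return combine_cv({"gam": cv_gam, "detection": cv_detection})
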