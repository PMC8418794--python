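"""Penalized regression spline machinery for count models.

Implements the additive-model layer of the density surface model: basis
construction (cubic regression splines for one covariate, thin-plate-type
radial bases for two, factor-smooth interactions for per-platform smooths,
all with optional whole-term shrinkage), count-family log-likelihoods
(Poisson, quasi-Poisson, negative binomial, Tweedie), penalized IRLS for the
coefficients given smoothing parameters, and smoothing-parameter selection by
Laplace-approximate restricted marginal likelihood (REML).

Smooth terms are written ``f(x) = sum_j beta_j b_j(x)`` with a quadratic
wiggliness penalty ``lambda * beta' S beta``; the *shrinkage* variant adds a
small penalty on the penalty null space so that ``lambda -> inf`` removes the
whole term (not merely its wiggly part).  Identifiability is handled by
absorbing a sum-to-zero-over-data constraint into every smooth block.

The REML criterion maximised over log smoothing parameters (and any family
nuisance parameters) is

    V(lambda) = l(beta_hat) - beta_hat' S_l beta_hat / (2 phi)
                + (1/2) log|S_l / phi|_+  - (1/2) log|(X'WX + S_l)/phi|
                + (M_p / 2) log(2 pi)

with ``S_l = sum_j lambda_j S_j``, ``|.|_+`` the pseudo-determinant over the
penalty range space, W the Fisher weights at the penalized MLE and ``M_p``
the dimension of the total penalty null space.  The Bayesian posterior
covariance of the coefficients is ``V_beta = phi (X'WX + S_l)^{-1}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special
from scipy.linalg import null_space
from scipy.special import gammaln, logsumexp

from .survey_io import ValidationError

EIG_TOL = 1e-9          # relative eigenvalue threshold for penalty rank
LOG_LAMBDA_BOUNDS = (-15.0, 28.0)
TWEEDIE_POWER_GRID = tuple(np.round(np.arange(1.1, 1.95, 0.1), 2))


class GamError(RuntimeError):
    pass


# ===========================================================================
# families
# ===========================================================================

def _poisson_loglik(y, mu):
    return np.sum(y * np.log(mu) - mu - gammaln(y + 1.0))


def _negbin_loglik(y, mu, theta):
    return np.sum(gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
                  + theta * np.log(theta / (theta + mu))
                  + y * np.log(mu / (theta + mu)))


def tweedie_loglik(y, mu, phi, power):
    """Exact Tweedie log-density, power in (1, 2), by series evaluation.

    The compound Poisson–gamma density has point mass at zero,
    ``log f(0) = -mu^(2-p) / (phi (2-p))``, and for ``y > 0`` the series of
    Dunn & Smyth evaluated in the log domain around its largest term.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if not (1.0 < power < 2.0):
        raise ValidationError("Tweedie power must lie in (1, 2)")
    if np.any(y < 0):
        raise ValidationError("negative response for Tweedie family")
    p = power
    base = (y * mu ** (1.0 - p) / (1.0 - p) - mu ** (2.0 - p) / (2.0 - p)) / phi
    pos = y > 0
    if not np.any(pos):
        return float(np.sum(base))
    yp = y[pos]
    alpha = (2.0 - p) / (p - 1.0)
    jmax = yp ** (2.0 - p) / ((2.0 - p) * phi)
    lo = max(1, int(np.floor(jmax.min())) - 40)
    hi = int(np.ceil(jmax.max())) + 40
    hi = min(hi, lo + 20000)
    j = np.arange(lo, hi + 1, dtype=float)[:, None]          # (J, 1)
    logy = np.log(yp)[None, :]
    logW = (j * alpha * logy
            - j * alpha * np.log(p - 1.0)
            - j * (1.0 + alpha) * np.log(phi)
            - j * np.log(2.0 - p)
            - gammaln(j + 1.0) - gammaln(j * alpha))
    log_a = logsumexp(logW, axis=0) - np.log(yp)
    out = np.sum(base) + np.sum(log_a)
    return float(out)


def family_loglik(family: str, y, mu, scale: float = 1.0,
                  power: float | None = None, theta: float | None = None,
                  ) -> float:
    """Log-likelihood of counts under the requested family (log link models).

    ``scale`` is the Tweedie/quasi dispersion phi; ``power`` the Tweedie
    index p in (1, 2); ``theta`` the negative-binomial size (Var =
    mu + mu^2/theta).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < 0):
        raise ValidationError("negative counts")
    if np.any(mu <= 0):
        raise ValidationError("mean must be positive")
    if family in ("poisson", "quasipoisson"):
        return float(_poisson_loglik(y, mu))
    if family == "negative_binomial":
        if theta is None or theta <= 0:
            raise ValidationError("negative_binomial needs theta > 0")
        return float(_negbin_loglik(y, mu, theta))
    if family == "tweedie":
        if power is None:
            raise ValidationError("tweedie needs a power in (1, 2)")
        return tweedie_loglik(y, mu, scale, power)
    raise ValidationError(f"unknown family {family!r}")


def _fisher_weight(family, mu, power=None, theta=None):
    # log link: w = (dmu/deta)^2 / V(mu), with the dispersion factored out
    if family in ("poisson", "quasipoisson"):
        return mu
    if family == "negative_binomial":
        return mu * theta / (theta + mu)
    if family == "tweedie":
        return mu ** (2.0 - power)
    raise ValidationError(f"unknown family {family!r}")


# ===========================================================================
# basis construction
# ===========================================================================

@dataclass
class SmoothSpec:
    """Declaration of one smooth model term.

    ``basis`` is one of ``cubic_spline`` (one covariate), ``tprs_shrinkage``
    (one or two covariates, radial basis with whole-term shrinkage) or
    ``factor_smooth`` (the base smooth replicated per level of ``by_factor``
    as deviations from a reference-level smooth).  ``k`` is the maximum basis
    size before identifiability constraints.
    """

    covariates: tuple[str, ...]
    basis: str = "tprs_shrinkage"
    k: int = 10
    by_factor: str | None = None
    shrinkage: bool = True
    shared_lambda: bool = False     # factor-smooth: one lambda across deviations
    fixed_log_lambda: float | None = None
    #: factor-smooth only: pin the reference-level smooth's log lambda
    fixed_ref_log_lambda: float | None = None

    def __post_init__(self):
        self.covariates = tuple(np.atleast_1d(self.covariates))
        if self.k < 3:
            raise ValidationError("basis size k must be >= 3")
        if self.basis == "factor_smooth" and self.by_factor is None:
            raise ValidationError("factor_smooth needs by_factor")


def _absorb_constraint(X: np.ndarray, S_list: list[np.ndarray]):
    """Absorb the sum-to-zero-over-data constraint 1'X beta = 0.

    Returns the reparameterized design (one fewer column), transformed
    penalties and the transform Z (applied to any prediction matrix).
    """
    C = X.sum(axis=0, keepdims=True)
    Z = null_space(C)
    if Z.shape[1] != X.shape[1] - 1:
        # constraint row was (numerically) zero: keep as-is
        Z = np.eye(X.shape[1])
    return X @ Z, [Z.T @ S @ Z for S in S_list], Z


def _shrinkage_penalty(S: np.ndarray, eps_factor: float = 0.1) -> np.ndarray:
    """Add a small penalty on the null space so lambda -> inf zeroes the term."""
    vals, vecs = np.linalg.eigh(S)
    tol = EIG_TOL * max(vals.max(), 1.0)
    null = vals < tol
    if not np.any(null):
        return S
    nz = vals[~null]
    eps = eps_factor * (nz.min() if nz.size else 1.0)
    return S + eps * (vecs[:, null] @ vecs[:, null].T)


class Term:
    """Base class: fit() learns state from training data, transform() maps
    any data frame to this term's design block."""

    name: str = ""
    penalized = False

    def fit(self, df: pd.DataFrame) -> None:   # pragma: no cover - interface
        raise NotImplementedError

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def local_penalties(self) -> list[tuple]:
        """(column range within the term, S, label, fixed log-lambda, group)
        tuples; blocks sharing a non-None group share one smoothing
        parameter."""
        return []


class InterceptTerm(Term):
    name = "intercept"

    def fit(self, df):
        pass

    def transform(self, df):
        return np.ones((len(df), 1))


class LinearTerm(Term):
    def __init__(self, column: str):
        self.column = column
        self.name = f"linear({column})"

    def fit(self, df):
        pass

    def transform(self, df):
        return df[[self.column]].to_numpy(dtype=float)


class FactorTerm(Term):
    """Unpenalized one-hot factor (all levels, no reference) — used for the
    per-platform intercepts beta_k, replacing the global intercept."""

    def __init__(self, column: str):
        self.column = column
        self.name = f"factor({column})"

    def fit(self, df):
        self.levels_ = tuple(sorted(df[self.column].astype(str).unique()))

    def transform(self, df):
        vals = df[self.column].astype(str)
        unknown = set(vals) - set(self.levels_)
        if unknown:
            raise ValidationError(f"unknown factor level(s) {sorted(unknown)}")
        return np.column_stack([(vals == lv).to_numpy(dtype=float)
                                for lv in self.levels_])


class CubicSplineTerm(Term):
    """Cubic B-spline basis with knots at covariate quantiles and an exact
    integrated-squared-second-derivative penalty."""

    penalized = True

    def __init__(self, column: str, k: int = 10, shrinkage: bool = False,
                 fixed_log_lambda: float | None = None):
        self.column = column
        self.k = int(k)
        self.shrinkage = shrinkage
        self.fixed_log_lambda = fixed_log_lambda
        self.name = f"s({column})"

    def fit(self, df):
        from scipy.interpolate import BSpline
        x = df[self.column].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValidationError(f"non-finite values in {self.column!r}")
        k = self.k
        n_distinct = len(np.unique(x))
        if k > n_distinct:
            warnings.warn(f"s({self.column}): k reduced {k} -> {n_distinct} "
                          "(distinct covariate values)")
            k = max(4, n_distinct)
        k = max(k, 4)
        n_interior = k - 4
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(np.unique(x), qs)
        else:
            interior = np.array([])
        lo, hi = x.min(), x.max()
        t = np.r_[[lo] * 4, interior, [hi] * 4]
        self._knots = t
        self._range = (lo, hi)
        self._nb = k
        S = self._second_deriv_gram(t, k)
        X = self._raw(x)
        Xc, S_list, Z = _absorb_constraint(X, [S])
        S1 = S_list[0]
        if self.shrinkage:
            S1 = _shrinkage_penalty(S1)
        self._Z = Z
        self._S = 0.5 * (S1 + S1.T)

    @staticmethod
    def _second_deriv_gram(t, k):
        from scipy.interpolate import BSpline
        S = np.zeros((k, k))
        # second derivatives of cubics are piecewise linear: Gauss exact
        gx, gw = np.polynomial.legendre.leggauss(3)
        breaks = np.unique(t)
        eye = np.eye(k)
        for a, b in zip(breaks[:-1], breaks[1:]):
            xm = 0.5 * (a + b) + 0.5 * (b - a) * gx
            wm = 0.5 * (b - a) * gw
            vals = np.column_stack([
                np.nan_to_num(BSpline(t, eye[i], 3, extrapolate=False)(xm, nu=2))
                for i in range(k)])                       # (ngauss, k)
            S += (vals * wm[:, None]).T @ vals
        return 0.5 * (S + S.T)

    def _raw(self, x):
        from scipy.interpolate import BSpline
        lo, hi = self._range
        xc = np.clip(x, lo, hi)   # clamp: constant extrapolation beyond range
        X = np.nan_to_num(
            BSpline.design_matrix(xc, self._knots, 3,
                                  extrapolate=False).toarray())
        # at the right boundary only the last basis function is non-zero
        X[xc == hi, :] = 0.0
        X[xc == hi, -1] = 1.0
        return X

    def transform(self, df):
        x = df[self.column].to_numpy(dtype=float)
        return self._raw(x) @ self._Z

    def local_penalties(self):
        return [(slice(0, self._S.shape[0]), self._S, self.name,
                 self.fixed_log_lambda, None)]


class TprsTerm(Term):
    """Thin-plate-type radial basis (eigen-truncated) for 1 or 2 covariates.

    Follows the low-rank thin plate regression spline construction: radial
    kernel evaluated between data points, truncated to the leading ``k``
    eigenvectors, polynomial null space (constant absorbed by the model
    intercept), wiggliness penalty from the kernel eigenvalues.  The
    shrinkage variant adds a small ridge on the null space of the penalty so
    the whole term can shrink to zero.
    """

    penalized = True

    def __init__(self, columns: tuple[str, ...], k: int = 10,
                 shrinkage: bool = True, fixed_log_lambda: float | None = None,
                 max_knots: int = 300):
        self.columns = tuple(columns)
        if len(self.columns) not in (1, 2):
            raise ValidationError("tprs basis takes 1 or 2 covariates")
        self.k = int(k)
        self.shrinkage = shrinkage
        self.fixed_log_lambda = fixed_log_lambda
        self.max_knots = max_knots
        self.name = f"s({','.join(self.columns)})"

    def _eta(self, r):
        d = len(self.columns)
        with np.errstate(divide="ignore", invalid="ignore"):
            if d == 2:
                v = r ** 2 * np.log(r)
            else:
                v = r ** 3
        return np.where(r > 0, v, 0.0)

    def fit(self, df):
        P = df[list(self.columns)].to_numpy(dtype=float)
        if not np.all(np.isfinite(P)):
            raise ValidationError(f"non-finite values in {self.columns}")
        uniq = np.unique(P, axis=0)
        if len(uniq) > self.max_knots:
            step = len(uniq) / self.max_knots
            uniq = uniq[(np.arange(self.max_knots) * step).astype(int)]
        self._scale = max(np.ptp(uniq, axis=0).max(), 1e-12)
        self._pts = uniq / self._scale
        npts = len(self._pts)
        d = len(self.columns)
        null_dim = d + 1
        k = min(self.k, npts)
        if k < null_dim + 1:
            raise ValidationError(f"{self.name}: k={self.k} too small")
        if k < self.k:
            warnings.warn(f"{self.name}: k reduced {self.k} -> {k}")
        E = self._eta(_pairwise_dist(self._pts, self._pts))
        vals, vecs = np.linalg.eigh(E)
        order = np.argsort(-np.abs(vals))[: k - null_dim + d]  # spare room for constraint
        Uk = vecs[:, order]
        Dk = vals[order]
        T = np.column_stack([np.ones(npts), self._pts])
        Zc = null_space(T.T @ Uk)
        self._delta_basis = Uk @ Zc                # (npts, k')
        S_R = Zc.T @ (Uk * Dk).T @ Uk @ Zc         # Zc' Dk Zc in delta coords
        S_R = 0.5 * (S_R + S_R.T)
        # clip tiny negative curvature from truncation
        w, V = np.linalg.eigh(S_R)
        S_R = (V * np.clip(w, 0.0, None)) @ V.T
        kR = self._delta_basis.shape[1]
        # term block = [radial, linear coords]; constant left to the intercept
        X = np.column_stack([self._radial(P / self._scale), P / self._scale])
        S_full = np.zeros((kR + d, kR + d))
        S_full[:kR, :kR] = S_R
        Xc, S_list, Z2 = _absorb_constraint(X, [S_full])
        S1 = S_list[0]
        if self.shrinkage:
            S1 = _shrinkage_penalty(S1)
        self._Z2 = Z2
        self._S = 0.5 * (S1 + S1.T)

    def _radial(self, Pn):
        return self._eta(_pairwise_dist(Pn, self._pts)) @ self._delta_basis

    def transform(self, df):
        P = df[list(self.columns)].to_numpy(dtype=float) / self._scale
        X = np.column_stack([self._radial(P), P])
        return X @ self._Z2

    def local_penalties(self):
        return [(slice(0, self._S.shape[0]), self._S, self.name,
                 self.fixed_log_lambda, None)]


def _pairwise_dist(A, B):
    return np.sqrt(np.maximum(
        np.sum(A ** 2, 1)[:, None] + np.sum(B ** 2, 1)[None, :]
        - 2.0 * A @ B.T, 0.0))


class FactorSmoothTerm(Term):
    """Reference-level smooth plus per-level deviation smooths.

    The deviation block for each non-reference level contains a level
    indicator (intercept deviation) and the base smooth's columns masked to
    that level, under a full-rank shrinkage penalty — so letting the
    deviation smoothing parameters go to infinity collapses the model onto
    the single shared smooth.
    """

    penalized = True

    def __init__(self, base: Term, by_factor: str, shared_lambda: bool = False,
                 fixed_dev_log_lambda: float | None = None):
        self.base = base
        self.by_factor = by_factor
        self.shared_lambda = shared_lambda
        self.fixed_dev_log_lambda = fixed_dev_log_lambda
        self.name = f"{base.name}:by({by_factor})"

    def fit(self, df):
        self.base.fit(df)
        self.levels_ = tuple(sorted(df[self.by_factor].astype(str).unique()))
        if len(self.levels_) < 2:
            raise ValidationError("factor_smooth needs >= 2 levels")
        base_pens = self.base.local_penalties()
        if len(base_pens) != 1:
            raise GamError("factor_smooth base must carry one penalty")
        _, S_base, _, _, _ = base_pens[0]
        kb = S_base.shape[0]
        # deviation penalty: normalized wiggliness penalty plus identity, so a
        # single smoothing parameter controls both the level and wiggliness of
        # each deviation and lambda -> inf removes the deviation entirely
        S_dev = np.eye(kb + 1)
        snorm = float(np.linalg.eigvalsh(S_base).max())
        if snorm > 0:
            S_dev[1:, 1:] += S_base / snorm
        self._S_dev = S_dev
        self._kb = kb

    def transform(self, df):
        Xb = self.base.transform(df)
        lev = df[self.by_factor].astype(str).to_numpy()
        blocks = [Xb]
        for lv in self.levels_[1:]:
            ind = (lev == lv).astype(float)
            blocks.append(np.column_stack([ind, Xb * ind[:, None]]))
        return np.column_stack(blocks)

    def local_penalties(self):
        base_pen = self.base.local_penalties()[0]
        out = [(slice(0, self._kb), base_pen[1], f"{self.name}[ref]",
                base_pen[3], None)]
        start = self._kb
        group = f"{self.name}[dev]" if self.shared_lambda else None
        for lv in self.levels_[1:]:
            out.append((slice(start, start + self._kb + 1), self._S_dev,
                        f"{self.name}[dev:{lv}]", self.fixed_dev_log_lambda,
                        group))
            start += self._kb + 1
        return out


def build_term(spec: SmoothSpec) -> Term:
    """Instantiate the term a :class:`SmoothSpec` declares."""
    if spec.basis == "factor_smooth":
        base = build_term(SmoothSpec(spec.covariates, basis="tprs_shrinkage"
                                     if len(spec.covariates) == 2 else "cubic_spline",
                                     k=spec.k, shrinkage=True,
                                     fixed_log_lambda=spec.fixed_ref_log_lambda))
        return FactorSmoothTerm(base, spec.by_factor,
                                shared_lambda=spec.shared_lambda,
                                fixed_dev_log_lambda=spec.fixed_log_lambda)
    if spec.basis == "cubic_spline":
        if len(spec.covariates) != 1:
            raise ValidationError("cubic_spline takes exactly one covariate")
        return CubicSplineTerm(spec.covariates[0], k=spec.k,
                               shrinkage=spec.shrinkage,
                               fixed_log_lambda=spec.fixed_log_lambda)
    if spec.basis == "tprs_shrinkage":
        return TprsTerm(spec.covariates, k=spec.k, shrinkage=spec.shrinkage,
                        fixed_log_lambda=spec.fixed_log_lambda)
    raise ValidationError(f"unknown basis {spec.basis!r}")


@dataclass
class PenaltyBlock:
    cols: slice               # global design-matrix columns
    S: np.ndarray
    label: str
    fixed_log_lambda: float | None
    group: str | None = None  # blocks sharing a group share one lambda
    rank: int = 0
    logdet: float = 0.0

    def __post_init__(self):
        vals = np.linalg.eigvalsh(self.S)
        tol = EIG_TOL * max(vals.max(), 1.0)
        nz = vals[vals > tol]
        self.rank = int(nz.size)
        self.logdet = float(np.sum(np.log(nz))) if nz.size else 0.0

    def embed(self, P: int) -> np.ndarray:
        out = np.zeros((P, P))
        out[self.cols, self.cols] = self.S
        return out


class Design:
    """Assembled model design: terms -> (X, penalty blocks, column map)."""

    def __init__(self, terms: list[Term]):
        self.terms = terms

    def fit(self, df: pd.DataFrame) -> "Design":
        X_blocks, self.term_cols, self.penalties = [], {}, []
        start = 0
        for t in self.terms:
            t.fit(df)
            Xb = t.transform(df)
            X_blocks.append(Xb)
            self.term_cols[t.name] = slice(start, start + Xb.shape[1])
            for loc, S, label, fx, grp in t.local_penalties():
                gsl = slice(start + loc.start, start + loc.stop)
                self.penalties.append(PenaltyBlock(gsl, S, label, fx, grp))
            start += Xb.shape[1]
        self.X = np.column_stack(X_blocks) if X_blocks else np.empty((len(df), 0))
        self.P = start
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        return np.column_stack([t.transform(df) for t in self.terms]) \
            if self.terms else np.empty((len(df), 0))

    @property
    def null_dim(self) -> int:
        return self.P - sum(p.rank for p in self.penalties)


# ===========================================================================
# penalized IRLS + REML
# ===========================================================================

@dataclass
class PenalizedFit:
    """A fitted penalized count model (log link)."""

    beta_hat: np.ndarray
    V_beta: np.ndarray              # Bayesian posterior covariance phi*(X'WX+S)^-1
    lambda_hat: np.ndarray          # per penalty block, fit order
    family: str
    scale: float                    # dispersion phi (1 for poisson/negbin)
    power: float | None             # tweedie index
    theta: float | None             # negbin size
    loglik: float
    reml_score: float
    edf_total: float
    edf_by_term: dict
    fitted: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    design: Design | None = None
    penalty_labels: tuple = ()
    XtWX: np.ndarray | None = None

    @property
    def aic(self) -> float:
        """AIC = -2 l(beta_hat) + 2 * total effective degrees of freedom."""
        if np.isnan(self.loglik):
            return np.nan
        return -2.0 * self.loglik + 2.0 * self.edf_total


def _irls(y, X, S_total, offset, family, power, theta, beta0=None,
          max_iter=200, tol=1e-11):
    """Penalized IRLS for fixed penalty; returns (beta, mu, XtWX_chol_parts)."""
    y = np.asarray(y, dtype=float)
    n, P = X.shape
    if beta0 is None:
        mu = np.maximum(y, 0.0) + 0.5
        eta = np.log(mu) - offset
    else:
        eta = X @ beta0
        mu = np.exp(np.clip(eta + offset, -300, 300))
    beta = np.zeros(P) if beta0 is None else beta0.copy()

    def pll(b):
        m = np.exp(np.clip(X @ b + offset, -300, 300))
        ll = _quasi_loglik_core(family, y, m, power, theta)
        return ll - 0.5 * b @ S_total @ b

    last = -np.inf
    for it in range(max_iter):
        w = _fisher_weight(family, mu, power, theta)
        w = np.clip(w, 1e-12, 1e12)
        z = eta + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X + S_total
        try:
            c, low = linalg.cho_factor(A)
        except linalg.LinAlgError:
            try:
                jit = 1e-10 * float(np.mean(np.diag(A))) + 1e-300
                c, low = linalg.cho_factor(A + jit * np.eye(P))
            except linalg.LinAlgError:
                raise GamError("IRLS: singular penalized information matrix")
        beta_new = linalg.cho_solve((c, low), XtW @ z)
        # step halving on the penalized log-likelihood
        step = beta_new - beta
        obj = pll(beta_new)
        halvings = 0
        while (not np.isfinite(obj) or obj < last - 1e-8) and halvings < 30:
            step *= 0.5
            beta_new = beta + step
            obj = pll(beta_new)
            halvings += 1
        if halvings == 30 and (not np.isfinite(obj) or obj < last - 1e-6):
            raise GamError("IRLS diverged (step-halving exhausted)")
        step_size = np.max(np.abs(beta_new - beta)) if it else np.inf
        beta = beta_new
        eta = X @ beta
        mu = np.exp(np.clip(eta + offset, -300, 300))
        if (abs(obj - last) < tol * (1.0 + abs(obj))
                and step_size < 1e-9 * (1.0 + np.max(np.abs(beta)))):
            last = obj
            break
        last = obj
    w = np.clip(_fisher_weight(family, mu, power, theta), 1e-12, 1e12)
    XtWX = (X.T * w) @ X
    return beta, mu, XtWX


def _quasi_loglik_core(family, y, mu, power, theta):
    """Likelihood kernel used inside IRLS (cheap; Tweedie uses its
    quasi-likelihood deviance kernel, the full series only at convergence)."""
    if family in ("poisson", "quasipoisson"):
        return float(np.sum(y * np.log(mu) - mu))
    if family == "negative_binomial":
        return float(np.sum(y * np.log(mu / (theta + mu))
                            - theta * np.log(theta + mu)))
    if family == "tweedie":
        p = power
        return float(np.sum(y * mu ** (1 - p) / (1 - p) - mu ** (2 - p) / (2 - p)))
    raise ValidationError(family)


def _assemble_S(penalties, log_lambdas, P):
    S = np.zeros((P, P))
    for pen, ll in zip(penalties, log_lambdas):
        lam = np.exp(np.clip(ll, *LOG_LAMBDA_BOUNDS))
        S[pen.cols, pen.cols] += lam * pen.S
    return S


def _reml_score(log_lambdas, y, X, penalties, offset, family, power, theta,
                phi, beta_warm=None):
    P = X.shape[1]
    S = _assemble_S(penalties, log_lambdas, P)
    beta, mu, XtWX = _irls(y, X, S, offset, family, power, theta, beta0=beta_warm)
    ll = family_loglik(family if family != "quasipoisson" else "poisson",
                       y, mu, scale=phi, power=power, theta=theta)
    pen_quad = float(beta @ S @ beta)
    logdet_S = 0.0
    rank_total = 0
    for pen, lam_l in zip(penalties, log_lambdas):
        lam_l = float(np.clip(lam_l, *LOG_LAMBDA_BOUNDS))
        logdet_S += pen.rank * lam_l + pen.logdet
        rank_total += pen.rank
    A = XtWX + S
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, beta
    Mp = P - rank_total
    score = (ll - pen_quad / (2.0 * phi)
             + 0.5 * (logdet_S - rank_total * np.log(phi))
             - 0.5 * (logdet_A - P * np.log(phi))
             + 0.5 * Mp * np.log(2.0 * np.pi))
    return -score, beta   # minimise


def fit_penalized(y, design: Design, offset=None, family: str = "poisson",
                  power: float | None = None, theta: float | None = None,
                  estimate_power: bool = False,
                  ) -> PenalizedFit:
    """Fit the penalized count model; REML-select free smoothing parameters.

    Coefficients for fixed smoothing parameters come from penalized IRLS; the
    outer criterion (Laplace-approximate REML) is optimised over the log
    smoothing parameters of all penalty blocks without a
    ``fixed_log_lambda``, plus ``log phi`` (Tweedie) and ``log theta``
    (negative binomial, when not supplied).  The Tweedie index ``p`` is
    profiled over a fixed grid when ``estimate_power``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValidationError("negative counts")
    X = design.X
    n, P = X.shape
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValidationError("non-finite offset")
    penalties = design.penalties

    if family == "tweedie":
        powers = TWEEDIE_POWER_GRID if (estimate_power or power is None) else (power,)
    else:
        powers = (None,)

    best = None
    for pw in powers:
        res = _fit_at_power(y, X, design, penalties, offset, family, pw, theta)
        if best is None or res["reml"] < best["reml"]:
            best = res
    return _finalize_fit(best, y, X, design, penalties, offset, family)


def _fit_at_power(y, X, design, penalties, offset, family, power, theta):
    P = X.shape[1]
    slot_of = {}
    free_slots = []
    for i, pen in enumerate(penalties):
        if pen.fixed_log_lambda is not None:
            continue
        key = pen.group if pen.group is not None else f"_pen{i}"
        if key not in slot_of:
            slot_of[key] = len(free_slots)
            free_slots.append(key)
        # noqa: slot recorded per penalty below
    free_map = [(i, slot_of[pen.group if pen.group is not None else f"_pen{i}"])
                for i, pen in enumerate(penalties)
                if pen.fixed_log_lambda is None]
    fixed_ll = np.array([p.fixed_log_lambda if p.fixed_log_lambda is not None
                         else 0.0 for p in penalties])
    est_phi = family == "tweedie"
    est_theta = family == "negative_binomial" and theta is None
    n_extra = int(est_phi) + int(est_theta)

    def unpack(par):
        ll = fixed_ll.copy()
        for i, slot in free_map:
            ll[i] = par[slot]
        k = len(free_slots)
        phi = float(np.exp(par[k])) if est_phi else 1.0
        th = float(np.exp(par[k + int(est_phi)])) if est_theta else theta
        return ll, phi, th

    def objective(par):
        ll, phi, th = unpack(par)
        try:
            score, _ = _reml_score(ll, y, X, penalties, offset, family,
                                   power, th, phi)
        except (GamError, ValidationError, FloatingPointError):
            return 1e12
        return score if np.isfinite(score) else 1e12

    npar = len(free_slots) + n_extra
    if npar == 0:
        ll, phi, th = unpack(np.empty(0))
        score, beta = _reml_score(ll, y, X, penalties, offset, family,
                                  power, th, phi)
        return {"log_lambdas": ll, "phi": phi, "theta": th, "power": power,
                "reml": score}
    x0 = np.zeros(npar)
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-6,
                                     "maxiter": 300 * npar, "adaptive": True})
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        # restart from a coarse lambda grid
        cand = None
        for g in (-5.0, 0.0, 5.0, 10.0):
            x = np.full(npar, g)
            v = objective(x)
            if cand is None or v < cand[0]:
                cand = (v, x)
        res = optimize.minimize(objective, cand[1], method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": 300 * npar})
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            raise GamError("REML optimisation failed from all restarts")
    ll, phi, th = unpack(res.x)
    return {"log_lambdas": ll, "phi": phi, "theta": th, "power": power,
            "reml": float(res.fun)}


def _finalize_fit(best, y, X, design, penalties, offset, family):
    P = X.shape[1]
    ll_vec, phi, th, power = (best["log_lambdas"], best["phi"], best["theta"],
                              best["power"])
    S = _assemble_S(penalties, ll_vec, P)
    beta, mu, XtWX = _irls(y, X, S, offset, family, power, th)
    A = XtWX + S
    Ainv = np.linalg.inv(A)
    F = Ainv @ XtWX
    edf_total = float(np.trace(F))
    edf_by_term = {name: float(np.sum(np.diag(F)[sl]))
                   for name, sl in design.term_cols.items()}
    if family == "quasipoisson":
        pearson = float(np.sum((y - mu) ** 2 / mu))
        phi = pearson / max(len(y) - edf_total, 1.0)
        loglik = np.nan
    else:
        loglik = family_loglik(family, y, mu, scale=phi, power=power, theta=th)
    V_beta = phi * Ainv
    V_beta = 0.5 * (V_beta + V_beta.T)
    return PenalizedFit(
        beta_hat=beta, V_beta=V_beta,
        lambda_hat=np.exp(np.clip(ll_vec, *LOG_LAMBDA_BOUNDS)),
        family=family, scale=phi, power=power, theta=th,
        loglik=float(loglik) if loglik == loglik else np.nan,
        reml_score=float(best["reml"]), edf_total=edf_total,
        edf_by_term=edf_by_term, fitted=mu, y=y, offset=offset,
        design=design, penalty_labels=tuple(p.label for p in penalties),
        XtWX=XtWX)


def model_aic(fit: PenalizedFit) -> float:
    """GAM AIC: -2 log-likelihood at the penalized MLE + 2 * total EDF."""
    return fit.aic
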