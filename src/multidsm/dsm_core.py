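"""Multi-platform density surface model assembly and fitting.

Segment counts from all platforms enter one penalized count model with a
log offset built from each segment's effective area,

    offset_i = log( a_i * p_i * g(0)_i * u_i ),

where ``a`` is the covered area, ``p`` the platform's average detection
probability for the segment, ``g(0)`` the trackline-detection multiplier and
``u`` the availability.  Three model variants express how density may differ
between platforms:

* variant A — common intercept: differences in counts are attributed to
  detectability alone;
* variant B — per-platform intercepts ``beta_k``: density level may differ
  by platform;
* variant C — factor-smooth interactions: the smooth terms themselves vary
  by platform, fitted as deviations from a reference-level smooth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gam_engine
from .detection import DetectionFit
from .gam_engine import (Design, FactorTerm, InterceptTerm, LinearTerm,
                         PenalizedFit, SmoothSpec, build_term)
from .survey_io import ValidationError

VARIANTS = ("A_common", "B_factor_intercept", "C_factor_smooth")


@dataclass
class DsmSpec:
    """Declaration of a density surface model.

    ``terms`` lists the smooth terms; under variant C every smooth becomes a
    factor-smooth over platform (deviations from a reference level) unless it
    already declares a ``by_factor``.  ``linear_terms`` admits unpenalized
    covariates, as in a GLM.
    """

    variant: str = "A_common"
    terms: list[SmoothSpec] = field(default_factory=list)
    family: str = "tweedie"
    power: float | None = None
    theta: float | None = None
    linear_terms: tuple[str, ...] = ()

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}; "
                                  f"choose from {VARIANTS}")


@dataclass
class DsmFit:
    """A fitted DSM: the penalized fit plus offset provenance."""

    pfit: PenalizedFit
    spec: DsmSpec
    segments: pd.DataFrame
    offset_parts: pd.DataFrame       # per-segment a, p, g0, u
    platform_ids: tuple[str, ...]
    detection_fits: dict = field(default_factory=dict)
    #: joint posterior covariance after variance propagation (beta block
    #: first, then the detection-derivative random-effect block); None until
    #: propagate_variance() has run.
    V_beta_theta: np.ndarray | None = None
    propagated: bool = False

    @property
    def design(self) -> Design:
        return self.pfit.design

    def predict_mu(self, segments: pd.DataFrame | None = None,
                   offset: np.ndarray | None = None) -> np.ndarray:
        """Fitted mean counts for segment rows (training rows by default)."""
        if segments is None:
            return self.pfit.fitted
        X = self.design.transform(segments)
        if offset is None:
            offset = np.zeros(len(segments))
        return np.exp(X @ self.pfit.beta_hat + offset)

    @property
    def aic(self) -> float:
        return self.pfit.aic


def build_offset(segments: pd.DataFrame, detection_fits: dict[str, DetectionFit],
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-segment log effective area, ``log(a * p * g0 * u)``.

    ``p`` is each platform's fitted segment-level average detection
    probability (1 for strip platforms); ``g0`` and ``u`` default to the
    ``g0``/``availability`` segment columns (1 where absent).  MRDS combined
    fits already fold their estimated g(0) into ``p``, in which case the
    ``g0`` column holds fixed multipliers only (e.g. an aerial platform's
    external estimate).  Returns (offset vector, provenance table).
    """
    a = segments["area"].to_numpy(dtype=float)
    if np.any(a <= 0):
        raise ValidationError("segment areas must be > 0")
    g0 = (segments["g0"].to_numpy(dtype=float) if "g0" in segments.columns
          else np.ones(len(segments)))
    u = (segments["availability"].to_numpy(dtype=float)
         if "availability" in segments.columns else np.ones(len(segments)))
    p = np.empty(len(segments))
    for i, (sid, pid) in enumerate(zip(segments["segment_id"],
                                       segments["platform_id"].astype(str))):
        if pid not in detection_fits:
            raise ValidationError(f"segment {sid!r}: no detection fit for "
                                  f"platform {pid!r}")
        fit = detection_fits[pid]
        if fit.key == "strip":
            p[i] = 1.0
            continue
        if sid not in fit.p_by_segment:
            raise ValidationError(f"segment {sid!r}: detection fit for "
                                  f"{pid!r} has no p for it")
        p[i] = fit.p_by_segment[sid]
    bad = (p <= 0) | ~np.isfinite(p) | (g0 <= 0) | (u <= 0)
    if bad.any():
        sid = segments["segment_id"].iloc[int(np.argmax(bad))]
        raise ValidationError(f"segment {sid!r}: nonpositive offset component")
    parts = pd.DataFrame({"segment_id": segments["segment_id"].to_numpy(),
                          "platform_id": segments["platform_id"].to_numpy(),
                          "area": a, "p": p, "g0": g0, "u": u})
    return np.log(a * p * g0 * u), parts


def _assemble_terms(spec: DsmSpec, platform_ids: tuple[str, ...]):
    terms = []
    if spec.variant == "B_factor_intercept":
        if len(platform_ids) < 2:
            raise ValidationError("variant B needs >= 2 platforms")
        terms.append(FactorTerm("platform_id"))
    else:
        terms.append(InterceptTerm())
    for c in spec.linear_terms:
        terms.append(LinearTerm(c))
    for s in spec.terms:
        if spec.variant == "C_factor_smooth" and s.by_factor is None:
            if len(platform_ids) < 2:
                raise ValidationError("variant C needs >= 2 platforms")
            s = SmoothSpec(s.covariates, basis="factor_smooth", k=s.k,
                           by_factor="platform_id",
                           shared_lambda=s.shared_lambda,
                           fixed_log_lambda=s.fixed_log_lambda,
                           fixed_ref_log_lambda=s.fixed_ref_log_lambda)
        terms.append(build_term(s))
    return terms


def fit_dsm(spec: DsmSpec, segments: pd.DataFrame,
            detection_fits: dict[str, DetectionFit]) -> DsmFit:
    """Assemble the offset and design for the requested variant and fit.

    ``segments`` must already be expanded for simultaneous protocols
    (duplicated segment rows, one per platform) and carry any fixed
    multiplier columns (``g0``, ``availability``).
    """
    platform_ids = tuple(sorted(segments["platform_id"].astype(str).unique()))
    offset, parts = build_offset(segments, detection_fits)
    seg = segments.copy()
    seg["platform_id"] = seg["platform_id"].astype(str)
    design = Design(_assemble_terms(spec, platform_ids)).fit(seg)
    y = seg["count"].to_numpy(dtype=float)
    pfit = gam_engine.fit_penalized(
        y, design, offset=offset, family=spec.family, power=spec.power,
        theta=spec.theta, estimate_power=(spec.family == "tweedie"
                                          and spec.power is None))
    return DsmFit(pfit=pfit, spec=spec, segments=seg, offset_parts=parts,
                  platform_ids=platform_ids, detection_fits=dict(detection_fits))


def pearson_chi2(observed: np.ndarray, expected: np.ndarray) -> float:
    """Pearson chi-square, ``sum (O - E)^2 / E``, over aggregation groups."""
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if np.any(E <= 0):
        raise ValidationError("expected counts must be > 0")
    return float(np.sum((O - E) ** 2 / E))


def observed_expected(fit: DsmFit, group_by: str) -> pd.DataFrame:
    """Observed vs expected counts aggregated by a covariate, with chi2.

    The grouping covariate need not be in the model — aggregating to a
    coarser level than the segment is what makes the diagnostic informative,
    since the smoother predicts small positive values where exact zeros were
    observed.  Empty groups are excluded with a warning.  The returned frame
    carries the Pearson chi-square in ``.attrs["chi2"]``.
    """
    if group_by not in fit.segments.columns:
        raise ValidationError(f"grouping covariate {group_by!r} not in segments")
    df = pd.DataFrame({"group": fit.segments[group_by].to_numpy(),
                       "observed": fit.pfit.y, "expected": fit.pfit.fitted})
    tab = df.groupby("group", dropna=False).sum().reset_index()
    empty = tab["expected"] <= 0
    if empty.any():
        warnings.warn(f"excluded {int(empty.sum())} empty group(s)")
        tab = tab.loc[~empty].reset_index(drop=True)
    tab.attrs["chi2"] = pearson_chi2(tab["observed"], tab["expected"])
    return tab


def per_platform_totals(fit: DsmFit) -> pd.DataFrame:
    """Observed and fitted totals per platform (a coarse fit diagnostic)."""
    return observed_expected(fit, "platform_id")


def dsm_report(fit: DsmFit) -> str:
    p = fit.pfit
    lines = [f"Density surface model — variant {fit.spec.variant}, "
             f"family {p.family}"]
    if p.family == "tweedie":
        lines.append(f"  Tweedie power p = {p.power}, dispersion phi = {p.scale:.4f}")
    if p.family == "negative_binomial":
        lines.append(f"  NB size theta = {p.theta:.4f}")
    lines.append(f"  n segments: {len(p.y)}   platforms: "
                 f"{', '.join(fit.platform_ids)}")
    lines.append(f"  REML score: {-p.reml_score:.4f}   AIC: {p.aic:.4f}   "
                 f"total EDF: {p.edf_total:.3f}")
    for name, sl in p.design.term_cols.items():
        lines.append(f"  term {name:28s} edf {p.edf_by_term[name]:7.3f}")
    for label, lam in zip(p.penalty_labels, p.lambda_hat):
        lines.append(f"  lambda[{label}] = {lam:.4g}")
    tot = per_platform_totals(fit)
    for _, r in tot.iterrows():
        lines.append(f"  platform {r['group']}: observed {r['observed']:.0f} "
                     f"fitted {r['expected']:.1f}")
    return "\n".join(lines)
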