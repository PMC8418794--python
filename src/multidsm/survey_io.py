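"""Data model and delimited-text I/O for multi-platform distance sampling surveys.

The analysis unit is the *segment*: a short contiguous piece of transect
effort with an associated covered area, a count of individuals, environmental
covariates and (optionally) an availability probability.  Each segment belongs
to a *platform* — a survey/protocol combination with its own detection
process (conventional or multiple-covariate line/point transect distance
sampling, double-observer line transects, or strip/plot transects where
detection is assumed certain).

Files are plain comma-separated UTF-8 text with a mandatory header row.
Missing values are empty fields; missing model covariates are rejected, not
imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("multidsm")

PROTOCOLS = ("line_cds", "line_mcds", "point", "strip", "mrds_io")

#: Columns with reserved meaning in segments.csv.
SEGMENT_COLUMNS = ("segment_id", "platform_id", "effort", "area", "count", "availability")
#: Columns with reserved meaning in observations.csv.
OBSERVATION_COLUMNS = ("object_id", "segment_id", "distance", "bin", "size",
                       "detected_by_1", "detected_by_2")


class SchemaError(ValueError):
    """A required column is missing or a file does not match its schema."""


class ValidationError(ValueError):
    """Table contents violate an invariant (bad distance, unknown id, ...)."""


@dataclass
class Platform:
    """A survey/protocol combination with its own detection process.

    Distances, truncation and bin cutpoints share one user-declared length
    unit; areas are in the square of that unit.
    """

    platform_id: str
    protocol: str
    truncation_w: float = np.nan
    bin_cutpoints: np.ndarray | None = None
    sides: str = "two"
    simultaneous_with: str | None = None
    #: fixed multiplier on detectability at zero distance (e.g. from a prior
    #: double-observer study) and its CV; ``None`` means estimated or 1.
    fixed_g0: float | None = None
    fixed_g0_cv: float = 0.0
    availability_cv: float = 0.0
    #: segment-level covariate names entering the detection scale parameter
    scale_covariates: tuple[str, ...] = ()
    key: str = "half_normal"

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValidationError(
                f"platform {self.platform_id!r}: unknown protocol {self.protocol!r}")
        if self.protocol != "strip" or np.isfinite(self.truncation_w):
            if not self.truncation_w > 0:
                raise ValidationError(
                    f"platform {self.platform_id!r}: truncation_w must be > 0")
        if self.bin_cutpoints is not None:
            c = np.asarray(self.bin_cutpoints, dtype=float)
            if c.ndim != 1 or len(c) < 2:
                raise ValidationError("bin_cutpoints needs >= 2 values")
            if not np.all(np.diff(c) > 0):
                raise ValidationError("bin_cutpoints must be strictly ascending")
            if c[0] != 0 or not np.isclose(c[-1], self.truncation_w):
                raise ValidationError(
                    "bin_cutpoints must start at 0 and end at truncation_w")
            self.bin_cutpoints = c
        if self.sides not in ("one", "two"):
            raise ValidationError("sides must be 'one' or 'two'")
        self.scale_covariates = tuple(self.scale_covariates)

    @property
    def is_binned(self) -> bool:
        return self.bin_cutpoints is not None

    @property
    def n_sides(self) -> int:
        return 1 if self.sides == "one" else 2


def load_platforms(source: str | Path | dict) -> dict[str, Platform]:
    """Read the platform registry from a YAML file (or an equivalent dict).

    Keys per platform: ``protocol``, ``truncation``, ``cutpoints``, ``sides``,
    ``simultaneous_with``, ``g0``, ``g0_cv``, ``availability_cv``,
    ``scale_covariates``, ``key``.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            source = yaml.safe_load(fh)
    platforms: dict[str, Platform] = {}
    for pid, cfg in source.items():
        cfg = dict(cfg or {})
        platforms[pid] = Platform(
            platform_id=pid,
            protocol=cfg.get("protocol", "line_cds"),
            truncation_w=float(cfg.get("truncation", np.nan)),
            bin_cutpoints=(np.asarray(cfg["cutpoints"], dtype=float)
                           if cfg.get("cutpoints") is not None else None),
            sides=cfg.get("sides", "two"),
            simultaneous_with=cfg.get("simultaneous_with"),
            fixed_g0=cfg.get("g0"),
            fixed_g0_cv=float(cfg.get("g0_cv", 0.0)),
            availability_cv=float(cfg.get("availability_cv", 0.0)),
            scale_covariates=tuple(cfg.get("scale_covariates", ()) or ()),
            key=cfg.get("key", "half_normal"),
        )
    # cross-check simultaneity symmetry
    for p in platforms.values():
        s = p.simultaneous_with
        if s is not None and s not in platforms:
            raise ValidationError(
                f"platform {p.platform_id!r}: simultaneous_with {s!r} unknown")
    return platforms


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def validate_segments(segments: pd.DataFrame,
                      platforms: dict[str, Platform]) -> pd.DataFrame:
    """Validate and normalise a segment table.

    Adds defaults (``availability`` = 1), derives ``area`` =
    sides * truncation_w * effort where absent, and checks invariants.
    """
    _require_columns(segments, ["segment_id", "platform_id"], "segments")
    seg = segments.copy()
    if seg["segment_id"].duplicated().any():
        raise ValidationError("segments: duplicate segment_id values")
    unknown = set(seg["platform_id"].astype(str)) - set(platforms)
    if unknown:
        raise ValidationError(f"segments reference unknown platform_id {sorted(unknown)}")
    if "availability" not in seg.columns:
        seg["availability"] = 1.0
    seg["availability"] = seg["availability"].astype(float).fillna(1.0)
    if not ((seg["availability"] > 0) & (seg["availability"] <= 1)).all():
        raise ValidationError("availability must lie in (0, 1]")
    if "area" not in seg.columns or seg["area"].isna().any():
        if "effort" not in seg.columns:
            raise SchemaError("segments: need 'area' or 'effort' to derive it")
        w = seg["platform_id"].map(lambda k: platforms[str(k)].truncation_w)
        ns = seg["platform_id"].map(lambda k: platforms[str(k)].n_sides)
        derived = ns.astype(float) * w.astype(float) * seg["effort"].astype(float)
        if "area" in seg.columns:
            seg["area"] = seg["area"].astype(float).fillna(derived)
        else:
            seg["area"] = derived
    seg["area"] = seg["area"].astype(float)
    if not (seg["area"] > 0).all():
        raise ValidationError("segment areas must be > 0")
    return seg


def truncate(observations: pd.DataFrame, platform: Platform) -> pd.DataFrame:
    """Drop observations beyond the platform's truncation distance.

    Binned data are left unchanged (bins already respect the truncation).
    Negative distances are a validation error.
    """
    if platform.protocol == "strip" or platform.is_binned:
        return observations
    if "distance" not in observations.columns:
        raise SchemaError("observations: 'distance' column required for "
                          f"protocol {platform.protocol!r}")
    d = observations["distance"].astype(float)
    if (d < 0).any():
        raise ValidationError("negative distances in observations")
    keep = d <= platform.truncation_w
    dropped = int((~keep).sum())
    if dropped:
        log.info("platform %s: dropped %d observation(s) beyond w=%g",
                 platform.platform_id, dropped, platform.truncation_w)
    return observations.loc[keep].reset_index(drop=True)


def recount_segments(segments: pd.DataFrame, observations: pd.DataFrame,
                     platforms: dict[str, Platform]) -> pd.DataFrame:
    """Recompute per-segment counts ``n`` from attached observations.

    ``n`` is the sum of group sizes of the segment's (already truncated)
    observations; segments with no observations get 0.
    """
    seg = segments.copy()
    if len(observations):
        obs = observations.copy()
        if "size" not in obs.columns:
            obs["size"] = 1
        obs["size"] = obs["size"].astype(float)
        if (obs["size"] < 1).any():
            raise ValidationError("group sizes must be >= 1")
        totals = obs.groupby("segment_id")["size"].sum()
        unknown = set(totals.index) - set(seg["segment_id"])
        if unknown:
            raise ValidationError(
                f"observations reference unknown segment_id {sorted(unknown)[:5]}")
        seg["count"] = seg["segment_id"].map(totals).fillna(0.0)
    else:
        seg["count"] = 0.0
    return seg


def read_survey(segments_path: str | Path, observations_path: str | Path,
                platforms: dict[str, Platform],
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read, validate and truncate a survey; returns (segments, observations).

    Observations beyond each platform's truncation are dropped (with a logged
    count) and segment counts are recomputed from the surviving observations.
    """
    for p in (segments_path, observations_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    seg = pd.read_csv(segments_path)
    obs = pd.read_csv(observations_path)
    _require_columns(obs, ["segment_id"], "observations")
    seg = validate_segments(seg, platforms)
    seg_platform = seg.set_index("segment_id")["platform_id"].astype(str)
    missing = set(obs["segment_id"]) - set(seg_platform.index)
    if missing:
        raise ValidationError(
            f"observations reference unknown segment_id {sorted(missing)[:5]}")
    obs = obs.copy()
    obs["platform_id"] = obs["segment_id"].map(seg_platform)
    parts = []
    for pid, chunk in obs.groupby("platform_id", sort=False):
        parts.append(truncate(chunk.reset_index(drop=True), platforms[str(pid)]))
    obs = (pd.concat(parts, ignore_index=True) if parts
           else obs.iloc[0:0].copy())
    seg = recount_segments(seg, obs, platforms)
    return seg, obs


def write_survey(segments: pd.DataFrame, observations: pd.DataFrame,
                 segments_path: str | Path, observations_path: str | Path) -> None:
    segments.to_csv(segments_path, index=False)
    observations.to_csv(observations_path, index=False)


def duplicate_segments(segments: pd.DataFrame, observations: pd.DataFrame,
                       platforms: dict[str, Platform],
                       pair: tuple[str, str],
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand one physical segment set for two simultaneous protocols.

    Seabirds-at-sea style designs record two protocols on the same effort
    (e.g. birds on the water by line transect, flying birds by strip
    transect).  Each physical segment becomes two analysis rows — one per
    platform — carrying that platform's own count; shared environmental
    covariates are identical across the copies.  Segment ids are suffixed
    ``:{platform_id}`` so every analysis row keeps a unique id, and
    observation segment ids are remapped to the copy of their platform.

    ``observations`` must carry a ``platform_id`` column assigning each
    detection to one protocol of the pair.
    """
    a, b = pair
    for pid in pair:
        if pid not in platforms:
            raise ValidationError(f"unknown platform {pid!r}")
    if platforms[a].simultaneous_with != b and platforms[b].simultaneous_with != a:
        raise ValidationError(f"platforms {a!r} and {b!r} are not marked simultaneous")
    if "platform_id" not in observations.columns:
        raise SchemaError("observations need a platform_id column to split "
                          "counts between simultaneous protocols")
    out_seg = []
    for pid in pair:
        copy = segments.copy()
        copy["platform_id"] = pid
        copy["segment_id"] = segments["segment_id"].astype(str) + ":" + pid
        out_seg.append(copy)
    seg2 = pd.concat(out_seg, ignore_index=True)
    # per-platform areas may differ (e.g. different strip widths)
    if "effort" in seg2.columns:
        w = seg2["platform_id"].map(lambda k: platforms[str(k)].truncation_w)
        ns = seg2["platform_id"].map(lambda k: platforms[str(k)].n_sides)
        seg2["area"] = ns.astype(float) * w.astype(float) * seg2["effort"].astype(float)
    obs2 = observations.copy()
    bad = ~obs2["platform_id"].isin(pair)
    if bad.any():
        raise ValidationError("observations carry platform ids outside the pair")
    obs2["segment_id"] = (obs2["segment_id"].astype(str) + ":"
                          + obs2["platform_id"].astype(str))
    seg2 = recount_segments(seg2, obs2, platforms)
    return seg2, obs2


def validate_grid(grid: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Check a prediction grid: positive areas, all model covariates present."""
    _require_columns(grid, ["area"], "grid")
    if not (grid["area"].astype(float) > 0).all():
        raise ValidationError("grid cell areas must be > 0")
    _require_columns(grid, covariates, "grid")
    if grid[covariates].isna().any().any():
        raise ValidationError("grid has missing values in model covariates")
    return grid


def assign_bins(distances: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    """Map exact distances to bin indices.

    Bins are half-open ``[c_j, c_{j+1})`` except the last, which is closed at
    the truncation distance; distances outside ``[0, w]`` raise.
    """
    d = np.asarray(distances, dtype=float)
    if (d < 0).any() or (d > cutpoints[-1]).any():
        raise ValidationError("distance outside [0, truncation_w]")
    idx = np.searchsorted(cutpoints, d, side="right") - 1
    return np.minimum(idx, len(cutpoints) - 2)
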