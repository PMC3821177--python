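"""Design-based stereological density estimation.

Implements the optical-fractionator workflow: an unbiased counting frame
with top/right inclusion edges, numerical density from pooled disector
counts, a Cavalieri point-counting reference volume, and their combination

    E_n = N_v * V_ref,        N_v = sum(Q) / sum(V_dis),

where Q is the count in one disector and V_dis its volume.  Because N_v
and V_ref refer to a common tissue volume, the reported density E_n/V_ref
is numerically identical to N_v; both are carried so the identity can be
asserted on every estimate.

All estimators are pure functions of validated record types and are
invariant to the order of their input records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import validate_region
from .units import disector_volume_mm3, um_to_mm

__all__ = [
    "Frame",
    "DisectorSample",
    "SectionProfile",
    "DensityEstimate",
    "count_frame",
    "numerical_density",
    "numerical_density_se",
    "cavalieri_volume",
    "fractionator_estimate",
    "estimate_densities",
    "read_counting_records",
    "read_cavalieri_records",
    "write_density_csv",
    "COUNT_COLUMNS",
    "CAVALIERI_COLUMNS",
    "DENSITY_COLUMNS",
]


# ---------------------------------------------------------------------------
# counting frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Frame:
    """Axis-aligned counting frame.  Top and right edges are inclusion
    edges; bottom and left edges are exclusion edges."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self):
        if not (self.width > 0 and self.height > 0):
            raise ValueError("frame must have positive area")

    @property
    def x1(self) -> float:
        return self.x0 + self.width

    @property
    def y1(self) -> float:
        return self.y0 + self.height


def _touches_up_ray(x, y, r, ray_x, y0):
    """Disc touches the vertical ray x = ray_x, y >= y0 (closed)."""
    dy = np.maximum(y0 - y, 0.0)
    dx = ray_x - x
    return dx * dx + dy * dy <= r * r


def _touches_down_ray(x, y, r, ray_x, y1):
    """Disc touches the vertical ray x = ray_x, y <= y1 (closed)."""
    dy = np.maximum(y - y1, 0.0)
    dx = ray_x - x
    return dx * dx + dy * dy <= r * r


def _touches_hseg(x, y, r, seg_y, x0, x1):
    """Disc touches the horizontal segment y = seg_y, x0 <= x <= x1."""
    dx = np.clip(x, x0, x1) - x
    dy = seg_y - y
    return dx * dx + dy * dy <= r * r


def count_frame(profiles, frame: Frame, *, return_mask: bool = False):
    """Count 2D profiles under the unbiased-frame rule.

    A profile is a disc ``(x, y, r)``; ``r = 0`` gives the unique-point
    rule.  A profile is counted iff it intersects the closed frame and
    does not touch the classical forbidden line: the left edge extended
    upward to infinity, the bottom edge, and the downward extension of
    the right edge below the frame.  This is the frame-based statement
    of "entirely within, or touching the top or right edge"; the
    infinite extensions are what make an exhaustive tiling of the plane
    count every profile exactly once, including profiles tangent to a
    shared edge or straddling a tiling corner.

    Parameters
    ----------
    profiles : array-like, shape (n, 3) or (n, 2)
        Columns x, y[, radius]; missing radius means points.
    frame : Frame
    return_mask : bool
        If True, also return the boolean inclusion mask.
    """
    p = np.asarray(profiles, dtype=float)
    if p.size == 0:
        q = 0
        return (q, np.zeros(0, dtype=bool)) if return_mask else q
    if p.ndim == 1:
        p = p[None, :]
    x, y = p[:, 0], p[:, 1]
    r = p[:, 2] if p.shape[1] > 2 else np.zeros_like(x)

    if np.any(2 * r > min(frame.width, frame.height)):
        warnings.warn(
            "profile footprint larger than the counting frame; the "
            "inclusion rule is still applied",
            stacklevel=2,
        )

    # disc intersects the closed rectangle
    cx = np.clip(x, frame.x0, frame.x1)
    cy = np.clip(y, frame.y0, frame.y1)
    intersects = (cx - x) ** 2 + (cy - y) ** 2 <= r * r

    forbidden = (
        _touches_up_ray(x, y, r, frame.x0, frame.y0)
        | _touches_hseg(x, y, r, frame.y0, frame.x0, frame.x1)
        | _touches_down_ray(x, y, r, frame.x1, frame.y0)
    )

    mask = intersects & ~forbidden
    q = int(mask.sum())
    return (q, mask) if return_mask else q


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisectorSample:
    """One counting-frame placement swept through the guarded core of a
    section: geometry plus the raw count Q."""

    animal_id: str
    subdivision: str
    section_index: int
    frame_area_mm2: float
    disector_height_um: float
    q: int

    def __post_init__(self):
        validate_region(self.subdivision)
        if self.frame_area_mm2 <= 0:
            raise ValueError("frame_area_mm2 must be > 0")
        if self.disector_height_um <= 0:
            raise ValueError("disector_height_um must be > 0")
        if self.q < 0 or int(self.q) != self.q:
            raise ValueError("Q must be a non-negative integer")

    @property
    def v_dis_mm3(self) -> float:
        return disector_volume_mm3(self.frame_area_mm2, self.disector_height_um)


@dataclass(frozen=True)
class SectionProfile:
    """Per-section point-grid hits for Cavalieri volume estimation."""

    animal_id: str
    subdivision: str
    section_index: int
    points_hit: int
    area_per_point_mm2: float
    section_spacing_um: float

    def __post_init__(self):
        validate_region(self.subdivision)
        if self.points_hit < 0:
            raise ValueError("points_hit must be >= 0")
        if self.area_per_point_mm2 <= 0:
            raise ValueError("area_per_point_mm2 must be > 0")
        if self.section_spacing_um <= 0:
            raise ValueError("section_spacing_um must be > 0")


@dataclass(frozen=True)
class DensityEstimate:
    """Optical-fractionator output for one animal x subdivision."""

    animal_id: str
    subdivision: str
    nv_per_mm3: float
    vref_mm3: float
    en: float
    density_per_mm3: float
    n_disectors: int
    total_q: int
    vref_mode: str = "cavalieri"
    nv_se_per_mm3: float = field(default=float("nan"))

    def __post_init__(self):
        for name in ("nv_per_mm3", "vref_mm3", "en", "density_per_mm3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not math.isclose(self.en, self.nv_per_mm3 * self.vref_mm3,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("E_n must equal N_v * V_ref")
        if not math.isclose(self.density_per_mm3, self.nv_per_mm3,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("density must equal N_v (common reference volume)")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _check_single_unit(records, kind):
    if not records:
        raise ValueError(f"empty {kind} list")
    keys = {(s.animal_id, s.subdivision) for s in records}
    if len(keys) > 1:
        raise ValueError(
            f"{kind} records mix animals/subdivisions: {sorted(keys)}"
        )
    return keys.pop()


def numerical_density(samples: list[DisectorSample]) -> float:
    """Numerical density N_v = sum(Q) / sum(V_dis), in cells/mm^3.

    With a constant disector volume this is the classical
    sum(Q)/(n * V_dis); the ratio-of-sums form is its standard
    generalization when V_dis varies across samples.
    """
    _check_single_unit(samples, "disector sample")
    total_q = sum(s.q for s in samples)
    total_v = sum(s.v_dis_mm3 for s in samples)
    return total_q / total_v


def numerical_density_se(samples: list[DisectorSample]) -> float:
    """Poisson-count standard error of N_v: sqrt(sum Q)/sum(V_dis)."""
    _check_single_unit(samples, "disector sample")
    total_q = sum(s.q for s in samples)
    total_v = sum(s.v_dis_mm3 for s in samples)
    return math.sqrt(total_q) / total_v


def cavalieri_volume(profiles: list[SectionProfile]) -> float:
    """Cavalieri reference volume, mm^3.

    V_ref = sum(points_hit * area_per_point) * section_spacing.  The
    estimator's contract requires one common spacing; unequal spacing is
    rejected rather than approximated.
    """
    _check_single_unit(profiles, "section profile")
    spacings = {p.section_spacing_um for p in profiles}
    if len(spacings) > 1 and not np.allclose(
        sorted(spacings), min(spacings), rtol=1e-9
    ):
        raise ValueError(
            f"inconsistent section spacing across profiles: {sorted(spacings)}"
        )
    spacing_mm = um_to_mm(profiles[0].section_spacing_um)
    area_mm2 = sum(p.points_hit * p.area_per_point_mm2 for p in profiles)
    return area_mm2 * spacing_mm


def fractionator_estimate(
    samples: list[DisectorSample],
    profiles: list[SectionProfile] | None = None,
) -> DensityEstimate:
    """Combine disector counts and reference volume into a DensityEstimate.

    When no Cavalieri profiles are supplied, V_ref defaults to the total
    sampled disector volume ("sampled-volume mode"); the estimate is
    labeled accordingly.  Density always equals N_v: the common reference
    volume cancels, which is what makes the procedure robust to volume
    changes of the nucleus.
    """
    animal, subdiv = _check_single_unit(samples, "disector sample")
    nv = numerical_density(samples)
    se = numerical_density_se(samples)
    if profiles is not None:
        p_animal, p_subdiv = _check_single_unit(profiles, "section profile")
        if (p_animal, p_subdiv) != (animal, subdiv):
            raise ValueError(
                f"samples are for {(animal, subdiv)} but profiles for "
                f"{(p_animal, p_subdiv)}"
            )
        vref = cavalieri_volume(profiles)
        mode = "cavalieri"
    else:
        vref = sum(s.v_dis_mm3 for s in samples)
        mode = "sampled-volume"
    total_q = sum(s.q for s in samples)
    return DensityEstimate(
        animal_id=animal,
        subdivision=subdiv,
        nv_per_mm3=nv,
        vref_mm3=vref,
        en=nv * vref,
        density_per_mm3=nv,
        n_disectors=len(samples),
        total_q=total_q,
        vref_mode=mode,
        nv_se_per_mm3=se,
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

COUNT_COLUMNS = [
    "animal_id", "subdivision", "section_index", "frame_x_um", "frame_y_um",
    "frame_area_mm2", "section_thickness_um", "guard_um_top",
    "guard_um_bottom", "disector_height_um", "Q",
]

CAVALIERI_COLUMNS = [
    "animal_id", "subdivision", "section_index", "points_hit",
    "area_per_point_mm2", "section_spacing_um",
]

DENSITY_COLUMNS = [
    "animal_id", "subdivision", "Nv_per_mm3", "Vref_mm3", "En",
    "density_per_mm3", "n_disectors", "total_Q", "vref_mode",
]


def _require_columns(df: pd.DataFrame, columns, path):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_counting_records(path) -> pd.DataFrame:
    """Read and validate a disector counting-record CSV (one row per
    disector placement)."""
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, path)
    df["animal_id"] = df["animal_id"].astype(str)
    for sub in df["subdivision"].unique():
        validate_region(sub)
    rows_to_samples(df)  # raises on any invalid record
    return df


def read_cavalieri_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CAVALIERI_COLUMNS, path)
    df["animal_id"] = df["animal_id"].astype(str)
    for sub in df["subdivision"].unique():
        validate_region(sub)
    return df


def rows_to_samples(df: pd.DataFrame) -> list[DisectorSample]:
    return [
        DisectorSample(
            animal_id=str(r.animal_id),
            subdivision=r.subdivision,
            section_index=int(r.section_index),
            frame_area_mm2=float(r.frame_area_mm2),
            disector_height_um=float(r.disector_height_um),
            q=int(r.Q),
        )
        for r in df.itertuples(index=False)
    ]


def rows_to_profiles(df: pd.DataFrame) -> list[SectionProfile]:
    return [
        SectionProfile(
            animal_id=str(r.animal_id),
            subdivision=r.subdivision,
            section_index=int(r.section_index),
            points_hit=int(r.points_hit),
            area_per_point_mm2=float(r.area_per_point_mm2),
            section_spacing_um=float(r.section_spacing_um),
        )
        for r in df.itertuples(index=False)
    ]


def estimate_densities(
    counts: pd.DataFrame,
    cavalieri: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the fractionator for every animal x subdivision in *counts*.

    Returns one row per animal x subdivision with the DENSITY_COLUMNS
    schema.  Row order of the inputs is irrelevant; output is sorted by
    (animal_id, subdivision).
    """
    out = []
    for (animal, subdiv), grp in counts.groupby(
        ["animal_id", "subdivision"], sort=True
    ):
        samples = rows_to_samples(grp)
        profiles = None
        if cavalieri is not None:
            sel = cavalieri[
                (cavalieri["animal_id"].astype(str) == str(animal))
                & (cavalieri["subdivision"] == subdiv)
            ]
            if len(sel):
                profiles = rows_to_profiles(sel)
        est = fractionator_estimate(samples, profiles)
        out.append(
            {
                "animal_id": est.animal_id,
                "subdivision": est.subdivision,
                "Nv_per_mm3": est.nv_per_mm3,
                "Vref_mm3": est.vref_mm3,
                "En": est.en,
                "density_per_mm3": est.density_per_mm3,
                "n_disectors": est.n_disectors,
                "total_Q": est.total_q,
                "vref_mode": est.vref_mode,
            }
        )
    return pd.DataFrame(out, columns=DENSITY_COLUMNS)


def write_density_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
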