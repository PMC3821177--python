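"""Synthetic tissue: ground-truth 3D cell fields and disector records.

The study's raw counting data are not published, so every downstream
stage is validated against simulated tissue with known density.  The
generator emulates exactly what the analysis assumes:

* 3D soma centroids as a homogeneous Poisson point process (optionally a
  Matern-II hard-core process as a realism check),
* transverse sectioning into 25-50 um slabs, with somata modeled as
  spheres so cells cut by a knife plane appear as fragments ("caps") in
  neighbouring slabs,
* optical-disector sampling: square counting frames placed without
  overlap in the section plane, a guard zone at each z-face, and cells
  counted by their centroid falling in the guarded core under the
  unbiased frame rule (top/right inclusion edges),
* a cohort layer in which each region's true density rises linearly
  with age plus Gaussian between-animal noise.

A naive 2D profile count (every visible profile, fragments included,
divided by frame area x thickness) is provided as the biased comparator:
it overestimates by the factor (t + 2r)/t, so thinner sections
overestimate more — the artifact the guarded disector removes.

For the homogeneous Poisson process, counts in non-overlapping disectors
are independent Poisson(lambda * V_dis) variables, so the cohort
generator offers an exact "counts" route that draws Q directly without
materializing points; the "points" route builds the full 3D scenes.  The
two routes produce identically distributed records in Poisson mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .regions import REGIONS
from .stereology import COUNT_COLUMNS, Frame, count_frame
from .units import UM_PER_MM, disector_volume_mm3, um3_to_mm3

__all__ = [
    "SyntheticScene",
    "Slab",
    "CohortConfig",
    "generate_scene",
    "section_scene",
    "place_frames",
    "sample_disectors",
    "naive_profile_count",
    "estimate_scene_density",
    "naive_scene_density",
    "synthesize_cohort",
    "synthesize_true_densities",
    "thickness_bias_experiment",
    "DEMOGRAPHICS_COLUMNS",
    "TRUTH_COLUMNS",
]

DEMOGRAPHICS_COLUMNS = ["animal_id", "age_months", "sex", "thickness_um", "group"]
TRUTH_COLUMNS = ["animal_id", "subdivision", "true_density_per_mm3"]

#: Section thicknesses used in the source cohort.
STANDARD_THICKNESSES_UM = (25.0, 40.0, 50.0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticScene:
    """Ground-truth 3D cell field.

    ``true_density`` is the *realized* density (points per unit volume),
    not the process intensity, so estimator bias checks compare against
    what is actually in the box.
    """

    scene_id: str
    bounds_um: tuple[float, float, float]
    points_um: np.ndarray  # (n, 3)
    soma_radius_um: float
    true_density_per_mm3: float

    def __post_init__(self):
        b = np.asarray(self.bounds_um, dtype=float)
        if b.shape != (3,) or np.any(b <= 0):
            raise ValueError(f"degenerate bounds {self.bounds_um}")
        if not 0 < self.soma_radius_um < min(b):
            raise ValueError("soma_radius must be positive and smaller than "
                             "the smallest box dimension")
        p = self.points_um
        if len(p) and (np.any(p < 0) or np.any(p > b)):
            raise ValueError("points outside scene bounds")
        expected = len(p) / um3_to_mm3(float(np.prod(b))) if len(p) else 0.0
        if not math.isclose(self.true_density_per_mm3, expected,
                            rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("true_density inconsistent with point count")

    @property
    def volume_mm3(self) -> float:
        return um3_to_mm3(float(np.prod(self.bounds_um)))


def generate_scene(
    bounds_um,
    true_density_per_mm3: float,
    soma_radius_um: float = 6.0,
    seed=None,
    *,
    hard_core: bool = False,
    scene_id: str = "scene",
) -> SyntheticScene:
    """Draw a random cell field at the given intensity (cells/mm^3).

    Default is a homogeneous Poisson process.  With ``hard_core=True`` a
    Matern-II process with minimum centroid separation 2*soma_radius is
    used; the proposal intensity is solved from the target intensity via
    the Matern-II retention formula, so the realized mean density still
    matches the request (up to boundary effects).
    """
    b = np.asarray(bounds_um, dtype=float)
    if b.shape != (3,) or np.any(b <= 0):
        raise ValueError(f"degenerate bounds {bounds_um!r}")
    if true_density_per_mm3 < 0:
        raise ValueError(f"negative density {true_density_per_mm3}")
    rng = _as_rng(seed)
    vol_um3 = float(np.prod(b))
    lam_um3 = true_density_per_mm3 / UM_PER_MM**3  # intensity per um^3

    if not hard_core:
        n = rng.poisson(lam_um3 * vol_um3)
        pts = rng.uniform(0.0, 1.0, size=(n, 3)) * b
    else:
        # Matern II: lam_target = (1 - exp(-lam_p * v_h)) / v_h
        v_h = 4.0 / 3.0 * math.pi * (2.0 * soma_radius_um) ** 3
        x = lam_um3 * v_h
        if x >= 1.0:
            raise ValueError(
                "target density too high for hard-core separation "
                f"2r = {2 * soma_radius_um} um (packing limit exceeded)"
            )
        lam_p = -math.log1p(-x) / v_h if x > 0 else 0.0
        n_prop = rng.poisson(lam_p * vol_um3)
        props = rng.uniform(0.0, 1.0, size=(n_prop, 3)) * b
        marks = rng.uniform(size=n_prop)
        keep = np.ones(n_prop, dtype=bool)
        if n_prop > 1:
            tree = cKDTree(props)
            for i, j in tree.query_pairs(2.0 * soma_radius_um):
                if marks[i] < marks[j]:
                    keep[j] = False
                else:
                    keep[i] = False
        pts = props[keep]

    density = len(pts) / um3_to_mm3(vol_um3)
    return SyntheticScene(
        scene_id=scene_id,
        bounds_um=tuple(b),
        points_um=pts,
        soma_radius_um=soma_radius_um,
        true_density_per_mm3=density,
    )


# ---------------------------------------------------------------------------
# sectioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Slab:
    """One tissue section cut from a scene.

    ``points_um`` are the somata whose centroid lies in [z0, z1);
    ``fragmented`` flags those whose soma sphere straddles a cut face;
    ``caps_um`` are centroids of cells from neighbouring slabs whose
    sphere pokes into this one (their visible fragments).
    """

    index: int
    z0_um: float
    z1_um: float
    footprint_um: tuple[float, float]
    points_um: np.ndarray
    fragmented: np.ndarray
    caps_um: np.ndarray
    soma_radius_um: float

    @property
    def thickness_um(self) -> float:
        return self.z1_um - self.z0_um


def section_scene(scene: SyntheticScene, thickness_um: float, axis: int = 2
                  ) -> list[Slab]:
    """Cut the scene into slabs of the given thickness along *axis*.

    Slabs tile the extent with no gaps or overlap; a trailing remainder
    becomes a thinner final slab.  Every slab face (including the outer
    block faces) is treated as a knife plane for fragmentation, so the
    expected fragmented fraction per slab is ~ 2r/t.
    """
    if thickness_um <= 0:
        raise ValueError("thickness must be > 0")
    extent = scene.bounds_um[axis]
    if thickness_um >= extent:
        warnings.warn(
            f"thickness {thickness_um} um >= scene extent {extent} um; "
            "returning a single slab", stacklevel=2,
        )
        thickness_um = extent

    order = [i for i in range(3) if i != axis]
    footprint = (scene.bounds_um[order[0]], scene.bounds_um[order[1]])
    pts = scene.points_um
    z = pts[:, axis]
    r = scene.soma_radius_um

    edges = np.arange(0.0, extent, thickness_um)
    if extent - edges[-1] < 1e-9:  # exact tiling
        edges = edges[:-1]
    uppers = np.append(edges[1:], extent)

    slabs = []
    for k, (z0, z1) in enumerate(zip(edges, uppers)):
        last = k == len(edges) - 1
        member = (z >= z0) & ((z <= z1) if last else (z < z1))
        frag = member & ((z - r < z0) | (z + r > z1))
        cap = ~member & (z + r > z0) & (z - r < z1)
        # reorder columns to (x, y, z) with x, y the in-plane axes
        cols = order + [axis]
        slabs.append(Slab(
            index=k, z0_um=float(z0), z1_um=float(z1),
            footprint_um=footprint,
            points_um=pts[member][:, cols],
            fragmented=frag[member],
            caps_um=pts[cap][:, cols],
            soma_radius_um=r,
        ))
    return slabs


# ---------------------------------------------------------------------------
# disector sampling
# ---------------------------------------------------------------------------

def place_frames(
    footprint_um,
    frame_side_um: float,
    n_frames: int,
    rng,
    *,
    placement: str = "uniform",
    max_tries: int = 10_000,
) -> np.ndarray:
    """Lower-left corners of non-overlapping square frames in a footprint.

    ``placement='uniform'`` draws corners uniformly at random, rejecting
    overlaps; ``'systematic'`` lays a systematic grid with a random
    offset.  Raises if the frames cannot fit, naming the limiting
    dimension.
    """
    w, h = footprint_um
    s = frame_side_um
    for dim, ext in (("x", w), ("y", h)):
        if s > ext:
            raise ValueError(
                f"frame side {s:.1f} um exceeds slab footprint {dim} extent "
                f"{ext:.1f} um ({dim} is the limiting dimension)"
            )
    if n_frames * s * s > w * h:
        raise ValueError(
            f"{n_frames} non-overlapping frames of side {s:.1f} um cannot "
            f"fit a {w:.0f} x {h:.0f} um footprint (area is the limiting "
            "dimension)"
        )
    rng = _as_rng(rng)

    if placement == "systematic":
        nx = max(1, int(w // s))
        ny = max(1, int(math.ceil(n_frames / nx)))
        if ny * s > h or nx * ny < n_frames:
            raise ValueError(
                "systematic grid cannot host the requested frames; the "
                f"y extent {h:.0f} um is the limiting dimension"
            )
        ox = rng.uniform(0.0, w - nx * s) if w > nx * s else 0.0
        oy = rng.uniform(0.0, h - ny * s) if h > ny * s else 0.0
        grid = [(ox + i * s, oy + j * s) for j in range(ny) for i in range(nx)]
        return np.asarray(grid[:n_frames], dtype=float)

    # dart throwing with restarts: an unlucky early frame can block every
    # remaining position, so a stuck configuration is discarded wholesale
    tries_per_frame = max(50, max_tries // 100)
    for _restart in range(max_tries // tries_per_frame):
        corners: list[tuple[float, float]] = []
        while len(corners) < n_frames:
            for _ in range(tries_per_frame):
                cx = rng.uniform(0.0, w - s)
                cy = rng.uniform(0.0, h - s)
                if all(abs(cx - px) >= s or abs(cy - py) >= s
                       for px, py in corners):
                    corners.append((cx, cy))
                    break
            else:
                break  # restart from scratch
        if len(corners) == n_frames:
            return np.asarray(corners, dtype=float)
    raise ValueError(
        f"could not place {n_frames} non-overlapping frames of side "
        f"{s:.1f} um in a {w:.0f} x {h:.0f} um footprint after {max_tries} "
        "attempts (footprint area is the limiting dimension)"
    )


def sample_disectors(
    slab: Slab,
    frame_area_mm2: float,
    guard_fraction: float,
    n_disectors: int,
    seed=None,
    *,
    placement: str = "uniform",
) -> pd.DataFrame:
    """Count cells in randomly placed optical disectors within a slab.

    Returns one row per disector with the counting-record geometry
    columns (identity columns are stamped by the cohort generator).  A
    cell is counted iff its centroid z lies in the guarded core and its
    centroid passes the unbiased frame rule in the section plane;
    fragments whose centroid sits outside the core are never counted.
    """
    if not 0 <= guard_fraction < 0.5:
        raise ValueError("guard_fraction must be in [0, 0.5)")
    t = slab.thickness_um
    guard_um = guard_fraction * t
    height_um = t - 2.0 * guard_um
    if height_um <= 0:
        raise ValueError("guard zones leave no disector height")

    rng = _as_rng(seed)
    side_um = math.sqrt(frame_area_mm2) * UM_PER_MM
    corners = place_frames(slab.footprint_um, side_um, n_disectors, rng,
                           placement=placement)

    z = slab.points_um[:, 2]
    in_core = (z >= slab.z0_um + guard_um) & (z < slab.z1_um - guard_um + 1e-12)
    core_xy = slab.points_um[in_core][:, :2]

    rows = []
    for fx, fy in corners:
        q = count_frame(core_xy, Frame(fx, fy, side_um, side_um))
        rows.append({
            "section_index": slab.index,
            "frame_x_um": fx,
            "frame_y_um": fy,
            "frame_area_mm2": frame_area_mm2,
            "section_thickness_um": t,
            "guard_um_top": guard_um,
            "guard_um_bottom": guard_um,
            "disector_height_um": height_um,
            "Q": q,
        })
    return pd.DataFrame(rows)


def naive_profile_count(slab: Slab, frame: Frame) -> int:
    """Biased 2D count: every profile visible in the slab, fragments
    included, under the same frame rule.  Profiles are taken at the soma
    equatorial radius."""
    r = slab.soma_radius_um
    xy = np.vstack([slab.points_um[:, :2], slab.caps_um[:, :2]]) \
        if len(slab.caps_um) else slab.points_um[:, :2]
    if len(xy) == 0:
        return 0
    profiles = np.column_stack([xy, np.full(len(xy), r)])
    return count_frame(profiles, frame)


# ---------------------------------------------------------------------------
# scene-level density estimates (validation harness)
# ---------------------------------------------------------------------------

def estimate_scene_density(
    scene: SyntheticScene,
    thickness_um: float,
    guard_fraction: float,
    frame_area_mm2: float,
    disectors_per_slab: int,
    seed=None,
) -> float:
    """Guarded optical-disector density estimate of a scene, cells/mm^3."""
    rng = _as_rng(seed)
    total_q = 0
    total_v = 0.0
    for slab in section_scene(scene, thickness_um):
        rec = sample_disectors(slab, frame_area_mm2, guard_fraction,
                               disectors_per_slab, rng)
        total_q += int(rec["Q"].sum())
        total_v += float(
            (rec["frame_area_mm2"] * rec["disector_height_um"] / UM_PER_MM).sum()
        )
    return total_q / total_v


def naive_scene_density(
    scene: SyntheticScene,
    thickness_um: float,
    frame_area_mm2: float,
    frames_per_slab: int,
    seed=None,
) -> float:
    """Naive profile-count density (count/area/thickness), cells/mm^3.

    Counts every visible profile including fragments; no guard zones.
    Overestimates by ~ (t + 2r)/t, worse for thinner sections.
    """
    rng = _as_rng(seed)
    side_um = math.sqrt(frame_area_mm2) * UM_PER_MM
    n = 0
    v = 0.0
    for slab in section_scene(scene, thickness_um):
        corners = place_frames(slab.footprint_um, side_um, frames_per_slab, rng)
        for fx, fy in corners:
            n += naive_profile_count(slab, Frame(fx, fy, side_um, side_um))
            v += disector_volume_mm3(frame_area_mm2, slab.thickness_um)
    return n / v


def thickness_bias_experiment(
    true_density_per_mm3: float,
    thicknesses_um=(25.0, 50.0),
    n_replicates: int = 500,
    seed=None,
    *,
    scene_xy_um: float = 400.0,
    n_sections: int = 4,
    soma_radius_um: float = 6.0,
    guard_fraction: float = 0.2,
    frame_area_mm2: float = 0.01,
    disectors_per_slab: int = 4,
) -> pd.DataFrame:
    """Paired comparison of naive vs guarded estimates across thicknesses.

    Each replicate draws one scene per thickness (common depth so volumes
    match) and estimates its density both ways.  Returns per-thickness
    mean estimates; the naive column reproduces the thin-section
    overestimation, the disector column does not.
    """
    rng = _as_rng(seed)
    depth = n_sections * max(thicknesses_um)
    rows = []
    for rep in range(n_replicates):
        rep_seed = rng.integers(2**31)
        for t in thicknesses_um:
            r = np.random.default_rng(rep_seed)
            scene = generate_scene(
                (scene_xy_um, scene_xy_um, depth), true_density_per_mm3,
                soma_radius_um, r, scene_id=f"rep{rep}",
            )
            d_dis = estimate_scene_density(
                scene, t, guard_fraction, frame_area_mm2, disectors_per_slab, r)
            d_naive = naive_scene_density(
                scene, t, frame_area_mm2, disectors_per_slab, r)
            rows.append({
                "replicate": rep, "thickness_um": t,
                "true_density": scene.true_density_per_mm3,
                "disector": d_dis, "naive": d_naive,
            })
    return pd.DataFrame(rows)


def synthesize_animal_densities(config: "CohortConfig", rng=None
                                ) -> pd.DataFrame:
    """Per-animal estimated densities without materializing records.

    For the homogeneous Poisson process the pooled count over an
    animal's disectors is Poisson(lambda * sum V_dis), so the
    fractionator density sum(Q)/sum(V_dis) can be drawn in one step.
    This is the same distribution the full record-level route induces;
    it exists so replicate-heavy studies (type-I rates, power curves)
    stay cheap.  Returns truth plus the estimated density per
    animal x region along with ages.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    truth = synthesize_true_densities(config, rng)
    guard = config.guard_fraction
    t = truth["thickness_um"].to_numpy()
    height_um = t * (1.0 - 2.0 * guard)
    v_total = config.disectors_per_animal * disector_volume_mm3(
        config.frame_area_mm2, height_um)
    q = rng.poisson(truth["true_density_per_mm3"].to_numpy() * v_total)
    out = truth.copy()
    out["total_Q"] = q
    out["density_per_mm3"] = q / v_total
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cross-sectional aging cohort.

    Defaults emulate the source cohort: seven animals spanning 15-35
    monkey-years, nine regions whose parvalbumin-positive density rises
    linearly with age above a common baseline, 0.5 mm^2 counting frames,
    and 25/40/50 um sections with 20% guard zones.  The number of
    sections and disectors per animal is not reported anywhere for the
    original study; 8 sections x 4 disectors is this package's invented
    default (see docs/methods.md).
    """

    n_animals: int = 7
    age_range_months: tuple[float, float] = (180.0, 420.0)
    baseline_density: float | dict = 4000.0       # cells/mm^3 at min age
    slope: float | dict = 10.5                    # cells/mm^3 per month
    animal_sd: float = 500.0                      # between-animal noise
    section_thickness: float | tuple = 40.0       # um, per animal
    guard_fraction: float = 0.2
    frame_area_mm2: float = 0.5
    disectors_per_animal: int = 32
    seed: int = 0
    # structural knobs beyond the headline conditions
    n_sections: int = 8
    scene_xy_um: float = 2500.0
    soma_radius_um: float = 6.0
    hard_core: bool = False
    mode: str = "counts"                          # "counts" | "points"
    placement: str = "uniform"
    regions: tuple[str, ...] = REGIONS
    allow_nonstandard_thickness: bool = False

    def __post_init__(self):
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        lo, hi = self.age_range_months
        if not lo < hi:
            raise ValueError("age_range_months must satisfy min < max")
        if self.animal_sd < 0:
            raise ValueError("animal_sd must be >= 0")
        for region in self.regions:
            if self._region_value(self.baseline_density, region) < 0:
                raise ValueError("baseline_density must be >= 0")
        if not 0 <= self.guard_fraction < 0.5:
            raise ValueError("guard_fraction must be in [0, 0.5)")
        if self.frame_area_mm2 <= 0:
            raise ValueError("frame_area_mm2 must be > 0")
        if self.disectors_per_animal < 1 or self.n_sections < 1:
            raise ValueError("need >= 1 disector and >= 1 section")
        if self.mode not in ("counts", "points"):
            raise ValueError("mode must be 'counts' or 'points'")
        for t in self.thickness_per_animal():
            if t <= 0:
                raise ValueError("section thickness must be > 0")
            if (not self.allow_nonstandard_thickness
                    and t not in STANDARD_THICKNESSES_UM):
                raise ValueError(
                    f"section thickness {t} um is outside the study set "
                    f"{STANDARD_THICKNESSES_UM}; set "
                    "allow_nonstandard_thickness=True to override"
                )

    @staticmethod
    def _region_value(value, region):
        if isinstance(value, dict):
            return float(value[region])
        return float(value)

    def thickness_per_animal(self) -> list[float]:
        t = self.section_thickness
        if isinstance(t, (int, float)):
            return [float(t)] * self.n_animals
        t = list(t)
        if len(t) != self.n_animals:
            raise ValueError("section_thickness list must have one entry "
                             "per animal")
        return [float(x) for x in t]

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "age_range_months" in d:
            d["age_range_months"] = tuple(d["age_range_months"])
        if isinstance(d.get("section_thickness"), list):
            d["section_thickness"] = tuple(d["section_thickness"])
        if isinstance(d.get("regions"), list):
            d["regions"] = tuple(d["regions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def synthesize_true_densities(config: CohortConfig, rng=None) -> pd.DataFrame:
    """Ages and ground-truth densities for one cohort.

    Ages are evenly spaced over the configured range; each animal x
    region density is baseline + slope*(age - min age) + N(0, animal_sd),
    floored at zero.  Returns one row per animal x region plus the
    demographic columns used downstream.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    lo, hi = config.age_range_months
    ages = np.linspace(lo, hi, config.n_animals)
    thicknesses = config.thickness_per_animal()
    rows = []
    for i, age in enumerate(ages):
        animal = f"A{i + 1}"
        sex = "F" if i % 2 == 0 else "M"
        for region in config.regions:
            base = config._region_value(config.baseline_density, region)
            slope = config._region_value(config.slope, region)
            lam = base + slope * (age - lo) + rng.normal(0.0, config.animal_sd)
            rows.append({
                "animal_id": animal,
                "age_months": float(age),
                "sex": sex,
                "thickness_um": thicknesses[i],
                "subdivision": region,
                "true_density_per_mm3": max(lam, 0.0),
            })
    return pd.DataFrame(rows)


def _disectors_per_section(config: CohortConfig) -> list[int]:
    base, extra = divmod(config.disectors_per_animal, config.n_sections)
    return [base + (1 if k < extra else 0) for k in range(config.n_sections)]


def synthesize_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one cohort: (demographics, counting records, ground truth).

    The demographics table mirrors the study's demographic columns with
    ``group`` left blank (it is recomputed downstream from age).  The
    counting-record table passes the stereology module's validation
    as-is.  The ground-truth table records every density the generator
    used, for parameter-recovery checks.
    """
    root = np.random.SeedSequence(config.seed)
    truth_rng = np.random.default_rng(root.spawn(1)[0])
    truth_long = synthesize_true_densities(config, truth_rng)

    demographics = (
        truth_long[DEMOGRAPHICS_COLUMNS[:-1]]
        .drop_duplicates("animal_id")
        .assign(group="")
        .reset_index(drop=True)
    )
    truth = truth_long[TRUTH_COLUMNS].copy()

    per_section = _disectors_per_section(config)
    guard = config.guard_fraction
    count_frames_rows = []
    child_seeds = root.spawn(len(truth) + 1)[1:]

    for (row, seq) in zip(truth_long.itertuples(index=False), child_seeds):
        rng = np.random.default_rng(seq)
        t = row.thickness_um
        lam = row.true_density_per_mm3
        if config.mode == "points":
            depth = config.n_sections * t
            scene = generate_scene(
                (config.scene_xy_um, config.scene_xy_um, depth), lam,
                config.soma_radius_um, rng, hard_core=config.hard_core,
                scene_id=f"{row.animal_id}:{row.subdivision}",
            )
            slabs = section_scene(scene, t)
            for slab, n_dis in zip(slabs, per_section):
                if n_dis == 0:
                    continue
                rec = sample_disectors(slab, config.frame_area_mm2, guard,
                                       n_dis, rng, placement=config.placement)
                rec.insert(0, "animal_id", row.animal_id)
                rec.insert(1, "subdivision", row.subdivision)
                count_frames_rows.append(rec)
        else:
            # exact Poisson shortcut: Q ~ Poisson(lam * V_dis) per disector
            guard_um = guard * t
            height_um = t - 2.0 * guard_um
            v_dis = disector_volume_mm3(config.frame_area_mm2, height_um)
            side_um = math.sqrt(config.frame_area_mm2) * UM_PER_MM
            for k, n_dis in enumerate(per_section):
                if n_dis == 0:
                    continue
                corners = place_frames(
                    (config.scene_xy_um, config.scene_xy_um), side_um,
                    n_dis, rng, placement=config.placement)
                qs = rng.poisson(lam * v_dis, size=n_dis)
                rec = pd.DataFrame({
                    "animal_id": row.animal_id,
                    "subdivision": row.subdivision,
                    "section_index": k,
                    "frame_x_um": corners[:, 0],
                    "frame_y_um": corners[:, 1],
                    "frame_area_mm2": config.frame_area_mm2,
                    "section_thickness_um": t,
                    "guard_um_top": guard_um,
                    "guard_um_bottom": guard_um,
                    "disector_height_um": height_um,
                    "Q": qs,
                })
                count_frames_rows.append(rec)

    counts = pd.concat(count_frames_rows, ignore_index=True)[COUNT_COLUMNS]
    return demographics, counts, truth
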