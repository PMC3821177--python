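"""End-to-end orchestration: simulate -> estimate -> infer.

A `RunConfig` names either real input files (counting records,
optional Cavalieri records, demographics) or a `simulate` block driving
the synthetic-tissue generator — never both.  `run_pipeline` executes
the stages in order, writes every intermediate and final table under
the output directory, and records a manifest (config hash, seed, row
counts, package version) so identical configs reproduce byte-identical
outputs.

All randomness flows from the single root seed, split per stage with
`numpy.random.SeedSequence`, so each stage is individually
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aging import PVAgingModel
from .demographics import CUTOFF_HUMAN_YEARS
from .regions import REGIONS
from .stereology import (
    COUNT_COLUMNS,
    estimate_densities,
    read_cavalieri_records,
    read_counting_records,
)
from .synthetic import CohortConfig, synthesize_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("pvstereo")


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    out_dir: str
    counts_path: str | None = None
    cavalieri_path: str | None = None
    demographics_path: str | None = None
    simulate: CohortConfig | None = None
    r_cutoff: float = 0.7
    alpha_regression: float = 0.01
    alpha_mc: float = 0.05
    alpha_ttest: float = 0.01
    cutoff_human_years: float = CUTOFF_HUMAN_YEARS
    mc_iterations: int = 1000
    tail: str = "signed"
    seed: int = 0

    def __post_init__(self):
        has_files = self.counts_path is not None or \
            self.demographics_path is not None
        if has_files and self.simulate is not None:
            raise ValueError("config must name input files OR a simulate "
                             "block, not both")
        if not has_files and self.simulate is None:
            raise ValueError("config names neither input files nor a "
                             "simulate block")
        if has_files and (self.counts_path is None
                          or self.demographics_path is None):
            raise ValueError("file mode needs both counts and demographics "
                             "paths")
        for name in ("alpha_regression", "alpha_mc", "alpha_ttest"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.r_cutoff < 1:
            raise ValueError("r_cutoff must be in [0, 1)")
        if self.mc_iterations < 1:
            raise ValueError("mc_iterations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        cfg = cls(**raw, simulate=None if sim is None
                  else CohortConfig.from_dict(sim))
        return cfg

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            sim = asdict(self.simulate)
            sim["age_range_months"] = list(sim["age_range_months"])
            sim["regions"] = list(sim["regions"])
            if isinstance(sim.get("section_thickness"), tuple):
                sim["section_thickness"] = list(sim["section_thickness"])
            d["simulate"] = sim
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def validate_inputs(counts: pd.DataFrame,
                    demographics: pd.DataFrame) -> list[dict]:
    """Machine-readable validation of the two input tables.

    Returns a list of violations, each naming the table, row, rule and
    message; an empty list means the inputs are valid.
    """
    violations: list[dict] = []

    def flag(table, row, rule, message):
        violations.append({"table": table, "row": row, "rule": rule,
                           "message": message})

    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        flag("counts", None, "columns", f"missing columns {missing}")
        return violations
    for c in ("animal_id", "age_months"):
        if c not in demographics.columns:
            flag("demographics", None, "columns", f"missing column {c!r}")
            return violations

    for i, row in counts.iterrows():
        if row["subdivision"] not in REGIONS:
            flag("counts", int(i), "subdivision",
                 f"unknown subdivision {row['subdivision']!r}")
        if not row["Q"] >= 0 or row["Q"] != int(row["Q"]):
            flag("counts", int(i), "Q",
                 f"Q must be a non-negative integer, got {row['Q']!r}")
        if not row["frame_area_mm2"] > 0:
            flag("counts", int(i), "frame_area",
                 f"frame_area_mm2 must be > 0, got {row['frame_area_mm2']!r}")
        if not row["disector_height_um"] > 0:
            flag("counts", int(i), "disector_height",
                 "disector_height_um must be > 0, got "
                 f"{row['disector_height_um']!r}")
        if row["disector_height_um"] > row["section_thickness_um"]:
            flag("counts", int(i), "disector_height",
                 "disector height exceeds section thickness")

    for i, row in demographics.iterrows():
        if not row["age_months"] > 0:
            flag("demographics", int(i), "age",
                 f"age_months must be > 0, got {row['age_months']!r}")

    known = set(demographics["animal_id"].astype(str))
    for animal in counts["animal_id"].astype(str).unique():
        if animal not in known:
            flag("counts", None, "referential_integrity",
                 f"animal_id {animal!r} absent from demographics")
    return violations


def _stage(name, t0, **info):
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all outputs under out_dir.

    Returns a bundle with every table plus the manifest.  Any stage
    error aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        t0 = time.perf_counter()
        cavalieri = None
        if config.simulate is not None:
            stage = "simulate"
            sim = config.simulate
            demographics, counts, truth = synthesize_cohort(sim)
            demographics.to_csv(out / "demographics.csv", index=False)
            counts.to_csv(out / "counting_records.csv", index=False)
            truth.to_csv(out / "ground_truth.csv", index=False)
            _stage(stage, t0, animals=len(demographics), records=len(counts))
        else:
            stage = "read-inputs"
            counts = read_counting_records(config.counts_path)
            demographics = pd.read_csv(config.demographics_path)
            if config.cavalieri_path is not None:
                cavalieri = read_cavalieri_records(config.cavalieri_path)
            _stage(stage, t0, records=len(counts))

        stage = "validate"
        t0 = time.perf_counter()
        violations = validate_inputs(counts, demographics)
        if violations:
            raise ValueError(f"input validation failed: {violations}")
        _stage(stage, t0, violations=0)

        stage = "estimate"
        t0 = time.perf_counter()
        densities = estimate_densities(counts, cavalieri)
        densities.to_csv(out / "densities.csv", index=False)
        _stage(stage, t0, estimates=len(densities))

        stage = "infer"
        t0 = time.perf_counter()
        model = PVAgingModel(densities, demographics,
                             cutoff_human_years=config.cutoff_human_years)
        infer_seed = int(
            np.random.SeedSequence(config.seed).spawn(2)[1]
            .generate_state(1, dtype=np.uint32)[0] % (2**31)
        )
        results = model.fit(
            mc_iterations=config.mc_iterations, seed=infer_seed,
            tail=config.tail, r_cutoff=config.r_cutoff,
            alpha_regression=config.alpha_regression,
            alpha_mc=config.alpha_mc, alpha_ttest=config.alpha_ttest,
        )
        results.save(out)
        _stage(stage, t0, regions=len(results.regressions))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "package": "pvstereo",
        "version": __version__,
        "config": config.to_jsonable(),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "row_counts": {
            "demographics": len(demographics),
            "counting_records": len(counts),
            "densities": len(densities),
            "regressions": len(results.regressions),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "demographics": demographics,
        "counts": counts,
        "densities": densities,
        "results": results,
        "manifest": manifest,
    }
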