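"""End-to-end orchestration: simulate -> quantify -> fit -> project -> compare.

A run is described by a flat TOML config naming an ordered subset of
stages with one parameter block per stage; CSV is the interchange format
between stages and a JSON manifest records inputs, outputs, parameters,
the global seed and package versions so deterministic stages can be
re-run bit-identically.
"""

from __future__ import annotations

import csv
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import numpy as np

from . import __version__
from .growth import BurdenRecord, GrowthFit, fit_growth
from .phago import Trajectory, fit_decay
from .survival import (
    DEFAULT_THRESHOLD_MM2,
    CohortProjection,
    ProjectionConfig,
    build_km,
    logrank,
    project_cohort,
)
from . import synthetic

logger = logging.getLogger("metkit")

COHORT_HEADER = ["mouse_id", "group", "day", "area_mm2", "nodule_count"]

STAGES = ("simulate", "quant", "fit", "project", "compare", "phago")

GROUP_PRESETS = {
    "untreated": synthetic.untreated_power_spec,
    "treated": synthetic.treated_power_spec,
    "exponential": synthetic.exponential_spec,
}


class PipelineError(RuntimeError):
    """A stage could not run; the message names the stage."""


# ---------------------------------------------------------------------------
# cohort CSV interchange
# ---------------------------------------------------------------------------

def read_cohort_csv(path: str | Path) -> list[BurdenRecord]:
    """Read burden records from a cohort CSV.

    Expected header: ``mouse_id,group,day,area_mm2,nodule_count`` (the
    last column optional and possibly empty).  Malformed rows are rejected
    with their line number.
    """
    path = Path(path)
    records: list[BurdenRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        required = ["mouse_id", "group", "day", "area_mm2"]
        missing = [c for c in required if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing columns: {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                nodules_raw = (row.get("nodule_count") or "").strip()
                rec = BurdenRecord(
                    mouse_id=row["mouse_id"],
                    group=row["group"],
                    day=float(row["day"]),
                    area_mm2=float(row["area_mm2"]),
                    nodule_count=int(nodules_raw) if nodules_raw else None,
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            records.append(rec)
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_cohort_csv(records: Iterable[BurdenRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_HEADER)
        for r in records:
            writer.writerow(
                [r.mouse_id, r.group, f"{r.day:g}",
                 repr(r.area_mm2),
                 "" if r.nodule_count is None else r.nodule_count]
            )


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Read a (day, burden) trajectory CSV with header ``day,burden``."""
    days, burden = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if not reader.fieldnames or not {"day", "burden"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns day,burden")
        for lineno, row in enumerate(reader, start=2):
            try:
                days.append(float(row["day"]))
                burden.append(float(row["burden"]))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    if not days:
        raise ValueError(f"{path}: no records")
    return Trajectory(days=tuple(days), burden=tuple(burden))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    stages: tuple[str, ...]
    seed: int
    outdir: Path
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}; valid: {STAGES}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValueError(f"stages must respect the order {STAGES}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        stages = tuple(raw.pop("stages", []))
        if not stages:
            raise ValueError(f"{path}: config must list at least one stage")
        seed = int(raw.pop("seed", 0))
        outdir = Path(raw.pop("outdir", "metkit_run"))
        return cls(stages=stages, seed=seed, outdir=outdir,
                   params={k: dict(v) for k, v in raw.items() if isinstance(v, dict)})


def _stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    ss = np.random.SeedSequence([global_seed, STAGES.index(stage), index])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _run_simulate(cfg: RunConfig, manifest: dict) -> None:
    p = cfg.params.get("simulate", {})
    groups = p.get("groups", ["untreated", "treated"])
    overrides: dict[str, Any] = {}
    if "days" in p:
        overrides["sacrifice_days"] = tuple(float(d) for d in p["days"])
    for key in ("mice_per_day", "dispersion", "noise_gsd"):
        if key in p:
            overrides[key] = p[key]
    records: list[BurdenRecord] = []
    for i, g in enumerate(groups):
        if g not in GROUP_PRESETS:
            raise PipelineError(
                f"stage 'simulate': unknown group preset {g!r}; valid: {sorted(GROUP_PRESETS)}"
            )
        spec = GROUP_PRESETS[g](seed=_stage_seed(cfg.seed, "simulate", i), **overrides)
        recs, _ = synthetic.gen_cohort(spec)
        records.extend(recs)
    out = cfg.outdir / "cohort.csv"
    write_cohort_csv(records, out)
    logger.info("simulate: %d records across groups %s -> %s", len(records), groups, out)
    manifest["outputs"]["cohort_csv"] = str(out)


def _run_quant(cfg: RunConfig, manifest: dict) -> None:
    from .imaging import quantify_lobe
    from .synthetic import LobeImage
    from PIL import Image as PILImage

    p = cfg.params.get("quant", {})
    image_dir = p.get("images")
    if image_dir is None or not Path(image_dir).is_dir():
        raise PipelineError(f"stage 'quant': missing image directory {image_dir!r}")
    mm_per_px = float(p.get("mm_per_px", 0.05))
    min_px = int(p.get("min_nodule_px", 5))
    tumor_is_dark = bool(p.get("tumor_is_dark", True))
    rows = []
    paths = sorted(Path(image_dir).glob("*.png")) + sorted(Path(image_dir).glob("*.tif*"))
    if not paths:
        raise PipelineError(f"stage 'quant': no PNG/TIFF images in {image_dir!r}")
    for img_path in paths:
        arr = np.asarray(PILImage.open(img_path).convert("RGB"))
        mask = np.ones(arr.shape[:2], dtype=bool)
        mask_path = img_path.with_name(img_path.stem + "_mask.png")
        if mask_path.exists():
            mask = np.asarray(PILImage.open(mask_path).convert("L")) > 0
        if img_path.stem.endswith("_mask"):
            continue
        img = LobeImage(pixels=arr, mm_per_px=mm_per_px, lobe_mask=mask)
        m = quantify_lobe(img, tumor_is_dark=tumor_is_dark, min_nodule_px=min_px)
        rows.append([img_path.name, m.threshold_level, m.tumor_area_mm2,
                     m.lobe_area_mm2, m.tumor_fraction, m.nodule_count])
    out = cfg.outdir / "burdens.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["file", "threshold", "tumor_area_mm2", "lobe_area_mm2", "fraction", "nodules"])
        w.writerows(rows)
    logger.info("quant: %d lobes -> %s", len(rows), out)
    manifest["outputs"]["burdens_csv"] = str(out)


def _cohort_input(cfg: RunConfig, stage: str) -> list[BurdenRecord]:
    p = cfg.params.get(stage, {})
    path = Path(p.get("cohort", cfg.outdir / "cohort.csv"))
    if not path.exists():
        raise PipelineError(f"stage '{stage}': missing cohort CSV {path}")
    return read_cohort_csv(path)


def _run_fit(cfg: RunConfig, manifest: dict) -> dict[str, GrowthFit]:
    p = cfg.params.get("fit", {})
    family = p.get("family", "power")
    records = _cohort_input(cfg, "fit")
    fits: dict[str, GrowthFit] = {}
    payload = {}
    for group in sorted({r.group for r in records}):
        recs = [r for r in records if r.group == group]
        fit = fit_growth(recs, family=family, area_floor=float(p.get("area_floor", 0.0)))
        fits[group] = fit
        payload[group] = {
            "family": fit.family, "A0": fit.amplitude, "exponent": fit.exponent,
            "stderr": fit.stderr_exponent, "n_obs": fit.n_obs,
            "n_zero_excluded": fit.n_zero_excluded,
        }
        logger.info("fit[%s]: %s A0=%.4g exponent=%.4g (n=%d)",
                    group, family, fit.amplitude, fit.exponent, fit.n_obs)
    out = cfg.outdir / "fits.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(payload, indent=2))
    manifest["outputs"]["fits_json"] = str(out)
    return fits


def _run_project(cfg: RunConfig, manifest: dict, fits: dict[str, GrowthFit]) -> None:
    p = cfg.params.get("project", {})
    threshold = float(p.get("threshold_mm2", DEFAULT_THRESHOLD_MM2))
    records = _cohort_input(cfg, "project")
    if not fits:
        fits_path = Path(p.get("fits", cfg.outdir / "fits.json"))
        if not fits_path.exists():
            raise PipelineError(f"stage 'project': missing fits JSON {fits_path}")
        raw = json.loads(fits_path.read_text())
        fits = {
            g: GrowthFit(family=v["family"], amplitude=v["A0"], exponent=v["exponent"],
                         n_obs=max(int(v.get("n_obs", 2)), 2))
            for g, v in raw.items()
        }
    proj_rows = []
    for group in sorted({r.group for r in records}):
        if group not in fits:
            raise PipelineError(f"stage 'project': no fit for group {group!r}")
        config = ProjectionConfig.from_fit(fits[group], threshold_mm2=threshold)
        proj = project_cohort([r for r in records if r.group == group], config)
        for r in proj.results:
            proj_rows.append([r.mouse_id, group, r.measurement_day, r.amplitude_i,
                              r.crossing_day, r.event_time, int(r.event), r.flag])
        km = build_km(proj.event_times, proj.events)
        km_path = cfg.outdir / f"km_{group}.csv"
        with open(km_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", "survival", "at_risk"])
            for t, s, n in zip(km.event_times, km.survival_prob, km.n_at_risk):
                w.writerow([t, s, n])
        logger.info("project[%s]: median projected survival %.2f d -> %s",
                    group, proj.median_crossing_day, km_path)
        manifest["outputs"][f"km_{group}_csv"] = str(km_path)
    out = cfg.outdir / "projections.csv"
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mouse_id", "group", "day", "amplitude", "crossing_day",
                    "event_time", "event", "flag"])
        w.writerows(proj_rows)
    manifest["outputs"]["projections_csv"] = str(out)


def _run_compare(cfg: RunConfig, manifest: dict) -> None:
    p = cfg.params.get("compare", {})
    proj_path = Path(p.get("projections", cfg.outdir / "projections.csv"))
    if not proj_path.exists():
        raise PipelineError(f"stage 'compare': missing projections CSV {proj_path}")
    groups: dict[str, tuple[list[float], list[bool]]] = {}
    with open(proj_path, newline="") as fh:
        for row in csv.DictReader(fh):
            g = groups.setdefault(row["group"], ([], []))
            g[0].append(float(row["event_time"]))
            g[1].append(bool(int(row["event"])))
    names = p.get("groups", sorted(groups))
    if len(names) != 2 or any(n not in groups for n in names):
        raise PipelineError(f"stage 'compare': need two known groups, got {names}")
    chi2, pval = logrank(groups[names[0]], groups[names[1]])
    out = cfg.outdir / "compare.json"
    out.write_text(json.dumps({"groups": list(names), "chi_square": chi2, "p_value": pval},
                              indent=2))
    logger.info("compare %s vs %s: chi2=%.3f p=%.3g", names[0], names[1], chi2, pval)
    manifest["outputs"]["compare_json"] = str(out)


def _run_phago(cfg: RunConfig, manifest: dict) -> None:
    p = cfg.params.get("phago", {})
    traj_path = p.get("trajectory")
    if traj_path is None:
        spec = synthetic.TrajectorySpec(seed=_stage_seed(cfg.seed, "phago"),
                                        noise_gsd=float(p.get("noise_gsd", 1.1)))
        traj = synthetic.gen_trajectory(spec)
    else:
        if not Path(traj_path).exists():
            raise PipelineError(f"stage 'phago': missing trajectory CSV {traj_path!r}")
        traj = read_trajectory_csv(traj_path)
    window = tuple(p.get("window", (0.0, 8.0)))
    tau = fit_decay(traj, window=window)  # type: ignore[arg-type]
    out = cfg.outdir / "decay.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps({"tau_days": tau, "window": list(window)}, indent=2))
    logger.info("phago: tau=%.3f d -> %s", tau, out)
    manifest["outputs"]["decay_json"] = str(out)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write a run manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``):
    stages, seed, per-stage parameters, outputs and package versions —
    enough to re-run deterministic stages bit-identically.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "stages": list(config.stages),
        "seed": config.seed,
        "parameters": config.params,
        "outputs": {},
        "versions": {"metkit": __version__, "numpy": np.__version__},
    }
    fits: dict[str, GrowthFit] = {}
    for stage in config.stages:
        logger.info("--- stage %s (seed %d) ---", stage, config.seed)
        if stage == "simulate":
            _run_simulate(config, manifest)
        elif stage == "quant":
            _run_quant(config, manifest)
        elif stage == "fit":
            fits = _run_fit(config, manifest)
        elif stage == "project":
            _run_project(config, manifest, fits)
        elif stage == "compare":
            _run_compare(config, manifest)
        elif stage == "phago":
            _run_phago(config, manifest)
    manifest_path = config.outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
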