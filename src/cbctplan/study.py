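"""Cohort study: three planning strategies evaluated against the ground truth.

For every phantom in a seeded synthetic cohort the study generates

* the ground truth anatomy (in-room CT analogue),
* a CBCT-like corrupted image of it, and
* an earlier planning anatomy with systematic target drift,

then optimizes one plan per strategy:

* ``tb_offline`` — planned on the earlier anatomy with 3 mm setup / 3% range
  robustness (the offline, non-adaptive clinical reference),
* ``cbct_rrsX`` — planned daily on the CBCT with 1 mm setup robustness and a
  sweep of range robustness settings (default 3, 6, 8, 10, 12%),
* ``ctor_online`` — planned daily on the ground truth itself with 1 mm / 3%
  (the ceiling of what online adaptation can achieve).

Every plan is forward-evaluated on the ground truth with the 1 mm / 3%
evaluation scenario set; results are collected in a long-format table (one
row per phantom x strategy) with per-target VoxMin V94%, OAR mean doses,
NTCPs and planning-image HU error statistics, plus population summaries
(median, best-to-worst-interpolated 90th percentile, outlier counts, paired
signed-rank tests against the offline baseline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluate import (
    NTCPModel,
    default_ntcp_models,
    evaluate_plan,
    paired_signed_rank,
    population_percentile,
)
from .optimize import ObjectiveConfig, Plan, SolverOptions, optimize_plan
from .phantoms import (
    AnatomyChangeParams,
    ErrorFieldParams,
    ImageGrid,
    PhantomConfig,
    StructureSet,
    generate_cbct,
    generate_phantom,
    generate_planning_anatomy,
)
from .physics import (
    DEFAULT_BEAM_ANGLES,
    BraggParams,
    CalibrationCurve,
    InfluenceEngine,
    design_spots,
    filter_spots,
    hu_to_rsp,
)
from .scenarios import scenario_set

__all__ = ["StudyConfig", "StudyResult", "run_study", "summarize"]

BASELINE_STRATEGY = "tb_offline"


@dataclass
class StudyConfig:
    """Cohort size, seeds, strategy settings and evaluation settings."""

    n_phantoms: int = 23
    base_seed: int = 1
    cbct_rrs: Tuple[float, ...] = (0.03, 0.06, 0.08, 0.10, 0.12)
    srs_online: float = 1.0
    rrs_online_reference: float = 0.03
    srs_offline: float = 3.0
    rrs_offline: float = 0.03
    eval_srs: float = 1.0
    eval_rrs: float = 0.03
    beam_angles: Tuple[float, ...] = DEFAULT_BEAM_ANGLES
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    error_field: ErrorFieldParams = field(default_factory=ErrorFieldParams)
    anatomy_change: AnatomyChangeParams = field(default_factory=AnatomyChangeParams)
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    solver: SolverOptions = field(default_factory=SolverOptions)
    ntcp_models: Optional[List[NTCPModel]] = None

    def __post_init__(self) -> None:
        if self.n_phantoms < 2:
            raise ValueError("cohort size must be >= 2")
        if not self.cbct_rrs:
            raise ValueError("the RRS sweep must be non-empty")

    def phantom_seed(self, i: int) -> int:
        return self.base_seed + i

    def cbct_seed(self, i: int) -> int:
        return (self.base_seed + i + 100_003) % (2**31 - 1)

    def anatomy_seed(self, i: int) -> int:
        return (self.base_seed + i + 200_003) % (2**31 - 1)

    @classmethod
    def small(cls, n_phantoms: int = 3, **kwargs) -> "StudyConfig":
        """Desk-test preset: compact phantoms, 3 beams, short RRS sweep."""
        defaults = dict(
            n_phantoms=n_phantoms,
            cbct_rrs=(0.03, 0.10),
            beam_angles=(50.0, 160.0, 260.0),
            phantom=PhantomConfig.compact(),
            solver=SolverOptions(maxiter_feasibility=150, maxiter_oar=80),
        )
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class StudyResult:
    """Long-format per-phantom x strategy table (one row each)."""

    table: pd.DataFrame
    config: Optional[StudyConfig] = None

    def strategies(self) -> List[str]:
        return list(self.table["strategy"].unique())


def _strategy_label(rrs: float) -> str:
    return f"cbct_rrs{round(rrs * 100):g}"


def _plan_one(
    planning_image: ImageGrid,
    planning_structs: StructureSet,
    srs: float,
    rrs: float,
    config: StudyConfig,
    curve: CalibrationCurve,
    label: str,
    engine_cache: Dict[str, InfluenceEngine],
    cache_key: str,
    range_expansion: float,
) -> Plan:
    rsp = hu_to_rsp(planning_image, curve)
    if cache_key in engine_cache:
        engine = engine_cache[cache_key]
    else:
        beams = design_spots(
            rsp, planning_structs, config.beam_angles,
            range_expansion=range_expansion, shift_margin=srs,
        )
        beams = filter_spots(beams, rsp, planning_structs.avoidance)
        engine = InfluenceEngine(rsp, beams)
        engine_cache[cache_key] = engine
    scen = scenario_set(srs, rrs, planning_image.ndim)
    roi = (
        planning_structs.ctv_low
        | planning_structs.ctv_high
        | _ring(planning_structs, planning_image.spacing, config.objective.ring_margin_mm)
    )
    for oar in planning_structs.oars.values():
        roi |= oar
    vox = np.flatnonzero(roi.ravel())
    influences = engine.influence_set(scen, vox)
    return optimize_plan(
        influences,
        planning_structs,
        config.objective,
        config.solver,
        beams=engine.beams,
        spacing=planning_image.spacing,
        label=label,
    )


def _ring(structs: StructureSet, spacing, margin_mm: float) -> np.ndarray:
    from .optimize import _ring_mask

    return _ring_mask(structs, spacing, margin_mm)


def run_study(
    config: Optional[StudyConfig] = None,
    *,
    curve: Optional[CalibrationCurve] = None,
    out_dir: Optional[Path] = None,
    resume: bool = False,
    progress: bool = False,
) -> StudyResult:
    """Run the full cohort study; fully seeded and resumable per phantom.

    With ``out_dir`` set, per-phantom result rows are cached as JSON;
    ``resume=True`` skips phantoms whose cache file already exists.
    """
    cfg = config or StudyConfig()
    curve = curve or CalibrationCurve.default()
    models = cfg.ntcp_models or default_ntcp_models()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows: List[Dict[str, object]] = []
    for i in range(cfg.n_phantoms):
        pid = cfg.phantom_seed(i)
        cache_file = out_dir / f"phantom_{pid}.json" if out_dir is not None else None
        if resume and cache_file is not None and cache_file.exists():
            rows.extend(json.loads(cache_file.read_text()))
            continue
        if progress:
            print(f"[cbctplan] phantom {i + 1}/{cfg.n_phantoms} (seed {pid})")
        truth_img, truth_structs = generate_phantom(pid, cfg.phantom)
        cbct_img = generate_cbct(
            truth_img, truth_structs, cfg.error_field, cfg.cbct_seed(i)
        )
        plan_img, plan_structs = generate_planning_anatomy(
            truth_img, truth_structs, cfg.anatomy_change, cfg.anatomy_seed(i)
        )

        jobs: List[Tuple[str, ImageGrid, StructureSet, float, float, str]] = [
            (BASELINE_STRATEGY, plan_img, plan_structs, cfg.srs_offline,
             cfg.rrs_offline, "planning_ct"),
        ]
        for rrs in cfg.cbct_rrs:
            jobs.append(
                (_strategy_label(rrs), cbct_img, truth_structs, cfg.srs_online,
                 rrs, "cbct")
            )
        jobs.append(
            ("ctor_online", truth_img, truth_structs, cfg.srs_online,
             cfg.rrs_online_reference, "ctor")
        )

        # spot lattices (and hence engines) are per image *and* per RRS: the
        # range-scaled scenarios need ranges outside the nominal WEPL
        # extent, and each plan gets the lattice sized for its own setting
        # (energy layers are re-selected per plan, as adaptive planning
        # systems do)
        engine_cache: Dict[str, InfluenceEngine] = {}
        phantom_rows: List[Dict[str, object]] = []
        for label, img, structs, srs, rrs, image_key in jobs:
            row: Dict[str, object] = {
                "phantom": pid, "strategy": label, "srs_mm": srs, "rrs": rrs,
            }
            try:
                plan = _plan_one(
                    img, structs, srs, rrs, cfg, curve, label, engine_cache,
                    f"{image_key}_rrs{rrs}", rrs,
                )
            except Exception as exc:  # infeasible geometry is recorded, not fatal
                row.update({"feasible": False, "error": str(exc)})
                phantom_rows.append(row)
                continue
            report = evaluate_plan(
                plan, truth_img, truth_structs,
                curve=curve, eval_srs=cfg.eval_srs, eval_rrs=cfg.eval_rrs,
                ntcp_models=models,
                planning_image=img if image_key != "ctor" else None,
                dose_high=cfg.objective.dose_high, dose_low=cfg.objective.dose_low,
                strategy=label,
            )
            row.update(
                {
                    "feasible": plan.feasible,
                    "v94_ctv_high": report.v94["ctv_high"],
                    "v94_ctv_low": report.v94["ctv_low"],
                    "total_weight": plan.total_weight,
                    "mae": report.mae if report.mae is not None else 0.0,
                    "me": report.me if report.me is not None else 0.0,
                }
            )
            for name, val in report.oar_mean.items():
                row[f"mean_{name}"] = val
            for name, val in report.ntcp.items():
                row[f"ntcp_{name}"] = val
            phantom_rows.append(row)
        if cache_file is not None:
            cache_file.write_text(json.dumps(phantom_rows))
        rows.extend(phantom_rows)

    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(out_dir / "study_results.csv", index=False)
    return StudyResult(table=table, config=cfg)


def summarize(
    result: StudyResult, baseline: str = BASELINE_STRATEGY
) -> Dict[str, pd.DataFrame]:
    """Population summary per strategy plus paired comparisons to a baseline.

    Returns ``per_strategy`` (median and 90th-percentile coverage, counts of
    phantoms with V94% < 95%, median OAR means and NTCPs) and ``vs_baseline``
    (mean +- sd NTCP difference in percentage points and signed-rank
    p-values, per strategy).
    """
    df = result.table
    if baseline not in set(df["strategy"]):
        raise ValueError(f"baseline strategy {baseline!r} missing from the result")
    ok = df[df.get("feasible", True) == True]  # noqa: E712

    ntcp_cols = [c for c in df.columns if c.startswith("ntcp_")]
    oar_cols = [c for c in df.columns if c.startswith("mean_")]

    per_rows = []
    for strat, sub in ok.groupby("strategy", sort=False):
        row: Dict[str, object] = {"strategy": strat, "n": len(sub)}
        for ctv in ("ctv_high", "ctv_low"):
            vals = sub[f"v94_{ctv}"].to_numpy()
            row[f"median_v94_{ctv}"] = float(np.median(vals))
            row[f"p90_v94_{ctv}"] = (
                population_percentile(vals, 0.90, worse="lower")
                if vals.size >= 2 else float(vals[0])
            )
            row[f"n_outlier_{ctv}"] = int(np.sum(vals < 95.0))  # strict inequality
        for c in oar_cols + ntcp_cols:
            row[f"median_{c}"] = float(np.median(sub[c]))
        per_rows.append(row)
    per_strategy = pd.DataFrame(per_rows)

    base = ok[ok["strategy"] == baseline].set_index("phantom")
    vs_rows = []
    for strat, sub in ok.groupby("strategy", sort=False):
        sub = sub.set_index("phantom")
        common = base.index.intersection(sub.index)
        if len(common) == 0:
            continue
        row = {"strategy": strat, "n_pairs": len(common)}
        for c in ntcp_cols:
            delta = (sub.loc[common, c] - base.loc[common, c]).to_numpy()
            row[f"delta_{c}_mean_pp"] = float(delta.mean())
            row[f"delta_{c}_sd_pp"] = float(delta.std(ddof=1)) if len(common) > 1 else 0.0
            if strat != baseline and len(common) >= 5:
                test = paired_signed_rank(
                    sub.loc[common, c].to_numpy(), base.loc[common, c].to_numpy()
                )
                row[f"p_{c}"] = test.pvalue
        for c in oar_cols:
            delta = (sub.loc[common, c] - base.loc[common, c]).to_numpy()
            row[f"delta_{c}_mean"] = float(delta.mean())
            row[f"frac_lower_{c}"] = float(np.mean(delta < 0))
        vs_rows.append(row)
    vs_baseline = pd.DataFrame(vs_rows)
    return {"per_strategy": per_strategy, "vs_baseline": vs_baseline}
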