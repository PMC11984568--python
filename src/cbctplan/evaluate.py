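"""Plan evaluation: robust coverage, HU error statistics, NTCP, population
percentiles and paired significance testing.

Robust target coverage is always assessed on the voxel-wise minimum (VoxMin)
dose over an evaluation scenario set: for each voxel the worst dose across
scenarios is kept, and V94% (the percentage of target voxels at or above 94%
of the prescription) is read off that composite.  Organ-at-risk doses are
evaluated in the nominal scenario and mapped to normal-tissue complication
probability (NTCP) through logistic models whose coefficients are editable
configuration, not hard-coded clinical truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .phantoms import ImageGrid, StructureSet
from .physics import (
    Beam,
    BraggParams,
    CalibrationCurve,
    InfluenceEngine,
    hu_to_rsp,
)
from .scenarios import Scenario, scenario_set

__all__ = [
    "NTCPModel",
    "PlanEvalReport",
    "voxmin",
    "v_metric",
    "compute_mae_me",
    "ntcp",
    "population_percentile",
    "paired_signed_rank",
    "SignedRankResult",
    "default_ntcp_models",
    "evaluate_plan",
]

AIR_THRESHOLD_HU = -960.0


def voxmin(doses: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise minimum dose over a scenario set."""
    doses = [np.asarray(d, dtype=float) for d in doses]
    if not doses:
        raise ValueError("voxmin needs at least one dose grid")
    shape = doses[0].shape
    if any(d.shape != shape for d in doses):
        raise ValueError("all dose grids must share one shape")
    return np.minimum.reduce(doses)


def v_metric(
    dose: np.ndarray,
    mask: np.ndarray,
    prescription: float,
    threshold_fraction: float = 0.94,
) -> float:
    """Percent of mask voxels receiving >= threshold_fraction x prescription."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure mask")
    sel = np.asarray(dose, dtype=float)[mask]
    return 100.0 * np.mean(sel >= threshold_fraction * prescription)


def compute_mae_me(
    test: ImageGrid,
    reference: ImageGrid,
    external: np.ndarray,
    air_threshold: float = AIR_THRESHOLD_HU,
) -> Tuple[float, float]:
    """Mean absolute / mean signed CT-number error inside the external contour.

    Voxels whose *reference* CT number is below ``air_threshold`` (air
    cavities) are excluded.  Returns ``(MAE, ME)`` in HU.
    """
    if not test.same_grid(reference):
        raise ValueError("images must share a grid")
    sel = np.asarray(external, dtype=bool) & (reference.values >= air_threshold)
    if not sel.any():
        raise ValueError("no voxels survive the external/air exclusion")
    diff = test.values[sel] - reference.values[sel]
    return float(np.mean(np.abs(diff))), float(np.mean(diff))


@dataclass(frozen=True)
class NTCPModel:
    """Logistic complication model: NTCP = 1 / (1 + exp(-(b0 + sum b_i x_i))).

    ``coefficients`` maps dose-metric names (e.g. ``"mean_parotid"``, in Gy)
    to per-Gy coefficients.
    """

    name: str
    intercept: float
    coefficients: Dict[str, float]

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("NTCP model needs at least one coefficient")


def default_ntcp_models() -> List[NTCPModel]:
    """Editable defaults: one xerostomia-like and one dysphagia-like model."""
    return [
        NTCPModel("xerostomia", -2.2, {"mean_parotid": 0.054}),
        NTCPModel("dysphagia", -3.2, {"mean_constrictor": 0.058}),
    ]


def ntcp(dose_metrics: Dict[str, float], model: NTCPModel) -> float:
    """Complication probability (fraction in [0, 1]) from named dose metrics."""
    s = model.intercept
    for metric, coef in model.coefficients.items():
        if metric not in dose_metrics:
            raise KeyError(f"dose metric {metric!r} missing for model {model.name!r}")
        s += coef * dose_metrics[metric]
    return float(1.0 / (1.0 + np.exp(-s)))


def population_percentile(
    values: Sequence[float],
    fraction: float = 0.90,
    worse: str = "lower",
) -> float:
    """Population percentile counted from best toward worst performers.

    Values are sorted from best to worst (``worse='lower'``: low values are
    bad, so best-to-worst is descending).  The fractional rank is
    ``r = fraction * n`` (1-indexed toward the worst), and the result is the
    linear interpolation between ranks floor(r) and ceil(r); e.g. for n = 23
    and fraction 0.90, between the 20th and 21st worst performers.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two values")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if worse == "lower":
        ordered = np.sort(vals)[::-1]
    elif worse == "higher":
        ordered = np.sort(vals)
    else:
        raise ValueError("worse must be 'lower' or 'higher'")
    r = fraction * vals.size
    lo = max(int(np.floor(r)), 1)
    hi = min(int(np.ceil(r)), vals.size)
    if lo == hi:
        return float(ordered[lo - 1])
    frac = r - lo
    return float(ordered[lo - 1] * (1.0 - frac) + ordered[hi - 1] * frac)


class SignedRankResult(NamedTuple):
    statistic: float  # signed rank sum, positive when a tends above b
    pvalue: float
    significant: bool
    degenerate: bool  # all paired differences were zero


def paired_signed_rank(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    The statistic reported is the signed rank sum ``sum(sign(d) * rank|d|)``
    over nonzero differences (antisymmetric under swapping the samples); the
    p-value comes from the standard test (exact for small samples without
    ties).  If every difference is zero the test is degenerate: p = 1 is
    returned with a warning.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired samples of equal length >= 5")
    d = a - b
    nz = d != 0
    if not nz.any():
        warnings.warn("all paired differences are zero; signed-rank test degenerate")
        return SignedRankResult(0.0, 1.0, False, True)
    ranks = stats.rankdata(np.abs(d[nz]))
    signed_sum = float(np.sum(np.sign(d[nz]) * ranks))
    res = stats.wilcoxon(a, b)
    p = float(res.pvalue)
    return SignedRankResult(signed_sum, p, p < alpha, False)


# ---------------------------------------------------------------------------
# Full plan evaluation on the ground truth
# ---------------------------------------------------------------------------


@dataclass
class PlanEvalReport:
    """Ground-truth evaluation of one plan.

    ``v94`` per target (percent, VoxMin over the evaluation scenario set),
    nominal mean dose per OAR (Gy), NTCP per model (percent), and — when a
    planning image is supplied — its MAE/ME versus the ground truth (HU).
    """

    strategy: str
    v94: Dict[str, float]
    oar_mean: Dict[str, float]
    ntcp: Dict[str, float]
    mae: Optional[float] = None
    me: Optional[float] = None
    extras: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.v94.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"V94 for {k} outside [0, 100]: {v}")
        for k, v in self.ntcp.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"NTCP for {k} outside [0, 100]: {v}")


def evaluate_plan(
    plan,
    ground_truth: ImageGrid,
    structures: StructureSet,
    *,
    curve: Optional[CalibrationCurve] = None,
    eval_srs: float = 1.0,
    eval_rrs: float = 0.03,
    ntcp_models: Optional[Sequence[NTCPModel]] = None,
    planning_image: Optional[ImageGrid] = None,
    air_threshold: float = AIR_THRESHOLD_HU,
    dose_high: float = 70.0,
    dose_low: float = 54.25,
    bragg: Optional[BraggParams] = None,
    strategy: str = "",
) -> PlanEvalReport:
    """Forward-compute a plan on the ground truth and report robust metrics.

    The influence of the plan's beams is rebuilt on the ground-truth RSP map
    for the evaluation scenario set (default 1 mm / 3%); V94% per target is
    read off the VoxMin composite, OAR mean doses off the nominal scenario.
    """
    models = list(ntcp_models) if ntcp_models is not None else default_ntcp_models()
    rsp = hu_to_rsp(ground_truth, curve)
    scen = scenario_set(eval_srs, eval_rrs, ground_truth.ndim)

    roi = structures.ctv_low | structures.ctv_high
    for oar in structures.oars.values():
        roi |= oar
    vox = np.flatnonzero(roi.ravel())
    engine = InfluenceEngine(rsp, plan.beams, bragg=bragg)
    influences = engine.influence_set(scen, vox)

    w = np.asarray(plan.weights, dtype=float)
    doses = [inf.dose(w) for inf in influences]
    vmin = voxmin(doses)
    nominal = doses[0]  # scenario_set puts the nominal scenario first

    def sub(mask: np.ndarray) -> np.ndarray:
        return np.flatnonzero(np.isin(vox, np.flatnonzero(mask.ravel())))

    v94 = {
        "ctv_high": _v94_on(vmin, sub(structures.ctv_high), dose_high),
        "ctv_low": _v94_on(vmin, sub(structures.ctv_low), dose_low),
    }
    oar_mean = {
        name: float(nominal[sub(mask)].mean()) if mask.any() else 0.0
        for name, mask in structures.oars.items()
    }
    metrics = {f"mean_{name}": v for name, v in oar_mean.items()}
    ntcp_pct = {m.name: 100.0 * ntcp(metrics, m) for m in models}

    mae = me = None
    if planning_image is not None:
        mae, me = compute_mae_me(
            planning_image, ground_truth, structures.external, air_threshold
        )
    return PlanEvalReport(
        strategy=strategy or getattr(plan, "label", ""),
        v94=v94,
        oar_mean=oar_mean,
        ntcp=ntcp_pct,
        mae=mae,
        me=me,
    )


def _v94_on(vmin: np.ndarray, idx: np.ndarray, prescription: float) -> float:
    if idx.size == 0:
        raise ValueError("target has no voxels in the evaluation region")
    return 100.0 * float(np.mean(vmin[idx] >= 0.94 * prescription))
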