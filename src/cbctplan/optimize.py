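"""Mini-max scenario-based robust spot-weight optimization.

Weights are nonnegative and the target dose requirements must hold in *every*
optimization scenario (equivalently, in the voxel-wise minimum over the
scenario set): at least 98% of each target's voxels at or above 94% of its
prescription.  The combinatorial V94 constraint is enforced through a smooth
surrogate — per scenario, a quadratic pull of target voxels toward their
prescription plus a strongly weighted quadratic hinge below the 94% level —
followed by a direct V94 verification on the scenario-set VoxMin; a failed
verification triggers one penalty escalation before the plan is declared
infeasible.

Subject to robust coverage, organ-at-risk mean doses (nominal scenario) are
minimized in priority order: each optimized level is frozen as a constraint
with 2% slack before the next is addressed, with the total spot weight (a
monitor-unit stand-in) as a final light regularizer.  Only the targets and a
ring around the low-dose target are handled robustly; OARs and the ring enter
in the nominal scenario only.

The solver is a bound-constrained quasi-Newton method (L-BFGS-B) from a
uniform initialization; the path is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize as sciopt, sparse

from .phantoms import StructureSet
from .physics import Beam, DoseInfluence
from .scenarios import Scenario

__all__ = [
    "ObjectiveConfig",
    "SolverOptions",
    "Plan",
    "InfeasiblePlanError",
    "optimize_plan",
    "worst_case_objective",
]


class InfeasiblePlanError(RuntimeError):
    """Raised when robust coverage cannot be met; carries the achieved V94."""

    def __init__(self, message: str, achieved_v94: Dict[str, float]):
        super().__init__(message)
        self.achieved_v94 = achieved_v94


@dataclass
class ObjectiveConfig:
    """Prescriptions, coverage requirement and prioritized OAR objectives."""

    dose_high: float = 70.0
    dose_low: float = 54.25
    coverage_fraction: float = 0.94
    coverage_min_pct: float = 98.0
    oar_priority: Tuple[str, ...] = ("parotid", "constrictor")
    ring_margin_mm: float = 10.0
    ring_weight: float = 0.3
    oar_slack: float = 0.02

    def __post_init__(self) -> None:
        if not self.dose_high > self.dose_low > 0:
            raise ValueError("require dose_high > dose_low > 0")
        if not self.oar_priority:
            raise ValueError("OAR priority list must be non-empty")


@dataclass
class SolverOptions:
    """Deterministic solver controls (all configurable)."""

    tol: float = 1e-9
    maxiter_feasibility: int = 200
    maxiter_oar: int = 100
    coverage_penalty: float = 50.0
    penalty_escalation: float = 10.0
    oar_tradeoff: float = 3e-4  # initial weight of the OAR term per Gy
    oar_backoff_factor: float = 0.25
    oar_backoff_steps: int = 3
    phase_kappa_boost: float = 4.0  # extra coverage defense during OAR phases
    mu_tradeoff: float = 0.01  # final monitor-unit (total weight) phase
    mu_slack: float = 0.02  # tolerated relative growth of the target objective
    weight_regularizer: float = 1e-6
    raise_on_infeasible: bool = False


@dataclass(eq=False)
class Plan:
    """Optimized spot weights plus provenance and solver diagnostics."""

    weights: np.ndarray
    beams: List[Beam]
    scenarios: List[Scenario]
    srs: float = float("nan")
    rrs: float = float("nan")
    label: str = ""
    feasible: bool = True
    diagnostics: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("spot weights must be nonnegative")
        if self.beams:
            n = sum(b.n_spots for b in self.beams)
            if self.weights.size != n:
                raise ValueError("weight count must equal the surviving spot count")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


# ---------------------------------------------------------------------------


def _indices_in(voxel_indices: np.ndarray, mask: np.ndarray) -> np.ndarray:
    flat = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
    return np.flatnonzero(np.isin(voxel_indices, flat))


def _ring_mask(structures: StructureSet, spacing: Sequence[float], margin_mm: float) -> np.ndarray:
    it = max(1, int(round(margin_mm / float(min(spacing)))))
    ring = ndimage.binary_dilation(structures.ctv_low, iterations=it)
    return ring & ~structures.ctv_low & structures.external


class _RobustProblem:
    """Objective/gradient evaluations shared by the solver phases."""

    def __init__(
        self,
        influences: Sequence[DoseInfluence],
        structures: StructureSet,
        objective: ObjectiveConfig,
        spacing: Sequence[float],
    ) -> None:
        self.obj = objective
        self.influences = list(influences)
        vox = self.influences[0].voxel_indices
        for inf in self.influences:
            if inf.matrix.shape[0] != self.influences[0].matrix.shape[0]:
                raise ValueError("influence matrices must share the spot dimension")
            if not np.array_equal(inf.voxel_indices, vox):
                raise ValueError("influence matrices must share the voxel selection")
        self.n_spots = self.influences[0].n_spots

        idx_h = _indices_in(vox, structures.ctv_high)
        idx_l = _indices_in(vox, structures.ctv_low & ~structures.ctv_high)
        ring = _ring_mask(structures, spacing, objective.ring_margin_mm)
        idx_r = _indices_in(vox, ring)
        if idx_h.size == 0:
            raise ValueError("ctv_high has no voxels in the influence region")
        self.idx_h, self.idx_l, self.idx_r = idx_h, idx_l, idx_r

        # per-scenario submatrices over the voxels each term needs, stacked
        # horizontally so one matvec serves all scenarios at once
        mats_h, mats_l = [], []
        for inf in self.influences:
            csc = inf.matrix.tocsc()
            mats_h.append(csc[:, idx_h])
            if idx_l.size:
                mats_l.append(csc[:, idx_l])
        self.mat_h_all = sparse.hstack(mats_h, format="csr")
        self.mat_l_all = sparse.hstack(mats_l, format="csr") if mats_l else None
        nominal = [inf for inf in self.influences if inf.scenario.is_nominal]
        self.nominal = nominal[0] if nominal else self.influences[0]
        csc0 = self.nominal.matrix.tocsc()
        self.mat_r = csc0[:, idx_r].tocsr() if idx_r.size else None
        # nominal mean-dose gradient vector per OAR
        self.oar_grad: Dict[str, np.ndarray] = {}
        for name, mask in structures.oars.items():
            idx = _indices_in(vox, mask)
            if idx.size:
                g = np.asarray(csc0[:, idx].sum(axis=1)).ravel() / idx.size
            else:
                g = np.zeros(self.n_spots)
            self.oar_grad[name] = g

    # -- metrics -----------------------------------------------------------

    def scenario_target_doses(self, w: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(n_scenarios, |H|) and (n_scenarios, |L\\H|) dose arrays."""
        ns = len(self.influences)
        dh = np.asarray(self.mat_h_all.T @ w).reshape(ns, self.idx_h.size)
        if self.mat_l_all is not None:
            dl = np.asarray(self.mat_l_all.T @ w).reshape(ns, self.idx_l.size)
        else:
            dl = np.empty((ns, 0))
        return dh, dl

    def voxmin_v94(self, w: np.ndarray) -> Dict[str, float]:
        dh, dl = self.scenario_target_doses(w)
        vh = dh.min(axis=0)
        cov_h = 100.0 * np.mean(vh >= self.obj.coverage_fraction * self.obj.dose_high)
        if self.idx_l.size:
            # ctv_low includes the high-dose voxels, judged at the low prescription
            vl = dl.min(axis=0)
            tl = self.obj.coverage_fraction * self.obj.dose_low
            n_pass = np.sum(vl >= tl) + np.sum(vh >= tl)
            cov_l = 100.0 * n_pass / (self.idx_l.size + self.idx_h.size)
        else:
            cov_l = cov_h
        return {"ctv_high": float(cov_h), "ctv_low": float(cov_l)}

    def oar_mean(self, w: np.ndarray, name: str) -> float:
        return float(self.oar_grad[name] @ w)

    # -- smooth objective --------------------------------------------------

    def coverage_terms(self, w: np.ndarray, kappa: float) -> Tuple[float, np.ndarray]:
        """Quadratic prescription pull + hinge below the 94% level, averaged
        over scenarios; returns (value, gradient)."""
        obj = self.obj
        ph, pl = obj.dose_high, obj.dose_low
        th, tl = obj.coverage_fraction * ph, obj.coverage_fraction * pl
        ns = len(self.influences)
        dh = np.asarray(self.mat_h_all.T @ w).ravel()
        nh = dh.size
        res = (dh - ph) / ph
        short = np.maximum(th - dh, 0.0) / ph
        f = np.mean(res**2) + kappa * np.mean(short**2)
        g = self.mat_h_all @ ((2.0 * res - 2.0 * kappa * short) / (ph * nh))
        if self.mat_l_all is not None:
            dl = np.asarray(self.mat_l_all.T @ w).ravel()
            nl = dl.size
            # pull toward the prescription; hinge only below the 94% level
            under = np.maximum(pl - dl, 0.0) / pl
            short_l = np.maximum(tl - dl, 0.0) / pl
            over = np.maximum(dl - ph, 0.0) / ph
            f += np.mean(under**2) + kappa * np.mean(short_l**2) + np.mean(over**2)
            g += self.mat_l_all @ (
                (-2.0 * under - 2.0 * kappa * short_l) / (pl * nl)
                + 2.0 * over / (ph * nl)
            )
        return f, g

    def ring_term(self, w: np.ndarray) -> Tuple[float, np.ndarray]:
        if self.mat_r is None:
            return 0.0, np.zeros(self.n_spots)
        d = np.asarray(self.mat_r.T @ w).ravel()
        over = np.maximum(d - self.obj.dose_low, 0.0) / self.obj.dose_low
        f = self.obj.ring_weight * np.mean(over**2)
        g = self.mat_r @ (2.0 * self.obj.ring_weight * over / (self.obj.dose_low * d.size))
        return f, g

    def initial_weights(self) -> np.ndarray:
        w = np.ones(self.n_spots)
        doses = self.scenario_target_doses(w)
        dh = doses[0][0]
        mean = dh.mean()
        if mean <= 0:
            raise InfeasiblePlanError(
                "no spot reaches the high-dose target", {"ctv_high": 0.0, "ctv_low": 0.0}
            )
        return w * (self.obj.dose_high / mean)


def optimize_plan(
    influences: Sequence[DoseInfluence],
    structures: StructureSet,
    objective: Optional[ObjectiveConfig] = None,
    options: Optional[SolverOptions] = None,
    *,
    beams: Optional[List[Beam]] = None,
    spacing: Optional[Sequence[float]] = None,
    label: str = "",
) -> Plan:
    """Optimize nonnegative spot weights over the given scenario influences.

    ``spacing`` (mm) is needed to build the ring structure; it defaults to
    2 mm isotropic.  ``beams`` is carried into the returned plan for later
    forward evaluation.
    """
    if not influences:
        raise ValueError("at least one scenario influence is required")
    obj = objective or ObjectiveConfig()
    opt = options or SolverOptions()
    spacing = tuple(spacing) if spacing is not None else (2.0, 2.0)
    prob = _RobustProblem(influences, structures, obj, spacing)

    reg = opt.weight_regularizer / prob.n_spots

    def feasibility_objective(w, kappa):
        f1, g1 = prob.coverage_terms(w, kappa)
        f2, g2 = prob.ring_term(w)
        return f1 + f2 + reg * w.sum(), g1 + g2 + reg

    w0 = prob.initial_weights()
    bounds = [(0.0, None)] * prob.n_spots
    kappa = opt.coverage_penalty
    escalations = 0
    w = w0
    while True:
        res = sciopt.minimize(
            feasibility_objective, w, args=(kappa,), jac=True, method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opt.maxiter_feasibility, "ftol": opt.tol, "gtol": 1e-12},
        )
        w = np.maximum(res.x, 0.0)
        cov = prob.voxmin_v94(w)
        ok = all(c >= obj.coverage_min_pct for c in cov.values())
        if ok or escalations >= 1:
            break
        kappa *= opt.penalty_escalation
        escalations += 1
    feasible = all(c >= obj.coverage_min_pct for c in cov.values())
    diagnostics: Dict[str, object] = {
        "coverage_after_feasibility": dict(cov),
        "penalty_escalations": escalations,
        "feasibility_iterations": int(res.nit),
    }
    if not feasible:
        if opt.raise_on_infeasible:
            raise InfeasiblePlanError(
                f"robust coverage not attainable (achieved {cov})", cov
            )
        diagnostics["infeasible"] = True

    # prioritized OAR phases (nominal scenario only), 2% slack freeze
    achieved: Dict[str, float] = {}
    if feasible:
        for name in obj.oar_priority:
            if name not in prob.oar_grad:
                continue
            gvec = prob.oar_grad[name]
            lam = opt.oar_tradeoff
            kappa_phase = kappa * opt.phase_kappa_boost
            w_best = w
            for _ in range(opt.oar_backoff_steps + 1):
                def phase_objective(x):
                    f, g = feasibility_objective(x, kappa_phase)
                    f += lam * float(gvec @ x)
                    g = g + lam * gvec
                    for prev, cap in achieved.items():
                        m = float(prob.oar_grad[prev] @ x)
                        exc = max(m - cap, 0.0)
                        f += 100.0 * exc**2
                        g = g + 200.0 * exc * prob.oar_grad[prev]
                    return f, g

                res = sciopt.minimize(
                    phase_objective, w, jac=True, method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": opt.maxiter_oar, "ftol": opt.tol, "gtol": 1e-12},
                )
                cand = np.maximum(res.x, 0.0)
                cov_c = prob.voxmin_v94(cand)
                if all(c >= obj.coverage_min_pct for c in cov_c.values()):
                    w_best = cand
                    break
                # OAR pressure broke robust coverage: back off deterministically
                lam *= opt.oar_backoff_factor
            w = w_best
            achieved[name] = prob.oar_mean(w, name) * (1.0 + obj.oar_slack)
            diagnostics[f"oar_mean_{name}"] = prob.oar_mean(w, name)

        # final priority level: total spot weight (monitor-unit economy).
        # Accepted only if robust coverage holds, the target objective does
        # not degrade beyond a small slack, and frozen OAR levels are kept;
        # this strips weight from spots the plan does not need.
        f_target0, _ = feasibility_objective(w, kappa)
        w_scale = max(float(np.mean(w)), 1e-12)
        lam_mu = opt.mu_tradeoff
        for _ in range(opt.oar_backoff_steps + 1):
            def mu_objective(x):
                f, g = feasibility_objective(x, kappa * opt.phase_kappa_boost)
                f += lam_mu * x.sum() / (prob.n_spots * w_scale)
                g = g + lam_mu / (prob.n_spots * w_scale)
                for prev, cap in achieved.items():
                    m = float(prob.oar_grad[prev] @ x)
                    exc = max(m - cap, 0.0)
                    f += 100.0 * exc**2
                    g = g + 200.0 * exc * prob.oar_grad[prev]
                return f, g

            res = sciopt.minimize(
                mu_objective, w, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": opt.maxiter_oar, "ftol": opt.tol, "gtol": 1e-12},
            )
            cand = np.maximum(res.x, 0.0)
            cov_c = prob.voxmin_v94(cand)
            f_target_c, _ = feasibility_objective(cand, kappa)
            ok_cov = all(c >= obj.coverage_min_pct for c in cov_c.values())
            ok_obj = f_target_c <= f_target0 * (1.0 + opt.mu_slack) + 1e-12
            if ok_cov and ok_obj and cand.sum() < w.sum():
                w = cand
                break
            lam_mu *= opt.oar_backoff_factor

    cov = prob.voxmin_v94(w)
    diagnostics["coverage_final"] = dict(cov)
    diagnostics["oar_means_final"] = {
        name: prob.oar_mean(w, name) for name in prob.oar_grad
    }
    scen = [inf.scenario for inf in influences]
    srs = max((float(np.linalg.norm(s.shift)) for s in scen), default=0.0)
    rrs = max((abs(s.density_scale - 1.0) for s in scen), default=0.0)
    return Plan(
        weights=w,
        beams=list(beams) if beams is not None else [],
        scenarios=scen,
        srs=srs,
        rrs=rrs,
        label=label,
        feasible=bool(feasible and all(c >= obj.coverage_min_pct for c in cov.values())),
        diagnostics=diagnostics,
    )


def worst_case_objective(
    weights: np.ndarray,
    influences: Sequence[DoseInfluence],
    mask: np.ndarray,
    metric: str = "mean_dose",
    *,
    prescription: float = 1.0,
    threshold_fraction: float = 0.94,
) -> float:
    """Worst case of a structure metric over the scenario set.

    ``mean_dose`` (a cost) takes the maximum over scenarios; ``coverage``
    (percent of voxels at or above the threshold, a benefit) the minimum.
    """
    if not influences:
        raise ValueError("empty scenario list")
    w = np.asarray(weights, dtype=float)
    idx = _indices_in(influences[0].voxel_indices, mask)
    if idx.size == 0:
        raise ValueError("mask has no voxels in the influence region")
    values = []
    for inf in influences:
        d = inf.dose(w)[idx]
        if metric == "mean_dose":
            values.append(float(d.mean()))
        elif metric == "coverage":
            values.append(100.0 * float(np.mean(d >= threshold_fraction * prescription)))
        else:
            raise ValueError("metric must be 'mean_dose' or 'coverage'")
    return max(values) if metric == "mean_dose" else min(values)
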