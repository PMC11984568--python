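"""Toy pencil-beam proton dose engine.

The engine converts CT numbers to relative stopping power (RSP) through a
piecewise-linear calibration curve, traces water-equivalent path length
(WEPL) through the voxel grid with parallel-beam geometry, evaluates an
analytic Bragg depth-dose curve per spot, and assembles sparse dose-influence
matrices (spots x voxels) per error scenario.

It is deliberately simple — no Monte Carlo transport, nuclear halo, or
depth-dependent lateral scattering — but preserves the two mechanisms the
robust-planning study turns on: range errors (density/WEPL scaling) and setup
errors (isocenter shifts).  For a parallel beam, moving the beam relative to
the patient leaves the WEPL of every material point unchanged and only
displaces the spot axes laterally; scenario shifts are realized exactly that
way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, sparse

from .phantoms import ImageGrid, StructureSet
from .scenarios import Scenario

__all__ = [
    "CalibrationCurve",
    "RSPMap",
    "Beam",
    "BraggParams",
    "DoseInfluence",
    "InfluenceEngine",
    "hu_to_rsp",
    "scale_density",
    "trace_wepl",
    "bragg_curve",
    "design_spots",
    "filter_spots",
    "build_influence",
]

RBE_FACTOR = 1.1  # constant relative biological effectiveness for protons

DEFAULT_BEAM_ANGLES = (50.0, 100.0, 160.0, 200.0, 260.0, 310.0)


@dataclass(eq=False)
class CalibrationCurve:
    """Piecewise-linear HU -> RSP calibration.

    Nodes must have strictly increasing HU and non-decreasing, non-negative
    RSP, and must contain the water anchor (0 HU, RSP 1.0).  Outside the node
    range the curve clamps to the end nodes.
    """

    hu: np.ndarray
    rsp: np.ndarray

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.rsp = np.asarray(self.rsp, dtype=float)
        if self.hu.ndim != 1 or self.hu.shape != self.rsp.shape or self.hu.size < 2:
            raise ValueError("curve needs >= 2 (HU, RSP) node pairs")
        if np.any(np.diff(self.hu) <= 0):
            raise ValueError("HU nodes must be strictly increasing")
        if np.any(self.rsp < 0) or np.any(np.diff(self.rsp) < 0):
            raise ValueError("RSP nodes must be non-negative and non-decreasing")
        water = np.interp(0.0, self.hu, self.rsp)
        if abs(water - 1.0) > 1e-9:
            raise ValueError("curve must pass through the water anchor (0 HU, 1.0)")

    @classmethod
    def default(cls) -> "CalibrationCurve":
        return cls(
            hu=np.array([-1024.0, 0.0, 1000.0, 3071.0]),
            rsp=np.array([0.001, 1.0, 1.55, 2.4]),
        )

    def __call__(self, hu_values: np.ndarray) -> np.ndarray:
        return np.interp(hu_values, self.hu, self.rsp)


@dataclass(eq=False)
class RSPMap:
    """Relative stopping power per voxel, sharing grid metadata with its image."""

    values: np.ndarray
    spacing: Tuple[float, ...]
    origin: Tuple[float, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if np.any(self.values < 0):
            raise ValueError("RSP values must be non-negative")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def axis_coords(self) -> Tuple[np.ndarray, ...]:
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(self.ndim)
        )


def hu_to_rsp(image: ImageGrid, curve: Optional[CalibrationCurve] = None) -> RSPMap:
    """Convert CT numbers to relative stopping power (piecewise linear)."""
    c = curve or CalibrationCurve.default()
    return RSPMap(c(image.values), image.spacing, image.origin)


def scale_density(rsp: RSPMap, factor: float) -> RSPMap:
    """Uniformly scale the stopping-power map (range-error scenarios)."""
    if factor <= 0:
        raise ValueError("density scale factor must be > 0")
    return RSPMap(rsp.values * factor, rsp.spacing, rsp.origin)


# ---------------------------------------------------------------------------
# Ray tracing
# ---------------------------------------------------------------------------


def trace_wepl(
    rsp: RSPMap,
    entry: Sequence[float],
    direction: Sequence[float],
    step: float = 0.5,
    interpolation: str = "linear",
) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative WEPL profile along one ray.

    Returns ``(depths, wepl)``: geometric depth from the entry point (mm) and
    the monotone non-decreasing cumulative water-equivalent depth at each
    sample.  Samples outside the grid contribute zero (vacuum).  An empty
    profile is returned if the ray never intersects the grid bounding box.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    entry = np.asarray(entry, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    origin = np.asarray(rsp.origin)
    spacing = np.asarray(rsp.spacing)
    lo = origin - 0.5 * spacing
    hi = origin + (np.asarray(rsp.shape) - 0.5) * spacing

    # slab clipping of the ray segment inside the bounding box
    t0, t1 = 0.0, np.inf
    for a in range(rsp.ndim):
        d, e = direction[a], entry[a]
        if abs(d) < 1e-12:
            if e < lo[a] or e > hi[a]:
                return np.empty(0), np.empty(0)
        else:
            ta, tb = (lo[a] - e) / d, (hi[a] - e) / d
            t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
    if t1 <= t0:
        return np.empty(0), np.empty(0)

    n = int(np.ceil((t1 - t0) / step))
    mids = t0 + (np.arange(n) + 0.5) * step
    pts = entry[None, :] + mids[:, None] * direction[None, :]
    idx = (pts - origin[None, :]) / spacing[None, :]
    order = {"linear": 1, "nearest": 0}[interpolation]
    vals = ndimage.map_coordinates(
        rsp.values, idx.T, order=order, mode="constant", cval=0.0
    )
    depths = t0 + (np.arange(n) + 1) * step
    return depths, np.cumsum(vals) * step


# ---------------------------------------------------------------------------
# Depth-dose model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BraggParams:
    """Analytic Bragg-curve shape parameters (mm, unitless).

    The curve is a narrow Gaussian peak at the nominal range on top of a
    smooth entrance plateau that switches off ``plateau_setback`` mm proximal
    to the peak.  The peak width shrinks for short ranges
    (``sigma = min(peak_sigma, sigma_range_fraction * range)``) so the distal
    falloff always drops below 1% of the peak by 1.2x the nominal range.
    """

    peak_sigma: float = 3.0
    plateau: float = 0.3
    plateau_tau: float = 2.5
    plateau_setback: float = 10.0
    sigma_range_fraction: float = 0.06


def bragg_curve(
    nominal_range,
    depth,
    params: Optional[BraggParams] = None,
) -> np.ndarray:
    """Relative dose at water-equivalent ``depth`` for a spot of given range.

    Normalized to 1.0 at its maximum, which sits at ``depth = nominal_range``.
    Broadcasts over array inputs; negative depths are rejected.
    """
    p = params or BraggParams()
    r = np.asarray(nominal_range, dtype=float)
    z = np.asarray(depth, dtype=float)
    if np.any(r <= 0):
        raise ValueError("nominal_range must be > 0")
    if np.any(z < 0):
        raise ValueError("depth must be >= 0")
    sigma = np.minimum(p.peak_sigma, p.sigma_range_fraction * r)
    peak = np.exp(-((z - r) ** 2) / (2.0 * sigma**2))
    plat = p.plateau * 0.5 * (1.0 - np.tanh((z - (r - p.plateau_setback)) / p.plateau_tau))
    norm = 1.0 + p.plateau * 0.5 * (1.0 - np.tanh(p.plateau_setback / p.plateau_tau))
    return (peak + plat) / norm


# ---------------------------------------------------------------------------
# Beams and spots
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class Beam:
    """One parallel beam: gantry angle plus its spot lattice.

    Spots are stored as parallel arrays of lateral axis positions (mm, world
    lateral coordinate) and nominal ranges (mm WEPL).
    """

    angle_deg: float
    lateral: np.ndarray
    nominal_range: np.ndarray
    lateral_sigma: float = 4.0

    def __post_init__(self) -> None:
        self.lateral = np.atleast_1d(np.asarray(self.lateral, dtype=float))
        self.nominal_range = np.atleast_1d(np.asarray(self.nominal_range, dtype=float))
        if self.lateral.shape != self.nominal_range.shape:
            raise ValueError("lateral and nominal_range must have equal length")
        if np.any(self.nominal_range <= 0):
            raise ValueError("nominal ranges must be > 0")
        if self.lateral_sigma <= 0:
            raise ValueError("lateral_sigma must be > 0")

    @property
    def n_spots(self) -> int:
        return self.lateral.size

    def direction(self) -> np.ndarray:
        t = np.deg2rad(self.angle_deg)
        return np.array([np.cos(t), np.sin(t)])

    def lateral_axis(self) -> np.ndarray:
        t = np.deg2rad(self.angle_deg)
        return np.array([-np.sin(t), np.cos(t)])

    def subset(self, keep: np.ndarray) -> "Beam":
        return Beam(
            self.angle_deg, self.lateral[keep], self.nominal_range[keep],
            self.lateral_sigma,
        )


class _BeamTrace:
    """Per-beam WEPL lookup on a (lateral, depth) ray grid (2-D parallel beam)."""

    def __init__(
        self,
        rsp: RSPMap,
        angle_deg: float,
        ray_spacing: float = 2.0,
        step: float = 1.0,
    ) -> None:
        if rsp.ndim != 2:
            raise ValueError("the influence engine supports 2-D grids")
        t = np.deg2rad(angle_deg)
        self.d = np.array([np.cos(t), np.sin(t)])
        self.l = np.array([-np.sin(t), np.cos(t)])
        self.ray_spacing = ray_spacing
        self.step = step

        origin = np.asarray(rsp.origin)
        extent = origin + (np.asarray(rsp.shape) - 1) * np.asarray(rsp.spacing)
        corners = np.array(
            [[origin[0], origin[1]], [origin[0], extent[1]],
             [extent[0], origin[1]], [extent[0], extent[1]]]
        )
        ts = corners @ self.l
        ss = corners @ self.d
        self.t0 = ts.min() - 2 * ray_spacing
        self.s0 = ss.min() - 2 * step
        nt = int(np.ceil((ts.max() + 2 * ray_spacing - self.t0) / ray_spacing)) + 1
        ns = int(np.ceil((ss.max() + 2 * step - self.s0) / step)) + 1

        lat = self.t0 + np.arange(nt) * ray_spacing
        dep = self.s0 + (np.arange(ns) + 0.5) * step
        pts = (
            lat[:, None, None] * self.l[None, None, :]
            + dep[None, :, None] * self.d[None, None, :]
        )  # (nt, ns, 2)
        idx = (pts - origin[None, None, :]) / np.asarray(rsp.spacing)[None, None, :]
        vals = ndimage.map_coordinates(
            rsp.values, [idx[..., 0], idx[..., 1]], order=1, mode="constant", cval=0.0
        )
        # cumulative WEPL at depth coordinate s0 + (j+1)*step
        self.wepl_grid = np.cumsum(vals, axis=1) * step

    def beam_coords(self, points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return points @ self.l, points @ self.d

    def wepl_at(self, points: np.ndarray) -> np.ndarray:
        t, s = self.beam_coords(points)
        it = (t - self.t0) / self.ray_spacing
        js = (s - self.s0) / self.step - 1.0
        return ndimage.map_coordinates(
            self.wepl_grid, [it, js], order=1, mode="nearest"
        )


@dataclass(eq=False)
class DoseInfluence:
    """Sparse linear map from nonnegative spot weights to voxel doses.

    ``matrix`` is (n_spots, n_selected_voxels), RBE-weighted Gy per unit spot
    weight; ``voxel_indices`` are flat indices into the grid the columns refer
    to.
    """

    matrix: sparse.csr_matrix
    voxel_indices: np.ndarray
    scenario: Scenario
    grid_shape: Tuple[int, ...]
    rbe_factor: float = RBE_FACTOR

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    def dose(self, weights: np.ndarray) -> np.ndarray:
        """Dose (Gy) at the selected voxels for the given spot weights."""
        w = np.asarray(weights, dtype=float)
        if w.shape != (self.n_spots,):
            raise ValueError("weight vector length must equal the spot count")
        return np.asarray(self.matrix.T @ w).ravel()

    def dose_grid(self, weights: np.ndarray) -> np.ndarray:
        """Dose embedded in the full grid (zeros outside the selection)."""
        out = np.zeros(int(np.prod(self.grid_shape)))
        out[self.voxel_indices] = self.dose(weights)
        return out.reshape(self.grid_shape)


class InfluenceEngine:
    """Builds per-scenario influence matrices, caching per-beam WEPL traces.

    The expensive part (ray tracing through the RSP map) depends only on the
    beam angle and the image, so it is shared across all scenarios; a scenario
    then costs one Bragg/lateral-Gaussian evaluation per spot.
    """

    def __init__(
        self,
        rsp: RSPMap,
        beams: Sequence[Beam],
        *,
        bragg: Optional[BraggParams] = None,
        rbe_factor: float = RBE_FACTOR,
        sparse_threshold: float = 1e-4,
        ray_spacing: float = 2.0,
        step: float = 1.0,
    ) -> None:
        if not beams or sum(b.n_spots for b in beams) == 0:
            raise ValueError("at least one beam with spots is required")
        self.rsp = rsp
        self.beams = list(beams)
        self.bragg = bragg or BraggParams()
        self.rbe_factor = rbe_factor
        self.sparse_threshold = sparse_threshold
        self._traces = [
            _BeamTrace(rsp, b.angle_deg, ray_spacing, step) for b in self.beams
        ]
        self._vox_cache: Dict[bytes, list] = {}

    @property
    def n_spots(self) -> int:
        return sum(b.n_spots for b in self.beams)

    def _voxel_data(self, voxel_indices: np.ndarray) -> list:
        key = voxel_indices.tobytes()
        if key not in self._vox_cache:
            centers_all = _voxel_centers(self.rsp)
            pts = centers_all[voxel_indices]
            per_beam = []
            for trace in self._traces:
                t, _ = trace.beam_coords(pts)
                w = trace.wepl_at(pts)
                per_beam.append((t, w))
            self._vox_cache[key] = per_beam
        return self._vox_cache[key]

    def influence(
        self, scenario: Scenario, voxel_indices: Optional[np.ndarray] = None
    ) -> DoseInfluence:
        if voxel_indices is None:
            voxel_indices = np.arange(int(np.prod(self.rsp.shape)))
        voxel_indices = np.asarray(voxel_indices)
        per_beam = self._voxel_data(voxel_indices)
        shift = np.asarray(scenario.shift, dtype=float)[: self.rsp.ndim]
        rows = []
        for beam, trace, (t, w) in zip(self.beams, self._traces, per_beam):
            if beam.n_spots == 0:
                continue
            # the beam shifted by -shift: spot axes move laterally
            t_spots = beam.lateral + shift @ trace.l
            wepl = np.maximum(w * scenario.density_scale, 0.0)
            depth = wepl[None, :]
            ranges = beam.nominal_range[:, None]
            block = bragg_curve(ranges, depth, self.bragg)
            block *= np.exp(
                -((t[None, :] - t_spots[:, None]) ** 2)
                / (2.0 * beam.lateral_sigma**2)
            )
            rows.append(block)
        dense = np.concatenate(rows, axis=0) * self.rbe_factor
        # sparsify: drop entries below threshold x each spot's maximum
        maxima = dense.max(axis=1, keepdims=True)
        dense[dense < self.sparse_threshold * np.maximum(maxima, 1e-300)] = 0.0
        mat = sparse.csr_matrix(dense)
        return DoseInfluence(
            mat, voxel_indices, scenario, self.rsp.shape, self.rbe_factor
        )

    def influence_set(
        self,
        scenarios: Sequence[Scenario],
        voxel_indices: Optional[np.ndarray] = None,
    ) -> List[DoseInfluence]:
        return [self.influence(s, voxel_indices) for s in scenarios]


def _voxel_centers(rsp: RSPMap) -> np.ndarray:
    mesh = np.meshgrid(*rsp.axis_coords(), indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def build_influence(
    beams: Sequence[Beam],
    rsp: RSPMap,
    scenario: Scenario,
    structures: Optional[StructureSet] = None,
    *,
    voxel_indices: Optional[np.ndarray] = None,
    bragg: Optional[BraggParams] = None,
    rbe_factor: float = RBE_FACTOR,
    sparse_threshold: float = 1e-4,
) -> DoseInfluence:
    """Assemble the sparse dose-influence matrix for one scenario.

    If ``voxel_indices`` is omitted, columns default to the voxels inside the
    external contour (when ``structures`` is given) or the whole grid.
    """
    if voxel_indices is None and structures is not None:
        voxel_indices = np.flatnonzero(structures.external.ravel())
    engine = InfluenceEngine(
        rsp, beams, bragg=bragg, rbe_factor=rbe_factor,
        sparse_threshold=sparse_threshold,
    )
    return engine.influence(scenario, voxel_indices)


# ---------------------------------------------------------------------------
# Spot design and filtering
# ---------------------------------------------------------------------------


def design_spots(
    rsp: RSPMap,
    structures: StructureSet,
    angles: Sequence[float] = DEFAULT_BEAM_ANGLES,
    *,
    lateral_spacing: float = 5.0,
    range_spacing: float = 5.0,
    lateral_margin: float = 6.0,
    range_margin: float = 3.0,
    range_expansion: float = 0.0,
    shift_margin: float = 3.0,
    lateral_sigma: float = 4.0,
) -> List[Beam]:
    """Lay out a target-conformal spot lattice per beam angle.

    For each angle, lateral spot positions tile the low-dose target's lateral
    extent (plus margin) and, per lateral position, nominal ranges tile the
    WEPL interval spanned by target voxels near that axis (plus margin), at
    the configured spacings.  ``range_expansion`` widens the range interval
    by the fractional density scaling the plan will be optimized with
    (range-error scenarios need peaks proximal/distal to the nominal
    extent), i.e. it should be at least the plan's range robustness setting.
    ``shift_margin`` (mm) widens the lateral neighborhood whose target WEPLs
    define each range interval, so that laterally shifted scenarios — where a
    voxel may sit behind very different upstream material, e.g. an air
    cavity — remain coverable; it should be at least the setup robustness
    setting.
    """
    target = structures.ctv_low
    idx = np.flatnonzero(target.ravel())
    if idx.size == 0:
        raise ValueError("target mask is empty")
    centers = _voxel_centers(rsp)[idx]
    beams = []
    for angle in angles:
        trace = _BeamTrace(rsp, angle)
        t, _ = trace.beam_coords(centers)
        w = trace.wepl_at(centers)
        lat_positions = np.arange(
            t.min() - lateral_margin, t.max() + lateral_margin + 1e-9, lateral_spacing
        )
        spot_lat, spot_rng = [], []
        for lp in lat_positions:
            near = np.abs(t - lp) <= lateral_spacing + shift_margin
            if not near.any():
                continue
            w_lo = max(
                (1.0 - range_expansion) * w[near].min() - range_margin,
                2.0 * range_spacing,
            )
            w_hi = (1.0 + range_expansion) * w[near].max() + range_margin
            if w_hi < w_lo:
                continue
            ranges = np.arange(w_lo, w_hi + 1e-9, range_spacing)
            spot_lat.extend([lp] * ranges.size)
            spot_rng.extend(ranges.tolist())
        if spot_lat:
            beams.append(
                Beam(angle, np.array(spot_lat), np.array(spot_rng), lateral_sigma)
            )
    if not beams:
        raise ValueError("no deliverable spots found for the given geometry")
    return beams


def filter_spots(
    beams: Sequence[Beam],
    rsp: RSPMap,
    avoidance: np.ndarray,
    *,
    step: float = 1.0,
) -> List[Beam]:
    """Remove spots whose central ray crosses an avoidance voxel proximal to
    the Bragg peak (nominal scenario); surviving spot order is preserved."""
    avoidance = np.asarray(avoidance, dtype=bool)
    if not avoidance.any():
        return [b.subset(np.ones(b.n_spots, dtype=bool)) for b in beams]
    origin = np.asarray(rsp.origin)
    spacing = np.asarray(rsp.spacing)
    out = []
    for beam in beams:
        trace = _BeamTrace(rsp, beam.angle_deg, step=step)
        ns = trace.wepl_grid.shape[1]
        dep = trace.s0 + (np.arange(ns) + 0.5) * step
        keep = np.ones(beam.n_spots, dtype=bool)
        for i in range(beam.n_spots):
            pts = beam.lateral[i] * trace.l[None, :] + dep[:, None] * trace.d[None, :]
            idx = np.rint((pts - origin[None, :]) / spacing[None, :]).astype(int)
            inside = np.all((idx >= 0) & (idx < np.asarray(rsp.shape)[None, :]), axis=1)
            avoid_hit = np.zeros(ns, dtype=bool)
            avoid_hit[inside] = avoidance[idx[inside, 0], idx[inside, 1]]
            # WEPL along this central ray
            it = (beam.lateral[i] - trace.t0) / trace.ray_spacing
            wepl = ndimage.map_coordinates(
                trace.wepl_grid, [np.full(ns, it), np.arange(ns, dtype=float)],
                order=1, mode="nearest",
            )
            proximal = wepl < beam.nominal_range[i]
            if np.any(avoid_hit & proximal):
                keep[i] = False
        out.append(beam.subset(keep))
    return out
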