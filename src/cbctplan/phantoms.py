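"""Synthetic head-and-neck-like phantom cohorts.

Generates the three anatomies the planning study needs:

* a ground-truth voxel image ("in-room CT") with body, bone shell, air cavity,
  nested clinical target volumes and organs at risk;
* a paired CBCT-like image obtained by corrupting the ground truth with a
  structured Hounsfield-unit error field (global elevation, spatially
  correlated noise, boosted errors around bone/air interfaces, and a small
  rigid intra-fraction motion residue);
* an earlier "planning-CT" anatomy in which the targets have drifted, used to
  emulate a non-adaptive/offline planning workflow.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Optional, Tuple

import numpy as np
from scipy import ndimage

HU_MIN = -1024.0
HU_MAX = 3071.0

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "ImageGrid",
    "StructureSet",
    "PhantomConfig",
    "ErrorFieldParams",
    "AnatomyChangeParams",
    "generate_phantom",
    "generate_cbct",
    "generate_planning_anatomy",
]


@dataclass(eq=False)
class ImageGrid:
    """Regular voxel grid of CT numbers (HU).

    ``values[i, j]`` lives at world position ``origin + index * spacing`` (mm);
    2-D grids are the default study geometry, 3-D grids are accepted.
    """

    values: np.ndarray
    spacing: Tuple[float, ...]
    origin: Tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("ImageGrid supports 2-D or 3-D arrays")
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * self.values.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.values.ndim:
            raise ValueError("spacing length must match image dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.origin is None:
            self.origin = (0.0,) * self.values.ndim
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.origin) != self.values.ndim:
            raise ValueError("origin length must match image dimensionality")
        if self.values.size and (
            self.values.min() < HU_MIN or self.values.max() > HU_MAX
        ):
            raise ValueError(f"HU values must lie within [{HU_MIN}, {HU_MAX}]")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def axis_coords(self) -> Tuple[np.ndarray, ...]:
        """World coordinate (mm) of voxel centres, one 1-D array per axis."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(self.ndim)
        )

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, ndim) array of world coordinates in C (flat) order."""
        mesh = np.meshgrid(*self.axis_coords(), indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def same_grid(self, other: "ImageGrid") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        return ImageGrid(values, self.spacing, self.origin)


@dataclass(eq=False)
class StructureSet:
    """Named binary masks aligned to one grid.

    Invariants: ``ctv_high ⊆ ctv_low ⊆ external``, all masks share one shape,
    and every organ at risk is disjoint from ``ctv_high``.
    """

    external: np.ndarray
    ctv_high: np.ndarray
    ctv_low: np.ndarray
    oars: Dict[str, np.ndarray]
    avoidance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.external = np.asarray(self.external, dtype=bool)
        self.ctv_high = np.asarray(self.ctv_high, dtype=bool)
        self.ctv_low = np.asarray(self.ctv_low, dtype=bool)
        self.oars = {k: np.asarray(v, dtype=bool) for k, v in self.oars.items()}
        if self.avoidance is None:
            self.avoidance = np.zeros_like(self.external)
        self.avoidance = np.asarray(self.avoidance, dtype=bool)
        shape = self.external.shape
        for name, mask in self.items():
            if mask.shape != shape:
                raise ValueError(f"mask {name!r} shape {mask.shape} != {shape}")
        if not self.oars:
            raise ValueError("at least one organ at risk is required")
        if np.any(self.ctv_high & ~self.ctv_low):
            raise ValueError("ctv_high must be contained in ctv_low")
        if np.any(self.ctv_low & ~self.external):
            raise ValueError("ctv_low must be contained in external")
        for name, oar in self.oars.items():
            if np.any(oar & self.ctv_high):
                raise ValueError(f"OAR {name!r} overlaps ctv_high")

    def items(self) -> Iterator[Tuple[str, np.ndarray]]:
        yield "external", self.external
        yield "ctv_high", self.ctv_high
        yield "ctv_low", self.ctv_low
        for name, mask in self.oars.items():
            yield f"oar_{name}", mask
        yield "avoidance", self.avoidance

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.external.shape


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Geometry and tissue parameters of the synthetic axial-slice phantom.

    Lengths are millimetres in world coordinates; semi-axes are given as
    (y, x) pairs.  ``*_jitter`` entries are the half-width of the uniform
    per-phantom variation applied to the corresponding quantity.
    """

    shape: Tuple[int, ...] = (128, 128)
    spacing: float = 2.0
    hu_air: float = -1000.0
    hu_soft: float = 30.0
    hu_bone: float = 700.0

    body_semi: Tuple[float, float] = (75.0, 92.0)
    body_jitter: float = 4.0
    shell_band: Tuple[float, float] = (0.86, 0.96)  # normalized body radius
    vertebra_offset: Tuple[float, float] = (42.0, 0.0)
    vertebra_radius: float = 10.0
    cavity_offset: Tuple[float, float] = (-30.0, -10.0)
    cavity_semi: Tuple[float, float] = (12.0, 16.0)
    cavity_jitter: float = 3.0
    ctv_low_offset: Tuple[float, float] = (5.0, 32.0)
    ctv_low_semi: Tuple[float, float] = (21.0, 26.0)
    ctv_jitter: float = 3.0
    ctv_high_semi: Tuple[float, float] = (10.0, 13.0)
    parotid_offset: Tuple[float, float] = (-26.0, 20.0)
    parotid_semi: Tuple[float, float] = (10.0, 12.0)
    constrictor_offset: Tuple[float, float] = (28.0, 2.0)
    constrictor_semi: Tuple[float, float] = (6.0, 16.0)
    oar_jitter: float = 2.0
    metal_radius: float = 0.0  # 0 disables the avoidance ("metal") disk
    metal_offset: Tuple[float, float] = (-15.0, 20.0)

    @classmethod
    def compact(cls) -> "PhantomConfig":
        """Half-scale geometry on a 64x64 grid, for quick tests."""
        base = cls()
        scaled = {}
        for name in (
            "body_semi", "vertebra_offset", "cavity_offset", "cavity_semi",
            "ctv_low_offset", "ctv_low_semi", "ctv_high_semi",
            "parotid_offset", "parotid_semi", "constrictor_offset",
            "constrictor_semi", "metal_offset",
        ):
            scaled[name] = tuple(0.5 * v for v in getattr(base, name))
        return replace(
            base,
            shape=(64, 64),
            body_jitter=2.0,
            cavity_jitter=1.5,
            ctv_jitter=1.5,
            oar_jitter=1.0,
            vertebra_radius=5.0,
            **scaled,
        )


def _ellipse_mask(
    coords: Tuple[np.ndarray, np.ndarray],
    center: Tuple[float, float],
    semi: Tuple[float, float],
) -> np.ndarray:
    yy = (coords[0][:, None] - center[0]) / semi[0]
    xx = (coords[1][None, :] - center[1]) / semi[1]
    return yy**2 + xx**2 <= 1.0


def _check_inside(
    name: str,
    center: Tuple[float, float],
    semi: Tuple[float, float],
    extent: Tuple[float, float],
) -> None:
    for a in range(2):
        if center[a] - semi[a] < 0 or center[a] + semi[a] > extent[a]:
            raise ValueError(
                f"structure {name!r} (center {center}, semi-axes {semi}) "
                f"does not fit inside the grid extent {extent}"
            )


def generate_phantom(
    seed: int, config: Optional[PhantomConfig] = None
) -> Tuple[ImageGrid, StructureSet]:
    """Generate one seeded phantom: noise-free HU image plus structure masks."""
    cfg = config or PhantomConfig()
    if len(cfg.shape) != 2:
        raise ValueError("generate_phantom builds 2-D (axial slice) phantoms")
    rng = np.random.default_rng(seed)
    spacing = (cfg.spacing, cfg.spacing)
    extent = tuple((n - 1) * cfg.spacing for n in cfg.shape)
    center = tuple(e / 2.0 for e in extent)
    coords = tuple(
        np.arange(n) * cfg.spacing for n in cfg.shape
    )

    def jitter(half: float, size: int = 2) -> np.ndarray:
        return rng.uniform(-half, half, size=size)

    body_semi = np.asarray(cfg.body_semi) + jitter(cfg.body_jitter)
    body_c = np.asarray(center)
    _check_inside("body", tuple(body_c), tuple(body_semi), extent)
    body = _ellipse_mask(coords, tuple(body_c), tuple(body_semi))

    # bone: elliptical shell near the body surface plus a vertebra-like disk
    yy = (coords[0][:, None] - body_c[0]) / body_semi[0]
    xx = (coords[1][None, :] - body_c[1]) / body_semi[1]
    rnorm = np.sqrt(yy**2 + xx**2)
    shell = (rnorm >= cfg.shell_band[0]) & (rnorm <= cfg.shell_band[1])
    vert_c = body_c + np.asarray(cfg.vertebra_offset) + jitter(1.5)
    vert = _ellipse_mask(
        coords, tuple(vert_c), (cfg.vertebra_radius, cfg.vertebra_radius)
    )
    bone = (shell | vert) & body

    cavity_c = body_c + np.asarray(cfg.cavity_offset) + jitter(cfg.cavity_jitter)
    cavity_semi = np.maximum(np.asarray(cfg.cavity_semi) + jitter(1.5), 4.0)
    _check_inside("air_cavity", tuple(cavity_c), tuple(cavity_semi), extent)
    cavity = _ellipse_mask(coords, tuple(cavity_c), tuple(cavity_semi)) & body

    low_c = body_c + np.asarray(cfg.ctv_low_offset) + jitter(cfg.ctv_jitter)
    low_semi = np.maximum(np.asarray(cfg.ctv_low_semi) + jitter(2.0), 6.0)
    _check_inside("ctv_low", tuple(low_c), tuple(low_semi), extent)
    high_c = low_c + jitter(min(3.0, cfg.ctv_jitter))
    high_semi = np.maximum(np.asarray(cfg.ctv_high_semi) + jitter(1.0), 4.0)
    ctv_low = _ellipse_mask(coords, tuple(low_c), tuple(low_semi))
    ctv_high = _ellipse_mask(coords, tuple(high_c), tuple(high_semi))
    ctv_low |= ctv_high
    ctv_low &= body & ~cavity
    ctv_high &= ctv_low

    par_c = body_c + np.asarray(cfg.parotid_offset) + jitter(cfg.oar_jitter)
    par = _ellipse_mask(coords, tuple(par_c), tuple(cfg.parotid_semi)) & body
    con_c = body_c + np.asarray(cfg.constrictor_offset) + jitter(cfg.oar_jitter)
    con = _ellipse_mask(coords, tuple(con_c), tuple(cfg.constrictor_semi)) & body
    # both OAR analogues abut the elective target but are kept out of it, so
    # their dose is penumbra- and margin-driven
    par &= ~ctv_low
    con &= ~ctv_low

    avoidance = np.zeros(cfg.shape, dtype=bool)
    hu = np.full(cfg.shape, cfg.hu_air)
    hu[body] = cfg.hu_soft
    hu[bone] = cfg.hu_bone
    hu[cavity] = cfg.hu_air
    if cfg.metal_radius > 0:
        metal_c = body_c + np.asarray(cfg.metal_offset)
        metal = _ellipse_mask(
            coords, tuple(metal_c), (cfg.metal_radius, cfg.metal_radius)
        ) & body
        avoidance |= metal
        hu[metal] = HU_MAX

    image = ImageGrid(hu, spacing)
    structures = StructureSet(
        external=body,
        ctv_high=ctv_high,
        ctv_low=ctv_low,
        oars={"parotid": par, "constrictor": con},
        avoidance=avoidance,
    )
    return image, structures


# ---------------------------------------------------------------------------
# CBCT-like HU corruption
# ---------------------------------------------------------------------------


@dataclass
class ErrorFieldParams:
    """Statistical description of the CBCT HU-error field.

    Defaults are calibrated so a default-geometry cohort reproduces the
    population CT-number error statistics the study design assumes
    (population-mean MAE ~145 HU, ME ~22 HU inside the body, air excluded).

    * ``global_offset_*``: per-image constant HU elevation, drawn once per
      phantom from N(mean, sd).
    * ``noise_amplitude`` / ``noise_corr_length``: zero-mean spatially
      correlated field (low-pass filtered white noise), sd in HU and Gaussian
      correlation length in mm.
    * ``interface_amplitude``: extra error inside a band around bone/air
      boundaries (dilated boundary, ``interface_radius_vox``); the band error
      has mean ``interface_bias * interface_amplitude`` (CBCT numbers tend to
      be elevated near interfaces) and sd ``interface_amplitude``.
    * ``motion_sd``: sd (mm per axis) of a small rigid displacement applied to
      the anatomy before differencing, emulating intra-fraction motion.
    """

    global_offset_mean: float = 15.0
    global_offset_sd: float = 20.0
    noise_amplitude: float = 100.0
    noise_corr_length: float = 25.0
    interface_amplitude: float = 240.0
    interface_bias: float = 0.25
    interface_radius_vox: int = 2
    motion_sd: float = 0.7

    def __post_init__(self) -> None:
        for name in ("noise_amplitude", "interface_amplitude", "global_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_corr_length <= 0:
            raise ValueError("noise_corr_length must be > 0")
        if self.motion_sd < 0:
            raise ValueError("motion_sd must be >= 0")

    @classmethod
    def zero(cls) -> "ErrorFieldParams":
        return cls(
            global_offset_mean=0.0,
            global_offset_sd=0.0,
            noise_amplitude=0.0,
            interface_amplitude=0.0,
            motion_sd=0.0,
        )


def _correlated_field(
    rng: np.random.Generator,
    shape: Tuple[int, ...],
    corr_length_mm: float,
    spacing: Tuple[float, ...],
    norm_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Random field with ~Gaussian correlation (low-pass filtered white
    noise), normalized to unit sd inside ``norm_mask`` (whole grid if None)."""
    white = rng.standard_normal(shape)
    sigma_vox = [corr_length_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = smooth[norm_mask].std() if norm_mask is not None else smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth / sd


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def generate_cbct(
    ct: ImageGrid,
    structures: StructureSet,
    params: Optional[ErrorFieldParams] = None,
    seed: int = 0,
) -> ImageGrid:
    """Corrupt a ground-truth image into a CBCT-like image (seeded)."""
    p = params or ErrorFieldParams()
    if ct.shape != structures.shape:
        raise ValueError("image and structures must share a grid")
    rng = np.random.default_rng(seed)
    values = ct.values

    # intra-fraction motion residue: the CBCT sees a slightly moved anatomy
    if p.motion_sd > 0:
        disp_mm = rng.normal(0.0, p.motion_sd, size=ct.ndim)
        disp_vox = disp_mm / np.asarray(ct.spacing)
        values = ndimage.shift(values, disp_vox, order=1, mode="nearest")

    error = np.zeros(ct.shape)
    if p.global_offset_sd > 0 or p.global_offset_mean != 0:
        error += rng.normal(p.global_offset_mean, p.global_offset_sd)
    if p.noise_amplitude > 0:
        error += p.noise_amplitude * _correlated_field(
            rng, ct.shape, p.noise_corr_length, ct.spacing,
            norm_mask=structures.external,
        )
    if p.interface_amplitude > 0:
        bone = ct.values >= 300.0
        air_cavity = (ct.values < -960.0) & structures.external
        edges = _boundary(bone) | _boundary(air_cavity)
        band = ndimage.binary_dilation(edges, iterations=p.interface_radius_vox)
        band_noise = _correlated_field(
            rng, ct.shape, 0.5 * p.noise_corr_length, ct.spacing
        )
        error += band * p.interface_amplitude * (p.interface_bias + band_noise)

    corrupted = np.clip(values + error, HU_MIN, HU_MAX)
    return ct.with_values(corrupted)


# ---------------------------------------------------------------------------
# Earlier planning-CT anatomy
# ---------------------------------------------------------------------------


@dataclass
class AnatomyChangeParams:
    """Systematic inter-fraction change applied to derive the earlier anatomy.

    The clinical target volumes of the earlier planning anatomy are rigidly
    shifted (magnitude |N(shift_mean, shift_sd)| mm, clipped at ``shift_max``,
    random direction) and isotropically rescaled about the low-dose target's
    centroid (factor N(1, scale_sd)).  The HU image is unchanged: the targets
    are soft-tissue-equivalent, so target drift is invisible in HU.
    """

    shift_mean: float = 2.5
    shift_sd: float = 1.2
    shift_max: float = 6.0
    scale_sd: float = 0.04

    @classmethod
    def zero(cls) -> "AnatomyChangeParams":
        return cls(shift_mean=0.0, shift_sd=0.0, shift_max=0.0, scale_sd=0.0)


def _transform_mask(
    mask: np.ndarray,
    shift_vox: np.ndarray,
    scale: float,
    center_vox: np.ndarray,
) -> np.ndarray:
    if scale == 1.0 and not np.any(shift_vox):
        return mask.copy()
    matrix = np.eye(mask.ndim) / scale
    offset = center_vox - center_vox / scale - shift_vox / scale
    out = ndimage.affine_transform(
        mask.astype(float), matrix, offset=offset, order=1, mode="constant"
    )
    return out >= 0.5


def generate_planning_anatomy(
    ct: ImageGrid,
    structures: StructureSet,
    params: Optional[AnatomyChangeParams] = None,
    seed: int = 0,
) -> Tuple[ImageGrid, StructureSet]:
    """Derive the earlier planning anatomy by drifting the targets (seeded)."""
    p = params or AnatomyChangeParams()
    rng = np.random.default_rng(seed)
    magnitude = min(abs(rng.normal(p.shift_mean, p.shift_sd)), p.shift_max)
    angle = rng.uniform(0.0, 2.0 * np.pi)
    direction = np.array([np.cos(angle), np.sin(angle)])[: ct.ndim]
    if ct.ndim == 3:
        direction = np.append(direction, 0.0)
    shift_mm = magnitude * direction
    scale = float(np.clip(rng.normal(1.0, p.scale_sd), 0.85, 1.15)) if p.scale_sd > 0 else 1.0

    spacing = np.asarray(ct.spacing)
    shift_vox = shift_mm / spacing
    idx = np.argwhere(structures.ctv_low)
    if idx.size == 0:
        raise ValueError("ctv_low is empty")
    center_vox = idx.mean(axis=0)

    # reject transforms that would push the target out of the grid
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    for corner in (lo, hi):
        moved = (corner - center_vox) * scale + center_vox + shift_vox
        if np.any(moved < 0) or np.any(moved > np.asarray(ct.shape) - 1):
            raise ValueError("anatomy change moves the target outside the grid")

    new_high = _transform_mask(structures.ctv_high, shift_vox, scale, center_vox)
    new_low = _transform_mask(structures.ctv_low, shift_vox, scale, center_vox)
    new_low |= new_high
    # targets stay in soft tissue: clip at the body and at air cavities
    not_air = ct.values >= -960.0
    new_low &= structures.external & not_air
    new_high &= new_low
    if not new_high.any() or not new_low.any():
        raise ValueError("anatomy change produced an empty target")

    oars = {k: v & ~new_high for k, v in structures.oars.items()}
    new_structs = StructureSet(
        external=structures.external.copy(),
        ctv_high=new_high,
        ctv_low=new_low,
        oars=oars,
        avoidance=structures.avoidance.copy(),
    )
    return ct.with_values(ct.values.copy()), new_structs
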