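"""Error-scenario sets for robust optimization and robust evaluation.

A scenario couples an isocenter shift (magnitude = setup robustness setting,
SRS, in mm) with a mass-density scale factor (1 +- range robustness setting,
RRS).  The set always contains the nominal scenario (no shift, scale 1) plus
one scenario per (direction, +-RRS) pair, so its size is
``1 + 2 * n_directions``: 29 scenarios for the standard 14-direction 3-D set,
17 for the 8-direction 2-D set.  Range errors occur only in combination with
shifts — there are no pure-range scenarios.

The same constructor serves optimization and evaluation sets, so the two can
never drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["Scenario", "generate_scenarios", "default_directions", "scenario_set"]


@dataclass(frozen=True)
class Scenario:
    """One robust-optimization error realization."""

    shift: Tuple[float, ...]
    density_scale: float
    label: str = "shift+range"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift", tuple(float(s) for s in self.shift))
        if self.density_scale <= 0:
            raise ValueError("density_scale must be > 0")
        if self.label == "nominal":
            if any(s != 0 for s in self.shift) or self.density_scale != 1.0:
                raise ValueError("nominal scenario must have zero shift and scale 1")

    @property
    def is_nominal(self) -> bool:
        return self.label == "nominal"

    @classmethod
    def nominal(cls, ndim: int = 2) -> "Scenario":
        return cls((0.0,) * ndim, 1.0, "nominal")


def default_directions(dimension: int) -> List[np.ndarray]:
    """Standard unit shift directions.

    3-D: the 14-direction set of 6 cube faces plus 8 normalized cube
    vertices; 2-D: 4 axes plus 4 normalized diagonals (8 directions).
    """
    if dimension == 2:
        raw = [
            (1, 0), (-1, 0), (0, 1), (0, -1),
            (1, 1), (1, -1), (-1, 1), (-1, -1),
        ]
    elif dimension == 3:
        raw = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        ] + [(sy, sx, sz) for sy in (1, -1) for sx in (1, -1) for sz in (1, -1)]
    else:
        raise ValueError("dimension must be 2 or 3")
    return [np.asarray(v, dtype=float) / np.linalg.norm(v) for v in raw]


def generate_scenarios(
    srs: float,
    rrs: float,
    directions: Sequence[Sequence[float]],
) -> List[Scenario]:
    """Nominal scenario plus one per (direction, +-RRS) pair.

    ``srs`` is the shift magnitude in mm; ``rrs`` the fractional density
    scaling.  The returned count is ``1 + 2 * len(directions)``.
    """
    if srs < 0:
        raise ValueError("srs must be >= 0")
    if not 0 <= rrs < 1:
        raise ValueError("rrs must lie in [0, 1)")
    directions = [np.asarray(d, dtype=float) for d in directions]
    if not directions and srs > 0:
        raise ValueError("directions must be non-empty when srs > 0")
    ndim = directions[0].size if directions else 2
    scenarios = [Scenario.nominal(ndim)]
    for d in directions:
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("shift directions must be nonzero")
        unit = d / norm
        for sign in (-1.0, 1.0):
            scenarios.append(
                Scenario(tuple(srs * unit), 1.0 + sign * rrs, "shift+range")
            )
    return scenarios


def scenario_set(srs: float, rrs: float, dimension: int = 2) -> List[Scenario]:
    """Convenience wrapper: default direction set for the given dimension."""
    return generate_scenarios(srs, rrs, default_directions(dimension))
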