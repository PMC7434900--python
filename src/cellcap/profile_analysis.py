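"""Proliferation-capacity profiles over founder size, and their shape.

A profile sweeps the founder newborn size ``V0`` over a grid, computes the
proliferation capacity at each point, and classifies the resulting curve as
increasing, decreasing, constant, unimodal (bell-shaped, the signature of a
target cell size), unimodal-then-increasing, or other.  Normalization —
sizes by the homeostatic size V̄, capacities by the capacity at a reference
size — matches how such curves are conventionally plotted and makes the
shape label invariant to any global rescaling of the capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .growth_laws import GrowthLaw
from .proliferation import ExperimentConfig, proliferation_capacity
from .size_dynamics import DivisionRule

__all__ = [
    "SHAPES",
    "ProfileConfig",
    "Profile",
    "default_grid",
    "compute_profile",
    "classify_shape",
]

SHAPES = (
    "increasing",
    "decreasing",
    "constant",
    "unimodal",
    "unimodal_then_increasing",
    "other",
)

#: relative tolerance below which neighbouring capacities count as equal
DEFAULT_SHAPE_TOL = 1e-9


def default_grid(vbar: float, n_points: int = 200, lo: Optional[float] = None,
                 hi: Optional[float] = None) -> np.ndarray:
    """Geometric founder-size grid, by default spanning [V̄/10, 3V̄]."""
    lo = vbar / 10.0 if lo is None else lo
    hi = 3.0 * vbar if hi is None else hi
    if not (0 < lo < hi):
        raise UsageError(f"grid bounds must satisfy 0 < lo < hi, got ({lo}, {hi})")
    return np.geomspace(lo, hi, n_points)


@dataclass(frozen=True)
class ProfileConfig:
    """Sweep settings: the ``v0`` grid, normalization flag, reference size.

    ``v0_grid=None`` defers to :func:`default_grid` at compute time;
    ``reference_size=None`` defaults to the rule's V̄.
    """

    v0_grid: Optional[np.ndarray] = None
    normalize: bool = True
    reference_size: Optional[float] = None

    def resolved_grid(self, vbar: float) -> np.ndarray:
        grid = default_grid(vbar) if self.v0_grid is None else np.asarray(self.v0_grid, float)
        if grid.ndim != 1 or len(grid) < 2 or not np.all(np.diff(grid) > 0) or grid[0] <= 0:
            raise UsageError("v0_grid must be a strictly increasing 1-d array of positive sizes")
        return grid


@dataclass(frozen=True)
class Profile:
    """A computed capacity-vs-founder-size curve with its shape label."""

    v0: np.ndarray
    capacity: np.ndarray
    v0_normalized: np.ndarray
    capacity_normalized: np.ndarray
    shape: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v0": self.v0,
                "capacity": self.capacity,
                "v0_normalized": self.v0_normalized,
                "capacity_normalized": self.capacity_normalized,
            }
        )

    def to_csv(self, path) -> None:
        """Write the profile with repr-exact double precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, tol: float = DEFAULT_SHAPE_TOL) -> "Profile":
        capacity = frame["capacity"].to_numpy(float)
        return cls(
            v0=frame["v0"].to_numpy(float),
            capacity=capacity,
            v0_normalized=frame["v0_normalized"].to_numpy(float),
            capacity_normalized=frame["capacity_normalized"].to_numpy(float),
            shape=classify_shape(capacity, tol=tol),
        )

    @classmethod
    def from_csv(cls, path, tol: float = DEFAULT_SHAPE_TOL) -> "Profile":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"), tol=tol)

    def plot(self, ax=None, normalized: bool = True):
        """Plot the profile (normalized axes by default); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.v0_normalized if normalized else self.v0
        y = self.capacity_normalized if normalized else self.capacity
        ax.plot(x, y)
        ax.set_xlabel("newborn size / V̄" if normalized else "newborn size")
        ax.set_ylabel("proliferation capacity" + (" (normalized)" if normalized else ""))
        ax.set_title(f"shape: {self.shape}")
        return ax


def compute_profile(
    rule: DivisionRule,
    law: GrowthLaw,
    t_f: float,
    cfg: Optional[ProfileConfig] = None,
    tol: float = DEFAULT_SHAPE_TOL,
) -> Profile:
    """Sweep ``v0`` over the grid and build the classified capacity profile.

    The x-axis is normalized by V̄ and the y-axis by the capacity at the
    reference size (linearly interpolated when it is not a grid point).
    """
    cfg = cfg or ProfileConfig()
    grid = cfg.resolved_grid(rule.vbar)
    capacity = np.array(
        [
            proliferation_capacity(rule, law, ExperimentConfig(t_f=t_f, v0=v0)).capacity
            for v0 in grid
        ]
    )
    reference = cfg.reference_size if cfg.reference_size is not None else rule.vbar
    if cfg.normalize:
        ref_capacity = float(np.interp(reference, grid, capacity))
        capacity_normalized = capacity / ref_capacity
    else:
        capacity_normalized = capacity.copy()
    return Profile(
        v0=grid,
        capacity=capacity,
        v0_normalized=grid / rule.vbar,
        capacity_normalized=capacity_normalized,
        shape=classify_shape(capacity, tol=tol),
    )


def classify_shape(capacities: Sequence[float], tol: float = DEFAULT_SHAPE_TOL) -> str:
    """Label a curve by the signs of its neighbour differences.

    Differences smaller than ``tol`` (relative to the larger neighbour) are
    treated as zero; runs of equal signs are collapsed, and flat stretches
    inside an otherwise monotone or unimodal curve are ignored.  Patterns:
    ``+`` increasing, ``−`` decreasing, all-zero constant, ``+−`` unimodal,
    ``+−+`` unimodal-then-increasing, anything else other.
    """
    c = np.asarray(capacities, float)
    if c.ndim != 1 or len(c) < 5:
        raise UsageError(f"need at least 5 points to classify a shape, got {c.shape}")
    diffs = np.diff(c)
    scale = np.maximum(np.abs(c[:-1]), np.abs(c[1:]))
    signs = np.where(np.abs(diffs) <= tol * scale, 0, np.sign(diffs)).astype(int)
    nonzero = signs[signs != 0]
    if len(nonzero) == 0:
        return "constant"
    pattern = [int(nonzero[0])]
    for s in nonzero[1:]:
        if s != pattern[-1]:
            pattern.append(int(s))
    if pattern == [1]:
        return "increasing"
    if pattern == [-1]:
        return "decreasing"
    if pattern == [1, -1]:
        return "unimodal"
    if pattern == [1, -1, 1]:
        return "unimodal_then_increasing"
    return "other"
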