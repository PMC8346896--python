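"""Age-basis construction for group trajectories.

Each latent group's expected count follows a log-linear curve in an age
basis: polynomial powers of a rescaled age (default cubic) or a cubic
B-spline with interior knots.  Age is transformed as
``a* = (age - center) / scale`` before powers are taken; with the default
center 21.5 and scale 10, ages 10–33 map to roughly [-1.15, 1.15], which
keeps the cubic design matrix well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["TrajectorySpec"]


@dataclass(frozen=True)
class TrajectorySpec:
    """Basis specification shared by (or specific to) a trajectory group.

    Parameters
    ----------
    kind : {"polynomial", "spline"}
    degree : int
        Polynomial degree (ignored for splines, which are cubic).
    knots : tuple of float
        Interior knot ages for the spline basis; must be strictly
        increasing and strictly inside the observed age range.
    center, scale : float
        Age transform ``a* = (age - center) / scale`` applied before the
        polynomial powers.  Splines operate on raw ages.
    """

    kind: str = "polynomial"
    degree: int = 3
    knots: tuple = field(default_factory=tuple)
    center: float = 21.5
    scale: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("polynomial", "spline"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "polynomial" and self.degree < 0:
            raise ValueError("polynomial degree must be >= 0")
        if self.kind == "spline":
            k = np.asarray(self.knots, dtype=float)
            if len(k) and not np.all(np.diff(k) > 0):
                raise ValueError("spline knots must be strictly increasing")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n_basis(self) -> int:
        """Number of basis columns (including the implicit intercept)."""
        if self.kind == "polynomial":
            return self.degree + 1
        return len(self.knots) + 4  # cubic B-spline dimension

    @property
    def total_order(self) -> int:
        """Ordering key for model-selection tie-breaks: lower is simpler."""
        return self.n_basis - 1

    def transform(self, ages) -> np.ndarray:
        return (np.asarray(ages, dtype=float) - self.center) / self.scale

    def design(self, ages, age_range: tuple[float, float] | None = None) -> np.ndarray:
        """Design matrix (len(ages) × n_basis) for the log-rate model."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        if self.kind == "polynomial":
            a = self.transform(ages)
            return np.vander(a, self.degree + 1, increasing=True)
        lo = min(ages.min(), *(self.knots or (ages.min(),)))
        hi = max(ages.max(), *(self.knots or (ages.max(),)))
        if age_range is not None:
            lo, hi = min(lo, age_range[0]), max(hi, age_range[1])
        inner = np.asarray(self.knots, dtype=float)
        if len(inner) and (inner.min() <= lo or inner.max() >= hi):
            raise ValueError("spline knots must lie strictly inside the age range")
        t = np.concatenate([[lo] * 4, inner, [hi] * 4])
        return BSpline.design_matrix(ages, t, 3, extrapolate=True).toarray()

    def validate_for_range(self, lo: float, hi: float) -> None:
        if self.kind == "spline" and len(self.knots):
            k = np.asarray(self.knots, dtype=float)
            if k.min() <= lo or k.max() >= hi:
                raise ValueError(
                    f"spline knots {self.knots} not strictly inside observed ages [{lo}, {hi}]"
                )
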