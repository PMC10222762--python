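"""Tablet geometry: surface area, volume and surface-area-to-volume ratio.

Extended-release matrix tablets release drug from a hydrated HPMC gel layer,
so the exposed surface per unit volume (SA/V, cm^-1) is a first-order driver
of the release rate: for two tablets of the same formulation, the one with
the higher SA/V dissolves faster.  Round tablets are modelled as cylinders,

    SA = 2*pi*r*(r + t),    V = pi*r^2*t,

and square tablets as rectangular prisms,

    SA = 2*l^2 + 4*l*t,     V = t*l^2,

with r the radius, l the side length and t the thickness, all in cm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TabletShape",
    "TabletDimensions",
    "GeometryResult",
    "BatchGeometrySummary",
    "tablet_geometry",
    "batch_geometry_summary",
    "read_dimensions_csv",
]


class TabletShape(str, enum.Enum):
    CYLINDER = "cylinder"
    RECT_PRISM = "rect_prism"


class InvalidDimensionError(ValueError):
    """A tablet dimension violated positivity or shape constraints."""


@dataclass(frozen=True)
class TabletDimensions:
    """Measured dimensions of a single tablet.

    ``cross_dim_cm`` is the diameter for a cylinder and the side length for
    a rectangular prism.  ``weight_mg`` is informational only (it does not
    enter the geometry) but must be positive when given.
    """

    shape: TabletShape
    thickness_cm: float
    cross_dim_cm: float
    weight_mg: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", TabletShape(self.shape))
        if not self.thickness_cm > 0:
            raise InvalidDimensionError(
                f"thickness must be > 0 cm, got {self.thickness_cm}"
            )
        if not self.cross_dim_cm > 0:
            raise InvalidDimensionError(
                f"cross dimension must be > 0 cm, got {self.cross_dim_cm}"
            )
        if self.weight_mg is not None and not self.weight_mg > 0:
            raise InvalidDimensionError(
                f"weight must be > 0 mg when given, got {self.weight_mg}"
            )


@dataclass(frozen=True)
class GeometryResult:
    surface_area_cm2: float
    volume_cm3: float
    sa_v_per_cm: float


def tablet_geometry(dim: TabletDimensions) -> GeometryResult:
    """Surface area (cm^2), volume (cm^3) and SA/V (cm^-1) of one tablet."""
    t = dim.thickness_cm
    if dim.shape is TabletShape.CYLINDER:
        r = dim.cross_dim_cm / 2.0
        sa = 2.0 * math.pi * r * (r + t)
        v = math.pi * r * r * t
    else:
        l = dim.cross_dim_cm
        sa = 2.0 * l * l + 4.0 * l * t
        v = t * l * l
    return GeometryResult(surface_area_cm2=sa, volume_cm3=v, sa_v_per_cm=sa / v)


@dataclass(frozen=True)
class BatchGeometrySummary:
    """Per-batch mean and sample SD (n-1 denominator) of tablet measurements.

    ``sa_v_mean`` is the mean of per-tablet SA/V ratios by default
    (``method='mean_of_ratios'``); ``method='ratio_of_means'`` instead
    evaluates SA/V once at the mean dimensions, in which case ``sa_v_sd``
    is not defined and reported as NaN.
    """

    n: int
    shape: TabletShape
    thickness_mean: float
    thickness_sd: float
    cross_dim_mean: float
    cross_dim_sd: float
    sa_v_mean: float
    sa_v_sd: float
    weight_mean: float | None
    weight_sd: float | None
    method: str
    single_unit: bool  # SD reported as 0 from a single tablet


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 1:
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1))


def batch_geometry_summary(
    dims: Sequence[TabletDimensions], method: str = "mean_of_ratios"
) -> BatchGeometrySummary:
    """Summarise a batch of tablets of one product (same shape required)."""
    if len(dims) == 0:
        raise InvalidDimensionError("batch must contain at least one tablet")
    shapes = {d.shape for d in dims}
    if len(shapes) > 1:
        raise InvalidDimensionError(f"mixed shapes in batch: {sorted(s.value for s in shapes)}")
    if method not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown method {method!r}")
    shape = dims[0].shape
    t = np.array([d.thickness_cm for d in dims], dtype=float)
    c = np.array([d.cross_dim_cm for d in dims], dtype=float)
    weights = [d.weight_mg for d in dims]
    t_mean, t_sd = _mean_sd(t)
    c_mean, c_sd = _mean_sd(c)
    if all(w is not None for w in weights):
        w_mean, w_sd = _mean_sd(np.array(weights, dtype=float))
    else:
        w_mean = w_sd = None
    if method == "mean_of_ratios":
        ratios = np.array([tablet_geometry(d).sa_v_per_cm for d in dims])
        sa_v_mean, sa_v_sd = _mean_sd(ratios)
    else:
        mean_dim = TabletDimensions(shape=shape, thickness_cm=t_mean, cross_dim_cm=c_mean)
        sa_v_mean = tablet_geometry(mean_dim).sa_v_per_cm
        sa_v_sd = float("nan")
    return BatchGeometrySummary(
        n=len(dims),
        shape=shape,
        thickness_mean=t_mean,
        thickness_sd=t_sd,
        cross_dim_mean=c_mean,
        cross_dim_sd=c_sd,
        sa_v_mean=sa_v_mean,
        sa_v_sd=sa_v_sd,
        weight_mean=w_mean,
        weight_sd=w_sd,
        method=method,
        single_unit=len(dims) == 1,
    )


def read_dimensions_csv(path) -> dict[str, list[TabletDimensions]]:
    """Read a tablet-dimension table, one row per tablet.

    Expected columns: ``product, shape, thickness_cm, cross_dim_cm, weight_mg``
    (``weight_mg`` optional).  Returns a mapping product -> tablets.
    """
    df = pd.read_csv(path)
    required = {"product", "shape", "thickness_cm", "cross_dim_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dimension CSV missing columns: {sorted(missing)}")
    out: dict[str, list[TabletDimensions]] = {}
    for _, row in df.iterrows():
        w = row.get("weight_mg")
        out.setdefault(str(row["product"]), []).append(
            TabletDimensions(
                shape=TabletShape(row["shape"]),
                thickness_cm=float(row["thickness_cm"]),
                cross_dim_cm=float(row["cross_dim_cm"]),
                weight_mg=None if w is None or pd.isna(w) else float(w),
            )
        )
    return out


def summary_table(batches: dict[str, Sequence[TabletDimensions]]) -> pd.DataFrame:
    """Product-level summary frame (weight, thickness, cross dim, SA/V)."""
    rows = []
    for product, dims in batches.items():
        s = batch_geometry_summary(dims)
        rows.append(
            {
                "product": product,
                "n": s.n,
                "shape": s.shape.value,
                "weight_mg_mean": s.weight_mean,
                "weight_mg_sd": s.weight_sd,
                "thickness_cm_mean": s.thickness_mean,
                "thickness_cm_sd": s.thickness_sd,
                "cross_dim_cm_mean": s.cross_dim_mean,
                "cross_dim_cm_sd": s.cross_dim_sd,
                "sa_v_mean": s.sa_v_mean,
                "sa_v_sd": s.sa_v_sd,
            }
        )
    return pd.DataFrame(rows)
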