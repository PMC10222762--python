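"""Dissolution kinetics, profile handling and specification windows.

A dissolution profile is the cumulative percent of label dose dissolved at
each sampling time for one or more replicate tablet units.  ER matrix
profiles are smooth and saturating, so the Weibull function

    F(t) = fmax * (1 - exp(-(t / td)^b))

is used as the canonical release model: ``fmax`` is the asymptotic percent
released, ``td`` the time at which 63.2% of ``fmax`` has been released and
``b`` the shape (b < 1 decelerating, b = 1 first-order, b > 1 sigmoid).

Specification windows are point constraints of the pharmacopeial kind
("1 h: < 20%", "4 h: 38-48%", "24 h: not less than 80%") checked against the
mean profile across units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DissolutionProfile",
    "WeibullParams",
    "SpecPoint",
    "DissolutionSpec",
    "weibull_release",
    "fit_release",
    "q_at",
    "check_spec",
    "derive_spec",
]

Q_MAX_ALLOWED = 110.0  # small analytic overshoot above 100% tolerated
MONOTONE_NOISE_TOL = 2.0  # % of label: allowed per-unit dip from assay noise


class ProfileError(ValueError):
    """Invalid dissolution profile or incompatible profile grids."""


@dataclass(frozen=True)
class WeibullParams:
    fmax: float  # % of label, asymptotic release
    td: float    # h, 63.2% time scale
    b: float     # dimensionless shape

    def __post_init__(self) -> None:
        if not 0 < self.fmax <= 100:
            raise ValueError(f"fmax must be in (0, 100], got {self.fmax}")
        if not self.td > 0:
            raise ValueError(f"td must be > 0, got {self.td}")
        if not self.b > 0:
            raise ValueError(f"b must be > 0, got {self.b}")


def weibull_release(t, p: WeibullParams):
    """Cumulative % dissolved at time(s) ``t`` (hours) under ``p``.

    F(0) = 0 and F is monotone non-decreasing, bounded by ``p.fmax``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("release time must be >= 0 h")
    out = p.fmax * (1.0 - np.exp(-((t / p.td) ** p.b)))
    return float(out) if out.ndim == 0 else out


@dataclass
class DissolutionProfile:
    """Cumulative %-dissolved series for ``n_units`` replicate tablets.

    ``q`` has shape (n_units, n_times); times are hours, strictly increasing
    with the first sample after t = 0 (Q at t = 0 is 0 by definition).
    """

    times: np.ndarray
    q: np.ndarray
    product_id: str = ""
    method_id: str = ""
    overshoot_flag: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        if self.times.ndim != 1 or self.times.size < 1:
            raise ProfileError("times must be a non-empty 1-D array")
        if self.times[0] <= 0:
            raise ProfileError("first sampling time must be > 0 h")
        if np.any(np.diff(self.times) <= 0):
            raise ProfileError("sampling times must be strictly increasing")
        if self.q.shape[1] != self.times.size:
            raise ProfileError(
                f"q has {self.q.shape[1]} columns but {self.times.size} times"
            )
        if np.any(self.q < 0) or np.any(self.q > Q_MAX_ALLOWED):
            raise ProfileError(f"q must lie in [0, {Q_MAX_ALLOWED}] % of label")
        self.overshoot_flag = bool(np.any(self.q > 100.0))
        dips = -np.diff(self.q, axis=1)
        if np.any(dips > MONOTONE_NOISE_TOL):
            raise ProfileError(
                "per-unit series decrease by more than the "
                f"{MONOTONE_NOISE_TOL}% noise tolerance"
            )

    @property
    def n_units(self) -> int:
        return self.q.shape[0]

    def mean_q(self) -> np.ndarray:
        return self.q.mean(axis=0)


def q_at(profile: DissolutionProfile, t: float) -> float:
    """Mean % dissolved at time ``t`` by linear interpolation.

    Exact at sample times; Q(0) = 0 by definition.  Extrapolation beyond the
    last sample is refused.
    """
    if t < 0 or t > profile.times[-1]:
        raise ProfileError(
            f"t={t} h outside the sampled range [0, {profile.times[-1]}] h"
        )
    tgrid = np.concatenate(([0.0], profile.times))
    qgrid = np.concatenate(([0.0], profile.mean_q()))
    return float(np.interp(t, tgrid, qgrid))


def fit_release(profile: DissolutionProfile) -> tuple[WeibullParams, float]:
    """Least-squares Weibull fit to the mean profile; returns (params, RMSE %).

    Raises ``ProfileError`` for degenerate (flat-zero) profiles and a
    ``RuntimeError`` carrying the best-so-far parameters on non-convergence.
    """
    if profile.times.size < 4:
        raise ProfileError("need at least 4 time points to fit release")
    t = profile.times
    y = profile.mean_q()
    if np.all(y <= 1e-12):
        raise ProfileError("profile is identically zero; nothing to fit")

    def model(tt, fmax, td, b):
        return fmax * (1.0 - np.exp(-((tt / td) ** b)))

    fmax0 = min(100.0, max(float(y[-1]), 1.0))
    # crude td guess: first time reaching 63.2% of the final level
    level = 0.632 * max(float(y[-1]), 1e-9)
    idx = int(np.searchsorted(y, level))
    td0 = float(t[min(idx, t.size - 1)])
    p0 = (fmax0, max(td0, t[0]), 1.0)
    bounds = ([1e-6, 1e-6, 1e-3], [100.0, 1e4, 20.0])
    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy rarely fails here
        raise RuntimeError(f"Weibull fit did not converge (start {p0})") from exc
    params = WeibullParams(fmax=float(popt[0]), td=float(popt[1]), b=float(popt[2]))
    resid = y - model(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return params, rmse


@dataclass(frozen=True)
class SpecPoint:
    """One specification window: bounds in % dissolved at ``time_h``.

    ``inclusive`` applies to both bounds; a strict upper bound encodes
    the "< 20%" style of the first-hour limit.
    """

    time_h: float
    lower: float | None = None
    upper: float | None = None
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError("spec point needs at least one bound")
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")

    def passes(self, value: float) -> bool:
        ok = True
        if self.lower is not None:
            ok &= value >= self.lower if self.inclusive else value > self.lower
        if self.upper is not None:
            ok &= value <= self.upper if self.inclusive else value < self.upper
        return bool(ok)


@dataclass(frozen=True)
class DissolutionSpec:
    points: tuple[SpecPoint, ...]

    def __post_init__(self) -> None:
        times = [p.time_h for p in self.points]
        if sorted(times) != times or len(set(times)) != len(times):
            raise ValueError("spec times must be strictly increasing")


def er_reference_spec() -> DissolutionSpec:
    """The proposed desvenlafaxine-ER specification windows."""
    from .datasets import ER_SPEC_WINDOWS

    return DissolutionSpec(
        points=tuple(
            SpecPoint(time_h=t, lower=lo, upper=hi, inclusive=inc)
            for t, lo, hi, inc in ER_SPEC_WINDOWS
        )
    )


def check_spec(
    profile: DissolutionProfile, spec: DissolutionSpec
) -> tuple[dict[float, bool], bool]:
    """Check the mean profile against each spec window.

    Returns ``(per_time_pass, overall_pass)``.  All spec times must fall
    within the profile's sampled range.
    """
    last = profile.times[-1]
    bad = [p.time_h for p in spec.points if p.time_h > last]
    if bad:
        raise ProfileError(f"spec times {bad} beyond last sample at {last} h")
    result = {p.time_h: p.passes(q_at(profile, p.time_h)) for p in spec.points}
    return result, all(result.values())


def derive_spec(
    profiles: Sequence[DissolutionProfile],
    times: Sequence[float] | None = None,
    margin: float = 2.0,
    rounding: int = 1,
) -> DissolutionSpec:
    """Derive specification windows spanning a set of acceptable profiles.

    At each time: lower = floor(min mean Q - margin), upper =
    ceil(max mean Q + margin), both to the nearest ``rounding`` percent and
    clipped to [0, 100].  The first time point is emitted upper-only and the
    last lower-only, matching the usual ER-specification format.  All bounds
    are inclusive, which guarantees every input profile passes the derived
    spec for any margin >= 0.
    """
    if len(profiles) < 2:
        raise ProfileError("need the reference plus at least one candidate profile")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    base = profiles[0].times
    for p in profiles[1:]:
        if p.times.size != base.size or not np.allclose(p.times, base):
            raise ProfileError("profiles are on incompatible sampling grids")
    if times is None:
        times = [t for t in (1.0, 4.0, 8.0, 16.0, 24.0) if t <= base[-1]]
    times = sorted(times)
    points = []
    for i, t in enumerate(times):
        values = [q_at(p, t) for p in profiles]
        lo = rounding * math.floor((min(values) - margin) / rounding)
        hi = rounding * math.ceil((max(values) + margin) / rounding)
        lo = max(0.0, float(lo))
        hi = min(100.0, float(hi))
        if i == 0:
            points.append(SpecPoint(time_h=t, upper=hi))
        elif i == len(times) - 1:
            points.append(SpecPoint(time_h=t, lower=lo))
        else:
            if not lo < hi:  # fully degenerate window after clipping
                lo = max(0.0, hi - float(rounding))
            points.append(SpecPoint(time_h=t, lower=lo, upper=hi))
    return DissolutionSpec(points=tuple(points))
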