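"""Synthetic study fixtures: products, dissolution runs, observed plasma.

No raw dissolution or plasma data are deposited for the desvenlafaxine ER
study, so this module generates stand-ins with the *effect structure* the
study established, on the published sampling grid (1, 2, 4, 8, 12, 16, 20,
24 h, six units per run):

* three products whose tablet dimensions (and hence SA/V) match the
  published means/SDs; a higher SA/V accelerates release by shrinking the
  Weibull time scale, ``td_eff = td / (hydro * (sa_v / sa_v_ref)^s)``;
* nine dissolution methods (the L9 runs): the apparatus carries a
  hydrodynamic multiplier (basket 0.8 — low hydrodynamics; paddle without
  sinker 0.75 — tablet adheres to the vessel; paddle with sinker 1.0),
  while medium and rotation speed are generated as true nulls, encoding
  the study's screening conclusion;
* an "observed" reference plasma curve: the forward CAT simulation of the
  reference in vivo release plus optional multiplicative residual noise —
  a stand-in for the unpublished 44-volunteer bioequivalence curve.

The reference release parameters (fmax 95%, td 7.1 h, b 0.9) place the
reference profile inside the proposed specification windows.  Replicate
noise is tablet-dominated: a per-unit log-normal multiplier (CV 3%) and
per-unit offset plus small per-point jitter, with within-unit monotonicity
restored by a cumulative maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import datasets
from .dissolution import DissolutionProfile, WeibullParams, weibull_release
from .geometry import TabletDimensions, TabletShape, tablet_geometry
from .pk import (
    AbsorptionParams,
    DispositionParams,
    PlasmaProfile,
    derive_disposition,
    simulate_oral_cat,
)

__all__ = [
    "ProductFixture",
    "MethodFixture",
    "StudyFixture",
    "make_study_fixture",
    "simulate_dissolution",
    "simulate_observed_plasma",
]

APPARATUS_MULTIPLIERS = {"basket": 0.8, "paddle": 0.75, "paddle_sinker": 1.0}
REFERENCE_RELEASE = WeibullParams(fmax=95.0, td=7.1, b=0.9)
SA_V_REFERENCE = 8.479  # cm^-1, the reference product's SA/V anchor
DEFAULT_SA_V_SENSITIVITY = 2.0
DEFAULT_UNIT_NOISE_CV = 0.03
# absolute noise components, scaled to the same CV knob so that CV 0 gives
# identical replicate units: per-unit offset (tablet-level assay bias) and
# per-point sampling jitter, both in % of label
UNIT_OFFSET_SD_PER_CV = 50.0   # 1.5% of label at the default CV 3%
POINT_JITTER_SD_PER_CV = 10.0  # 0.3% of label at the default CV 3%


@dataclass(frozen=True)
class ProductFixture:
    """Generating truth for one drug product."""

    product_id: str
    dims_mean: TabletDimensions
    thickness_sd: float
    cross_dim_sd: float
    weight_sd: float
    release: WeibullParams = REFERENCE_RELEASE
    sa_v_sensitivity: float = DEFAULT_SA_V_SENSITIVITY
    in_doe: bool = True

    def __post_init__(self) -> None:
        if self.sa_v_sensitivity < 0:
            raise ValueError("sa_v_sensitivity must be >= 0")

    @property
    def sa_v(self) -> float:
        return tablet_geometry(self.dims_mean).sa_v_per_cm

    def sample_tablets(self, n: int, rng: np.random.Generator) -> list[TabletDimensions]:
        """Draw n tablets around the mean dimensions (normal, reported SDs)."""
        t = rng.normal(self.dims_mean.thickness_cm, self.thickness_sd, n)
        c = rng.normal(self.dims_mean.cross_dim_cm, self.cross_dim_sd, n)
        w = rng.normal(self.dims_mean.weight_mg, self.weight_sd, n)
        return [
            TabletDimensions(
                shape=self.dims_mean.shape,
                thickness_cm=float(ti),
                cross_dim_cm=float(ci),
                weight_mg=float(wi),
            )
            for ti, ci, wi in zip(t, c, w)
        ]


@dataclass(frozen=True)
class MethodFixture:
    """One dissolution test condition with its generating multiplier."""

    medium: str
    apparatus: str
    speed_rpm: int
    hydro_multiplier: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.apparatus not in APPARATUS_MULTIPLIERS:
            raise ValueError(f"unknown apparatus {self.apparatus!r}")
        if self.hydro_multiplier == 0.0:
            object.__setattr__(
                self, "hydro_multiplier", APPARATUS_MULTIPLIERS[self.apparatus]
            )
        if not self.hydro_multiplier > 0:
            raise ValueError("hydro multiplier must be > 0")

    @property
    def label(self) -> str:
        return f"{self.apparatus}/{self.speed_rpm}rpm/{self.medium}"


@dataclass(frozen=True)
class StudyFixture:
    products: Mapping[str, ProductFixture]
    methods: tuple[MethodFixture, ...]  # the nine L9 run conditions, in order
    disposition: DispositionParams
    absorption: AbsorptionParams
    seed: int
    params_log: Mapping[str, object]


def _product_fixtures() -> dict[str, ProductFixture]:
    products: dict[str, ProductFixture] = {}
    for name, d in datasets.PRODUCT_DIMENSIONS.items():
        products[name] = ProductFixture(
            product_id=name,
            dims_mean=TabletDimensions(
                shape=d["shape"],
                thickness_cm=d["thickness_cm"],
                cross_dim_cm=d["cross_dim_cm"],
                weight_mg=d["weight_mg"],
            ),
            thickness_sd=d["thickness_sd"],
            cross_dim_sd=d["cross_dim_sd"],
            weight_sd=d["weight_sd"],
        )
    # external-validation product, not part of the DoE: dimensions close to
    # the reference, hence a nearly matching release rate
    products["Generic #3"] = ProductFixture(
        product_id="Generic #3",
        dims_mean=TabletDimensions(
            shape=TabletShape.CYLINDER, thickness_cm=0.500, cross_dim_cm=0.900,
            weight_mg=345.0,
        ),
        thickness_sd=0.005,
        cross_dim_sd=0.002,
        weight_sd=4.0,
        in_doe=False,
    )
    return products


def make_study_fixture(seed: int) -> StudyFixture:
    """Deterministic full-study generating truth for a given seed."""
    products = _product_fixtures()
    methods = tuple(
        MethodFixture(
            medium=row.medium, apparatus=row.apparatus, speed_rpm=int(row.speed_rpm)
        )
        for row in datasets.DOE_RUNS.itertuples()
    )
    disposition = DispositionParams()
    absorption = AbsorptionParams()
    params_log = {
        "seed": seed,
        "apparatus_multipliers": dict(APPARATUS_MULTIPLIERS),
        "reference_release": {
            "fmax": REFERENCE_RELEASE.fmax,
            "td": REFERENCE_RELEASE.td,
            "b": REFERENCE_RELEASE.b,
        },
        "sa_v_reference": SA_V_REFERENCE,
        "sa_v_sensitivity": DEFAULT_SA_V_SENSITIVITY,
        "unit_noise_cv": DEFAULT_UNIT_NOISE_CV,
        "medium_multiplier": 1.0,  # true null
        "speed_multiplier": 1.0,   # true null
        "iv_cohort_body_weight_kg": datasets.DISPOSITION["iv_cohort_body_weight_kg"],
        "products": {
            name: {
                "sa_v": p.sa_v,
                "shape": p.dims_mean.shape.value,
                "in_doe": p.in_doe,
            }
            for name, p in products.items()
        },
    }
    return StudyFixture(
        products=products,
        methods=methods,
        disposition=disposition,
        absorption=absorption,
        seed=seed,
        params_log=params_log,
    )


def effective_release(
    product: ProductFixture,
    method: MethodFixture,
    sa_v_ref: float = SA_V_REFERENCE,
) -> WeibullParams:
    """Release curve under a test condition: faster with SA/V and hydrodynamics."""
    factor = method.hydro_multiplier * (product.sa_v / sa_v_ref) ** product.sa_v_sensitivity
    return WeibullParams(
        fmax=product.release.fmax, td=product.release.td / factor, b=product.release.b
    )


def simulate_dissolution(
    product: ProductFixture,
    method: MethodFixture,
    n_units: int = 6,
    seed: int | np.random.Generator = 0,
    noise_cv: float = DEFAULT_UNIT_NOISE_CV,
    times=None,
    sa_v_ref: float = SA_V_REFERENCE,
) -> DissolutionProfile:
    """Simulate one dissolution run (n replicate units on the 1-24 h grid)."""
    if n_units < 1:
        raise ValueError("need at least one unit")
    if noise_cv < 0 or noise_cv > 0.5:
        raise ValueError("noise CV must lie in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(times if times is not None else datasets.DISSOLUTION_TIMES_H, float)
    params = effective_release(product, method, sa_v_ref=sa_v_ref)
    clean = weibull_release(t, params)
    if noise_cv == 0:
        q = np.tile(clean, (n_units, 1))
    else:
        # tablet-level variability dominates dissolution replicates: a
        # per-unit multiplier (content/release) and per-unit offset, plus
        # small per-point sampling jitter; cumulative max restores
        # within-unit monotonicity
        sigma = np.sqrt(np.log1p(noise_cv**2))
        unit_mult = rng.lognormal(-0.5 * sigma**2, sigma, size=(n_units, 1))
        unit_offset = rng.normal(0.0, UNIT_OFFSET_SD_PER_CV * noise_cv, (n_units, 1))
        jitter = rng.normal(0.0, POINT_JITTER_SD_PER_CV * noise_cv, (n_units, t.size))
        q = np.maximum.accumulate(clean[None, :] * unit_mult + unit_offset + jitter, axis=1)
        q = np.clip(q, 0.0, 100.0)
    return DissolutionProfile(
        times=t, q=q, product_id=product.product_id, method_id=method.label
    )


def simulate_observed_plasma(
    disposition: DispositionParams,
    absorption: AbsorptionParams,
    in_vivo_release,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    t_end_h: float = 72.0,
    dt_h: float = 0.25,
) -> PlasmaProfile:
    """Forward-simulated reference plasma curve with residual assay noise.

    ``in_vivo_release`` follows the :func:`dissopk.pk.simulate_oral_cat`
    convention (None = IR bolus, or a cumulative (times, fraction) pair).
    With ``noise_cv = 0`` this is exactly the forward simulation.
    """
    d = derive_disposition(disposition)
    profile = simulate_oral_cat(
        d, absorption, release=in_vivo_release, t_end_h=t_end_h, dt_h=dt_h
    )
    if noise_cv == 0:
        return profile
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    noise = rng.lognormal(-0.5 * sigma**2, sigma, size=profile.conc_ng_ml.size)
    return PlasmaProfile(
        times_h=profile.times_h, conc_ng_ml=profile.conc_ng_ml * noise
    )
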