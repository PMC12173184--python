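"""Synthetic rheometry and velocimetry generators.

No public measurement archive exists for this problem, so every pipeline
stage is exercised against synthetic data carrying the statistical structure
of the real acquisitions:

* rheometer curves: power-law viscosity with multiplicative lognormal point
  noise (the repeatability band of a cone-plate measurement), plus optional
  sample-to-sample (K, n) variability — repeated measurements of nominally
  identical aliquots spread fitted K by ~20% and fitted n by ~9%, far more
  than point scatter alone explains;
* velocity stacks: a converged flow solution sampled on the velocimetry
  lattice (in-plane resolution ~37 um, layer spacing 33/66 um, guard layers
  outside the channel), with per-layer multiplicative flow fluctuations (up
  to 7% of peak velocity — whole layers drift because they are acquired
  sequentially), additive pixel noise (the 4e-5 m/s single-frame standard
  deviation, averaged over the ~100 image pairs that make up one layer), and
  a per-layer rigid jitter of the side-wall position (~5% of the width).

All generators are deterministic under a fixed seed; per-component
substreams are derived from the single global seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import InvalidModelError
from .geometry import ChannelGeometry
from .rheology import PowerLawFluid, RheometryDataset
from .solution import FlowSolution
from .stacks import VelocityStack
from .units import ul_per_min_to_m3_per_s

__all__ = [
    "NoiseModel",
    "default_shear_rate_grid",
    "generate_rheometry",
    "generate_repeatability_ensemble",
    "generate_velocity_stack",
    "StudyCase",
    "study_case",
    "STUDY_CASE_LABELS",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise parameters of the synthetic measurement emulation.

    Parameters
    ----------
    rheometry_cv
        Multiplicative lognormal coefficient of variation per rheometer
        point (default 0.10: a +-20% ~ 2-sigma repeatability band).
    sample_k_cv, sample_n_cv
        Sample-to-sample lognormal variability of the true (K, n) between
        replicate rheometry measurements; defaults calibrated by simulation
        (together with the point noise and the measurement grid) so that the
        max deviation of fitted parameters across 100 replicates is ~20% on
        K and ~9% on n.
    layer_fluctuation_frac
        Per-layer multiplicative velocity offset amplitude, uniform within
        +- this fraction (default 0.07: flow drift between sequentially
        acquired layers reaches 7% of the peak velocity).
    velocity_sd
        Additive velocity noise standard deviation of a single velocimetry
        frame pair [m/s] (default 4e-5).
    images_per_layer
        Frame pairs averaged into one layer field (default 100).
    x_stations
        Independent streamwise velocimetry stations averaged into a layer's
        y-profile (default 40: the interrogation window tiles the field of
        view along the flow, and fully developed flow makes the stations
        replicates). The additive noise applied to a layer profile is
        ``velocity_sd / sqrt(images_per_layer * x_stations)``.
    width_jitter_frac
        Rigid per-layer jitter of the side-wall position, uniform within
        +- this fraction of the channel width (default 0.05).
    seed
        Global seed; per-component substreams are derived from it.
    """

    rheometry_cv: float = 0.10
    sample_k_cv: float = 0.07
    sample_n_cv: float = 0.02
    layer_fluctuation_frac: float = 0.07
    velocity_sd: float = 4e-5
    images_per_layer: int = 100
    x_stations: int = 40
    width_jitter_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rheometry_cv",
            "sample_k_cv",
            "sample_n_cv",
            "layer_fluctuation_frac",
            "velocity_sd",
            "width_jitter_frac",
        ):
            if getattr(self, name) < 0:
                raise InvalidModelError(f"{name} must be >= 0")
        if self.images_per_layer < 1 or self.x_stations < 1:
            raise InvalidModelError("images_per_layer and x_stations must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic substream generator for one component."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    @property
    def layer_velocity_sd(self) -> float:
        """Additive noise sd of an averaged layer profile."""
        return self.velocity_sd / np.sqrt(self.images_per_layer * self.x_stations)


_STREAM_RHEOMETRY = 0
_STREAM_SAMPLE_PARAMS = 1
_STREAM_STACK = 2


def default_shear_rate_grid(n_low: int = 15, n_high: int = 6) -> np.ndarray:
    """Measurement design of a rheometer sweep: log-spaced points over
    0.01-100 1/s, concentrated in the 0.01-1 1/s decade pair where the
    channel actually operates."""
    low = np.geomspace(0.01, 1.0, n_low)
    high = np.geomspace(1.0, 100.0, n_high)[1:]
    return np.concatenate([low, high])


def generate_rheometry(
    fluid: PowerLawFluid,
    shear_rates,
    noise: NoiseModel = NoiseModel(),
    *,
    rng: np.random.Generator | None = None,
) -> RheometryDataset:
    """Synthesize one rheometer sweep: mu_i = K g_i^(n-1) exp(eps_i).

    ``eps_i ~ Normal(0, sigma)`` with sigma = ln(1 + cv^2)^(1/2) (lognormal
    with the requested coefficient of variation); reproducible under a fixed
    seed.
    """
    g = np.asarray(shear_rates, dtype=float)
    if g.size == 0:
        raise InvalidModelError("empty shear-rate grid")
    if np.any(g <= 0) or np.any(g > 100.0):
        raise InvalidModelError("shear rates must lie in (0, 100] 1/s")
    if rng is None:
        rng = noise.rng(_STREAM_RHEOMETRY)
    mu = fluid.K * g ** (fluid.n - 1.0)
    if noise.rheometry_cv > 0:
        sigma = np.sqrt(np.log1p(noise.rheometry_cv**2))
        mu = mu * np.exp(rng.normal(0.0, sigma, size=g.shape))
    return RheometryDataset(
        shear_rate=g, viscosity=mu, label=fluid.label, temperature=fluid.temperature
    )


def generate_repeatability_ensemble(
    fluid: PowerLawFluid,
    shear_rates,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 100,
) -> list[RheometryDataset]:
    """Replicate rheometry sweeps with sample-to-sample (K, n) variability.

    Each replicate draws its own true parameters
    ``K_i = K exp(N(0, sample_k_cv))``, ``n_i = n exp(N(0, sample_n_cv))``
    (different aliquots, days, and rheometer refills of nominally the same
    medium) and then a full point-noise sweep.
    """
    rng_params = noise.rng(_STREAM_SAMPLE_PARAMS)
    rng_points = noise.rng(_STREAM_RHEOMETRY)
    out = []
    for _ in range(n_replicates):
        k_i = fluid.K * np.exp(rng_params.normal(0.0, noise.sample_k_cv))
        n_i = fluid.n * np.exp(rng_params.normal(0.0, noise.sample_n_cv))
        replicate = PowerLawFluid(
            K=k_i,
            n=n_i,
            shear_rate_window=fluid.shear_rate_window,
            label=fluid.label,
            temperature=fluid.temperature,
        )
        out.append(generate_rheometry(replicate, shear_rates, noise, rng=rng_points))
    return out


def _layer_positions(
    h: float,
    delta_z: float,
    guard_layers: int,
    delta_z_center: float | None,
    wall_band: float,
) -> np.ndarray:
    if delta_z_center is None:
        n_lo = guard_layers
        start = -n_lo * delta_z
        return np.arange(start, h + guard_layers * delta_z + delta_z / 2, delta_z)
    # two-zone acquisition: fine steps within wall_band of each wall,
    # coarse steps across the channel centre
    zs = [-(i + 1) * delta_z for i in range(guard_layers)][::-1]
    z = 0.0
    while z < wall_band:
        zs.append(z)
        z += delta_z
    while z < h - wall_band:
        zs.append(z)
        z += delta_z_center
    while z <= h:
        zs.append(z)
        z += delta_z
    zs.extend(zs[-1] + (i + 1) * delta_z for i in range(guard_layers))
    return np.asarray(zs)


def generate_velocity_stack(
    solution: FlowSolution,
    delta_z: float = 33e-6,
    delta_y: float = 37e-6,
    noise: NoiseModel = NoiseModel(),
    *,
    guard_layers: int = 1,
    delta_z_center: float | None = None,
    wall_band: float = 1e-4,
) -> VelocityStack:
    """Sample a flow solution on a velocimetry lattice and apply the noise model.

    Layers run from ``guard_layers`` spacings below the bottom wall to the
    same above the membrane (quiet guard layers let the wall locator work as
    it does on real stacks). ``delta_z_center`` switches to the two-zone
    acquisition used in practice: ``delta_z`` within ``wall_band`` of either
    wall, coarser spacing across the plug-flow centre, which is what keeps a
    full-channel measurement at a manageable 16-25 layers.

    Noise-free generation returns exactly the bilinear interpolation of the
    solution at the sample points.
    """
    w, h = solution.geometry.w, solution.geometry.h
    if not (0 < delta_z < h and 0 < delta_y < w):
        raise InvalidModelError("layer/in-plane spacing must be positive and smaller than the channel")
    z_layers = _layer_positions(h, delta_z, guard_layers, delta_z_center, wall_band)
    # the in-plane field of view must cover the walls even when jittered
    y_margin = guard_layers * delta_y + noise.width_jitter_frac * w
    y = np.arange(-y_margin, w + y_margin + delta_y / 2, delta_y)

    interp = RegularGridInterpolator(
        (solution.z, solution.y), solution.u, bounds_error=False, fill_value=0.0
    )
    rng = noise.rng(_STREAM_STACK)
    u_max = solution.u_max
    u = np.zeros((z_layers.size, y.size))
    for il, z_pos in enumerate(z_layers):
        shift = (
            rng.uniform(-noise.width_jitter_frac * w, noise.width_jitter_frac * w)
            if noise.width_jitter_frac > 0
            else 0.0
        )
        pts = np.column_stack([np.full(y.size, z_pos), y - shift])
        layer = interp(pts)
        if noise.layer_fluctuation_frac > 0:
            layer = layer * (
                1.0
                + rng.uniform(-noise.layer_fluctuation_frac, noise.layer_fluctuation_frac)
            )
        if noise.velocity_sd > 0:
            layer = layer + rng.normal(0.0, noise.layer_velocity_sd, size=y.size)
        u[il, :] = layer
    meta = {
        "fluid": solution.fluid.label or f"K={solution.fluid.K},n={solution.fluid.n}",
        "flow_rate_m3_s": f"{solution.Q:.6e}",
        "seed": str(noise.seed),
        "u_max_true_m_s": f"{u_max:.6e}",
    }
    return VelocityStack(
        z=z_layers, y=y, u=u, delta_z=delta_z, delta_y=delta_y, metadata=meta
    )


# ---------------------------------------------------------------------------
# Canonical study conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyCase:
    """Parameter bundle for one of the study's membrane shear-stress cases."""

    fluid: PowerLawFluid
    geometry: ChannelGeometry
    flow_rate: float  # [m^3/s]


#: Fitted power-law parameters (K [Pa s^n], n) per medium, plus the two
#: Newtonian references: water (handbook 20 degC viscosity) and the constant
#: literature viscosity conventionally assumed for DMEM + 10% FBS.
_CASES: dict[str, tuple[float, float, float | None]] = {
    "DMEM+10% FBS": (0.028, 0.31, 20.0),
    "DMEM+5% FBS": (0.037, 0.33, 20.0),
    "DMEM+1% FBS": (0.016, 0.51, 20.0),
    "DMEM+10% FBS 37C": (0.005, 0.54, 37.0),
    "water": (1.0e-3, 1.0, 20.0),
    "literature": (9.3e-4, 1.0, None),
}

STUDY_CASE_LABELS = tuple(_CASES)

#: Study channel: 1.2 mm wide, 1.25 mm high, 15 mm long (18 mm^2 overlap).
STUDY_GEOMETRY = ChannelGeometry(w=1.2e-3, h=1.25e-3, L=15e-3)

#: Default perfusion rate, 4 uL/min.
STUDY_FLOW_RATE = ul_per_min_to_m3_per_s(4.0)


def study_case(label: str) -> StudyCase:
    """Return the (fluid, geometry, flow rate) bundle for a named study case.

    Labels: ``"DMEM+10% FBS"``, ``"DMEM+5% FBS"``, ``"DMEM+1% FBS"``,
    ``"DMEM+10% FBS 37C"``, ``"water"``, ``"literature"``.
    """
    try:
        K, n, temp = _CASES[label]
    except KeyError:
        raise KeyError(
            f"unknown study case {label!r}; expected one of {STUDY_CASE_LABELS}"
        ) from None
    fluid = PowerLawFluid(K=K, n=n, label=label, temperature=temp)
    return StudyCase(fluid=fluid, geometry=STUDY_GEOMETRY, flow_rate=STUDY_FLOW_RATE)
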