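"""Layered velocity-field ("stack") analysis: the measurement-side pipeline.

Velocimetry in a microchannel produces one 2-D streamwise-velocity field per
microscope focal plane; stacking the planes along z gives u_x on a (y, z)
lattice with in-plane resolution delta_y (~37 um) and layer spacing delta_z
(~33 or 66 um). This module assembles such stacks, locates the channel walls
from where the measured velocity dies out, and converts near-wall velocity
gradients plus measured rheology into a membrane shear-stress profile — the
same chain used on real acquisitions, so that synthetic stacks exercise it
end to end.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import InsufficientDataError, InvalidModelError
from .rheology import PowerLawFluid
from .solution import FlowSolution, WallShearMap

__all__ = [
    "VelocityStack",
    "ChannelBoundsEstimate",
    "assemble_velocity_stack",
    "locate_channel_walls",
    "wall_shear_from_stack",
    "compare_profiles",
    "read_stack",
    "write_stack",
]


@dataclass(frozen=True)
class VelocityStack:
    """z-ordered layers of streamwise velocity u_x(y) on a shared y grid.

    ``u`` is indexed ``u[layer, iy]``; ``z`` holds the layer positions
    (strictly increasing, not necessarily uniform when the acquisition
    coarsens toward the channel centre). ``delta_z``/``delta_y`` record the
    nominal spacings; metadata carries the fluid label and nominal flow rate.
    """

    z: np.ndarray
    y: np.ndarray
    u: np.ndarray
    delta_z: float
    delta_y: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        y = np.asarray(self.y, dtype=float)
        u = np.asarray(self.u, dtype=float)
        if u.shape != (z.size, y.size):
            raise InvalidModelError(
                f"u shape {u.shape} inconsistent with {z.size} layers x {y.size} y-points"
            )
        if np.any(np.diff(z) <= 0):
            raise InvalidModelError("layer z positions must be strictly increasing")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "u", u)

    @property
    def n_layers(self) -> int:
        return self.z.size


@dataclass(frozen=True)
class ChannelBoundsEstimate:
    """Estimated channel extent from a velocity stack."""

    z_bottom: float
    z_top: float
    y_left: float
    y_right: float
    method: str = "zero-velocity"

    def __post_init__(self) -> None:
        if not (self.z_top > self.z_bottom and self.y_right > self.y_left):
            raise InvalidModelError("degenerate channel bounds")

    @property
    def height(self) -> float:
        return self.z_top - self.z_bottom

    @property
    def width(self) -> float:
        return self.y_right - self.y_left


def assemble_velocity_stack(
    layers,
    *,
    delta_y: float | None = None,
    metadata: dict | None = None,
) -> VelocityStack:
    """Build a validated stack from (z, field) layer pairs.

    ``layers`` is an iterable of ``(z, u)`` with ``u`` either a 1-D y-profile
    or a 2-D (x, y) field, which is averaged over x (the flow is fully
    developed along the channel, so x frames are replicates). Layers may
    arrive in any order; duplicate z positions or inconsistent grid widths
    are rejected.
    """
    layers = list(layers)
    if len(layers) < 3:
        raise InsufficientDataError(f"need >= 3 layers, got {len(layers)}")
    zs, profiles = [], []
    for z_pos, arr in layers:
        a = np.asarray(arr, dtype=float)
        if a.ndim == 2:
            a = a.mean(axis=0)
        elif a.ndim != 1:
            raise InvalidModelError("layer fields must be 1-D (y) or 2-D (x, y)")
        zs.append(float(z_pos))
        profiles.append(a)
    widths = {p.size for p in profiles}
    if len(widths) != 1:
        raise InvalidModelError(f"inconsistent y-grids across layers: sizes {sorted(widths)}")
    z = np.array(zs)
    if np.unique(z).size != z.size:
        raise InvalidModelError("duplicate layer z positions")
    order = np.argsort(z)
    z = z[order]
    u = np.vstack([profiles[i] for i in order])
    dz = float(np.median(np.diff(z)))
    ny = u.shape[1]
    dy = float(delta_y) if delta_y is not None else dz
    y = np.arange(ny) * dy
    return VelocityStack(z=z, y=y, u=u, delta_z=dz, delta_y=dy, metadata=metadata or {})


def locate_channel_walls(stack: VelocityStack, velocity_floor: float) -> ChannelBoundsEstimate:
    """Estimate the channel extent from where measured velocity dies out.

    The first and last layers whose peak speed exceeds ``velocity_floor``
    bracket the flow; the wall is the point where the velocity drops to
    zero, estimated by linearly extrapolating the peak speeds of the two
    outermost flowing layers, and clipped to at most one layer spacing
    beyond the last flowing layer (the wall cannot lie past the first quiet
    layer). Laterally, each flowing layer's profile is crossed with the
    floor (linear interpolation) and the side walls are the medians of the
    per-layer crossings — robust against the layer-to-layer rigid jitter of
    the slightly jagged real walls.
    """
    peak_per_layer = np.abs(stack.u).max(axis=1)
    alive = np.flatnonzero(peak_per_layer > velocity_floor)
    if alive.size == 0:
        raise InvalidModelError("no layer exceeds the velocity floor")
    lo, hi = alive[0], alive[-1]
    dz_lo = stack.z[lo] - stack.z[lo - 1] if lo > 0 else stack.delta_z
    dz_hi = stack.z[hi + 1] - stack.z[hi] if hi < stack.n_layers - 1 else stack.delta_z
    z_top = float(stack.z[hi] + dz_hi)
    if hi > 0 and peak_per_layer[hi - 1] > peak_per_layer[hi]:
        step = stack.z[hi] - stack.z[hi - 1]
        reach = peak_per_layer[hi] * step / (peak_per_layer[hi - 1] - peak_per_layer[hi])
        z_top = float(stack.z[hi] + min(reach, dz_hi))
    z_bottom = float(stack.z[lo] - dz_lo)
    if lo < stack.n_layers - 1 and peak_per_layer[lo + 1] > peak_per_layer[lo]:
        step = stack.z[lo + 1] - stack.z[lo]
        reach = peak_per_layer[lo] * step / (peak_per_layer[lo + 1] - peak_per_layer[lo])
        z_bottom = float(stack.z[lo] - min(reach, dz_lo))

    lefts, rights = [], []
    for il in alive:
        prof = np.abs(stack.u[il, :])
        live = np.flatnonzero(prof > velocity_floor)
        if live.size == 0:
            continue
        jl, jr = live[0], live[-1]
        if jl > 0:
            lefts.append(
                np.interp(velocity_floor, [prof[jl - 1], prof[jl]], [stack.y[jl - 1], stack.y[jl]])
            )
        else:
            lefts.append(stack.y[0])
        if jr < prof.size - 1:
            rights.append(
                np.interp(velocity_floor, [prof[jr + 1], prof[jr]], [stack.y[jr + 1], stack.y[jr]])
            )
        else:
            rights.append(stack.y[-1])
    if not lefts:
        raise InvalidModelError("no y column exceeds the velocity floor")
    y_left = float(np.median(lefts))
    y_right = float(np.median(rights))
    return ChannelBoundsEstimate(z_bottom=z_bottom, z_top=z_top, y_left=y_left, y_right=y_right)


def wall_shear_from_stack(
    stack: VelocityStack,
    bounds: ChannelBoundsEstimate,
    fluid: PowerLawFluid,
    *,
    membrane: str = "top",
    order: int = 1,
) -> WallShearMap:
    """Membrane shear-stress profile from near-wall measured velocities.

    The wall shear rate at each y is a one-sided finite difference of u_x
    across the layers nearest the membrane, with zero velocity imposed at the
    estimated wall position. ``order=1`` uses the single nearest in-channel
    layer (default; this distance — one layer spacing — is how measured
    near-wall gradients are formed); ``order=2`` adds the next layer for a
    second-order estimate on the (possibly non-uniform) spacing. The stress
    is tau(y) = K gamma_dot(y)^n evaluated with the *measured* rheology.
    """
    if membrane == "top":
        z_wall = bounds.z_top
        inside = np.flatnonzero((stack.z < z_wall) & (stack.z > bounds.z_bottom))
        nearest = inside[::-1]  # closest to the top wall first
    elif membrane == "bottom":
        z_wall = bounds.z_bottom
        inside = np.flatnonzero((stack.z > z_wall) & (stack.z < bounds.z_top))
        nearest = inside
    else:
        raise ValueError("membrane must be 'top' or 'bottom'")
    if nearest.size < 2:
        raise InsufficientDataError(
            "need >= 2 layers inside the channel adjacent to the membrane"
        )
    i1 = nearest[0]
    d1 = abs(z_wall - stack.z[i1])
    if order == 1:
        g = np.abs(stack.u[i1, :]) / d1
    elif order == 2:
        i2 = nearest[1]
        d2 = abs(z_wall - stack.z[i2])
        # quadratic through (0, 0), (d1, u1), (d2, u2): u'(0)
        u1, u2 = stack.u[i1, :], stack.u[i2, :]
        g = np.abs((u1 * d2 * d2 - u2 * d1 * d1) / (d1 * d2 * (d2 - d1)))
    else:
        raise ValueError("order must be 1 or 2")
    tau = np.asarray(fluid.shear_stress(g))
    return WallShearMap(wall="top" if membrane == "top" else "bottom",
                        coordinate=stack.y.copy(), tau=tau)


def compare_profiles(
    stack: VelocityStack,
    solution: FlowSolution,
    y_fractions=(0.5, 1 / 3, 1 / 6),
    *,
    bounds: ChannelBoundsEstimate | None = None,
    error_band: float = 0.10,
) -> list[dict]:
    """Compare measured z-profiles with a model solution at chosen y stations.

    For each requested fraction of the channel width, the model field is
    interpolated onto the stack's sample points and the maximum and RMS
    deviations are reported relative to the model's peak velocity (how
    percent errors are conventionally quoted for these measurements), flagged
    against a tolerance band (default 10%).

    If ``bounds`` is given, stack coordinates are mapped into the channel
    frame (wall at zero) before interpolation; otherwise the stack is assumed
    to share the solution's coordinates.
    """
    y_off = bounds.y_left if bounds is not None else 0.0
    z_off = bounds.z_bottom if bounds is not None else 0.0
    zs = stack.z - z_off
    inside_z = (zs >= 0) & (zs <= solution.geometry.h)
    if not np.any(inside_z):
        raise InvalidModelError("stack and solution domains do not overlap")
    interp = RegularGridInterpolator(
        (solution.z, solution.y), solution.u, bounds_error=False, fill_value=0.0
    )
    u_ref_max = solution.u_max
    out = []
    for frac in y_fractions:
        iy = int(np.argmin(np.abs((stack.y - y_off) - frac * solution.geometry.w)))
        # compare at the measured column actually nearest the requested station
        y_pos = stack.y[iy] - y_off
        pts = np.column_stack([zs[inside_z], np.full(inside_z.sum(), y_pos)])
        u_model = interp(pts)
        u_meas = stack.u[inside_z, iy]
        dev = (u_meas - u_model) / u_ref_max
        out.append(
            {
                "y_fraction": float(frac),
                "max_rel_dev": float(np.max(np.abs(dev))),
                "rms_rel_dev": float(np.sqrt(np.mean(dev**2))),
                "within_band": bool(np.max(np.abs(dev)) <= error_band),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Stack text I/O: one row per (layer, z, y, u_x) with a '#' header block.
# ---------------------------------------------------------------------------

_FMT = "%.9e"


def write_stack(stack: VelocityStack, path: str | Path) -> None:
    """Write a stack as delimited text; round-trips bit-exactly at this precision."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# delta_z: {_FMT % stack.delta_z}\n")
    buf.write(f"# delta_y: {_FMT % stack.delta_y}\n")
    for key, val in stack.metadata.items():
        buf.write(f"# {key}: {val}\n")
    buf.write("layer,z,y,u_x\n")
    for il in range(stack.n_layers):
        for iy in range(stack.y.size):
            buf.write(
                f"{il},{_FMT % stack.z[il]},{_FMT % stack.y[iy]},{_FMT % stack.u[il, iy]}\n"
            )
    path.write_text(buf.getvalue())


def read_stack(path: str | Path) -> VelocityStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    meta: dict = {}
    rows = []
    header_seen = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            header_seen = True  # column header
            continue
        il, z_, y_, u_ = line.split(",")
        rows.append((int(il), float(z_), float(y_), float(u_)))
    if not rows:
        raise InvalidModelError(f"{path}: empty stack file")
    delta_z = float(meta.pop("delta_z"))
    delta_y = float(meta.pop("delta_y"))
    layers = sorted({r[0] for r in rows})
    z = np.array([next(r[1] for r in rows if r[0] == il) for il in layers])
    ys = sorted({r[2] for r in rows})
    y = np.array(ys)
    u = np.zeros((len(layers), len(ys)))
    y_index = {v: i for i, v in enumerate(ys)}
    l_index = {il: i for i, il in enumerate(layers)}
    for il, z_, y_, u_ in rows:
        u[l_index[il], y_index[y_]] = u_
    return VelocityStack(z=z, y=y, u=u, delta_z=delta_z, delta_y=delta_y, metadata=meta)
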