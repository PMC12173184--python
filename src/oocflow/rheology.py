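"""Ostwald-de Waele (power-law) rheology: model, evaluation, and fitting.

Serum-supplemented culture media (DMEM + FBS) are shear thinning over the
shear-rate decades relevant to organ-on-a-chip flow (roughly 0.01-100 1/s).
Their viscosity is modelled as

    mu(gamma_dot) = K * gamma_dot**(n - 1)

with flow consistency ``K`` [Pa s^n] and flow index ``n`` (dimensionless,
n = 1 Newtonian, n < 1 shear thinning). The model diverges as gamma_dot -> 0,
so evaluation clamps the shear rate at a small regularisation floor
``gamma_eps`` far below the measurable range; this only affects the channel
centreline where the true shear rate vanishes by symmetry.

Fitting is a straight-line least squares in log-log space,
``log mu = log K + (n - 1) log gamma_dot``, which weights every measured
decade evenly and matches the linear appearance of the data on log-log axes.
A direct nonlinear fit is available as an option.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import InsufficientDataError, InvalidModelError

__all__ = [
    "DEFAULT_GAMMA_EPS",
    "PowerLawFluid",
    "RheometryDataset",
    "FitResult",
    "fit_power_law",
    "repeatability_spread",
    "read_rheometry",
    "write_rheometry",
]

#: Shear-rate regularisation floor [1/s]; four decades below the smallest
#: trustworthy rheometer point (0.01 1/s), so it never touches fitted data.
DEFAULT_GAMMA_EPS = 1e-6


@dataclass(frozen=True)
class PowerLawFluid:
    """Two-parameter power-law (Ostwald-de Waele) fluid.

    Parameters
    ----------
    K
        Flow consistency [Pa s^n], strictly positive.
    n
        Flow index [-], strictly positive. ``n == 1`` is Newtonian with
        constant viscosity ``K``.
    shear_rate_window
        ``(lo, hi)`` shear-rate range [1/s] over which the model was
        calibrated and is trusted. Evaluation outside it is permitted but
        warned about below the lower edge, where rheometer data are
        unreliable.
    label
        Free-text sample description, e.g. ``"DMEM + 10% FBS"``.
    temperature
        Sample temperature [degC], or None if unknown.
    gamma_eps
        Regularisation floor for the shear rate [1/s].
    """

    K: float
    n: float
    shear_rate_window: tuple[float, float] = (0.01, 100.0)
    label: str = ""
    temperature: float | None = None
    gamma_eps: float = DEFAULT_GAMMA_EPS

    def __post_init__(self) -> None:
        if not (self.K > 0 and math.isfinite(self.K)):
            raise InvalidModelError(f"flow consistency K must be > 0, got {self.K}")
        if not (self.n > 0 and math.isfinite(self.n)):
            raise InvalidModelError(f"flow index n must be > 0, got {self.n}")
        lo, hi = self.shear_rate_window
        if not (0 < lo < hi):
            raise InvalidModelError(
                f"shear-rate window must satisfy 0 < lo < hi, got ({lo}, {hi})"
            )
        if not self.gamma_eps > 0:
            raise InvalidModelError("gamma_eps must be > 0")

    @property
    def is_newtonian(self) -> bool:
        return self.n == 1.0

    def viscosity(self, shear_rate, *, warn_extrapolation: bool = True):
        """Apparent viscosity mu = K * max(gamma_dot, gamma_eps)**(n-1) [Pa s].

        Vectorised over arrays. ``shear_rate`` may be zero; the clamp keeps
        the result finite. Warns once per call when evaluated below the
        trusted window (measurements there were unreliable), unless
        ``warn_extrapolation=False`` (used by field evaluations where
        sub-window values are expected near the centreline).
        """
        g = np.asarray(shear_rate, dtype=float)
        if np.any(g < 0):
            raise ValueError("shear rate must be >= 0")
        if warn_extrapolation and np.any((g > 0) & (g < self.shear_rate_window[0])):
            warnings.warn(
                f"viscosity evaluated below the trusted shear-rate window "
                f"(< {self.shear_rate_window[0]} 1/s); extrapolating the power law",
                stacklevel=2,
            )
        g = np.maximum(g, self.gamma_eps)
        out = self.K * g ** (self.n - 1.0)
        return out if out.ndim else float(out)

    def shear_stress(self, shear_rate):
        """Shear-stress magnitude tau = K * gamma_dot**n [Pa] (clamped)."""
        g = np.maximum(np.asarray(shear_rate, dtype=float), self.gamma_eps)
        out = self.K * g**self.n
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class RheometryDataset:
    """A set of (shear rate, viscosity) rheometer points for one sample.

    Points are sorted by shear rate on construction; all values must be
    strictly positive and shear rates distinct.
    """

    shear_rate: np.ndarray
    viscosity: np.ndarray
    label: str = ""
    temperature: float | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.shear_rate, dtype=float)
        mu = np.asarray(self.viscosity, dtype=float)
        if g.shape != mu.shape or g.ndim != 1:
            raise ValueError("shear_rate and viscosity must be 1-D and equal length")
        if np.any(g <= 0) or np.any(mu <= 0):
            raise InvalidModelError("rheometry values must be strictly positive")
        order = np.argsort(g)
        g, mu = g[order], mu[order]
        if np.any(np.diff(g) <= 0):
            raise InvalidModelError("duplicate shear-rate values in dataset")
        object.__setattr__(self, "shear_rate", g)
        object.__setattr__(self, "viscosity", mu)

    def __len__(self) -> int:
        return self.shear_rate.size


@dataclass(frozen=True)
class FitResult:
    """Power-law fit of a rheometry dataset.

    ``se_logK`` and ``se_n`` are standard errors of the intercept (natural
    log of K) and slope from the log-log regression; ``r_squared`` is the
    goodness of fit in log-log space.
    """

    fluid: PowerLawFluid
    se_logK: float
    se_n: float
    r_squared: float

    def summary(self) -> dict:
        """Plain-dict fit report (JSON-serialisable)."""
        return {
            "label": self.fluid.label,
            "temperature_C": self.fluid.temperature,
            "K_Pa_sn": self.fluid.K,
            "n": self.fluid.n,
            "se_logK": self.se_logK,
            "se_n": self.se_n,
            "r_squared": self.r_squared,
            "shear_rate_window_1_per_s": list(self.fluid.shear_rate_window),
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def fit_power_law(
    data: RheometryDataset,
    *,
    method: str = "loglog",
    gamma_eps: float = DEFAULT_GAMMA_EPS,
) -> FitResult:
    """Fit (K, n) to a rheometry dataset.

    ``method="loglog"`` (default) is ordinary least squares on
    ``ln mu = ln K + (n-1) ln gamma_dot``; exact on noiseless power-law data.
    ``method="nls"`` is direct nonlinear least squares on the linear scale,
    seeded by the log-log estimate (weights the high-viscosity points more).

    The returned fluid's trusted window is the data's shear-rate range.
    """
    if len(data) < 3:
        raise InsufficientDataError(
            f"power-law fit needs >= 3 points, got {len(data)}"
        )
    x = np.log(data.shear_rate)
    y = np.log(data.viscosity)
    res = stats.linregress(x, y)
    n = res.slope + 1.0
    K = math.exp(res.intercept)
    se_n = float(res.stderr)
    se_logK = float(res.intercept_stderr)
    r2 = float(res.rvalue**2)

    if method == "nls":
        popt, pcov = optimize.curve_fit(
            lambda g, K_, n_: K_ * g ** (n_ - 1.0),
            data.shear_rate,
            data.viscosity,
            p0=[K, n],
        )
        K, n = float(popt[0]), float(popt[1])
        se_logK = float(np.sqrt(pcov[0, 0])) / K  # delta-method on ln K
        se_n = float(np.sqrt(pcov[1, 1]))
        pred = K * data.shear_rate ** (n - 1.0)
        ss_res = float(np.sum((data.viscosity - pred) ** 2))
        ss_tot = float(np.sum((data.viscosity - data.viscosity.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    elif method != "loglog":
        raise ValueError(f"unknown fit method {method!r}")

    fluid = PowerLawFluid(
        K=K,
        n=n,
        shear_rate_window=(float(data.shear_rate[0]), float(data.shear_rate[-1])),
        label=data.label,
        temperature=data.temperature,
        gamma_eps=gamma_eps,
    )
    return FitResult(fluid=fluid, se_logK=se_logK, se_n=se_n, r_squared=r2)


def repeatability_spread(fits: Sequence[FitResult]) -> tuple[float, float]:
    """Maximum relative deviation of (K, n) from their ensemble means.

    Mirrors how measurement repeatability is quoted for rheometer ensembles:
    the spread of fitted K across repeated measurements of nominally the same
    sample (about 20% for serum-supplemented DMEM) and of fitted n (about 9%).

    Returns ``(spread_K, spread_n)``, each ``max_i |p_i - mean| / mean``.
    """
    if len(fits) < 2:
        raise InsufficientDataError("repeatability spread needs >= 2 fits")
    Ks = np.array([f.fluid.K for f in fits])
    ns = np.array([f.fluid.n for f in fits])
    spread_K = float(np.max(np.abs(Ks - Ks.mean())) / Ks.mean())
    spread_n = float(np.max(np.abs(ns - ns.mean())) / ns.mean())
    return spread_K, spread_n


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# Format: optional '#' comment lines (``# key: value`` rows carry metadata),
# then a header ``shear_rate,viscosity`` and one row per point, SI units.
# ---------------------------------------------------------------------------

def read_rheometry(path: str | Path) -> RheometryDataset:
    """Read a rheometry table (CSV/TSV, '#' comments, SI units)."""
    path = Path(path)
    label = ""
    temperature: float | None = None
    rows: list[tuple[float, float]] = []
    header_seen = False
    delim = ","
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip().lower()
                if key in ("label", "sample"):
                    label = val.strip()
                elif key.startswith("temperature"):
                    try:
                        temperature = float(val.strip())
                    except ValueError:
                        pass
            continue
        if not header_seen:
            delim = "\t" if "\t" in line else ","
            cols = [c.strip().lower() for c in line.split(delim)]
            if cols[:2] != ["shear_rate", "viscosity"]:
                raise ValueError(
                    f"{path}: expected header 'shear_rate,viscosity', got {line!r}"
                )
            header_seen = True
            continue
        parts = line.split(delim)
        rows.append((float(parts[0]), float(parts[1])))
    if not header_seen:
        raise ValueError(f"{path}: no header row found")
    g, mu = (np.array(c) for c in zip(*rows))
    return RheometryDataset(shear_rate=g, viscosity=mu, label=label, temperature=temperature)


def write_rheometry(data: RheometryDataset, path: str | Path, *, comments: Sequence[str] = ()) -> None:
    """Write a rheometry table in the format :func:`read_rheometry` reads."""
    path = Path(path)
    lines = []
    if data.label:
        lines.append(f"# label: {data.label}")
    if data.temperature is not None:
        lines.append(f"# temperature_C: {data.temperature}")
    lines.extend(f"# {c}" for c in comments)
    lines.append("shear_rate,viscosity")
    lines.extend(
        f"{g:.10e},{mu:.10e}" for g, mu in zip(data.shear_rate, data.viscosity)
    )
    path.write_text("\n".join(lines) + "\n")


def refit(data: RheometryDataset, **kwargs) -> PowerLawFluid:
    """Convenience: fit and return just the fluid."""
    return fit_power_law(data, **kwargs).fluid
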