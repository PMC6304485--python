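"""Forward signal models for liver IVIM diffusion MRI and multi-echo R2* relaxometry.

The intravoxel incoherent motion (IVIM) model describes the diffusion-weighted
signal of perfused tissue as a biexponential decay in the b-value:

    SI(b) / SI0 = (1 - f) * exp(-b * D) + f * exp(-b * D*)

where ``D`` is the true (Brownian) diffusion coefficient, ``D*`` the
pseudo-diffusion coefficient of capillary microcirculation, and ``f`` the
perfusion fraction of the voxel signal.  Multi-echo gradient-echo decay is the
monoexponential ``SI(TE) = SI0 * exp(-R2* * TE)`` with the effective transverse
relaxation rate R2* = 1/T2*.

Units: diffusion coefficients are stored in mm^2/s (typical liver values are
on the order of 1e-3 mm^2/s), b-values in s/mm^2, echo times in milliseconds,
R2* in Hz (so TE is converted ms -> s inside the model).  Magnitude noise is
Rician, the standard model for magnitude-reconstructed MRI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np

__all__ = [
    "IvimParameters",
    "RelaxometryParameters",
    "AcquisitionProtocol",
    "SignalCurve",
    "ivim_signal",
    "r2star_signal",
    "generate_curve",
    "add_rician_noise",
]

CurveKind = Literal["diffusion", "relaxometry"]


@dataclass(frozen=True)
class IvimParameters:
    """Voxel- or ROI-level IVIM parameter triple.

    Attributes
    ----------
    D : float
        True diffusion coefficient, mm^2/s.
    D_star : float
        Pseudo-diffusion coefficient, mm^2/s.
    f : float
        Perfusion fraction in [0, 1].
    """

    D: float
    D_star: float
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"perfusion fraction f={self.f} outside [0, 1]")
        if self.D < 0 or self.D_star < 0:
            raise ValueError("diffusion coefficients must be non-negative")

    def scaled(self) -> tuple[float, float, float]:
        """Return (D*, D, f) with diffusivities on the conventional 1e-3 mm^2/s scale."""
        return self.D_star * 1e3, self.D * 1e3, self.f


@dataclass(frozen=True)
class RelaxometryParameters:
    """Monoexponential T2*-decay parameters.

    ``R2_star`` is the transverse relaxation rate in Hz; ``SI0`` the signal at
    TE = 0 in arbitrary units.
    """

    R2_star: float
    SI0: float = 1.0

    def __post_init__(self) -> None:
        if self.R2_star < 0:
            raise ValueError("R2* must be non-negative")
        if self.SI0 <= 0:
            raise ValueError("SI0 must be positive")

    @property
    def T2_star_ms(self) -> float:
        """T2* = 1/R2* in milliseconds (inf when R2* = 0)."""
        return float("inf") if self.R2_star == 0 else 1e3 / self.R2_star


def _default_protocol_dict() -> dict:
    with resources.files("ivimr2").joinpath("data/default_protocol.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition description: diffusion b-values and gradient-echo echo times.

    The default is an 11-b-value DWI protocol (0-1000 s/mm^2) and a 16-echo
    gradient-echo protocol (3.4-92.1 ms), as used for rodent liver imaging at
    1.5 T.
    """

    b_values: tuple[float, ...]
    echo_times_ms: tuple[float, ...]
    SI0: float = 1000.0

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        te = np.asarray(self.echo_times_ms, dtype=float)
        if b.size < 2 or b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing and start at 0")
        if te.size < 2 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing and positive")
        if self.SI0 <= 0:
            raise ValueError("SI0 must be positive")

    @classmethod
    def default(cls) -> "AcquisitionProtocol":
        d = _default_protocol_dict()
        return cls(tuple(d["b_values"]), tuple(d["echo_times_ms"]), d.get("SI0", 1000.0))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "AcquisitionProtocol":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["b_values"]), tuple(d["echo_times_ms"]), d.get("SI0", 1000.0))

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "b_values": list(self.b_values),
                    "echo_times_ms": list(self.echo_times_ms),
                    "SI0": self.SI0,
                },
                fh,
                indent=2,
            )


@dataclass(frozen=True)
class SignalCurve:
    """A sampled decay curve: signal intensity versus b-value or echo time."""

    abscissa: tuple[float, ...]
    intensities: tuple[float, ...]
    kind: CurveKind = "diffusion"

    def __post_init__(self) -> None:
        x = np.asarray(self.abscissa, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if x.shape != y.shape:
            raise ValueError("abscissa and intensities must have the same length")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.kind not in ("diffusion", "relaxometry"):
            raise ValueError(f"unknown curve kind {self.kind!r}")

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.abscissa, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.intensities, dtype=float)

    def __len__(self) -> int:
        return len(self.abscissa)


def ivim_signal(
    params: IvimParameters,
    b: Union[float, Sequence[float], np.ndarray],
    SI0: float,
) -> Union[float, np.ndarray]:
    """Evaluate the biexponential IVIM signal at diffusion weighting ``b``.

    Parameters
    ----------
    params : IvimParameters
        IVIM triple (D, D*, f) in mm^2/s and fraction.
    b : float or array
        Diffusion weighting in s/mm^2; must be >= 0.
    SI0 : float
        Signal at b = 0, arbitrary units, > 0.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b-values must be non-negative")
    if SI0 <= 0:
        raise ValueError("SI0 must be positive")
    si = SI0 * (
        (1.0 - params.f) * np.exp(-b_arr * params.D)
        + params.f * np.exp(-b_arr * params.D_star)
    )
    return float(si) if np.isscalar(b) else si


def r2star_signal(
    params: RelaxometryParameters,
    TE_ms: Union[float, Sequence[float], np.ndarray],
) -> Union[float, np.ndarray]:
    """Monoexponential gradient-echo decay SI0 * exp(-R2* * TE).

    ``TE_ms`` is in milliseconds; R2* is in Hz, so TE is converted to seconds.
    """
    te = np.asarray(TE_ms, dtype=float)
    if np.any(te < 0):
        raise ValueError("echo times must be non-negative")
    si = params.SI0 * np.exp(-params.R2_star * te * 1e-3)
    return float(si) if np.isscalar(TE_ms) else si


def generate_curve(
    params: Union[IvimParameters, RelaxometryParameters],
    protocol: AcquisitionProtocol,
    kind: CurveKind | None = None,
) -> SignalCurve:
    """Sample the appropriate forward model at every protocol point (noise-free).

    The curve kind is inferred from the parameter type when not given.
    """
    if kind is None:
        kind = "diffusion" if isinstance(params, IvimParameters) else "relaxometry"
    if kind == "diffusion":
        if not isinstance(params, IvimParameters):
            raise TypeError("diffusion curves require IvimParameters")
        x = protocol.b_values
        y = ivim_signal(params, np.asarray(x), protocol.SI0)
    elif kind == "relaxometry":
        if not isinstance(params, RelaxometryParameters):
            raise TypeError("relaxometry curves require RelaxometryParameters")
        x = protocol.echo_times_ms
        y = r2star_signal(
            RelaxometryParameters(params.R2_star, protocol.SI0), np.asarray(x)
        )
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return SignalCurve(tuple(x), tuple(np.asarray(y)), kind)


def add_rician_noise(
    curve: SignalCurve,
    sigma: float,
    seed: Union[int, np.random.Generator, None] = None,
) -> SignalCurve:
    """Corrupt a curve with Rician magnitude noise of scale ``sigma``.

    Each intensity S is replaced by sqrt((S + n1)^2 + n2^2) with n1, n2
    independent N(0, sigma^2) draws, the magnitude of a complex signal with
    additive Gaussian noise in both channels.  ``sigma = 0`` returns the curve
    unchanged.  Deterministic under a fixed seed.
    """
    if sigma < 0:
        raise ValueError("noise scale sigma must be non-negative")
    if sigma == 0:
        return curve
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = curve.y
    noisy = np.hypot(y + rng.normal(0.0, sigma, y.shape), rng.normal(0.0, sigma, y.shape))
    return SignalCurve(curve.abscissa, tuple(noisy), curve.kind)
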