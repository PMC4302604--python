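"""Stereographic projection of spherical directions with latitude compression.

The standard projection from the south pole sends a direction with latitude
kappa and longitude tau to the plane point

    x + i y = tan(kappa / 2) exp(i tau)

so the north pole (kappa = 0) maps to the origin and the south pole to
infinity.  Visual contrast can be tuned by substituting kappa -> f(kappa)
before projecting.  Two fixed compressions are provided:

* ``logistic_sq``:    f(kappa) = 1 / (1 + exp(kappa^2))
* ``inverse_quartic``: f(kappa) = 1 / (1 + kappa^4)

Both are *decreasing* in kappa, which reverses the radial order of the plot
(the north pole lands at radius tan(0.25) ~ 0.255 rather than 0); they are
implemented exactly in this form because the published density maps use them
as printed.  The longitude is always preserved.
"""

from __future__ import annotations

import math

import numpy as np

from .frames import SphericalDirection

__all__ = [
    "COMPRESSIONS",
    "apply_compression",
    "invert_compression",
    "stereographic_project",
    "inverse_stereographic",
]

COMPRESSIONS = ("identity", "logistic_sq", "inverse_quartic")


def _check_kind(kind: str) -> None:
    if kind not in COMPRESSIONS:
        raise ValueError(f"unknown compression {kind!r}; choose from {COMPRESSIONS}")


def apply_compression(kappa, kind: str = "identity"):
    """f(kappa) for kappa in [0, pi]; scalar or array."""
    _check_kind(kind)
    k = np.asarray(kappa, dtype=float)
    if np.any(k < 0) or np.any(k > math.pi + 1e-12):
        raise ValueError("kappa outside [0, pi]")
    if kind == "identity":
        out = k
    elif kind == "logistic_sq":
        out = 1.0 / (1.0 + np.exp(k * k))
    else:  # inverse_quartic
        out = 1.0 / (1.0 + k ** 4)
    return float(out) if np.isscalar(kappa) else out


def invert_compression(value, kind: str = "identity"):
    """Inverse of :func:`apply_compression` on [0, pi]; errors outside the image."""
    _check_kind(kind)
    v = np.asarray(value, dtype=float)
    if kind == "identity":
        if np.any(v < 0) or np.any(v > math.pi + 1e-12):
            raise ValueError("value outside the image [0, pi] of the identity compression")
        out = v
    elif kind == "logistic_sq":
        lo = 1.0 / (1.0 + math.exp(math.pi ** 2))
        if np.any(v > 0.5 + 1e-15) or np.any(v < lo - 1e-15):
            raise ValueError("value outside the image of the logistic_sq compression")
        out = np.sqrt(np.log(np.clip(1.0 / np.clip(v, lo, 0.5) - 1.0, 0.0, None)))
    else:
        lo = 1.0 / (1.0 + math.pi ** 4)
        if np.any(v > 1.0 + 1e-15) or np.any(v < lo - 1e-15):
            raise ValueError("value outside the image of the inverse_quartic compression")
        out = (1.0 / np.clip(v, lo, 1.0) - 1.0) ** 0.25
    out = np.clip(out, 0.0, math.pi)
    return float(out) if np.isscalar(value) else out


def stereographic_project(
    direction: SphericalDirection | tuple[float, float],
    compression: str = "identity",
) -> tuple[float, float]:
    """Project a spherical direction to the plane; returns (x, y).

    Raises when the compressed latitude sits at the projection pole
    (kappa = pi with the identity compression).
    """
    if isinstance(direction, SphericalDirection):
        kappa, tau = direction.latitude, direction.longitude
    else:
        kappa, tau = direction
    f = apply_compression(kappa, compression)
    if f >= math.pi - 1e-12:
        raise ValueError("south pole maps to infinity under stereographic projection")
    r = math.tan(f / 2.0)
    return (r * math.cos(tau), r * math.sin(tau))


def inverse_stereographic(
    point: tuple[float, float], compression: str = "identity"
) -> SphericalDirection:
    """Exact inverse of :func:`stereographic_project`."""
    x, y = point
    r = math.hypot(x, y)
    f = 2.0 * math.atan(r)
    kappa = invert_compression(f, compression)
    tau = math.atan2(y, x) if r > 0 else 0.0
    kappa = float(kappa)
    if kappa < 1e-12 or math.pi - kappa < 1e-12:
        tau = 0.0
    return SphericalDirection(latitude=kappa, longitude=tau)
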