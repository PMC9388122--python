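"""Worm-like-chain mechanics of the DNA tether.

Everything downstream (spool model, trace analysis, the synthetic generator)
converts between force, extension and base pairs through this module.  The
model is the Marko-Siggia interpolation formula for the inextensible WLC,

    F(u) = (kT / Lp) * [ 1/(4 (1 - u)^2) - 1/4 + u ],      u = x / L,

with an enthalpic stretching correction ``u -> u + F/S`` (stretch modulus S)
applied at all forces, so that the relative extension of the tether at force
F is ``u(F) = u_MS(F) + F/S``.  Defaults are canonical dsDNA constants:
Lp = 50 nm, S = 1200 pN, kT = 4.11 pN nm (23 C), rise 0.34 nm/bp.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "WLCParams",
    "TetherModel",
    "wlc_force",
    "wlc_relative_extension",
    "wlc_extension",
    "bp_from_delta_extension",
]

# relative extensions this close to full stretch are treated as out of domain
_U_MAX = 1.0 - 1e-9


@dataclass(frozen=True)
class WLCParams:
    """Polymer constants of the DNA tether.

    persistence_length : nm, bending stiffness scale (> 0)
    stretch_modulus    : pN, enthalpic stretch modulus; ``math.inf`` selects
                         the inextensible model
    thermal_energy     : pN nm
    rise_per_bp        : nm of contour per base pair, physical range (0.2, 0.4)
    """

    persistence_length: float = 50.0
    stretch_modulus: float = 1200.0
    thermal_energy: float = 4.11
    rise_per_bp: float = 0.34

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0")
        if self.thermal_energy <= 0:
            raise ValueError("thermal_energy must be > 0")
        if not (0.2 < self.rise_per_bp < 0.4):
            raise ValueError("rise_per_bp outside physical range (0.2, 0.4) nm")
        if self.stretch_modulus <= 0:
            raise ValueError("stretch_modulus must be > 0 (use math.inf for inextensible)")

    @property
    def inextensible(self) -> bool:
        return math.isinf(self.stretch_modulus)


@dataclass(frozen=True)
class TetherModel:
    """A DNA tether: handle contour plus DNA released from the nucleosome."""

    handle_bp: int
    released_bp: float = 0.0
    params: WLCParams = WLCParams()

    def __post_init__(self) -> None:
        if self.handle_bp < 0 or self.released_bp < 0:
            raise ValueError("base-pair counts must be >= 0")

    @property
    def contour_length(self) -> float:
        """Total free contour in nm."""
        return (self.handle_bp + self.released_bp) * self.params.rise_per_bp

    def extension(self, force: float) -> float:
        return wlc_extension(force, self.contour_length, self.params)


def _ms_force(u, params: WLCParams):
    """Inextensible Marko-Siggia force at relative extension u (vectorised)."""
    u = np.asarray(u, dtype=float)
    return (params.thermal_energy / params.persistence_length) * (
        0.25 / (1.0 - u) ** 2 - 0.25 + u
    )


def wlc_force(relative_extension: float, params: WLCParams = WLCParams()) -> float:
    """Force (pN) at a given relative extension of the tether.

    For the extensible model the relation ``u = u_MS(F) + F/S`` is implicit in
    F and is solved by bracketed root finding; for the inextensible model the
    Marko-Siggia formula is evaluated directly.  ``relative_extension`` must
    lie in [0, 1) for the inextensible model; the extensible model also
    accepts the enthalpic regime up to 1 + F/S where the chain stretches
    beyond its B-form contour.
    """
    u = float(relative_extension)
    if params.inextensible:
        if not 0.0 <= u < 1.0:
            raise ValueError(f"relative_extension must be in [0, 1), got {u}")
        return float(_ms_force(u, params)) if u > 0.0 else 0.0
    if u < 0.0 or u >= 1.2:
        raise ValueError(f"relative_extension out of range [0, 1.2): {u}")
    if u == 0.0:
        return 0.0

    def residual(f: float) -> float:
        return wlc_relative_extension(f, params) - u

    # bracket from above: the MS force at min(u, ~1) is an upper bound in the
    # entropic regime; expand geometrically to cover the enthalpic regime
    f_hi = max(float(_ms_force(min(u, _U_MAX - 1e-6), params)), 1e-9)
    while residual(f_hi) < 0.0:
        f_hi *= 2.0
        if f_hi > 1e6:
            raise ValueError("no finite force reaches the requested extension")
    return float(brentq(residual, 0.0, f_hi, xtol=1e-12, rtol=1e-14))


def wlc_relative_extension(force, params: WLCParams = WLCParams()):
    """Relative extension x/L at force (pN).  Vectorised over ``force``.

    Inverts Marko-Siggia by bracketed root finding (tolerance 1e-12 in u) and
    adds the F/S stretching term for the extensible model.
    """
    scalar = np.isscalar(force)
    f = np.atleast_1d(np.asarray(force, dtype=float))
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    u = np.empty_like(f)
    for i, fi in enumerate(f):
        if fi == 0.0:
            u[i] = 0.0
            continue
        u[i] = brentq(lambda x: float(_ms_force(x, params)) - fi, 0.0, _U_MAX,
                      xtol=1e-12, rtol=1e-14)
    if not params.inextensible:
        u = u + f / params.stretch_modulus
    return float(u[0]) if scalar else u


@functools.lru_cache(maxsize=8)
def _u_table(params: WLCParams, f_max: float = 60.0, n: int = 4096):
    grid = np.linspace(0.0, f_max, n)
    u = np.array([wlc_relative_extension(float(f), params) for f in grid])
    return grid, u


def relative_extension_fast(force, params: WLCParams = WLCParams()):
    """Vectorised x/L via a cached dense interpolation table.

    Used by the trace generator and detectors where millions of evaluations
    are needed; interpolation error is far below instrument noise.  Exact
    root-finding (:func:`wlc_relative_extension`) remains the reference.
    """
    grid, u = _u_table(params)
    return np.interp(np.asarray(force, dtype=float), grid, u)


def wlc_extension(force: float, contour_length: float,
                  params: WLCParams = WLCParams()) -> float:
    """End-to-end extension (nm) of ``contour_length`` nm of DNA at ``force`` pN.

    Raises for force <= 0 (the chain has no defined extension without tension).
    """
    if force <= 0:
        raise ValueError("force must be > 0")
    if contour_length < 0:
        raise ValueError("contour_length must be >= 0")
    return contour_length * wlc_relative_extension(force, params)


def bp_from_delta_extension(delta_x: float, force: float,
                            params: WLCParams = WLCParams()) -> float:
    """Geometry-free conversion of an extension change to released base pairs.

    The naive inversion ``bp = dx / (rise * u(F))``: it ignores any change in
    the particle's entry-exit chord and serves as the zero-radius baseline of
    the geometric model.
    """
    if delta_x < 0:
        raise ValueError("delta_x must be >= 0")
    if force <= 0:
        raise ValueError("force must be > 0")
    return delta_x / (params.rise_per_bp * wlc_relative_extension(force, params))
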