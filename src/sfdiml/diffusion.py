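"""Standard diffusion approximation of spatial-frequency-domain reflectance.

Forward model: with transport coefficient ``mu_tr = mu_a + mu_s'``, reduced
albedo ``a' = mu_s'/mu_tr``, projection wavenumber ``k = 2*pi*fx`` and
``mu_eff' = sqrt(3*mu_a*mu_tr + k^2)``, the diffuse reflectance of a
semi-infinite medium under sinusoidal irradiance is

    Rd(fx) = 3*A*a' / ((mu_eff'/mu_tr + 1) * (mu_eff'/mu_tr + 3*A))

where ``A = (1 - R_eff) / (2*(1 + R_eff))`` is the partial-current boundary
constant and ``R_eff`` is the effective internal reflection coefficient of
the index-mismatched boundary, taken from the standard polynomial fit
``R_eff(n) = 0.0636*n + 0.668 + 0.710/n - 1.440/n^2``.

The inverse problem for the two-frequency pair (R0, Rn) is solved
semi-analytically: at fx = 0 the reflectance depends on the optical
properties only through the reduced albedo, so R0 pins down ``a'`` by a 1-D
monotone bisection; Rn then yields ``mu_eff'/mu_tr`` in closed form
(quadratic), from which ``mu_tr`` and hence (mu_a, mu_s') follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mc_transport import (
    DEFAULT_FX_N,
    MU_A_RANGE,
    MU_SP_RANGE,
    OpticalProperties,
)

__all__ = [
    "DiffusionParams",
    "diffusion_rd",
    "diffusion_invert",
    "DiffusionForward",
    "STATUS_OK",
    "STATUS_OUT_OF_DOMAIN",
    "STATUS_INVALID",
]

# Per-pixel status codes shared across inversion back-ends.
STATUS_OK = 0
STATUS_OUT_OF_DOMAIN = 1
STATUS_INVALID = 2


@dataclass(frozen=True)
class DiffusionParams:
    """Boundary constants of the diffusion model for a given index ratio."""

    refractive_index_ratio: float = 1.43

    def __post_init__(self) -> None:
        if self.refractive_index_ratio < 1.0:
            raise ValueError("refractive_index_ratio must be >= 1")

    @property
    def r_eff(self) -> float:
        """Effective internal reflection coefficient (polynomial fit)."""
        n = self.refractive_index_ratio
        return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2

    @property
    def boundary_a(self) -> float:
        """Partial-current boundary constant A = (1-R_eff)/(2(1+R_eff))."""
        r = self.r_eff
        return (1.0 - r) / (2.0 * (1.0 + r))


def _rd_from_albedo(a_prime, x, boundary_a):
    """Rd given reduced albedo a' and x = mu_eff'/mu_tr (array-friendly)."""
    three_a = 3.0 * boundary_a
    return three_a * a_prime / ((x + 1.0) * (x + three_a))


def diffusion_rd(props, params: DiffusionParams = DiffusionParams(), fx: float = 0.0):
    """Diffuse reflectance of the diffusion model at spatial frequency ``fx``.

    ``props`` may be an :class:`OpticalProperties` (returns a float) or a
    pair of arrays ``(mu_a, mu_s_prime)`` (returns an array).
    """
    if fx < 0.0:
        raise ValueError("fx must be >= 0")
    if isinstance(props, OpticalProperties):
        mu_a, mu_sp = props.mu_a, props.mu_s_prime
        scalar = True
    else:
        mu_a, mu_sp = np.asarray(props[0], float), np.asarray(props[1], float)
        scalar = False
    mu_tr = mu_a + mu_sp
    if np.any(np.asarray(mu_tr) <= 0.0):
        raise ValueError("mu_a + mu_s_prime must be > 0")
    a_prime = mu_sp / mu_tr
    k = 2.0 * math.pi * fx
    x = np.sqrt(3.0 * mu_a * mu_tr + k * k) / mu_tr
    rd = _rd_from_albedo(a_prime, x, params.boundary_a)
    return float(rd) if scalar else rd


def _albedo_from_r0(r0, boundary_a, n_iter: int = 80):
    """Invert R0 = Rd(a', fx=0) for the reduced albedo by bisection.

    At fx = 0, x = sqrt(3*(1 - a')), so R0 is a strictly increasing function
    of a' with R0(0) = 0 and R0(1) = 1; the root is unique.
    """
    lo = np.zeros_like(r0)
    hi = np.ones_like(r0)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        val = _rd_from_albedo(mid, np.sqrt(3.0 * (1.0 - mid)), boundary_a)
        take = val < r0
        lo = np.where(take, mid, lo)
        hi = np.where(take, hi, mid)
    return 0.5 * (lo + hi)


def diffusion_invert(
    r0,
    rn,
    params: DiffusionParams = DiffusionParams(),
    fx_n: float = DEFAULT_FX_N,
):
    """Recover (mu_a, mu_s') from calibrated reflectance at fx=0 and fx_n.

    Returns ``(mu_a, mu_s_prime, status)`` arrays of the broadcast shape of
    the inputs.  Pixels with no solution (non-finite input, reflectance
    outside (0, 1), Rn >= R0, or a recovered pair outside the supported
    domain) are flagged in ``status`` rather than raising.
    """
    if fx_n <= 0.0:
        raise ValueError("fx_n must be > 0")
    r0 = np.asarray(r0, float)
    rn = np.asarray(rn, float)
    r0b, rnb = np.broadcast_arrays(r0, rn)
    shape = r0b.shape
    r0f = r0b.ravel().copy()
    rnf = rnb.ravel().copy()
    status = np.full(r0f.shape, STATUS_OK, dtype=np.uint8)
    bad_input = ~np.isfinite(r0f) | ~np.isfinite(rnf)
    status[bad_input] = STATUS_INVALID
    # Zero frequency contrast (Rn >= R0) carries no scattering information
    # within the model's monotone regime; reflectance must lie in (0, 1).
    degenerate = (~bad_input) & (
        (r0f <= 0.0) | (r0f >= 1.0) | (rnf <= 0.0) | (rnf >= r0f)
    )
    status[degenerate] = STATUS_OUT_OF_DOMAIN
    ok = status == STATUS_OK
    mu_a = np.full(r0f.shape, np.nan)
    mu_sp = np.full(r0f.shape, np.nan)
    if np.any(ok):
        A = params.boundary_a
        three_a = 3.0 * A
        a_prime = _albedo_from_r0(r0f[ok], A)
        # Rn = 3A a' / ((x+1)(x+3A))  =>  quadratic in x = mu_eff'/mu_tr
        c = three_a - three_a * a_prime / rnf[ok]
        disc = (1.0 + three_a) ** 2 - 4.0 * c
        x = 0.5 * (-(1.0 + three_a) + np.sqrt(np.maximum(disc, 0.0)))
        # x^2 = 3(1-a') + k^2/mu_tr^2 must exceed its fx=0 value
        k = 2.0 * math.pi * fx_n
        x2_excess = x * x - 3.0 * (1.0 - a_prime)
        solvable = x2_excess > 0.0
        mu_tr = np.full(a_prime.shape, np.nan)
        mu_tr[solvable] = k / np.sqrt(x2_excess[solvable])
        mu_a_ok = (1.0 - a_prime) * mu_tr
        mu_sp_ok = a_prime * mu_tr
        mu_a[ok] = mu_a_ok
        mu_sp[ok] = mu_sp_ok
        sub = status[ok]
        sub[~solvable] = STATUS_OUT_OF_DOMAIN
        outside = (
            solvable
            & (
                (mu_a_ok < MU_A_RANGE[0] - 1e-9)
                | (mu_a_ok > MU_A_RANGE[1] + 1e-9)
                | (mu_sp_ok < MU_SP_RANGE[0] * (1 - 1e-9))
                | (mu_sp_ok > MU_SP_RANGE[1] * (1 + 1e-9))
            )
        )
        sub[outside] = STATUS_OUT_OF_DOMAIN
        status[ok] = sub
    return mu_a.reshape(shape), mu_sp.reshape(shape), status.reshape(shape)


class DiffusionForward:
    """Forward-model handle backed by the diffusion closed form.

    Exposes the same protocol as the white-MC evaluator so LUT construction
    and calibration can run on either light-propagation model.
    """

    def __init__(
        self,
        params: DiffusionParams = DiffusionParams(),
        fx_n: float = DEFAULT_FX_N,
    ) -> None:
        self.params = params
        self.fx_n = float(fx_n)
        self.provenance = f"diffusion(n={params.refractive_index_ratio}, fx_n={fx_n})"

    def reflectance_pairs(self, mu_a, mu_s_prime):
        mu_a = np.atleast_1d(np.asarray(mu_a, float))
        mu_sp = np.atleast_1d(np.asarray(mu_s_prime, float))
        r0 = diffusion_rd((mu_a, mu_sp), self.params, 0.0)
        rn = diffusion_rd((mu_a, mu_sp), self.params, self.fx_n)
        return r0, rn

    def reflectance(self, props: OpticalProperties, fx: float) -> float:
        return diffusion_rd(props, self.params, fx)
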