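"""Independent brute-force Monte-Carlo oracle with explicit absorption.

Deliberately structured unlike the package kernel: absorption is applied as
an albedo weight at every interaction (no white rescaling, no histogram),
and the frequency-domain reflectance is estimated directly by weighting
each exit event with cos(2*pi*fx*x_exit).  Used only to cross-check the
white-MC + similarity + Hankel pipeline on single property pairs.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def mc_reflectance_oracle(n_photons, mu_a, mu_s, g, n_rel, fx, seed, n_batches):
    """Batch means of (R_total, R_fx) for a semi-infinite medium."""
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    k = 2.0 * math.pi * fx
    batch_r0 = np.zeros(n_batches)
    batch_rn = np.zeros(n_batches)
    per_batch = n_photons // n_batches
    for batch in range(n_batches):
        acc0 = 0.0
        accn = 0.0
        for _ in range(per_batch):
            w = 1.0
            x = 0.0
            y = 0.0
            z = 0.0
            ux = 0.0
            uy = 0.0
            uz = 1.0
            alive = True
            while alive:
                step = -math.log(1.0 - np.random.random()) / mu_t
                while step > 0.0:
                    d_b = -z / uz if uz < 0.0 else 1e308
                    if d_b <= step:
                        x += ux * d_b
                        y += uy * d_b
                        z = 0.0
                        # Fresnel (unpolarised) from inside
                        ci = -uz
                        si2 = 1.0 - ci * ci
                        st2 = n_rel * n_rel * si2
                        if st2 >= 1.0:
                            refl = 1.0
                        else:
                            ct = math.sqrt(1.0 - st2)
                            rs = (n_rel * ci - ct) / (n_rel * ci + ct)
                            rp = (n_rel * ct - ci) / (n_rel * ct + ci)
                            refl = 0.5 * (rs * rs + rp * rp)
                        if np.random.random() >= refl:
                            acc0 += w
                            accn += w * math.cos(k * x)
                            alive = False
                            break
                        uz = -uz
                        step -= d_b
                    else:
                        x += ux * step
                        y += uy * step
                        z += uz * step
                        step = 0.0
                if not alive:
                    break
                w *= albedo
                u = np.random.random()
                if g > 1e-6:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                    cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                else:
                    cos_t = 1.0 - 2.0 * u
                if cos_t > 1.0:
                    cos_t = 1.0
                elif cos_t < -1.0:
                    cos_t = -1.0
                sin_t = math.sqrt(1.0 - cos_t * cos_t)
                phi = 2.0 * math.pi * np.random.random()
                cos_p = math.cos(phi)
                sin_p = math.sin(phi)
                if abs(uz) > 0.99999:
                    ux = sin_t * cos_p
                    uy = sin_t * sin_p
                    uz = cos_t * (1.0 if uz >= 0.0 else -1.0)
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
                    ny = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
                    nz = -sin_t * cos_p * den + uz * cos_t
                    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
                    ux = nx / norm
                    uy = ny / norm
                    uz = nz / norm
                if w < 1e-4:
                    if np.random.random() * 10.0 < 1.0:
                        w *= 10.0
                    else:
                        break
        batch_r0[batch] = acc0 / per_batch
        batch_rn[batch] = accn / per_batch
    return batch_r0, batch_rn


def oracle_estimate(n_photons, mu_a, mu_s_prime, g, n_rel, fx, seed, n_batches=25):
    """(mean, standard error) of R_total and R_fx from the brute-force MC."""
    mu_s = mu_s_prime / (1.0 - g) if g > 0 else mu_s_prime
    b0, bn = mc_reflectance_oracle(
        n_photons, mu_a, mu_s, g, n_rel, fx, seed, n_batches
    )
    return (
        float(b0.mean()),
        float(b0.std(ddof=1) / math.sqrt(n_batches)),
        float(bn.mean()),
        float(bn.std(ddof=1) / math.sqrt(n_batches)),
    )
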