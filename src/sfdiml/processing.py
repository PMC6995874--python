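"""Demodulation of phase-shifted fringe stacks and phantom calibration.

A two-frequency SFDI acquisition records, at the working frequency fn, three
images of sinusoidally patterned illumination with phase offsets 0, 2*pi/3
and 4*pi/3.  The per-pixel modulation amplitude is recovered with the
classic three-phase formula

    A = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2)

which is exact for an ideal sinusoid sampled at 2*pi/3 spacing, independent
of the global fringe phase.  The planar (fx = 0) amplitude is the
three-phase mean.  Amplitudes are converted to absolute diffuse reflectance
against a reference phantom of known optical properties:

    Rn = (An / An_ref) * Rn_ref

with ``Rn_ref`` evaluated by a forward light-propagation model at the
phantom properties.  Camera gain and illumination intensity cancel in the
ratio, so amplitude maps may be in arbitrary camera units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml

from .diffusion import STATUS_INVALID, STATUS_OK, STATUS_OUT_OF_DOMAIN
from .mc_transport import OpticalProperties

__all__ = [
    "PhaseStack",
    "ReflectancePair",
    "demodulate_ac",
    "demodulate_dc",
    "calibrate",
    "reference_reflectance",
    "load_phase_stack",
    "save_phase_stack",
    "save_reflectance_map",
    "load_reflectance_map",
]

#: Canonical three-phase offsets (radians).
DEFAULT_PHASES = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)

#: Pixels whose reference amplitude falls below this fraction of the
#: reference maximum are flagged invalid instead of producing infinities.
REFERENCE_AMPLITUDE_FLOOR = 1e-6


@dataclass
class PhaseStack:
    """Three equal-shape intensity images of one projected frequency."""

    images: np.ndarray  # (3, H, W)
    spatial_frequency: float  # mm^-1
    pixel_pitch: float  # mm / pixel
    phases: tuple = DEFAULT_PHASES

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[0] != 3:
            raise ValueError(
                f"expected a (3, H, W) stack, got shape {self.images.shape}"
            )
        if np.any(self.images < 0):
            raise ValueError("intensities must be >= 0")
        if self.spatial_frequency < 0:
            raise ValueError("spatial_frequency must be >= 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")

    @property
    def shape(self):
        return self.images.shape[1:]


@dataclass
class ReflectancePair:
    """Calibrated diffuse reflectance maps at fx=0 and fx=fn, plus flags."""

    r0: np.ndarray
    rn: np.ndarray
    fx_n: float
    status: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.r0 = np.asarray(self.r0, float)
        self.rn = np.asarray(self.rn, float)
        if self.r0.shape != self.rn.shape:
            raise ValueError("R0 and Rn must share a shape")
        if self.status is None:
            self.status = np.full(self.r0.shape, STATUS_OK, dtype=np.uint8)


def _check_stack(stack: PhaseStack) -> np.ndarray:
    imgs = stack.images
    if imgs.shape[0] != 3:
        raise ValueError("three phase images are required")
    return imgs


def demodulate_ac(stack: PhaseStack) -> np.ndarray:
    """Per-pixel modulation amplitude of the patterned illumination.

    Exact for ideal three-phase sinusoidal illumination at 2*pi/3 spacing;
    invariant to a global phase offset of the projected pattern.
    """
    i1, i2, i3 = _check_stack(stack)
    return (math.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )


def demodulate_dc(stack: PhaseStack) -> np.ndarray:
    """Per-pixel planar (fx = 0) amplitude: the three-phase mean."""
    i1, i2, i3 = _check_stack(stack)
    return (i1 + i2 + i3) / 3.0


def reference_reflectance(forward, ref_props: OpticalProperties, fx: float) -> float:
    """Simulated diffuse reflectance of the calibration phantom at ``fx``.

    Uses the handle's vectorised two-frequency path when ``fx`` matches one
    of its working frequencies (so calibration is numerically identical to
    LUT/training evaluations of the same model), falling back to the exact
    scalar evaluation otherwise.
    """
    fx_n = getattr(forward, "fx_n", None)
    if fx == 0.0 or (fx_n is not None and fx == fx_n):
        r0, rn = forward.reflectance_pairs(
            np.array([ref_props.mu_a]), np.array([ref_props.mu_s_prime])
        )
        return float(r0[0]) if fx == 0.0 else float(rn[0])
    return float(forward.reflectance(ref_props, fx))


def calibrate(
    a_sample: np.ndarray,
    a_ref: np.ndarray,
    ref_props: OpticalProperties,
    fx: float,
    forward,
):
    """Convert amplitude maps to absolute diffuse reflectance.

    Returns ``(reflectance, status)``.  Pixels where the reference amplitude
    is below ``REFERENCE_AMPLITUDE_FLOOR`` of its maximum are flagged
    invalid; calibrated values outside [0, 1] are flagged out-of-domain but
    not clamped, so inversion back-ends can apply their own policy.
    """
    if not ref_props.in_training_domain():
        raise ValueError(
            "reference phantom properties outside the supported domain"
        )
    a_sample = np.asarray(a_sample, float)
    a_ref = np.asarray(a_ref, float)
    if a_sample.shape != a_ref.shape:
        raise ValueError("sample and reference amplitude maps must share a shape")
    rd_ref = reference_reflectance(forward, ref_props, fx)
    status = np.full(a_sample.shape, STATUS_OK, dtype=np.uint8)
    floor = REFERENCE_AMPLITUDE_FLOOR * float(np.max(a_ref)) if a_ref.size else 0.0
    invalid = (
        ~np.isfinite(a_sample) | ~np.isfinite(a_ref) | (a_ref <= floor)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = a_sample / a_ref * rd_ref
    refl[invalid] = np.nan
    status[invalid] = STATUS_INVALID
    out_of_range = ~invalid & ((refl < 0.0) | (refl > 1.0))
    status[out_of_range] = STATUS_OUT_OF_DOMAIN
    return refl, status


# ---------------------------------------------------------------------------
# File formats: TIFF stacks with YAML sidecar metadata
# ---------------------------------------------------------------------------


def save_phase_stack(path, stack: PhaseStack) -> None:
    """Write a three-page float32 TIFF plus a ``<path>.yaml`` sidecar."""
    tifffile.imwrite(
        str(path), stack.images.astype(np.float32), photometric="minisblack"
    )
    meta = {
        "spatial_frequency_per_mm": float(stack.spatial_frequency),
        "pixel_pitch_mm": float(stack.pixel_pitch),
        "phases_rad": [float(p) for p in stack.phases],
    }
    with open(f"{path}.yaml", "w") as f:
        yaml.safe_dump(meta, f)


def load_phase_stack(path) -> PhaseStack:
    """Read a multi-page TIFF stack and its YAML sidecar."""
    images = tifffile.imread(str(path))
    if images.ndim == 2:
        raise ValueError("expected a 3-page stack, got a single image")
    try:
        with open(f"{path}.yaml") as f:
            meta = yaml.safe_load(f)
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"missing sidecar metadata {path}.yaml (frequency, pixel pitch)"
        ) from exc
    return PhaseStack(
        images=np.asarray(images, float),
        spatial_frequency=float(meta["spatial_frequency_per_mm"]),
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        phases=tuple(meta.get("phases_rad", DEFAULT_PHASES)),
    )


def save_reflectance_map(path, reflectance: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(reflectance, np.float32))


def load_reflectance_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), float)
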