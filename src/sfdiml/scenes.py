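"""Synthetic SFDI scenes: fringe-stack rendering and the end-to-end pipeline.

The scene generator stands in for a real acquisition: it renders the three
phase-shifted camera images of a sinusoidally illuminated, piecewise-
homogeneous turbid slab, given a forward light-propagation model for each
region's diffuse reflectance.  Per pixel the recorded intensity is

    I_k = gain * (dc_level * R0 + ac_level * Rn * cos(2*pi*fx*x + phi_k))

with optional additive Gaussian read noise and Poisson shot noise applied
last.  Each pixel is treated as locally homogeneous (no lateral transport
across region edges), which is adequate for patch-interior statistics.

``run_pipeline`` wires the full processing chain of a two-frequency
acquisition: demodulate the sample and reference stacks, calibrate to
absolute reflectance, invert with one or more back-ends, and report
per-region statistics and cross-method percentage-difference maps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .diffusion import STATUS_OK
from .inversion import PropertyMaps
from .mc_transport import DEFAULT_FX_N, OpticalProperties
from .processing import (
    DEFAULT_PHASES,
    PhaseStack,
    ReflectancePair,
    calibrate,
    demodulate_ac,
    demodulate_dc,
)

__all__ = [
    "Region",
    "SceneSpec",
    "SceneRender",
    "render_stacks",
    "reference_scene",
    "six_patch_scene",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger(__name__)

#: Paper-style phantom property ranges used by :func:`six_patch_scene`.
PHANTOM_MU_A_RANGE = (0.0135, 0.0437)
PHANTOM_MU_SP_RANGE = (0.982, 1.326)


@dataclass(frozen=True)
class Region:
    """A homogeneous patch: an axis-aligned rectangle or a disk (pixels)."""

    kind: str  # "rect" or "disk"
    params: tuple  # rect: (row0, col0, row1, col1); disk: (row, col, radius)
    props: OpticalProperties

    def mask(self, shape) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        if self.kind == "rect":
            r0, c0, r1, c1 = self.params
            return (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
        if self.kind == "disk":
            r, c, rad = self.params
            return (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        raise ValueError(f"unknown region kind {self.kind!r}")


@dataclass
class SceneSpec:
    """Synthetic scene description: geometry, optics, illumination, camera."""

    shape: tuple = (256, 256)
    pixel_pitch: float = 0.15  # mm / pixel
    background: OpticalProperties = field(
        default_factory=lambda: OpticalProperties(0.0117, 1.0827)
    )
    regions: tuple = ()
    spatial_frequency: float = DEFAULT_FX_N  # mm^-1
    phases: tuple = DEFAULT_PHASES
    dc_level: float = 0.5
    ac_level: float = 0.5
    gain: float = 1000.0  # camera units per unit reflectance-weighted level
    noise_sigma: float = 0.0  # additive Gaussian, camera units
    poisson: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for reg in self.regions:
            if not reg.props.in_training_domain():
                raise ValueError(
                    f"region properties {reg.props} outside the supported domain"
                )
        if not self.background.in_training_domain():
            raise ValueError("background properties outside the supported domain")
        if self.dc_level < self.ac_level:
            raise ValueError(
                "dc_level must be >= ac_level for non-negative illumination"
            )

    def to_yaml(self, path) -> None:
        payload = {
            "shape": [int(s) for s in self.shape],
            "pixel_pitch": float(self.pixel_pitch),
            "background": [
                float(self.background.mu_a),
                float(self.background.mu_s_prime),
            ],
            "regions": [
                {
                    "kind": r.kind,
                    "params": [int(p) for p in r.params],
                    "mu_a": float(r.props.mu_a),
                    "mu_s_prime": float(r.props.mu_s_prime),
                }
                for r in self.regions
            ],
            "spatial_frequency": float(self.spatial_frequency),
            "phases": [float(p) for p in self.phases],
            "dc_level": float(self.dc_level),
            "ac_level": float(self.ac_level),
            "gain": float(self.gain),
            "noise_sigma": float(self.noise_sigma),
            "poisson": bool(self.poisson),
            "rng_seed": int(self.rng_seed),
        }
        with open(path, "w") as f:
            yaml.safe_dump(payload, f)

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        with open(path) as f:
            d = yaml.safe_load(f)
        regions = tuple(
            Region(
                kind=r["kind"],
                params=tuple(r["params"]),
                props=OpticalProperties(r["mu_a"], r["mu_s_prime"]),
            )
            for r in d.get("regions", ())
        )
        bg = d.get("background", [0.0117, 1.0827])
        return cls(
            shape=tuple(d.get("shape", (256, 256))),
            pixel_pitch=float(d.get("pixel_pitch", 0.15)),
            background=OpticalProperties(bg[0], bg[1]),
            regions=regions,
            spatial_frequency=float(d.get("spatial_frequency", DEFAULT_FX_N)),
            phases=tuple(d.get("phases", DEFAULT_PHASES)),
            dc_level=float(d.get("dc_level", 0.5)),
            ac_level=float(d.get("ac_level", 0.5)),
            gain=float(d.get("gain", 1000.0)),
            noise_sigma=float(d.get("noise_sigma", 0.0)),
            poisson=bool(d.get("poisson", False)),
            rng_seed=int(d.get("rng_seed", 0)),
        )


@dataclass
class SceneRender:
    """Rendered stacks plus the ground truth that produced them."""

    stack_fn: PhaseStack  # patterned illumination at fx = spatial_frequency
    stack_f0: PhaseStack  # planar illumination (fx = 0)
    truth: PropertyMaps
    amplitude_dc: np.ndarray  # noise-free gain * dc_level * R0
    amplitude_ac: np.ndarray  # noise-free gain * ac_level * Rn
    region_labels: np.ndarray  # 0 = background, i >= 1 = regions[i-1]


def _region_maps(spec: SceneSpec, forward):
    """Per-pixel (R0, Rn) and truth maps from region-wise forward calls."""
    labels = np.zeros(spec.shape, dtype=np.int32)
    for i, reg in enumerate(spec.regions, start=1):
        labels[reg.mask(spec.shape)] = i
    all_props = [spec.background] + [r.props for r in spec.regions]
    mu_a = np.array([p.mu_a for p in all_props])
    mu_sp = np.array([p.mu_s_prime for p in all_props])
    r0_by_label, rn_by_label = forward.reflectance_pairs(mu_a, mu_sp)
    r0 = r0_by_label[labels]
    rn = rn_by_label[labels]
    truth = PropertyMaps(
        mu_a=mu_a[labels],
        mu_s_prime=mu_sp[labels],
        status=np.full(spec.shape, STATUS_OK, dtype=np.uint8),
    )
    return r0, rn, truth, labels


def render_stacks(spec: SceneSpec, forward) -> SceneRender:
    """Render the two phase stacks (fx = fn and fx = 0) of a scene.

    Bitwise reproducible at a fixed ``spec.rng_seed``.
    """
    r0, rn, truth, labels = _region_maps(spec, forward)
    a_dc = spec.gain * spec.dc_level * r0
    a_ac = spec.gain * spec.ac_level * rn
    x_mm = np.arange(spec.shape[1]) * spec.pixel_pitch
    rng = np.random.default_rng(spec.rng_seed)

    def _noise(img):
        if spec.poisson:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        if spec.noise_sigma > 0.0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        return np.maximum(img, 0.0)

    fringes = [
        np.cos(2.0 * np.pi * spec.spatial_frequency * x_mm + phi)[None, :]
        for phi in spec.phases
    ]
    imgs_fn = np.stack([_noise(a_dc + a_ac * f) for f in fringes])
    imgs_f0 = np.stack([_noise(a_dc.copy()) for _ in spec.phases])
    stack_fn = PhaseStack(
        images=imgs_fn,
        spatial_frequency=spec.spatial_frequency,
        pixel_pitch=spec.pixel_pitch,
        phases=spec.phases,
    )
    stack_f0 = PhaseStack(
        images=imgs_f0,
        spatial_frequency=0.0,
        pixel_pitch=spec.pixel_pitch,
        phases=spec.phases,
    )
    return SceneRender(
        stack_fn=stack_fn,
        stack_f0=stack_f0,
        truth=truth,
        amplitude_dc=a_dc,
        amplitude_ac=a_ac,
        region_labels=labels,
    )


def reference_scene(
    spec: SceneSpec, ref_props: OpticalProperties, seed_offset: int = 1
) -> SceneSpec:
    """A homogeneous calibration-phantom scene matching ``spec``'s camera."""
    return SceneSpec(
        shape=spec.shape,
        pixel_pitch=spec.pixel_pitch,
        background=ref_props,
        regions=(),
        spatial_frequency=spec.spatial_frequency,
        phases=spec.phases,
        dc_level=spec.dc_level,
        ac_level=spec.ac_level,
        gain=spec.gain,
        noise_sigma=spec.noise_sigma,
        poisson=spec.poisson,
        rng_seed=spec.rng_seed + seed_offset,
    )


def six_patch_scene(
    shape=(360, 240),
    patch_size: int = 100,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> SceneSpec:
    """Six square phantoms spanning tissue-like property ranges.

    Patch properties are spaced across mu_a in [0.0135, 0.0437] mm^-1 and
    mu_s' in [0.982, 1.326] mm^-1, arranged on a 3 x 2 grid.
    """
    mu_a_vals = np.linspace(*PHANTOM_MU_A_RANGE, 6)
    mu_sp_vals = np.linspace(*PHANTOM_MU_SP_RANGE, 6)
    regions = []
    pad_r = shape[0] // 3
    pad_c = shape[1] // 2
    for idx in range(6):
        gr, gc = divmod(idx, 2)
        r0 = gr * pad_r + (pad_r - patch_size) // 2
        c0 = gc * pad_c + (pad_c - patch_size) // 2
        regions.append(
            Region(
                kind="rect",
                params=(r0, c0, r0 + patch_size, c0 + patch_size),
                props=OpticalProperties(mu_a_vals[idx], mu_sp_vals[idx]),
            )
        )
    return SceneSpec(
        shape=shape,
        regions=tuple(regions),
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Outputs of the demodulate -> calibrate -> invert chain."""

    reflectance: ReflectancePair
    maps: dict  # method name -> PropertyMaps
    region_stats: list  # rows of per-region mean/std per method
    difference_maps: dict  # (method_a, method_b) -> dict of pct maps

    def report(self) -> dict:
        return {
            "region_stats": self.region_stats,
            "methods": sorted(self.maps),
            "flagged_fraction": {
                name: float(np.mean(m.status != STATUS_OK))
                for name, m in self.maps.items()
            },
        }

    def save_report(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.report(), f, indent=2)


def _percent_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a - b) / b * 100.0


def run_pipeline(
    sample_fn: PhaseStack,
    ref_fn: PhaseStack,
    ref_props: OpticalProperties,
    forward,
    inverters: dict,
    sample_f0: PhaseStack | None = None,
    ref_f0: PhaseStack | None = None,
    region_labels: np.ndarray | None = None,
    dc_source: str = "fn_mean",
) -> PipelineResult:
    """Demodulate, calibrate and invert a two-frequency acquisition.

    ``inverters`` maps method names to callables ``(r0, rn) ->
    PropertyMaps``.  The planar (fx = 0) amplitude is taken from the
    three-phase mean of the patterned stack by default (``dc_source =
    'fn_mean'``); pass ``dc_source='f0_stack'`` with explicit planar stacks
    to use a separately acquired fx = 0 measurement.
    """
    if dc_source not in ("fn_mean", "f0_stack"):
        raise ValueError("dc_source must be 'fn_mean' or 'f0_stack'")
    if dc_source == "f0_stack" and (sample_f0 is None or ref_f0 is None):
        raise ValueError("dc_source='f0_stack' requires the planar stacks")
    fx_n = sample_fn.spatial_frequency
    logger.info("demodulating stacks (fx_n=%.3g mm^-1)", fx_n)
    a_ac = demodulate_ac(sample_fn)
    a_ac_ref = demodulate_ac(ref_fn)
    if dc_source == "fn_mean":
        a_dc = demodulate_dc(sample_fn)
        a_dc_ref = demodulate_dc(ref_fn)
    else:
        a_dc = demodulate_dc(sample_f0)
        a_dc_ref = demodulate_dc(ref_f0)
    r0, status0 = calibrate(a_dc, a_dc_ref, ref_props, 0.0, forward)
    rn, statusn = calibrate(a_ac, a_ac_ref, ref_props, fx_n, forward)
    refl = ReflectancePair(
        r0=r0, rn=rn, fx_n=fx_n, status=np.maximum(status0, statusn)
    )
    maps = {}
    for name, invert in inverters.items():
        logger.info("inverting with %s", name)
        result = invert(r0, rn)
        # propagate calibration flags
        result.status = np.maximum(result.status, refl.status)
        maps[name] = result
    region_stats = []
    if region_labels is not None:
        for name, m in maps.items():
            for lbl in np.unique(region_labels):
                mask = (region_labels == lbl) & m.ok
                if not np.any(mask):
                    continue
                region_stats.append(
                    {
                        "method": name,
                        "region": int(lbl),
                        "n_pixels": int(mask.sum()),
                        "mu_a_mean": float(np.mean(m.mu_a[mask])),
                        "mu_a_std": float(np.std(m.mu_a[mask])),
                        "mu_s_prime_mean": float(np.mean(m.mu_s_prime[mask])),
                        "mu_s_prime_std": float(np.std(m.mu_s_prime[mask])),
                    }
                )
    difference_maps = {}
    names = sorted(maps)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            difference_maps[(na, nb)] = {
                "mu_a_pct": _percent_difference(maps[na].mu_a, maps[nb].mu_a),
                "mu_s_prime_pct": _percent_difference(
                    maps[na].mu_s_prime, maps[nb].mu_s_prime
                ),
            }
    return PipelineResult(
        reflectance=refl,
        maps=maps,
        region_stats=region_stats,
        difference_maps=difference_maps,
    )
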