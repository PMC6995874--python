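"""Inversion back-ends: forward LUTs, ensemble regression, error metrics.

Two families of learned inverse are provided for the two-frequency mapping
(R0, Rn) <-> (mu_a, mu_s'):

* **LUT inversion** - a rectangular grid over the property domain is pushed
  through a forward model; a query reflectance pair is located inside the
  forward image of one grid cell (walking cell-to-cell from a nearest-node
  seed, guided by the inverse bilinear coordinates) and inverted bilinearly
  within that cell.  Exact at grid nodes, with off-grid error bounded by one
  property-space cell.
* **Random-forest regression** - a multi-output ensemble of regression
  trees fit on uniformly sampled property pairs and their forward
  reflectances; prediction is a vectorised per-pixel map evaluation.

The benchmark error metric is the mean relative error in percent, computed
separately for mu_a and mu_s'.  Relative error in mu_a is ill-defined near
mu_a = 0 (the sampled range includes zero), so samples with true mu_a below
a configurable floor (default 1e-3 mm^-1) are excluded from the mu_a metric
and the excluded fraction is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import joblib
import numpy as np
from numba import njit
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestRegressor

from .diffusion import STATUS_INVALID, STATUS_OK, STATUS_OUT_OF_DOMAIN
from .mc_transport import MU_A_RANGE, MU_SP_RANGE

__all__ = [
    "ForwardLUT",
    "TrainingSet",
    "InversionModel",
    "PropertyMaps",
    "build_forward_lut",
    "lut_invert",
    "generate_training_set",
    "train_regressor",
    "predict_properties",
    "mean_relative_error",
    "benchmark_methods",
    "MU_A_ERROR_FLOOR",
]

#: Samples with true mu_a below this floor (mm^-1) are excluded from the
#: mu_a relative-error metric (division-by-near-zero guard).  This choice
#: moves the headline error numbers and is documented prominently.
MU_A_ERROR_FLOOR = 1e-3

_MODEL_FORMAT_VERSION = 1


@dataclass
class PropertyMaps:
    """Per-pixel mu_a and mu_s' maps (mm^-1) with per-pixel status flags."""

    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        if not (self.mu_a.shape == self.mu_s_prime.shape == self.status.shape):
            raise ValueError("property maps and status must share a shape")

    @property
    def ok(self) -> np.ndarray:
        return self.status == STATUS_OK


@dataclass
class ForwardLUT:
    """Forward-mapped rectangular grid over (mu_a, mu_s').

    ``r0[i, j]`` and ``rn[i, j]`` are the reflectances of
    ``(mu_a_axis[i], mu_s_axis[j])`` under the generating forward model.
    """

    mu_a_axis: np.ndarray
    mu_s_axis: np.ndarray
    r0: np.ndarray
    rn: np.ndarray
    fx_n: float
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        p, q = self.mu_a_axis.size, self.mu_s_axis.size
        if self.r0.shape != (p, q) or self.rn.shape != (p, q):
            raise ValueError("table shape does not match the axes")
        for name, ax in (("mu_a_axis", self.mu_a_axis), ("mu_s_axis", self.mu_s_axis)):
            if np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if not (np.all(np.isfinite(self.r0)) and np.all(np.isfinite(self.rn))):
            raise ValueError("table values must be finite")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("mu_a_axis", "mu_s_axis", "r0", "rn"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["fx_n"] = self.fx_n
            f.attrs["provenance"] = self.provenance

    @classmethod
    def from_hdf5(cls, path) -> "ForwardLUT":
        with h5py.File(path, "r") as f:
            return cls(
                mu_a_axis=f["mu_a_axis"][...],
                mu_s_axis=f["mu_s_axis"][...],
                r0=f["r0"][...],
                rn=f["rn"][...],
                fx_n=float(f.attrs["fx_n"]),
                provenance=str(f.attrs["provenance"]),
            )


def build_forward_lut(
    p: int,
    q: int,
    forward,
    fx_n: float | None = None,
    mu_a_range=MU_A_RANGE,
    mu_s_range=MU_SP_RANGE,
) -> ForwardLUT:
    """Evaluate the forward model on a uniform p x q property grid."""
    if p < 2 or q < 2:
        raise ValueError("grid sizes must be >= 2")
    fx_n = float(getattr(forward, "fx_n", fx_n) if fx_n is None else fx_n)
    mu_a_axis = np.linspace(mu_a_range[0], mu_a_range[1], p)
    mu_s_axis = np.linspace(mu_s_range[0], mu_s_range[1], q)
    aa, ss = np.meshgrid(mu_a_axis, mu_s_axis, indexing="ij")
    r0, rn = forward.reflectance_pairs(aa.ravel(), ss.ravel())
    r0 = r0.reshape(p, q)
    rn = rn.reshape(p, q)
    bad = ~(np.isfinite(r0) & np.isfinite(rn))
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise RuntimeError(
            "forward model failed at node "
            f"(mu_a={mu_a_axis[i]:.6g}, mu_s'={mu_s_axis[j]:.6g})"
        )
    return ForwardLUT(
        mu_a_axis=mu_a_axis,
        mu_s_axis=mu_s_axis,
        r0=r0,
        rn=rn,
        fx_n=fx_n,
        provenance=getattr(forward, "provenance", "unknown"),
    )


# ---------------------------------------------------------------------------
# Inverse bilinear interpolation on the forward-mapped grid
# ---------------------------------------------------------------------------


@njit(cache=True)
def _lut_walk(r0g, rng_, q0, qn, seed_i, seed_j, max_steps):
    """Locate and bilinearly invert the forward-image cell of each query.

    Returns local coordinates (cell index i, j and fractional a, b) plus a
    flag: 0 = interior cell found, 1 = query outside the mapped manifold
    (coordinates clamped to the nearest boundary cell).
    """
    n_q = q0.size
    p, q = r0g.shape
    out_i = np.empty(n_q, np.int64)
    out_j = np.empty(n_q, np.int64)
    out_a = np.empty(n_q)
    out_b = np.empty(n_q)
    out_flag = np.zeros(n_q, np.uint8)
    for k in range(n_q):
        i = seed_i[k]
        j = seed_j[k]
        t0 = q0[k]
        tn = qn[k]
        a = 0.5
        b = 0.5
        found = False
        for _ in range(max_steps):
            f00_0 = r0g[i, j]
            f10_0 = r0g[i + 1, j]
            f01_0 = r0g[i, j + 1]
            f11_0 = r0g[i + 1, j + 1]
            f00_n = rng_[i, j]
            f10_n = rng_[i + 1, j]
            f01_n = rng_[i, j + 1]
            f11_n = rng_[i + 1, j + 1]
            # Newton iterations for the inverse bilinear coordinates
            a = 0.5
            b = 0.5
            for _ in range(25):
                w00 = (1.0 - a) * (1.0 - b)
                w10 = a * (1.0 - b)
                w01 = (1.0 - a) * b
                w11 = a * b
                g0 = w00 * f00_0 + w10 * f10_0 + w01 * f01_0 + w11 * f11_0 - t0
                gn = w00 * f00_n + w10 * f10_n + w01 * f01_n + w11 * f11_n - tn
                da_0 = (1.0 - b) * (f10_0 - f00_0) + b * (f11_0 - f01_0)
                db_0 = (1.0 - a) * (f01_0 - f00_0) + a * (f11_0 - f10_0)
                da_n = (1.0 - b) * (f10_n - f00_n) + b * (f11_n - f01_n)
                db_n = (1.0 - a) * (f01_n - f00_n) + a * (f11_n - f10_n)
                det = da_0 * db_n - db_0 * da_n
                if det == 0.0:
                    break
                step_a = (g0 * db_n - gn * db_0) / det
                step_b = (da_0 * gn - da_n * g0) / det
                a -= step_a
                b -= step_b
                # keep Newton from running away inside a single cell solve
                if a < -50.0:
                    a = -50.0
                elif a > 51.0:
                    a = 51.0
                if b < -50.0:
                    b = -50.0
                elif b > 51.0:
                    b = 51.0
                if abs(step_a) < 1e-13 and abs(step_b) < 1e-13:
                    break
            tol = 1e-9
            inside_a = -tol <= a <= 1.0 + tol
            inside_b = -tol <= b <= 1.0 + tol
            if inside_a and inside_b:
                found = True
                break
            # move to the cell suggested by the local coordinates
            ni = i + int(np.floor(a)) if not inside_a else i
            nj = j + int(np.floor(b)) if not inside_b else j
            if ni < 0:
                ni = 0
            elif ni > p - 2:
                ni = p - 2
            if nj < 0:
                nj = 0
            elif nj > q - 2:
                nj = q - 2
            if ni == i and nj == j:
                # pressed against the manifold boundary: no containing cell
                break
            i = ni
            j = nj
        if not found:
            out_flag[k] = 1
        if a < 0.0:
            a = 0.0
        elif a > 1.0:
            a = 1.0
        if b < 0.0:
            b = 0.0
        elif b > 1.0:
            b = 1.0
        # snap to exact node hits
        if a < 1e-9:
            a = 0.0
        elif a > 1.0 - 1e-9:
            a = 1.0
        if b < 1e-9:
            b = 0.0
        elif b > 1.0 - 1e-9:
            b = 1.0
        out_i[k] = i
        out_j[k] = j
        out_a[k] = a
        out_b[k] = b
    return out_i, out_j, out_a, out_b, out_flag


class _LutIndex:
    """Cached nearest-node seeder for a LUT (log-reflectance KD-tree)."""

    def __init__(self, lut: ForwardLUT):
        self.lut = lut
        p, q = lut.r0.shape
        pts = np.column_stack(
            [
                np.log(np.maximum(lut.r0.ravel(), 1e-300)),
                np.log(np.maximum(lut.rn.ravel(), 1e-300)),
            ]
        )
        self.tree = cKDTree(pts)
        self.shape = (p, q)

    def seed(self, q0, qn):
        pts = np.column_stack(
            [
                np.log(np.maximum(q0, 1e-300)),
                np.log(np.maximum(qn, 1e-300)),
            ]
        )
        _, idx = self.tree.query(pts, workers=1)
        p, q = self.shape
        i = np.minimum(idx // q, p - 2).astype(np.int64)
        j = np.minimum(idx % q, q - 2).astype(np.int64)
        return i, j


_lut_index_cache: dict[int, _LutIndex] = {}


def _lut_seeder(lut: ForwardLUT) -> _LutIndex:
    key = id(lut)
    entry = _lut_index_cache.get(key)
    if entry is None or entry.lut is not lut:
        _lut_index_cache.clear()
        entry = _LutIndex(lut)
        _lut_index_cache[key] = entry
    return entry


def lut_invert(lut: ForwardLUT, r0_map, rn_map) -> PropertyMaps:
    """Invert reflectance maps through the forward LUT.

    Inverse bilinear interpolation on the (R0, Rn) manifold: each query is
    located in the forward image of a grid cell (cell walk from a
    nearest-node seed) and the cell's bilinear map is inverted.  Queries
    outside the mapped manifold get the nearest boundary answer plus an
    out-of-domain flag; non-finite queries are flagged invalid.
    """
    r0_map = np.asarray(r0_map, float)
    rn_map = np.asarray(rn_map, float)
    if r0_map.shape != rn_map.shape:
        raise ValueError("R0 and Rn maps must share a shape")
    shape = r0_map.shape
    q0 = r0_map.ravel()
    qn = rn_map.ravel()
    status = np.full(q0.shape, STATUS_OK, dtype=np.uint8)
    mu_a = np.full(q0.shape, np.nan)
    mu_sp = np.full(q0.shape, np.nan)
    finite = np.isfinite(q0) & np.isfinite(qn)
    status[~finite] = STATUS_INVALID
    if np.any(finite):
        seeder = _lut_seeder(lut)
        si, sj = seeder.seed(q0[finite], qn[finite])
        p, q = lut.r0.shape
        i, j, a, b, flag = _lut_walk(
            lut.r0, lut.rn, q0[finite], qn[finite], si, sj, 4 * (p + q)
        )
        ha = np.diff(lut.mu_a_axis)
        hs = np.diff(lut.mu_s_axis)
        mu_a[finite] = lut.mu_a_axis[i] + a * ha[i]
        mu_sp[finite] = lut.mu_s_axis[j] + b * hs[j]
        sub = status[finite]
        sub[flag == 1] = STATUS_OUT_OF_DOMAIN
        status[finite] = sub
    return PropertyMaps(
        mu_a=mu_a.reshape(shape),
        mu_s_prime=mu_sp.reshape(shape),
        status=status.reshape(shape),
    )


# ---------------------------------------------------------------------------
# Training sets and the ensemble regressor
# ---------------------------------------------------------------------------


@dataclass
class TrainingSet:
    """Uniformly sampled property pairs with their forward reflectances."""

    r0: np.ndarray
    rn: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    mu_a_range: tuple = MU_A_RANGE
    mu_s_range: tuple = MU_SP_RANGE
    rng_seed: int = 0
    provenance: str = "unknown"

    @property
    def n(self) -> int:
        return self.r0.size

    @property
    def inputs(self) -> np.ndarray:
        return np.column_stack([self.r0, self.rn])

    @property
    def targets(self) -> np.ndarray:
        return np.column_stack([self.mu_a, self.mu_s_prime])

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            r0=self.r0,
            rn=self.rn,
            mu_a=self.mu_a,
            mu_s_prime=self.mu_s_prime,
            mu_a_range=np.asarray(self.mu_a_range),
            mu_s_range=np.asarray(self.mu_s_range),
            rng_seed=self.rng_seed,
            provenance=np.bytes_(self.provenance.encode()),
        )

    @classmethod
    def load(cls, path) -> "TrainingSet":
        with np.load(path) as z:
            return cls(
                r0=z["r0"],
                rn=z["rn"],
                mu_a=z["mu_a"],
                mu_s_prime=z["mu_s_prime"],
                mu_a_range=tuple(z["mu_a_range"]),
                mu_s_range=tuple(z["mu_s_range"]),
                rng_seed=int(z["rng_seed"]),
                provenance=bytes(z["provenance"]).decode(),
            )


def generate_training_set(
    n: int,
    seed: int,
    forward,
    fx_n: float | None = None,
    mu_a_range=MU_A_RANGE,
    mu_s_range=MU_SP_RANGE,
) -> TrainingSet:
    """Draw ``n`` property pairs uniformly and attach forward reflectances.

    Reproducible bit-for-bit at a fixed seed (PCG64 stream).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu_a = rng.uniform(mu_a_range[0], mu_a_range[1], n)
    mu_sp = rng.uniform(mu_s_range[0], mu_s_range[1], n)
    r0, rn = forward.reflectance_pairs(mu_a, mu_sp)
    return TrainingSet(
        r0=r0,
        rn=rn,
        mu_a=mu_a,
        mu_s_prime=mu_sp,
        mu_a_range=tuple(mu_a_range),
        mu_s_range=tuple(mu_s_range),
        rng_seed=seed,
        provenance=getattr(forward, "provenance", "unknown"),
    )


@dataclass
class InversionModel:
    """Trained multi-output ensemble mapping (R0, Rn) -> (mu_a, mu_s')."""

    estimator: RandomForestRegressor
    n_estimators: int
    min_samples_leaf: int
    rng_seed: int
    training_provenance: dict = field(default_factory=dict)
    mu_a_range: tuple = MU_A_RANGE
    mu_s_range: tuple = MU_SP_RANGE

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": _MODEL_FORMAT_VERSION,
                "estimator": self.estimator,
                "n_estimators": self.n_estimators,
                "min_samples_leaf": self.min_samples_leaf,
                "rng_seed": self.rng_seed,
                "training_provenance": self.training_provenance,
                "mu_a_range": self.mu_a_range,
                "mu_s_range": self.mu_s_range,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "InversionModel":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != _MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {version!r} "
                f"(expected {_MODEL_FORMAT_VERSION})"
            )
        payload = dict(payload)
        payload.pop("format_version")
        return cls(**payload)


def train_regressor(
    ts: TrainingSet,
    n_estimators: int = 15,
    min_samples_leaf: int = 2,
    seed: int = 0,
) -> InversionModel:
    """Fit the random-forest inverse map on a training set.

    Hyperparameter defaults (15 trees, minimum 2 samples per leaf) follow
    the two-frequency SFDI regression setup; training is single-threaded
    and reproducible at a fixed seed.
    """
    if ts.n < 1:
        raise ValueError("training set is empty")
    inputs = ts.inputs
    targets = ts.targets
    constant_inputs = np.all(inputs == inputs[0], axis=None)
    if constant_inputs and not np.all(targets == targets[0]):
        raise ValueError(
            "degenerate training set: constant reflectance inputs with "
            "varying targets cannot define an inverse map"
        )
    est = RandomForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(inputs, targets)
    return InversionModel(
        estimator=est,
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        rng_seed=seed,
        training_provenance={
            "n": ts.n,
            "training_seed": ts.rng_seed,
            "forward": ts.provenance,
        },
        mu_a_range=ts.mu_a_range,
        mu_s_range=ts.mu_s_range,
    )


def predict_properties(model: InversionModel, r0_map, rn_map) -> PropertyMaps:
    """Vectorised per-pixel prediction of optical-property maps."""
    r0_map = np.asarray(r0_map, float)
    rn_map = np.asarray(rn_map, float)
    if r0_map.shape != rn_map.shape:
        raise ValueError("R0 and Rn maps must share a shape")
    shape = r0_map.shape
    q0 = r0_map.ravel()
    qn = rn_map.ravel()
    status = np.full(q0.shape, STATUS_OK, dtype=np.uint8)
    mu_a = np.full(q0.shape, np.nan)
    mu_sp = np.full(q0.shape, np.nan)
    finite = np.isfinite(q0) & np.isfinite(qn)
    status[~finite] = STATUS_INVALID
    if np.any(finite):
        pred = model.estimator.predict(np.column_stack([q0[finite], qn[finite]]))
        mu_a[finite] = pred[:, 0]
        mu_sp[finite] = pred[:, 1]
    return PropertyMaps(
        mu_a=mu_a.reshape(shape),
        mu_s_prime=mu_sp.reshape(shape),
        status=status.reshape(shape),
    )


# ---------------------------------------------------------------------------
# Error metrics and the method benchmark
# ---------------------------------------------------------------------------


def _as_pair(x):
    if isinstance(x, PropertyMaps):
        return x.mu_a, x.mu_s_prime
    return np.asarray(x[0], float), np.asarray(x[1], float)


def mean_relative_error(pred, truth, mu_a_floor: float = MU_A_ERROR_FLOOR) -> dict:
    """Mean of |pred - truth| / truth * 100, per parameter.

    ``pred`` and ``truth`` are :class:`PropertyMaps` or ``(mu_a, mu_s')``
    array pairs.  True mu_a below ``mu_a_floor`` is excluded from the mu_a
    metric; the excluded fraction is reported as ``mu_a_excluded_fraction``.
    """
    pa, ps = _as_pair(pred)
    ta, ts = _as_pair(truth)
    if pa.shape != ta.shape or ps.shape != ts.shape:
        raise ValueError("prediction and truth shapes must match")
    eval_a = ta >= mu_a_floor
    eval_s = ts > 0.0
    if not (np.any(eval_a) and np.any(eval_s)):
        raise ValueError("no evaluable samples above the truth floors")
    err_a = np.abs(pa[eval_a] - ta[eval_a]) / ta[eval_a] * 100.0
    err_s = np.abs(ps[eval_s] - ts[eval_s]) / ts[eval_s] * 100.0
    return {
        "mu_a_pct": float(np.mean(err_a)),
        "mu_s_prime_pct": float(np.mean(err_s)),
        "mu_a_excluded_fraction": float(1.0 - np.mean(eval_a)),
        "n_mu_a": int(eval_a.sum()),
        "n_mu_s_prime": int(eval_s.sum()),
    }


def benchmark_methods(test: TrainingSet, methods: dict, mu_a_floor: float = MU_A_ERROR_FLOOR):
    """Per-parameter mean relative errors of each inversion method.

    ``methods`` maps a name to a callable ``(r0, rn) -> PropertyMaps``.
    Returns a list of rows (dicts) suitable for CSV/JSON serialisation.
    """
    rows = []
    truth = (test.mu_a, test.mu_s_prime)
    for name, invert in methods.items():
        maps = invert(test.r0, test.rn)
        metrics = mean_relative_error(maps, truth, mu_a_floor=mu_a_floor)
        rows.append({"method": name, **metrics})
    return rows
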