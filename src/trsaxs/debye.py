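"""Theoretical SAXS curves from Calpha conformers via the Debye formula.

    I(q) = f(q)^2 * [N + 2 sum_{i<j} sin(q r_ij) / (q r_ij)]

with identical per-residue form factors f. The exact double sum is O(N^2)
per q point; the histogram path bins the pair distances once (O(N^2)) and
evaluates I(q) from bin counts, which is what makes a 10,000-chain pool
tractable on one CPU.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .io import ScatteringProfile
from .pool import Conformer, ConformerPool

# log-spaced: low-q density supports Guinier windows up to Rg ~ 100 A while
# still covering the fractal window (0.04-0.1) and the Kratky tail
DEFAULT_Q_GRID = np.geomspace(0.005, 0.5, 101)  # 1/A
DEFAULT_BIN_WIDTH = 0.5                          # A
THEORY_SIGMA = 1e-6  # nominal positive sigma for theoretical curves


@dataclass(frozen=True)
class FormFactorModel:
    """Per-residue form factor. ``point``: f = 1. ``gaussian-dummy``:
    f(q) = exp(-q^2 w^2 / 2), mimicking residue-level density falloff."""

    kind: str = "point"
    width: float = 3.0

    def __post_init__(self):
        if self.kind not in ("point", "gaussian-dummy"):
            raise ValueError(f"unknown form factor kind {self.kind!r}")

    def __call__(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if self.kind == "point":
            return np.ones_like(q)
        return np.exp(-(q**2) * self.width**2 / 2.0)


def debye_intensity(
    coords: np.ndarray,
    q_grid: np.ndarray,
    ff: FormFactorModel = FormFactorModel(),
    method: str = "exact",
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> np.ndarray:
    """Orientation-averaged intensity of one conformer on ``q_grid``."""
    q = np.asarray(q_grid, dtype=float)
    n = len(coords)
    f2 = ff(q) ** 2
    if n == 1:
        return f2 * 1.0
    r = pdist(coords)
    if method == "exact":
        # sinc(q r / pi) = sin(q r)/(q r), with the q->0 limit built in
        s = np.sinc(np.outer(q, r) / np.pi).sum(axis=1)
    elif method == "histogram":
        edges = np.arange(0.0, r.max() + bin_width, bin_width)
        counts, _ = np.histogram(r, bins=edges)
        sum_r, _ = np.histogram(r, bins=edges, weights=r)
        sum_r2, _ = np.histogram(r, bins=edges, weights=r**2)
        nz = counts > 0
        # per-bin mean distance makes the quadrature first-order exact; the
        # per-bin variance term restores second order, keeping 0.5 A bins
        # accurate well below 0.3% up to q = 0.5 1/A
        r_eff = sum_r[nz] / counts[nz]
        var = np.maximum(sum_r2[nz] / counts[nz] - r_eff**2, 0.0)
        x = np.outer(q, r_eff)
        sinc = np.sinc(x / np.pi)
        # d^2/dr^2 sinc(qr) = q^2 * ((2 - x^2) sin x - 2 x cos x) / x^3
        with np.errstate(divide="ignore", invalid="ignore"):
            g = ((2.0 - x**2) * np.sin(x) - 2.0 * x * np.cos(x)) / x**3
        g = np.where(x < 1e-4, -1.0 / 3.0, g)
        corr = sinc + 0.5 * (q**2)[:, None] * g * var[None, :]
        s = corr @ counts[nz]
    else:
        raise ValueError(f"unknown method {method!r}")
    return f2 * (n + 2.0 * s)


def debye_profile(
    conformer: Conformer,
    q_grid: np.ndarray = DEFAULT_Q_GRID,
    ff: FormFactorModel = FormFactorModel(),
    method: str = "exact",
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> ScatteringProfile:
    """Theoretical curve for a single conformer (sigma nominal, not used)."""
    I = debye_intensity(conformer.coords, q_grid, ff, method, bin_width)
    return ScatteringProfile(
        np.asarray(q_grid, dtype=float), I,
        np.full(len(q_grid), THEORY_SIGMA),
        label=f"debye:{conformer.id}",
    )


def _cache_key(pool_seed, q_grid, ff, method, bin_width, n) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(q_grid, dtype=float).tobytes())
    h.update(f"{pool_seed}|{ff.kind}|{ff.width}|{method}|{bin_width}|{n}".encode())
    return h.hexdigest()[:16]


def pool_profiles(
    pool: ConformerPool,
    q_grid: np.ndarray = DEFAULT_Q_GRID,
    ff: FormFactorModel = FormFactorModel(),
    method: str | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    cache_dir=None,
) -> np.ndarray:
    """Profile matrix (n_conformers x n_q), rows in pool order.

    ``method`` defaults to "histogram" for pools of >= 1000 conformers and
    "exact" below. With ``cache_dir`` set, the matrix is persisted as .npy
    with a JSON sidecar keyed by (pool seed, q grid, form factor, method);
    a corrupt cache entry triggers recomputation with a warning.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if method is None:
        method = "histogram" if len(pool) >= 1000 else "exact"
    q = np.asarray(q_grid, dtype=float)
    key = _cache_key(pool.seed, q, ff, method, bin_width, len(pool))
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        npy, meta = cache_dir / f"profiles-{key}.npy", cache_dir / f"profiles-{key}.json"
        if npy.exists() and meta.exists():
            try:
                mat = np.load(npy)
                info = json.loads(meta.read_text())
                if mat.shape == (len(pool), len(q)) and info.get("key") == key:
                    return mat
            except Exception:
                import warnings

                warnings.warn("corrupt profile cache; recomputing")
    mat = np.empty((len(pool), len(q)))
    for k, c in enumerate(pool.conformers):
        mat[k] = debye_intensity(c.coords, q, ff, method, bin_width)
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        np.save(npy, mat)
        meta.write_text(json.dumps({
            "key": key, "pool_seed": pool.seed, "method": method,
            "ff": {"kind": ff.kind, "width": ff.width},
            "bin_width": bin_width, "shape": list(mat.shape),
        }))
    return mat
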