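"""Random pools of self-avoiding coarse-grained Calpha chains.

Conformers model a 140-residue disordered protein as a virtual-bond chain:
fixed 3.8 A Calpha-Calpha bonds, pseudo-bond angles drawn uniformly from a
regime-specific range, uniform dihedrals, and hard-sphere excluded volume
between non-adjacent residues. A pool mixes flexible / intermediate / stiff
regimes so its Rg distribution spans compact (~20-35 A) through extended
(>55 A) conformations, matching the two populations an ensemble fit must be
able to select between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

BOND_LENGTH = 3.8        # A, virtual Calpha-Calpha bond
EV_CUTOFF = 3.8          # A, hard-sphere cutoff between non-adjacent Calpha
N_RES_DEFAULT = 140

#: pseudo-bond angle ranges (deg, vertex angle; 180 = straight) per regime
STIFFNESS_REGIMES = {
    "flexible": (65.0, 145.0),
    "intermediate": (90.0, 160.0),
    "stiff": (120.0, 175.0),
}
DEFAULT_REGIME_WEIGHTS = {"flexible": 0.5, "intermediate": 0.3, "stiff": 0.2}


class ChainGenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class DomainScheme:
    """Named 1-based inclusive residue pairs for domain-distance analysis.

    Defaults follow the alpha-synuclein convention: NTD 1-60, NAC 61-90,
    CTD 91-140, plus the end-to-end and inter-domain pairs.
    """

    pairs: dict = field(
        default_factory=lambda: {
            "ree": (1, 140),
            "ntd_internal": (1, 60),
            "nac_internal": (61, 90),
            "ctd_internal": (91, 140),
            "ntd_nac": (1, 90),
            "nac_ctd": (61, 140),
        }
    )

    def validate(self, n_res: int) -> None:
        for name, (a, b) in self.pairs.items():
            if not (1 <= a <= n_res and 1 <= b <= n_res):
                raise ValueError(f"pair {name} = ({a}, {b}) outside [1, {n_res}]")


@dataclass(frozen=True)
class Conformer:
    """A single Calpha trace."""

    coords: np.ndarray   # (n_res, 3), Angstrom
    id: int = 0

    @property
    def n_res(self) -> int:
        return len(self.coords)


@njit(cache=True)
def _build_chain(n_res, seed, amin_deg, amax_deg, bond, ev_cut,
                 max_retries, max_restarts):  # pragma: no cover - numba
    np.random.seed(seed)
    amin = amin_deg * np.pi / 180.0
    amax = amax_deg * np.pi / 180.0
    ev2 = ev_cut * ev_cut
    coords = np.zeros((n_res, 3))
    for _restart in range(max_restarts):
        coords[0, 0] = 0.0
        coords[0, 1] = 0.0
        coords[0, 2] = 0.0
        coords[1, 0] = bond
        coords[1, 1] = 0.0
        coords[1, 2] = 0.0
        ok_chain = True
        i = 2
        while i < n_res:
            placed = False
            for _try in range(max_retries):
                theta = amin + (amax - amin) * np.random.random()
                phi = -np.pi + 2.0 * np.pi * np.random.random()
                # frame at atom i-1: previous bond direction and a normal
                bx = coords[i - 1, 0] - coords[i - 2, 0]
                by = coords[i - 1, 1] - coords[i - 2, 1]
                bz = coords[i - 1, 2] - coords[i - 2, 2]
                bn = np.sqrt(bx * bx + by * by + bz * bz)
                bx /= bn; by /= bn; bz /= bn
                if i == 2:
                    ax, ay, az = 0.0, 1.0, 0.0
                else:
                    ax = coords[i - 2, 0] - coords[i - 3, 0]
                    ay = coords[i - 2, 1] - coords[i - 3, 1]
                    az = coords[i - 2, 2] - coords[i - 3, 2]
                # n = b x a, normal to the previous-bond plane
                nx = by * az - bz * ay
                ny = bz * ax - bx * az
                nz = bx * ay - by * ax
                nn = np.sqrt(nx * nx + ny * ny + nz * nz)
                if nn < 1e-10:
                    ax, ay, az = 0.0, 0.0, 1.0
                    nx = by * az - bz * ay
                    ny = bz * ax - bx * az
                    nz = bx * ay - by * ax
                    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
                nx /= nn; ny /= nn; nz /= nn
                # m = n x b completes the right-handed frame
                mx = ny * bz - nz * by
                my = nz * bx - nx * bz
                mz = nx * by - ny * bx
                # local displacement: vertex angle theta at atom i-1
                ct = np.cos(np.pi - theta)  # angle between bond vectors
                st = np.sin(np.pi - theta)
                dx = bond * ct
                dm = bond * st * np.cos(phi)
                dn = bond * st * np.sin(phi)
                px = coords[i - 1, 0] + dx * bx + dm * mx + dn * nx
                py = coords[i - 1, 1] + dx * by + dm * my + dn * ny
                pz = coords[i - 1, 2] + dx * bz + dm * mz + dn * nz
                clash = False
                for j in range(i - 1):
                    rx = px - coords[j, 0]
                    ry = py - coords[j, 1]
                    rz = pz - coords[j, 2]
                    if rx * rx + ry * ry + rz * rz < ev2:
                        clash = True
                        break
                if not clash:
                    coords[i, 0] = px
                    coords[i, 1] = py
                    coords[i, 2] = pz
                    placed = True
                    break
            if not placed:
                ok_chain = False
                break
            i += 1
        if ok_chain:
            return coords, 0
    return coords, 1


def generate_chain(
    n_res: int = N_RES_DEFAULT,
    seed: int = 0,
    angle_range: tuple = STIFFNESS_REGIMES["flexible"],
    bond_length: float = BOND_LENGTH,
    ev_cutoff: float = EV_CUTOFF,
    max_retries: int = 50,
    max_restarts: int = 100,
    conformer_id: int = 0,
) -> Conformer:
    """Grow one self-avoiding chain, deterministically for a given seed."""
    if n_res < 3:
        raise ValueError("n_res must be >= 3")
    coords, fail = _build_chain(
        n_res, int(seed) % (2**31), float(angle_range[0]), float(angle_range[1]),
        float(bond_length), float(ev_cutoff), int(max_retries), int(max_restarts),
    )
    if fail:
        raise ChainGenerationError(
            f"restart budget exhausted (n_res={n_res}, angles={angle_range}, "
            f"ev={ev_cutoff})"
        )
    return Conformer(coords.copy(), id=conformer_id)


def radius_of_gyration(coords: np.ndarray) -> float:
    """Unit-mass Rg of a coordinate set."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(c**2, axis=1))))


def chain_metrics(conformer: Conformer, scheme: DomainScheme | None = None) -> dict:
    """Per-conformer geometry row: rg, ree, and the scheme's pair distances."""
    scheme = scheme or DomainScheme()
    scheme.validate(conformer.n_res)
    row = {"id": conformer.id, "rg": radius_of_gyration(conformer.coords)}
    for name, (a, b) in scheme.pairs.items():
        d = float(np.linalg.norm(conformer.coords[a - 1] - conformer.coords[b - 1]))
        row[name] = d
    return row


@dataclass
class ConformerPool:
    """A pool of conformers with their metrics table.

    ``metrics`` has one row per conformer, columns ``id, rg, ree`` and the
    six domain-pair distances, all in Angstrom.
    """

    conformers: list
    metrics: pd.DataFrame
    seed: int
    settings: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def rg(self) -> np.ndarray:
        return self.metrics["rg"].to_numpy()

    def subpool_indices(self, compact_below: float = 35.0, extended_above: float = 45.0):
        """(compact_idx, extended_idx) by Rg cutoffs."""
        rg = self.rg
        return np.flatnonzero(rg < compact_below), np.flatnonzero(rg > extended_above)


def generate_pool(
    n: int,
    n_res: int = N_RES_DEFAULT,
    seed: int = 0,
    regime_weights: dict | None = None,
    scheme: DomainScheme | None = None,
    **chain_kw,
) -> ConformerPool:
    """Draw ``n`` chains from the stiffness mixture and tabulate metrics.

    Fully reproducible from (seed, settings): regimes and per-chain seeds
    derive from one seeded generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = regime_weights or DEFAULT_REGIME_WEIGHTS
    names = sorted(weights)
    w = np.array([weights[k] for k in names], dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    regime_idx = rng.choice(len(names), size=n, p=w)
    chain_seeds = rng.integers(0, 2**31 - 1, size=n)
    scheme = scheme or DomainScheme()
    conformers, rows = [], []
    for k in range(n):
        regime = names[regime_idx[k]]
        c = generate_chain(
            n_res=n_res, seed=int(chain_seeds[k]),
            angle_range=STIFFNESS_REGIMES[regime],
            conformer_id=k, **chain_kw,
        )
        conformers.append(c)
        row = chain_metrics(c, scheme)
        row["regime"] = regime
        rows.append(row)
    metrics = pd.DataFrame(rows)
    settings = {
        "n": n, "n_res": n_res, "regime_weights": dict(weights),
        "scheme": dict(scheme.pairs), **chain_kw,
    }
    return ConformerPool(conformers, metrics, seed=int(seed), settings=settings)


def write_pool_pdb(pool_or_conformers, dest) -> None:
    """Multi-model Calpha-only PDB (ATOM records, 1-based residue numbering)."""
    conformers = getattr(pool_or_conformers, "conformers", pool_or_conformers)
    lines = []
    for m, c in enumerate(conformers, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (x, y, z) in enumerate(c.coords, start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        from pathlib import Path

        Path(dest).write_text(text)


def read_pool_pdb(source) -> list:
    """Read Calpha coordinates back from a (multi-model) PDB file."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        from pathlib import Path

        lines = Path(source).read_text().splitlines()
    models, cur = [], []
    for line in lines:
        if line.startswith("ATOM") and line[12:16].strip() == "CA":
            cur.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        elif line.startswith("ENDMDL") and cur:
            models.append(np.asarray(cur))
            cur = []
    if cur:
        models.append(np.asarray(cur))
    return [Conformer(m, id=k) for k, m in enumerate(models)]
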