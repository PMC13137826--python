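"""Ground-truth-labelled synthetic TR-SAXS time series.

The forward model mirrors the structure the analysis assumes: a monomeric
140-residue disordered chain whose ensemble mixes a compact population
(Rg below ~35 A) and an extended population (Rg above ~45 A). At each time
point a finite 50-member ensemble is drawn with extended probability f(t)
(exponential relaxation f(t) = f_inf + (f0 - f_inf) e^{-k t}), its average
Debye curve is scaled by the dilution c(t), and counting-statistics noise is
added. Matched buffer frames (noise around zero) exercise the subtraction
stage. Every draw is recorded, so recovery can be scored against both the
nominal f(t) and the realized finite-sample fraction.

The dilution follows c(t) = c_inf + (1 - c_inf) e^{-(t - t_lag)/tau} with a
short diffusion lag (c = 1 for t <= t_lag): the protein leaves the focused
center stream only after the side buffer has diffused in, so the earliest
frames still see the undiluted concentration and the first-frame-normalized
I(0) trace decays to ~c_inf, the protein inlet's flow share (~1/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .debye import DEFAULT_Q_GRID, FormFactorModel, pool_profiles
from .io import ScatteringProfile, TimeSeries
from .pool import ConformerPool

TIME_STEP = 0.18           # s
TIME_END = 3.64            # s
COMPACT_BELOW = 35.0       # A
EXTENDED_ABOVE = 45.0      # A


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticScenario:
    """All parameters of one synthetic study condition (the ground truth)."""

    preset: str
    f0: float                  # initial extended fraction
    f_inf: float               # asymptotic extended fraction
    k: float                   # 1/s, relaxation rate of f(t)
    c_inf: float = 1.0 / 3.0   # dilution plateau (protein inlet flow share)
    tau: float = 0.8           # s, dilution time constant
    t_lag: float = 0.4         # s, diffusion lag before dilution reaches the center
    times: np.ndarray = field(
        default_factory=lambda: np.round(
            np.arange(TIME_STEP, TIME_END + 1e-9, TIME_STEP), 10
        )
    )
    ensemble_size: int = 50
    noise_at_i0: float = 0.01  # relative sigma at the forward intensity
    compact_below: float = COMPACT_BELOW
    extended_above: float = EXTENDED_ABOVE
    draw_seed: int = 0         # ensemble draws (the ground truth)
    noise_seed: int = 1        # measurement noise only

    def __post_init__(self):
        f = self.extended_fraction(self.times)
        if np.any((f < 0) | (f > 1)):
            raise ScenarioError("f(t) must stay within [0, 1]")
        c = self.dilution(self.times)
        if np.any((c <= 0) | (c > 1)):
            raise ScenarioError("c(t) must stay within (0, 1]")
        if np.any(np.diff(self.times) <= 0):
            raise ScenarioError("time grid must be increasing")

    def __eq__(self, other):
        if not isinstance(other, SyntheticScenario):
            return NotImplemented
        for f in self.__dataclass_fields__:
            a, b = getattr(self, f), getattr(other, f)
            if isinstance(a, np.ndarray):
                if not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True

    def extended_fraction(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.f_inf + (self.f0 - self.f_inf) * np.exp(-self.k * t)

    def dilution(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.where(
            t <= self.t_lag,
            1.0,
            self.c_inf + (1.0 - self.c_inf) * np.exp(-(t - self.t_lag) / self.tau),
        )


PRESETS = {
    # rapid loss of the extended population (strong, fast compaction)
    "fe-like": dict(f0=0.60, f_inf=0.0, k=2.0),
    # persistent elongation: high starting fraction relaxing only partly
    "cu-like": dict(f0=0.70, f_inf=0.40, k=0.8),
    # moderate compaction over the observation window
    "wt-like": dict(f0=0.50, f_inf=0.15, k=1.0),
    # no conformational kinetics; only dilution
    "inert": dict(f0=0.35, f_inf=0.35, k=0.0),
}


def make_scenario(preset: str, seed: int = 0, **overrides) -> SyntheticScenario:
    """Build a preset scenario; identical arguments give identical scenarios."""
    if preset not in PRESETS:
        raise ScenarioError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[preset])
    params.update(overrides)
    return SyntheticScenario(
        preset=preset, draw_seed=int(seed), noise_seed=int(seed) + 1, **params
    )


@dataclass
class SimulationResult:
    """Synthetic frames with their buffers and per-frame ground truth."""

    series: TimeSeries          # raw (pre-subtraction) sample frames
    buffers: list               # matched noise-only buffer profiles
    ground_truth: pd.DataFrame  # per-frame truth: f, c, apparent Rg, ...
    multisets: list             # drawn conformer indices per frame
    scenario: SyntheticScenario


def simulate_timeseries(
    scn: SyntheticScenario,
    pool: ConformerPool,
    profiles: np.ndarray | None = None,
    q_grid: np.ndarray = DEFAULT_Q_GRID,
    ff: FormFactorModel = FormFactorModel(),
) -> SimulationResult:
    """Generate one synthetic time series from a conformer pool.

    ``profiles`` may pass a precomputed pool profile matrix (rows in pool
    order) to avoid recomputation across scenarios sharing a pool.
    """
    compact_idx, extended_idx = pool.subpool_indices(
        scn.compact_below, scn.extended_above
    )
    if len(compact_idx) == 0 or len(extended_idx) == 0:
        raise ScenarioError(
            "pool lacks conformers on one side of the Rg cutoffs "
            f"(<{scn.compact_below} A: {len(compact_idx)}, "
            f">{scn.extended_above} A: {len(extended_idx)})"
        )
    if profiles is None:
        profiles = pool_profiles(pool, q_grid, ff)
    q = np.asarray(q_grid, dtype=float)
    draw_rng = np.random.default_rng(scn.draw_seed)
    noise_rng = np.random.default_rng(scn.noise_seed)
    f_t = scn.extended_fraction(scn.times)
    c_t = scn.dilution(scn.times)
    rg = pool.rg
    ree = pool.metrics["ree"].to_numpy()

    frames, buffers, rows, multisets = [], [], [], []
    for j, t in enumerate(scn.times):
        is_ext = draw_rng.random(scn.ensemble_size) < f_t[j]
        members = np.where(
            is_ext,
            extended_idx[draw_rng.integers(0, len(extended_idx), scn.ensemble_size)],
            compact_idx[draw_rng.integers(0, len(compact_idx), scn.ensemble_size)],
        )
        model = c_t[j] * profiles[members].mean(axis=0)
        i0 = model[0]
        # counting-statistics-like noise: relative error grows as I falls
        sigma = scn.noise_at_i0 * np.sqrt(np.maximum(model, 1e-12 * i0) * i0)
        sample = model + noise_rng.normal(0.0, sigma)
        buffer_noise = noise_rng.normal(0.0, sigma)
        frames.append(ScatteringProfile(q, sample, sigma, label=f"t={t:.2f}s"))
        buffers.append(
            ScatteringProfile(q, buffer_noise, sigma, label=f"buffer t={t:.2f}s")
        )
        multisets.append(members.copy())
        rg2 = rg[members] ** 2
        rows.append({
            "time_s": float(t),
            "f_nominal": float(f_t[j]),
            "f_realized": float(np.mean(is_ext)),
            "c": float(c_t[j]),
            "rg_apparent_A": float(np.sqrt(rg2.mean())),
            "rg_mean_A": float(rg[members].mean()),
            "ree_mean_A": float(ree[members].mean()),
        })
    series = TimeSeries(tuple(frames), scn.times)
    return SimulationResult(
        series=series, buffers=buffers,
        ground_truth=pd.DataFrame(rows), multisets=multisets, scenario=scn,
    )


def write_scenario_dir(sim: SimulationResult, out_dir) -> Path:
    """Write the on-disk layout the CLI pipeline consumes:
    frame_###.dat / buffer_###.dat, ground_truth.csv, scenario.yaml."""
    import yaml

    from .io import write_profile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for j, (frame, buf) in enumerate(zip(sim.series.profiles, sim.buffers)):
        write_profile(frame, out / f"frame_{j:03d}.dat")
        write_profile(buf, out / f"buffer_{j:03d}.dat")
    sim.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    scn = sim.scenario
    meta = {
        "preset": scn.preset, "f0": scn.f0, "f_inf": scn.f_inf, "k": scn.k,
        "c_inf": scn.c_inf, "tau": scn.tau, "t_lag": scn.t_lag,
        "ensemble_size": scn.ensemble_size, "noise_at_i0": scn.noise_at_i0,
        "compact_below": scn.compact_below, "extended_above": scn.extended_above,
        "draw_seed": scn.draw_seed, "noise_seed": scn.noise_seed,
        "times_s": [float(t) for t in scn.times],
    }
    (out / "scenario.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return out


MASS_SPLIT = 0.5 * (COMPACT_BELOW + EXTENDED_ABOVE)


def extended_mass(res_fractions: dict, pool: ConformerPool,
                  split: float = MASS_SPLIT) -> float:
    """Fraction of ensemble weight on the extended side of the Rg axis.

    The default split is the midpoint of the excluded 35-45 A band: planted
    truths contain no conformers there, but a fitted ensemble may, and each
    such conformer is attributed to the nearer population.
    """
    rg = pool.rg
    return float(sum(f for i, f in res_fractions.items() if rg[i] > split))
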