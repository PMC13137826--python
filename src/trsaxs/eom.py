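"""Genetic-algorithm selection of a fixed-size sub-ensemble from a pool.

The model curve of a candidate ensemble is the plain average of its member
profiles; an overall scale and (optionally) a constant background are fitted
in closed form, so the fitness of a chromosome — a multiset of pool indices,
repetition allowed — is the reduced chi^2 of that average against the
experimental curve. Elitism makes the fitness trace non-increasing, and the
initial population is seeded with the best single-conformer ensembles, so
the final chi^2 can never exceed that of the best lone conformer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io import ScatteringProfile
from .pool import ConformerPool


class FitDegenerateError(RuntimeError):
    """Normal equations singular (e.g. constant model curve)."""


@dataclass(frozen=True)
class GASettings:
    """Knobs of the selection GA (defaults mirror standard EOM practice:
    50-member ensembles, 50 ensembles per generation, 1000 generations,
    constant background fitted)."""

    ensemble_size: int = 50
    n_ensembles_per_generation: int = 50
    n_generations: int = 1000
    mutation_rate: float = 0.1
    crossover_rate: float = 0.5
    elite_count: int = 5
    seed: int = 0
    fit_background: bool = True
    stall_generations: int = 100
    stall_tol: float = 1e-4

    def __post_init__(self):
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if not self.elite_count < self.n_ensembles_per_generation:
            raise ValueError("elite_count must be < population size")


@dataclass(frozen=True)
class EnsembleFitResult:
    """Best ensemble found by the GA."""

    multiplicities: dict        # conformer id -> count, counts sum to size
    fractions: dict             # conformer id -> count / ensemble_size
    chi2: float                 # reduced chi^2 of the best ensemble
    scale: float
    background: float
    generations_run: int
    fitness_trace: np.ndarray   # best chi^2 per generation, non-increasing
    ensemble_size: int
    pool_seed: int = -1
    settings: GASettings = field(default=None)

    def weight_vector(self, n_pool: int) -> np.ndarray:
        w = np.zeros(n_pool)
        for idx, frac in self.fractions.items():
            w[idx] = frac
        return w


def chi2_fit(exp: ScatteringProfile, model: np.ndarray, fit_background: bool = True):
    """Closed-form weighted LSQ of I_exp against c*model + b.

    Returns ``(reduced_chi2, c, b)`` with K-2 degrees of freedom when the
    background is fitted, K-1 otherwise.
    """
    chi2, c, b = _chi2_fit_many(
        exp.intensity, exp.sigma, model[None, :], fit_background
    )
    return float(chi2[0]), float(c[0]), float(b[0])


def _chi2_fit_many(I, sigma, models, fit_background):
    """Vectorized chi2_fit over rows of ``models`` (P x K)."""
    w = 1.0 / sigma**2
    K = len(I)
    Sw = w.sum()
    Swi = (w * I).sum()
    Swm = models @ w
    Swmm = (models**2) @ w
    Swmi = models @ (w * I)
    if fit_background:
        denom = Sw * Swmm - Swm**2
        bad = np.abs(denom) < 1e-12 * max(Sw, 1.0) * np.maximum(Swmm, 1e-30)
        if np.all(bad):
            raise FitDegenerateError("constant model: scale/background unidentifiable")
        denom = np.where(bad, np.nan, denom)
        c = (Sw * Swmi - Swm * Swi) / denom
        b = (Swi - c * Swm) / Sw
        dof = max(K - 2, 1)
    else:
        if np.all(Swmm <= 0):
            raise FitDegenerateError("zero model: scale unidentifiable")
        c = Swmi / Swmm
        b = np.zeros_like(c)
        dof = max(K - 1, 1)
    resid2 = ((I[None, :] - c[:, None] * models - b[:, None]) / sigma[None, :]) ** 2
    chi2 = resid2.sum(axis=1) / dof
    chi2 = np.where(np.isfinite(chi2), chi2, np.inf)
    return chi2, c, b


def ga_select(
    exp: ScatteringProfile,
    profiles: np.ndarray,
    settings: GASettings = GASettings(),
    pool_seed: int = -1,
) -> EnsembleFitResult:
    """Select the best multiset of ``ensemble_size`` pool rows for ``exp``.

    Operators: elitism (top ``elite_count`` copied), binary tournament
    selection, per-slot uniform crossover at ``crossover_rate``, per-slot
    random-reset mutation at ``mutation_rate``. Stops early when the best
    chi^2 improves by less than ``stall_tol`` over ``stall_generations``
    consecutive generations. Bit-stable for fixed settings.
    """
    n_pool, n_q = profiles.shape
    S, P = settings.ensemble_size, settings.n_ensembles_per_generation
    if n_pool < 1:
        raise ValueError("empty profile matrix")
    if len(exp) != n_q:
        raise ValueError("experimental curve and profile matrix q grids differ")
    rng = np.random.default_rng(settings.seed)

    # singleton screen: chi2 of every lone conformer (vectorized); used to
    # seed the population so the GA starts no worse than the best single model
    single_chi2, _, _ = _chi2_fit_many(
        exp.intensity, exp.sigma, profiles, settings.fit_background
    )
    order = np.argsort(single_chi2)
    pop = rng.integers(0, n_pool, size=(P, S))
    n_seeded = min(max(P // 10, 1), len(order))
    for k in range(n_seeded):
        pop[k, :] = order[k]

    def evaluate(pop):
        models = profiles[pop].mean(axis=1)
        return _chi2_fit_many(exp.intensity, exp.sigma, models, settings.fit_background)

    trace = []
    best_chrom, best_chi2, best_cb = None, np.inf, (np.nan, np.nan)
    stall = 0
    gen = 0
    for gen in range(1, settings.n_generations + 1):
        chi2, c, b = evaluate(pop)
        idx = np.argsort(chi2)
        if chi2[idx[0]] < best_chi2 - settings.stall_tol:
            stall = 0
        else:
            stall += 1
        if chi2[idx[0]] < best_chi2:
            best_chi2 = float(chi2[idx[0]])
            best_chrom = pop[idx[0]].copy()
            best_cb = (float(c[idx[0]]), float(b[idx[0]]))
        trace.append(best_chi2)
        if stall >= settings.stall_generations:
            break
        # next generation
        new_pop = np.empty_like(pop)
        elite = pop[idx[: settings.elite_count]]
        new_pop[: settings.elite_count] = elite
        n_children = P - settings.elite_count
        # binary tournament: lower chi2 wins
        cand = rng.integers(0, P, size=(2, 2, n_children))
        t1 = np.where(chi2[cand[0, 0]] <= chi2[cand[0, 1]], cand[0, 0], cand[0, 1])
        t2 = np.where(chi2[cand[1, 0]] <= chi2[cand[1, 1]], cand[1, 0], cand[1, 1])
        pa, pb = pop[t1], pop[t2]
        cross = rng.random(size=(n_children, S)) < settings.crossover_rate
        children = np.where(cross, pb, pa)
        mut = rng.random(size=(n_children, S)) < settings.mutation_rate
        children[mut] = rng.integers(0, n_pool, size=int(mut.sum()))
        new_pop[settings.elite_count:] = children
        pop = new_pop

    counts = Counter(int(i) for i in best_chrom)
    fractions = {i: n / S for i, n in counts.items()}
    return EnsembleFitResult(
        multiplicities=dict(counts),
        fractions=fractions,
        chi2=best_chi2,
        scale=best_cb[0],
        background=best_cb[1],
        generations_run=gen,
        fitness_trace=np.asarray(trace),
        ensemble_size=S,
        pool_seed=pool_seed,
        settings=settings,
    )


def rg_distribution(
    res: EnsembleFitResult,
    pool: ConformerPool,
    bin_width: float = 2.0,
):
    """Fraction-weighted Rg histogram of the selected ensemble, with the
    pool's unweighted histogram on the same bins for reference.

    Returns ``(edges, weighted_hist, pool_hist)``; both histograms sum to 1.
    """
    if res.pool_seed != -1 and res.pool_seed != pool.seed:
        raise ValueError(
            f"provenance mismatch: result from pool seed {res.pool_seed}, "
            f"got pool seed {pool.seed}"
        )
    rg = pool.rg
    lo = np.floor(rg.min() / bin_width) * bin_width
    hi = np.ceil(rg.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    w = res.weight_vector(len(pool))
    weighted, _ = np.histogram(rg, bins=edges, weights=w)
    reference, _ = np.histogram(rg, bins=edges)
    weighted = weighted / weighted.sum()
    reference = reference / reference.sum()
    return edges, weighted, reference


def exhaustive_select(
    exp: ScatteringProfile,
    profiles: np.ndarray,
    ensemble_size: int,
    fit_background: bool = True,
):
    """Brute-force best multiset over all C(n+k-1, k) combinations.

    Only feasible for tiny pools; serves as an oracle for the GA.
    """
    from itertools import combinations_with_replacement

    best = (np.inf, None, np.nan, np.nan)
    for combo in combinations_with_replacement(range(profiles.shape[0]), ensemble_size):
        model = profiles[list(combo)].mean(axis=0)
        chi2, c, b = chi2_fit(exp, model, fit_background)
        if chi2 < best[0]:
            best = (chi2, combo, c, b)
    return best
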