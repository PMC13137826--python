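"""Scalar descriptors of single SAXS curves.

Covers the classic low-q Guinier fit (ln I linear in q^2), a polymer-physics
Rg estimator for disordered chains built on the Debye function with an
optional Flory exponent, the Kratky transform, the intermediate-q mass
fractal dimension D_m, and the normalized forward-intensity trace used to
follow dilution in the mixer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .io import ScatteringProfile, TimeSeries

GUINIER_QRG_LIMIT = 1.1
IDP_QRG_LIMIT = 3.0
FRACTAL_LOG_WINDOW = (-1.4, -1.0)


class FitError(RuntimeError):
    """A descriptor fit could not be completed."""


@dataclass(frozen=True)
class GuinierFit:
    """Result of a low-q Rg/I(0) fit."""

    rg: float            # Angstrom
    i0: float            # forward intensity, same units as I(q)
    q_window: tuple      # (qmin, qmax) used, 1/Angstrom
    qmax_rg: float       # qmax * Rg of the accepted window
    r2: float            # coefficient of determination
    n_points: int
    method: str = "guinier"
    diagnostics: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return bool(self.diagnostics.get("degenerate", False))


@dataclass(frozen=True)
class FractalFit:
    """Power-law exponent of I(q) ~ q^-Dm in the intermediate-q window."""

    dm: float
    dm_se: float
    log_window: tuple
    n_points: int
    intercept: float = np.nan


def _wls_line(x, y, w):
    """Weighted least squares y = a + b x; returns a, b, r2, se_b."""
    W = np.asarray(w, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    WX = X * W[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
    resid = y - X @ beta
    ss_res = float(np.sum(W * resid**2))
    ybar = float(np.sum(W * y) / np.sum(W))
    ss_tot = float(np.sum(W * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(x) - 2, 1)
    cov = np.linalg.inv(WX.T @ X) * ss_res / dof
    return beta[0], beta[1], r2, float(np.sqrt(max(cov[1, 1], 0.0)))


def guinier_fit(
    profile: ScatteringProfile,
    qrg_limit: float = GUINIER_QRG_LIMIT,
    min_points: int = 5,
    max_iter: int = 100,
) -> GuinierFit:
    """Iterative sigma-weighted Guinier fit ln I = ln I0 - q^2 Rg^2 / 3.

    The low-q window starts at the full positive-intensity range and is
    shrunk from above until qmax*Rg <= ``qrg_limit`` is self-consistent.
    A near-zero slope (flat curve) is returned with Rg < 1 A and the
    ``degenerate`` flag rather than an error.
    """
    pos = profile.intensity > 0
    q, I, s = profile.q[pos], profile.intensity[pos], profile.sigma[pos]
    if len(q) < min_points:
        raise FitError("fewer than %d positive-intensity points" % min_points)
    hi = len(q)
    last_window = (float(q[0]), float(q[hi - 1]))
    for _ in range(max_iter):
        if hi < min_points:
            raise FitError(f"no self-consistent Guinier window; last tried {last_window}")
        x = q[:hi] ** 2
        y = np.log(I[:hi])
        w = (I[:hi] / s[:hi]) ** 2  # sigma of ln I is s/I
        a, b, r2, _ = _wls_line(x, y, w)
        rg = float(np.sqrt(max(-3.0 * b, 0.0)))
        last_window = (float(q[0]), float(q[hi - 1]))
        if rg < 1.0:
            return GuinierFit(
                rg=rg, i0=float(np.exp(a)), q_window=last_window,
                qmax_rg=float(q[hi - 1] * rg), r2=r2, n_points=hi,
                diagnostics={"degenerate": True},
            )
        if q[hi - 1] * rg <= qrg_limit:
            return GuinierFit(
                rg=rg, i0=float(np.exp(a)), q_window=last_window,
                qmax_rg=float(q[hi - 1] * rg), r2=r2, n_points=hi,
            )
        # shrink to the largest window consistent with the current Rg estimate
        new_hi = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        hi = new_hi if new_hi < hi else hi - 1
    raise FitError(f"Guinier window did not converge; last tried {last_window}")


def debye_function(x: np.ndarray) -> np.ndarray:
    """Gaussian-chain Debye function P(x) = 2(e^-x - 1 + x)/x^2, x=(qRg)^2."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x > 1e-8
    out[nz] = 2.0 * (np.expm1(-x[nz]) + x[nz]) / x[nz] ** 2
    return out


def generalized_debye(q, rg, nu):
    """Excluded-volume chain form factor with Flory exponent nu
    (incomplete-gamma formulation; reduces to the Debye function at nu=1/2)."""
    q = np.asarray(q, dtype=float)
    u = (q * rg) ** 2 * (2 * nu + 1) * (2 * nu + 2) / 6.0
    u = np.maximum(u, 1e-12)
    a1, a2 = 1.0 / (2 * nu), 1.0 / nu
    g1 = special.gammainc(a1, u) * special.gamma(a1)
    g2 = special.gammainc(a2, u) * special.gamma(a2)
    return g1 / (nu * u ** a1) - g2 / (nu * u ** a2)


def idp_rg(
    profile: ScatteringProfile,
    fit_qrg_max: float = IDP_QRG_LIMIT,
    fit_nu: bool = False,
) -> GuinierFit:
    """Polymer-corrected Rg for disordered chains.

    Fits I(q) = I0 * P(q Rg) over the extended window q*Rg <= ``fit_qrg_max``,
    where P is the Gaussian-chain Debye function, optionally generalized with
    a fitted Flory exponent nu. The wider window makes the estimator usable
    where a strict Guinier window would keep almost no points.
    """
    guess = guinier_fit(profile, min_points=5)
    rg0, i00 = (guess.rg if guess.rg > 1 else 20.0), guess.i0

    def model(q, i0, rg, nu=0.5):
        if fit_nu:
            return i0 * generalized_debye(q, rg, nu)
        return i0 * debye_function((q * rg) ** 2)

    rg_cur = rg0
    for _ in range(5):
        m = profile.q * rg_cur <= fit_qrg_max
        m &= profile.intensity > 0
        if m.sum() < 5:
            raise FitError("fewer than 5 points in the IDP fit window")
        q, I, s = profile.q[m], profile.intensity[m], profile.sigma[m]
        p0 = [i00, rg_cur] + ([0.5] if fit_nu else [])
        bounds = ([0, 1] + ([0.2] if fit_nu else []),
                  [np.inf, 1e4] + ([1.0] if fit_nu else []))
        try:
            popt, pcov = optimize.curve_fit(
                model, q, I, p0=p0, sigma=s, absolute_sigma=True,
                bounds=bounds, maxfev=20000,
            )
        except RuntimeError as e:  # pragma: no cover - scipy convergence failure
            raise FitError(f"IDP fit did not converge: {e}") from e
        if abs(popt[1] - rg_cur) < 1e-6 * max(rg_cur, 1.0):
            rg_cur = popt[1]
            break
        rg_cur = popt[1]
    i0, rg = float(popt[0]), float(popt[1])
    resid = (I - model(q, *popt)) / s
    red_chi2 = float(np.sum(resid**2) / max(len(q) - len(popt), 1))
    diags = {"reduced_chi2": red_chi2, "poor_fit": red_chi2 > 5.0}
    if fit_nu:
        diags["nu"] = float(popt[2])
    ss_tot = float(np.sum(((I - I.mean()) / s) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return GuinierFit(
        rg=rg, i0=i0, q_window=(float(q[0]), float(q[-1])),
        qmax_rg=float(q[-1] * rg), r2=r2, n_points=int(m.sum()),
        method="idp-debye", diagnostics=diags,
    )


def kratky(profile: ScatteringProfile) -> ScatteringProfile:
    """Kratky transform (q, q^2 I(q)) with propagated sigma. No smoothing."""
    return ScatteringProfile(
        profile.q,
        profile.q**2 * profile.intensity,
        profile.q**2 * profile.sigma,
        label=f"kratky:{profile.label}",
    )


def fractal_fit(
    profile: ScatteringProfile,
    log_window: tuple = FRACTAL_LOG_WINDOW,
    weighted: bool = False,
) -> FractalFit:
    """Mass fractal dimension from log10 I = log10 I0 - Dm * log10 q.

    Ordinary (unweighted) least squares over the intermediate-q window
    q in [10^lo, 10^hi] 1/Angstrom; points with I <= 0 are excluded first.
    """
    lo, hi = 10.0 ** log_window[0], 10.0 ** log_window[1]
    m = (profile.q >= lo) & (profile.q <= hi) & (profile.intensity > 0)
    if m.sum() < 5:
        raise FitError(
            f"fewer than 5 usable points in the log-window [{lo:.4g}, {hi:.4g}]"
        )
    x = np.log10(profile.q[m])
    y = np.log10(profile.intensity[m])
    if weighted:
        w = (profile.intensity[m] / profile.sigma[m]) ** 2
    else:
        w = np.ones_like(x)
    a, b, _, se_b = _wls_line(x, y, w)
    return FractalFit(
        dm=float(-b), dm_se=se_b, log_window=tuple(log_window),
        n_points=int(m.sum()), intercept=float(a),
    )


def forward_intensity_trace(
    series: TimeSeries,
    mode: str = "guinier-i0",
) -> list:
    """I(0) per time point normalized by the first time point.

    ``mode`` is ``"guinier-i0"`` (I0 from the Guinier fit) or ``"lowq-mean"``
    (mean of the 5 lowest-q intensities). Returns a list of
    ``(time_s, i0_normalized)``.
    """
    if len(series) < 2:
        raise FitError("need >= 2 time points for a trace")
    i0s = []
    for k, p in enumerate(series.profiles):
        if mode == "guinier-i0":
            try:
                i0s.append(guinier_fit(p).i0)
            except FitError as e:
                raise FitError(f"Guinier failure at time index {k}: {e}") from e
        elif mode == "lowq-mean":
            i0s.append(float(np.mean(p.intensity[:5])))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    i0s = np.asarray(i0s)
    return list(zip(series.times.tolist(), (i0s / i0s[0]).tolist()))
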