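"""Closed-form scattering references for homogeneous bodies and ideal chains.

Used as independent oracles: a uniform sphere has analytic I(q), p(r), and
Rg = R*sqrt(3/5); an ideal Gaussian chain has the Debye intensity. Nothing
here depends on the fitting code it is used to check.
"""

from __future__ import annotations

import numpy as np

from .io import ScatteringProfile
from .profiles import debye_function


def sphere_intensity(q, radius, i0=1.0):
    """Uniform-sphere form factor intensity
    I(q) = I0 * [3 (sin u - u cos u)/u^3]^2, u = qR."""
    u = np.asarray(q, dtype=float) * radius
    amp = np.ones_like(u)
    nz = np.abs(u) > 1e-8
    amp[nz] = 3.0 * (np.sin(u[nz]) - u[nz] * np.cos(u[nz])) / u[nz] ** 3
    return i0 * amp**2


def sphere_pddf(r, radius, i0=1.0):
    """Uniform-sphere distance distribution on 0 <= r <= 2R,
    p(r) = c * r^2 (1 - 3r/(4R) + r^3/(16 R^3)), normalized so that
    4 pi * integral p dr = i0."""
    r = np.asarray(r, dtype=float)
    x = r / radius
    p = np.where(
        (r >= 0) & (r <= 2 * radius),
        r**2 * (1.0 - 0.75 * x + x**3 / 16.0),
        0.0,
    )
    norm = np.trapezoid(p, r)
    return p * (i0 / (4.0 * np.pi * norm)) if norm > 0 else p


def sphere_rg(radius):
    return radius * np.sqrt(3.0 / 5.0)


def gaussian_chain_intensity(q, rg, i0=1.0):
    """Debye intensity of an ideal Gaussian chain."""
    return i0 * debye_function((np.asarray(q, dtype=float) * rg) ** 2)


def gaussian_chain_profile(q, rg, i0=1.0, rel_sigma=0.01, label=""):
    """Noiseless Debye curve packaged as a profile with nominal uncertainties."""
    q = np.asarray(q, dtype=float)
    I = gaussian_chain_intensity(q, rg, i0)
    return ScatteringProfile(q, I, rel_sigma * np.abs(I), label=label)


def sphere_profile(q, radius, i0=1.0, rel_sigma=0.01, label=""):
    """Noiseless sphere curve packaged as a profile with nominal uncertainties."""
    q = np.asarray(q, dtype=float)
    I = sphere_intensity(q, radius, i0)
    sig = rel_sigma * np.maximum(np.abs(I), 1e-12 * i0)
    return ScatteringProfile(q, I, sig, label=label)


def power_law_profile(q, exponent, prefactor=1.0, rel_sigma=0.01, label=""):
    """I(q) = prefactor * q**(-exponent) packaged as a profile."""
    q = np.asarray(q, dtype=float)
    I = prefactor * q ** (-exponent)
    return ScatteringProfile(q, I, rel_sigma * np.abs(I), label=label)
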