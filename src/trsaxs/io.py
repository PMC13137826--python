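"""Reading, writing, averaging, and buffer-subtracting SAXS profiles.

A profile is a triple (q, I, sigma) on a strictly increasing q grid in
inverse Angstroms. Time series bundle profiles recorded at increasing
times after mixing and are cropped to a common q range so that every
downstream fit sees one shared grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: relative tolerance for declaring two q grids identical
Q_GRID_RTOL = 1e-9

#: synthesized relative uncertainty for 2-column files
DEFAULT_SIGMA_FRACTION = 0.02

MIN_POINTS = 8


class SaxsIOError(ValueError):
    """Malformed or inconsistent SAXS input."""


class GridMismatchError(SaxsIOError):
    """Operation requires identical q grids."""


@dataclass(frozen=True)
class ScatteringProfile:
    """A measured or simulated 1-D scattering curve.

    Parameters
    ----------
    q : array
        Momentum transfer, 1/Angstrom, strictly increasing, all > 0.
    intensity : array
        I(q), arbitrary units.
    sigma : array
        1-sigma uncertainty per point, all > 0.
    label : str
        Free-text condition / time-point tag.
    flags : tuple of str
        Quality flags accumulated by processing steps.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""
    flags: tuple = ()

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if not (len(q) == len(i) == len(s)):
            raise SaxsIOError("q, intensity, sigma must share a length")
        if len(q) < MIN_POINTS:
            raise SaxsIOError(f"profile needs >= {MIN_POINTS} points, got {len(q)}")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise SaxsIOError("q must be strictly increasing and positive")
        if np.any(s <= 0):
            raise SaxsIOError("all sigma must be > 0")
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(i)) and np.all(np.isfinite(s))):
            raise SaxsIOError("non-finite values in profile")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return len(self.q)

    def same_grid(self, other: "ScatteringProfile") -> bool:
        return len(self) == len(other) and np.allclose(
            self.q, other.q, rtol=Q_GRID_RTOL, atol=0.0
        )

    def crop(self, qmin: float = -np.inf, qmax: float = np.inf) -> "ScatteringProfile":
        m = (self.q >= qmin) & (self.q <= qmax)
        return replace(self, q=self.q[m], intensity=self.intensity[m], sigma=self.sigma[m])

    def with_flag(self, flag: str) -> "ScatteringProfile":
        return replace(self, flags=self.flags + (flag,))


@dataclass(frozen=True)
class TimeSeries:
    """Ordered SAXS profiles on a shared q grid with their times (s)."""

    profiles: tuple
    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if len(t) != len(self.profiles):
            raise SaxsIOError("one time per profile required")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise SaxsIOError("times must be non-negative and increasing")
        ref = self.profiles[0]
        for p in self.profiles[1:]:
            if not ref.same_grid(p):
                raise GridMismatchError("time series profiles must share a q grid")
        object.__setattr__(self, "profiles", tuple(self.profiles))
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.profiles)


def _parse_rows(source) -> np.ndarray:
    """Parse numeric rows from a text stream or path; skips '#' comments and
    non-numeric header lines."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    rows = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(x) for x in parts[:3]]
        except ValueError:
            continue  # header / footer text
        if len(vals) >= 2:
            rows.append(vals + [np.nan] * (3 - len(vals)))
    if not rows:
        raise SaxsIOError("no numeric rows found")
    return np.asarray(rows, dtype=float)


def read_profile(
    source,
    dialect: str = "three-column",
    label: str = "",
    sigma_fraction: float = DEFAULT_SIGMA_FRACTION,
    q_units: str = "A",
) -> ScatteringProfile:
    """Read a plain-text SAXS profile.

    ``dialect`` is ``"three-column"`` (sigma optional, synthesized as
    ``sigma_fraction * |I|`` when missing) or ``"atsas-dat"`` (three columns
    required). ``q_units="nm"`` converts q from 1/nm to 1/Angstrom on load.
    Rows with non-finite q or I are dropped with a logged count.
    """
    if dialect not in ("three-column", "atsas-dat"):
        raise SaxsIOError(f"unknown dialect {dialect!r}")
    rows = _parse_rows(source)
    n_raw = len(rows)
    q, inten, sig = rows[:, 0], rows[:, 1], rows[:, 2]
    if np.all(np.isnan(sig)):
        if dialect == "atsas-dat":
            raise SaxsIOError("atsas-dat requires a third (sigma) column")
        sig = sigma_fraction * np.abs(inten)
        log.info("no sigma column: synthesized sigma = %.3g * |I|", sigma_fraction)
    keep = np.isfinite(q) & np.isfinite(inten) & np.isfinite(sig) & (sig > 0) & (q > 0)
    if keep.sum() < n_raw:
        log.warning("dropped %d invalid rows of %d", n_raw - keep.sum(), n_raw)
    q, inten, sig = q[keep], inten[keep], sig[keep]
    order = np.argsort(q, kind="stable")
    q, inten, sig = q[order], inten[order], sig[order]
    if np.any(np.diff(q) <= 0):
        raise SaxsIOError("duplicate q values after sorting")
    if q_units == "nm":
        q = q / 10.0
    if len(q) < MIN_POINTS:
        raise SaxsIOError(f"fewer than {MIN_POINTS} valid rows ({len(q)})")
    return ScatteringProfile(q, inten, sig, label=label)


def write_profile(profile: ScatteringProfile, dest) -> None:
    """Write a 3-column .dat file at 17 significant digits (lossless for
    finite doubles, so read_profile round-trips bit-identically)."""
    header = f"# {profile.label}\n# q(1/A) I(q) sigma\n" if profile.label else "# q(1/A) I(q) sigma\n"
    body = "\n".join(
        f"{q:.17g} {i:.17g} {s:.17g}"
        for q, i, s in zip(profile.q, profile.intensity, profile.sigma)
    )
    text = header + body + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def subtract_buffer(
    sample: ScatteringProfile,
    buffer: ScatteringProfile,
    scale: float = 1.0,
) -> ScatteringProfile:
    """Pointwise sample - scale*buffer with error propagation.

    Negative resulting intensities are retained (clipping would bias the
    low-q Guinier region); the profile is flagged when more than 20% of
    points go negative.
    """
    if scale <= 0:
        raise SaxsIOError("scale must be positive")
    if not sample.same_grid(buffer):
        raise GridMismatchError("sample/buffer q grids differ")
    inten = sample.intensity - scale * buffer.intensity
    sig = np.sqrt(sample.sigma**2 + scale**2 * buffer.sigma**2)
    out = ScatteringProfile(sample.q, inten, sig, label=sample.label, flags=sample.flags)
    if np.mean(inten < 0) > 0.20:
        out = out.with_flag("mostly-negative-after-subtraction")
    return out


def average_frames(
    frames: Sequence[ScatteringProfile],
    outlier_cut: float = 3.0,
):
    """Inverse-variance-weighted per-q mean over repeated frames.

    Frames whose median standardized deviation from the per-q median frame
    exceeds ``outlier_cut`` are excluded — a radiation-damage guard (the
    median reference keeps one grossly damaged frame from dragging the
    center and rejecting good frames). Returns ``(profile, excluded_indices)``.
    """
    if len(frames) < 2:
        raise SaxsIOError("need >= 2 frames to average")
    ref = frames[0]
    for f in frames[1:]:
        if not ref.same_grid(f):
            raise GridMismatchError("frames must share a q grid")
    I = np.stack([f.intensity for f in frames])
    S = np.stack([f.sigma for f in frames])
    W = 1.0 / S**2

    center = np.median(I, axis=0)
    # per-frame median of |I_f - center| / sigma_f: robust to a few bad q bins
    dev = np.median(np.abs(I - center) / S, axis=1)
    keep = dev <= outlier_cut
    excluded = [int(i) for i in np.flatnonzero(~keep)]
    if not np.any(keep):
        raise SaxsIOError("all frames rejected by outlier cut")
    Ik, Wk = I[keep], W[keep]
    mean = np.sum(Wk * Ik, axis=0) / np.sum(Wk, axis=0)
    sig = 1.0 / np.sqrt(np.sum(Wk, axis=0))
    out = ScatteringProfile(ref.q, mean, sig, label=ref.label)
    if excluded:
        out = out.with_flag(f"excluded-frames:{','.join(map(str, excluded))}")
    return out, excluded


def crop_common_range(profiles: Iterable[ScatteringProfile]):
    """Crop every profile to the intersection q range
    [max of minima, min of maxima]."""
    profiles = list(profiles)
    qmin = max(p.q[0] for p in profiles)
    qmax = min(p.q[-1] for p in profiles)
    if qmin >= qmax:
        raise SaxsIOError("profiles share no common q range")
    return [p.crop(qmin, qmax) for p in profiles]


def make_timeseries(profiles: Sequence[ScatteringProfile], times: Sequence[float]) -> TimeSeries:
    """Bundle profiles into a TimeSeries after common-range cropping."""
    return TimeSeries(tuple(crop_common_range(profiles)), np.asarray(times, dtype=float))
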