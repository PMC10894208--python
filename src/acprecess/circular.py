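"""Circular statistics shared by all pipelines.

Conventions used package-wide: 0 deg = stimulation peak, 180 deg =
stimulation trough; angles increase counter-clockwise.  Internally phases
are radians in [0, 2*pi); every public interface speaks degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "PhaseSample",
    "CircularSummary",
    "ZeroResultantError",
    "compute_plv",
    "circular_mean",
    "rayleigh_test",
    "circ_lin_corr",
    "angular_difference",
    "summarize",
    "wrap_deg",
]

#: resultant lengths below this are treated as a zero resultant
RESULTANT_TOL = 1e-9


class ZeroResultantError(ValueError):
    """Raised when a circular mean is requested for a zero-resultant sample."""


def wrap_deg(angle):
    """Wrap angle(s) in degrees to [0, 360)."""
    wrapped = np.mod(angle, 360.0)
    # np.mod can round up to exactly 360.0 for tiny negative inputs
    return np.where(wrapped >= 360.0, 0.0, wrapped)[()]


@dataclass(frozen=True)
class PhaseSample:
    """A set of event phases (radians, wrapped to [0, 2*pi))."""

    phases: np.ndarray

    def __post_init__(self):
        phases = np.mod(np.asarray(self.phases, dtype=float).ravel(), 2.0 * np.pi)
        object.__setattr__(self, "phases", phases)

    @property
    def n(self) -> int:
        return self.phases.size

    @classmethod
    def from_degrees(cls, degrees) -> "PhaseSample":
        return cls(np.deg2rad(np.asarray(degrees, dtype=float)))

    @property
    def degrees(self) -> np.ndarray:
        return np.rad2deg(self.phases)

    @classmethod
    def from_csv(cls, path) -> "PhaseSample":
        """Read a one-column CSV of phases in degrees."""
        deg = np.loadtxt(path, delimiter=",", ndmin=1)
        return cls.from_degrees(deg)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.degrees, delimiter=",", fmt="%.10g")

    def resultant(self) -> complex:
        """Mean resultant vector, sum(exp(i*theta)) / n."""
        if self.n == 0:
            raise ValueError("empty phase sample has no resultant")
        return complex(np.exp(1j * self.phases).sum() / self.n)


@dataclass(frozen=True)
class CircularSummary:
    """PLV, preferred phase (degrees) and Rayleigh p for one phase sample.

    ``phase_defined`` is the explicit flag for an undefined preferred
    phase (zero resultant or empty sample); when False ``preferred_phase``
    holds NaN and must not be interpreted.
    """

    plv: float
    preferred_phase: float
    rayleigh_p: float
    n: int
    phase_defined: bool = field(default=True)

    def to_json(self, path=None) -> str:
        payload = {
            "plv": self.plv,
            "preferred_phase_deg": None if not self.phase_defined else self.preferred_phase,
            "rayleigh_p": self.rayleigh_p,
            "n": self.n,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_plv(sample: PhaseSample) -> float:
    """Phase-locking value |sum_k exp(i*theta_k)| / N.

    0 means no synchronization, 1 perfect synchronization.
    """
    if sample.n == 0:
        raise ValueError("PLV requires at least one event")
    return float(abs(sample.resultant()))


def circular_mean(sample: PhaseSample, tol: float = RESULTANT_TOL) -> float:
    """Circular (resultant-vector) mean of the sample, degrees in [0, 360).

    Raises :class:`ZeroResultantError` when the resultant length is below
    ``tol`` (e.g. antipodal or uniform samples), rather than silently
    returning 0.
    """
    if sample.n == 0:
        raise ValueError("circular mean of an empty sample")
    r = sample.resultant()
    if abs(r) <= tol:
        raise ZeroResultantError(
            f"resultant length {abs(r):.3g} below tolerance; mean undefined"
        )
    return float(wrap_deg(np.rad2deg(np.angle(r))))


def rayleigh_test(sample: PhaseSample) -> float:
    """Rayleigh test of circular non-uniformity; returns the p value.

    Uses the standard small-sample correction
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` where ``Rn`` is
    the un-normalized resultant length n*R.
    """
    n = sample.n
    if n < 2:
        raise ValueError("Rayleigh test requires at least 2 events")
    rn = n * compute_plv(sample)
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - rn * rn)) - (1.0 + 2.0 * n))
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def circ_lin_corr(phases: PhaseSample, covariate) -> tuple[float, float]:
    """Circular-linear correlation between phases and a linear covariate.

    r = sqrt((r_cx^2 + r_sx^2 - 2 r_cx r_sx r_cs) / (1 - r_cs^2)) with
    r_cx = corr(cos theta, x), r_sx = corr(sin theta, x),
    r_cs = corr(cos theta, sin theta); the p value comes from a
    chi-square(2) distribution on n*r^2.
    """
    x = np.asarray(covariate, dtype=float).ravel()
    if phases.n != x.size:
        raise ValueError("phases and covariate must have equal length")
    n = phases.n
    if n < 3:
        raise ValueError("circular-linear correlation requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: correlation degenerate")
    c = np.cos(phases.phases)
    s = np.sin(phases.phases)
    if np.ptp(c) == 0 and np.ptp(s) == 0:
        raise ValueError("constant phase: correlation degenerate")

    def _corr(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))

    rcx = _corr(c, x)
    rsx = _corr(s, x)
    rcs = _corr(c, s)
    denom = 1.0 - rcs * rcs
    if denom <= 0:
        raise ValueError("degenerate phase distribution (|corr(cos, sin)| = 1)")
    r2 = (rcx * rcx + rsx * rsx - 2.0 * rcx * rsx * rcs) / denom
    r = float(np.sqrt(max(r2, 0.0)))
    p = float(stats.chi2.sf(n * r * r, df=2))
    return r, p


def angular_difference(a: float, b: float) -> float:
    """Minimal signed rotation from ``a`` to ``b``, degrees in (-180, 180].

    Positive values are counter-clockwise (increasing phase); the 180 deg
    tie is broken positive.
    """
    d = np.mod(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), 360.0)
    d = np.where(d > 180.0, d - 360.0, d)
    return float(d) if d.ndim == 0 else d


def summarize(sample: PhaseSample) -> CircularSummary:
    """Full circular summary (PLV, preferred phase, Rayleigh p) of a sample.

    The preferred phase is flagged undefined (``phase_defined=False``)
    for empty or zero-resultant samples instead of propagating NaN
    silently.
    """
    if sample.n == 0:
        return CircularSummary(0.0, float("nan"), 1.0, 0, phase_defined=False)
    plv = compute_plv(sample)
    p = rayleigh_test(sample) if sample.n >= 2 else 1.0
    try:
        mu = circular_mean(sample)
        defined = True
    except ZeroResultantError:
        mu = float("nan")
        defined = False
    return CircularSummary(plv, mu, p, sample.n, phase_defined=defined)
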