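"""Two-site cooperative binding model for a DNA probe.

A probe carries two binding sites for a protein complex.  At equilibrium,
with free-complex concentration ``c`` and single-site dissociation constant
``Kd``, the statistical weight of single-site occupancy is ``alpha = c / Kd``
and the four microstates (empty, site A, site B, doubly bound) carry
Boltzmann weights ``{1, alpha, alpha, C * alpha**2}``, where ``C`` is the
cooperativity factor: binding to the second site has dissociation constant
``Kd / C``, so ``C > 1`` means positive cooperativity, ``C = 1`` independent
sites, and ``C < 1`` negative cooperativity.

Grouping by the number of bound complexes gives the occupancy probabilities

    P0 = 1 / Z,   P1 = 2*alpha / Z,   P2 = C*alpha**2 / Z,
    Z  = 1 + 2*alpha + C*alpha**2.

Real probe preparations retain a visible singly shifted band even at
saturating protein, which is modelled as a fraction ``f`` of probes competent
to bind two complexes; the remaining ``1 - f`` bind at most one, with the
single-site binding polynomial ``1 + 2*alpha``:

    P0 = f/Z + (1-f)/(1+2*alpha)
    P1 = f*2*alpha/Z + (1-f)*2*alpha/(1+2*alpha)
    P2 = f*C*alpha**2/Z

All concentrations are in nM throughout; unit conversion is the caller's
responsibility.  The complex concentration entering ``alpha`` is the nominal
titrated concentration — no free/total (ligand-depletion) correction is
applied, which is an assumption when the probe concentration is comparable
to the lowest titration point.

Everything here is pure computation over scalars or NumPy arrays; no I/O,
no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "ModelParams",
    "OccupancyDistribution",
    "statistical_weight",
    "pure_occupancy",
    "mixture_occupancy",
    "mean_sites_filled",
    "second_site_kd",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-site binding model.

    Attributes
    ----------
    kd : float
        Dissociation constant of a complex for a single site, in nM.
        Strictly positive.
    C : float
        Dimensionless cooperativity factor; the second-site dissociation
        constant is ``kd / C``.  Strictly positive.
    f : float
        Fraction of probes competent to bind two complexes, in [0, 1].
    """

    kd: float
    C: float
    f: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.kd) or self.kd <= 0:
            raise ValueError(f"kd must be finite and > 0, got {self.kd!r}")
        if not np.isfinite(self.C) or self.C <= 0:
            raise ValueError(f"C must be finite and > 0, got {self.C!r}")
        if not np.isfinite(self.f) or not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f!r}")

    @property
    def kd_second(self) -> float:
        """Dissociation constant for the second site, ``kd / C`` (nM)."""
        return self.kd / self.C


class OccupancyDistribution(NamedTuple):
    """Probabilities of a probe carrying 0, 1, or 2 complexes.

    Components are nonnegative and sum to 1.  Each field is a float for
    scalar inputs or an ndarray for vectorized evaluation.
    """

    p0: float | NDArray[np.float64]
    p1: float | NDArray[np.float64]
    p2: float | NDArray[np.float64]

    def as_array(self) -> NDArray[np.float64]:
        """Stack as an array with the band axis last."""
        return np.stack(np.broadcast_arrays(self.p0, self.p1, self.p2), axis=-1)

    def mean_occupancy(self) -> float | NDArray[np.float64]:
        """Expected number of bound complexes, ``P1 + 2*P2``."""
        return self.p1 + 2.0 * self.p2


def statistical_weight(
    conc: ArrayLike, kd: float
) -> float | NDArray[np.float64]:
    """Statistical weight ``alpha = conc / kd`` of single-site occupancy.

    Parameters
    ----------
    conc : array_like
        Free complex concentration(s), nM, nonnegative.
    kd : float
        Single-site dissociation constant, nM, strictly positive.
    """
    conc = np.asarray(conc, dtype=float)
    if not np.isfinite(kd) or kd <= 0:
        raise ValueError(f"kd must be finite and > 0, got {kd!r}")
    if np.any(conc < 0) or not np.all(np.isfinite(conc)):
        raise ValueError("concentrations must be finite and nonnegative")
    alpha = conc / kd
    return float(alpha) if alpha.ndim == 0 else alpha


def _check_alpha_C(alpha: ArrayLike, C: float) -> NDArray[np.float64]:
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be finite and nonnegative")
    if not np.isfinite(C) or C <= 0:
        raise ValueError(f"C must be finite and > 0, got {C!r}")
    return alpha


def pure_occupancy(alpha: ArrayLike, C: float) -> OccupancyDistribution:
    """Occupancy distribution when every probe can bind two complexes.

    ``(P0, P1, P2) = (1, 2*alpha, C*alpha**2) / (1 + 2*alpha + C*alpha**2)``.

    ``alpha = 0`` returns exactly (1, 0, 0) without forming ``C*alpha**2``,
    so extreme ``C`` cannot produce spurious overflow at zero concentration.
    """
    alpha = _check_alpha_C(alpha, C)
    scalar = alpha.ndim == 0
    a = np.atleast_1d(alpha)
    p0 = np.ones_like(a)
    p1 = np.zeros_like(a)
    p2 = np.zeros_like(a)
    pos = a > 0
    if np.any(pos):
        ap = a[pos]
        z = 1.0 + 2.0 * ap + C * ap * ap
        p0[pos] = 1.0 / z
        p1[pos] = 2.0 * ap / z
        p2[pos] = C * ap * ap / z
    if scalar:
        return OccupancyDistribution(float(p0[0]), float(p1[0]), float(p2[0]))
    return OccupancyDistribution(p0, p1, p2)


def mixture_occupancy(
    alpha: ArrayLike, C: float, f: float
) -> OccupancyDistribution:
    """Occupancy distribution for a probe pool with two-site fraction ``f``.

    A fraction ``f`` of probes follows the two-site polynomial
    ``1 + 2*alpha + C*alpha**2``; the remaining ``1 - f`` can bind at most
    one complex (polynomial ``1 + 2*alpha``), so ``P2`` carries the ``f``
    component only.
    """
    alpha = _check_alpha_C(alpha, C)
    if not np.isfinite(f) or not 0.0 <= f <= 1.0:
        raise ValueError(f"f must lie in [0, 1], got {f!r}")
    two = pure_occupancy(alpha, C)
    scalar = alpha.ndim == 0
    a = np.atleast_1d(alpha)
    z1 = 1.0 + 2.0 * a
    q0, q1 = 1.0 / z1, 2.0 * a / z1
    p0 = f * np.atleast_1d(two.p0) + (1.0 - f) * q0
    p1 = f * np.atleast_1d(two.p1) + (1.0 - f) * q1
    p2 = f * np.atleast_1d(two.p2)
    if scalar:
        return OccupancyDistribution(float(p0[0]), float(p1[0]), float(p2[0]))
    return OccupancyDistribution(p0, p1, p2)


def mean_sites_filled(
    alpha: ArrayLike, C: float, f: float
) -> float | NDArray[np.float64]:
    """Average number of sites filled, ``P1 + 2*P2``, in [0, 1 + f].

    Monotonically nondecreasing in ``alpha``; saturates at ``1 + f`` because
    the single-site-only fraction contributes at most one bound complex.
    """
    return mixture_occupancy(alpha, C, f).mean_occupancy()


def second_site_kd(params: ModelParams) -> float:
    """Dissociation constant for binding the second site, ``kd / C`` (nM)."""
    return params.kd_second
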