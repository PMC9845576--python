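"""Isotope-notation types and conversions.

All delta values are per-mil (permil) deviations from an international
reference scale: atmospheric N2 for 15N/14N and VSMOW for 18O/16O.  The
15N site preference of N2O (``sp``) is the difference between the delta
value of the central (alpha) and the peripheral (beta) nitrogen atom and
is diagnostic of the microbial production pathway.

Conversions between delta notation and atom fraction are exact (no
small-ratio linearisation) and mutually inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .constants import A15_NATURAL_PCT, R15_AIR_N2


class Reference(str, Enum):
    """Isotope reference scale a delta value is expressed against."""

    AIR_N2 = "AIR_N2"
    VSMOW = "VSMOW"


class ScaleMismatchError(ValueError):
    """Raised when delta values on different reference scales are combined."""


@dataclass(frozen=True)
class IsotopeValue:
    """A delta value in permil with its reference scale and optional 1-sigma.

    Parameters
    ----------
    value : float
        Per-mil deviation from the reference ratio.  Must exceed -1000
        (an atom fraction of exactly zero or below is non-physical).
    reference : Reference
        ``AIR_N2`` for 15N, ``VSMOW`` for 18O.
    sigma : float, optional
        One-sigma measurement uncertainty in permil.
    """

    value: float
    reference: Reference = Reference.AIR_N2
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"delta value must be finite, got {self.value}")
        if self.value <= -1000.0:
            raise ValueError(
                f"delta value must exceed -1000 permil, got {self.value}"
            )
        if self.sigma is not None and self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")


@dataclass(frozen=True)
class AtomFraction:
    """Mole fraction of the heavy isotope (dimensionless, 0..1)."""

    x: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise ValueError(f"atom fraction must lie in [0, 1], got {self.x}")

    @property
    def as_percent(self) -> float:
        """Atom-% representation (x * 100)."""
        return 100.0 * self.x

    @classmethod
    def from_percent(cls, pct: float) -> "AtomFraction":
        return cls(pct / 100.0)


@dataclass(frozen=True)
class SitePreferencePair:
    """Alpha/beta 15N delta values of N2O with derived SP and bulk."""

    d15n_alpha: IsotopeValue
    d15n_beta: IsotopeValue
    d15n_bulk: IsotopeValue
    sp: float
    sigma_sp: Optional[float] = None


def _as_delta(d: "IsotopeValue | float", reference: Reference) -> IsotopeValue:
    if isinstance(d, IsotopeValue):
        if d.reference is not reference:
            raise ScaleMismatchError(
                f"expected delta on {reference.value} scale, got {d.reference.value}"
            )
        return d
    return IsotopeValue(float(d), reference)


def delta_to_atom_fraction(d: "IsotopeValue | float") -> AtomFraction:
    """Convert a 15N delta value (AIR-N2 scale) to an atom fraction.

    x = ((d/1000 + 1) R_STD) / (1 + (d/1000 + 1) R_STD)

    with R_STD = 0.0036765, the 15N/14N ratio of atmospheric N2.
    Strictly increasing in d; d = 0 maps to natural abundance
    (0.36630 atom-%).
    """
    dv = _as_delta(d, Reference.AIR_N2)
    r = (dv.value / 1000.0 + 1.0) * R15_AIR_N2
    return AtomFraction(r / (1.0 + r))


def atom_fraction_to_delta(x: "AtomFraction | float") -> IsotopeValue:
    """Exact algebraic inverse of :func:`delta_to_atom_fraction`."""
    xv = x.x if isinstance(x, AtomFraction) else float(x)
    if not 0.0 < xv < 1.0:
        raise ValueError(f"atom fraction must lie in (0, 1), got {xv}")
    r = xv / (1.0 - xv)
    return IsotopeValue((r / R15_AIR_N2 - 1.0) * 1000.0, Reference.AIR_N2)


def atom_percent_excess(
    labeled: "AtomFraction | float", natural: "AtomFraction | float | None" = None
) -> float:
    """Atom-% 15N excess (APE) of a labeled pool over its natural abundance.

    APE = atom-%(labeled) - atom-%(natural).  When no paired
    natural-abundance sample exists, the AIR-N2 derived 0.36630 atom-%
    is used.  The result may be slightly negative for unlabeled pools
    within measurement noise; callers should treat such values as
    below detection.
    """
    lab = labeled if isinstance(labeled, AtomFraction) else AtomFraction(labeled)
    if natural is None:
        nat_pct = A15_NATURAL_PCT
    else:
        nat = natural if isinstance(natural, AtomFraction) else AtomFraction(natural)
        nat_pct = nat.as_percent
    return lab.as_percent - nat_pct


def correct_o18_for_water(
    d18o_n2o: "IsotopeValue | float", d18o_h2o: "IsotopeValue | float"
) -> IsotopeValue:
    """Reference the d18O of N2O to the water it was produced from.

    d18O(N2O/H2O) = d18O(N2O) - d18O(H2O); both inputs on the VSMOW
    scale.  Uncertainties combine in quadrature when both are present.
    """
    n2o = _as_delta(d18o_n2o, Reference.VSMOW)
    h2o = _as_delta(d18o_h2o, Reference.VSMOW)
    sigma = None
    if n2o.sigma is not None and h2o.sigma is not None:
        sigma = math.hypot(n2o.sigma, h2o.sigma)
    elif n2o.sigma is not None:
        sigma = n2o.sigma
    elif h2o.sigma is not None:
        sigma = h2o.sigma
    return IsotopeValue(n2o.value - h2o.value, Reference.VSMOW, sigma)


def site_preference(
    alpha: "IsotopeValue | float",
    beta: "IsotopeValue | float",
    bulk: "IsotopeValue | float | None" = None,
    tol: float = 1e-6,
) -> SitePreferencePair:
    """Form the 15N site preference from alpha and beta position deltas.

    sp = d15N(alpha) - d15N(beta); bulk defaults to the arithmetic mean
    of the two positions.  If an independently measured bulk value is
    supplied it is checked for consistency with the positional mean to
    ``tol`` permil (measurement-scale tolerance, not machine epsilon).
    """
    a = _as_delta(alpha, Reference.AIR_N2)
    b = _as_delta(beta, Reference.AIR_N2)
    sigma_sp = None
    sigma_bulk = None
    if a.sigma is not None and b.sigma is not None:
        sigma_sp = math.hypot(a.sigma, b.sigma)
        sigma_bulk = sigma_sp / 2.0
    mean = (a.value + b.value) / 2.0
    if bulk is None:
        blk = IsotopeValue(mean, Reference.AIR_N2, sigma_bulk)
    else:
        blk = _as_delta(bulk, Reference.AIR_N2)
        if abs(blk.value - mean) > max(tol, 3.0 * (blk.sigma or 0.0)):
            raise ValueError(
                "measured bulk d15N inconsistent with the alpha/beta mean: "
                f"{blk.value} vs {mean}"
            )
    return SitePreferencePair(a, b, blk, a.value - b.value, sigma_sp)
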