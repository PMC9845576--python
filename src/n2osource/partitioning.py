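"""15N-tracer partitioning of emitted N2O between source pools.

After labeling one dissolved pool (NH4+ or NO3-) with 15N, the 15N
content of emitted N2O tells which pool produced it.  Two routes are
implemented:

* **Non-equilibrium isotopologue route** (15NO3- labeled units): when
  N2O is produced from a mixture of one highly enriched pool and pools
  near natural abundance, its molecular masses 44/45/46 deviate from
  the binomial (random) distribution implied by the bulk 15N content.
  Assuming a random 15N distribution *within* each pool, the measured
  bulk 15N atom fraction ``a_m`` and the doubly-15N-substituted species
  fraction ``m2`` determine both the enrichment ``ap`` of the active
  labeled pool and the fraction ``x`` of N2O derived from it:

      u = a_m - a_bgd,  v = m2 - a_bgd**2
      ap = v/u - a_bgd,  x = u / (ap - a_bgd)

* **Bulk mixing route** (mandatory for 15NH4+ labeled units, where
  labeled N can reach N2O through two pools): the fraction of
  NO3--derived N2O follows from a two-endmember mixing equation on the
  atom fractions of the emitted N2O and the two measured pools:

      f_PN2O = (a_N2O - a_NH4) / (a_NO3 - a_NH4)

Ion-current ratios 45R/46R are reduced to (a_m, m2) after removing the
oxygen-17/18 contributions via the mass-dependent triple-oxygen
relation (17R = K * 18R**0.516, VSMOW-anchored), with the d18O of the
N2O supplied or assumed (the 15N label does not alter the oxygen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .constants import A15_NATURAL, BETA_O17, K_O17, R18_VSMOW


@dataclass(frozen=True)
class TwoPoolResult:
    """Inverted two-pool solution (enrichment of the labeled pool and
    the fraction of N2O derived from it)."""

    ap: float
    x: float
    below_detection: bool = False
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PartitionResult:
    """Source split of the total N2O flux for one labeled unit."""

    f_pn2o: float
    f_nh4: float
    no3_derived_flux: float
    nh4_derived_flux: float
    total_flux: float
    f_pn2o_raw: float
    flags: tuple[str, ...] = ()


def oxygen_ratios_from_d18o(d18o_vsmow: float) -> tuple[float, float]:
    """(17R, 16O-normalised) and 18R of N2O oxygen from its d18O value.

    18R = (d/1000 + 1) * R18_VSMOW; 17R follows the mass-dependent
    relation 17R = K * 18R**beta with beta = 0.516 anchored at VSMOW.
    """
    r18 = (d18o_vsmow / 1000.0 + 1.0) * R18_VSMOW
    r17 = K_O17 * r18**BETA_O17
    return r17, r18


def isotopologue_ratios(a_m: float, m2: float, d18o_vsmow: float) -> tuple[float, float]:
    """Forward model: ion-current ratios (45R, 46R) of N2O.

    ``a_m`` is the bulk 15N atom fraction and ``m2`` the fraction of
    molecules carrying two 15N atoms (the N-substitution classes are
    q2 = m2, q1 = 2(a_m - m2), q0 = 1 - q1 - q2).  Oxygen isotopes are
    independent of the N pools.  Exact in ratio space (masses 47/48
    drop out of the 45/44 and 46/44 ratios).
    """
    q2 = m2
    q1 = 2.0 * (a_m - m2)
    q0 = 1.0 - q1 - q2
    if q0 <= 0 or q1 < 0 or q2 < 0:
        raise ValueError("inconsistent (a_m, m2): substitution classes not a simplex")
    r17, r18 = oxygen_ratios_from_d18o(d18o_vsmow)
    u1 = q1 / q0
    u2 = q2 / q0
    return u1 + r17, u2 + u1 * r17 + r18


def n_classes_from_ratios(
    r45: float, r46: float, d18o_vsmow: float
) -> tuple[float, float]:
    """Invert (45R, 46R) to (a_m, m2) after the 17O/18O correction."""
    if r45 <= 0 or r46 <= 0:
        raise ValueError("ion-current ratios must be positive")
    r17, r18 = oxygen_ratios_from_d18o(d18o_vsmow)
    u1 = r45 - r17
    u2 = r46 - u1 * r17 - r18
    if u1 < 0 or u2 < 0:
        raise ValueError("ratios below the pure-oxygen contribution; check d18O")
    q0 = 1.0 / (1.0 + u1 + u2)
    q1 = u1 * q0
    q2 = u2 * q0
    return q1 / 2.0 + q2, q2


def forward_two_pool(x: float, ap: float, a_bgd: float) -> tuple[float, float]:
    """Forward two-pool isotopologue model: (a_m, m2) of the mixture.

    A fraction ``x`` of the N2O draws both N atoms from the labeled
    pool (atom fraction ``ap``, binomially distributed) and ``1 - x``
    from the background pool at ``a_bgd``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    a_m = x * ap + (1.0 - x) * a_bgd
    m2 = x * ap**2 + (1.0 - x) * a_bgd**2
    return a_m, m2


def two_pool_nonequilibrium(
    a_m: float, m2: float, a_bgd: float = A15_NATURAL, atol: float = 1e-12
) -> TwoPoolResult:
    """Invert the two-pool model: recover (ap, x) from (a_m, m2).

    Exact algebraic inverse of :func:`forward_two_pool`.  When the bulk
    enrichment does not exceed the background (u <= 0) the result is a
    below-detection marker; an ap above 1 is clipped and flagged.
    """
    u = a_m - a_bgd
    if u <= atol:
        return TwoPoolResult(math.nan, 0.0, below_detection=True,
                             flags=("no detectable label in N2O",))
    v = m2 - a_bgd**2
    ap = v / u - a_bgd
    flags: list[str] = []
    if ap > 1.0:
        flags.append(f"ap above 1 (raw {ap:.4f}); clipped")
        ap = 1.0
    if ap <= a_bgd:
        # m2 consistent with a single pool barely above background.
        return TwoPoolResult(a_m, 1.0, flags=tuple(flags) + ("ap at bulk value",))
    x = u / (ap - a_bgd)
    if x > 1.0:
        flags.append(f"x above 1 (raw {x:.4f}); clipped")
        x = 1.0
    return TwoPoolResult(ap, x, flags=tuple(flags))


def two_pool_from_ratios(
    r45: float, r46: float, d18o_vsmow: float, a_bgd: float = A15_NATURAL
) -> TwoPoolResult:
    """Two-pool inversion straight from ion-current ratios."""
    a_m, m2 = n_classes_from_ratios(r45, r46, d18o_vsmow)
    return two_pool_nonequilibrium(a_m, m2, a_bgd)


def emitted_atom_fraction(
    a_sample: float, conc_ppb: float, a_ambient: float, ambient_ppb: float
) -> float:
    """15N atom fraction of the emitted N2O, removing the atmospheric share.

    Atom fractions mix linearly with concentration (two N per molecule
    on both sides), so the correction mirrors the delta mixing model.
    """
    dc = conc_ppb - ambient_ppb
    if dc <= 0:
        raise ValueError("sample concentration must exceed ambient")
    return (conc_ppb * a_sample - ambient_ppb * a_ambient) / dc


def atmospheric_correction_fraction(
    x_total: float, conc_ppb: float, ambient_ppb: float
) -> tuple[float, tuple[str, ...]]:
    """Rescale a labeled-pool fraction of *measured* N2O to the emitted basis.

    Atmospheric N2O carries no label, so
    f_emitted = x_total * conc / (conc - ambient); clipped to [0, 1]
    with a flag when sampling noise pushes it outside.
    """
    dc = conc_ppb - ambient_ppb
    if dc <= 0:
        raise ValueError("sample concentration must exceed ambient")
    f = x_total * conc_ppb / dc
    flags: tuple[str, ...] = ()
    if f < 0.0 or f > 1.0:
        flags = (f"fraction out of [0,1] (raw {f:.4f}); clipped",)
        f = min(1.0, max(0.0, f))
    return f, flags


def f_from_mixing(a_n2o: float, a_no3: float, a_nh4: float) -> tuple[float, tuple[str, ...]]:
    """NO3--derived fraction of emitted N2O from pool atom fractions.

    f_PN2O = (a_N2O - a_NH4) / (a_NO3 - a_NH4).  The pool enrichments
    must be the *measured* values at the matching time point (label
    dilution matters), not the nominal label strengths.
    """
    denom = a_no3 - a_nh4
    if denom == 0.0:
        raise ValueError("NO3 and NH4 pool enrichments are equal; mixing degenerate")
    f = (a_n2o - a_nh4) / denom
    flags: tuple[str, ...] = ()
    if f < 0.0 or f > 1.0:
        flags = (f"f_PN2O out of [0,1] (raw {f:.4f}); clipped",)
        f = min(1.0, max(0.0, f))
    return f, flags


def partition_flux(
    f_pn2o: float,
    total_flux: float,
    f_pn2o_raw: Optional[float] = None,
    flags: tuple[str, ...] = (),
) -> PartitionResult:
    """Split the total N2O flux into NO3-- and NH4+-derived components.

    The NO3--derived flux is f_PN2O * total; the NH4+-derived flux is
    the remainder, so the two always sum to the total.  Assumes the
    labeled-pool emission grows linearly over the chamber closure, like
    the total N2O.
    """
    if not 0.0 <= f_pn2o <= 1.0:
        raise ValueError("f_PN2O must lie in [0, 1] (clip upstream with a flag)")
    no3 = f_pn2o * total_flux
    return PartitionResult(
        f_pn2o=f_pn2o,
        f_nh4=1.0 - f_pn2o,
        no3_derived_flux=no3,
        nh4_derived_flux=total_flux - no3,
        total_flux=total_flux,
        f_pn2o_raw=f_pn2o if f_pn2o_raw is None else f_pn2o_raw,
        flags=flags,
    )


def nd_cnd_fraction(f_bd: float, f_pn2o: float) -> tuple[float, tuple[str, ...]]:
    """Combined nitrifier-denitrification / coupled fraction.

    f_nD/cND = f_bD - f_PN2O: the part of the map-derived denitrifier
    fraction not explained by NO3--derived N2O.  A negative value is
    returned with a flag (it signals a violated equal-pool assumption,
    not an error).
    """
    for name, v in (("f_bD", f_bd), ("f_PN2O", f_pn2o)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    d = f_bd - f_pn2o
    flags = ("negative: f_PN2O exceeds f_bD (active-pool assumption violated)",) if d < 0 else ()
    return d, flags
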