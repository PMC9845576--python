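"""Atmospheric-mixing correction of N2O isotopocule measurements.

Chamber headspace N2O is a two-component mixture of ambient
(atmospheric) N2O and N2O emitted from the substrate.  Because delta
values mix linearly when weighted by concentration, the emitted
signature follows from the measured mixture and the ambient reference:

    delta_emitted = (C_s * delta_s - C_atm * delta_atm) / (C_s - C_atm)

The correction is applied to d15N-alpha and d15N-beta individually (the
site preference of a mixture is not the mixture of site preferences,
but alpha and beta each mix linearly, so correcting them separately is
exact) and to d18O; SP and bulk are formed afterwards.  As the sample
concentration approaches ambient the denominator vanishes and the
propagated uncertainty diverges, hence samples less than a margin
(default 65 ppb) above ambient are excluded, with first-order Gaussian
error propagation documenting the uncertainty of the retained ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

#: Default 1-sigma measurement uncertainties (typical IRMS / GC values).
DEFAULT_SIGMA_DELTA = 0.5  # permil, per delta value
DEFAULT_SIGMA_CONC = 2.0  # ppb

#: Default minimum excess of sample over ambient concentration (ppb).
DEFAULT_MARGIN_PPB = 65.0


@dataclass(frozen=True)
class AmbientAir:
    """Ambient-air N2O reference for one campaign."""

    conc_ppb: float
    d15n_alpha: float
    d15n_beta: float
    d18o: float

    def __post_init__(self) -> None:
        if self.conc_ppb <= 0:
            raise ValueError("ambient concentration must be positive")

    @property
    def sp(self) -> float:
        return self.d15n_alpha - self.d15n_beta

    @property
    def d15n_bulk(self) -> float:
        return (self.d15n_alpha + self.d15n_beta) / 2.0


@dataclass(frozen=True)
class MeasurementSigmas:
    """1-sigma uncertainties of one isotopocule measurement."""

    sigma_delta: float = DEFAULT_SIGMA_DELTA
    sigma_conc_ppb: float = DEFAULT_SIGMA_CONC
    sigma_ambient_delta: float = DEFAULT_SIGMA_DELTA
    sigma_ambient_conc_ppb: float = DEFAULT_SIGMA_CONC


@dataclass(frozen=True)
class IsotopoculeSample:
    """One chamber-headspace isotopocule measurement with its ambient ref."""

    conc_ppb: float
    d15n_alpha: float
    d15n_beta: float
    d18o: float
    ambient: AmbientAir
    campaign_id: Optional[str] = None
    sample_id: Optional[str] = None
    sigmas: MeasurementSigmas = field(default_factory=MeasurementSigmas)

    def __post_init__(self) -> None:
        if self.conc_ppb <= 0:
            raise ValueError("sample concentration must be positive")

    @property
    def sp(self) -> float:
        return self.d15n_alpha - self.d15n_beta


@dataclass(frozen=True)
class EmittedDelta:
    """Substrate-emitted isotopocule values after mixing correction."""

    sp: float
    d18o: float
    d15n_bulk: float
    d15n_alpha: float
    d15n_beta: float
    sigma_sp: Optional[float] = None
    sigma_d18o: Optional[float] = None
    excluded: bool = False
    reason: Optional[str] = None
    sample_id: Optional[str] = None
    campaign_id: Optional[str] = None


def _mix_corrected(cs: float, ca: float, ds: float, da: float) -> float:
    return (cs * ds - ca * da) / (cs - ca)


def mixing_sigma(
    cs: float,
    ca: float,
    ds: float,
    da: float,
    sigma_ds: float,
    sigma_da: float,
    sigma_cs: float,
    sigma_ca: float,
) -> float:
    """First-order (delta-method) sigma of the mixing-corrected delta.

    Partial derivatives of g = (cs ds - ca da)/(cs - ca):
      dg/dds = cs/(cs-ca)          dg/dda = -ca/(cs-ca)
      dg/dcs = ca (da-ds)/(cs-ca)^2   dg/dca = cs (ds-da)/(cs-ca)^2
    """
    dc = cs - ca
    if dc <= 0:
        raise ValueError("sample concentration must exceed ambient")
    terms = (
        (cs / dc) * sigma_ds,
        (ca / dc) * sigma_da,
        (ca * (da - ds) / dc**2) * sigma_cs,
        (cs * (ds - da) / dc**2) * sigma_ca,
    )
    return math.sqrt(sum(t * t for t in terms))


def correct_delta_mixing(sample: IsotopoculeSample) -> EmittedDelta:
    """Remove the atmospheric N2O contribution from one sample.

    Returns an :class:`EmittedDelta`; when the concentration difference
    is non-positive the result is flagged ``excluded`` (no NaN
    propagation downstream).  SP uncertainty is propagated jointly:
    because the mixing formula is linear in the delta value, SP obeys
    the same formula with sigma(SP) = sqrt(2) * sigma(delta) on each
    side, which keeps the alpha/beta correlation through the shared
    concentrations exact.
    """
    amb = sample.ambient
    dc = sample.conc_ppb - amb.conc_ppb
    if dc <= 0:
        return EmittedDelta(
            math.nan, math.nan, math.nan, math.nan, math.nan,
            excluded=True,
            reason="sample concentration not above ambient",
            sample_id=sample.sample_id, campaign_id=sample.campaign_id,
        )
    cs, ca = sample.conc_ppb, amb.conc_ppb
    alpha_e = _mix_corrected(cs, ca, sample.d15n_alpha, amb.d15n_alpha)
    beta_e = _mix_corrected(cs, ca, sample.d15n_beta, amb.d15n_beta)
    d18o_e = _mix_corrected(cs, ca, sample.d18o, amb.d18o)

    s = sample.sigmas
    sig_sp = mixing_sigma(
        cs, ca, sample.sp, amb.sp,
        math.sqrt(2.0) * s.sigma_delta, math.sqrt(2.0) * s.sigma_ambient_delta,
        s.sigma_conc_ppb, s.sigma_ambient_conc_ppb,
    )
    sig_o = mixing_sigma(
        cs, ca, sample.d18o, amb.d18o,
        s.sigma_delta, s.sigma_ambient_delta,
        s.sigma_conc_ppb, s.sigma_ambient_conc_ppb,
    )
    return EmittedDelta(
        sp=alpha_e - beta_e,
        d18o=d18o_e,
        d15n_bulk=(alpha_e + beta_e) / 2.0,
        d15n_alpha=alpha_e,
        d15n_beta=beta_e,
        sigma_sp=sig_sp,
        sigma_d18o=sig_o,
        sample_id=sample.sample_id,
        campaign_id=sample.campaign_id,
    )


def forward_mix(
    c_emitted: float, delta_emitted: float, ambient_conc: float, ambient_delta: float
) -> tuple[float, float]:
    """Forward two-pool mixing: (total concentration, mixture delta).

    The exact inverse of :func:`correct_delta_mixing` for a single
    delta; used as an independent oracle in tests and by the synthetic
    experiment generator.
    """
    cs = c_emitted + ambient_conc
    ds = (c_emitted * delta_emitted + ambient_conc * ambient_delta) / cs
    return cs, ds


def apply_concentration_threshold(
    samples: Iterable[IsotopoculeSample],
    margin_ppb: float = DEFAULT_MARGIN_PPB,
    ambient_ppb: Optional[float] = None,
) -> tuple[list[IsotopoculeSample], list[tuple[IsotopoculeSample, str]]]:
    """Split samples into (retained, excluded-with-reason) by concentration.

    A sample is retained when its concentration is at least
    ``ambient + margin`` ppb (inclusive boundary: the margin is a
    minimum difference).  The ambient value defaults to each sample's
    own campaign reference, giving per-campaign absolute thresholds.
    """
    if margin_ppb <= 0:
        raise ValueError("margin must be positive")
    retained: list[IsotopoculeSample] = []
    excluded: list[tuple[IsotopoculeSample, str]] = []
    for s in samples:
        base = ambient_ppb if ambient_ppb is not None else s.ambient.conc_ppb
        threshold = base + margin_ppb
        if s.conc_ppb >= threshold:
            retained.append(s)
        else:
            excluded.append(
                (s, f"concentration {s.conc_ppb:.1f} ppb below threshold "
                    f"{threshold:.1f} ppb (ambient {base:.1f} + margin {margin_ppb:.0f})")
            )
    return retained, excluded


def with_sigmas(sample: IsotopoculeSample, sigmas: MeasurementSigmas) -> IsotopoculeSample:
    """Copy of ``sample`` carrying different measurement uncertainties."""
    return replace(sample, sigmas=sigmas)
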