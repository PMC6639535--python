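"""Parametric NMRD (R1-versus-field) dispersion models.

An NMRD profile is the longitudinal relaxation rate R1 = 1/T1 as a function
of magnetic field strength (equivalently proton Larmor frequency,
f = (gamma/2pi) * B0 with gamma/2pi = 42.578 MHz/T).  This module provides
phenomenological building blocks:

* :class:`PowerLawModel` -- R1(f) = a * f**b, the standard empirical model
  for tissue dispersion.
* :class:`LorentzianDispersionModel` -- a high-field plateau plus a sum of
  Lorentzian dispersion steps, the generic shape of paramagnetic-ion
  solutions such as MnCl2.
* :class:`QuadrupolarPeakSet` -- localized R1 enhancements where the proton
  Larmor frequency matches 14N quadrupolar transitions in immobilised
  proteins (dominant peak near 60 mT for protons).
* :class:`TissueDispersionModel` -- baseline + concentration-scaled specific
  term (+ optional concentration-scaled quadrupolar peaks).  Changing the
  concentration shifts the profile vertically without changing the shape of
  the specific term.

Canonical internal units: frequency in Hz, field in tesla, rates in s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np

__all__ = [
    "GAMMA_HZ_PER_T",
    "larmor_frequency",
    "field_from_frequency",
    "PowerLawModel",
    "LorentzianDispersionModel",
    "QuadrupolarPeakSet",
    "TissueDispersionModel",
    "phantom_reference_library",
]

#: Proton gyromagnetic ratio over 2*pi, in Hz per tesla.
GAMMA_HZ_PER_T = 42.578e6


def larmor_frequency(field_T):
    """Proton Larmor frequency f = (gamma/2pi) * B0.

    Parameters
    ----------
    field_T : float or array
        Magnetic field in tesla (>= 0).

    Returns
    -------
    float or array
        Frequency in Hz.  1.5 T maps to 63.867 MHz; 50 uT to ~2.13 kHz.
    """
    return GAMMA_HZ_PER_T * np.asarray(field_T, dtype=float) if np.ndim(field_T) else GAMMA_HZ_PER_T * float(field_T)


def field_from_frequency(frequency_Hz):
    """Inverse of :func:`larmor_frequency` (exact)."""
    return np.asarray(frequency_Hz, dtype=float) / GAMMA_HZ_PER_T if np.ndim(frequency_Hz) else float(frequency_Hz) / GAMMA_HZ_PER_T


def _as_freq(field_T=None, frequency_Hz=None):
    """Resolve the (field | frequency) keyword pair to a frequency in Hz."""
    if (field_T is None) == (frequency_Hz is None):
        raise ValueError("give exactly one of field_T or frequency_Hz")
    f = larmor_frequency(field_T) if frequency_Hz is None else np.asarray(frequency_Hz, dtype=float)
    if np.any(np.asarray(f) <= 0):
        raise ValueError("field/frequency must be positive for R1 evaluation")
    return f


@dataclass(frozen=True)
class PowerLawModel:
    """Empirical power-law dispersion R1(f) = a * f**b.

    ``a`` has units s^-1 Hz^-b; ``b`` is dimensionless (b < 0 for a
    decreasing profile, b = 0 for a flat one).
    """

    a: float
    b: float

    def r1(self, frequency_Hz):
        f = np.asarray(frequency_Hz, dtype=float)
        out = self.a * f ** self.b
        return float(out) if out.ndim == 0 else out

    def scaled(self, factor: float) -> "PowerLawModel":
        return replace(self, a=self.a * factor)


@dataclass(frozen=True)
class LorentzianDispersionModel:
    """High-field plateau plus Lorentzian dispersion steps.

    R1(f) = r1_offset + sum_i A_i / (1 + (2 pi f tau_i)^2)

    with amplitudes ``A_i`` in s^-1 and correlation times ``tau_i`` in s.
    Monotone non-increasing in f; R1(0) = r1_offset + sum(A_i) and
    R1 -> r1_offset at high field.
    """

    r1_offset: float
    terms: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple((float(a), float(t)) for a, t in self.terms))

    def r1(self, frequency_Hz):
        f = np.asarray(frequency_Hz, dtype=float)
        out = np.full_like(f, self.r1_offset, dtype=float)
        for amp, tau in self.terms:
            out = out + amp / (1.0 + (2.0 * np.pi * f * tau) ** 2)
        return float(out) if out.ndim == 0 else out

    def scaled(self, factor: float) -> "LorentzianDispersionModel":
        return replace(
            self,
            r1_offset=self.r1_offset * factor,
            terms=tuple((a * factor, t) for a, t in self.terms),
        )


@dataclass(frozen=True)
class QuadrupolarPeakSet:
    """Lorentzian-shaped R1 peaks in frequency.

    Each peak ``(centre_Hz, width_Hz, amplitude)`` contributes
    ``amplitude * w**2 / (w**2 + (f - fc)**2)``, non-negative everywhere and
    maximal at its centre.  The default set used for cross-linked protein
    gels places peaks at the 14N cross-relaxation proton frequencies 0.66,
    2.1 and 2.75 MHz, the dominant one corresponding to a field near 60 mT.
    """

    peaks: Tuple[Tuple[float, float, float], ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "peaks", tuple((float(c), float(w), float(a)) for c, w, a in self.peaks)
        )

    def r1(self, frequency_Hz):
        f = np.asarray(frequency_Hz, dtype=float)
        out = np.zeros_like(f, dtype=float)
        for fc, w, amp in self.peaks:
            out = out + amp * w**2 / (w**2 + (f - fc) ** 2)
        return float(out) if out.ndim == 0 else out

    def scaled(self, factor: float) -> "QuadrupolarPeakSet":
        return replace(self, peaks=tuple((c, w, a * factor) for c, w, a in self.peaks))

    @property
    def band(self) -> Tuple[float, float]:
        """Frequency interval (Hz) covering all peaks +/- 2 widths."""
        if not self.peaks:
            return (0.0, 0.0)
        lo = min(c - 2 * w for c, w, _ in self.peaks)
        hi = max(c + 2 * w for c, w, _ in self.peaks)
        return (lo, hi)


BaselineModel = Union[PowerLawModel, LorentzianDispersionModel]


#: Default quadrupolar peak set for cross-linked BSA, per unit % w/w.
#: Centres at the 14N transition proton frequencies; the dominant 2.75 MHz
#: peak corresponds to ~65 mT.
DEFAULT_BSA_PEAKS = QuadrupolarPeakSet(
    peaks=(
        (0.66e6, 0.15e6, 0.020),
        (2.10e6, 0.25e6, 0.035),
        (2.75e6, 0.30e6, 0.055),
    )
)


@dataclass(frozen=True)
class TissueDispersionModel:
    """Material dispersion = baseline + concentration * specific term.

    R1(f; c) = R1_baseline(f) + c * r1_specific(f) [+ c * peaks(f)]

    ``specific_dispersion`` is the per-unit-concentration contribution (same
    model family as the baseline); ``quadrupolar`` (optional) also scales
    linearly with concentration.  Concentration units are whatever the
    material uses (mM for MnCl2, % w/w for BSA).
    """

    name: str
    diamagnetic_baseline: BaselineModel
    specific_dispersion: BaselineModel
    concentration: float
    quadrupolar: Optional[QuadrupolarPeakSet] = None
    concentration_units: str = ""

    def r1(self, field_T=None, frequency_Hz=None):
        """R1 in s^-1 at the given field (T) or frequency (Hz)."""
        f = _as_freq(field_T, frequency_Hz)
        out = np.asarray(self.diamagnetic_baseline.r1(f), dtype=float)
        out = out + self.concentration * np.asarray(self.specific_dispersion.r1(f))
        if self.quadrupolar is not None:
            out = out + self.concentration * np.asarray(self.quadrupolar.r1(f))
        return float(out) if out.ndim == 0 else out

    def t1(self, field_T=None, frequency_Hz=None):
        """T1 = 1/R1 in seconds."""
        return 1.0 / self.r1(field_T=field_T, frequency_Hz=frequency_Hz)

    def at_concentration(self, c: float) -> "TissueDispersionModel":
        """Same material at a different concentration (shape preserved)."""
        return replace(self, concentration=float(c))


def r1_at(model: TissueDispersionModel, field_T=None, frequency_Hz=None):
    """Functional alias for :meth:`TissueDispersionModel.r1`."""
    return model.r1(field_T=field_T, frequency_Hz=frequency_Hz)


# ---------------------------------------------------------------------------
# Reference library for the seven-bottle phantom.
#
# The bottle phantom holds MnCl2 solutions at 0.38, 0.52, 0.74 and 1.00 mM
# and cross-linked BSA gels at 5, 10 and 20 % w/w.  The parameter values
# below are frozen phenomenological fixtures (two-term Lorentzian for the
# paramagnetic MnCl2 contribution; shallow power law plus quadrupolar peaks
# for immobilised protein), chosen to give realistic T1 ranges and shapes;
# they are fixtures of this package, not literature relaxivities.
# ---------------------------------------------------------------------------

_WATER_BASELINE = LorentzianDispersionModel(r1_offset=0.28, terms=((0.08, 2e-9),))

#: Per-mM MnCl2 contribution: dispersion steps at ~100 ns and ~5 ns, spread
#: so the profile is close to log-log linear across the imaging band (the
#: smooth-dispersion shape the quadrupolar-peak feature must not flag).
_MNCL2_SPECIFIC = LorentzianDispersionModel(r1_offset=3.0, terms=((12.0, 1e-7), (12.0, 5e-9)))

#: BSA gel baseline (water + formaldehyde), almost flat.
_BSA_BASELINE = PowerLawModel(a=0.65, b=-0.04)

#: Per-% w/w BSA contribution: shallow power law (b < 0).
_BSA_SPECIFIC = PowerLawModel(a=1.6, b=-0.16)

MNCL2_CONCENTRATIONS_MM = (0.38, 0.52, 0.74, 1.00)
BSA_CONCENTRATIONS_PCT = (5.0, 10.0, 20.0)


def _mncl2(c: float) -> TissueDispersionModel:
    return TissueDispersionModel(
        name=f"MnCl2 {c:g} mM",
        diamagnetic_baseline=_WATER_BASELINE,
        specific_dispersion=_MNCL2_SPECIFIC,
        concentration=c,
        quadrupolar=None,
        concentration_units="mM",
    )


def _bsa(c: float) -> TissueDispersionModel:
    return TissueDispersionModel(
        name=f"BSA {c:g} % w/w",
        diamagnetic_baseline=_BSA_BASELINE,
        specific_dispersion=_BSA_SPECIFIC,
        concentration=c,
        quadrupolar=DEFAULT_BSA_PEAKS,
        concentration_units="% w/w",
    )


def phantom_reference_library():
    """Dispersion models for the seven-bottle phantom plus the references.

    Returns
    -------
    dict
        ``{"bottles": {name: model} (7 entries),
           "references": {"MnCl2": model at 0.74 mM, "BSA": model at 20 %}}``

    The four MnCl2 entries share an identical per-mM specific term and the
    three BSA entries an identical per-% term, so concentration only shifts
    each family's profile vertically.  Only the BSA entries carry a
    quadrupolar peak set.  Concentration of an unknown profile is estimated
    against the 0.74 mM MnCl2 or 20 % BSA reference.
    """
    bottles = {}
    for c in MNCL2_CONCENTRATIONS_MM:
        m = _mncl2(c)
        bottles[m.name] = m
    for c in BSA_CONCENTRATIONS_PCT:
        m = _bsa(c)
        bottles[m.name] = m
    references = {"MnCl2": _mncl2(0.74), "BSA": _bsa(20.0)}
    return {"bottles": bottles, "references": references}
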