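"""Field waveforms, protocol validation and longitudinal relaxation.

A fast field-cycling (FFC) acquisition switches the main field B0 between
three levels inside every repetition: a polarisation plateau that builds
longitudinal magnetisation, an evolution plateau at the field being probed,
and a detection plateau at the readout field where RF pulses are applied and
the spin echo is acquired.  Ramps between levels run at a fixed slew rate
(operationally 12 T/s; hard safety ceiling 20 T/s to avoid peripheral nerve
stimulation).

Longitudinal magnetisation is normalised so that equilibrium at the 0.2 T
maximum field equals 1; equilibrium at any field B is m0(B) = B / 0.2.  Its
evolution through an arbitrary piecewise-linear B0(t) obeys

    dMz/dt = (m0(B(t)) - Mz) / T1(B(t)),

solved in closed form on constant-field segments and by midpoint-exponential
sub-stepping on ramps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dispersion import TissueDispersionModel

__all__ = [
    "B_MAX",
    "B_MIN_EVOLUTION",
    "SLEW_CEILING",
    "FieldWaveform",
    "FFCProtocol",
    "MagnetisationState",
    "MagnetSpec",
    "build_ir_waveform",
    "validate_protocol",
    "ProtocolReport",
    "relax_mz",
    "ir_signal",
]

#: Maximum main field (T); magnetisation is normalised to equilibrium here.
B_MAX = 0.2
#: Lowest usable evolution field (T), ~ the Earth's field.
B_MIN_EVOLUTION = 50e-6
#: Hard slew ceiling (T/s), peripheral-nerve-stimulation safety limit.
SLEW_CEILING = 20.0
#: Evaluation floor for T1(B): dispersion models are clamped here near B=0.
B_EVAL_FLOOR = 50e-6


@dataclass(frozen=True)
class MagnetSpec:
    """Nominal electrical ratings of the resistive field-cycling magnet.

    Derived quantities used by the control software: the coil resistance
    implied by the drive point, and the field resolution of the 16-bit DAC
    that sets the field (with its Larmor-frequency equivalent).
    """

    drive_voltage: float = 55.9  # V at full field
    drive_current: float = 1950.0  # A at full field
    full_field: float = B_MAX  # T
    dac_bits: int = 16

    @property
    def resistance(self) -> float:
        """Coil resistance in ohms (V/I at the nominal drive point)."""
        return self.drive_voltage / self.drive_current

    @property
    def dac_step(self) -> float:
        """Field resolution of the DAC in tesla (full_field / 2**bits)."""
        return self.full_field / 2**self.dac_bits

    @property
    def dac_step_hz(self) -> float:
        """Larmor-frequency equivalent of one DAC step, in Hz."""
        from .dispersion import GAMMA_HZ_PER_T

        return GAMMA_HZ_PER_T * self.dac_step


@dataclass(frozen=True)
class FieldWaveform:
    """Piecewise-linear B0(t) given by ordered (time, field) breakpoints."""

    times: Tuple[float, ...]
    fields: Tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        b = np.asarray(self.fields, dtype=float)
        if t.ndim != 1 or t.shape != b.shape or t.size < 2:
            raise ValueError("need matching 1-D times/fields with >= 2 breakpoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if np.any(b < -1e-12) or np.any(b > B_MAX + 1e-12):
            raise ValueError(f"fields must lie in [0, {B_MAX}] T")
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "fields", tuple(b))

    @property
    def duration(self) -> float:
        return self.times[-1] - self.times[0]

    def field_at(self, t):
        """Linear interpolation of B0 at time(s) t (clamped at the ends)."""
        return np.interp(t, self.times, self.fields)

    def max_slew(self) -> float:
        t = np.asarray(self.times)
        b = np.asarray(self.fields)
        return float(np.max(np.abs(np.diff(b) / np.diff(t))))

    def segments(self):
        """Yield (t0, t1, b0, b1) per linear segment."""
        for i in range(len(self.times) - 1):
            yield self.times[i], self.times[i + 1], self.fields[i], self.fields[i + 1]

    def duty(self) -> float:
        """Time-averaged (B/B_MAX)^2 over the waveform.

        Resistive dissipation scales with I^2 and hence B^2, so this is the
        thermally relevant duty fraction: 1.0 for continuous full-field
        operation, 0.42 for continuous 0.13 T.
        """
        total = 0.0
        for t0, t1, b0, b1 in self.segments():
            # integral of (a + (b-a) s)^2 ds over [0,1] = (a^2 + a b + b^2)/3
            a, b = b0 / B_MAX, b1 / B_MAX
            total += (t1 - t0) * (a * a + a * b + b * b) / 3.0
        return total / self.duration


@dataclass(frozen=True)
class MagnetisationState:
    """Longitudinal magnetisation, normalised to equilibrium at B_MAX."""

    mz: float = 0.0

    @staticmethod
    def equilibrium(field_T: float) -> "MagnetisationState":
        return MagnetisationState(mz=field_T / B_MAX)


def m0(field_T):
    """Field-proportional equilibrium magnetisation, m0(B) = B / B_MAX."""
    return np.asarray(field_T) / B_MAX if np.ndim(field_T) else field_T / B_MAX


@dataclass(frozen=True)
class FFCProtocol:
    """Field-cycling spin-echo acquisition description.

    One repetition (per evolution field/time) is: ramp to the polarisation
    field, polarise; ramp to the detection field for the inversion pulse
    (short plateau); ramp to the evolution field and evolve; ramp back to the
    detection field, wait the stabilisation delay (field ringing dies out),
    then excite and acquire the echo.
    """

    polarisation_field: float = B_MAX
    polarisation_time: float = 0.5
    evolution_fields: Tuple[float, ...] = (0.002, 0.02, 0.2)
    evolution_times: Tuple[Tuple[float, ...], ...] = ((0.05, 0.1, 0.2, 0.4, 0.8, 1.6),) * 3
    detection_field: float = B_MAX
    slew_rate: float = 12.0
    stabilisation_delay: float = 0.015
    inversion_plateau: float = 0.002
    echo_time: float = 0.026
    repetition_time: float = 4.0
    matrix: Tuple[int, int] = (128, 128)
    fov: Tuple[float, float] = (0.4, 0.4)
    slice_thickness: float = 0.01

    def __post_init__(self):
        object.__setattr__(self, "evolution_fields", tuple(float(b) for b in self.evolution_fields))
        object.__setattr__(
            self,
            "evolution_times",
            tuple(tuple(float(t) for t in ts) for ts in self.evolution_times),
        )
        if len(self.evolution_times) != len(self.evolution_fields):
            raise ValueError("need one evolution-time sequence per evolution field")


@dataclass
class ProtocolReport:
    ok: bool
    violations: List[str]
    duty: float


def _ramp_time(b0: float, b1: float, slew: float) -> float:
    return abs(b1 - b0) / slew


def build_ir_waveform(
    protocol: FFCProtocol,
    evolution_index: int,
    evolution_time: Optional[float] = None,
    detection_duration: Optional[float] = None,
):
    """Waveform and event times for one inversion-recovery repetition.

    Returns
    -------
    (FieldWaveform, dict)
        The B0(t) trajectory and an events dict with ``inversion_time``
        (middle of the short detection plateau carrying the 180 deg pulse)
        and ``excitation_time`` (end of the stabilisation delay, where the
        90 deg pulse plays and the echo phase starts).
    """
    p = protocol
    b_evo = p.evolution_fields[evolution_index]
    if evolution_time is None:
        evolution_time = p.evolution_times[evolution_index][0]
    if detection_duration is None:
        detection_duration = max(2 * p.echo_time, 0.01)
    slew = p.slew_rate

    times = [0.0]
    fields = [0.0]

    def seg(duration, b_end):
        if duration < 0:
            raise ValueError("infeasible timing: negative plateau duration")
        if duration > 0:
            times.append(times[-1] + duration)
            fields.append(b_end)

    seg(_ramp_time(0.0, p.polarisation_field, slew), p.polarisation_field)
    seg(p.polarisation_time, p.polarisation_field)
    seg(_ramp_time(p.polarisation_field, p.detection_field, slew), p.detection_field)
    inv_start = times[-1]
    seg(p.inversion_plateau, p.detection_field)
    inversion_time = inv_start + p.inversion_plateau / 2.0
    seg(_ramp_time(p.detection_field, b_evo, slew), b_evo)
    seg(evolution_time, b_evo)
    seg(_ramp_time(b_evo, p.detection_field, slew), p.detection_field)
    seg(p.stabilisation_delay, p.detection_field)
    excitation_time = times[-1]
    seg(detection_duration, p.detection_field)

    wf = FieldWaveform(times=tuple(times), fields=tuple(fields))
    events = {"inversion_time": inversion_time, "excitation_time": excitation_time}
    return wf, events


def validate_protocol(protocol: FFCProtocol) -> ProtocolReport:
    """Check a protocol against the scanner's physical limits.

    Fails when the slew rate exceeds the 20 T/s ceiling, any field is out of
    the [50 uT, 0.2 T] operating range, plateau timing is infeasible, or the
    time-averaged power duty (mean of (B/0.2)^2 over each repetition period)
    exceeds 50 % -- continuous operation is only thermally safe up to 0.13 T,
    where the duty is 42 %.
    """
    p = protocol
    violations = []
    if p.slew_rate > SLEW_CEILING:
        violations.append(f"slew rate {p.slew_rate} T/s exceeds the {SLEW_CEILING} T/s safety ceiling")
    if p.slew_rate <= 0:
        violations.append("slew rate must be positive")
    for name, b in (("polarisation", p.polarisation_field), ("detection", p.detection_field)):
        if not (0.0 <= b <= B_MAX + 1e-12):
            violations.append(f"{name} field {b} T outside [0, {B_MAX}] T")
    for b in p.evolution_fields:
        if not (B_MIN_EVOLUTION - 1e-12 <= b <= B_MAX + 1e-12):
            violations.append(f"evolution field {b} T outside [{B_MIN_EVOLUTION}, {B_MAX}] T")

    duties = []
    if not violations:
        for i in range(len(p.evolution_fields)):
            for t_evo in p.evolution_times[i]:
                try:
                    wf, _ = build_ir_waveform(p, i, evolution_time=t_evo)
                except ValueError as exc:
                    violations.append(str(exc))
                    continue
                if wf.duration > p.repetition_time + 1e-12:
                    violations.append(
                        f"waveform for field index {i}, t_evo {t_evo}: duration "
                        f"{wf.duration:.3f}s exceeds TR {p.repetition_time}s"
                    )
                    continue
                # idle remainder of TR sits at zero field
                duties.append(wf.duty() * wf.duration / p.repetition_time)
    duty = float(np.mean(duties)) if duties else float("nan")
    if duties and duty > 0.5 + 1e-9:
        violations.append(f"time-averaged power duty {duty:.1%} exceeds the 50% thermal limit")
    return ProtocolReport(ok=not violations, violations=violations, duty=duty)


def duty_of_constant_field(field_T: float) -> float:
    """Power duty of continuous operation at a fixed field."""
    return (field_T / B_MAX) ** 2


# ---------------------------------------------------------------------------
# Longitudinal relaxation through B0(t)
# ---------------------------------------------------------------------------


def _t1_of(model: TissueDispersionModel, b: float) -> float:
    return model.t1(field_T=max(b, B_EVAL_FLOOR))


def relax_mz(
    waveform: FieldWaveform,
    model: TissueDispersionModel,
    initial: MagnetisationState = MagnetisationState(0.0),
    inversion_events: Sequence[float] = (),
    db_step: float = 1e-3,
    dt_step: Optional[float] = None,
):
    """Propagate Mz through a field waveform with optional ideal inversions.

    On constant-field segments the closed-form exponential relaxation toward
    m0(B) is used.  On ramps the segment is split into sub-steps of at most
    ``db_step`` tesla (and ``dt_step`` seconds if given) and each sub-step is
    advanced with the exponential evaluated at its midpoint field, which is
    second-order accurate in the sub-step size.  An inversion event is an
    ideal instantaneous 180 deg pulse: Mz -> -Mz.  Dispersion models are
    evaluated no lower than 50 uT (the scanner's own field floor) so B = 0
    is well-defined.

    Returns
    -------
    (times, mz) : two 1-D arrays
        Mz sampled at every breakpoint, sub-step boundary and inversion
        event (the value immediately after the flip).
    """
    inv = sorted(float(t) for t in inversion_events)
    t_out = [waveform.times[0]]
    m_out = [initial.mz]
    mz = initial.mz
    inv_i = 0

    def advance_const(t0, t1, b):
        nonlocal mz, inv_i
        t = t0
        while inv_i < len(inv) and t <= inv[inv_i] <= t1:
            ti = inv[inv_i]
            mz = _step_const(mz, b, ti - t)
            mz = -mz
            t_out.append(ti)
            m_out.append(mz)
            t = ti
            inv_i += 1
        if dt_step is not None and t1 - t > dt_step:
            for te in np.arange(t + dt_step, t1, dt_step):
                mz = _step_const(mz, b, dt_step)
                t_out.append(float(te))
                m_out.append(mz)
                t = float(te)
        mz = _step_const(mz, b, t1 - t)
        t_out.append(t1)
        m_out.append(mz)

    def _step_const(m, b, dt):
        if dt <= 0:
            return m
        t1v = _t1_of(model, b)
        eq = m0(b)
        return eq + (m - eq) * math.exp(-dt / t1v)

    for t0, t1, b0, b1 in waveform.segments():
        if b0 == b1:
            advance_const(t0, t1, b0)
            continue
        n = max(1, int(math.ceil(abs(b1 - b0) / db_step)))
        if dt_step is not None:
            n = max(n, int(math.ceil((t1 - t0) / dt_step)))
        edges = np.linspace(t0, t1, n + 1)
        bs = np.linspace(b0, b1, n + 1)
        for k in range(n):
            bm = 0.5 * (bs[k] + bs[k + 1])
            mz = _step_const(mz, bm, edges[k + 1] - edges[k])
        t_out.append(t1)
        m_out.append(mz)

    return np.asarray(t_out), np.asarray(m_out)


def ir_signal(
    protocol: FFCProtocol,
    model: TissueDispersionModel,
    evolution_index: int,
    evolution_time: float,
    t2: float = 0.1,
    db_step: float = 1e-3,
) -> float:
    """Detected signed echo amplitude for one IR field-cycling repetition.

    The spin system starts fully relaxed at zero field, is polarised,
    inverted at the detection field, left to evolve at the selected
    evolution field for ``evolution_time``, returned to the detection field
    and excited after the stabilisation delay.  The detected amplitude is Mz
    at excitation weighted by the spin-echo T2 decay exp(-TE/T2).

    As ``evolution_time`` varies with everything else fixed, the result
    follows S(t) = S_inf + (S_0 - S_inf) exp(-t / T1(B_evo)) exactly, which
    is what per-voxel T1 fitting relies on.
    """
    wf, events = build_ir_waveform(protocol, evolution_index, evolution_time)
    t_arr, m_arr = relax_mz(
        wf,
        model,
        initial=MagnetisationState(0.0),
        inversion_events=[events["inversion_time"]],
        db_step=db_step,
    )
    # Mz at excitation = end of the stabilisation delay; the trajectory
    # samples every breakpoint, so interpolate at the excitation time.
    mz_exc = float(np.interp(events["excitation_time"], t_arr, m_arr))
    return mz_exc * math.exp(-protocol.echo_time / t2)
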