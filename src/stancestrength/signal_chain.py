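"""Emulation of the force-platform acquisition electronics.

The platform measures ground reaction force with triaxial strain-gauge
bridges.  Each axis produces a small differential voltage (~10 mV full
scale) that is amplified by an instrumentation amplifier with a mid-rail
offset, digitised by a 16-bit ADC, and converted to newtons with a
per-axis linear calibration (zero offset and gain factor).  This module
models the settled, ideal behaviour of that chain so that force <->
voltage <-> ADC conversions — and the device's printed sanity numbers
(LSB sizes, regulator resolution, amplifier gain) — are computable and
testable on a desk, without hardware.

The closed-loop supply regulation is modelled statically: only the
settled output values matter for the analysis, not the feedback
dynamics.  Rail saturation is reported as a flag, never an exception —
a genuine maximal effort may legitimately clip and the pipeline must
carry that fact along rather than die.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "RegulatorSpec",
    "AmplifierSpec",
    "AdcSpec",
    "CalibrationSpec",
    "SensorChainSpec",
    "VoltageTrace",
    "AmplifierOutput",
    "VoltageOutput",
    "SignalChainError",
    "regulator_vout",
    "regulation_resolution",
    "required_gain",
    "amplifier_out",
    "adc_lsb",
    "quantize",
    "voltage_to_force",
    "force_to_voltage",
    "calibrate",
    "DEFAULT_CHAIN",
]


class SignalChainError(ValueError):
    """Invalid electronics parameter or out-of-range signal."""


@dataclass(frozen=True)
class RegulatorSpec:
    """Adjustable LDO regulator feeding the sensor bridges.

    The output is set by two external resistors: V_OUT = V_REF * (1 + R2/R1).
    A PWM-driven trim loop keeps V_OUT inside ``v_out_range`` with
    ``pwm_counts`` steps per period.
    """

    v_ref_internal: float = 1.25  # volts
    r1: float = 240.0  # ohms
    r2: float = 1680.0  # ohms
    v_out_range: tuple[float, float] = (9.950, 10.050)  # volts
    pwm_counts: int = 1000

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise SignalChainError(f"r1 must be > 0, got {self.r1}")
        if self.r2 < 0:
            raise SignalChainError(f"r2 must be >= 0, got {self.r2}")
        lo, hi = self.v_out_range
        if not lo < hi:
            raise SignalChainError(f"v_out_range must be increasing, got {self.v_out_range}")
        if self.pwm_counts < 1:
            raise SignalChainError(f"pwm_counts must be >= 1, got {self.pwm_counts}")


@dataclass(frozen=True)
class AmplifierSpec:
    """Instrumentation amplifier stage: gain plus mid-rail offset."""

    gain: float = 360.0
    v_ref_offset: float = 1800.0  # mV, shifts bipolar signal onto single rail
    supply: float = 3600.0  # mV

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise SignalChainError(f"gain must be > 0, got {self.gain}")
        if not 0 <= self.v_ref_offset <= self.supply:
            raise SignalChainError(
                f"v_ref_offset {self.v_ref_offset} outside [0, {self.supply}] mV"
            )


@dataclass(frozen=True)
class AdcSpec:
    """Successive-approximation ADC: resolution in bits against a supply reference."""

    bits: int = 16
    noise_free_bits: int = 14
    supply: float = 3600.0  # mV

    def __post_init__(self) -> None:
        if not 1 <= self.noise_free_bits <= self.bits <= 32:
            raise SignalChainError(
                f"need 1 <= noise_free_bits <= bits <= 32, got "
                f"({self.noise_free_bits}, {self.bits})"
            )
        if self.supply <= 0:
            raise SignalChainError(f"supply must be > 0, got {self.supply}")


@dataclass(frozen=True)
class CalibrationSpec:
    """Per-axis linear force calibration: F = (ADC_mV - zero_offset) * gain_factor."""

    zero_offset: float = 1800.0  # mV at zero force
    gain_factor: float = 0.4  # N per mV
    supply: float = 3600.0  # mV, for range checks

    def __post_init__(self) -> None:
        if self.gain_factor <= 0:
            raise SignalChainError(f"gain_factor must be > 0, got {self.gain_factor}")
        if not 0 <= self.zero_offset <= self.supply:
            raise SignalChainError(
                f"zero_offset {self.zero_offset} outside ADC range [0, {self.supply}] mV"
            )


@dataclass(frozen=True)
class SensorChainSpec:
    """All electronics constants of the acquisition chain, with device defaults."""

    regulator: RegulatorSpec = field(default_factory=RegulatorSpec)
    amplifier: AmplifierSpec = field(default_factory=AmplifierSpec)
    adc: AdcSpec = field(default_factory=AdcSpec)
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    fs: float = 1400.0  # Hz

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SensorChainSpec":
        d = json.loads(text)
        reg = dict(d.get("regulator", {}))
        if "v_out_range" in reg:
            reg["v_out_range"] = tuple(reg["v_out_range"])
        return cls(
            regulator=RegulatorSpec(**reg),
            amplifier=AmplifierSpec(**d.get("amplifier", {})),
            adc=AdcSpec(**d.get("adc", {})),
            calibration=CalibrationSpec(**d.get("calibration", {})),
            fs=float(d.get("fs", 1400.0)),
        )


DEFAULT_CHAIN = SensorChainSpec()


@dataclass
class VoltageTrace:
    """Conditioned per-axis voltages (mV) sampled uniformly at ``fs``."""

    fs: float
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SignalChainError(f"fs must be > 0, got {self.fs}")
        self.fx = np.asarray(self.fx, dtype=float)
        self.fy = np.asarray(self.fy, dtype=float)
        self.fz = np.asarray(self.fz, dtype=float)
        if not (len(self.fx) == len(self.fy) == len(self.fz)):
            raise SignalChainError("voltage channels must have equal length")


class AmplifierOutput(NamedTuple):
    mv: float
    saturated: bool


class VoltageOutput(NamedTuple):
    mv: float
    saturated: bool


def regulator_vout(spec: RegulatorSpec) -> float:
    """Settled regulator output in volts: V_REF * (1 + R2/R1)."""
    return spec.v_ref_internal * (1.0 + spec.r2 / spec.r1)


def regulation_resolution(v_low: float, v_high: float, steps: int) -> float:
    """Voltage step (volts) of a trim loop spanning [v_low, v_high] in ``steps`` counts."""
    if steps < 1:
        raise SignalChainError(f"steps must be >= 1, got {steps}")
    if not v_high > v_low:
        raise SignalChainError(f"need v_high > v_low, got ({v_low}, {v_high})")
    return (v_high - v_low) / steps


def required_gain(full_scale_out_mv: float, full_scale_in_mv: float) -> float:
    """Amplifier gain needed to map a full-scale input onto a full-scale output.

    The bridge's ~10 mV useful signal must fill the ADC's input range,
    e.g. 3600 mV / 10 mV = 360.
    """
    if full_scale_in_mv <= 0 or full_scale_out_mv <= 0:
        raise SignalChainError("full-scale voltages must be > 0")
    return full_scale_out_mv / full_scale_in_mv


def amplifier_out(v_plus: float, v_minus: float, spec: AmplifierSpec) -> AmplifierOutput:
    """Instrumentation-amplifier output: G*(V+ - V-) + V_REF, clipped to the rails.

    Saturation is flagged, not raised: a maximal effort may clip legitimately.
    """
    raw = spec.gain * (v_plus - v_minus) + spec.v_ref_offset
    clipped = min(max(raw, 0.0), spec.supply)
    # at or beyond a rail is indistinguishable from clipping -> flag it
    return AmplifierOutput(mv=clipped, saturated=(raw >= spec.supply or raw <= 0.0))


def adc_lsb(spec: AdcSpec, use_noise_free: bool = False) -> float:
    """ADC step size in mV: supply / 2**bits (or noise-free bits if flagged)."""
    bits = spec.noise_free_bits if use_noise_free else spec.bits
    return spec.supply / (2**bits)


def quantize(voltage_mv: float, spec: AdcSpec, use_noise_free: bool = False) -> float:
    """Round a conditioned voltage to the nearest ADC grid point (k * LSB)."""
    if not 0.0 <= voltage_mv <= spec.supply:
        raise SignalChainError(
            f"voltage {voltage_mv} mV outside ADC range [0, {spec.supply}] mV"
        )
    lsb = adc_lsb(spec, use_noise_free=use_noise_free)
    return round(voltage_mv / lsb) * lsb


def voltage_to_force(adc_mv: float | np.ndarray, cal: CalibrationSpec) -> float | np.ndarray:
    """Convert a conditioned ADC voltage (mV) to force in newtons.

    F = (ADC_mV - zero_offset) * gain_factor; the sign distinguishes
    tension (positive) from compression (negative).
    """
    return (np.asarray(adc_mv, dtype=float) - cal.zero_offset) * cal.gain_factor


def force_to_voltage(force_n: float, cal: CalibrationSpec) -> VoltageOutput:
    """Inverse calibration used by the simulator: newtons -> conditioned mV.

    Exact inverse of :func:`voltage_to_force` before quantization.  A result
    outside [0, supply] is clipped and flagged as saturated.
    """
    raw = force_n / cal.gain_factor + cal.zero_offset
    clipped = min(max(raw, 0.0), cal.supply)
    return VoltageOutput(mv=clipped, saturated=(raw != clipped))


def calibrate(
    unloaded_mv: Sequence[float],
    loaded_mv: Sequence[float],
    known_force: float,
    supply: float = 3600.0,
) -> CalibrationSpec:
    """Derive a per-axis calibration from an unloaded and a known-load recording.

    zero_offset is the unloaded mean; gain_factor maps the voltage step to
    the known reference force.  Manufacturing spread makes both per-axis
    quantities, which is why each bridge is calibrated independently.
    """
    unloaded = np.asarray(unloaded_mv, dtype=float)
    loaded = np.asarray(loaded_mv, dtype=float)
    if unloaded.size == 0 or loaded.size == 0:
        raise SignalChainError("calibration traces must be non-empty")
    if known_force <= 0:
        raise SignalChainError(f"known_force must be > 0, got {known_force}")
    zero = float(unloaded.mean())
    delta = float(loaded.mean()) - zero
    if delta == 0.0:
        raise SignalChainError("degenerate calibration: loaded mean equals unloaded mean")
    return CalibrationSpec(zero_offset=zero, gain_factor=known_force / delta, supply=supply)


def voltage_trace_to_force(trace: VoltageTrace, cal: CalibrationSpec) -> dict[str, np.ndarray]:
    """Batch conversion of a conditioned voltage trace to per-axis forces (N).

    Realises the device's acquisition loop (read -> convert -> emit) as a
    pure batch function over the recorded samples.
    """
    return {
        axis: voltage_to_force(getattr(trace, axis), cal)
        for axis in ("fx", "fy", "fz")
    }
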