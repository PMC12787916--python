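"""Acquisition-chain arithmetic: supply regulation, amplification, ADC, calibration.

Recomputes the platform's electronics constants from first principles and
demonstrates the force <-> voltage <-> ADC round trip.
"""

from stancestrength import signal_chain as sc

reg = sc.RegulatorSpec()  # 1.25 V reference, R1 = 240 ohm, R2 = 1680 ohm
print(f"bridge supply V_OUT             : {sc.regulator_vout(reg):.2f} V")
print(f"trim resolution over [9.95,10.05]: "
      f"{sc.regulation_resolution(9.950, 10.050, 1000) * 1e6:.0f} uV/step")
print(f"required amplifier gain (10 mV -> 3.6 V): {sc.required_gain(3600, 10):.0f}x")

adc = sc.AdcSpec(bits=16, noise_free_bits=14, supply=3600.0)
print(f"16-bit LSB at 3.6 V supply      : {sc.adc_lsb(adc):.4f} mV")
print(f"14-bit (noise-free) LSB         : {sc.adc_lsb(adc, use_noise_free=True):.4f} mV")

# calibrate one axis against a 10 kg reference weight (98.1 N)
cal = sc.calibrate(unloaded_mv=[1800.2] * 100, loaded_mv=[2050.6] * 100, known_force=98.1)
print(f"calibration: zero {cal.zero_offset:.1f} mV, gain {cal.gain_factor:.4f} N/mV")

force = 403.5  # a sustained maximal pull, in newtons
mv = sc.force_to_voltage(force, cal)
recovered = sc.voltage_to_force(sc.quantize(mv.mv, adc), cal)
print(f"{force} N -> {mv.mv:.3f} mV -> ADC grid -> {recovered:.3f} N "
      f"(error {abs(recovered - force) * 1e3:.2f} mN, bound "
      f"{cal.gain_factor * sc.adc_lsb(adc) / 2 * 1e3:.2f} mN)")
# The round-trip error never exceeds gain_factor * LSB / 2: the digitisation
# step, not the arithmetic, limits force resolution.
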