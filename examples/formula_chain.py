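"""From raw pulse transit times to all five stiffness indexes.

A subject with a 1.30 m aortic-valve-to-ankle path, transit times
tb = 60 ms and tba = 100 ms, and brachial pressures 140/80 mmHg.
"""

from cavikit import (
    HemoConstants,
    PressurePair,
    WaveTiming,
    cavi0_from_cavi,
    stiffness_from_timing,
)

timing = WaveTiming(path_length=1.30, tb=0.060, tba=0.100)
pressures = PressurePair(sbp=140.0, dbp=80.0)
constants = HemoConstants()  # a=1, b=0: raw Bramwell-Hill beta scale

out = stiffness_from_timing(timing, pressures, constants)
print(f"haPWV  = {out.pwv:.3f} m/s   (path / (tb + tba))")
print(f"beta   = {out.beta:.3f}      (Bramwell-Hill stiffness)")
print(f"CAVI   = {out.cavi:.3f}      (a*beta + b)")
print(f"beta0  = {out.beta0:.3f}      (beta - ln(DBP/100))")
print(f"CAVI0  = {out.cavi0:.3f}      (2*rho*PWV^2/DBP - ln(DBP/100))")

# A CAVI measured by a device with unknown (a, b) converts to the same
# CAVI0 as the direct formula, because the conversion undoes the scaling.
scaled = HemoConstants(scale_a=0.7, offset_b=3.0)
cavi_device = 0.7 * out.beta + 3.0
print(f"converted CAVI0 from device-scaled CAVI: "
      f"{cavi0_from_cavi(cavi_device, pressures, scaled):.3f} (identical)")
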