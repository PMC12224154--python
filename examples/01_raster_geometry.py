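"""Raster-scan geometry: pulse pitch, spot overlap and washout check.

The laser rasters the gel in flyback mode; the stage speed and repetition
rate set the distance between pulses (the map pixel pitch), and the
inter-pulse interval must exceed the ablation-cell washout time or
particles smear into following pixels.
"""

from upcount import RasterPlan, check_washout, overlap_fractions, pulse_pitch

plan = RasterPlan(spot_diameter=30.0, scan_speed=150.0, repetition_rate=10.0,
                  line_spacing=15.0, area_width=1000.0, area_height=1000.0,
                  washout_time_ms=75.0)

pitch = pulse_pitch(plan)
along, between = overlap_fractions(plan)
diag = check_washout(plan)

print(f"pulse pitch:        {pitch:.1f} um  (map pixel size along the line)")
print(f"spot overlap:       {along:.0%} along the line, {between:.0%} between lines")
print(f"washout check:      {'pass' if diag.passed else 'WARN'} - {diag.message}")
print(f"lines / duration:   {plan.n_lines} lines, {plan.total_duration_s:.0f} s schedule")

# At 150 um/s and 10 Hz the pulses fall 15 um apart, so with 15 um line
# spacing the count map has 15 x 15 um pixels, and the 100 ms between
# pulses comfortably exceeds the ~75 ms cell washout.
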