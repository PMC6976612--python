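"""Calibrate a display and estimate viewing distance from blind-spot sweeps.

A participant matched the on-screen card image to a physical credit
card at 342.4 px, and five sweep trials logged the dot offsets below.
The script prints the display's logical pixel density, the mean
fixation-to-blind-spot offset, and the derived viewing distance.
"""

from vchinrest import BlindspotTrial, backsolve_alpha, compute_lpd, estimate_distance

cal = compute_lpd(card_image_width_px=342.4)
print(f"logical pixel density: {cal.lpd:.3f} px/mm "
      f"(card image {cal.card_image_width_px} px over 85.60 mm)")

# five keypress offsets, px (roughly a 50 cm seat with a little noise)
offsets_px = [509.3, 512.1, 505.8, 514.6, 508.2]
trials = [BlindspotTrial(disappear_offset_px=o) for o in offsets_px]

result = estimate_distance(trials, cal, alpha_deg=13.5)
print(f"mean on-screen offset s = {result.s_mm:.1f} mm over {result.n_trials} sweeps")
print(f"estimated viewing distance d = s / tan(13.5 deg) = {result.d_mm / 10:.1f} cm")

# validation-style arithmetic: if the true distance had been fixed at
# 53 cm by a chinrest, the sweeps imply this blind-spot entry angle:
print(f"entry angle if d were exactly 53 cm: "
      f"{backsolve_alpha(530.0, result):.2f} deg")
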