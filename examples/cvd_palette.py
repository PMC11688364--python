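"""Colour-vision-deficiency simulation on a display palette.

Applies the shipped severity-1.0 deuteranopia matrix to a few panel
colours.  The transform runs in linear RGB (sRGB decode -> 3x3 matrix ->
sRGB encode, clipped to gamut); red/green pairs collapse toward similar
hues, which is exactly what an experimenter must check before relying on a
red "failure" light.
"""

from matbsim import ColorProfile, apply_cvd

profile = ColorProfile(cvd_mode="deutan")
palette = {
    "light_on (red)": (0.90, 0.10, 0.10),
    "light_off (green)": (0.10, 0.80, 0.10),
    "fuel (amber)": (0.95, 0.75, 0.10),
    "panel (grey)": (0.50, 0.50, 0.50),
}
print(f"{'element':<20}{'original':>22}{'deutan-simulated':>24}")
for name, rgb in palette.items():
    out = apply_cvd(rgb, profile)
    print(f"{name:<20}" + f"({rgb[0]:.2f}, {rgb[1]:.2f}, {rgb[2]:.2f})".rjust(22)
          + f"({out[0]:.2f}, {out[1]:.2f}, {out[2]:.2f})".rjust(24))
print("\nNote how the red and green lights converge: a deutan observer would")
print("see both as muddy yellows, so state must also be coded by position.")
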