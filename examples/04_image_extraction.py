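"""Round-trip a profile through a rendered image and ROI extraction.

Renders a synthetic wild-type ptc-lacZ profile as a noisy 2-D image,
extracts the column-mean profile from a rectangular ROI (the manual
rectangle-averaging workflow), and landmarks the reporter rise and peak.
"""

from hhquant import CH_PTC, extract_profile, find_landmarks, render_image, simulate_profile, smooth
from hhquant.datatypes import APProfile
from hhquant.simulate import GENOTYPES, SimParams

params = SimParams(noise_sd_frac=0.0, offset_sd=0.0, scale_sd_frac=0.0)
profile = simulate_profile(params, GENOTYPES["WT"])

image = render_image(profile, CH_PTC, height=120, noise_sd_frac=0.1, seed=1)
print(f"rendered image: {image.shape[0]} x {image.shape[1]} pixels")

extracted = extract_profile(image, (0, 10, image.shape[1], 100), channel=CH_PTC)
smoothed = APProfile("roi", "WT", extracted.x, {CH_PTC: smooth(extracted.channels[CH_PTC], 5)})
lm = find_landmarks(smoothed)

# extracted positions are pixel column indices; column i holds position x[i]
to_um = lambda px: profile.x[int(px)]
print(f"reporter baseline  : {lm.baseline:6.1f} a.u.")
print(f"initial rise at    : {to_um(lm.x_rise):6.1f} um")
print(f"50% rise at        : {to_um(lm.x_half):6.1f} um")
print(f"peak at            : {to_um(lm.x_peak):6.1f} um (the AP compartment boundary)")
print(
    "\nAveraging 100 pixel rows suppresses the 10% per-pixel noise, so the"
    "\nlandmarks match the noise-free generating profile to about a grid step."
)
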