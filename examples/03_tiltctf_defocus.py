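"""Defocus-gradient-compensated CTF estimation on a tilted micrograph.

Simulates a 45-degree-tilted micrograph (defocus varies linearly across the
image, perpendicular to the tilt axis), then fits defocus from a plain
tile-averaged power spectrum and from the gradient-compensated spectrum.
Compensation rescales each tile's frequency axis so its Thon rings land at
the reference defocus before averaging; it also determines the geometric
handedness (which side of the tilt axis is closer to focus).
"""

from dataclasses import replace

from tomokit.ctf import (
    CtfParams,
    TiltGeometry,
    determine_handedness,
    fit_defocus,
    tilt_compensated_ps,
)
from tomokit.synthetic import simulate_ctf_micrograph

TRUE_DEFOCUS = 26000.0  # A (2.6 um underfocus) at the tilt axis
params = CtfParams(voltage=300, cs=2.7, amplitude_contrast=0.07, pixel_size=3.0,
                   defocus=TRUE_DEFOCUS)
geometry = TiltGeometry(tilt_angle=45.0, handedness=1)

image = simulate_ctf_micrograph((1024, 1024), params, geom=geometry, seed=5,
                                strip_width=32)

fit_p = replace(params, defocus=0.0)
ps_plain = tilt_compensated_ps(image, TiltGeometry(tilt_angle=0.0), params,
                               tile=256, defocus_ref=25000.0)
plain = fit_defocus(ps_plain, fit_p, search_range=(15000, 40000),
                    search_step=200)
ps_comp = tilt_compensated_ps(image, geometry, params, tile=256,
                              defocus_ref=plain.defocus)
comp = fit_defocus(ps_comp, fit_p, search_range=(15000, 40000),
                   search_step=200)

print(f"true defocus at the tilt axis: {TRUE_DEFOCUS:.0f} A")
print(f"plain tile average:        {plain.defocus:8.0f} A  (score {plain.score:.3f})")
print(f"gradient-compensated:      {comp.defocus:8.0f} A  (score {comp.score:.3f})")

hand = determine_handedness([image], [geometry], params, tile=256,
                            defocus_ref=plain.defocus,
                            search_range=(15000, 40000), search_step=200)
print(f"handedness: {hand.handedness:+d}  "
      f"(score +1: {hand.score_positive:.3f}, score -1: {hand.score_negative:.3f})")
print("\nThe compensated fit scores markedly higher: the tilt smears Thon")
print("rings in a plain average, and compensation restores them.")
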