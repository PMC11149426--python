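"""Muscle micro-stimulation: does the plant implement Listing's law?

Applies a Gaussian command pulse (21 ms full width at half maximum) to the
lateral or medial rectus while the eye holds fixations at 13 different
vertical eccentricities, and regresses the accumulated cyclo-torsion on the
initial elevation.  If the plant's mechanics implemented Listing's law the
torsion would be position-independent (zero slope); instead it grows
linearly with eccentricity, with opposite signs for the two muscles -- the
plant alone does not encode the law, the motor commands must.
"""

from bioeye import StimulationConfig, default_plant
from bioeye.experiments import stimulate_muscle

plant = default_plant()
for muscle in ("LR", "MR"):
    res = stimulate_muscle(StimulationConfig(muscle=muscle, amplitude=6.0),
                           plant)
    print(f"{muscle}: delta_r_x = {res.slope:+.3f} * r_y(0) "
          f"{res.intercept:+.4f}   (r2 = {res.r2:.3f})")
print("opposite slopes + high r2: stimulation-induced torsion is linear in")
print("the initial eccentricity and violates Listing's law, so the law is")
print("implemented by the learned commands, not by the plant mechanics.")
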