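"""Devereux LV mass, LV mass index and LVH classification.

Computes LV mass from M-mode echocardiographic dimensions (cm), indexes it
by height squared (g/m^2) and applies the sex-specific LVH cut-offs
(female > 110, male > 125 g/m^2, strictly exceeded).
"""
from rarecnv import EchoMeasurements, compute_lv_mass, compute_lvmi, classify_lvh
from rarecnv.phenotype import lvh_label

patients = [
    ("hypertensive man, thickened walls", "male", EchoMeasurements(lvidd=5.6, pwtd=1.45, ivstd=1.45, height=1.60)),
    ("hypertensive man, normal walls", "male", EchoMeasurements(lvidd=4.9, pwtd=0.88, ivstd=0.92, height=1.62)),
    ("hypertensive woman, borderline", "female", EchoMeasurements(lvidd=5.1, pwtd=1.10, ivstd=1.10, height=1.55)),
]

print(f"{'description':38s} {'LV mass (g)':>12s} {'LVMI (g/m2)':>12s}  status")
for desc, sex, echo in patients:
    mass = compute_lv_mass(echo)
    lvmi = compute_lvmi(mass, echo.height)
    status = lvh_label(classify_lvh(lvmi, sex))
    print(f"{desc:38s} {mass:12.1f} {lvmi:12.1f}  {status}")

print(
    "\nLV mass = 0.8*{1.04*[(LVIDD+PWTD+IVSTD)^3 - LVIDD^3]} + 0.6 g; LVMI =\n"
    "mass/height^2. A subject is LVH only when LVMI strictly exceeds the\n"
    "sex-specific threshold."
)
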