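"""The hydrogen-bond energy model.

Evaluates the bond energy as a function of the hydrogen–acceptor
distance with ideal (unit) angular scale factors, and shows how the two
piecewise-linear angle ramps attenuate it.  The energy plateaus at the
25 kJ/mol optimum up to 2.1 Å, falls linearly to zero at 2.6 Å, and a
bond only counts when the scaled energy exceeds 6.25 kJ/mol (25% of the
optimum) — which with ideal geometry happens below 2.475 Å.
"""

from gagnet import HBondCriteria, hbond_energy, scale_factor

criteria = HBondCriteria()
print("distance (A) -> energy (kJ/mol), ideal geometry")
for d in (1.6, 2.1, 2.35, 2.475, 2.6):
    marker = " <- detection threshold" if abs(d - 2.475) < 1e-9 else ""
    print(f"  {d:5.3f} -> {hbond_energy(d, 1, 1, criteria):6.2f}{marker}")

print("\ndonor-H-acceptor angle -> scale factor (ramp 100-165 deg)")
for angle in (100, 132.5, 165, 180):
    print(f"  {angle:6.1f} -> {scale_factor(angle, *criteria.dha_ramp):.2f}")

e = hbond_energy(1.8, scale_factor(150, *criteria.dha_ramp),
                 scale_factor(120, *criteria.hax_ramp), criteria)
print(f"\nbent bond at 1.8 A (DHA 150 deg, HAX 120 deg): {e:.2f} kJ/mol")
print("the product of the two ramps scales the plateau energy down")
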