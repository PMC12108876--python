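"""Which corrective load dominates at a given Cobb angle?

Compares the apex bending moments of axial traction (P (d/2) sin(theta/2))
and the lateral three-point load ((Q/2)(d/2) cos(theta/2)) and prints the
crossover angle where they are equal.
"""

from scolibeam import CobbGeometry, crossover_angle, dominant_load

P = Q = 200.0  # N, equal magnitudes
d = 0.196  # chord between end vertebrae, m

for theta in (20.0, 40.0, 53.13, 70.0, 90.0):
    cmp_ = dominant_load(P, Q, CobbGeometry(theta_deg=theta, d=d))
    print(
        f"Cobb {theta:6.2f} deg: M_P = {cmp_.M_P:6.3f} N·m, "
        f"M_Q = {cmp_.M_Q:6.3f} N·m  ->  {cmp_.dominant}"
    )

print(f"\ncrossover at equal loads: {crossover_angle(P, Q):.2f} deg")

# Below ~53 deg the lateral load is the stronger corrective lever; above
# it axial traction wins — so milder curves favour lateral correction and
# severe curves favour traction, independent of the chord length d.
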