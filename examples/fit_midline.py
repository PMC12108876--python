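"""Fit the initial lateral-displacement cubic to the bundled midline.

Reads the 29-point coronal midline of the reference patient, transforms
it to the midpoint-origin beam frame (metres), and fits the cubic
y0(x) = a3 x^3 + a2 x^2 + a1 x + a0 by ordinary least squares.
"""

from scolibeam import (
    curve_length,
    fit_initial_displacement,
    max_deviation,
    reference_midline,
    to_beam_frame,
)

curve = reference_midline()
dev, at = max_deviation(curve)
print(f"curve length: {curve_length(curve):.0f} mm")
print(f"max deviation: {dev:.2f} mm at X = {at:.0f} mm")

fit = fit_initial_displacement(to_beam_frame(curve))
a3, a2, a1, a0 = fit.profile.coefficients
print(f"y0(x) = {a3:.5f} x^3 + {a2:.5f} x^2 + {a1:.5f} x + {a0:.5f}  (SI)")
print(f"fit RMSE: {fit.rmse_m * 1000:.2f} mm over {fit.n_points} points")

# The coefficients describe the pre-treatment deviation: a0 is the lateral
# offset at the curve midpoint (~33 mm) and the odd terms capture the
# asymmetry of the apex, which sits superior to the midpoint.
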