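"""Plan the traction treatment for the reference patient.

Solves the inverse problem: what total axial load nulls the lateral
displacement at the assessment station, how does a lateral three-point
load reduce it, and how many 260 N sessions accumulate the total.
"""

from scolibeam import (
    BeamParameters,
    REFERENCE_PROFILE,
    load_from_body_weight,
    required_axial_load,
    sessions_required,
    total_load_at_angle,
    tradeoff_curve,
)

params = BeamParameters(EI=15.1, L=0.196, Li=0.042)
P_session = load_from_body_weight(65.0, 0.40)  # 40% body weight -> 260 N
Q_session = load_from_body_weight(65.0, 0.25)  # 25% body weight -> 162.5 N

P_req = required_axial_load(REFERENCE_PROFILE, params)
print(f"per-session loads: axial {P_session:.1f} N, lateral {Q_session:.1f} N")
print(f"required total axial load (Q = 0): {P_req:.0f} N")
print(f"sessions at {P_session:.0f} N each: {sessions_required(P_req, P_session)}")
print(f"total load if pulled at 30 deg: {total_load_at_angle(P_req, 30.0):.0f} N")

print("\naxial-lateral trade-off at the assessment station:")
for entry in tradeoff_curve(REFERENCE_PROFILE, params).entries:
    print(f"  Q = {entry[0]:6.1f} N  ->  P_required = {entry[1]:8.1f} N")

# The required load far exceeds what one session can apply, so the
# protocol accumulates it over ~136 sessions; every newton of lateral
# load shaves a little off the axial total.
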