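"""Size western-blot bands against a ladder and assign them to MW groups.

Fits log10(mass) ~ Rf over the marker lane, then reads two fiber lanes
through the curve: one with a single ~131 kDa band and one showing the
dominant slow-muscle combination of a ~131 kDa and a ~115.5 kDa band.
"""

from smybpc import (
    BandObservation,
    assign_bands,
    default_ladder,
    fit_standard_curve,
    mw_groups,
    rf_for_mass,
)

ladder = default_ladder()
curve = fit_standard_curve(ladder)
print(
    f"standard curve: log10(kDa) = {curve.intercept:.3f} {curve.slope:+.3f} x Rf, "
    f"R^2 = {curve.fit_r2:.4f}"
)

groups = mw_groups()
bands = [
    BandObservation("fiber_1", rf_for_mass(curve, 131.0)),
    BandObservation("fiber_2", rf_for_mass(curve, 131.0)),
    BandObservation("fiber_2", rf_for_mass(curve, 115.5)),
]
for result in assign_bands(bands, curve, groups):
    print(
        f"{result.band.lane_id}: Rf {result.band.rf:.3f} -> "
        f"{result.band.estimated_mass:.1f} kDa -> group {result.group_index} "
        f"(candidates: {', '.join(result.candidate_variants)})"
    )

# A ~131 kDa band cannot be resolved to a single variant on a 1-D gel; the
# group call carries the candidate set (v1/v5/v202 for group 1) instead.
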