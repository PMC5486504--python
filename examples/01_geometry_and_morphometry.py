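"""Build the two sac families and measure their clinical 2-D morphometry.

Prints height, neck width, aspect ratio (AR = height/neck) and the neck
classification: narrow-necked means AR >= 1.4 with a neck under 4 mm.
"""

from hemoshear import make_geometry, measure_morphology

shallow = make_geometry("hemispherical-bump", parent_caliber=3.24, sac_size=2.0)
deep = make_geometry(
    "circular-sac-with-neck", parent_caliber=3.24,
    neck_width=2.0, sac_size=2.0, sac_offset=2.0,
)

for name, geom in (("hemispherical bump", shallow), ("constricted-neck flask", deep)):
    m = measure_morphology(geom)
    print(
        f"{name:>24}: height {m.height:5.2f} mm, neck {m.neck_width:4.2f} mm, "
        f"AR {m.aspect_ratio:4.2f}, dome arc {m.dome_measure:5.2f} mm "
        f"-> {m.neck_category.value}-necked"
    )

# A hemispherical bump always has AR 0.5 (height = radius, neck = diameter),
# the canonical wide-necked sac; lifting a constricted-neck sac two radii
# off the wall doubles the AR to 2.0, a deep narrow-necked sac.
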