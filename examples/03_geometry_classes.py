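"""The three vertebrobasilar configuration classes and their measurement.

Builds one geometry per class (Walking, Tuning Fork, Lambda), classifies it
back, measures the confluence angle, and shows the laminar entrance-length
rule used for flow extensions.
"""

from vbsflow import (
    FluidProperties,
    build_class_geometry,
    classify_configuration,
    confluence_angle,
    extrude_flow_extensions,
)

fluid = FluidProperties()
for cls in ("Walking", "TuningFork", "Lambda"):
    g = build_class_geometry(cls)
    measured = classify_configuration(g)
    ang = confluence_angle(g)
    ext = extrude_flow_extensions(g, {"LV": 2e-6, "RV": 2e-6}, fluid)
    print(
        f"{cls:>11}: classified as {measured:>11}, confluence angle "
        f"{ang:5.1f} deg, inlet extension {ext.extension_lengths['LV']*1e3:5.1f} mm"
    )
print(
    "\nThe classifier uses only relative tangents and bend directions, so\n"
    "it is invariant to patient positioning (rigid motion and mirroring).\n"
    "Extensions follow the laminar development length 0.06 Re D with a\n"
    "3-diameter floor, evaluated at the peak systolic inflow."
)
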