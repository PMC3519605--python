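"""Steady hemodynamics of a subject fixture at peak systole.

Builds the subject-A confluence, solves steady flow at the peak systolic
inflows, and reports wall-shear statistics, the apex low-shear region, and
the axial-profile structure along the basilar artery.
"""

import numpy as np

from vbsflow import (
    FluidProperties,
    build_computational_domain,
    extrude_flow_extensions,
    generate_confluence_geometry,
    generate_vertebral_waveforms,
    make_subject_fixture,
    sample_cross_sections,
    solve_steady,
)
from vbsflow.hemodynamics import (
    low_wss_regions,
    velocity_profile_metrics,
    wall_shear_stress_series,
    time_averaged_wss,
)

fluid = FluidProperties()
fx = make_subject_fixture("A")
lv, rv = generate_vertebral_waveforms(fx)
i = int(np.argmax(lv.values + rv.values))
peak = {"LV": lv.values[i] * 1e-6, "RV": rv.values[i] * 1e-6}

geom = generate_confluence_geometry(fx)
ext = extrude_flow_extensions(geom, peak, fluid, policy="profile")
rmin = min(float(c.radius.min()) for c in ext.branches.values())
domain = build_computational_domain(ext, 2 * rmin / 6)
field = solve_steady(domain, peak, fluid)

series = wall_shear_stress_series([field], domain, fluid)
wss = time_averaged_wss(series)
valid = series.valid
regions = low_wss_regions(wss, domain, threshold=1.0, valid=valid)
apex_area = sum(r.area for r in regions if "apex-adjacent" in r.tags)

print(f"subject A ({fx.geometry_class}), peak inflows "
      f"{peak['LV']*1e6:.2f} + {peak['RV']*1e6:.2f} ml/s")
print(f"wall shear stress      : max {wss[valid].max():.2f} Pa, "
      f"mean {wss[valid].mean():.2f} Pa")
print(f"low-WSS (<1 Pa) regions: {len(regions)}, apex-adjacent area "
      f"{apex_area*1e6:.2f} mm^2")

bas = domain.geometry.branches["BAS"]
D = 2 * float(bas.radius.mean())
cs = sample_cross_sections(domain.geometry, "BAS",
                           [0.12 * D, 1.5 * D, 0.6 * bas.length])
for m in velocity_profile_metrics(field, cs):
    skew = "n/a" if m.skew_index is None else f"{m.skew_index:+.2f}"
    print(f"  station {m.station*1e3:5.1f} mm: {m.peak_count} peak(s), "
          f"outer-wall skew {skew}, peak velocity {m.peak_value:.2f} m/s")
print("\nA low-shear pocket at the junction crux and high shear on the outer")
print("wall of the basilar curve are the expected confluence signatures.")
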