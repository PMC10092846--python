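"""Compute nest volumes from raw museum-style dimension measurements.

Builds two measurement records — one complete, one inner-only — runs the
half-spheroid geometry and prints the derived volumes.
"""

from cupnest import geometry

records = [
    geometry.MeasurementRecord(
        species_id="Turdus_merula", source="museum",
        dimensions=geometry.NestDimensions(
            outer_diameters=[14.2, 13.8, 14.5, 14.0],  # cm, four around the rim
            outer_heights=[9.1, 8.9],
            inner_diameters=[9.0, 9.2, 8.8, 9.1],
            inner_heights=[6.0, 6.2]),
        site_label="NHM_1902"),
    geometry.MeasurementRecord(
        species_id="Regulus_regulus", source="literature",
        dimensions=geometry.NestDimensions(
            inner_diameters=[4.8], inner_heights=[4.0])),
]

table = geometry.add_volume_columns(records)
cols = ["species_id", "full_volume", "inner_volume", "outer_volume", "rim_thickness"]
print(table[cols].to_string(index=False))
print()
print("outer_volume is the shell of nest material (full minus inner cup, cm^3);")
print("the literature record reports only the inner cup, so the outer columns are empty.")

# literature tuples like "14 x 13 cm, depth 6" are interpreted by convention:
frag = geometry.interpret_dimension_tuple([14.0, 13.0], "by_or_x")
depth = geometry.interpret_dimension_tuple([6.0], "plain")
dims = frag.merge(depth)
print(f"\n'14 x 13, depth 6' -> outer diameters {dims.outer_diameters}, "
      f"outer height {dims.outer_heights}")
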