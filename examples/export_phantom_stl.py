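"""Export the calibration ring structures as printable STL meshes.

The physical calibration workflow starts from watertight solid models of
the ring sets; this writes both age-group structures and reports the mesh
properties a print-prep tool would check.
"""

import trimesh

import headcirc as hc

for group in ("0-3", "3-18"):
    rings = hc.nellhaus_ring_set(group)
    path = f"rings_{group}.stl"
    hc.export_stl(rings, path, sections=256)
    mesh = trimesh.load(path)
    extent = mesh.bounds[1] - mesh.bounds[0]
    print(
        f"group {group}: {len(rings)} rings, {len(mesh.faces)} facets, "
        f"watertight={mesh.is_watertight}, "
        f"footprint {extent[0]:.0f} x {extent[1]:.0f} mm, "
        f"height {extent[2]:.0f} mm -> {path}"
    )

# Each ring is an extruded annulus (5 mm tall, 3 mm wall) whose outer
# diameter is the target circumference divided by pi; the largest footprint
# matches the biggest ring's outer diameter.
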