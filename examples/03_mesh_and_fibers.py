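"""Tetrahedral meshing, anatomical surface derivation and fiber assignment.

Meshes the phantom segmentation with the conforming 6-tet voxel split,
derives the boundary-condition surfaces by set operations on tag
boundaries, assigns rule-based orthotropic fiber triads, and prints the
transmural helix-angle profile: approximately linear from +60 degrees at
the endocardium to -60 degrees at the epicardium.
"""

import numpy as np

from cardiomesh import (
    FiberConfig,
    PhantomSpec,
    assign_fibers,
    derive_bc_surfaces,
    helix_angle_profile,
    make_biventricular_phantom,
    mesh_from_label_image,
    mesh_quality,
)

spec = PhantomSpec(
    lv_outer_radii=(16.0, 16.0, 24.0), lv_wall_thickness=5.0,
    rv_outer_radii=(17.0, 15.0, 21.0), rv_wall_thickness=3.0,
    rv_center_offset=(12.0, 0.0, 2.0), spacing=1.0,
)
image, _ = make_biventricular_phantom(spec)
mesh = mesh_from_label_image(image)
q = mesh_quality(mesh)
print(
    f"mesh: {mesh.n_elements} tets / {mesh.n_nodes} nodes, "
    f"mean edge {q['mean_edge_mm']:.3f} mm, "
    f"min radius ratio {q['min_radius_ratio']:.3f}"
)

bc = derive_bc_surfaces(mesh)
print("derived surfaces (faces):",
      {name: len(fs) for name, fs in bc.as_dict().items()},
      f"apex node {bc.apex_node}")

fibers = assign_fibers(mesh, bc, FiberConfig(alpha_endo=60.0, alpha_epi=-60.0))
fibers.validate(atol=1e-7)
print(f"fiber triads assigned to {int(fibers.myocardial.sum())} myocardial elements")

profile = helix_angle_profile(mesh, fibers, n_bins=7)
print("transmural helix-angle profile (endo -> epi):")
for c, a, n in zip(profile["bin_centers"], profile["mean_angle_deg"], profile["count"]):
    print(f"  d={c:.2f}  alpha={a:+6.1f} deg   ({n} elements)")
# d is the harmonic transmural coordinate (0 endocardium, 1 epicardium);
# the mean angle per bin follows the configured linear rule.
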