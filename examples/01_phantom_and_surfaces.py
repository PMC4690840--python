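"""Generate the analytic biventricular phantom and extract its tagged surface.

Builds the reduced two-shell phantom at clinical (1 mm) resolution, runs
per-tag marching-tetrahedra extraction, merges redundant interfaces, and
prints the bookkeeping that the merge guarantees: each anatomical region is
a closed surface whose enclosed volume tracks its voxel count, and the
LV/RV interface appears exactly once, labelled with both tags.
"""

import numpy as np

from cardiomesh import PhantomSpec, extract_tag_surface, make_biventricular_phantom, merge_tag_surfaces
from cardiomesh.surface_extraction import check_closed_manifold, faces_for_tag, signed_volume

spec = PhantomSpec(
    lv_outer_radii=(16.0, 16.0, 24.0), lv_wall_thickness=5.0,
    rv_outer_radii=(17.0, 15.0, 21.0), rv_wall_thickness=3.0,
    rv_center_offset=(12.0, 0.0, 2.0), spacing=1.0,
)
image, surfaces = make_biventricular_phantom(spec)
print(f"phantom: {image.dims} voxels at {image.spacing[0]:g} mm")
for tag, name in sorted(image.tag_table.items()):
    print(f"  {tag} {name:8s} {image.count(tag):7d} voxels")

tags = sorted(set(np.unique(image.voxels).tolist()) - {0})
merged = merge_tag_surfaces([extract_tag_surface(image, t) for t in tags], image)
print(f"merged surface: {merged.n_vertices} vertices, {merged.n_faces} faces")

iface = (merged.face_labels[:, 0] == 1) & (merged.face_labels[:, 1] == 2)
print(f"LV/RV interface faces (collapsed to single copies): {int(iface.sum())}")

for tag in tags:
    tris = faces_for_tag(merged, tag)
    vol = signed_volume(merged.vertices, tris)
    vox = image.count(tag) * image.voxel_volume
    print(
        f"  tag {tag}: closed={check_closed_manifold(tris)}  "
        f"surface volume {vol:9.1f} mm^3 vs voxel volume {vox:9.1f} mm^3"
    )
# The surface volume sits slightly below the voxel volume because the
# marching rule cuts voxel corners; closedness per tag is what the
# rasterizer later relies on.
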