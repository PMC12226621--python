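"""Isolate the large veins from a combined vessel segmentation.

Merges the phantom's veins and arteries into one 'CTA vessel segmentation',
then recovers the vein subset with morphological opening + connected
components — the same preprocessing a real CTA segmentation would get
before anchoring the learned initialization.
"""

from angioreg.geometry import VolumeGrid
from angioreg.phantom import PhantomParams, generate_vessel_phantom
from angioreg.vessels import VeinIsolationParams, isolate_veins

veins, arteries = generate_vessel_phantom(PhantomParams(seed=7))
combined = VolumeGrid(values=(veins.values | arteries.values), voxel_to_world=veins.voxel_to_world)

params = VeinIsolationParams(opening_radius=1, min_component_size=200, keep_top_k=4)
isolated = isolate_veins(combined, params)

true_veins = veins.values.astype(bool)
got = isolated.values.astype(bool)
dice = 2 * (true_veins & got).sum() / (true_veins.sum() + got.sum())

print(f"combined mask: {int(combined.values.sum())} voxels "
      f"({int(veins.values.sum())} vein + {int(arteries.values.sum())} artery)")
print(f"after opening(r={params.opening_radius}) + top-{params.keep_top_k} components: "
      f"{int(got.sum())} voxels")
print(f"Dice overlap with the true vein mask: {dice:.3f}")
print("values near 1 mean the opening erased the thin arteries and kept the thick arcs.")
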