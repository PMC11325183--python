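"""Superpose a synthetic ensemble and project it into a PCA subspace.

Embeds two-well samples as displacements of a 20-atom structure, aligns
every frame onto the first (Kabsch), fits a 3-component PCA and prints the
spectrum.  The two wells differ along essentially one direction, so PC1
should carry most of the variance and separate the wells cleanly.
"""

import numpy as np

import welltree as wt

spec = wt.WellSpec(
    centers=[[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]],
    widths=[1.0, 1.0],
    weights=[0.5, 0.5],
    labels=("open", "closed"),
)
samples = wt.sample_gaussian_wells(spec, n=400, seed=5)
ensemble = wt.embed_in_ensemble(samples, n_atoms=20, seed=6)
aligned = wt.superpose_frames(ensemble, reference=0)

model = wt.fit_pca(aligned, k=3)
proj = wt.project(model, aligned)

print(f"frames: {aligned.n_frames}, atoms: {aligned.n_atoms}")
for i, ev in enumerate(model.eigenvalues, start=1):
    print(f"PC{i}: eigenvalue {ev:8.3f} nm^2  "
          f"explained ratio {ev / model.total_variance:.3f}")
print(f"top-3 cumulative explained ratio: {wt.explained_ratio(model, 3):.3f}")

pc1 = proj.points[:, 0]
open_pc1 = pc1[samples.well_assignment == 0]
closed_pc1 = pc1[samples.well_assignment == 1]
print(f"PC1 means: open {open_pc1.mean():+.2f} nm, "
      f"closed {closed_pc1.mean():+.2f} nm")
print("The 12 nm well separation dominates PC1; the remaining components")
print("carry only the isotropic within-well motion.")
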