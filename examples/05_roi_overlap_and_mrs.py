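"""Voxel-mask overlap, density thresholding, and MRS quality rules on
small synthetic grids (stand-ins for real spectroscopy voxels and an
fMRI cluster)."""

import numpy as np

from effortpath import MrsQC, density_map, mrs_filter_and_correct, \
    overlap_stats, roi_mean, threshold_density

rng = np.random.default_rng(0)

# synthetic spectroscopy voxel placements: a 4x4x4 cube jittered per
# subject inside a 12x12x12 grid
masks = []
for _ in range(20):
    m = np.zeros((12, 12, 12), bool)
    ox, oy, oz = rng.integers(3, 6, size=3)
    m[ox:ox + 4, oy:oy + 4, oz:oz + 4] = True
    masks.append(m)
dm = density_map(masks)
core = threshold_density(dm, cutoff=0.9)
print(f"voxels sampled in >=90% of subjects: {int(core.sum())}")

cluster = np.zeros((12, 12, 12), bool)
cluster[4:8, 4:8, 4:8] = True  # synthetic activation cluster
stats = overlap_stats(cluster, core)
print(f"cluster-in-core overlap: {stats['pct_a_in_b']:.1f}% "
      f"of the cluster, {stats['pct_b_in_a']:.1f}% of the core")

activity = rng.normal(size=(12, 12, 12)) + 2.0 * cluster
print(f"mean activity inside the core mask: "
      f"{roi_mean(activity, core):.3f}")

qc = mrs_filter_and_correct([
    MrsQC(crlb=0.08, fgm=0.6, fwm=0.25, fcsf=0.15, raw_concentration=1.1),
    MrsQC(crlb=0.62, fgm=0.5, fwm=0.3, fcsf=0.2, raw_concentration=0.9),
])
print("\nMRS records (CRLB > 50% excluded; survivors CSF-corrected):")
print(qc[["crlb", "raw", "corrected", "excluded"]].round(3).to_string())
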