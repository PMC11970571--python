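"""Extract the full 42-feature radiomic vector (plus ROI volume) from one
phantom image after the standard preprocessing chain.
"""

from radcorr import CohortSpec, collewet_resegment, extract_all, generate_cohort, lloyd_quantize
from radcorr.features import FEATURES

spec = CohortSpec(
    n_patients=1,
    grid_shape=(32, 32, 32),
    roi_radii_log_median_mm=(10.0, 8.0, 9.0),
    n_fiducials=0,
    seed=3,
)
pat = generate_cohort(spec)[0]
vol = pat.volumes["CT"]

cw = collewet_resegment(vol, pat.mask)
q = lloyd_quantize(vol, cw.mask, cw.value_range, n_levels=64)
features = extract_all(q, vol)

vn_names = {f.name for f in FEATURES if f.vn_type != 0}
print(f"{len(features)} outputs (42 features + volume); 7 are volume-normalized\n")
for name, value in features.items():
    tag = " (VN)" if name in vn_names else ""
    print(f"{name:20s} {value:14.6g}{tag}")
# Count-based features like GLRLM_RP lie in (0, 1]; the volume-normalized
# non-uniformities (GLN, RLN, ZSN) are per-voxel rates and therefore small.
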