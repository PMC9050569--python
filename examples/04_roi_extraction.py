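"""Extract node time series from a toy 4-D volume.

Embeds a simulated subject's node signals into a small volume with four
ROI masks, confound signals and motion, then runs the full extraction:
DCT-band F-map peak for M1, correlation-placed spheres for putamen and
thalamus, whole-mask eigenvariate for the STN.  The recovered series
should correlate strongly (r > 0.9) with the embedded generators.
"""

import numpy as np

from bgdcm import canonical_scenario, extract_all_nodes, make_toy_volumes, simulate_bold
from bgdcm.network import DCMParams

scenario = canonical_scenario()
subject = DCMParams.from_vector(scenario.mean_vector())
ts = simulate_bold(subject, scenario, seed=7)

vol, masks, motion, nuisance = make_toy_volumes(ts, seed=7)
print(f"toy volume {vol.data.shape[:3]} voxels x {vol.n_time} volumes; "
      f"masks: { {k: int(m.data.sum()) for k, m in masks.items()} }")

out, report = extract_all_nodes(vol, masks, motion, nuisance)
print(f"mean framewise displacement {report['fd_mean_mm']:.2f} mm, "
      f"{report['n_dct']} in-band cosine regressors\n")

print(f"{'node':<6}{'r(planted)':>11}{'var.expl.%':>12}  sphere centre")
for k in ("M1", "PUT", "STN", "THAL"):
    r = np.corrcoef(ts.node_series[ts.node_labels.index(k)],
                    out.node_series[out.node_labels.index(k)])[0, 1]
    nd = report["nodes"][k]
    print(f"{k:<6}{r:>11.3f}{nd['variance_explained_pct']:>12.1f}  "
          f"{nd['sphere_centre']}")
print("\nr(planted) is the correlation between the extracted eigenvariate"
      "\nand the signal embedded in that mask — the extraction fidelity.")
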