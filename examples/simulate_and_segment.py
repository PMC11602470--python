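"""Plant a connectivity switch in synthetic EEG and recover it with EDMCC.

Generates a 60 s gamma-band trial whose coupling motif changes at t = 30 s,
then segments the recording by network-structure change. The printed
boundaries should include one within a second of the true switch; other
boundaries are forced maximum-length splits.
"""

import mwnetdyn as mw

library = mw.make_state_library(n_states=4, n_channels=8, seed=1)
fl_spec, _ = mw.benchmark_condition_specs()

recording, truth = mw.simulate_trial(
    library, fl_spec, duration=60, band="gamma", rate=256, seed=7,
    forced_path=[(0.0, 30.0, 0), (30.0, 60.0, 1)],
)
segmentation = mw.segment(recording)

print(f"true switch at t = {truth.change_points[0]:.2f} s")
print(f"{segmentation.n_segments} segments:")
for start, end in segmentation.spans:
    near = "  <- boundary near the true switch" if abs(start - 30.0) <= 1.0 else ""
    print(f"  [{start:6.2f}, {end:6.2f}) s{near}")

# p_diff contrasts between-segment vs within-segment structure; the
# EDMCC-over-sliding ordering is a distribution-level property, so average it
from mwnetdyn.benchmarks import segmentation_recovery

bench = segmentation_recovery(n_seeds=5, seed=0)
print(f"mean p_diff over 5 switching trials: "
      f"EDMCC {bench['p_diff_edmcc']:.3f} vs 2 s sliding {bench['p_diff_sliding']:.3f}")
print("higher p_diff = segment boundaries align better with structure changes")
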