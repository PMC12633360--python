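"""Compute one subject's TW-dFC map on the synthetic phantom.

Generates a bilateral seed with planted subregions, streamlines wired to
distal targets, and state-switching BOLD; pre-processes the BOLD (6 mm FWHM
smoothing, 0.01-0.1 Hz bandpass); then computes the 4D track-weighted
dynamic FC map with the default Hamming window of 85 timepoints.
"""

import numpy as np

from twdfc import PhantomConfig, WindowSpec, make_cohort
from twdfc.pipeline import preprocess, subject_twdfc

cfg = PhantomConfig()  # 32x32x24 @ 2 mm, T=300, TR=0.72 s, 2 latent states
phantom, (subject,) = make_cohort(cfg, n_subjects=1, master_seed=42)

bold = preprocess(subject["bold"])
m = subject_twdfc(bold, subject["tractogram"], phantom.seed_mask,
                  spec=WindowSpec(width=85, stride=1, taper="hamming"))

traversed = np.any(np.isfinite(m.data), axis=3)
vals = m.data[traversed]
print(f"frames (windows)        : {m.n_windows}")
print(f"window duration         : {m.spec.duration_s(bold.tr):.1f} s")
print(f"voxels traversed        : {int(traversed.sum())}")
print(f"map range               : [{np.nanmin(vals):.3f}, {np.nanmax(vals):.3f}]")
print(f"mean |frame-to-frame dFC change| : "
      f"{np.nanmean(np.abs(np.diff(vals, axis=1))):.4f}")
print(f"degenerate windows      : {m.provenance['n_degenerate_windows']}")

# Each frame holds, per voxel, the average windowed endpoint correlation of
# the streamlines crossing it; the frame-to-frame change reflects the
# phantom's latent coupling-state switches.
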