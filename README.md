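# twdfc — track-weighted dynamic functional connectivity

`twdfc` is a Python library (with a thin `twdfc` command line) for studying
structure–function relationships between a seed region — typically the
hippocampus — and the rest of the brain.  It fuses a seed-restricted
tractogram (diffusion MRI fibre-tracking) with resting-state BOLD fMRI into
**track-weighted dynamic functional connectivity (TW-dFC)** maps, derives a
data-driven parcellation of the seed from those maps, and contrasts the
resting-state functional connectivity of the resulting clusters across
subjects.

## The method

Each streamline *s* of a seed-restricted tractogram has one endpoint in the
seed mask and one in a distal grey-matter region.  It is assigned a
*dynamic functional weighting*: the sliding-window, Hamming-tapered Pearson
correlation between the BOLD series at its two endpoint voxels,

    FC_s(w) = corr_w( x_seed, x_distal ),   w = 1 … N,  N = ⌊(T − W)/stride⌋ + 1,

computed inside window *w* of width *W* timepoints (default W = 85, i.e.
61.2 s at TR = 0.72 s) with the taper entering as weights in a weighted
Pearson coefficient.  The weighting is projected onto every voxel *v* the
streamline traverses; where several streamlines cross one voxel their
weightings are averaged:

    TWdFC(v, w) = Σ_{s ∋ v} ω_s · FC_s(w) / Σ_{s ∋ v} ω_s,

with ω_s = 1 by default or a per-streamline weight (e.g. SIFT2) on request.
The result is a 4D image that carries grey-matter dynamic FC onto the
white-matter pathways mediating it.

Downstream, the library implements the two study stages built on this map:

1. **Parcellation** — subjects' TW-dFC maps are temporally concatenated,
   decomposed with PCA + fixed-point spatial ICA (component count chosen to
   retain ≥ 98 % of variance), component z-maps are thresholded by a
   Gaussian-mixture posterior, seed voxels are k-means clustered on their
   component feature vectors (k ∈ {4, 6, 8}), and mirror-symmetric
   left/right clusters are merged into bilateral clusters A, B, C, …
2. **Group FC contrasts** — per subject, each bilateral cluster's mean BOLD
   series is correlated with every brain voxel (Pearson r, Fisher z); each
   ordered cluster pair (X > Y) is tested with a paired one-tailed t-test,
   corrected voxel-wise with Benjamini–Hochberg FDR per contrast, and the
   corrected q-values converted to z-scores thresholded at 1.645.

A first-class synthetic-phantom module generates the inputs this analysis
assumes — a bilateral seed with planted subregions, streamlines wired
subregion → target, and BOLD whose inter-regional coupling switches between
latent states — with full ground truth, so every stage is testable end to
end at desk scale.

## Worked example

`examples/` contains one short script per capability.  For instance,
computing a single subject's TW-dFC map on the phantom
(`python examples/02_twdfc_map.py`) prints

```
frames (windows)        : 216
window duration         : 61.2 s
voxels traversed        : 3417
map range               : [-0.798, 0.916]
mean |frame-to-frame dFC change| : 0.0083
degenerate windows      : 0
```

— 216 frames because T = 300 volumes with an 85-volume window at stride 1
gives 300 − 85 + 1 windows; map values are correlations in [−1, 1]; the
frame-to-frame change reflects the phantom's latent coupling-state
switches.  Parcellating a three-subject cohort
(`python examples/03_parcellation.py`) prints

```
variance retained by ICA : 98.3%
bilateral merge          : {5: 'A', 6: 'A', 2: 'B', 1: 'B', 3: 'C', 4: 'C'}
ARI vs planted subregions: 0.879
```

— the automatic component selection stopped once ≥ 98 % of the concatenated
TW-dFC variance was retained, the six k-means clusters merged into three
bilateral clusters, and the adjusted Rand index of 0.88 against the planted
subregions means the parcellation essentially recovered the ground truth.
`examples/04_group_contrasts.py` shows the directional contrasts detecting a
planted coupling increase of cluster A in 100 % of affected voxels while all
other contrasts stay empty.

## Command line

```bash
twdfc synth --subjects 5 --rng 42 -o phantom/          # synthetic cohort
twdfc tracks info phantom/sub-00.tck                   # inspect a tractogram
twdfc preprocess bold.nii.gz --fwhm 6 --band 0.01 0.1 -o pre.nii.gz
twdfc seedtracks all.tck --seed hip.nii.gz -o seed.tck --table endpoints.tsv
twdfc map pre.nii.gz seed.tck --table endpoints.tsv --window 85 -o twdfc.nii.gz
twdfc parcellate twdfc*.nii.gz --seed-mask hip.nii.gz --k 6 -o parc.nii.gz
twdfc groupfc --bold-list subjects.txt --parcellation parc.nii.gz \
      --brain-mask brain.nii.gz -o contrasts/
```

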