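# visfill

Does an image-completion network represent scenes the way early visual
cortex does?  `visfill` is a testbed for that question: it compares layer
representations of a self-supervised encoder/decoder inpainting network
(and a feedforward classification-network baseline) against simulated
V1/V2 activity patterns using cross-validated representational similarity
analysis (RSA), for images whose lower-right quadrant is hidden behind a
white occluder.

The original paradigm pairs fMRI recordings from retinotopic cortex —
including the *occluded* region, which receives no feedforward stimulus
information, only feedback — with a U-Net trained to fill in the missing
quadrant.  No public fMRI dataset exists for this paradigm, so `visfill`
ships a first-class synthetic-data module that emulates the study design
(24 scenes in 6 categories, 18 subjects, 8 runs × 2 presentations, pRF
sizes growing linearly with eccentricity, voxel selection by 2σ pRF
containment) with a *known* planted geometry, turning the analysis into a
recovery problem with ground truth.

## The analysis

For each subject and each (ROI, quadrant) voxel group:

1. **Crossnobis RDMs.** The 8 runs are split into a fitting and a testing
   half (all C(8,4) = 70 assignments); within each half, two quarters of 2
   runs give a cross-validated linear discriminant contrast RDM,
   d(i,j) = (a_i − a_j)ᵀ Σ̂⁻¹ (b_i − b_j) / n_voxels, with a shrinkage
   noise covariance Σ̂.  Cross-validation makes the estimator unbiased
   (entries may be negative).
2. **Model prediction.** Candidate-model RDMs — squared Euclidean
   distances on PCA-reduced layer activations, restricted to the units
   whose receptive fields sit inside the analyzed quadrant — are fit to
   the fitting-half RDM by non-negative least squares, leaving two
   conditions out at a time (each fit uses the 231 entries among the other
   22 scenes) and predicting the held-out entry.
3. **Evaluation.** The predicted RDM is compared with the testing-half RDM
   by Kendall's τ-a, averaged over all 70 splits, and reported per
   subject × ROI × quadrant × layer with noise ceilings (mean /
   leave-one-subject-out τ-a against the group mean RDM) and paired group
   tests (t-test between models, Wilcoxon between network sections).

The network side is an 8-layer stride-2 convolutional encoder (kernel 4,
receptive fields 4 px → 766 px) mirrored by 8 transposed-convolution
decoder layers with skip connections, trained self-supervised to
reconstruct the un-occluded image.  15 layers are analyzed (8 encoder + 7
decoder) and sectioned into *spatial encoder* (RF fits inside a quadrant;
layers 1–5), *latent* (spatiotopy lost), and *spatial decoder* (retinotopy
regained by output position).  The baseline is the standard 16-layer
classification topology, analyzed at the 5 block-final convolutions.

## Worked example

```bash
python examples/04_recovery_study.py
```

simulates 18 subjects whose voxel geometry is planted from layer
`decoder_4`, runs the full RSA and prints:

```
group-mean Kendall tau-a per candidate layer (V1, occluded quadrant):
  decoder_4  +0.650  <- generating layer
  decoder_5  +0.417
  decoder_6  +0.301
  encoder_8  +0.218
  ...
  encoder_5  +0.000

noise ceiling: lower 0.744, upper 0.759
recovered generating layer: decoder_4
```

The generating layer wins by a wide margin; spatial-encoder layers score
at zero because their quadrant-restricted features carry no information
about the planted decoder geometry at this noise level.  Other entry
points: `examples/01…03` (stimuli, receptive-field arithmetic, inpainting
training) and `examples/05_full_pipeline.py` / the `visfill` CLI
(`generate | train | extract | reduce | rsa | report | all`), which writes
per-stage artifacts, a seeded manifest with content digests, and report
figures (component sweep, model comparison, per-layer section profile with
noise-ceiling band, CNN-RF vs pRF table).

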