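"""Desk-scale recovery study: plant a layer's geometry, try to find it.

Runs the complete analysis chain on one synthetic study — stimuli, network
activations, PCA reduction, voxel simulation with a known generating layer,
split-quarter cross-validated RSA — and reports the per-layer group-mean
similarities plus the noise ceiling.  The study design constants (24 scenes
in 6 categories, 18 subjects, 8 runs x 2 presentations, 70 splits, 15
analyzed layers) are the experiment's; the network runs at reduced channel
width (bottleneck 32) and the PCA stream is desk-sized so a study completes
in well under a minute on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features as ft
from . import network as nw
from . import reduction as rd
from . import rsa_core as rc
from . import synthetic_data as sd

__all__ = ["StudyResult", "run_recovery_study", "DESK_CHANNELS"]

DESK_CHANNELS = (4, 8, 8, 16, 16, 16, 16, 32)


@dataclass
class StudyResult:
    result: rc.RSAResult
    geometry_source: str
    roi: str
    quadrant: str

    def group_mean_taus(self) -> pd.Series:
        tab = self.result.table
        sub = tab[(tab.roi == self.roi) & (tab.quadrant == self.quadrant)]
        return sub.groupby("layer")["tau"].mean()

    def top_layer(self) -> str:
        return self.group_mean_taus().idxmax()

    def ceiling(self) -> tuple[float, float]:
        return self.result.ceilings[(self.roi, self.quadrant)]


def run_recovery_study(seed: int, noise_sd: float = 3.0,
                       geometry_source: str = "decoder_4",
                       n_subjects: int = 18, n_runs: int = 8,
                       n_images: int = 24, n_categories: int = 6,
                       image_size: int = 256,
                       encoder_channels=DESK_CHANNELS,
                       n_components: int = 16, n_fit_images: int = 48,
                       roi: str = "V1", quadrant: str = "occluded",
                       n_voxels: int = 120,
                       splits=None) -> StudyResult:
    """One full planted-geometry recovery experiment.

    Voxel data are simulated from ``geometry_source``'s reduced features;
    every analyzed layer then competes as a candidate model.  Returns the
    RSA result restricted to one (ROI, quadrant).
    """
    arch = nw.default_architecture(image_size, encoder_channels=encoder_channels)
    net = nw.EncoderDecoder(arch, seed=seed)
    stimuli = sd.generate_scene_set(n_images, n_categories, image_size, seed=seed)
    fit_set = sd.generate_scene_set(
        (n_fit_images // n_categories) * n_categories, n_categories, image_size,
        seed=seed + 1_000_003)
    fit_ids = [f"fit_{i}" for i in fit_set.ids]

    features: dict[str, dict[str, np.ndarray]] = {}
    test_occ = stimuli.occluded_images()
    fit_occ = fit_set.occluded_images()
    for q in ("nonoccluded", "occluded"):
        fit_feats = ft.quadrant_features(net, fit_occ, q, batch_size=16)
        test_feats = ft.quadrant_features(net, test_occ, q, batch_size=16)
        for layer, F in fit_feats.items():
            fitted = rd.fit_incremental_transform(
                [F], layer=layer, quadrant=q, n_components=n_components,
                fit_ids=fit_ids)
            fm = rd.transform(test_feats[layer], fitted, ids=stimuli.ids)
            features.setdefault(layer, {})[q] = fm.values

    prf = sd.select_voxels_by_prf(sd.plant_prf_map(
        sd.PRFConfig(n_voxels=n_voxels, image_size=image_size, seed=seed)))
    study = sd.StudyConfig(n_subjects=n_subjects, n_runs=n_runs, noise_sd=noise_sd,
                           geometry_source=geometry_source, seed=seed)
    dataset = sd.simulate_voxel_responses(stimuli, features, study, prf)

    sets = {layer: rc.regressors_from_features(
        layer, by_q[quadrant], condition_ids=stimuli.ids, mode="single")
        for layer, by_q in features.items()}
    if splits is None:
        splits = rc.enumerate_splits(n_runs)
    res = rc.crossvalidated_similarity(dataset, sets, splits,
                                       rois=(roi,), quadrants=(quadrant,))
    return StudyResult(res, geometry_source, roi, quadrant)
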