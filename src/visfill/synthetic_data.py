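"""Synthetic stimuli and simulated multi-subject voxel data.

No public fMRI dataset accompanies the occluded-scenes paradigm this package
analyses, so this module generates stand-ins whose statistical structure
matches the study design and whose generating geometry is known exactly,
enabling recovery tests:

* **Stimuli** — grayscale scenes synthesized from oriented band-pass noise.
  Each category owns a spectral prototype (orientation x spatial-frequency
  band plus a 1/f background and a shared prototype phase field); images
  within a category jitter the prototype phase, so within-category pixel
  correlations exceed between-category correlations by construction.
  Default: 24 images, 6 categories, matching the experiment's design.
  The occluder is a white box over the lower-right quadrant.

* **pRF maps** — voxels tile the two lower visual-field quadrants; the
  Gaussian spread grows linearly with eccentricity (sigma = intercept +
  slope x ecc), with a steeper slope for V2 than V1.  At the default
  degree-to-pixel scale (19.5 deg -> 256 px horizontally) the V1 sigmas span
  roughly 3-16 px and V2 3-21 px.  Voxel inclusion requires the 2-sigma disc
  around the pRF centre to lie fully inside the quadrant region.

* **Voxel responses** — each voxel reads one dimension of a planted mixture
  of candidate feature spaces (a sparse non-negative readout: stacked random
  permutation assignments with positive per-voxel gains), restricted at
  quadrant granularity to the voxel's pRF side.  18 subjects x 8 runs x
  24 conditions by default, with 2 presentations per run (16 total);
  run-level Gaussian noise has heteroscedastic variances and optional
  AR(1)-style neighbour correlation.  The planted geometry's squared
  Euclidean RDM is stored as ground truth.

All randomness flows from a single seed through a named SeedSequence
hierarchy, so identical configs give bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rf_geometry import deg_to_px

__all__ = [
    "SPAN_X_DEG",
    "SPAN_Y_DEG",
    "StimulusSet",
    "StudyConfig",
    "PRFConfig",
    "PRFMap",
    "VoxelDataset",
    "generate_scene_set",
    "apply_occluder",
    "category_contrast",
    "plant_prf_map",
    "select_voxels_by_prf",
    "simulate_voxel_responses",
    "quadrant_region_deg",
    "split_half_reliability",
]

SPAN_X_DEG = 19.5   # stimulus width in degrees of visual angle
SPAN_Y_DEG = 14.7   # stimulus height


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

@dataclass
class StimulusSet:
    """Grayscale scene images with category labels and the occluder mask."""

    images: np.ndarray            # (n, H, W) in [0, 1]
    categories: np.ndarray        # (n,) int labels
    ids: list[str]
    occluder_mask: np.ndarray     # (H, W) bool, True inside the occluder

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def image_size(self) -> int:
        return self.images.shape[1]

    def occluded_images(self) -> np.ndarray:
        return np.stack([apply_occluder(im, self.occluder_mask) for im in self.images])

    def save(self, directory: str | Path) -> None:
        """8-bit PNGs plus a JSON sidecar (ids, categories, occluder rect)."""
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for im, iid in zip(self.images, self.ids):
            Image.fromarray(np.round(im * 255).astype(np.uint8), mode="L").save(
                directory / f"{iid}.png")
        h, w = self.occluder_mask.shape
        rows = np.where(self.occluder_mask.any(axis=1))[0]
        cols = np.where(self.occluder_mask.any(axis=0))[0]
        sidecar = {
            "ids": self.ids,
            "categories": [int(c) for c in self.categories],
            "image_size": [h, w],
            "occluder_rect": [int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1],
        }
        (directory / "stimuli.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "StimulusSet":
        from PIL import Image

        directory = Path(directory)
        meta = json.loads((directory / "stimuli.json").read_text())
        images = np.stack([
            np.asarray(Image.open(directory / f"{iid}.png"), dtype=float) / 255.0
            for iid in meta["ids"]])
        h, w = meta["image_size"]
        mask = np.zeros((h, w), dtype=bool)
        r0, r1, c0, c1 = meta["occluder_rect"]
        mask[r0:r1, c0:c1] = True
        return cls(images, np.asarray(meta["categories"]), list(meta["ids"]), mask)


def _lower_right_mask(image_size: int) -> np.ndarray:
    mask = np.zeros((image_size, image_size), dtype=bool)
    h = image_size // 2
    mask[h:, h:] = True
    return mask


def apply_occluder(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """White-box occlusion of the lower-right quadrant; other pixels untouched."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("pixel values must lie in [0, 1]")
    if mask is None:
        mask = _lower_right_mask(image.shape[0])
    out = image.copy()
    out[mask] = 1.0
    return out


def generate_scene_set(n_images: int = 24, n_categories: int = 6,
                       image_size: int = 256, seed: int = 0,
                       phase_jitter: float = 0.7) -> StimulusSet:
    """Synthesize a categorized scene set from oriented band-pass prototypes.

    Each category gets an amplitude spectrum concentrated around a
    category-specific orientation and spatial-frequency band (on a 1/f
    background) and a shared random prototype phase field; per-image phase
    jitter (sd ``phase_jitter`` radians) creates exemplar variation while
    preserving within-category structure.
    """
    if image_size < 64:
        raise ValueError(f"image_size must be >= 64, got {image_size}")
    if n_images % n_categories != 0:
        raise ValueError(
            f"n_images ({n_images}) must be divisible by n_categories ({n_categories})")
    per_cat = n_images // n_categories
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    fy = np.fft.fftfreq(image_size)[:, None] * image_size   # cycles per image
    fx = np.fft.fftfreq(image_size)[None, :] * image_size
    rho = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    rho_safe = np.where(rho == 0, 1.0, rho)

    images, cats, ids = [], [], []
    sf_centers = np.geomspace(8, 40, n_categories)
    for c in range(n_categories):
        ori = c * np.pi / n_categories + rng.uniform(-0.1, 0.1)
        sf = sf_centers[c]
        band = np.exp(-(np.log(rho_safe / sf)) ** 2 / (2 * 0.35 ** 2))
        dtheta = np.angle(np.exp(1j * 2 * (theta - ori))) / 2  # orientation is pi-periodic
        orient = np.exp(-dtheta ** 2 / (2 * np.deg2rad(18) ** 2))
        amp = band * orient + 0.25 / rho_safe
        amp[0, 0] = 0.0
        proto_phase = rng.uniform(0, 2 * np.pi, size=amp.shape)
        for j in range(per_cat):
            phase = proto_phase + phase_jitter * rng.standard_normal(amp.shape)
            img = np.real(np.fft.ifft2(amp * np.exp(1j * phase)))
            lo, hi = np.percentile(img, [1, 99])
            img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
            images.append(img)
            cats.append(c)
            ids.append(f"cat{c}_im{j}")
    return StimulusSet(np.stack(images), np.asarray(cats), ids,
                       _lower_right_mask(image_size))


def category_contrast(stimuli: StimulusSet) -> tuple[float, float] | None:
    """Mean within- vs between-category pixel correlation; ``None`` (flagged)
    when there is a single image per category."""
    cats = stimuli.categories
    if all(np.sum(cats == c) < 2 for c in np.unique(cats)):
        return None
    flat = stimuli.images.reshape(stimuli.n_images, -1)
    corr = np.corrcoef(flat)
    same = cats[:, None] == cats[None, :]
    off = ~np.eye(len(cats), dtype=bool)
    return float(corr[same & off].mean()), float(corr[~same].mean())


# ---------------------------------------------------------------------------
# pRF maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRFConfig:
    """Linear sigma-vs-eccentricity model per ROI, in degrees of visual angle."""

    n_voxels: int = 120               # simulated voxels per (ROI, quadrant) group
    v1_intercept: float = 0.229       # deg; ~3 px at the default scale
    v1_slope: float = 0.081           # deg sigma per deg eccentricity
    v2_intercept: float = 0.229
    v2_slope: float = 0.112
    image_size: int = 256
    center_jitter: float = 0.3        # fraction of a grid cell
    seed: int = 0

    def __post_init__(self):
        for name in ("v1_intercept", "v2_intercept"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("v1_slope", "v2_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PRFMap:
    """Per-voxel pRF parameters with ROI and quadrant tags."""

    x: np.ndarray           # deg, positive = right
    y: np.ndarray           # deg, positive = up
    sigma: np.ndarray       # deg
    roi: np.ndarray         # "V1" | "V2"
    quadrant: np.ndarray    # "occluded" (lower right) | "nonoccluded" (lower left)
    lines: dict             # roi -> (intercept, slope)
    image_size: int = 256

    @property
    def n_voxels(self) -> int:
        return len(self.x)

    @property
    def eccentricity(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    def sigma_px(self) -> np.ndarray:
        return deg_to_px(self.sigma, SPAN_X_DEG, self.image_size)

    def mask(self, roi: str | None = None, quadrant: str | None = None) -> np.ndarray:
        m = np.ones(self.n_voxels, dtype=bool)
        if roi is not None:
            m &= self.roi == roi
        if quadrant is not None:
            m &= self.quadrant == quadrant
        return m

    def subset(self, keep: np.ndarray) -> "PRFMap":
        return PRFMap(self.x[keep], self.y[keep], self.sigma[keep],
                      self.roi[keep], self.quadrant[keep], dict(self.lines),
                      self.image_size)


def quadrant_region_deg(quadrant: str) -> tuple[float, float, float, float]:
    """(x0, x1, y0, y1) of a lower visual-field quadrant in degrees."""
    hx, hy = SPAN_X_DEG / 2, SPAN_Y_DEG / 2
    if quadrant == "occluded":        # lower right
        return (0.0, hx, -hy, 0.0)
    if quadrant == "nonoccluded":     # lower left
        return (-hx, 0.0, -hy, 0.0)
    raise ValueError(f"unknown quadrant {quadrant!r}")


def plant_prf_map(config: PRFConfig = PRFConfig()) -> PRFMap:
    """Tile the two lower quadrants with voxels for V1 and V2.

    Centres sit on a jittered grid inside each quadrant; sigma follows the
    ROI's linear eccentricity model.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    xs, ys, sig, rois, quads = [], [], [], [], []
    lines = {"V1": (config.v1_intercept, config.v1_slope),
             "V2": (config.v2_intercept, config.v2_slope)}
    g = int(np.ceil(np.sqrt(config.n_voxels)))
    for roi, (icpt, slope) in lines.items():
        for quadrant in ("nonoccluded", "occluded"):
            x0, x1, y0, y1 = quadrant_region_deg(quadrant)
            cw, ch = (x1 - x0) / g, (y1 - y0) / g
            cx = x0 + (np.arange(g) + 0.5) * cw
            cy = y0 + (np.arange(g) + 0.5) * ch
            gx, gy = np.meshgrid(cx, cy, indexing="xy")
            gx = gx.ravel()[:config.n_voxels] + rng.uniform(-config.center_jitter * cw,
                                                            config.center_jitter * cw,
                                                            config.n_voxels)
            gy = gy.ravel()[:config.n_voxels] + rng.uniform(-config.center_jitter * ch,
                                                            config.center_jitter * ch,
                                                            config.n_voxels)
            ecc = np.hypot(gx, gy)
            xs.append(gx)
            ys.append(gy)
            sig.append(icpt + slope * ecc)
            rois.append(np.full(config.n_voxels, roi, dtype=object))
            quads.append(np.full(config.n_voxels, quadrant, dtype=object))
    return PRFMap(np.concatenate(xs), np.concatenate(ys), np.concatenate(sig),
                  np.concatenate(rois).astype(str), np.concatenate(quads).astype(str),
                  lines, config.image_size)


class EmptySelectionError(ValueError):
    pass


def select_voxels_by_prf(obj, margin_sigma: float = 2.0):
    """Keep voxels whose ``margin_sigma``-sigma disc lies inside their quadrant.

    ``obj`` may be a :class:`PRFMap` or a :class:`VoxelDataset`; the same
    (sub-set) type is returned.  Raises :class:`EmptySelectionError` naming
    the ROI if a (ROI, quadrant) group ends up empty.
    """
    prf = obj.prf if isinstance(obj, VoxelDataset) else obj
    keep = np.zeros(prf.n_voxels, dtype=bool)
    for quadrant in ("nonoccluded", "occluded"):
        x0, x1, y0, y1 = quadrant_region_deg(quadrant)
        m = prf.quadrant == quadrant
        r = margin_sigma * prf.sigma
        keep |= m & (prf.x - r >= x0) & (prf.x + r <= x1) & \
            (prf.y - r >= y0) & (prf.y + r <= y1)
    for roi in np.unique(prf.roi):
        for quadrant in np.unique(prf.quadrant):
            grp = (prf.roi == roi) & (prf.quadrant == quadrant)
            if grp.any() and not (grp & keep).any():
                raise EmptySelectionError(
                    f"pRF containment removed every voxel of ROI {roi} ({quadrant})")
    if isinstance(obj, VoxelDataset):
        return obj.subset(keep)
    return prf.subset(keep)


# ---------------------------------------------------------------------------
# voxel-response simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Study-design constants plus simulation knobs.

    Defaults mirror the experimental design: 18 subjects, 8 runs with 2
    presentations each (16 per image).  ``mixing`` maps feature-space names
    to non-negative weights defining the planted geometry; ``geometry_source``
    is the shorthand for a single-space mixture.
    """

    n_subjects: int = 18
    n_runs: int = 8
    reps_per_run: int = 2
    noise_sd: float = 3.0   # gives ~0.5 split-half RDM reliability, typical of V1/V2 data
    geometry_source: str | None = None
    mixing: dict | None = None
    gain_sd: float = 0.2          # lognormal sd of per-voxel readout gains
    hetero_sd: float = 0.3        # lognormal sd of per-voxel noise scale
    ar_rho: float = 0.3           # neighbour noise correlation
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mixing is not None and any(w < 0 for w in self.mixing.values()):
            raise ValueError("mixing weights must be >= 0")
        if self.mixing is None and self.geometry_source is None:
            raise ValueError("specify geometry_source or mixing")

    @property
    def presentations(self) -> int:
        return self.n_runs * self.reps_per_run

    def weights(self) -> dict:
        if self.mixing is not None:
            return {k: v for k, v in self.mixing.items() if v > 0}
        return {self.geometry_source: 1.0}


@dataclass
class VoxelDataset:
    """subject x run x condition x voxel responses with planted ground truth."""

    responses: np.ndarray                 # (S, R, C, V)
    prf: PRFMap
    ground_truth: dict                    # quadrant -> RDM vector (sq. Euclid / dim)
    config: StudyConfig
    residuals: np.ndarray | None = None   # (S, R, C, V) retained noise draws
    condition_ids: list | None = None

    @property
    def n_subjects(self):
        return self.responses.shape[0]

    @property
    def n_runs(self):
        return self.responses.shape[1]

    @property
    def n_conditions(self):
        return self.responses.shape[2]

    def group(self, roi: str, quadrant: str) -> np.ndarray:
        """Responses restricted to one (ROI, quadrant) voxel group."""
        return self.responses[..., self.prf.mask(roi, quadrant)]

    def subset(self, keep: np.ndarray) -> "VoxelDataset":
        return VoxelDataset(self.responses[..., keep], self.prf.subset(keep),
                            dict(self.ground_truth), self.config,
                            None if self.residuals is None else self.residuals[..., keep],
                            self.condition_ids)

    # -- persistence --------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("responses", data=self.responses)
            if self.residuals is not None:
                f.create_dataset("residuals", data=self.residuals)
            g = f.create_group("prf")
            for k in ("x", "y", "sigma"):
                g.create_dataset(k, data=getattr(self.prf, k))
            g.create_dataset("roi", data=np.char.encode(self.prf.roi.astype(str)))
            g.create_dataset("quadrant", data=np.char.encode(self.prf.quadrant.astype(str)))
            g.attrs["lines"] = json.dumps(self.prf.lines)
            g.attrs["image_size"] = self.prf.image_size
            gt = f.create_group("ground_truth")
            for k, v in self.ground_truth.items():
                gt.create_dataset(k, data=v)
            f.attrs["config"] = json.dumps({**self.config.__dict__}, default=str)
            if self.condition_ids is not None:
                f.attrs["condition_ids"] = json.dumps(list(map(str, self.condition_ids)))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "VoxelDataset":
        import h5py

        with h5py.File(path, "r") as f:
            responses = f["responses"][...]
            residuals = f["residuals"][...] if "residuals" in f else None
            g = f["prf"]
            prf = PRFMap(g["x"][...], g["y"][...], g["sigma"][...],
                         np.char.decode(g["roi"][...]).astype(str),
                         np.char.decode(g["quadrant"][...]).astype(str),
                         json.loads(g.attrs["lines"]), int(g.attrs["image_size"]))
            gt = {k: f["ground_truth"][k][...] for k in f["ground_truth"]}
            raw = json.loads(f.attrs["config"])
            raw["mixing"] = raw.get("mixing") or None
            cfg = StudyConfig(**{k: raw[k] for k in StudyConfig.__dataclass_fields__ if k in raw})
            cond = json.loads(f.attrs["condition_ids"]) if "condition_ids" in f.attrs else None
        return cls(responses, prf, gt, cfg, residuals, cond)


def _normalize_space(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    F = F - F.mean(axis=0)
    scale = np.sqrt(np.mean(F.var(axis=0)))
    return F / scale if scale > 0 else F


def _planted_matrix(features_by_space: dict, quadrant: str, weights: dict) -> np.ndarray:
    parts = []
    for name, w in weights.items():
        if name not in features_by_space:
            raise KeyError(f"feature space {name!r} not supplied; have {sorted(features_by_space)}")
        F = features_by_space[name]
        if isinstance(F, dict):
            F = F[quadrant]
        parts.append(np.sqrt(w) * _normalize_space(F))
    n_cond = {p.shape[0] for p in parts}
    if len(n_cond) != 1:
        raise ValueError(f"feature spaces disagree on condition count: {sorted(n_cond)}")
    return np.concatenate(parts, axis=1)


def _sqeuclid_rdm(F: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(F, metric="sqeuclidean") / F.shape[1]


def simulate_voxel_responses(stimuli: StimulusSet | None, features_by_space: dict,
                             config: StudyConfig, prf: PRFMap) -> VoxelDataset:
    """Simulate the multi-subject dataset from a planted feature-space mixture.

    Each (ROI, quadrant) voxel group reads the mixture restricted to its
    quadrant; each voxel is assigned one mixture dimension (random
    permutation stacking, subject-specific) with a positive lognormal gain.
    Run-level noise is correlated Gaussian scaled by
    ``noise_sd / sqrt(reps_per_run)``.
    """
    weights = config.weights()
    root = np.random.SeedSequence([config.seed, 303])
    groups = [(roi, quad) for roi in ("V1", "V2") for quad in ("nonoccluded", "occluded")]
    child = {g: s for g, s in zip(groups, root.spawn(len(groups)))}

    planted = {q: _planted_matrix(features_by_space, q, weights)
               for q in ("nonoccluded", "occluded")}
    if stimuli is not None:
        for q, G in planted.items():
            if G.shape[0] != stimuli.n_images:
                raise ValueError(
                    f"feature spaces have {G.shape[0]} conditions but the stimulus "
                    f"set has {stimuli.n_images}")
    ground_truth = {q: _sqeuclid_rdm(G) for q, G in planted.items()}
    n_cond = next(iter(planted.values())).shape[0]

    S, R = config.n_subjects, config.n_runs
    resp_parts, noise_parts = [], []
    order = np.arange(prf.n_voxels)
    # assemble responses voxel-group by voxel-group, then restore prf order
    col_index = []
    for g in groups:
        roi, quad = g
        vmask = prf.mask(roi, quad)
        V = int(vmask.sum())
        if V == 0:
            continue
        col_index.append(order[vmask])
        rng = np.random.default_rng(child[g])
        G = planted[quad]
        d = G.shape[1]
        sigma_chol = _noise_chol(V, config, rng)
        resp = np.empty((S, R, n_cond, V))
        noise = np.empty((S, R, n_cond, V))
        for s in range(S):
            reps = int(np.ceil(V / d))
            dims = np.concatenate([rng.permutation(d) for _ in range(reps)])[:V]
            gains = np.exp(rng.normal(0.0, config.gain_sd, V)) if config.gain_sd > 0 \
                else np.ones(V)
            T = G[:, dims] * gains                       # (C, V) noiseless tuning
            sd = T.std(axis=0).mean()
            if sd > 0:
                T = T / sd
            z = rng.standard_normal((R, n_cond, V))
            eps = (config.noise_sd / np.sqrt(config.reps_per_run)) * (z @ sigma_chol.T)
            resp[s] = T[None] + eps
            noise[s] = eps
        resp_parts.append(resp)
        noise_parts.append(noise)
    cols = np.concatenate(col_index)
    inv = np.empty_like(cols)
    inv[cols] = np.arange(len(cols))
    responses = np.concatenate(resp_parts, axis=3)[..., inv]
    residuals = np.concatenate(noise_parts, axis=3)[..., inv]
    return VoxelDataset(responses, prf, ground_truth, config, residuals,
                        condition_ids=list(stimuli.ids) if stimuli is not None else None)


def _noise_chol(V: int, config: StudyConfig, rng: np.random.Generator) -> np.ndarray:
    scales = np.exp(rng.normal(0.0, config.hetero_sd, V))
    idx = np.arange(V)
    corr = config.ar_rho ** np.abs(idx[:, None] - idx[None, :])
    cov = corr * np.outer(scales, scales)
    return np.linalg.cholesky(cov)


def split_half_reliability(dataset: VoxelDataset, roi: str = "V1",
                           quadrant: str = "occluded") -> float:
    """Mean (over subjects) Spearman correlation between odd- and even-run
    squared-Euclidean RDMs; a simple data-reliability summary used by the
    noise-scaling checks."""
    from scipy.spatial.distance import pdist
    from scipy.stats import spearmanr

    resp = dataset.group(roi, quadrant)
    vals = []
    for s in range(dataset.n_subjects):
        a = resp[s, 0::2].mean(axis=0)
        b = resp[s, 1::2].mean(axis=0)
        vals.append(spearmanr(pdist(a, "sqeuclidean"), pdist(b, "sqeuclidean")).statistic)
    return float(np.mean(vals))
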