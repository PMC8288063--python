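"""Reproducible generate -> train -> extract -> reduce -> rsa -> report pipeline.

Each stage reads the artifacts of its upstream stages from the run
directory, writes its own, and appends a manifest entry (config snapshot,
derived seed, wall time, SHA-256 digests of inputs and outputs).
Deterministic stages re-run to identical digests.

Stage artifacts::

    stimuli/            test scene set (PNG + JSON sidecar)
    prf.json            planted pRF map after 2-sigma containment selection
    weights.npz         trained inpainting-network weights (+ train_trace.json)
    activations.h5      quadrant-restricted test activations per layer
    transforms.h5       fitted PCA transforms (mean, components, variance)
    features.h5         reduced test features per (family, layer, quadrant)
    voxels.h5           simulated multi-subject voxel dataset
    rsa_table.tsv       subject x roi x quadrant x layer tau values
    rsa_summary.json    noise ceilings + group statistics
    report/             tables and figures mirroring the result structure
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from . import network as nw
from . import reduction as rd
from . import rsa_core as rc
from . import synthetic_data as sd

__all__ = ["PipelineConfig", "PipelineError", "run_stage", "run_all", "make_report",
           "STAGES"]

STAGES = ("generate", "train", "extract", "reduce", "rsa", "report")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for every stage; master seed drives per-stage seeds."""

    out_dir: str = "runs/default"
    seed: int = 0
    # stimuli / study design
    n_images: int = 24
    n_categories: int = 6
    image_size: int = 256
    n_subjects: int = 18
    n_runs: int = 8
    reps_per_run: int = 2
    noise_sd: float = 3.0
    n_voxels: int = 120
    geometry_source: str = "decoder_4"
    # network
    encoder_channels: tuple[int, ...] = nw.DEFAULT_ENCODER_CHANNELS
    kernel: int = 4
    n_train_images: int = 198
    epochs: int = 5
    batch_size: int = 5
    learning_rate: float = 1e-3
    dropout: float = 0.2
    # reduction
    n_components: int = 1024
    n_fit_images: int = 2000
    fit_batch: int = 16
    # rsa
    regressor_mode: str = "pc-blocks"
    pc_block: int = 64
    n_splits: int | None = None
    include_vgg: bool = True
    vgg_channel_scale: float = 1.0

    @classmethod
    def desk_profile(cls, **overrides) -> "PipelineConfig":
        """Scaled-down profile that runs the full pipeline in minutes on one
        CPU: tiny channel counts (bottleneck 32), small PCA stream, and the
        closed-form single-regressor mode."""
        base = dict(
            encoder_channels=(4, 8, 8, 16, 16, 16, 16, 32),
            n_components=16, n_fit_images=96, n_train_images=60,
            epochs=2, regressor_mode="single", vgg_channel_scale=0.125,
            n_voxels=80,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "encoder_channels" in raw:
            raw["encoder_channels"] = tuple(raw["encoder_channels"])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def arch(self) -> nw.ArchitectureConfig:
        return nw.default_architecture(self.image_size, encoder_channels=self.encoder_channels,
                                       kernel=self.kernel, dropout=self.dropout)

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _digests(paths) -> dict:
    out = {}
    for p in paths:
        p = Path(p)
        if p.is_dir():
            for sub in sorted(p.rglob("*")):
                if sub.is_file():
                    out[str(sub)] = _sha256(sub)
        elif p.exists():
            out[str(p)] = _sha256(p)
    return out


def _append_manifest(out: Path, stage: str, config: PipelineConfig, seed: int,
                     inputs, outputs, t0: float) -> None:
    path = out / "run_manifest.json"
    entries = json.loads(path.read_text()) if path.exists() else []
    entries.append({
        "stage": stage,
        "seed": seed,
        "wall_time_s": round(time.time() - t0, 3),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "inputs": _digests(inputs),
        "outputs": _digests(outputs),
    })
    path.write_text(json.dumps(entries, indent=1))


def _require(out: Path, artifact: str, producer: str) -> Path:
    p = out / artifact
    if not p.exists():
        raise PipelineError(
            f"missing upstream artifact {artifact!r}; run the {producer!r} stage first")
    return p


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_generate(cfg: PipelineConfig, out: Path) -> list[Path]:
    seed = cfg.stage_seed("generate")
    stimuli = sd.generate_scene_set(cfg.n_images, cfg.n_categories, cfg.image_size, seed=seed)
    stimuli.save(out / "stimuli")
    prf = sd.select_voxels_by_prf(sd.plant_prf_map(
        sd.PRFConfig(n_voxels=cfg.n_voxels, image_size=cfg.image_size, seed=seed)))
    (out / "prf.json").write_text(json.dumps({
        "x": prf.x.tolist(), "y": prf.y.tolist(), "sigma": prf.sigma.tolist(),
        "roi": prf.roi.tolist(), "quadrant": prf.quadrant.tolist(),
        "lines": prf.lines, "image_size": prf.image_size}))
    return [out / "stimuli", out / "prf.json"]


def _load_prf(out: Path) -> sd.PRFMap:
    meta = json.loads((out / "prf.json").read_text())
    return sd.PRFMap(np.array(meta["x"]), np.array(meta["y"]), np.array(meta["sigma"]),
                     np.array(meta["roi"]), np.array(meta["quadrant"]),
                     meta["lines"], meta["image_size"])


def _training_images(cfg: PipelineConfig, n: int, seed: int) -> sd.StimulusSet:
    n_round = (n // cfg.n_categories) * cfg.n_categories
    return sd.generate_scene_set(max(n_round, cfg.n_categories), cfg.n_categories,
                                 cfg.image_size, seed=seed)


def _stage_train(cfg: PipelineConfig, out: Path) -> list[Path]:
    seed = cfg.stage_seed("train")
    train_set = _training_images(cfg, cfg.n_train_images, seed)
    holdout = _training_images(cfg, max(cfg.n_categories, cfg.n_train_images // 5), seed + 1)
    net = nw.EncoderDecoder(cfg.arch(), seed=seed)
    tc = nw.TrainingConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                           learning_rate=cfg.learning_rate, dropout=cfg.dropout, seed=seed)
    trace = nw.train_inpainting(
        net, train_set.occluded_images(), train_set.images, train_set.occluder_mask, tc,
        holdout=(holdout.occluded_images(), holdout.images))
    net.save_weights(out / "weights.npz")
    (out / "train_trace.json").write_text(json.dumps(trace, indent=1))
    return [out / "weights.npz", out / "train_trace.json"]


def _build_net(cfg: PipelineConfig, out: Path) -> nw.EncoderDecoder:
    net = nw.EncoderDecoder(cfg.arch(), seed=cfg.stage_seed("train"))
    weights = out / "weights.npz"
    if weights.exists():
        net.load_weights(weights)
    return net


def _stage_extract(cfg: PipelineConfig, out: Path) -> list[Path]:
    import h5py

    _require(out, "stimuli/stimuli.json", "generate")
    stimuli = sd.StimulusSet.load(out / "stimuli")
    net = _build_net(cfg, out)
    occluded = stimuli.occluded_images()
    path = out / "activations.h5"
    with h5py.File(path, "w") as f:
        f.attrs["ids"] = json.dumps(stimuli.ids)
        f.attrs["sections"] = json.dumps(dict(nw.analyzed_layers(cfg.arch())))
        for quadrant in ("nonoccluded", "occluded"):
            feats = ft.quadrant_features(net, occluded, quadrant)
            for layer, mat in feats.items():
                f.create_dataset(f"encdec/{layer}/{quadrant}", data=mat)
        if cfg.include_vgg:
            topo = nw.vgg16_topology(channel_scale=cfg.vgg_channel_scale)
            vnet = nw.build_vgg(topo, seed=cfg.stage_seed("extract"))
            for quadrant in ("nonoccluded", "occluded"):
                feats = ft.vgg_quadrant_features(vnet, topo, occluded, quadrant, cfg.image_size)
                for layer, mat in feats.items():
                    f.create_dataset(f"vgg/{layer}/{quadrant}", data=mat)
    return [path]


def _stage_reduce(cfg: PipelineConfig, out: Path) -> list[Path]:
    import h5py

    _require(out, "activations.h5", "extract")
    seed = cfg.stage_seed("reduce")
    stimuli = sd.StimulusSet.load(out / "stimuli")
    net = _build_net(cfg, out)
    fit_set = _training_images(cfg, cfg.n_fit_images, seed + 7)
    fit_ids = [f"fit_{i}" for i in range(fit_set.n_images)]
    fit_occ = fit_set.occluded_images()

    # one forward pass per batch, restricted for every (layer, quadrant)
    index = {q: ft.layer_unit_index(net.config, q) for q in ("nonoccluded", "occluded")}
    layers = list(index["occluded"])
    collected: dict[tuple[str, str], list[np.ndarray]] = {
        (l, q): [] for l in layers for q in index}
    for i in range(0, fit_set.n_images, cfg.fit_batch):
        acts = nw.forward_collect(net, fit_occ[i:i + cfg.fit_batch], layers,
                                  batch_size=cfg.fit_batch)
        for l in layers:
            for q in index:
                collected[(l, q)].append(ft._restrict(acts[l], index[q][l]))

    tpath, fpath = out / "transforms.h5", out / "features.h5"
    with h5py.File(tpath, "w") as tf, h5py.File(fpath, "w") as ff, \
            h5py.File(out / "activations.h5", "r") as af:
        ff.attrs["ids"] = json.dumps(stimuli.ids)
        ff.attrs["sections"] = af.attrs["sections"]
        for l in layers:
            for q in index:
                fitted = rd.fit_incremental_transform(
                    collected[(l, q)], layer=l, quadrant=q,
                    n_components=cfg.n_components, fit_ids=fit_ids)
                g = tf.create_group(f"encdec/{l}/{q}")
                g.create_dataset("mean", data=fitted.mean)
                g.create_dataset("components", data=fitted.components)
                g.create_dataset("explained_variance", data=fitted.explained_variance)
                g.attrs["n_requested"] = fitted.n_requested
                fm = rd.transform(af[f"encdec/{l}/{q}"][...], fitted, ids=stimuli.ids)
                ff.create_dataset(f"encdec/{l}/{q}", data=fm.values)
        if cfg.include_vgg and "vgg" in af:
            topo = nw.vgg16_topology(channel_scale=cfg.vgg_channel_scale)
            vnet = nw.build_vgg(topo, seed=cfg.stage_seed("extract"))
            vlayers = nw.vgg_analysis_layers(topo)
            vspec = ft.vgg_rf_spec(topo, cfg.image_size)
            from . import rf_geometry as rfg
            vregion = {"occluded": rfg.lower_right_quadrant(cfg.image_size),
                       "nonoccluded": rfg.lower_left_quadrant(cfg.image_size)}
            vunits = {}
            for l in vlayers:
                for q in index:
                    u = rfg.quadrant_units(vspec, l, vregion[q])
                    vunits[(l, q)] = u if len(u) else None
            vcollect: dict[tuple[str, str], list[np.ndarray]] = {
                (l, q): [] for l in vlayers for q in index}
            vbatch = min(cfg.fit_batch, 4)  # full-resolution convs are memory-hungry
            for i in range(0, fit_set.n_images, vbatch):
                acts = nw.vgg_forward_collect(vnet, fit_occ[i:i + vbatch], vlayers,
                                              batch_size=vbatch)
                for l in vlayers:
                    for q in index:
                        vcollect[(l, q)].append(ft._restrict(acts[l], vunits[(l, q)]))
            for l in vlayers:
                for q in index:
                    fitted = rd.fit_incremental_transform(
                        vcollect[(l, q)], layer=l, quadrant=q,
                        n_components=cfg.n_components, fit_ids=fit_ids)
                    fm = rd.transform(af[f"vgg/{l}/{q}"][...], fitted, ids=stimuli.ids)
                    ff.create_dataset(f"vgg/{l}/{q}", data=fm.values)
    return [tpath, fpath]


def _load_features(out: Path) -> tuple[dict, dict, dict]:
    import h5py

    with h5py.File(out / "features.h5", "r") as f:
        sections = json.loads(f.attrs["sections"])
        encdec = {l: {q: f[f"encdec/{l}/{q}"][...] for q in f[f"encdec/{l}"]}
                  for l in f["encdec"]}
        vgg = {}
        if "vgg" in f:
            vgg = {l: {q: f[f"vgg/{l}/{q}"][...] for q in f[f"vgg/{l}"]}
                   for l in f["vgg"]}
    return encdec, vgg, sections


def _stage_rsa(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "features.h5", "reduce")
    _require(out, "prf.json", "generate")
    seed = cfg.stage_seed("rsa")
    stimuli = sd.StimulusSet.load(out / "stimuli")
    encdec, vgg, sections = _load_features(out)
    prf = _load_prf(out)

    study = sd.StudyConfig(n_subjects=cfg.n_subjects, n_runs=cfg.n_runs,
                           reps_per_run=cfg.reps_per_run, noise_sd=cfg.noise_sd,
                           geometry_source=cfg.geometry_source, seed=seed)
    dataset = sd.simulate_voxel_responses(stimuli, encdec, study, prf)
    dataset.to_hdf5(out / "voxels.h5")

    model_sets = {}
    for l, by_q in encdec.items():
        model_sets[l] = by_q
    all_sets = {**model_sets, **{f"vgg:{l}": by_q for l, by_q in vgg.items()}}
    splits = rc.enumerate_splits(cfg.n_runs)
    if cfg.n_splits is not None:
        splits = splits[:cfg.n_splits]

    # quadrant-specific regressors: run the RSA once per quadrant
    tables = []
    ceilings = {}
    for quadrant in ("nonoccluded", "occluded"):
        sets_q = {
            name: rc.regressors_from_features(
                name, by_q[quadrant], condition_ids=stimuli.ids,
                mode=cfg.regressor_mode, block=cfg.pc_block)
            for name, by_q in all_sets.items()}
        res = rc.crossvalidated_similarity(dataset, sets_q, splits,
                                           quadrants=(quadrant,))
        tables.append(res.table)
        ceilings.update({f"{roi}/{q}": res.ceilings[(roi, q)] for roi, q in res.ceilings})
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "rsa_table.tsv", sep="\t", index=False)

    summary = {"ceilings": ceilings, "regressor_mode": cfg.regressor_mode,
               "geometry_source": cfg.geometry_source,
               "n_splits": len(splits), "stats": _summary_stats(table, sections)}
    (out / "rsa_summary.json").write_text(json.dumps(summary, indent=1))
    return [out / "voxels.h5", out / "rsa_table.tsv", out / "rsa_summary.json"]


def _summary_stats(table: pd.DataFrame, sections: dict) -> dict:
    """Paired model contrast (t-test) and encoder-vs-decoder contrast
    (Wilcoxon) per (roi, quadrant)."""
    stats = {}
    is_vgg = table["layer"].str.startswith("vgg:")
    for (roi, quadrant), sub in table.groupby(["roi", "quadrant"]):
        key = f"{roi}/{quadrant}"
        entry = {}
        ours = sub[~is_vgg.loc[sub.index]]
        theirs = sub[is_vgg.loc[sub.index]]
        if len(theirs):
            a = ours.groupby("subject")["tau"].mean().sort_index().to_numpy()
            b = theirs.groupby("subject")["tau"].mean().sort_index().to_numpy()
            entry["model_contrast"] = rc.group_stats(a, b, test="ttest")
        enc = ours[ours["layer"].map(lambda l: sections.get(l) == "spatial_encoder")]
        dec = ours[ours["layer"].map(lambda l: sections.get(l) == "spatial_decoder")]
        if len(enc) and len(dec):
            a = enc.groupby("subject")["tau"].mean().sort_index().to_numpy()
            b = dec.groupby("subject")["tau"].mean().sort_index().to_numpy()
            entry["encoder_vs_decoder"] = rc.group_stats(a, b, test="wilcoxon")
        stats[key] = entry
    return stats


def make_report(run_dir: str | Path, config: PipelineConfig | None = None) -> list[Path]:
    """Tables and figures mirroring the result structure: component sweep,
    model-vs-model comparison, per-layer section profile with noise-ceiling
    band, and the CNN-RF vs pRF size table.  Figures whose inputs are absent
    are skipped with a warning."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(run_dir)
    rep = out / "report"
    rep.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig(out_dir=str(out))
    artifacts: list[Path] = []

    table = pd.read_csv(_require(out, "rsa_table.tsv", "rsa"), sep="\t")
    summary = json.loads((out / "rsa_summary.json").read_text())
    sections = _load_features(out)[2]

    # (a) component sweep
    sweep_path = out / "sweep.tsv"
    if sweep_path.exists():
        sweep = pd.read_csv(sweep_path, sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
        for ax, quadrant in zip(axes, ("nonoccluded", "occluded")):
            for roi, sub in sweep[sweep.quadrant == quadrant].groupby("roi"):
                ax.errorbar(sub.n_components, sub.tau_mean, yerr=sub.tau_sd,
                            marker="o", capsize=3, label=roi)
            ax.set_xscale("log", base=2)
            ax.set_xlabel("principal components")
            ax.set_title(quadrant)
            ax.legend()
        axes[0].set_ylabel("Kendall tau-a")
        fig.tight_layout()
        fig.savefig(rep / "component_sweep.png", dpi=120)
        plt.close(fig)
        artifacts.append(rep / "component_sweep.png")
    else:
        warnings.warn("sweep.tsv not found; skipping the component-sweep figure")

    is_vgg = table["layer"].str.startswith("vgg:")

    # (b) model-vs-model comparison
    if is_vgg.any():
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), sharey=True)
        for ax, roi in zip(axes, ("V1", "V2")):
            sub = table[table.roi == roi]
            for pos, quadrant in enumerate(("nonoccluded", "occluded")):
                for off, (fam, m) in enumerate((("vgg16", is_vgg), ("enc/dec", ~is_vgg))):
                    vals = sub[(sub.quadrant == quadrant) & m.loc[sub.index]]
                    g = vals.groupby("subject")["tau"].mean()
                    ax.bar(pos * 2.5 + off, g.mean(), yerr=g.std() / np.sqrt(len(g)),
                           color="C0" if fam == "vgg16" else "C1",
                           label=fam if pos == 0 else None)
            ax.set_xticks([0.5, 3.0], ["nonoccluded", "occluded"])
            stat = summary["stats"].get(f"{roi}/occluded", {}).get("model_contrast")
            ax.set_title(f"{roi}" + (f"  (occ. p={stat['p']:.3g})" if stat else ""))
        axes[0].set_ylabel("Kendall tau-a")
        axes[0].legend()
        fig.tight_layout()
        fig.savefig(rep / "model_comparison.png", dpi=120)
        plt.close(fig)
        artifacts.append(rep / "model_comparison.png")
    else:
        warnings.warn("no baseline-network results; skipping the model comparison figure")

    # (c) per-layer profile with sections and noise-ceiling band
    ours = table[~is_vgg]
    layer_order = [l for l in sections if l in set(ours.layer)]
    colors = {"spatial_encoder": "#4878cf", "latent": "#e8b434", "spatial_decoder": "#6acc65"}
    fig, axes = plt.subplots(2, 2, figsize=(10, 6), sharex=True, sharey=True)
    for i, roi in enumerate(("V1", "V2")):
        for j, quadrant in enumerate(("nonoccluded", "occluded")):
            ax = axes[j, i]
            sub = ours[(ours.roi == roi) & (ours.quadrant == quadrant)]
            if not len(sub):
                continue
            g = sub.groupby("layer")["tau"].agg(["mean", "std", "count"]).reindex(layer_order)
            ax.bar(range(len(g)), g["mean"], yerr=g["std"] / np.sqrt(g["count"]),
                   color=[colors[sections[l]] for l in layer_order])
            ceil = summary["ceilings"].get(f"{roi}/{quadrant}")
            if ceil:
                ax.axhspan(ceil[0], ceil[1], color="grey", alpha=0.3)
            ax.set_title(f"{roi} {quadrant}")
            if i == 0:
                ax.set_ylabel("Kendall tau-a")
    for ax in axes[1]:
        ax.set_xticks(range(len(layer_order)))
        ax.set_xticklabels(layer_order, rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(rep / "layer_profile.png", dpi=120)
    plt.close(fig)
    artifacts.append(rep / "layer_profile.png")

    # (d) CNN RF vs pRF size table
    spec = nw.encoder_rf_spec(cfg.arch())
    rows = [(g.name, g.rf) for g in spec.layers[1:]]
    rf_tab = pd.DataFrame(rows, columns=["layer", "rf_px"])
    prf_path = out / "prf.json"
    if prf_path.exists():
        prf = _load_prf(out)
        for roi in ("V1", "V2"):
            px = prf.sigma_px()[prf.mask(roi)]
            rf_tab[f"prf_{roi}_px_min"] = round(float(px.min()), 2)
            rf_tab[f"prf_{roi}_px_max"] = round(float(px.max()), 2)
    rf_tab.to_csv(rep / "rf_comparison.tsv", sep="\t", index=False)
    artifacts.append(rep / "rf_comparison.tsv")
    return artifacts


def run_sweep(config: PipelineConfig, grid=None) -> Path:
    """Similarity as a function of component count (sweep table).

    Principal components are variance-ordered, so keeping the first ``n``
    columns of the stored reduced features reproduces an ``n``-component
    reduction without refitting; each grid value re-runs the RSA on the
    stored voxel dataset.  Writes ``sweep.tsv`` in the run directory.
    """
    out = Path(config.out_dir)
    _require(out, "features.h5", "reduce")
    _require(out, "voxels.h5", "rsa")
    stimuli = sd.StimulusSet.load(out / "stimuli")
    encdec, _, _ = _load_features(out)
    dataset = sd.VoxelDataset.from_hdf5(out / "voxels.h5")
    splits = rc.enumerate_splits(config.n_runs)
    if config.n_splits is not None:
        splits = splits[:config.n_splits]
    if grid is None:
        grid = [g for g in rd.DEFAULT_SWEEP_GRID if g <= config.n_components]

    def run_similarity(n: int) -> pd.DataFrame:
        tables = []
        for quadrant in ("nonoccluded", "occluded"):
            sets = {name: rc.regressors_from_features(
                name, by_q[quadrant][:, :n], condition_ids=stimuli.ids,
                mode=config.regressor_mode, block=config.pc_block)
                for name, by_q in encdec.items()}
            tables.append(rc.crossvalidated_similarity(
                dataset, sets, splits, quadrants=(quadrant,)).table)
        return pd.concat(tables, ignore_index=True)

    tab = rd.component_sweep(run_similarity, grid)
    tab.to_csv(out / "sweep.tsv", sep="\t", index=False)
    return out / "sweep.tsv"


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "train": _stage_train,
    "extract": _stage_extract,
    "reduce": _stage_reduce,
    "rsa": _stage_rsa,
}


def run_stage(name: str, config: PipelineConfig) -> list[Path]:
    """Run one pipeline stage; artifacts land in ``config.out_dir`` and the
    run manifest is appended."""
    if name not in STAGES:
        raise PipelineError(f"unknown stage {name!r}; stages are {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if name == "report":
        outputs = make_report(out, config)
        inputs = [out / "rsa_table.tsv", out / "rsa_summary.json"]
    else:
        upstream = {"generate": [], "train": [],
                    "extract": [out / "stimuli", out / "weights.npz"],
                    "reduce": [out / "activations.h5"],
                    "rsa": [out / "features.h5", out / "prf.json"]}[name]
        outputs = _STAGE_FUNCS[name](config, out)
        inputs = upstream
    _append_manifest(out, name, config, config.stage_seed(name), inputs, outputs, t0)
    return outputs


def run_all(config: PipelineConfig, train: bool = True) -> None:
    for stage in STAGES:
        if stage == "train" and not train:
            continue
        run_stage(stage, config)
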