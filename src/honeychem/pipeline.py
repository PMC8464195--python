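"""End-to-end orchestration: ingest/simulate -> window -> assemble ->
augment -> standardise -> analyses, with a manifest of every output.

Stage seeds are derived deterministically from the global seed, so a run is
reproducible from its config alone. The manifest lists every written file
with row/column counts and a SHA-256 checksum (figures are listed with
their size only, as image encoders are not part of the numeric contract).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .augmentation import AugmentationConfig, augment
from .classifier import ClassifierConfig, kfold_evaluate
from .features import (
    GridSpec,
    assemble_features,
    restrict_rf_window,
    standardise,
)
from .labels import format_sample_label
from .profiles import SUGARS, read_profile_table, write_profile_table
from .regression import compare_methods, fit_evaluate, sugar_regression_design
from .synthetic import StudyDesignConfig, generate_study
from .unsupervised import (
    cut_tree,
    dbscan_cluster,
    elbow_select_k,
    hierarchical_cluster,
    kmeans_cluster,
    pca_decompose,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, file-serialisable configuration of one pipeline run."""

    outdir: str = "honeychem_run"
    seed: int = 0
    log_level: str = "INFO"

    # input: a profile-table CSV, or the synthetic study when None
    input_path: str | None = None
    delimiter: str = ","
    noise_scale: float = 1.0

    # feature construction
    rf_low: float = 0.05
    rf_high: float = 0.60
    grid_step: float = 0.005

    # augmentation
    run_augmentation: bool = True
    outer_repeats: int = 50
    inner_repeats: int = 21
    rf_drift_bound: float = 0.0173
    au_noise_multiplier: float = 1.25
    sugar_noise_fraction: float = 0.05

    # analyses
    run_hierarchical: bool = True
    hierarchical_cut: int = 3
    run_kmeans: bool = True
    kmeans_k: int = 4
    kmeans_restarts: int = 25
    elbow_kmax: int = 10
    run_dbscan: bool = True
    dbscan_eps: float | None = None  # None: median min_pts-NN distance heuristic
    dbscan_min_pts: int = 3
    run_pca: bool = True
    pca_components: int = 10
    run_regression: bool = True
    regression_max_components: int = 15
    regression_folds: int = 10
    train_fraction: float = 0.7
    run_classifier: bool = False
    classifier_folds: int = 6
    classifier_feature_sets: tuple[str, ...] = ("sugars", "organics", "combined")
    classifier_hidden_sizes: tuple[int, ...] = (128, 64)
    classifier_dropout: float = 0.2
    classifier_pool_cells: int = 0
    classifier_max_epochs: int = 60
    classifier_patience: int = 10
    figures: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("classifier_feature_sets", "classifier_hidden_sizes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("design", "augmentation", "kmeans", "regression", "classifier")
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {n: int(s % 2**31) for n, s in zip(names, state)}


def _dbscan_eps_heuristic(values: np.ndarray, min_pts: int) -> float:
    from scipy.spatial.distance import cdist

    d = cdist(values, values)
    d.sort(axis=1)
    k = min(min_pts, values.shape[0] - 1)
    return float(np.median(d[:, k]))


class PipelineRun:
    """Accumulates outputs and manifest entries for one run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.entries: list[dict] = []
        self.reports: dict[str, dict] = {}

    def add_file(self, path: Path, kind: str, checksum: bool = True, **meta) -> None:
        entry = {"name": path.name, "path": str(path), "kind": kind, **meta}
        entry["bytes"] = path.stat().st_size
        if checksum:
            entry["sha256"] = _sha256(path)
        self.entries.append(entry)

    def write_json(self, name: str, payload: dict, kind: str = "report") -> Path:
        path = self.outdir / name
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        self.add_file(path, kind)
        self.reports[name] = payload
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return (and write) the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    run = PipelineRun(config)
    seeds = _stage_seeds(config.seed)

    # ingest or simulate ---------------------------------------------------
    if config.input_path is not None:
        table = read_profile_table(config.input_path, delimiter=config.delimiter)
    else:
        table = generate_study(
            StudyDesignConfig(noise_scale=config.noise_scale, seed=seeds["design"])
        )
    profile_path = run.outdir / "profiles.csv"
    write_profile_table(table, profile_path, delimiter=config.delimiter)
    run.add_file(profile_path, "table", rows=table.n_samples, cols=table.data.shape[1])

    # window + assemble + standardise --------------------------------------
    table = restrict_rf_window(table, config.rf_low, config.rf_high)
    grid = GridSpec(config.rf_low, config.rf_high, config.grid_step)
    raw = assemble_features(table, grid)
    raw_path = run.outdir / "features_raw.csv"
    raw.to_csv(raw_path)
    run.add_file(raw_path, "matrix", rows=raw.n_samples, cols=raw.n_features)
    std = standardise(raw)
    std_path = run.outdir / "features_standardised.csv"
    std.to_csv(std_path)
    run.add_file(std_path, "matrix", rows=std.n_samples, cols=std.n_features)

    # augmentation ----------------------------------------------------------
    aug_std = None
    if config.run_augmentation:
        aug_cfg = AugmentationConfig(
            rf_drift_bound=config.rf_drift_bound,
            au_noise_multiplier=config.au_noise_multiplier,
            sugar_noise_fraction=config.sugar_noise_fraction,
            outer_repeats=config.outer_repeats,
            inner_repeats=config.inner_repeats,
            seed=seeds["augmentation"],
        )
        augmented = augment(raw, aug_cfg)
        aug_std = standardise(augmented)
        aug_path = run.outdir / "features_augmented.npy"
        np.save(aug_path, aug_std.values.astype(np.float32))
        run.add_file(
            aug_path, "matrix", rows=augmented.n_samples, cols=augmented.n_features
        )
        run.write_json(
            "augmentation.json",
            {
                "config": dataclasses.asdict(aug_cfg),
                "rows_in": raw.n_samples,
                "rows_out": augmented.n_samples,
                "labels": [format_sample_label(l) for l in augmented.labels[:: max(1, augmented.n_samples // 100)]],
            },
        )

    # unsupervised ----------------------------------------------------------
    if config.run_hierarchical:
        hc = hierarchical_cluster(std)
        flat = cut_tree(hc, n_clusters=config.hierarchical_cut)
        payload = hc.to_dict()
        payload["flat_cut"] = {
            "n_clusters": config.hierarchical_cut,
            "assignments": flat.tolist(),
        }
        run.write_json("hierarchical.json", payload)
        if config.figures:
            _dendrogram_figure(run, hc, std)
    if config.run_kmeans:
        elbow_k = elbow_select_k(std, config.elbow_kmax, seed=seeds["kmeans"])
        km = kmeans_cluster(std, config.kmeans_k, config.kmeans_restarts, seeds["kmeans"])
        payload = km.to_dict()
        payload["elbow_k"] = elbow_k
        run.write_json("kmeans.json", payload)
        if config.figures:
            _kmeans_figure(run, km, raw)
    if config.run_dbscan:
        eps = config.dbscan_eps
        if eps is None:
            eps = _dbscan_eps_heuristic(std.values, config.dbscan_min_pts)
        db = dbscan_cluster(std, eps, config.dbscan_min_pts)
        payload = db.to_dict()
        payload["n_clusters"] = len(db.sizes)
        run.write_json("dbscan.json", payload)
    if config.run_pca:
        n_comp = min(config.pca_components, std.n_samples - 1, std.n_features)
        pca = pca_decompose(std, n_comp)
        run.write_json("pca.json", pca.to_dict())
        if config.figures:
            _pca_figures(run, pca, std)

    # regression -------------------------------------------------------------
    if config.run_regression:
        reg_payload = {}
        for sugar in SUGARS:
            X, y = sugar_regression_design(std, sugar)
            cmp = compare_methods(
                X,
                y,
                config.regression_max_components,
                folds=config.regression_folds,
                seed=seeds["regression"],
                target=sugar,
            )
            per_method = {"comparison": cmp.to_dict()}
            for method, n_comp in (("PCR", cmp.pcr_components), ("PLS", cmp.pls_components)):
                rep = fit_evaluate(
                    X,
                    y,
                    method,
                    n_comp,
                    train_fraction=config.train_fraction,
                    seed=seeds["regression"],
                    folds=config.regression_folds,
                    rmsecv=cmp.pcr_curve if method == "PCR" else cmp.pls_curve,
                    target=sugar,
                )
                per_method[method] = rep.to_dict()
            reg_payload[sugar] = per_method
        run.write_json("regression.json", reg_payload)
        if config.figures:
            _rmsecv_figure(run, reg_payload)

    # classifier --------------------------------------------------------------
    if config.run_classifier:
        cls_matrix = aug_std if aug_std is not None else std
        cls_cfg = ClassifierConfig(
            hidden_sizes=config.classifier_hidden_sizes,
            dropout=config.classifier_dropout,
            organic_pool_cells=config.classifier_pool_cells,
            max_epochs=config.classifier_max_epochs,
            patience=config.classifier_patience,
            folds=config.classifier_folds,
            seed=seeds["classifier"],
        )
        cls_payload = {}
        for fs in config.classifier_feature_sets:
            report = kfold_evaluate(cls_matrix, config=cls_cfg, feature_set=fs)
            cls_payload[fs] = report.to_dict()
        run.write_json("classifier.json", cls_payload)

    manifest = {
        "config": dataclasses.asdict(run.config),
        "stage_seeds": seeds,
        "outputs": run.entries,
    }
    with open(run.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d outputs in %s", len(run.entries), run.outdir)
    return manifest


# -- figures ----------------------------------------------------------------


def _save(run: PipelineRun, fig, name: str) -> None:
    path = run.outdir / name
    fig.savefig(path, dpi=110)
    import matplotlib.pyplot as plt

    plt.close(fig)
    run.add_file(path, "figure", checksum=False)


def _dendrogram_figure(run, hc, matrix) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    fig, ax = plt.subplots(figsize=(12, 4))
    dendrogram(
        hc.merge_tree,
        labels=[format_sample_label(l) for l in matrix.labels],
        ax=ax,
        leaf_font_size=5,
    )
    ax.set_ylabel("merge height (Euclidean)")
    _save(run, fig, "dendrogram.png")


def _kmeans_figure(run, km, raw) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    names = [f.name for f in raw.features]
    gf = raw.values[:, names.index("glucose")] + raw.values[:, names.index("fructose")]
    sm = raw.values[:, names.index("sucrose")] + raw.values[:, names.index("maltose")]
    fig, ax = plt.subplots()
    sc = ax.scatter(gf, sm, c=km.assignments, cmap="tab10", s=18)
    ax.set_xlabel("glucose + fructose")
    ax.set_ylabel("sucrose + maltose")
    fig.colorbar(sc, label="cluster")
    _save(run, fig, "kmeans_scatter.png")


def _pca_figures(run, pca, matrix) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.bar(
        np.arange(1, len(pca.explained_fraction) + 1),
        100 * pca.explained_fraction,
    )
    ax.set_xlabel("principal component")
    ax.set_ylabel("explained variance (%)")
    _save(run, fig, "pca_scree.png")

    fig, ax = plt.subplots()
    bases = [l.base for l in matrix.labels]
    for base in sorted(set(bases)):
        sel = [i for i, b in enumerate(bases) if b == base]
        ax.scatter(pca.scores[sel, 0], pca.scores[sel, 1], s=16, label=base)
    ax.set_xlabel(f"PC1 ({100 * pca.explained_fraction[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * pca.explained_fraction[1]:.1f}%)")
    ax.legend(fontsize=6)
    _save(run, fig, "pca_scores.png")


def _rmsecv_figure(run, reg_payload) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, (sugar, payload) in zip(axes.ravel(), reg_payload.items()):
        cmp = payload["comparison"]
        ks = np.arange(1, len(cmp["pcr_curve"]) + 1)
        ax.plot(ks, cmp["pcr_curve"], marker="o", ms=3, label="PCR")
        ax.plot(ks, cmp["pls_curve"], marker="s", ms=3, label="PLS")
        ax.set_title(sugar)
        ax.set_xlabel("components")
        ax.set_ylabel("RMSECV")
        ax.legend(fontsize=7)
    fig.tight_layout()
    _save(run, fig, "rmsecv_curves.png")


# -- summary ----------------------------------------------------------------


def summarise_run(manifest: dict | str) -> str:
    """Human-readable collation of every report in a run manifest."""
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            manifest = json.load(fh)
    outdir = Path(manifest["config"]["outdir"])
    if not manifest.get("outputs"):
        raise ValueError("empty manifest")

    def load(name: str) -> dict | None:
        path = outdir / name
        if any(e["name"] == name for e in manifest["outputs"]):
            if not path.exists():
                raise FileNotFoundError(f"manifest lists {name} but it is missing")
            with open(path) as fh:
                return json.load(fh)
        return None

    lines = [
        "# Run summary",
        f"seed: {manifest['config']['seed']}",
        "",
    ]
    aug = load("augmentation.json")
    if aug:
        lines += [
            f"Augmentation: {aug['rows_in']} -> {aug['rows_out']} rows "
            f"(outer {aug['config']['outer_repeats']} x inner {aug['config']['inner_repeats']})",
            "",
        ]
    km = load("kmeans.json")
    if km:
        sizes = ", ".join(str(v) for v in km["sizes"].values())
        lines += [
            f"k-means: k={km['params']['k']} (elbow suggests {km['elbow_k']}), "
            f"sizes [{sizes}], between_SS/total_SS = {100 * km['between_total_ratio']:.1f}%",
            "",
        ]
    db = load("dbscan.json")
    if db:
        lines += [
            f"DBSCAN: eps={db['params']['eps']:.3g}, minPts={db['params']['min_pts']} -> "
            f"{db['n_clusters']} clusters, {db['n_noise']} noise points",
            "",
        ]
    pca = load("pca.json")
    if pca:
        fr = pca["explained_fraction"]
        lines += [
            f"PCA: PC1 {100 * fr[0]:.1f}%, PC2 {100 * fr[1]:.1f}% "
            f"(PC1+PC2 {100 * (fr[0] + fr[1]):.1f}%)",
            "",
        ]
    reg = load("regression.json")
    if reg:
        lines.append("Regression (component count, test RMSEP, test R²):")
        lines.append("sugar | PCR | PLS")
        for sugar, payload in reg.items():
            pcr, pls = payload["PCR"], payload["PLS"]
            lines.append(
                f"{sugar} | {pcr['n_components']} comp, RMSEP {pcr['rmsep']:.4g}, R² {pcr['r2']:.4f}"
                f" | {pls['n_components']} comp, RMSEP {pls['rmsep']:.4g}, R² {pls['r2']:.4f}"
            )
        lines.append("")
    cls = load("classifier.json")
    if cls:
        sets = list(cls)
        lines.append("Classifier fold accuracies (%):")
        lines.append("fold | " + " | ".join(sets))
        n_folds = len(cls[sets[0]]["fold_accuracies"])
        for i in range(n_folds):
            lines.append(
                f"{i + 1} | "
                + " | ".join(f"{cls[s]['fold_accuracies'][i]:.2f}" for s in sets)
            )
        lines.append(
            "mean | " + " | ".join(f"{cls[s]['mean_accuracy']:.2f}" for s in sets)
        )
        lines.append("")
    return "\n".join(lines)
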