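"""End-to-end run: simulate or load -> preprocess -> features -> classify,
PCA and HCA -> JSON report.

The report is written with sorted keys and no timestamps, so two runs with
identical config and seed produce byte-identical files; wall-clock
information goes to the log, never into the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemometrics import cut_clusters, hca, pca
from .classify import cross_validate, make_splits
from .errors import RamanidError
from .features import feature_matrix, feature_names
from .io import load_spectrum_set, save_spectrum_set
from .library import load_library
from .preprocess import PreprocessConfig, run_pipeline
from .spectrum import SpectrumSet
from .synth import SyntheticConfig, simulate_dataset

log = logging.getLogger("ramanid")

__all__ = ["RunConfig", "run_end_to_end", "average_by_class"]


@dataclass
class RunConfig:
    """Configuration of a full run; every output artifact records the seed."""

    seed: int = 42
    manifest: str | None = None        # load measured spectra; None -> simulate
    out_dir: str = "ramanid_run"
    synthetic: SyntheticConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    window_width: float = 200.0
    peaks_per_window: int = 3
    min_prominence: float = 0.02
    n_trees: int = 100
    n_iterations: int = 3
    test_fraction: float = 0.30
    n_components: int = 3
    n_clusters: int = 4
    save_spectra: bool = False


def average_by_class(sset: SpectrumSet) -> tuple[np.ndarray, list[str]]:
    """Mean spectrum per class (rows follow class_names order).

    All spectra must share one grid — the preprocessing pipeline guarantees
    this when inputs were simulated or regridded onto a common axis.
    """
    rows, names = [], []
    for c in sset.class_names:
        members = [s for s in sset if s.label == c]
        if not members:
            continue
        grid = members[0].wavenumbers
        stack = np.vstack([s.regrid(grid).intensities for s in members])
        rows.append(stack.mean(axis=0))
        names.append(c)
    return np.vstack(rows), names


def run_end_to_end(cfg: RunConfig) -> dict:
    """Run the whole analysis and write ``report.json`` under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.manifest is not None:
        log.info("loading spectra from manifest %s", cfg.manifest)
        raw = load_spectrum_set(cfg.manifest)
    else:
        syn = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
        log.info("simulating %d classes x %d replicates (seed %d)",
                 14, syn.n_per_class, syn.seed)
        raw = simulate_dataset(load_library(), syn)

    pipe = run_pipeline(raw, cfg.preprocess)
    if pipe.errors:
        for src, msg in pipe.errors:
            log.error("preprocess failed for %s: %s", src, msg)
    if len(pipe.spectra) == 0:
        raise RamanidError("no spectrum survived preprocessing")
    if cfg.save_spectra:
        save_spectrum_set(pipe.spectra, out / "processed")

    feats = feature_matrix(
        pipe.spectra, window_width=cfg.window_width, k=cfg.peaks_per_window,
        lo=cfg.preprocess.crop_lo, hi=cfg.preprocess.crop_hi,
        min_prominence=cfg.min_prominence,
    )
    X = feats.drop(columns="label").to_numpy()
    y = feats["label"].to_numpy()

    plan = make_splits(y, n_iterations=cfg.n_iterations,
                       test_fraction=cfg.test_fraction, seed=cfg.seed)
    report_cls = cross_validate(X, y, plan, n_trees=cfg.n_trees, seed=cfg.seed)

    avg, class_names = average_by_class(pipe.spectra)
    pca_res = pca(avg, n_components=min(cfg.n_components, avg.shape[0] - 1))
    hca_res = hca(avg, metric="correlation", linkage="ward", labels=class_names)
    clusters = cut_clusters(hca_res, min(cfg.n_clusters, len(class_names)))

    report = {
        "seed": cfg.seed,
        "n_spectra": len(pipe.spectra),
        "preprocess_errors": pipe.errors,
        "feature_schema": feature_names(
            cfg.preprocess.crop_lo, cfg.preprocess.crop_hi,
            cfg.window_width, cfg.peaks_per_window,
        ),
        "classification": json.loads(report_cls.to_json()),
        "pca": {
            "eigenvalues": pca_res.eigenvalues.tolist(),
            "explained_pct": pca_res.explained_pct.tolist(),
            "cumulative_pct": pca_res.cumulative_pct.tolist(),
        },
        "hca": {
            "linkage": hca_res.linkage,
            "metric": hca_res.distance_metric,
            "merge_tree": hca_res.merge_tree.tolist(),
            "clusters": {c: int(g) for c, g in zip(class_names, clusters)},
        },
        "config": {
            "preprocess": dataclasses.asdict(cfg.preprocess),
            "synthetic": dataclasses.asdict(cfg.synthetic) if cfg.synthetic else None,
            "window_width": cfg.window_width,
            "peaks_per_window": cfg.peaks_per_window,
            "min_prominence": cfg.min_prominence,
            "n_trees": cfg.n_trees,
            "n_iterations": cfg.n_iterations,
            "test_fraction": cfg.test_fraction,
        },
    }
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
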