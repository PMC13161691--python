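"""End-to-end orchestration: simulate/load -> preprocess -> align -> voxelize
-> benchmark -> classify, driven by a single config mapping.

Every stage persists its artifact under the run directory together with a
manifest recording the config hash, seeds and stage status, so a run is
re-inspectable and deterministic: identical config and seeds give identical
feature matrices byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .align import (
    AlignerArchitecture,
    TrainConfig,
    apply_alignment,
    save_checkpoint,
    select_reference_batch,
    train_alignment,
)
from .classify import ClassifierConfig, leave_one_batch_out, screen_features, train_classifier, evaluate
from .core import ConfigurationError, EventMatrix, SampleSet, TransformState
from .fcs import read_fcs
from .metrics import kl_matrix, per_channel_wasserstein, preservation_summary, replicate_grouping, spearman_upper
from .preprocess import TransformParams, subsample, transform_sample
from .voxels import DiscretizationScheme, build_feature_matrix, filter_sparse

__all__ = ["load_config", "validate_config", "run_pipeline", "config_hash"]

logger = logging.getLogger(__name__)

STAGES = ("input", "preprocess", "align", "voxelize", "benchmark", "classify")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} did not parse to a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(cfg: dict) -> list[tuple[str, str]]:
    """Return (level, message) findings; 'error' findings block execution."""
    findings: list[tuple[str, str]] = []
    err = lambda msg: findings.append(("error", msg))
    warn = lambda msg: findings.append(("warning", msg))

    if ("simulate" in cfg) == ("input" in cfg):
        err("config must contain exactly one of 'simulate' or 'input'")
    if "input" in cfg:
        meta_path = Path(cfg["input"].get("metadata", ""))
        if not meta_path.is_file():
            err(f"input metadata table not found: {meta_path}")
        else:
            meta = pd.read_csv(meta_path, sep="\t")
            for col in ("sample_id", "batch_id", "path"):
                if col not in meta.columns:
                    err(f"metadata table lacks required column {col!r}")
            if "path" in meta.columns:
                for p in meta["path"]:
                    full = meta_path.parent / p
                    if not full.is_file():
                        err(f"sample file not found: {full}")
    if "simulate" in cfg:
        preset = cfg["simulate"].get("preset", "benchmark")
        if preset not in ("benchmark", "shifted_pair", "cohort"):
            err(f"unknown simulate preset {preset!r}")

    vox = cfg.get("voxelize", {})
    thresholds = vox.get("thresholds", [0.3, 0.6])
    if not (len(thresholds) == 2 and thresholds[0] < thresholds[1]):
        err(f"voxel thresholds must be two increasing values, got {thresholds}")
    sizes = vox.get("sizes", [3])
    if any(k not in (2, 3) for k in sizes):
        err(f"unsupported combination sizes {sizes} (only 2 and 3)")

    al = cfg.get("align", {})
    if al.get("epochs", 1) < 1:
        err("align.epochs must be >= 1")
    if "reference_batch" in al and "reference_seed" in al:
        warn("both reference_batch and reference_seed given; explicit batch wins")

    pre = cfg.get("preprocess", {})
    n_sub = pre.get("subsample", {}).get("n")
    if n_sub is not None and n_sub < 1:
        err("preprocess.subsample.n must be >= 1")
    return findings


def _load_input(cfg: dict) -> SampleSet:
    meta_path = Path(cfg["input"]["metadata"])
    meta = pd.read_csv(meta_path, sep="\t")
    samples = []
    for _, row in meta.iterrows():
        path = meta_path.parent / row["path"]
        if path.suffix.lower() == ".fcs":
            em = read_fcs(path)
            values, markers = em.values, em.marker_names
        else:
            df = pd.read_csv(path)
            values, markers = df.to_numpy(dtype=np.float64), list(df.columns)
        samples.append(
            EventMatrix(
                values=values,
                marker_names=markers,
                sample_id=str(row["sample_id"]),
                batch_id=str(row["batch_id"]),
                biological_id=str(row.get("biological_id", row["sample_id"])),
                label=None if pd.isna(row.get("label")) else str(row.get("label")),
                transform_state=TransformState.RAW,
            )
        )
    return SampleSet(samples)


def _simulate(cfg: dict) -> SampleSet:
    sim = cfg["simulate"]
    preset = sim.get("preset", "benchmark")
    seed = int(sim.get("seed", 0))
    n_cells = int(sim.get("n_cells", 5000))
    if preset == "benchmark":
        spec = synthetic.benchmark_spec(
            n_batches=int(sim.get("n_batches", 3)),
            n_cells_per_sample=n_cells,
            with_outlier=bool(sim.get("with_outlier", True)),
            seed=seed,
        )
        return synthetic.generate_dataset(spec)
    if preset == "shifted_pair":
        spec = synthetic.shifted_pair_spec(
            offset=float(sim.get("offset", 0.2)), n_cells_per_sample=n_cells, seed=seed
        )
        return synthetic.generate_dataset(spec)
    spec = synthetic.cohort_spec(
        shift=float(sim.get("shift", 0.15)),
        n_batches=int(sim.get("n_batches", 4)),
        n_cells_per_sample=n_cells,
        seed=seed,
    )
    return synthetic.generate_cohort(spec, n_per_class=int(sim.get("n_per_class", 20)))


def _preprocess(samples: SampleSet, cfg: dict) -> SampleSet:
    pre = cfg.get("preprocess", {})
    tcfg = pre.get("transform", {})
    kind = tcfg.get("kind", "none")
    out = []
    for s in samples:
        if kind != "none" and s.transform_state is not TransformState.TRANSFORMED:
            params = TransformParams(
                kind=kind,
                **{k: v for k, v in tcfg.items() if k in ("T", "W", "M", "A", "cofactor", "post_scale")},
            )
            s = transform_sample(s, params)
        elif s.transform_state is not TransformState.TRANSFORMED:
            # already in normalized units (synthetic data); mark as such
            s = s.with_values(s.values, TransformState.TRANSFORMED)
        sub = pre.get("subsample")
        if sub:
            s = subsample(s, int(sub["n"]), int(sub.get("seed", 0)))
        out.append(s)
    return SampleSet(out, samples.metadata)


def run_pipeline(cfg: dict, outdir: str | Path | None = None) -> Path:
    """Execute all stages; returns the run directory.

    Raises :class:`ConfigurationError` before any compute if validation finds
    blocking errors; on a stage failure, partial outputs remain on disk and
    the manifest marks the run incomplete with the failing stage.
    """
    findings = validate_config(cfg)
    errors = [msg for level, msg in findings if level == "error"]
    if errors:
        raise ConfigurationError("config validation failed: " + "; ".join(errors))

    outdir = Path(outdir or cfg.get("outdir", "cytovoxel_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    manifest = {"config_hash": chash, "stages": {}, "status": "incomplete"}

    def _checkpoint(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "done", **info}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    current = "input"
    try:
        # 1. input ---------------------------------------------------------
        samples = _simulate(cfg) if "simulate" in cfg else _load_input(cfg)
        samples.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        _checkpoint("input", n_samples=len(samples), batches=samples.batch_ids)

        # 2. preprocess ----------------------------------------------------
        current = "preprocess"
        samples = _preprocess(samples, cfg)
        _checkpoint("preprocess", n_cells=[s.n_cells for s in samples])

        # 3. align ---------------------------------------------------------
        current = "align"
        al = cfg.get("align", {})
        if al.get("enabled", True) and len(samples.batch_ids) >= 2:
            reference = al.get("reference_batch") or select_reference_batch(
                samples.batch_ids, int(al.get("reference_seed", 0))
            )
            tcfg = TrainConfig(
                epochs=int(al.get("epochs", 1200)),
                learning_rate=float(al.get("learning_rate", 0.002)),
                minibatch_size=int(al.get("minibatch_size", 1024)),
                beta0=float(al.get("beta0", 0.002)),
                histogram_bins=int(al.get("histogram_bins", 50)),
                seed=int(al.get("seed", 0)),
            )
            model = train_alignment(list(samples), reference, AlignerArchitecture(), tcfg)
            save_checkpoint(model, outdir / "alignment_model.json")
            aligned = SampleSet([apply_alignment(model, s) for s in samples], samples.metadata)
            _checkpoint("align", reference_batch=reference, epochs=tcfg.epochs, seed=tcfg.seed)
        else:
            aligned = samples
            _checkpoint("align", skipped=True)

        # 4. voxelize ------------------------------------------------------
        current = "voxelize"
        vox = cfg.get("voxelize", {})
        scheme = DiscretizationScheme(tuple(vox.get("thresholds", (0.3, 0.6))))
        sizes = tuple(vox.get("sizes", (3,)))
        vfm = build_feature_matrix(list(aligned), scheme, sizes)
        vfm = filter_sparse(vfm, float(vox.get("min_occupancy", 0.01)))
        vfm.to_tsv(outdir / "features.tsv")
        (outdir / "features_provenance.json").write_text(
            json.dumps(
                {
                    "config_hash": chash,
                    "thresholds": list(scheme.thresholds),
                    "sizes": list(sizes),
                    "min_occupancy": vox.get("min_occupancy", 0.01),
                    "n_features": len(vfm.feature_names),
                    "n_dropped": len(vfm.dropped),
                },
                indent=1,
            )
        )
        _checkpoint("voxelize", n_features=len(vfm.feature_names))

        # 5. benchmark -----------------------------------------------------
        current = "benchmark"
        bench = cfg.get("benchmark", {})
        report: dict = {"config_hash": chash}
        bins = int(bench.get("bins", 50))
        meta = samples.metadata
        has_replicates = (
            "biological_id" in meta.columns
            and meta["biological_id"].notna().all()
            and meta.duplicated("biological_id").any()
        )
        if has_replicates:
            grouping = replicate_grouping(meta)
            km_pre = kl_matrix(list(samples), bins=bins)
            km_post = kl_matrix(list(aligned), bins=bins)
            pre = preservation_summary(km_pre, grouping)
            post = preservation_summary(km_post, grouping, baseline=km_pre)
            report["kl_ratio_pre"] = pre.ratio
            report["kl_ratio_post"] = post.ratio
            report["spearman_rho_post_vs_pre"] = post.spearman_rho
            km_pre.to_csv(outdir / "kl_matrix_pre.tsv", sep="\t")
            km_post.to_csv(outdir / "kl_matrix_post.tsv", sep="\t")
            # per-channel Wasserstein between technical replicate pairs
            w_pre, w_post = [], []
            by_bio = meta.groupby("biological_id")["sample_id"].apply(list)
            for ids in by_bio:
                for i, a in enumerate(ids):
                    for b in ids[i + 1 :]:
                        w_pre.append(per_channel_wasserstein(samples[a], samples[b])[1])
                        w_post.append(per_channel_wasserstein(aligned[a], aligned[b])[1])
            if w_pre:
                report["replicate_wasserstein_pre"] = float(np.mean(w_pre))
                report["replicate_wasserstein_post"] = float(np.mean(w_post))
        (outdir / "benchmark.json").write_text(json.dumps(report, indent=1))
        _checkpoint("benchmark", computed=has_replicates)

        # 6. classify ------------------------------------------------------
        current = "classify"
        cl = cfg.get("classify", {})
        labels = meta.get("label")
        can_classify = labels is not None and labels.notna().all() and labels.nunique() >= 2
        if cl.get("enabled", can_classify) and can_classify:
            ccfg = ClassifierConfig(
                n_trees=int(cl.get("trees", 500)),
                max_depth=int(cl.get("depth", 6)),
                seed=int(cl.get("seed", 0)),
            )
            split = cl.get("split", "lobo")
            ordered = vfm.data.loc[meta["sample_id"]]
            if split == "lobo":
                pooled, folds = leave_one_batch_out(
                    ordered, labels.to_numpy(), meta["batch_id"].to_numpy(), ccfg
                )
                result = pooled.to_dict()
                result["folds"] = [f.to_dict() for f in folds]
            else:
                holdout = split.split(":", 1)[1]
                test = (meta["batch_id"] == holdout).to_numpy()
                clf = train_classifier(ordered[~test], labels[~test].to_numpy(), ccfg)
                rep = evaluate(clf, ordered[test].to_numpy(), labels[test].to_numpy(), ccfg.threshold,
                               split=f"holdout:{holdout}")
                result = rep.to_dict()
            screen = screen_features(vfm.data.loc[meta["sample_id"]], labels.to_numpy())
            screen.to_csv(outdir / "feature_screen.tsv", sep="\t", index=False)
            result["config_hash"] = chash
            (outdir / "classification.json").write_text(json.dumps(result, indent=1, default=float))
            _checkpoint("classify", split=split)
        else:
            _checkpoint("classify", skipped=True)

        manifest["status"] = "complete"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    except Exception:
        manifest["status"] = f"failed at stage {current}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        logger.exception("pipeline failed at stage %s", current)
        raise
    return outdir
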