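"""Seeded multi-batch cytometry simulator.

Each sample is a Gaussian-mixture draw in normalized marker space (one
component per cell population, e.g. CD4 T cells, CD8 T cells, B cells, NK
cells, myeloid cells), pushed through a per-batch monotone per-channel
distortion that emulates an antibody-dilution style batch effect
(``clip(gain * x**exponent + offset + noise, 0, 1)``).

Ground truth is fully known: biological replicates share population structure
up to a small subject-level jitter, technical replicates of one subject differ
only by the batch distortion, a planted outlier subject has strongly divergent
population proportions, and a planted class effect shifts the mixture weight
of one population so that a chosen hypervoxel's expected occupancy differs
between classes by a stated amount.

Determinism: every sample's random stream is derived from
``(master seed, biological id, batch id)`` via a stable hash, so adding
samples never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    EventMatrix,
    IdentityNotFoundError,
    SampleSet,
    TransformState,
)

__all__ = [
    "PopulationSpec",
    "BatchDistortion",
    "PlantedClassEffect",
    "SyntheticSpec",
    "generate_sample",
    "generate_dataset",
    "generate_cohort",
    "default_panel",
    "default_populations",
    "outlier_populations",
    "benchmark_spec",
    "shifted_pair_spec",
    "cohort_spec",
    "write_dataset",
]


@dataclass
class PopulationSpec:
    """One mixture component: a cell population in normalized marker space."""

    name: str
    mean: np.ndarray
    covariance: np.ndarray
    proportion: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        if self.covariance.ndim == 1:
            self.covariance = np.diag(self.covariance)
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ConfigurationError(f"covariance shape mismatch for population {self.name!r}")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-12):
            raise ConfigurationError(f"covariance not symmetric for population {self.name!r}")
        eigvals = np.linalg.eigvalsh(self.covariance)
        if eigvals.min() < -1e-10:
            raise ConfigurationError(f"covariance not PSD for population {self.name!r}")
        if not 0.0 <= self.proportion <= 1.0:
            raise ConfigurationError(f"proportion out of [0, 1] for population {self.name!r}")


@dataclass
class BatchDistortion:
    """Monotone per-channel intensity distortion for one batch.

    ``x -> clip(gain * x**exponent + offset + eps, 0, 1)`` with
    ``eps ~ Normal(0, noise_sd)``; gain and exponent must be positive so the
    composed map is strictly monotone increasing on ``[0, 1]`` per channel.
    Scalars broadcast across channels.
    """

    gain: float | np.ndarray = 1.0
    offset: float | np.ndarray = 0.0
    exponent: float | np.ndarray = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gain", "exponent"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ConfigurationError(f"distortion {name} must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = np.clip(values, 0.0, 1.0)
        out = np.asarray(self.gain) * x ** np.asarray(self.exponent) + np.asarray(self.offset)
        if self.noise_sd > 0:
            out = out + rng.normal(0.0, self.noise_sd, size=out.shape)
        return np.clip(out, 0.0, 1.0)

    def is_identity(self) -> bool:
        return (
            np.all(np.asarray(self.gain) == 1.0)
            and np.all(np.asarray(self.offset) == 0.0)
            and np.all(np.asarray(self.exponent) == 1.0)
            and self.noise_sd == 0.0
        )


@dataclass
class PlantedClassEffect:
    """Shift the expected occupancy of one hypervoxel between classes.

    Implemented by re-weighting the mixture: the population whose mean lies in
    the target voxel gains ``shift`` proportion in ``positive_label`` subjects,
    taken proportionally from the other populations.
    """

    markers: tuple[str, ...]
    levels: tuple[str, ...]  # per-marker "LOW"/"MED"/"HIGH"
    shift: float
    positive_label: str = "pos"
    thresholds: tuple[float, float] = (0.3, 0.6)

    def _level_of(self, value: float) -> str:
        lo, hi = self.thresholds
        if value < lo:
            return "LOW"
        if value > hi:
            return "HIGH"
        return "MED"

    def target_population(self, marker_names: list[str], populations: list[PopulationSpec]) -> str:
        idx = []
        for m in self.markers:
            if m not in marker_names:
                raise ConfigurationError(f"class-effect marker {m!r} not in panel")
            idx.append(marker_names.index(m))
        for pop in populations:
            levels = tuple(self._level_of(pop.mean[i]) for i in idx)
            if levels == tuple(self.levels):
                return pop.name
        raise ConfigurationError(
            f"no population occupies voxel {self.markers}={self.levels}; effect is impossible"
        )


@dataclass
class SyntheticSpec:
    """Full description of a seeded multi-batch synthetic experiment."""

    marker_names: list[str]
    populations: dict[str, list[PopulationSpec]]  # biological id -> mixture
    distortions: dict[str, BatchDistortion]  # batch id -> distortion
    n_cells_per_sample: int = 10_000
    labels: dict[str, str] = field(default_factory=dict)  # biological id -> class
    planted_outlier: str | None = None
    planted_class_effect: PlantedClassEffect | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.distortions) < 1:
            raise ConfigurationError("at least one batch distortion required")
        if self.n_cells_per_sample < 1:
            raise ConfigurationError("n_cells_per_sample must be >= 1")
        m = len(self.marker_names)
        for bio, pops in self.populations.items():
            total = sum(p.proportion for p in pops)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"proportions for {bio!r} sum to {total}, not 1")
            for p in pops:
                if p.mean.size != m:
                    raise ConfigurationError(f"population {p.name!r} dimension != panel size")
        if self.planted_outlier is not None and self.planted_outlier not in self.populations:
            raise IdentityNotFoundError(f"planted outlier {self.planted_outlier!r} unknown")
        if self.planted_class_effect is not None:
            # Validate the voxel is attainable for every biological identity.
            for pops in self.populations.values():
                self.planted_class_effect.target_population(self.marker_names, pops)

    @property
    def batch_ids(self) -> list[str]:
        return list(self.distortions)

    @property
    def biological_ids(self) -> list[str]:
        return list(self.populations)


def _sample_rng(seed: int, *identifiers: str) -> np.random.Generator:
    """Stable per-sample stream from (master seed, string identifiers)."""
    digest = hashlib.sha256("\x00".join(identifiers).encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def _shift_proportions(pops: list[PopulationSpec], target: str, shift: float) -> list[PopulationSpec]:
    base = {p.name: p.proportion for p in pops}
    if base[target] + shift > 1.0 or base[target] + shift < 0.0:
        raise ConfigurationError("planted class-effect shift pushes proportion outside [0, 1]")
    other_total = 1.0 - base[target]
    scale = (other_total - shift) / other_total
    out = []
    for p in pops:
        prop = base[target] + shift if p.name == target else p.proportion * scale
        out.append(PopulationSpec(p.name, p.mean, p.covariance, prop))
    return out


def _draw_mixture(
    pops: list[PopulationSpec], n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    props = np.array([p.proportion for p in pops])
    counts = rng.multinomial(n_cells, props)
    blocks = [
        rng.multivariate_normal(p.mean, p.covariance, size=int(c), method="cholesky")
        for p, c in zip(pops, counts)
        if c > 0
    ]
    cells = np.concatenate(blocks, axis=0)
    rng.shuffle(cells, axis=0)
    return np.clip(cells, 0.0, 1.0)


def _populations_for(spec: SyntheticSpec, biological_id: str) -> list[PopulationSpec]:
    pops = spec.populations[biological_id]
    effect = spec.planted_class_effect
    if effect is not None and spec.labels.get(biological_id) == effect.positive_label:
        target = effect.target_population(spec.marker_names, pops)
        pops = _shift_proportions(pops, target, effect.shift)
    return pops


def generate_sample(spec: SyntheticSpec, biological_id: str, batch_id: str) -> EventMatrix:
    """Draw one sample: mixture draw, then the batch's monotone distortion.

    Deterministic given ``(spec.seed, biological_id, batch_id)``.
    """
    if batch_id not in spec.distortions:
        raise IdentityNotFoundError(f"unknown batch id {batch_id!r}")
    if biological_id not in spec.populations:
        raise IdentityNotFoundError(f"unknown biological id {biological_id!r}")
    rng = _sample_rng(spec.seed, biological_id, batch_id)
    cells = _draw_mixture(_populations_for(spec, biological_id), spec.n_cells_per_sample, rng)
    values = spec.distortions[batch_id].apply(cells, rng)
    return EventMatrix(
        values=values,
        marker_names=list(spec.marker_names),
        sample_id=f"{biological_id}@{batch_id}",
        batch_id=batch_id,
        biological_id=biological_id,
        label=spec.labels.get(biological_id),
        transform_state=TransformState.TRANSFORMED,
    )


def generate_dataset(spec: SyntheticSpec) -> SampleSet:
    """One sample per (biological identity x batch), with a metadata table."""
    samples = [
        generate_sample(spec, bio, batch)
        for bio in spec.biological_ids
        for batch in spec.batch_ids
    ]
    return SampleSet(samples)


def generate_cohort(
    spec: SyntheticSpec,
    n_per_class: int,
    class_labels: tuple[str, str] = ("neg", "pos"),
    batch_ids: list[str] | None = None,
    proportion_jitter: float = 0.10,
) -> SampleSet:
    """A labeled cohort: one sample per subject, batches balanced by class.

    Subjects of each class are derived from the spec's first biological
    identity by a log-normal jitter of mixture proportions (subject-level
    biological variability); ``pos`` subjects additionally carry the planted
    class effect. Subjects are assigned round-robin to batches within class so
    every batch contains both classes (required for leave-one-batch-out
    evaluation).
    """
    if spec.planted_class_effect is None:
        raise ConfigurationError("cohort generation requires a planted_class_effect")
    batch_ids = batch_ids or spec.batch_ids
    base_bio = spec.biological_ids[0]
    base_pops = spec.populations[base_bio]
    effect = spec.planted_class_effect
    target = effect.target_population(spec.marker_names, base_pops)

    samples = []
    for label in class_labels:
        for i in range(n_per_class):
            subject = f"{label}{i:03d}"
            rng = _sample_rng(spec.seed, "cohort", subject)
            props = np.array([p.proportion for p in base_pops])
            props = props * np.exp(rng.normal(0.0, proportion_jitter, size=props.size))
            props = props / props.sum()
            pops = [
                PopulationSpec(p.name, p.mean, p.covariance, w)
                for p, w in zip(base_pops, props)
            ]
            if label == effect.positive_label:
                pops = _shift_proportions(pops, target, effect.shift)
            batch = batch_ids[i % len(batch_ids)]
            cell_rng = _sample_rng(spec.seed, subject, batch)
            cells = _draw_mixture(pops, spec.n_cells_per_sample, cell_rng)
            values = spec.distortions[batch].apply(cells, cell_rng)
            samples.append(
                EventMatrix(
                    values=values,
                    marker_names=list(spec.marker_names),
                    sample_id=f"{subject}@{batch}",
                    batch_id=batch,
                    biological_id=subject,
                    label=label,
                    transform_state=TransformState.TRANSFORMED,
                )
            )
    return SampleSet(samples)


# ---------------------------------------------------------------------------
# Ready-made specs


def default_panel() -> list[str]:
    return ["CD3", "CD19", "CD8", "CD44", "Ly6C", "NK1"]


def default_populations(sd: float = 0.06) -> list[PopulationSpec]:
    """Five splenocyte-like populations on the six-marker default panel."""
    var = sd * sd
    defs = [
        # name,        CD3   CD19  CD8   CD44  Ly6C  NK1    proportion
        ("T_CD4", [0.75, 0.10, 0.15, 0.45, 0.20, 0.10], 0.34),
        ("T_CD8", [0.75, 0.10, 0.75, 0.45, 0.20, 0.10], 0.16),
        ("B", [0.10, 0.80, 0.10, 0.40, 0.15, 0.10], 0.34),
        ("NK", [0.12, 0.10, 0.20, 0.50, 0.30, 0.80], 0.08),
        ("Myeloid", [0.10, 0.12, 0.10, 0.70, 0.75, 0.15], 0.08),
    ]
    return [PopulationSpec(n, np.array(m), np.full(6, var), p) for n, m, p in defs]


def outlier_populations(sd: float = 0.06) -> list[PopulationSpec]:
    """A lymphocyte-deficient mixture (no mature T/B cells), used as the
    planted biological outlier."""
    base = {p.name: p for p in default_populations(sd)}
    props = {"T_CD4": 0.03, "T_CD8": 0.02, "B": 0.05, "NK": 0.42, "Myeloid": 0.48}
    return [
        PopulationSpec(n, base[n].mean, base[n].covariance, w) for n, w in props.items()
    ]


def _jittered(pops: list[PopulationSpec], rng: np.random.Generator,
              prop_sd: float = 0.12, mean_sd: float = 0.012) -> list[PopulationSpec]:
    props = np.array([p.proportion for p in pops])
    props = props * np.exp(rng.normal(0.0, prop_sd, size=props.size))
    props /= props.sum()
    return [
        PopulationSpec(p.name, p.mean + rng.normal(0.0, mean_sd, size=p.mean.size),
                       p.covariance, w)
        for p, w in zip(pops, props)
    ]


def benchmark_spec(
    n_wildtype: int = 3,
    n_batches: int = 3,
    n_cells_per_sample: int = 10_000,
    with_outlier: bool = True,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> SyntheticSpec:
    """Replicate-vial benchmark: wild-type biological replicates split across
    batches with distinct monotone distortions, plus an optional outlier
    subject with divergent population proportions."""
    populations: dict[str, list[PopulationSpec]] = {}
    for i in range(n_wildtype):
        rng = _sample_rng(seed, "wildtype", str(i))
        populations[f"WT{i + 1}"] = _jittered(default_populations(), rng)
    if with_outlier:
        populations["outlier"] = outlier_populations()

    shapes = [
        BatchDistortion(),  # reference-like batch, no distortion
        BatchDistortion(gain=1.08, offset=0.05, exponent=1.0, noise_sd=noise_sd),
        BatchDistortion(gain=0.92, offset=-0.02, exponent=1.15, noise_sd=noise_sd),
        BatchDistortion(gain=1.0, offset=0.08, exponent=0.9, noise_sd=noise_sd),
    ]
    if n_batches > len(shapes):
        raise ConfigurationError(f"benchmark_spec supports at most {len(shapes)} batches")
    distortions = {f"batch{i + 1}": shapes[i] for i in range(n_batches)}
    return SyntheticSpec(
        marker_names=default_panel(),
        populations=populations,
        distortions=distortions,
        n_cells_per_sample=n_cells_per_sample,
        planted_outlier="outlier" if with_outlier else None,
        seed=seed,
    )


def shifted_pair_spec(
    offset: float = 0.2,
    n_biological: int = 2,
    n_cells_per_sample: int = 6_000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticSpec:
    """Two batches, the second displaced by a constant per-channel offset."""
    populations = {}
    for i in range(n_biological):
        rng = _sample_rng(seed, "wildtype", str(i))
        populations[f"WT{i + 1}"] = _jittered(default_populations(), rng)
    return SyntheticSpec(
        marker_names=default_panel(),
        populations=populations,
        distortions={
            "batch1": BatchDistortion(noise_sd=noise_sd),
            "batch2": BatchDistortion(offset=offset, noise_sd=noise_sd),
        },
        n_cells_per_sample=n_cells_per_sample,
        seed=seed,
    )


def cohort_spec(
    shift: float = 0.15,
    n_batches: int = 4,
    n_cells_per_sample: int = 2_000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticSpec:
    """Spec for labeled cohorts: CD3-high/CD8-high/CD19-low voxel occupancy is
    shifted upward in the positive class (CD8 T-cell expansion)."""
    distortions = {"batch1": BatchDistortion(noise_sd=noise_sd)}
    mild = [
        BatchDistortion(gain=1.04, offset=0.02, noise_sd=noise_sd),
        BatchDistortion(gain=0.97, offset=-0.015, noise_sd=noise_sd),
        BatchDistortion(gain=1.0, offset=0.03, exponent=1.05, noise_sd=noise_sd),
    ]
    for i in range(1, n_batches):
        distortions[f"batch{i + 1}"] = mild[(i - 1) % len(mild)]
    return SyntheticSpec(
        marker_names=default_panel(),
        populations={"base": default_populations()},
        distortions=distortions,
        n_cells_per_sample=n_cells_per_sample,
        planted_class_effect=PlantedClassEffect(
            markers=("CD3", "CD19", "CD8"),
            levels=("HIGH", "LOW", "HIGH"),
            shift=shift,
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Serialization


def write_dataset(dataset: SampleSet, outdir: str | Path) -> Path:
    """Write samples as delimited text plus a metadata table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in dataset:
        s.to_frame().to_csv(outdir / f"{s.sample_id}.csv", index=False)
    dataset.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    return outdir


def spec_to_json(spec: SyntheticSpec, path: str | Path) -> None:
    doc = {
        "marker_names": spec.marker_names,
        "n_cells_per_sample": spec.n_cells_per_sample,
        "seed": spec.seed,
        "planted_outlier": spec.planted_outlier,
        "labels": spec.labels,
        "populations": {
            bio: [
                {
                    "name": p.name,
                    "mean": p.mean.tolist(),
                    "covariance": p.covariance.tolist(),
                    "proportion": p.proportion,
                }
                for p in pops
            ]
            for bio, pops in spec.populations.items()
        },
        "distortions": {
            b: {
                "gain": np.asarray(d.gain).tolist(),
                "offset": np.asarray(d.offset).tolist(),
                "exponent": np.asarray(d.exponent).tolist(),
                "noise_sd": d.noise_sd,
            }
            for b, d in spec.distortions.items()
        },
    }
    if spec.planted_class_effect is not None:
        e = spec.planted_class_effect
        doc["planted_class_effect"] = {
            "markers": list(e.markers),
            "levels": list(e.levels),
            "shift": e.shift,
            "positive_label": e.positive_label,
            "thresholds": list(e.thresholds),
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def spec_from_json(path: str | Path) -> SyntheticSpec:
    doc = json.loads(Path(path).read_text())
    effect = None
    if "planted_class_effect" in doc:
        e = doc["planted_class_effect"]
        effect = PlantedClassEffect(
            markers=tuple(e["markers"]),
            levels=tuple(e["levels"]),
            shift=e["shift"],
            positive_label=e["positive_label"],
            thresholds=tuple(e["thresholds"]),
        )
    return SyntheticSpec(
        marker_names=doc["marker_names"],
        populations={
            bio: [
                PopulationSpec(p["name"], np.array(p["mean"]), np.array(p["covariance"]), p["proportion"])
                for p in pops
            ]
            for bio, pops in doc["populations"].items()
        },
        distortions={
            b: BatchDistortion(
                gain=np.array(d["gain"]) if isinstance(d["gain"], list) else d["gain"],
                offset=np.array(d["offset"]) if isinstance(d["offset"], list) else d["offset"],
                exponent=np.array(d["exponent"]) if isinstance(d["exponent"], list) else d["exponent"],
                noise_sd=d["noise_sd"],
            )
            for b, d in doc["distortions"].items()
        },
        n_cells_per_sample=doc["n_cells_per_sample"],
        labels=doc.get("labels") or {},
        planted_outlier=doc.get("planted_outlier"),
        planted_class_effect=effect,
        seed=doc["seed"],
    )
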