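"""Autoencoder batch alignment against a reference batch.

One model is trained jointly on cells pooled from every batch (reference
included) and applied uniformly to every sample. The objective combines

* an identity-anchored reconstruction term: mean squared error between the
  network output and its own input cells, which preserves per-cell structure,
  and
* a distribution-matching term: the mean over markers of the 1-D
  histogram-Wasserstein distance between the output's per-marker histograms
  and the pooled reference-batch histograms, weighted by a coefficient
  ``beta`` that decays linearly over training to a floor. Within a minibatch
  the distance is computed per acquisition batch and averaged, so every
  batch's output marginals are pulled onto the reference individually —
  matching only the pooled mixture would let batches sit on opposite sides
  of the target.

During training the histogram is made differentiable by soft binning (linear
interpolation between adjacent bin centers); on inputs located at bin centers
it coincides exactly with the hard-binned :func:`histogram_loss`. Because a
distributional term has O(1/n) per-cell gradients while the reconstruction
spring force is proportional to the displacement being corrected, the
histogram gradient is scaled by ``hist_grad_scale`` so the two terms are
commensurate; see the methods note for the balance argument.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    ConfigurationError,
    CytoVoxelError,
    EmptySampleError,
    EventMatrix,
    TransformState,
    check_shared_panel,
)
from .nn import MLP, Adam

__all__ = [
    "AlignerArchitecture",
    "TrainConfig",
    "ReferenceDistribution",
    "AlignmentModel",
    "select_reference_batch",
    "build_reference",
    "binned_wasserstein",
    "histogram_loss",
    "train_alignment",
    "apply_alignment",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)


@dataclass
class AlignerArchitecture:
    """Encoder widths are mirrored into the decoder; output width = input."""

    encoder_widths: tuple[int, ...] = (64, 32, 16)
    batch_norm: bool = True

    def widths(self, n_markers: int) -> list[int]:
        enc = list(self.encoder_widths)
        return [n_markers] + enc + enc[-2::-1] + [n_markers]


@dataclass
class TrainConfig:
    epochs: int = 1200
    learning_rate: float = 0.002
    minibatch_size: int = 1024
    beta0: float = 0.002
    beta_floor_frac: float = 0.25  # linear decay ends at beta0 * this
    histogram_bins: int = 50
    histogram_range: tuple[float, float] = (0.0, 1.0)
    hist_grad_scale: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.minibatch_size, self.histogram_bins) < 1:
            raise ConfigurationError("epochs, minibatch_size and histogram_bins must be positive")
        if self.learning_rate <= 0 or self.beta0 < 0:
            raise ConfigurationError("learning_rate must be positive and beta0 non-negative")
        if not 0.0 <= self.beta_floor_frac <= 1.0:
            raise ConfigurationError("beta_floor_frac must lie in [0, 1]")

    def beta_at(self, epoch: int) -> float:
        """Non-increasing linear schedule from beta0 down to its floor."""
        if self.epochs == 1:
            return self.beta0
        frac = epoch / (self.epochs - 1)
        return self.beta0 * (1.0 - (1.0 - self.beta_floor_frac) * frac)


@dataclass
class ReferenceDistribution:
    """Pooled per-marker histograms of the reference batch."""

    edges: np.ndarray  # shared bin edges, length bins + 1
    probs: np.ndarray  # (markers, bins), each row sums to 1
    marker_names: list[str]
    batch_id: str
    n_cells: int

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def select_reference_batch(batch_ids, seed: int) -> str:
    """Uniform seeded choice of the reference batch."""
    ids = sorted(batch_ids)
    if len(ids) < 2:
        raise ConfigurationError(
            "alignment needs >= 2 batches; a single batch needs no correction"
        )
    choice = ids[np.random.default_rng(seed).integers(len(ids))]
    logger.info("selected reference batch %r (seed %d)", choice, seed)
    return choice


def build_reference(
    samples: list[EventMatrix],
    bins: int = 50,
    histogram_range: tuple[float, float] = (0.0, 1.0),
) -> ReferenceDistribution:
    """Pool all reference-batch cells into normalized per-marker histograms."""
    if not samples:
        raise EmptySampleError("reference batch contains no samples")
    panel = check_shared_panel(samples)
    pooled = np.concatenate([s.values for s in samples], axis=0)
    if pooled.shape[0] == 0:
        raise EmptySampleError("reference batch contains no cells")
    lo, hi = histogram_range
    edges = np.linspace(lo, hi, bins + 1)
    clipped = np.clip(pooled, lo, hi)
    probs = np.stack(
        [np.histogram(clipped[:, j], bins=edges)[0] for j in range(pooled.shape[1])]
    ).astype(np.float64)
    probs /= probs.sum(axis=1, keepdims=True)
    return ReferenceDistribution(
        edges=edges,
        probs=probs,
        marker_names=panel,
        batch_id=samples[0].batch_id,
        n_cells=pooled.shape[0],
    )


def binned_wasserstein(p: np.ndarray, q: np.ndarray, bin_width: float) -> float:
    """1-D Wasserstein between two histograms sharing bin edges:
    cumulative-sum difference scaled by the bin width."""
    c = np.cumsum(np.asarray(p, dtype=np.float64) - np.asarray(q, dtype=np.float64))
    return float(np.abs(c).sum() * bin_width)


def histogram_loss(output: np.ndarray, ref: ReferenceDistribution) -> float:
    """Mean over markers of the binned Wasserstein distance to the reference."""
    output = np.asarray(output, dtype=np.float64)
    if output.ndim != 2 or output.shape[1] != ref.probs.shape[0]:
        raise ConfigurationError(
            f"output has {output.shape[1] if output.ndim == 2 else '?'} markers, "
            f"reference has {ref.probs.shape[0]}"
        )
    lo, hi = float(ref.edges[0]), float(ref.edges[-1])
    clipped = np.clip(output, lo, hi)
    total = 0.0
    for j in range(output.shape[1]):
        h = np.histogram(clipped[:, j], bins=ref.edges)[0].astype(np.float64)
        h /= h.sum()
        total += binned_wasserstein(h, ref.probs[j], ref.bin_width)
    return total / output.shape[1]


def _soft_histogram_wasserstein(
    y: np.ndarray, ref: ReferenceDistribution
) -> tuple[float, np.ndarray]:
    """Differentiable surrogate of :func:`histogram_loss`.

    Returns ``(mean-over-markers Wasserstein, dW/dy)`` where the soft
    histogram interpolates each cell's mass linearly between the two nearest
    bin centers. At bin centers it equals the hard-binned histogram exactly.
    """
    n, m = y.shape
    bins = ref.probs.shape[1]
    bw = ref.bin_width
    lo = float(ref.edges[0])
    c0 = lo + 0.5 * bw  # first bin center

    t = np.clip((y - c0) / bw, 0.0, bins - 1.0)
    k = np.minimum(t.astype(np.int64), bins - 2)
    frac = t - k
    interior = (t > 0.0) & (t < bins - 1.0)

    loss = 0.0
    grad = np.zeros_like(y)
    for j in range(m):
        h = np.zeros(bins)
        np.add.at(h, k[:, j], 1.0 - frac[:, j])
        np.add.at(h, k[:, j] + 1, frac[:, j])
        h /= n
        c = np.cumsum(h - ref.probs[j])
        loss += np.abs(c).sum() * bw
        # dW/dh_k = bw * sum_{l >= k} sign(c_l); per-cell grad via the two
        # soft-assignment weights (+-1/(n*bw) each).
        g = bw * np.sign(c)[::-1].cumsum()[::-1]
        grad[:, j] = np.where(
            interior[:, j], (g[k[:, j] + 1] - g[k[:, j]]) / (n * bw), 0.0
        )
    return loss / m, grad / m


@dataclass
class AlignmentModel:
    """Trained aligner: a pure per-cell map plus its provenance."""

    net: MLP
    architecture: AlignerArchitecture
    config: TrainConfig
    reference: ReferenceDistribution
    marker_names: list[str]
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    # columns: (reconstruction MSE, histogram loss) per epoch

    def transform(self, values: np.ndarray) -> np.ndarray:
        lo, hi = float(self.reference.edges[0]), float(self.reference.edges[-1])
        return np.clip(self.net.forward(np.asarray(values, dtype=np.float64)), lo, hi)


def train_alignment(
    samples: list[EventMatrix],
    reference_batch: str,
    arch: AlignerArchitecture | None = None,
    cfg: TrainConfig | None = None,
) -> AlignmentModel:
    """Train the aligner on cells pooled from all batches.

    The reference batch's pooled histograms are the distribution target; the
    model is later applied to every sample, reference included, so there is
    no reference/non-reference discontinuity.
    """
    arch = arch or AlignerArchitecture()
    cfg = cfg or TrainConfig()
    panel = check_shared_panel(samples)
    for s in samples:
        if s.transform_state is not TransformState.TRANSFORMED:
            raise ConfigurationError(f"sample {s.sample_id} is not transformed")
    ref_samples = [s for s in samples if s.batch_id == reference_batch]
    if not ref_samples:
        raise ConfigurationError(f"no samples in reference batch {reference_batch!r}")
    if all(s.batch_id == reference_batch for s in samples):
        raise ConfigurationError("alignment needs at least one non-reference batch")

    ref = build_reference(ref_samples, cfg.histogram_bins, cfg.histogram_range)
    data = np.concatenate([s.values for s in samples], axis=0)
    batch_codes = np.concatenate(
        [np.full(s.n_cells, i) for i, s in enumerate(samples)]
    )
    # group cells by acquisition batch, not by sample: the histogram term
    # aligns batch-level marginals and must stay blind to biology
    batch_names = {i: s.batch_id for i, s in enumerate(samples)}
    uniq = {b: j for j, b in enumerate(dict.fromkeys(batch_names[i] for i in batch_names))}
    batch_codes = np.array([uniq[batch_names[i]] for i in batch_codes])
    n, m = data.shape

    rng = np.random.default_rng(cfg.seed)
    net = MLP(arch.widths(m), arch.batch_norm, rng)
    opt = Adam(net.params(), cfg.learning_rate)

    trace = np.zeros((cfg.epochs, 2))
    for epoch in range(cfg.epochs):
        beta = cfg.beta_at(epoch)
        order = rng.permutation(n)
        recon_sum = hist_sum = 0.0
        n_batches = 0
        for start in range(0, n, cfg.minibatch_size):
            idx = order[start : start + cfg.minibatch_size]
            if idx.size < 2:
                continue  # batch-norm statistics need >= 2 cells
            x = data[idx]
            y = net.forward(x, training=True)
            resid = y - x
            recon = float(np.mean(resid**2))
            hist = 0.0
            dhist = np.zeros_like(y)
            groups = [batch_codes[idx] == b for b in np.unique(batch_codes[idx])]
            groups = [g for g in groups if g.sum() >= 32]  # need a stable histogram
            for g in groups:
                h, dh = _soft_histogram_wasserstein(y[g], ref)
                hist += h / len(groups)
                dhist[g] = dh / len(groups)
            if not np.isfinite(recon) or not np.isfinite(hist):
                raise CytoVoxelError(
                    f"non-finite loss at epoch {epoch}, minibatch {n_batches} "
                    f"(recon={recon}, hist={hist})"
                )
            grad = 2.0 * resid / resid.size + beta * cfg.hist_grad_scale * dhist
            net.backward(grad)
            opt.step()
            recon_sum += recon
            hist_sum += hist
            n_batches += 1
        trace[epoch] = (recon_sum / n_batches, hist_sum / n_batches)
        if epoch % max(1, cfg.epochs // 10) == 0:
            logger.info(
                "epoch %d/%d beta=%.2e recon=%.5f hist=%.5f",
                epoch, cfg.epochs, beta, *trace[epoch],
            )

    return AlignmentModel(
        net=net,
        architecture=arch,
        config=cfg,
        reference=ref,
        marker_names=panel,
        loss_trace=trace,
    )


def apply_alignment(model: AlignmentModel, em: EventMatrix) -> EventMatrix:
    """Apply the trained map row-wise; output clipped to the histogram range.

    Inference uses frozen normalization statistics, so the result depends only
    on each cell, never on the composition of the batch it arrives in.
    """
    if em.marker_names != model.marker_names:
        raise ConfigurationError(
            f"marker order {em.marker_names} does not match model {model.marker_names}"
        )
    return em.with_values(model.transform(em.values), TransformState.TRANSFORMED)


# ---------------------------------------------------------------------------
# Checkpointing (self-describing JSON)


def save_checkpoint(model: AlignmentModel, path: str | Path) -> Path:
    doc = {
        "architecture": {
            "encoder_widths": list(model.architecture.encoder_widths),
            "batch_norm": model.architecture.batch_norm,
        },
        "config": {
            "epochs": model.config.epochs,
            "learning_rate": model.config.learning_rate,
            "minibatch_size": model.config.minibatch_size,
            "beta0": model.config.beta0,
            "beta_floor_frac": model.config.beta_floor_frac,
            "histogram_bins": model.config.histogram_bins,
            "histogram_range": list(model.config.histogram_range),
            "hist_grad_scale": model.config.hist_grad_scale,
            "seed": model.config.seed,
        },
        "marker_names": model.marker_names,
        "reference": {
            "edges": model.reference.edges.tolist(),
            "probs": model.reference.probs.tolist(),
            "batch_id": model.reference.batch_id,
            "n_cells": model.reference.n_cells,
        },
        "loss_trace": model.loss_trace.tolist(),
        "state": model.net.state_dict(),
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_checkpoint(path: str | Path) -> AlignmentModel:
    doc = json.loads(Path(path).read_text())
    arch = AlignerArchitecture(
        encoder_widths=tuple(doc["architecture"]["encoder_widths"]),
        batch_norm=doc["architecture"]["batch_norm"],
    )
    cfg_doc = dict(doc["config"])
    cfg_doc["histogram_range"] = tuple(cfg_doc["histogram_range"])
    cfg = TrainConfig(**cfg_doc)
    ref = ReferenceDistribution(
        edges=np.array(doc["reference"]["edges"]),
        probs=np.array(doc["reference"]["probs"]),
        marker_names=doc["marker_names"],
        batch_id=doc["reference"]["batch_id"],
        n_cells=doc["reference"]["n_cells"],
    )
    m = len(doc["marker_names"])
    net = MLP(arch.widths(m), arch.batch_norm, np.random.default_rng(0))
    net.load_state_dict(doc["state"])
    return AlignmentModel(
        net=net,
        architecture=arch,
        config=cfg,
        reference=ref,
        marker_names=doc["marker_names"],
        loss_trace=np.array(doc["loss_trace"]),
    )
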