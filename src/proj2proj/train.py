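"""Training of the translation generator on paired projections.

Follows the protocol of the translation task: per-subject zero-center /
unit-std normalization of the MR inputs (label projections are normalized with
pooled statistics), alternating single-step discriminator/generator updates
with Adam at batch size one, and the edge-weighted objective.  Every source of
randomness (parameter init, epoch shuffling) derives from one seed, so a run
is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .edges import make_weight_map
from .features import RandomConvFeatureExtractor
from .networks import (
    DiscriminatorSpec,
    Generator,
    build_discriminator,
    build_generator,
    match_generator_specs,
)
from .nn import Adam, save_params
from .objective import combined_objective
from .projector import ProjectionImage, ProjectionPair

__all__ = [
    "TrainingConfig",
    "PairRecord",
    "PairedDataset",
    "TrainResult",
    "normalize_subject",
    "prepare_records",
    "train",
]


@dataclass
class TrainingConfig:
    """Training hyper-parameters.

    The defaults (300 epochs, Adam at learning rate 1e-4, batch size one)
    are the full-scale protocol; desk-scale runs typically cap
    ``max_iterations`` and raise the learning rate (see docs/methods.md).
    """

    epochs: int = 300
    learning_rate: float = 1e-4
    batch_size: int = 1
    seed: int = 0
    use_edge_weighting: bool = True
    architecture: str = "proposed"  # or "reference"
    max_iterations: int | None = None
    gan_weight: float = 1.0
    fm_weight: float = 1.0
    edge_threshold: float = 0.4
    edge_floor: float = 0.1
    generator_budget: int = 100_000
    n_levels: int = 2
    disc_layers: int = 3
    disc_channels: int = 16
    adam_betas: tuple[float, float] = (0.5, 0.999)

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("the training protocol uses batch size one")
        if self.architecture not in ("proposed", "reference"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class PairRecord:
    """One normalized training/evaluation pair plus its raw label (mask source)."""

    mr: np.ndarray
    label: np.ndarray
    raw_label: np.ndarray
    view: tuple[float, float]


@dataclass
class PairedDataset:
    """Per-subject paired projections, split into train and test views."""

    subjects: list[dict] = field(default_factory=list)
    # each: {"train": list[ProjectionPair], "test": list[ProjectionPair]}

    @classmethod
    def from_directory(cls, root) -> "PairedDataset":
        """Load a dataset laid out as subject_XX/{train,test}/{mr,xray}/view_####.tif."""
        from . import proj_io

        root = Path(root)
        subjects = []
        for sdir in sorted(root.glob("subject_*")):
            with open(sdir / "geometry.json") as fh:
                sidecar = json.load(fh)
            entry: dict = {}
            for split in ("train", "test"):
                views = [tuple(v) for v in sidecar[f"{split}_views"]]
                pairs = []
                for i, view in enumerate(views):
                    mr = proj_io.read_projection(sdir / split / "mr" / f"view_{i:04d}.tif", view, "mr")
                    xr = proj_io.read_projection(sdir / split / "xray" / f"view_{i:04d}.tif", view, "xray")
                    pairs.append(ProjectionPair(mr, xr))
                entry[split] = pairs
            subjects.append(entry)
        if not subjects:
            raise ValueError(f"no subject_* directories under {root}")
        return cls(subjects)


def normalize_subject(
    projections: list[ProjectionImage | np.ndarray],
    stats: tuple[float, float] | None = None,
) -> tuple[list[np.ndarray], tuple[float, float]]:
    """Zero-center and scale to unit standard deviation.

    Statistics are pooled over all given projections (one subject, one
    modality) unless ``stats`` provides precomputed (mean, std) — used to map
    a subject's held-out views with its training statistics.
    """
    if not projections:
        raise ValueError("need at least one projection")
    arrays = [p.pixels if isinstance(p, ProjectionImage) else np.asarray(p, float) for p in projections]
    if stats is None:
        pool = np.concatenate([a.ravel() for a in arrays])
        mean = float(pool.mean())
        std = float(pool.std())
        if std == 0.0:
            raise ValueError("zero variance: projections are constant, cannot normalize")
        stats = (mean, std)
    mean, std = stats
    return [(a - mean) / std for a in arrays], stats


def prepare_records(dataset: PairedDataset) -> tuple[list[PairRecord], list[PairRecord], dict]:
    """Normalize a dataset into flat train/test record lists.

    MR inputs are normalized per subject (train statistics, reused for that
    subject's test views); labels are normalized with statistics pooled over
    the whole training split.
    """
    label_pool = np.concatenate(
        [p.xray.pixels.ravel() for s in dataset.subjects for p in s["train"]]
    )
    l_mean, l_std = float(label_pool.mean()), float(label_pool.std())
    if l_std == 0.0:
        raise ValueError("zero variance in training labels")

    train_records: list[PairRecord] = []
    test_records: list[PairRecord] = []
    for subject in dataset.subjects:
        mr_train = [p.mr for p in subject["train"]]
        mr_norm, mr_stats = normalize_subject(mr_train)
        for pair, mr in zip(subject["train"], mr_norm):
            train_records.append(
                PairRecord(mr, (pair.xray.pixels - l_mean) / l_std, pair.xray.pixels, pair.mr.view)
            )
        if subject["test"]:
            mr_test, _ = normalize_subject([p.mr for p in subject["test"]], stats=mr_stats)
            for pair, mr in zip(subject["test"], mr_test):
                test_records.append(
                    PairRecord(mr, (pair.xray.pixels - l_mean) / l_std, pair.xray.pixels, pair.mr.view)
                )
    stats = {"label_mean": l_mean, "label_std": l_std}
    return train_records, test_records, stats


@dataclass
class TrainResult:
    generator: Generator
    history: list[dict]
    config: TrainingConfig
    stats: dict


def train(
    dataset: PairedDataset,
    config: TrainingConfig,
    out_dir=None,
    checkpoint_every: int = 1,
) -> TrainResult:
    """Train the generator/discriminator pair on a paired dataset.

    Alternates one discriminator step and one generator step per pair, Adam
    for both players.  The per-iteration loss breakdown is logged; a NaN in
    any loss aborts with a diagnostic.  With ``epochs=0`` the generator is
    returned untouched (freshly initialized from the seed).
    """
    train_records, _, stats = prepare_records(dataset)
    if not train_records:
        raise ValueError("dataset has no training pairs")

    rng = np.random.default_rng(config.seed)
    high_spec, bottleneck_spec = match_generator_specs(config.generator_budget, config.n_levels)
    gen_spec = high_spec if config.architecture == "proposed" else bottleneck_spec
    g_seed, d_seed, f_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
    generator = build_generator(gen_spec, seed=g_seed)
    discriminator = build_discriminator(
        DiscriminatorSpec(n_layers=config.disc_layers, base_channels=config.disc_channels),
        seed=d_seed,
    )
    extractor = RandomConvFeatureExtractor(seed=f_seed)

    weight_maps = []
    for rec in train_records:
        if config.use_edge_weighting:
            wm = make_weight_map(rec.label, config.edge_threshold, config.edge_floor)
            weight_maps.append(wm.weights)
        else:
            weight_maps.append(np.ones_like(rec.label))

    adam_g = Adam(generator.parameters(), lr=config.learning_rate, betas=config.adam_betas)
    adam_d = Adam(discriminator.parameters(), lr=config.learning_rate, betas=config.adam_betas)

    history: list[dict] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    iterations = 0
    stop = False
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_records))
        for idx in order:
            rec = train_records[int(idx)]
            g_out = generator(Tensor(rec.mr[None, :, :]))
            breakdown = combined_objective(
                rec.label, g_out, rec.mr, discriminator, extractor,
                weight_maps[int(idx)],
                gan_weight=config.gan_weight, fm_weight=config.fm_weight,
            )
            d_loss = float(breakdown.discriminator_loss.item())
            if not (np.isfinite(breakdown.weighted_total) and np.isfinite(d_loss)):
                raise RuntimeError(
                    f"non-finite loss at iteration {iterations} "
                    f"(generator {breakdown.weighted_total}, discriminator {d_loss})"
                )
            discriminator.zero_grad()
            breakdown.discriminator_loss.backward()
            adam_d.step()
            generator.zero_grad()
            breakdown.generator_loss.backward()
            adam_g.step()

            history.append(
                {
                    "iteration": iterations,
                    "epoch": epoch,
                    "gan_term": breakdown.gan_term,
                    "fm_term": breakdown.fm_term,
                    "weighted_total": breakdown.weighted_total,
                    "discriminator_loss": d_loss,
                }
            )
            iterations += 1
            if config.max_iterations is not None and iterations >= config.max_iterations:
                stop = True
                break
        if out_dir is not None and (epoch + 1) % checkpoint_every == 0:
            save_params(generator, out_dir / f"generator_epoch{epoch:04d}.npz")
        if stop:
            break

    if out_dir is not None:
        with open(out_dir / "history.jsonl", "w") as fh:
            for row in history:
                fh.write(json.dumps(row) + "\n")

    return TrainResult(generator=generator, history=history, config=config, stats=stats)
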