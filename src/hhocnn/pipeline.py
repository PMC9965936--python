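"""End-to-end orchestration: generate → preprocess → segment → extract →
train → evaluate.

Every stage's parameters live in :class:`PipelineConfig`; all randomness is
derived from the single global seed, so two runs with the same
configuration produce byte-identical metrics JSON.  The run writes every
intermediate artifact (processed images, label maps, the feature CSV, the
trained model, the metrics report and a manifest recording every parameter
and seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import cnn, features, metrics, preprocess, segmentation
from .phantom import LabeledDataset, PhantomSpec, generate_dataset, read_image_folder

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "segment_image"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with the global seed."""

    # data
    n_images: int = 100
    class_balance: float = 0.5
    test_fraction: float = 0.2
    data_dir: str | None = None  # read a two-folder dataset instead of phantoms
    # phantom rendering
    image_side: int = 64
    background_intensity: int = 20
    brain_intensity: int = 120
    tumor_intensity: int = 220
    tumor_radius: float = 7.0
    noise_sigma: float = 4.0
    salt_pepper: float = 0.02
    # preprocessing
    window: int = 3
    subhists: int = 2
    # segmentation
    clusters: int = 3
    fuzziness: float = 2.0
    tau: float | None = None  # None = 2 x pooled within-cluster std
    connectivity: int = 4
    segment_on: str = "denoised"  # or "equalized"
    # classifier
    classifier_input: str = "masked"  # or "whole"
    n_filters: int = 8
    kernel: int = 3
    pool: int = 2
    learning_rate: float = 0.1
    epochs: int = 40
    batch_size: int = 16
    refine_population: int = 8
    refine_iterations: int = 10
    # bookkeeping
    seed: int = 0
    out_dir: str = "hhocnn_run"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.subhists < 1:
            raise ValueError("subhists must be >= 1")
        if self.clusters < 1:
            raise ValueError("clusters must be >= 1")
        if self.fuzziness <= 1:
            raise ValueError("fuzziness must be > 1")
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.segment_on not in ("equalized", "denoised"):
            raise ValueError("segment_on must be 'equalized' or 'denoised'")
        if self.classifier_input not in ("masked", "whole"):
            raise ValueError("classifier_input must be 'masked' or 'whole'")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SegmentationOutput:
    """Per-image segmentation artifacts."""

    processed: np.ndarray  # image handed to region growing
    region_map: segmentation.RegionMap
    candidate: segmentation.CandidateRegion
    tau: float


def center_on_region(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Translate *img* so the centroid of *mask* sits at the image center.

    The classifier's fully connected layer is position-sensitive; rolling
    the masked candidate to a canonical position makes classification
    invariant to where the candidate happened to lie in the frame.
    """
    if not mask.any():
        return img
    ys, xs = np.nonzero(mask)
    h, w = img.shape
    dy = int(round((h - 1) / 2.0 - ys.mean()))
    dx = int(round((w - 1) / 2.0 - xs.mean()))
    return np.roll(np.roll(img, dy, axis=0), dx, axis=1)


def auto_tau(img: np.ndarray, partition: segmentation.FuzzyPartition) -> float:
    """Similarity threshold: twice the pooled within-cluster intensity std."""
    x = img.ravel().astype(np.float64)
    hard = partition.hard_labels()
    centers = partition.centers[:, 0]
    resid = x - centers[hard]
    return 2.0 * float(np.sqrt(np.mean(resid**2)))


def segment_image(
    img: np.ndarray, config: PipelineConfig, seed: int
) -> SegmentationOutput:
    """Preprocess one image and grow/select the candidate tumor region."""
    den = preprocess.median_filter(img, config.window)
    enh = preprocess.equalize(den, config.subhists)
    work = enh if config.segment_on == "equalized" else den
    part = segmentation.fcm_fit_image(
        work, c=config.clusters, m=config.fuzziness, seed=seed
    )
    seeds = segmentation.select_seeds(part, work)
    tau = config.tau if config.tau is not None else auto_tau(work, part)
    rmap = segmentation.region_grow(
        work, [(r, c) for r, c, _ in seeds], tau, config.connectivity
    )
    cand = segmentation.select_candidate(rmap, work)
    return SegmentationOutput(processed=work, region_map=rmap, candidate=cand, tau=tau)


@dataclass
class PipelineResult:
    config: PipelineConfig
    classification: metrics.MetricsReport
    segmentation_summary: dict
    feature_table: "object"
    model: cnn.CNNModel
    loss_history: list[float]
    refine_info: dict
    paths: dict = field(default_factory=dict)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write all artifacts to ``out_dir``."""
    out = Path(config.out_dir)
    for sub in ("processed", "labelmaps"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)  # dataset, fcm base, train, refine

    # stage 1: data
    if config.data_dir is not None:
        dataset = read_image_folder(config.data_dir)
        logger.info("read %d images from %s", len(dataset), config.data_dir)
    else:
        template = PhantomSpec(
            size=(config.image_side, config.image_side),
            background_intensity=config.background_intensity,
            brain_intensity=config.brain_intensity,
            tumor_intensity=config.tumor_intensity,
            tumor_radius=config.tumor_radius,
            noise_sigma=config.noise_sigma,
            salt_pepper=config.salt_pepper,
        )
        dataset = generate_dataset(
            config.n_images,
            config.class_balance,
            template,
            seed=seeds[0],
            test_fraction=config.test_fraction,
        )
        dataset.save(out / "dataset")

    # stages 2-3: preprocessing + segmentation per image
    fcm_seeds = _child_seeds(seeds[1], len(dataset))
    seg_outputs: list[SegmentationOutput] = []
    candidate_masks: list[np.ndarray] = []
    dices, pixel_accs = [], []
    for i, img in enumerate(dataset.images):
        try:
            seg = segment_image(img, config, fcm_seeds[i])
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise RuntimeError(f"segmentation failed on image {i}: {exc}") from exc
        seg_outputs.append(seg)
        candidate_masks.append(seg.candidate.mask)
        name = dataset.filenames[i] if dataset.filenames else f"img_{i:04d}.png"
        Image.fromarray(seg.processed.astype(np.uint8), mode="L").save(
            out / "processed" / name
        )
        lab = np.clip(seg.region_map.labels, 0, 255).astype(np.uint8)
        Image.fromarray(lab, mode="L").save(out / "labelmaps" / name)
        if dataset.masks is not None and dataset.labels[i] == 1:
            acc, dice = segmentation.segmentation_metrics(
                seg.candidate.mask, dataset.masks[i]
            )
            dices.append(dice)
            pixel_accs.append(acc)
    seg_summary = {
        "mean_dice_tumor": float(np.mean(dices)) if dices else None,
        "mean_pixel_accuracy_tumor": float(np.mean(pixel_accs)) if pixel_accs else None,
        "n_tumor_images_scored": len(dices),
        "mean_tau": float(np.mean([s.tau for s in seg_outputs])),
    }

    # stage 4: features
    table = features.build_feature_table(dataset, candidate_masks)
    table.to_csv(out / "features.csv", index=False)

    # stage 5: classification
    if config.classifier_input == "masked":
        clf_images = [
            center_on_region(np.where(m, s.processed, 0).astype(np.uint8), m)
            for m, s in zip(candidate_masks, seg_outputs)
        ]
    else:
        clf_images = [s.processed.astype(np.uint8) for s in seg_outputs]
    X = cnn.prepare_images(clf_images, config.image_side)
    y = dataset.labels.astype(float)
    train_idx = dataset.indices("train")
    test_idx = dataset.indices("test")
    arch = cnn.CNNConfig(
        input_side=config.image_side,
        n_filters=config.n_filters,
        kernel=config.kernel,
        pool=config.pool,
        seed=seeds[2],
    )
    tcfg = cnn.TrainConfig(
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        seed=seeds[2],
        refine_population=config.refine_population,
        refine_iterations=config.refine_iterations,
    )
    model = cnn.CNNModel(arch)
    history = cnn.train_gd(model, X[train_idx], y[train_idx], tcfg)
    model, refine_info = cnn.refine_hho(
        model, X[train_idx], y[train_idx], tcfg, seed=seeds[3]
    )
    model.save(out / "model.json")

    y_pred, probs = cnn.predict(model, X[test_idx])
    clf_report = metrics.compute_metrics(dataset.labels[test_idx], y_pred, probs)

    # stage 6: reporting
    paths = metrics.report(clf_report, out, extra={"segmentation": seg_summary})
    manifest = {
        "config": asdict(config),
        "stage_seeds": {
            "dataset": seeds[0],
            "fcm_base": seeds[1],
            "training": seeds[2],
            "refinement": seeds[3],
        },
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "refinement": {
            k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
            for k, v in refine_info.items()
        },
        "final_train_loss": history[-1] if history else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = out / "manifest.json"
    paths["features"] = out / "features.csv"
    paths["model"] = out / "model.json"

    return PipelineResult(
        config=config,
        classification=clf_report,
        segmentation_summary=seg_summary,
        feature_table=table,
        model=model,
        loss_history=history,
        refine_info=refine_info,
        paths=paths,
    )
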