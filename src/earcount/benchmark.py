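"""End-to-end smoke benchmark on synthetic scenes.

Trains a model on a small set of synthetic field scenes and evaluates
counting and segmentation quality on held-out scenes.  The score
threshold used for the count readout is calibrated on the *training*
scenes (the grid value minimizing count RMSE there), never on the
held-out set.  Used by the test suite and the acceptance script; the
problem sizes default to a desk-scale configuration (128^2 scenes, a few
hundred SGD iterations) that exercises every branch of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import CountPair, counting_metrics
from .inference import count_instances, predict
from .model import Model, ModelConfig, build_model
from .synth import SceneConfig, SyntheticScene, generate_scene
from .train import TrainConfig, TrainingSample, prepare_sample, train

THRESHOLD_GRID = np.round(np.arange(0.10, 0.65, 0.05), 2)


@dataclass
class SmokeResult:
    model: Model
    history: list
    count_threshold: float
    train_metrics: "object"
    test_metrics: "object"
    test_pairs: list[CountPair]
    density_pairs: list[CountPair]
    initial_loss: float
    final_loss: float
    initial_density_mse: float
    final_density_mse: float


def make_scenes(n: int, levels: tuple[int, ...], size: int, seed_base: int,
                ) -> list[SyntheticScene]:
    """Deterministic scene set cycling through ``levels``."""
    return [
        generate_scene(SceneConfig(image_size=(size, size),
                                   level=levels[i % len(levels)],
                                   seed=seed_base + i))
        for i in range(n)
    ]


def _count_scene(model: Model, scene: SyntheticScene, threshold: float,
                 density_alpha: float = 1.0) -> int:
    detections, _ = predict(model, scene.image, score_threshold=threshold,
                            density_alpha=density_alpha)
    return count_instances(detections, threshold)


def calibrate_count_threshold(model: Model, scenes: list[SyntheticScene],
                              grid=THRESHOLD_GRID,
                              density_alpha: float = 1.0) -> float:
    """Pick the detection-score threshold minimizing count RMSE on ``scenes``.

    Detections are computed once at the lowest grid value and re-thresholded,
    so calibration costs a single inference pass per scene.
    """
    lo = float(min(grid))
    per_scene_scores = []
    for scene in scenes:
        detections, _ = predict(model, scene.image, score_threshold=lo,
                                density_alpha=density_alpha)
        per_scene_scores.append(np.array([d.score for d in detections]))
    best_thr, best_rmse = lo, np.inf
    for thr in grid:
        errs = [
            (scene.count - int((scores >= thr).sum())) ** 2
            for scene, scores in zip(scenes, per_scene_scores)
        ]
        rmse = float(np.sqrt(np.mean(errs)))
        if rmse < best_rmse:
            best_thr, best_rmse = float(thr), rmse
    return best_thr


def run_smoke_benchmark(
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    n_train: int = 32,
    n_test: int = 16,
    scene_size: int = 128,
    train_levels: tuple[int, ...] = (1, 2),
    test_levels: tuple[int, ...] = (1,),
    seed: int = 0,
    density_alpha: float = 1.0,
) -> SmokeResult:
    """Train on synthetic scenes and evaluate held-out counting quality."""
    model_config = model_config or ModelConfig(
        input_size=(scene_size, scene_size))
    train_config = train_config or TrainConfig(seed=seed, learning_rate=0.02,
                                               iterations=200)
    train_scenes = make_scenes(n_train, train_levels, scene_size,
                               seed_base=1000 + 100000 * seed)
    test_scenes = make_scenes(n_test, test_levels, scene_size,
                              seed_base=5000 + 100000 * seed)
    samples = [
        prepare_sample(s.image, list(s.annotations), model_config)
        for s in train_scenes
    ]
    model = build_model(model_config, seed=seed)
    history = train(model, samples, train_config)

    threshold = calibrate_count_threshold(model, train_scenes,
                                          density_alpha=density_alpha)
    train_pairs = [
        CountPair(i, s.count, _count_scene(model, s, threshold, density_alpha))
        for i, s in enumerate(train_scenes)
    ]
    test_pairs = []
    density_pairs = []
    for i, scene in enumerate(test_scenes):
        detections, dmap = predict(model, scene.image,
                                   score_threshold=threshold,
                                   density_alpha=density_alpha)
        test_pairs.append(CountPair(i, scene.count,
                                    count_instances(detections, threshold)))
        density_pairs.append(CountPair(
            i, scene.count, float(dmap.sum()) if dmap is not None else 0.0))
    return SmokeResult(
        model=model,
        history=history,
        count_threshold=threshold,
        train_metrics=counting_metrics(train_pairs),
        test_metrics=counting_metrics(test_pairs),
        test_pairs=test_pairs,
        density_pairs=density_pairs,
        initial_loss=history[0].total,
        final_loss=history[-1].total,
        initial_density_mse=history[0].l_density,
        final_density_mse=history[-1].l_density,
    )
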