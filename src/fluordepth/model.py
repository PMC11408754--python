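"""Model/Results front end tying the pipeline together.

:class:`DepthConcModel` is built from a training dataset manifest (or
directly from a shape family name); ``fit()`` trains the two-arm network and
returns a :class:`DepthConcResults` carrying the trained weights, the
training history and evaluation helpers, with a ``summary()`` table in the
spirit of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation as ev
from .datasets import DatasetManifest, generate_test_set, generate_training_set, load_sample
from .network import (
    DepthConcPrediction,
    ModelConfig,
    SiameseCNN,
    TrainConfig,
    build_model,
    predict,
    train,
)

__all__ = ["DepthConcModel", "DepthConcResults", "cylinder_selftest"]


class DepthConcModel:
    """Two-arm SFDI depth/concentration regressor bound to a training set."""

    def __init__(
        self,
        manifest: DatasetManifest,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        seed: int = 0,
    ):
        self.manifest = manifest
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.seed = seed

    @classmethod
    def from_family(
        cls,
        family: str,
        n: int,
        seed: int = 0,
        bg_enabled: bool = False,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        **dataset_kw,
    ) -> "DepthConcModel":
        """Generate a seeded training set of one shape family and wrap it."""
        manifest = generate_training_set(family, n, bg_enabled=bg_enabled, seed=seed, **dataset_kw)
        return cls(manifest, model_config, train_config, seed=seed)

    def fit(self, verbose: bool = False) -> "DepthConcResults":
        net = build_model(self.model_config, seed=self.seed)
        history = train(net, self.manifest, self.train_config, verbose=verbose)
        return DepthConcResults(model=self, network=net, history=history)


@dataclass
class DepthConcResults:
    """Fitted network plus its training history and evaluation helpers."""

    model: DepthConcModel
    network: SiameseCNN
    history: dict
    reports: dict = field(default_factory=dict)

    def predict_record(self, record, root=None, flip_average: bool = False) -> DepthConcPrediction:
        (props, fluor), _ = load_sample(record, self.network.normalizer, root)
        return predict(self.network, props, fluor, flip_average=flip_average)

    def evaluate(
        self,
        manifest: DatasetManifest,
        support: str = "footprint",
        tag: str = "test",
        flip_average: bool = False,
    ):
        """Per-sample footprint errors + cohort stats on a test manifest."""
        errors = []
        for rec in manifest.records:
            pred = self.predict_record(rec, manifest.root, flip_average=flip_average)
            errors.append(ev.sample_error(pred, rec.truth, support, rec.id))
        report = ev.cohort_stats(errors)
        self.reports[tag] = report
        return report

    def summary(self) -> str:
        cfg = self.model.model_config
        tc = self.model.train_config
        h = self.history
        lines = [
            "Depth/concentration SFDI network fit",
            "=" * 52,
            f"{'training family':<28}{self.model.manifest.config.get('family', 'n/a')}",
            f"{'training samples':<28}{len(self.model.manifest.records)}",
            f"{'trainable parameters':<28}{self.network.parameter_count():,}",
            f"{'epochs run':<28}{len(h['train_loss'])}",
            f"{'best epoch (val loss)':<28}{h.get('best_epoch', -1)}",
            f"{'best val loss':<28}{h.get('best_val_loss', float('nan')):.5f}",
            f"{'initial learning rate':<28}{tc.learning_rate:g}",
            f"{'batch size':<28}{tc.batch_size}",
        ]
        for tag, rep in self.reports.items():
            lines += [
                "-" * 52,
                f"{tag} cohort (n={rep.n})",
                f"{'  depth error (mm)':<28}{rep.depth_mean_mm:.3f} +/- {rep.depth_sd_mm:.3f}",
                f"{'  conc error (ug/mL)':<28}{rep.conc_mean_ugml:.3f} +/- {rep.conc_sd_ugml:.3f}",
            ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.network.save(path)


#: Narrow filter schedule used by the CPU-scale self-test (same topology as
#: the committed architecture, ~24.5k parameters).
SELFTEST_CONFIG = ModelConfig(
    prop_channels=(8, 16),
    fluor_entry=8,
    fluor_channels=(12, 16),
    trunk_channels=16,
    head_channels=(12, 8),
)


def cylinder_selftest(
    n_train: int = 800,
    n_test: int = 100,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    verbose: bool = False,
) -> dict:
    """Scaled-down cylinder self-test: train on cylinders, test on cylinders.

    Emulates the in-silico self-consistency experiment (train and test on
    the same shape family, a 100-shape test cohort at the fixed test optics)
    at CPU scale: a narrow-width network, 800 training samples, small random
    crops, a step count sized for a single CPU, stochastic weight averaging
    over the late epochs, and flip-averaged prediction at evaluation.
    Returns the fitted results, the training history and the held-out
    cohort report.
    """
    tc = train_config or TrainConfig(
        learning_rate=1.5e-3, lr_decay=0.985, max_epochs=100, patience=100,
        batch_size=4, crop_size=32, seed=seed, swa_start=60,
    )
    model = DepthConcModel.from_family(
        "cylinder", n_train, seed=seed,
        model_config=model_config or SELFTEST_CONFIG,
        train_config=tc,
        val_fraction=0.02,
    )
    res = model.fit(verbose=verbose)
    test = generate_test_set("cylinder", n=n_test, seed=seed + 1)
    report = res.evaluate(test, flip_average=True)
    return {"results": res, "history": res.history, "report": report}
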