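"""Model-object front door: a decoder fitted to an epoch set.

``FacialExpressionDecoder`` wraps the pipeline the way statistical
modelling packages wrap an estimator: construct it from data, call
``fit()``, and read the estimates off the returned results object.
Fitting means cross-validated training of the CNN (with the genome either
fixed or searched by the genetic algorithm), optionally alongside the
wavelet + BPNN baseline, and the results object carries accuracies, kappa,
confusion matrices, the GA trace and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fexbci import baseline as bl
from fexbci.cnn import (FIXED_COMPARISON_GENOME, HyperparamGenome, TrainConfig,
                        build_model_spec, train_model)
from fexbci.evaluate import (FoldPlan, MetricsReport, compare_methods,
                             cross_validate, make_folds)
from fexbci.ga import CNNFitness, FitnessEvaluator, GAConfig, GAHistory, run_ga
from fexbci.synthdata import EpochSet

__all__ = ["FacialExpressionDecoder", "DecoderResults"]


def cnn_fit_predict(genome: HyperparamGenome, cfg: TrainConfig):
    """Fold worker: train a CNN with this genome, return test predictions."""
    def fp(train: EpochSet, test: EpochSet, fold_seed: int):
        spec = build_model_spec(genome, input_shape=train.data.shape[1:])
        model = train_model(spec, train, None, replace(cfg, seed=fold_seed))
        return model.predict(test)
    return fp


def bpnn_fit_predict(spec: bl.BPNNSpec = bl.BPNNSpec(),
                     wspec: bl.WaveletFeatureSpec = bl.WaveletFeatureSpec()):
    """Fold worker for the wavelet + BPNN baseline."""
    def fp(train: EpochSet, test: EpochSet, fold_seed: int):
        model = bl.train_bpnn(bl.wavelet_features(train, wspec), train.labels,
                              spec, seed=fold_seed)
        return model.predict(bl.wavelet_features(test, wspec))
    return fp


@dataclass
class DecoderResults:
    """Cross-validated performance of the decoder (and comparators)."""

    reports: dict[str, MetricsReport]
    genome: HyperparamGenome
    ga_history: GAHistory | None = None
    plan: FoldPlan | None = None
    comparison: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Facial-expression EEG decoder — cross-validated results",
            "=" * 58,
            f"folds: {self.plan.k} x {self.plan.repeats} repeat(s)"
            if self.plan else "folds: (external)",
            f"selected genome (k1,k2,k3,n1,n2): {self.genome.as_tuple()}",
            "",
            f"{'method':<14}{'mean acc':>10}{'sd':>8}{'p0':>8}{'kappa':>8}",
            "-" * 48,
        ]
        for name, rep in self.reports.items():
            kappa = f"{rep.kappa:.3f}" if rep.kappa is not None else "undef"
            lines.append(f"{name:<14}{rep.mean_accuracy:>10.3f}"
                         f"{rep.sd_accuracy:>8.3f}{rep.p0:>8.3f}{kappa:>8}")
        if self.ga_history is not None and len(self.ga_history):
            lines += ["", f"GA generations: {len(self.ga_history)}; "
                          f"final best fitness {self.ga_history.best_fitness[-1]:.3f}; "
                          f"fitness cache hits {self.ga_history.cache_hits}"]
        if self.comparison is not None:
            lines += ["", "method comparison:",
                      self.comparison.to_string(index=False)]
        return "\n".join(lines)


class FacialExpressionDecoder:
    """CNN(-GA) decoder of 4-class facial-expression EEG epochs.

    Parameters
    ----------
    epochs
        Labeled epoch set (preprocess beforehand with
        :func:`fexbci.bandpass_filter` / :func:`fexbci.clean_epochs` if the
        data are raw).
    genome
        ``"ga"`` to search the five hyperparameters with the genetic
        algorithm, or a fixed :class:`HyperparamGenome`.
    """

    def __init__(self, epochs: EpochSet,
                 genome: HyperparamGenome | str = "ga",
                 train_config: TrainConfig | None = None,
                 ga_config: GAConfig | None = None,
                 include_fixed_cnn: bool = True,
                 include_baseline: bool = True):
        if isinstance(genome, str) and genome != "ga":
            raise ValueError("genome must be 'ga' or a HyperparamGenome")
        self.epochs = epochs
        self.genome = genome
        self.train_config = train_config or TrainConfig()
        self.ga_config = ga_config or GAConfig()
        self.include_fixed_cnn = include_fixed_cnn
        self.include_baseline = include_baseline

    @classmethod
    def from_arrays(cls, data: np.ndarray, labels, fs: float = 1000.0,
                    **kwargs) -> "FacialExpressionDecoder":
        return cls(EpochSet(data=np.asarray(data), labels=np.asarray(labels),
                            fs=fs), **kwargs)

    def fit(self, k: int = 5, repeats: int = 2, seed: int = 0) -> DecoderResults:
        """Cross-validate the decoder; search the genome first if requested."""
        plan = make_folds(self.epochs.n_epochs, self.epochs.labels, k=k,
                          repeats=repeats, seed=seed)
        ga_history = None
        if self.genome == "ga":
            fitness = FitnessEvaluator(
                CNNFitness(self.epochs, mode=self.ga_config.fitness_mode,
                           seed=seed, train_cfg=self.train_config))
            genome, ga_history = run_ga(fitness, self.ga_config)
        else:
            genome = self.genome

        reports: dict[str, MetricsReport] = {}
        label = "cnn_ga" if self.genome == "ga" else "cnn"
        reports[label] = cross_validate(
            self.epochs, plan, cnn_fit_predict(genome, self.train_config))
        if self.include_fixed_cnn and genome != FIXED_COMPARISON_GENOME:
            reports["cnn_fixed"] = cross_validate(
                self.epochs, plan,
                cnn_fit_predict(FIXED_COMPARISON_GENOME, self.train_config))
        if self.include_baseline:
            reports["wt_bpnn"] = cross_validate(self.epochs, plan,
                                                bpnn_fit_predict())
        comparison = None
        if len(reports) >= 2:
            comparison = compare_methods(
                {name: rep.fold_accuracies for name, rep in reports.items()})
        return DecoderResults(reports=reports, genome=genome,
                              ga_history=ga_history, plan=plan,
                              comparison=comparison)
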