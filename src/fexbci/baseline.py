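"""Comparison method: wavelet energy/variance features + one-hidden-layer BPNN.

Each channel of an epoch is decomposed with a level-5 discrete wavelet
transform (db3 basis, periodised so the transform is orthogonal and energy
is conserved).  Two statistics pooled over all subband coefficients —
energy (sum of squares) and variance — give 2 features x 8 channels = 16
features per epoch.  A three-layer back-propagation network (16 inputs, one
hidden layer of 20 logistic units, 4 outputs) classifies the feature
vectors; features are standardised before training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from fexbci.synthdata import EpochSet, N_CLASSES

__all__ = ["WaveletFeatureSpec", "BPNNSpec", "wavelet_features", "train_bpnn"]


@dataclass(frozen=True)
class WaveletFeatureSpec:
    wavelet: str = "db3"
    level: int = 5
    mode: str = "periodization"

    def __post_init__(self):
        if self.level < 1:
            raise ValueError(f"level must be >= 1, got {self.level}")


@dataclass(frozen=True)
class BPNNSpec:
    """16-input, one-hidden-layer (20 units) back-propagation network.

    The output width defaults to the 4 expression classes.  (The original
    description of this baseline prints a two-node output layer, which does
    not fit a four-class task; the width is therefore configurable with 4 as
    the working default.)
    """

    n_hidden: int = 20
    n_outputs: int = N_CLASSES
    activation: str = "logistic"
    learning_rate: float = 0.01
    epochs: int = 500

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValueError("hidden layer needs at least one unit")


def wavelet_features(epochs: EpochSet,
                     spec: WaveletFeatureSpec = WaveletFeatureSpec()
                     ) -> np.ndarray:
    """(n, 16) feature matrix, channel-major: [ch0_energy, ch0_var, ch1_...].

    Energy and variance are pooled over the approximation and all detail
    coefficients of the level-5 decomposition.  With an orthogonal wavelet
    and periodised boundaries the energy feature equals the time-domain
    sum of squares (Parseval).
    """
    min_len = pywt.Wavelet(spec.wavelet).dec_len * 2 ** (spec.level - 1)
    if epochs.n_samples < min_len:
        raise ValueError(
            f"epoch length {epochs.n_samples} too short for a level-{spec.level} "
            f"{spec.wavelet} decomposition (needs >= {min_len})")
    n, C, _ = epochs.data.shape
    feats = np.empty((n, 2 * C))
    for i in range(n):
        for c in range(C):
            coeffs = pywt.wavedec(epochs.data[i, c], spec.wavelet,
                                  level=spec.level, mode=spec.mode)
            pooled = np.concatenate(coeffs)
            feats[i, 2 * c] = float((pooled**2).sum())
            feats[i, 2 * c + 1] = float(pooled.var())
    return feats


class BPNNModel:
    """Fitted baseline classifier (standardiser + MLP)."""

    def __init__(self, pipeline: Pipeline, spec: BPNNSpec):
        self._pipeline = pipeline
        self.spec = spec

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self._pipeline.predict(features)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self._pipeline.predict_proba(features)


def train_bpnn(features: np.ndarray, labels, spec: BPNNSpec = BPNNSpec(),
               seed: int = 0) -> BPNNModel:
    """Gradient-descent training of the 16-20-out network, seeded."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(features).all():
        raise ValueError("features contain non-finite values")
    if len(features) != len(labels):
        raise ValueError(f"{len(features)} feature rows for {len(labels)} labels")
    mlp = MLPClassifier(
        hidden_layer_sizes=(spec.n_hidden,),
        activation=spec.activation,
        solver="sgd",
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        momentum=0.9,
        random_state=seed,
        n_iter_no_change=spec.epochs,  # fixed-epoch training, no early stop
    )
    pipe = Pipeline([("scale", StandardScaler()), ("mlp", mlp)])
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pipe.fit(features, labels)
    return BPNNModel(pipe, spec)
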