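"""Synthetic 8-channel EEG epochs with class-separable spectral structure.

The generator emulates 4-second scalp recordings from a small prefrontal +
motor montage during four voluntary facial expressions (left smirk, right
smirk, furrow brow, raise brow; class ids 0-3 in that order).  Each epoch is
band-limited pink (1/f) background noise in microvolts; a class is made
separable by multiplying the power of its designated (channel, band) pairs
by a configurable gain.  Ocular, myogenic and power-line artifacts can be
injected additively on top of the clean signal so downstream artifact
removal can be scored against retained ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ChannelMontage", "ClassSignature", "EpochSet", "ArtifactSpec",
    "default_montage", "default_signatures", "generate_epochs",
    "inject_artifacts", "write_epochs", "read_epochs", "read_edf_epochs",
]

EPOCH_SECONDS = 4.0
N_CLASSES = 4
CLASS_NAMES = ("left_smirk", "right_smirk", "furrow_brow", "raise_brow")


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered set of 8 scalp electrodes with a cortical-region role each."""

    names: tuple[str, ...]
    roles: dict[str, str] = field(compare=False)

    def __post_init__(self):
        if len(self.names) != 8 or len(set(self.names)) != 8:
            raise ValueError("montage requires exactly 8 unique channel labels")
        missing = [n for n in self.names if n not in self.roles]
        if missing:
            raise ValueError(f"channels without a role: {missing}")
        bad = {n: r for n, r in self.roles.items() if r not in ("prefrontal", "motor")}
        if bad:
            raise ValueError(f"unknown roles (must be prefrontal|motor): {bad}")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def channels_with_role(self, role: str) -> list[str]:
        return [n for n in self.names if self.roles[n] == role]


def default_montage() -> ChannelMontage:
    """FC5, FC6, F7, F8, FZ over prefrontal cortex; C3, C4, CPz over motor."""
    names = ("FC5", "FC6", "F7", "F8", "FZ", "C3", "C4", "CPz")
    roles = {
        "FC5": "prefrontal", "FC6": "prefrontal", "F7": "prefrontal",
        "F8": "prefrontal", "FZ": "prefrontal",
        "C3": "motor", "C4": "motor", "CPz": "motor",
    }
    return ChannelMontage(names=names, roles=roles)


@dataclass(frozen=True)
class Coupling:
    """A band-limited source shared by two channels with a fixed polarity.

    The source is added to ``ch_a`` and, multiplied by ``sign`` (+1/-1), to
    ``ch_b``; ``strength`` is its power relative to the channel background.
    Couplings with equal strength but different signs leave every marginal
    channel spectrum untouched and differ only in cross-channel
    correlation - a synchrony cue rather than a power cue.
    """

    ch_a: str
    ch_b: str
    band: tuple[float, float]
    sign: int = 1
    strength: float = 1.0

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if self.strength <= 0:
            raise ValueError(f"strength must be > 0, got {self.strength}")


@dataclass(frozen=True)
class ClassSignature:
    """Spectral fingerprint of one expression class.

    ``band_gains`` maps ``(channel, (f_lo, f_hi))`` to a multiplicative power
    gain (> 0) applied to the background spectrum of that channel inside the
    band.  ``couplings`` add shared band-limited sources across channel
    pairs (see :class:`Coupling`).  ``lateralization`` > 1 boosts
    left-hemisphere channels (odd 10-20 indices) and attenuates
    right-hemisphere ones by the same factor.
    """

    class_id: int
    band_gains: dict[tuple[str, tuple[float, float]], float] = field(compare=False)
    lateralization: float | None = None
    couplings: tuple[Coupling, ...] = ()

    def __post_init__(self):
        if not 0 <= self.class_id < N_CLASSES:
            raise ValueError(f"class_id {self.class_id} outside 0..{N_CLASSES - 1}")
        for (ch, band), g in self.band_gains.items():
            if g <= 0:
                raise ValueError(f"gain for {ch} {band} must be > 0, got {g}")
            lo, hi = band
            if not 0 < lo < hi:
                raise ValueError(f"malformed band {band} for {ch}")


def _hemisphere(name: str) -> str:
    """left | right | midline, from the trailing 10-20 index digit."""
    tail = name[-1]
    if tail in ("z", "Z"):
        return "midline"
    return "left" if int(tail) % 2 == 1 else "right"


def default_signatures(gain: float = 4.0) -> tuple[ClassSignature, ...]:
    """Four distinct stipulated signatures (one per expression).

    Smirks load the contralateral prefrontal channels in the mu band; brow
    movements load midline/bilateral frontal channels in theta (furrow) or
    beta (raise).  The concrete values are a simulation design choice, not
    measurements.
    """
    mu, theta, beta = (8.0, 13.0), (4.0, 8.0), (20.0, 30.0)
    return (
        ClassSignature(0, {("FC6", mu): gain, ("F8", mu): gain}),
        ClassSignature(1, {("FC5", mu): gain, ("F7", mu): gain}),
        ClassSignature(2, {("FZ", theta): gain, ("F7", theta): gain, ("F8", theta): gain}),
        ClassSignature(3, {("FZ", beta): gain, ("FC5", beta): gain, ("FC6", beta): gain}),
    )


def coupling_signatures(strength: float = 4.0,
                        band: tuple[float, float] = (8.0, 13.0)
                        ) -> tuple[ClassSignature, ...]:
    """Four classes distinguished purely by cross-channel synchrony.

    Two shared band-limited sources - one driving the left prefrontal pair
    (FC5, F7), one the right pair (FC6, F8) - enter with a class-specific
    polarity pattern: (+,+), (+,-), (-,+), (-,-).  Every channel's marginal
    spectrum is identical across classes, so per-channel power statistics
    carry no class information; only the sign of the inter-channel
    correlation does.  ``strength`` is the shared-source power relative to
    the channel background inside ``band`` (4.0 gives an in-band
    correlation magnitude of 0.8).
    """
    def sig(cid, sl, sr):
        return ClassSignature(cid, {}, couplings=(
            Coupling("FC5", "F7", band, sign=sl, strength=strength),
            Coupling("FC6", "F8", band, sign=sr, strength=strength)))
    return (sig(0, 1, 1), sig(1, 1, -1), sig(2, -1, 1), sig(3, -1, -1))


def band_fraction(band: tuple[float, float], fs: float,
                  background_band: tuple[float, float] = (1.0, 45.0)) -> float:
    """Fraction of background (pink) power inside ``band`` for this fs."""
    T = round(EPOCH_SECONDS * fs)
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    w2 = _pink_spectrum_weights(freqs, background_band) ** 2
    mask = (freqs >= band[0]) & (freqs <= band[1])
    total = w2.sum()
    return float(w2[mask].sum() / total) if total > 0 else 0.0


def shift_signatures(gain: float, fs: float,
                     background_band: tuple[float, float],
                     bands: tuple[tuple[float, float], ...] | None = None
                     ) -> tuple[ClassSignature, ...]:
    """Power-preserving spectral-shape signatures.

    Each class concentrates its designated channels' power into one band
    (multiplying its power by ``gain``) while the whole channel is damped so
    the total channel power stays at the background level.  Per-channel
    summary statistics (total energy, broadband variance) are therefore
    class-blind; the classes differ only in where on the spectrum - and
    hence in what temporal autocorrelation - the power sits.  This is the
    regime in which a temporal-filter learner has an edge over pooled
    band-energy features.
    """
    if bands is None:
        nyq = fs / 2.0
        bands = ((8.0, 13.0), (4.0, 8.0), (min(15.0, 0.6 * nyq),
                                           min(22.0, 0.95 * nyq)))
    mu, theta, beta = bands[0], bands[1], bands[2]
    plan = {0: (("FC6", "F8"), mu), 1: (("FC5", "F7"), mu),
            2: (("FZ", "F7", "F8"), theta), 3: (("FZ", "FC5", "FC6"), beta)}
    sigs = []
    for cid, (chans, band) in plan.items():
        f = band_fraction(band, fs, background_band)
        damp = 1.0 / (1.0 + (gain - 1.0) * f)
        gains = {}
        for ch in chans:
            gains[(ch, band)] = gain
            gains[(ch, background_band)] = damp
        sigs.append(ClassSignature(cid, gains))
    return tuple(sigs)


@dataclass
class EpochSet:
    """n labeled epochs, each channels x samples in microvolts."""

    data: np.ndarray        # (n, C, T) float64, microvolts
    labels: np.ndarray      # (n,) int in 0..3
    fs: float = 1000.0
    montage: ChannelMontage = field(default_factory=default_montage)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (n, C, T), got shape {self.data.shape}")
        n, C, T = self.data.shape
        if C != len(self.montage.names):
            raise ValueError(f"{C} channels but montage has {len(self.montage.names)}")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} epochs")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite values")
        expected_T = round(EPOCH_SECONDS * self.fs)
        if T != expected_T:
            raise ValueError(f"T={T} but {EPOCH_SECONDS} s at fs={self.fs} needs {expected_T}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.labels.copy(), self.fs, self.montage)

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(self.data[idx], self.labels[idx], self.fs, self.montage)


@dataclass(frozen=True)
class ArtifactSpec:
    """Additive contamination model: EOG drift, EMG bursts, power-line hum.

    A zero amplitude disables that artifact entirely.  Amplitudes are peak
    values in microvolts; bands are in Hz and must sit inside (0, fs/2).
    """

    eog_amplitude: float = 0.0
    eog_band: tuple[float, float] = (0.3, 2.0)
    emg_amplitude: float = 0.0
    emg_band: tuple[float, float] = (30.0, 100.0)
    emg_channels: tuple[str, ...] = ("FC5", "FC6")
    powerline_amplitude: float = 0.0
    powerline_freq: float = 50.0

    def __post_init__(self):
        for name, amp in (("eog", self.eog_amplitude), ("emg", self.emg_amplitude),
                          ("powerline", self.powerline_amplitude)):
            if amp < 0:
                raise ValueError(f"{name} amplitude must be >= 0, got {amp}")


def _pink_spectrum_weights(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """1/sqrt(f) amplitude weights, hard band-limited; DC weight zero."""
    w = np.zeros_like(freqs)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    w[mask] = 1.0 / np.sqrt(freqs[mask])
    return w


def generate_epochs(
    n_per_class: int,
    signatures: tuple[ClassSignature, ...] | None = None,
    fs: float = 1000.0,
    seed: int = 0,
    montage: ChannelMontage | None = None,
    background_rms: float = 10.0,
    background_band: tuple[float, float] = (1.0, 45.0),
) -> EpochSet:
    """Generate 4 * n_per_class labeled epochs with class-dependent spectra.

    Each epoch is synthesised in the frequency domain: complex Gaussian
    coefficients weighted 1/sqrt(f) inside ``background_band`` (band-limited
    pink noise, scaled so a plain background channel has RMS
    ``background_rms`` microvolts), with the class signature's band power
    gains applied multiplicatively on its designated channels.  Identical
    (arguments, seed) give bit-identical output.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    if signatures is None:
        signatures = default_signatures()
    if len(signatures) != N_CLASSES:
        raise ValueError(f"need exactly {N_CLASSES} signatures, got {len(signatures)}")
    if len({s.class_id for s in signatures}) != N_CLASSES:
        raise ValueError("signatures must cover class ids 0..3 exactly once")
    montage = montage or default_montage()

    T = round(EPOCH_SECONDS * fs)
    C = len(montage.names)
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    base_w = _pink_spectrum_weights(freqs, background_band)
    # normalise so that an unmodified channel has time-domain RMS background_rms
    # Parseval: sum |X_k|^2 over rfft bins (doubling interior bins) = T * sum x^2
    bin_mult = np.full(len(freqs), 2.0)
    bin_mult[0] = 1.0
    if T % 2 == 0:
        bin_mult[-1] = 1.0
    # E|X_k|^2 = w_k^2 for unit complex Gaussian draws
    norm = np.sqrt((bin_mult * base_w**2).sum() / T)
    base_w = base_w * (background_rms / norm)

    # per-class amplitude weight matrices (C, F)
    sig_by_id = {s.class_id: s for s in sorted(signatures, key=lambda s: s.class_id)}
    class_w = np.empty((N_CLASSES, C, len(freqs)))
    for cid, sig in sig_by_id.items():
        w = np.tile(base_w, (C, 1))
        for (ch, (lo, hi)), gain in sig.band_gains.items():
            g = gain
            if sig.lateralization is not None:
                hemi = _hemisphere(ch)
                if hemi == "left":
                    g *= sig.lateralization
                elif hemi == "right":
                    g /= sig.lateralization
            ci = montage.index(ch)
            band_mask = (freqs >= lo) & (freqs <= hi)
            w[ci, band_mask] *= np.sqrt(g)
        class_w[cid] = w

    rng = np.random.default_rng(seed)
    n = N_CLASSES * n_per_class
    labels = np.repeat(np.arange(N_CLASSES), n_per_class)
    data = np.empty((n, C, T))
    for i, lab in enumerate(labels):
        re = rng.standard_normal((C, len(freqs)))
        im = rng.standard_normal((C, len(freqs)))
        X = (re + 1j * im) / np.sqrt(2.0) * class_w[lab]
        for cp in sig_by_id[int(lab)].couplings:
            mask = (freqs >= cp.band[0]) & (freqs <= cp.band[1])
            s_re = rng.standard_normal(len(freqs))
            s_im = rng.standard_normal(len(freqs))
            S = ((s_re + 1j * s_im) / np.sqrt(2.0)
                 * base_w * np.sqrt(cp.strength) * mask)
            X[montage.index(cp.ch_a)] += S
            X[montage.index(cp.ch_b)] += cp.sign * S
        data[i] = np.fft.irfft(X, n=T, axis=1) * np.sqrt(T)
    return EpochSet(data=data, labels=labels, fs=fs, montage=montage)


def _bandlimited_noise(rng: np.random.Generator, T: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-peak band-limited Gaussian noise trace of length T."""
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    X = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * mask
    x = np.fft.irfft(X, n=T)
    peak = np.abs(x).max()
    return x / peak if peak > 0 else x


def inject_artifacts(epochs: EpochSet, spec: ArtifactSpec, seed: int = 0) -> EpochSet:
    """Return clean epochs plus additive EOG/EMG/power-line components.

    The input is untouched, so the caller keeps the clean ground truth for
    recovery scoring.  EOG is a common low-frequency drift on all prefrontal
    channels; EMG is independent high-frequency noise per affected channel;
    power-line is a fixed-frequency sinusoid with a random phase shared by
    all channels of an epoch.
    """
    fs, T = epochs.fs, epochs.n_samples
    nyq = fs / 2.0
    for name, band in (("eog", spec.eog_band), ("emg", spec.emg_band)):
        amp = getattr(spec, f"{name}_amplitude")
        if amp > 0 and not (0 < band[0] < band[1] < nyq):
            raise ValueError(f"{name} band {band} outside (0, {nyq})")
    if spec.powerline_amplitude > 0 and not (0 < spec.powerline_freq < nyq):
        raise ValueError(f"power-line frequency {spec.powerline_freq} outside (0, {nyq})")

    out = epochs.copy()
    rng = np.random.default_rng(seed)
    frontal = [epochs.montage.index(ch)
               for ch in epochs.montage.channels_with_role("prefrontal")]
    emg_idx = [epochs.montage.index(ch) for ch in spec.emg_channels]
    t = np.arange(T) / fs
    for i in range(epochs.n_epochs):
        if spec.eog_amplitude > 0:
            drift = spec.eog_amplitude * _bandlimited_noise(rng, T, fs, spec.eog_band)
            out.data[i, frontal, :] += drift
        if spec.emg_amplitude > 0:
            hi = min(spec.emg_band[1], 0.99 * nyq)
            for ci in emg_idx:
                out.data[i, ci, :] += spec.emg_amplitude * _bandlimited_noise(
                    rng, T, fs, (spec.emg_band[0], hi))
        if spec.powerline_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            hum = spec.powerline_amplitude * np.sin(2 * np.pi * spec.powerline_freq * t + phase)
            out.data[i] += hum[None, :]
    return out


# ---------------------------------------------------------------------------
# container I/O: data.npy + meta.json sidecar in a directory

def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an epoch set as ``data.npy`` plus a ``meta.json`` sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "data.npy", epochs.data)
    meta = {
        "labels": epochs.labels.tolist(),
        "fs": epochs.fs,
        "montage": {"names": list(epochs.montage.names),
                    "roles": dict(epochs.montage.roles)},
        "class_names": list(CLASS_NAMES),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Read an epoch set written by :func:`write_epochs` (lossless)."""
    path = Path(path)
    data = np.load(path / "data.npy")
    meta = json.loads((path / "meta.json").read_text())
    montage = ChannelMontage(names=tuple(meta["montage"]["names"]),
                             roles=dict(meta["montage"]["roles"]))
    labels = np.asarray(meta["labels"], dtype=np.int64)
    if len(labels) != data.shape[0]:
        raise ValueError(
            f"container mismatch: {len(labels)} labels for {data.shape[0]} epochs")
    return EpochSet(data=data, labels=labels, fs=float(meta["fs"]), montage=montage)


def read_edf_epochs(edf_path: str | Path, events_path: str | Path,
                    montage: ChannelMontage | None = None) -> EpochSet:
    """Segment a continuous EDF recording into 4 s epochs.

    ``events_path`` is a TSV with columns ``onset_sample`` and ``label``.
    Channels are selected and reordered to the montage; epochs that run past
    the end of the recording raise.
    """
    import mne

    montage = montage or default_montage()
    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    T = round(EPOCH_SECONDS * fs)
    picks = [raw.ch_names.index(ch) for ch in montage.names]
    sig = raw.get_data()[picks] * 1e6  # mne returns volts; container is microvolts

    import pandas as pd

    events = pd.read_csv(events_path, sep="\t")
    if not {"onset_sample", "label"}.issubset(events.columns):
        raise ValueError("event table needs onset_sample and label columns")
    data, labels = [], []
    for _, row in events.iterrows():
        start = int(row["onset_sample"])
        if start < 0 or start + T > sig.shape[1]:
            raise ValueError(f"epoch at sample {start} exceeds the recording")
        data.append(sig[:, start:start + T])
        labels.append(int(row["label"]))
    return EpochSet(data=np.stack(data), labels=np.asarray(labels), fs=fs,
                    montage=montage)
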