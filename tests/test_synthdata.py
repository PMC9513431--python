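"""Generator properties: determinism, balance, spectral separability,
artifact injection and container round trips."""

import numpy as np
import pytest
from scipy.signal import welch

import fexbci
from fexbci.edf import write_edf
from fexbci.synthdata import (CLASS_NAMES, ChannelMontage, read_edf_epochs,
                              _hemisphere)


def band_power(x, fs, lo, hi):
    f, P = welch(x, fs=fs, nperseg=min(len(x), 1024))
    return P[(f >= lo) & (f <= hi)].sum()


class TestGenerateEpochs:
    def test_shape_balance_and_determinism(self):
        e1 = fexbci.generate_epochs(3, fs=250, seed=7)
        e2 = fexbci.generate_epochs(3, fs=250, seed=7)
        assert e1.data.shape == (12, 8, 1000)
        assert np.array_equal(e1.data, e2.data)
        counts = np.bincount(e1.labels, minlength=4)
        assert (counts == 3).all()
        assert np.isfinite(e1.data).all()

    def test_paper_scale_set_is_240_by_8_by_4000(self):
        # the offline protocol: 60 trials per expression, 4 s at 1 kHz
        e = fexbci.generate_epochs(60, fs=1000, seed=7)
        assert e.data.shape == (240, 8, 4000)

    def test_identical_signatures_remove_separability(self):
        sig = fexbci.ClassSignature
        same = tuple(sig(c, {("C3", (8.0, 13.0)): 2.0}) for c in range(4))
        e = fexbci.generate_epochs(6, same, fs=250, seed=5)
        ci = e.montage.index("C3")
        powers = [np.mean([band_power(e.data[i, ci], 250, 8, 13)
                           for i in np.flatnonzero(e.labels == c)])
                  for c in range(4)]
        assert max(powers) / min(powers) < 1.5  # no systematic class contrast

    def test_band_gain_targets_the_right_channel_and_class(self):
        sig = fexbci.ClassSignature
        sigs = (sig(0, {("C3", (8.0, 13.0)): 4.0}),
                sig(1, {}), sig(2, {}), sig(3, {}))
        e = fexbci.generate_epochs(50, sigs, fs=250, seed=2)
        ci = e.montage.index("C3")
        p = np.array([band_power(e.data[i, ci], 250, 8, 13)
                      for i in range(e.n_epochs)])
        cls0 = p[e.labels == 0]
        rest = p[e.labels != 0]
        wins = (cls0[:, None] > rest[None, :]).mean()
        assert wins >= 0.95

    def test_gain_dial_is_monotonic(self):
        means = []
        for gain in (1.5, 3.0, 6.0):
            sigs = (fexbci.ClassSignature(0, {("FZ", (4.0, 8.0)): gain}),
                    *[fexbci.ClassSignature(c, {}) for c in (1, 2, 3)])
            e = fexbci.generate_epochs(20, sigs, fs=250, seed=4)
            ci = e.montage.index("FZ")
            means.append(np.mean([band_power(e.data[i, ci], 250, 4, 8)
                                  for i in np.flatnonzero(e.labels == 0)]))
        assert means[0] < means[1] < means[2]

    def test_input_validation(self):
        with pytest.raises(ValueError, match="n_per_class"):
            fexbci.generate_epochs(0, fs=250, seed=0)
        with pytest.raises(ValueError, match="signatures"):
            fexbci.generate_epochs(1, fexbci.default_signatures()[:3],
                                   fs=250, seed=0)

    def test_montage_invariants(self):
        with pytest.raises(ValueError, match="8 unique"):
            ChannelMontage(names=("A",) * 8, roles={"A": "motor"})
        assert _hemisphere("C3") == "left"
        assert _hemisphere("FC6") == "right"
        assert _hemisphere("CPz") == "midline"


class TestSignatureFamilies:
    def test_shift_signatures_preserve_total_channel_power(self):
        from fexbci.synthdata import shift_signatures
        bg = (1.0, 19.0)
        sigs = shift_signatures(6.0, 40.0, bg)
        e = fexbci.generate_epochs(30, sigs, fs=40.0, seed=17,
                                   background_band=bg)
        ci = e.montage.index("FZ")  # targeted by classes 2 and 3
        var_by_class = np.array([e.data[e.labels == c][:, ci, :].var()
                                 for c in range(4)])
        assert var_by_class.max() / var_by_class.min() < 1.25

    def test_coupling_signatures_set_correlation_sign_not_power(self):
        from fexbci.synthdata import coupling_signatures
        bg = (1.0, 19.0)
        e = fexbci.generate_epochs(30, coupling_signatures(8.0), fs=40.0,
                                   seed=18, background_band=bg)
        a, b = e.montage.index("FC5"), e.montage.index("F7")
        corr = np.array([np.mean([np.corrcoef(e.data[i, a], e.data[i, b])[0, 1]
                                  for i in np.flatnonzero(e.labels == c)])
                         for c in range(4)])
        # left pair is positively coupled for classes 0/1, negatively for 2/3
        assert (corr[:2] > 0.3).all() and (corr[2:] < -0.3).all()
        var_by_class = np.array([e.data[e.labels == c][:, a, :].var()
                                 for c in range(4)])
        assert var_by_class.max() / var_by_class.min() < 1.25

    def test_coupling_validation(self):
        from fexbci.synthdata import Coupling
        with pytest.raises(ValueError, match="sign"):
            Coupling("FC5", "F7", (8.0, 13.0), sign=0)
        with pytest.raises(ValueError, match="strength"):
            Coupling("FC5", "F7", (8.0, 13.0), strength=0.0)


class TestInjectArtifacts:
    def test_zero_amplitudes_are_identity(self, small_epochs):
        out = fexbci.inject_artifacts(small_epochs, fexbci.ArtifactSpec(), seed=0)
        assert np.array_equal(out.data, small_epochs.data)

    def test_powerline_creates_dominant_spectral_peak(self):
        e = fexbci.generate_epochs(2, fs=250, seed=1)
        spec = fexbci.ArtifactSpec(powerline_amplitude=20.0, powerline_freq=50.0)
        out = fexbci.inject_artifacts(e, spec, seed=3)
        f, Pc = welch(e.data[0, 0], fs=250, nperseg=500)
        _, Pd = welch(out.data[0, 0], fs=250, nperseg=500)
        k = np.argmin(np.abs(f - 50.0))
        assert Pd[k] >= 10 * Pc[k]

    def test_eog_hits_frontal_channels_and_lowcut_recovers(self):
        e = fexbci.generate_epochs(2, fs=250, seed=8)
        out = fexbci.inject_artifacts(
            e, fexbci.ArtifactSpec(eog_amplitude=100.0), seed=9)
        ci = e.montage.index("F7")
        corr_cont = np.corrcoef(out.data[0, ci], e.data[0, ci])[0, 1]
        # ideal low-cut: remove the EOG band again
        hp = fexbci.bandpass_filter(out, fexbci.FilterSpec(band=(3.0, 45.0)))
        corr_filt = np.corrcoef(hp.data[0, ci], e.data[0, ci])[0, 1]
        assert corr_cont < corr_filt
        motor = e.montage.index("C3")
        assert np.array_equal(out.data[0, motor], e.data[0, motor])

    def test_band_validation(self, small_epochs):
        spec = fexbci.ArtifactSpec(eog_amplitude=1.0, eog_band=(0.3, 80.0))
        with pytest.raises(ValueError, match="band"):
            fexbci.inject_artifacts(small_epochs, spec, seed=0)  # fs/2 = 62.5


class TestContainerIO:
    def test_round_trip_is_lossless(self, small_epochs, tmp_path):
        fexbci.write_epochs(small_epochs, tmp_path / "e")
        back = fexbci.read_epochs(tmp_path / "e")
        assert np.array_equal(back.data, small_epochs.data)
        assert np.array_equal(back.labels, small_epochs.labels)
        assert back.fs == small_epochs.fs
        assert back.montage.names == small_epochs.montage.names

    def test_label_count_mismatch_raises(self, small_epochs, tmp_path):
        import json
        fexbci.write_epochs(small_epochs, tmp_path / "e")
        meta = json.loads((tmp_path / "e" / "meta.json").read_text())
        meta["labels"] = meta["labels"][:-1]
        (tmp_path / "e" / "meta.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="mismatch"):
            fexbci.read_epochs(tmp_path / "e")

    def test_edf_import_re_segments_a_continuous_recording(self, tmp_path):
        fs = 250
        src = fexbci.generate_epochs(1, fs=fs, seed=6)  # 4 epochs of 8 x 1000
        gap = np.zeros((8, 125))
        pieces, onsets, cursor = [], [], 0
        for i in range(src.n_epochs):
            pieces += [gap, src.data[i]]
            cursor += gap.shape[1]
            onsets.append(cursor)
            cursor += src.data[i].shape[1]
        continuous = np.concatenate(pieces, axis=1)
        edf = write_edf(tmp_path / "rec.edf", continuous, fs,
                        list(src.montage.names))
        tsv = tmp_path / "events.tsv"
        tsv.write_text("onset_sample\tlabel\n" + "\n".join(
            f"{o}\t{l}" for o, l in zip(onsets, src.labels)))
        back = read_edf_epochs(edf, tsv)
        assert back.data.shape == src.data.shape
        assert np.array_equal(back.labels, src.labels)
        # EDF stores int16-quantised physical values
        step = np.abs(continuous).max() / 32767
        assert np.abs(back.data - src.data).max() <= 2 * step

    def test_class_names_documented_order(self):
        assert CLASS_NAMES == ("left_smirk", "right_smirk", "furrow_brow",
                               "raise_brow")
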