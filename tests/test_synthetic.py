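import numpy as np
import pytest
from scipy.signal import welch
from scipy.spatial.distance import cdist

from onsnn import (
    BANDS,
    DriftEvent,
    SynthConfig,
    generate_segment,
    generate_stream,
    inject_concept_drift,
    inject_input_drift,
)


def band_powers(segment, bands=BANDS):
    """Welch-periodogram band powers, one value per (channel, band)."""
    f, P = welch(segment.values, fs=segment.sampling_rate, nperseg=512)
    return {name: P[:, (f >= lo) & (f < hi)].sum(axis=1)
            for name, (lo, hi) in bands.items()}


class TestGenerateSegment:
    def test_shape_and_determinism(self):
        cfg = SynthConfig()
        a = generate_segment("stress", cfg, seed=9)
        b = generate_segment("stress", cfg, seed=9)
        assert a.values.shape == (4, 1280)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            generate_segment("bored", SynthConfig(), seed=0)

    def test_noise_free_single_band_is_pure_oscillation(self):
        cfg = SynthConfig(
            class_profiles={"stress": {"alpha": 1.0}, "neutral": {"alpha": 1.0},
                            "positive": {"alpha": 1.0}},
            sinusoids_per_band=1, pink_sigma=0.0, white_sigma=0.0)
        seg = generate_segment("stress", cfg, seed=4)
        from scipy.signal import periodogram
        f, P = periodogram(seg.values, fs=seg.sampling_rate)
        peaks = f[P.argmax(axis=1)]
        lo, hi = BANDS["alpha"]
        assert ((peaks >= lo) & (peaks <= hi)).all()
        # essentially all power sits at the peak (no noise terms)
        assert (P.max(axis=1) / P.sum(axis=1) > 0.5).all()

    def test_class_band_rankings_recoverable_by_periodogram(self):
        cfg = SynthConfig()
        beta_over_alpha = {}
        for cls in cfg.classes:
            ratios = []
            for s in range(8):
                bp = band_powers(generate_segment(cls, cfg, seed=100 + s))
                ratios.append((bp["beta"] / bp["alpha"]).mean())
            beta_over_alpha[cls] = np.mean(ratios)
        assert beta_over_alpha["stress"] > beta_over_alpha["neutral"] > beta_over_alpha["positive"]


class TestGenerateStream:
    def test_default_counts(self):
        stream = generate_stream(SynthConfig(seed=1))
        assert len(stream) == 72
        labels = [s.label for s in stream]
        for cls in ("stress", "neutral", "positive"):
            assert labels.count(cls) == 24

    def test_reproducible_ordering_and_content(self):
        a = generate_stream(SynthConfig(seed=5, n_samples=12))
        b = generate_stream(SynthConfig(seed=5, n_samples=12))
        assert [s.label for s in a] == [s.label for s in b]
        np.testing.assert_array_equal(a[3].segment.values, b[3].segment.values)

    def test_empty_drift_schedule_is_stationary(self):
        plain = generate_stream(SynthConfig(seed=2, n_samples=12))
        again = generate_stream(SynthConfig(seed=2, n_samples=12, drift_schedule=()))
        np.testing.assert_array_equal(plain[7].segment.values,
                                      again[7].segment.values)


class TestInputDrift:
    def test_identity_scale(self):
        stream = generate_stream(SynthConfig(seed=0, n_samples=12))
        out = inject_input_drift(stream, at=6, scale=1.0)
        np.testing.assert_array_equal(out[8].segment.values,
                                      stream[8].segment.values)

    def test_variance_scales_quadratically_and_labels_unchanged(self):
        stream = generate_stream(SynthConfig(seed=0, n_samples=12))
        out = inject_input_drift(stream, at=6, scale=2.0)
        for i in range(12):
            assert out[i].label == stream[i].label
            v0 = stream[i].segment.values.var()
            v1 = out[i].segment.values.var()
            assert v1 == pytest.approx(v0 * (4.0 if i >= 6 else 1.0))

    def test_out_of_range_index_rejected(self):
        stream = generate_stream(SynthConfig(seed=0, n_samples=12))
        with pytest.raises(IndexError):
            inject_input_drift(stream, at=12, scale=2.0)


class TestConceptDrift:
    swap = {"stress": "positive", "positive": "stress"}

    def test_identity_mapping(self):
        stream = generate_stream(SynthConfig(seed=0, n_samples=12))
        out = inject_concept_drift(stream, at=6, mapping={})
        assert [s.label for s in out] == [s.label for s in stream]

    def test_labels_permuted_inputs_untouched(self):
        stream = generate_stream(SynthConfig(seed=0, n_samples=12))
        out = inject_concept_drift(stream, at=6, mapping=self.swap)
        for i in range(12):
            np.testing.assert_array_equal(out[i].segment.values,
                                          stream[i].segment.values)
            expected = stream[i].label if i < 6 else self.swap.get(
                stream[i].label, stream[i].label)
            assert out[i].label == expected

    def test_non_bijective_mapping_rejected(self):
        stream = generate_stream(SynthConfig(seed=0, n_samples=12))
        with pytest.raises(ValueError):
            inject_concept_drift(stream, at=6,
                                 mapping={"stress": "neutral", "positive": "neutral"})

    def test_pooled_variance_preserved(self):
        stream = generate_stream(SynthConfig(seed=3))
        out = inject_concept_drift(stream, at=36, mapping=self.swap)
        pre = np.mean([s.segment.values.var() for s in out[:36]])
        post = np.mean([s.segment.values.var() for s in out[36:]])
        assert post == pytest.approx(pre, rel=0.15)

    def test_schedule_applied_by_generate_stream(self):
        ev = DriftEvent(at=6, kind="concept",
                        mapping=(("stress", "positive"), ("positive", "stress")))
        plain = generate_stream(SynthConfig(seed=4, n_samples=12))
        drifted = generate_stream(SynthConfig(seed=4, n_samples=12,
                                              drift_schedule=(ev,)))
        assert [s.label for s in drifted] != [s.label for s in plain]
        np.testing.assert_array_equal(drifted[9].segment.values,
                                      plain[9].segment.values)


def test_band_power_classifier_separability_floor():
    """A trivial nearest-band-power classifier clears 90% on default streams."""
    stream = generate_stream(SynthConfig(seed=6))
    feats = []
    for s in stream:
        bp = band_powers(s.segment)
        feats.append(np.concatenate([bp[b] for b in BANDS]))
    feats = np.asarray(feats)
    labels = np.asarray([s.label for s in stream])
    D = cdist(feats, feats)
    np.fill_diagonal(D, np.inf)
    assert (labels[D.argmin(axis=1)] == labels).mean() > 0.9
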