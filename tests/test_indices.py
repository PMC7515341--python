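"""Band splitting, 2-D Shannon entropy, and the eight-index feature vector."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mtfse import (
    BAND_EDGES,
    INDEX_NAMES,
    Quantizer,
    TFSI,
    compute_indices,
    shannon_entropy_image,
    split_bands,
)
from oracles import naive_entropy


def random_tfsi(seed: int, n_time: int = 20, n_freq: int = 64) -> TFSI:
    rng = np.random.default_rng(seed)
    return TFSI(
        power=rng.uniform(0, 100, size=(n_time, n_freq)),
        time_axis=np.arange(n_time, dtype=float),
        freq_axis=np.linspace(0, 0.4, n_freq),
        window_length_s=64.0,
        hop_s=4.0,
    )


class TestSplitBands:
    def test_partition_matches_brute_force_membership(self):
        tfsi = random_tfsi(0, n_freq=256)
        subs = split_bands(tfsi)
        # brute-force band assignment of each grid frequency
        expected = {"VLF": 0, "LF": 0, "HF": 0}
        for f in tfsi.freq_axis:
            if f < 0.04:
                expected["VLF"] += 1
            elif f < 0.15:
                expected["LF"] += 1
            else:
                expected["HF"] += 1
        assert {k: v.shape[1] for k, v in subs.items()} == expected
        # frozen counts for the canonical 256-point grid
        assert expected == {"VLF": 26, "LF": 70, "HF": 160}
        assert sum(expected.values()) == 256
        assert all(v.shape[0] == tfsi.n_time for v in subs.values())

    def test_single_tone_at_0p2hz_leaves_vlf_lf_empty_of_power(self):
        freqs = np.linspace(0, 0.4, 256)
        power = np.zeros((10, 256))
        power[:, np.argmin(np.abs(freqs - 0.2))] = 5.0
        tfsi = TFSI(power, np.arange(10.0), freqs, 64.0, 4.0)
        subs = split_bands(tfsi)
        assert not subs["VLF"].any() and not subs["LF"].any()
        assert subs["HF"].any()

    def test_band_edges_are_the_canonical_hrv_bands(self):
        assert BAND_EDGES == {"VLF": (0.0, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}

    def test_wrong_frequency_span_rejected(self):
        bad = TFSI(
            np.ones((4, 8)), np.arange(4.0), np.linspace(0, 0.3, 8), 64.0, 4.0
        )
        with pytest.raises(ValueError, match="span"):
            split_bands(bad)


class TestShannonEntropyImage:
    def test_constant_image_has_zero_entropy(self):
        q = Quantizer(n_levels=256, log_base=10)
        assert shannon_entropy_image(np.full((5, 7), 3.3), q, (0.0, 10.0)) == 0.0
        # constant image whose range collapses to a point is also valid
        assert shannon_entropy_image(np.full((5, 7), 3.3), q, (3.3, 3.3)) == 0.0

    def test_equiprobable_bins_reach_log_k(self):
        k = 16
        q = Quantizer(n_levels=k, log_base=10)
        img = (np.arange(k) + 0.5) / k  # one pixel per bin
        assert shannon_entropy_image(img, q, (0.0, 1.0)) == pytest.approx(
            math.log10(k), abs=1e-12
        )

    def test_worked_two_by_two_example(self):
        # pixels binned to probabilities {0.5, 0.25, 0.25}: entropy 1.5 bits
        img = np.array([[0.1, 0.1], [0.4, 0.9]])
        q = Quantizer(n_levels=4, log_base=2)
        assert shannon_entropy_image(img, q, (0.0, 1.0)) == pytest.approx(1.5, abs=1e-12)

    def test_max_value_lands_in_top_bin(self):
        q = Quantizer(n_levels=4, log_base=2)
        img = np.array([1.0, 1.0])  # at the range maximum
        assert shannon_entropy_image(img, q, (0.0, 1.0)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_naive_histogram_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(-3, 7, size=(17, 23))
        q = Quantizer(n_levels=64, log_base=10)
        grange = (float(img.min()), float(img.max()))
        ours = shannon_entropy_image(img, q, grange)
        assert ours == pytest.approx(naive_entropy(img, 64, 10, grange), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        img=arrays(
            np.float64,
            st.tuples(st.integers(1, 8), st.integers(1, 8)),
            elements=st.floats(0, 1e6, allow_nan=False),
        ),
        k=st.integers(2, 512),
    )
    def test_entropy_bounds_property(self, img, k):
        q = Quantizer(n_levels=k, log_base=10)
        h = shannon_entropy_image(img, q, (float(img.min()), float(img.max())))
        assert 0.0 <= h <= math.log10(k) + 1e-12

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy_image(np.empty((0, 3)), Quantizer(), (0.0, 1.0))


class TestComputeIndices:
    def test_fixed_order_and_ratio_identities(self):
        tfsi = random_tfsi(1)
        vec = compute_indices(tfsi)
        d = vec.as_dict()
        assert tuple(d) == INDEX_NAMES
        # definitional identities hold exactly in floating point
        assert d["ShEnpVLF"] == d["ShEnVLF"] / d["ShEnTotal"]
        assert d["ShEnpLF"] == d["ShEnLF"] / d["ShEnTotal"]
        assert d["ShEnpHF"] == d["ShEnHF"] / d["ShEnTotal"]
        assert d["ShEnLF/HF"] == d["ShEnLF"] / d["ShEnHF"]

    def test_entropies_within_quantizer_bounds(self):
        q = Quantizer(n_levels=32, log_base=2)
        for seed in range(10):
            vec = compute_indices(random_tfsi(seed), q)
            for v in (vec.shen_vlf, vec.shen_lf, vec.shen_hf, vec.shen_total):
                assert 0.0 <= v <= q.max_entropy + 1e-12

    @pytest.mark.parametrize("factor", [10.0, 0.5, 3.7])
    def test_scale_invariance(self, factor):
        tfsi = random_tfsi(2)
        base = compute_indices(tfsi).as_array()
        scaled = compute_indices(tfsi.scaled(factor)).as_array()
        np.testing.assert_array_equal(base, scaled)

    def test_partition_completeness(self):
        tfsi = random_tfsi(3, n_freq=200)
        subs = split_bands(tfsi)
        assert sum(s.size for s in subs.values()) == tfsi.power.size

    def test_degenerate_constant_image_flags_ratios_missing(self):
        tfsi = TFSI(
            np.full((10, 64), 2.0),
            np.arange(10.0),
            np.linspace(0, 0.4, 64),
            64.0,
            4.0,
        )
        vec = compute_indices(tfsi)
        assert vec.shen_total == 0.0
        assert vec.shen_pvlf is None and vec.shen_lf_hf is None
        assert not vec.is_complete
        assert np.isnan(vec.as_array()[-1])

    def test_lf_dominant_exceeds_hf_dominant_on_lf_hf_ratio(self):
        # segments whose dominant oscillation sits in LF (0.10 Hz) must score a
        # higher ShEnLF/HF than matched segments dominated by HF (0.25 Hz)
        from mtfse import (
            build_tfsi,
            generate_rr,
            interpolate_resample,
            remove_artifacts,
            segment_and_label,
        )
        from mtfse.synthetic import SynthConfig

        def segment(dominant_lf: bool, seed: int):
            lf_amp, hf_amp = (40.0, 10.0) if dominant_lf else (10.0, 40.0)
            cfg = SynthConfig(
                mean_rr=800.0,
                osc_components=((0.10, lf_amp, 0.0), (0.25, hf_amp, 0.0)),
                noise_sd=10.0,
                seed=seed,
            )
            rr, ann = generate_rr(cfg)
            return interpolate_resample(
                segment_and_label(remove_artifacts(rr), ann, "C")[0]
            )

        wins = 0
        for seed in range(20):
            lf = compute_indices(build_tfsi(segment(True, 1000 + seed)))
            hf = compute_indices(build_tfsi(segment(False, 1000 + seed)))
            wins += lf.shen_lf_hf > hf.shen_lf_hf
        assert wins == 20
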