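"""Atmospheric-scattering synthesis: transmission, compositing, inversion,
depth generation and dataset construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dunet.haze_synthesis import (
    DatasetManifest,
    SynthesisParams,
    apply_asm,
    build_dataset,
    generate_synthetic_depth,
    invert_asm,
    load_image,
    split_counts,
    transmission_from_depth,
)

A_PAPER = 170 / 255


class TestTransmission:
    def test_closed_form_values(self):
        d = np.array([[0.0, 0.5], [1.0, 0.25]])
        t = transmission_from_depth(d, beta=2.0)
        np.testing.assert_allclose(
            t, [[1.0, 0.36787944117144233], [0.1353352832366127, np.exp(-0.5)]],
            rtol=1e-12,
        )

    def test_zero_depth_gives_unit_transmission_for_any_beta(self):
        d = np.zeros((4, 4))
        for beta in (0.0, 1.0, 3.7):
            np.testing.assert_array_equal(transmission_from_depth(d, beta), 1.0)

    def test_monotone_decreasing_in_beta_and_depth(self):
        d = np.linspace(0.1, 1.0, 10).reshape(2, 5)
        t1 = transmission_from_depth(d, 1.0)
        t2 = transmission_from_depth(d, 2.0)
        assert np.all(t2 < t1)
        assert np.all(np.diff(transmission_from_depth(d, 2.0).ravel()) < 0)
        assert np.all((t1 > 0) & (t1 <= 1))

    def test_rejects_negative_beta_and_bad_depth(self):
        with pytest.raises(ValueError):
            transmission_from_depth(np.zeros((2, 2)), -0.1)
        with pytest.raises(ValueError):
            transmission_from_depth(np.array([[np.nan]]), 1.0)
        with pytest.raises(ValueError):
            transmission_from_depth(np.array([[-0.5]]), 1.0)


class TestASM:
    def test_scalar_arithmetic_example(self):
        # J=100, t=0.5, A=170 on the 8-bit scale -> I = 135
        j = np.full((1, 1, 3), 100 / 255)
        t = np.full((1, 1), 0.5)
        i = apply_asm(j, t, A_PAPER)
        np.testing.assert_allclose(i, 135 / 255, rtol=1e-12)
        back = invert_asm(i, t, A_PAPER)
        np.testing.assert_allclose(back, 100 / 255, rtol=1e-12)

    def test_limits(self):
        rng = np.random.default_rng(0)
        j = rng.uniform(0, 1, (5, 5, 3))
        np.testing.assert_array_equal(apply_asm(j, np.ones((5, 5)), 0.3), j)
        np.testing.assert_allclose(
            apply_asm(j, np.zeros((5, 5)), 0.3), 0.3, rtol=1e-12
        )
        # I == A -> J == A regardless of t
        i = np.full((5, 5, 3), 0.42)
        np.testing.assert_allclose(
            invert_asm(i, np.full((5, 5), 0.6), 0.42), 0.42, rtol=1e-12
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        j = rng.uniform(0, 1, (6, 6, 3))
        t = rng.uniform(0.1, 1.0, (6, 6))
        a = rng.uniform(0, 1)
        rec = invert_asm(apply_asm(j, t, a), t, a)
        assert np.max(np.abs(rec - j)) < 1e-6

    def test_contrast_shrinks_monotonically_with_beta_under_uniform_depth(self):
        rng = np.random.default_rng(1)
        j = rng.uniform(0, 1, (16, 16, 3))
        d0 = 0.5
        stds = []
        for beta in (0.5, 1.0, 2.0, 3.0):
            t = transmission_from_depth(np.full((16, 16), d0), beta)
            stds.append(apply_asm(j, t, A_PAPER).std())
        assert all(a > b for a, b in zip(stds, stds[1:]))
        # std(I) = exp(-beta d0) * std(J) exactly for constant depth
        np.testing.assert_allclose(stds[0], np.exp(-0.5 * d0) * j.std(), rtol=1e-10)

    def test_invert_rejects_nonpositive_or_floored_t(self):
        i = np.full((2, 2, 3), 0.5)
        with pytest.raises(ValueError):
            invert_asm(i, np.zeros((2, 2)), 0.5)
        with pytest.raises(ValueError):
            invert_asm(i, np.full((2, 2), 1e-5), 0.5)  # below the 1e-3 floor

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            apply_asm(np.zeros((4, 4, 3)), np.zeros((3, 3)), 0.5)


class TestSyntheticDepth:
    def test_normalization_and_determinism(self):
        d1 = generate_synthetic_depth(32, 24, seed=5, smoothness=4.0)
        d2 = generate_synthetic_depth(32, 24, seed=5, smoothness=4.0)
        d3 = generate_synthetic_depth(32, 24, seed=6, smoothness=4.0)
        assert d1.shape == (32, 24)
        assert d1.min() == 0.0 and d1.max() == 1.0
        np.testing.assert_array_equal(d1, d2)
        assert np.any(d1 != d3)

    def test_rejects_degenerate_shape(self):
        with pytest.raises(ValueError):
            generate_synthetic_depth(4, 64, seed=0)


class TestSplit:
    @pytest.mark.parametrize("n,expected", [
        (1978, (1385, 197, 396)),   # the published dataset size
        (10, (7, 1, 2)),
        (9, (6, 1, 2)),
        (3, (2, 0, 1)),
    ])
    def test_counts(self, n, expected):
        assert split_counts(n) == expected

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(n=st.integers(3, 100_000))
    def test_total_conserved(self, n):
        tr, va, te = split_counts(n)
        assert tr + va + te == n
        assert tr >= 0 and va >= 0 and te >= 0

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_counts(100, (0.5, 0.2, 0.2))


class TestBuildDataset:
    def test_manifest_split_and_round_trip(self, tmp_path, clear_dir):
        params = SynthesisParams(beta=2.0, A=A_PAPER, seed=3, smoothness=8.0)
        manifest = build_dataset(clear_dir, params, tmp_path / "out")
        assert manifest.counts() == {"train": 7, "val": 1, "test": 2}
        assert len({e.hazy_path for e in manifest.entries}) == 10

        # every pair inverts back to the clear image within 8-bit quantization
        for i, entry in enumerate(manifest.entries[:3]):
            clear = load_image(entry.clear_path)
            hazy = load_image(entry.hazy_path)
            stem = entry.clear_path.rsplit("/", 1)[-1].replace(".png", "")
            depth = np.load(tmp_path / "out" / "depth" / f"{stem}.npy")
            t = transmission_from_depth(depth.astype(np.float64), params.beta)
            rec = invert_asm(hazy, t, params.A)
            # one 8-bit quantization step on I is amplified by at most 1/t
            tol = (0.5 / 255) / t.min() + 0.5 / 255 + 1e-6
            assert np.max(np.abs(rec - clear)) <= tol

    def test_split_assignment_deterministic(self, tmp_path, clear_dir):
        params = SynthesisParams(seed=11)
        m1 = build_dataset(clear_dir, params, tmp_path / "a")
        m2 = build_dataset(clear_dir, params, tmp_path / "b")
        assert [e.split for e in m1.entries] == [e.split for e in m2.entries]

    def test_constant_zero_depth_reproduces_clear_file(self, tmp_path, clear_dir):
        depth_dir = tmp_path / "depths"
        depth_dir.mkdir()
        for p in clear_dir.iterdir():
            np.save(depth_dir / f"{p.stem}.npy", np.zeros((48, 48), np.float32))
        manifest = build_dataset(clear_dir, SynthesisParams(seed=0),
                                 tmp_path / "out", depth_dir=depth_dir)
        e = manifest.entries[0]
        np.testing.assert_array_equal(load_image(e.hazy_path), load_image(e.clear_path))

    def test_manifest_csv_round_trip(self, tmp_path, tiny_dataset):
        data_dir, manifest, _ = tiny_dataset
        loaded = DatasetManifest.load(data_dir / "manifest.csv")
        assert [e.split for e in loaded.entries] == [e.split for e in manifest.entries]
        assert loaded.counts() == manifest.counts()

    def test_empty_dir_raises(self, tmp_path):
        empty = tmp_path / "none"
        empty.mkdir()
        with pytest.raises(RuntimeError):
            build_dataset(empty, SynthesisParams(), tmp_path / "out")

    def test_beta_cap_enforced(self, tmp_path, clear_dir):
        with pytest.raises(ValueError):
            build_dataset(clear_dir, SynthesisParams(beta=5.0), tmp_path / "out")


def test_params_validation():
    with pytest.raises(ValueError):
        SynthesisParams(beta=-1.0)
    with pytest.raises(ValueError):
        SynthesisParams(A=1.5)
    assert math.isclose(SynthesisParams().A, 170 / 255)
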