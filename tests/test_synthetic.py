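"""Synthetic generator: geometry, noise calibration, missing wedge."""

import numpy as np
import pytest
from scipy import ndimage

from mvtomo.io_volumes import Volume
from mvtomo.synthetic import (CapacityError, SimulationConfig, add_noise,
                              apply_missing_wedge, simulate_dataset,
                              simulate_patch)


def cfg(**kw):
    base = dict(shape=(24, 24, 24), n_classes=3, particles_per_patch=(3, 3),
                radius_range=(2.0, 3.5), snr=float("inf"), seed=11)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulatePatch:
    def test_particle_count_and_components(self):
        vol, lab, parts = simulate_patch(cfg())
        assert len(parts) == 3
        _, n = ndimage.label(lab.labels > 0, structure=np.ones((3, 3, 3)))
        assert n == 3

    def test_determinism(self):
        a = simulate_patch(cfg())
        b = simulate_patch(cfg())
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)
        assert a[2] == b[2]

    def test_noiseless_foreground_brighter(self):
        vol, lab, _ = simulate_patch(cfg())
        fg = vol.data[lab.labels > 0]
        bg = vol.data[lab.labels == 0]
        assert fg.mean() > bg.mean()
        assert bg.mean() == pytest.approx(0.0, abs=1e-6)

    def test_labels_inside_nominal_radius(self):
        vol, lab, parts = simulate_patch(cfg())
        coords = np.argwhere(lab.labels > 0)
        for v in coords:
            assert any(
                np.linalg.norm(v - np.array(p.center)) <= p.radius + 1e-6
                for p in parts
            )

    def test_center_voxel_carries_class(self):
        _, lab, parts = simulate_patch(cfg())
        for p in parts:
            c = tuple(int(round(v)) for v in p.center)
            assert lab.labels[c] == p.class_id

    def test_particles_disjoint(self):
        _, _, parts = simulate_patch(cfg())
        for i, a in enumerate(parts):
            for b in parts[i + 1:]:
                d = np.linalg.norm(np.subtract(a.center, b.center))
                assert d > a.radius + b.radius

    def test_capacity_error_when_overcrowded(self):
        crowded = cfg(shape=(16, 16, 16), particles_per_patch=(30, 30),
                      radius_range=(3.0, 3.0), max_place_tries=100)
        with pytest.raises(CapacityError):
            simulate_patch(crowded)

    def test_class_frequencies_uniform(self):
        """With uniform class sampling, frequencies converge (chi-square)."""
        from scipy.stats import chisquare

        counts = np.zeros(3)
        data = simulate_dataset(cfg(n_classes=3), 400, seed=5)
        for _, _, parts in data:
            for p in parts:
                counts[p.class_id - 1] += 1
        assert counts.sum() == 1200
        assert chisquare(counts).pvalue > 1e-4


class TestAddNoise:
    def test_infinite_snr_identity(self, random_volume):
        out = add_noise(random_volume, float("inf"), seed=0)
        np.testing.assert_array_equal(out.data, random_volume.data)

    @pytest.mark.parametrize("snr", [0.03, 0.05, 1.0])
    def test_variance_ratio_calibrated(self, snr):
        rng = np.random.default_rng(8)
        sig = rng.normal(size=(64, 64, 64)).astype(np.float32)
        vol = Volume(sig)
        noisy = add_noise(vol, snr, seed=21)
        noise = noisy.data - sig
        ratio = np.var(sig) / np.var(noise)
        assert ratio == pytest.approx(snr, rel=0.1)

    def test_different_seeds_same_level(self):
        rng = np.random.default_rng(8)
        vol = Volume(rng.normal(size=(48, 48, 48)).astype(np.float32))
        n1 = add_noise(vol, 0.05, seed=1).data - vol.data
        n2 = add_noise(vol, 0.05, seed=2).data - vol.data
        assert not np.allclose(n1, n2)
        assert np.var(n1) == pytest.approx(np.var(n2), rel=0.1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            add_noise(Volume(np.ones((8, 8, 8), dtype=np.float32)), 0.05, seed=0)

    def test_nonpositive_snr_rejected(self, random_volume):
        with pytest.raises(ValueError):
            add_noise(random_volume, 0.0, seed=0)


class TestMissingWedge:
    def test_near_identity_limit(self, rng):
        vol = Volume(rng.normal(size=(16, 16, 16)).astype(np.float32))
        out = apply_missing_wedge(vol, 89.9)
        span = vol.data.max() - vol.data.min()
        assert np.abs(out.data - vol.data).max() < 1e-6 * span

    def test_wedge_interior_coefficients_zeroed(self, rng):
        vol = Volume(rng.normal(size=(16, 16, 16)).astype(np.float32))
        out = apply_missing_wedge(vol, 60.0)
        spec = np.fft.fftn(out.data.astype(np.float64))
        kh = np.fft.fftfreq(16)[:, None, None]
        kd = np.fft.fftfreq(16)[None, None, :]
        # strictly inside the wedge by more than one cell's angular extent
        angle = np.degrees(np.arctan2(np.abs(kd), np.abs(kh) + 0.5 / 16))
        wedge = np.broadcast_to(angle > 60.0, spec.shape)
        assert wedge.any()
        # zero up to the float32 storage round-trip of the output volume
        assert np.abs(spec[wedge]).max() < 1e-5 * np.abs(spec).max()
        # something must actually have been removed
        assert not np.allclose(out.data, vol.data)

    def test_energy_non_increasing(self, rng):
        vol = Volume(rng.normal(size=(12, 12, 12)).astype(np.float32))
        out = apply_missing_wedge(vol, 45.0)
        assert np.sum(out.data**2) <= np.sum(vol.data**2) + 1e-3

    def test_output_real_and_shape(self, rng):
        vol = Volume(rng.normal(size=(8, 10, 12)).astype(np.float32))
        out = apply_missing_wedge(vol, 55.0)
        assert out.data.shape == vol.data.shape
        assert np.isrealobj(out.data)

    @pytest.mark.parametrize("bad", [0.0, 90.0, -5.0, 120.0])
    def test_angle_range(self, random_volume, bad):
        with pytest.raises(ValueError):
            apply_missing_wedge(random_volume, bad)


def test_dataset_determinism():
    a = simulate_dataset(cfg(), 4, seed=9)
    b = simulate_dataset(cfg(), 4, seed=9)
    for (va, la, pa), (vb, lb, pb) in zip(a, b):
        np.testing.assert_array_equal(va.data, vb.data)
        assert pa == pb
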