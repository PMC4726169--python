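"""Segmentation, signed distances, and the gold distance profile."""

import numpy as np
import pytest

from goldendose.imaging import (
    CellImage,
    DistanceProfile,
    SegmentationError,
    gold_distance_profile,
    pool_profiles,
    profile_summary,
    profile_to_shell,
    segment_nucleus,
    signed_distance_map,
)
from goldendose.synthetic import DeltaRing, SyntheticCellSpec, UniformAnnulus, make_cell_image


def disk_image(radius_px=50, shape=(128, 128), amplitude=100.0, pixel_size=0.1):
    yy, xx = np.indices(shape)
    c = (np.array(shape) - 1) / 2
    rr = np.hypot(yy - c[0], xx - c[1])
    nucleus = np.where(rr <= radius_px, amplitude, 0.0)
    return CellImage(nucleus, np.ones(shape), pixel_size), rr


class TestSegmentation:
    def test_noiseless_disk_recovered_exactly(self):
        image, rr = disk_image()
        mask = segment_nucleus(image)
        assert np.array_equal(mask.mask, rr <= 50)

    def test_blurred_disk_radius_within_one_pixel(self):
        spec = SyntheticCellSpec(seed=0, noise=False)
        image, truth = make_cell_image(spec)
        mask = segment_nucleus(image)
        radius_um = np.sqrt(mask.mask.sum() / np.pi) * spec.pixel_size
        assert radius_um == pytest.approx(truth["nucleus_radius_um"], abs=spec.pixel_size)

    def test_threshold_modes_give_nested_masks(self, noisy_cell):
        _, image, _ = noisy_cell
        low = segment_nucleus(image, "low").mask
        auto = segment_nucleus(image, "automatic").mask
        high = segment_nucleus(image, "high").mask
        assert np.all(auto <= low) and np.all(high <= auto)
        assert low.sum() > auto.sum() > high.sum()

    def test_flat_channel_rejected(self):
        image = CellImage(np.ones((32, 32)), np.ones((32, 32)), 0.1)
        with pytest.raises(SegmentationError):
            segment_nucleus(image)

    def test_unknown_mode_rejected(self, noisy_cell):
        with pytest.raises(ValueError):
            segment_nucleus(noisy_cell[1], "medium")


class TestSignedDistance:
    def test_disk_distances_match_analytic_field(self):
        image, rr = disk_image()
        mask = segment_nucleus(image)
        dist = signed_distance_map(mask, image.pixel_size)
        centre = np.unravel_index(np.argmin(rr), rr.shape)
        # centre sits half a pixel off the lattice and the boundary layer is
        # one pixel thick: allow two pixels of discretisation error
        assert dist[centre] == pytest.approx(-50 * 0.1, abs=0.2)
        assert np.all(dist[mask.boundary] == 0.0)
        # compare with |x - c| - rho away from the discrete boundary
        analytic = (rr - 50) * 0.1
        err = np.abs(dist - analytic)
        assert np.quantile(err, 0.99) < 2 * 0.1

    def test_sign_convention_negative_inside(self):
        image, rr = disk_image()
        mask = segment_nucleus(image)
        dist = signed_distance_map(mask, image.pixel_size)
        inside = mask.mask & ~mask.boundary
        assert np.all(dist[inside] < 0)
        assert np.all(dist[~mask.mask] > 0)


class TestProfile:
    def test_uniform_gold_gives_flat_unit_profile(self):
        image, _ = disk_image()
        mask = segment_nucleus(image)
        prof = gold_distance_profile(image, mask)
        assert np.allclose(prof.intensity, 1.0)

    def test_mass_conservation(self, noisy_cell):
        _, image, _ = noisy_cell
        mask = segment_nucleus(image)
        prof = gold_distance_profile(image, mask)
        assert prof.total_signal() == pytest.approx(
            float(image.gold_channel.sum()), rel=1e-6
        )

    def test_delta_ring_peaks_in_its_bin(self):
        spec = SyntheticCellSpec(
            gold_radial_density=DeltaRing(2.0), noise=False, psf_fwhm=1e-3, seed=0
        )
        image, _ = make_cell_image(spec)
        mask = segment_nucleus(image)
        prof = gold_distance_profile(image, mask)
        peak = prof.bin_centers[np.argmax(prof.intensity)]
        assert abs(peak - 2.0) <= prof.bin_width

    def test_lower_threshold_shifts_profile_to_negative_distances(self, noisy_cell):
        _, image, _ = noisy_cell

        def mean_distance(mode):
            mask = segment_nucleus(image, mode)
            prof = gold_distance_profile(image, mask)
            return np.average(prof.bin_centers, weights=prof.signal_sums)

        assert mean_distance("low") < mean_distance("automatic") < mean_distance("high")

    def test_pooling_accumulates_sums_and_counts(self, noisy_cell):
        _, image, _ = noisy_cell
        mask = segment_nucleus(image)
        prof = gold_distance_profile(image, mask)
        pooled = pool_profiles([prof, prof])
        assert np.allclose(pooled.intensity, prof.intensity)
        assert np.allclose(pooled.n_pixels, 2 * prof.n_pixels)

    def test_invalid_bin_width_rejected(self, noisy_cell):
        _, image, _ = noisy_cell
        with pytest.raises(ValueError):
            gold_distance_profile(image, segment_nucleus(image), bin_width=0.0)


def make_profile(centers, intensity, n_pixels=None, bw=0.25):
    centers = np.asarray(centers, float)
    intensity = np.asarray(intensity, float)
    n = np.ones_like(intensity) if n_pixels is None else np.asarray(n_pixels, float)
    return DistanceProfile(centers, intensity, n, bw)


class TestSummary:
    def test_single_bin_profile(self):
        prof = make_profile([0.5], [3.0])
        s = profile_summary(prof)
        assert s["peak_offset_um"] == 0.5
        assert s["fraction_inside"] == 0.0

    def test_symmetric_profile_has_half_mass_inside(self):
        prof = make_profile([-0.5, -0.25, 0.25, 0.5], [1, 2, 2, 1])
        assert profile_summary(prof)["fraction_inside"] == pytest.approx(0.5)

    def test_decay_distance_is_shallowest_subthreshold_bin(self):
        prof = make_profile([-1.0, -0.75, -0.5, 0.0, 0.5], [0.01, 0.02, 0.5, 1.0, 10.0])
        assert profile_summary(prof)["inside_decay_distance_um"] == 0.75

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            profile_summary(make_profile([0.0, 0.5], [0.0, 0.0]))


class TestProfileToShell:
    def test_uniform_annulus_recovers_methods_shell(self):
        spec = SyntheticCellSpec(
            gold_radial_density=UniformAnnulus(0.0, 10.0),
            noise=False,
            psf_fwhm=1e-3,
            seed=0,
        )
        image, _ = make_cell_image(spec)
        mask = segment_nucleus(image)
        prof = gold_distance_profile(image, mask)
        shell = profile_to_shell(prof, 7.0, quantiles=(0.0, 1.0))
        assert shell.d1 == pytest.approx(7.0, abs=prof.bin_width)
        assert shell.d2 == pytest.approx(17.0, abs=2 * prof.bin_width)

    def test_membrane_delta_gives_minimal_shell(self):
        prof = make_profile([0.0], [5.0])
        shell = profile_to_shell(prof, 7.0)
        assert shell.d1 == 7.0
        # all mass clamped into [0, bw/2] -> d2 one half-bin out
        assert shell.d2 == pytest.approx(7.0 + prof.bin_width / 2)

    def test_intranuclear_leakage_clamped_at_membrane(self):
        leaky = make_profile([-0.5, -0.25, 2.0], [1.0, 1.0, 10.0])
        shell = profile_to_shell(leaky, 7.0)
        assert shell.d1 == 7.0  # leakage cannot pull d1 inside the nucleus

    def test_no_extranuclear_mass_rejected(self):
        prof = make_profile([-1.0, -0.5], [1.0, 1.0])
        with pytest.raises(ValueError):
            profile_to_shell(prof, 7.0)

    def test_bad_quantiles_rejected(self):
        prof = make_profile([0.5], [1.0])
        with pytest.raises(ValueError):
            profile_to_shell(prof, 7.0, quantiles=(0.9, 0.1))
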