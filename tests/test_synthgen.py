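"""The generator's truth must be exact: analytic region means, determinism,
photon statistics, and the closed-form internalization curve."""

import numpy as np
import pytest

import flarequant as fq
from flarequant.synthgen import PlacementError, pm_fraction_curve

from _oracles import label_components_3d


REGIONS = ("pm_ring", "invaginations", "cytoplasm", "foci")


def test_same_seed_bit_identical():
    specs = fq.random_cell_specs(3, seed=2, n_invaginations=1, n_foci=1)
    a = fq.generate_field(specs, fq.NoiseSpec(seed=11))[0].data
    b = fq.generate_field(specs, fq.NoiseSpec(seed=11))[0].data
    assert np.array_equal(a, b)
    c = fq.generate_field(specs, fq.NoiseSpec(seed=12))[0].data
    assert not np.array_equal(a, c)


def test_noise_free_region_means_are_analytic(single_cell_field):
    stack, _, gt = single_cell_field
    for label in gt.labels:
        for chan in ("reference", "tested"):
            img = stack.channel(chan)
            for region in REGIONS:
                m = gt.region_masks[label][region]
                if m.any():
                    assert img[m].mean() == pytest.approx(
                        gt.expected[label][chan][region], abs=1e-12
                    )


def test_region_masks_disjoint_within_cell(single_cell_field):
    _, mask, gt = single_cell_field
    for label in gt.labels:
        masks = [gt.region_masks[label][r] for r in REGIONS]
        total = np.zeros_like(masks[0], dtype=int)
        for m in masks:
            total += m
        assert total.max() <= 1  # pairwise disjoint
        union = np.logical_or.reduce(masks)
        assert not np.any(union & ~mask.cell(label))


def test_no_pm_enrichment_when_pm_fraction_zero(noiseless):
    spec = fq.CellSpec(center=(50.0, 50.0), pm_fraction=0.0, n_foci=0)
    stack, _, gt = fq.generate_field([spec], noiseless, shape=(100, 100))
    tested = stack.channel("tested")
    ring = gt.region_masks[1]["pm_ring"]
    cyto = gt.region_masks[1]["cytoplasm"]
    assert tested[ring].mean() == pytest.approx(tested[cyto].mean(), abs=1e-12)
    # and with shot noise the two means agree within Poisson error
    noisy, _, _ = fq.generate_field(
        [spec], fq.NoiseSpec(gain=1.0, read_sigma=0.0, background_level=0.0, seed=4),
        shape=(100, 100),
    )
    t = noisy.channel("tested")
    sem = np.sqrt(spec.base_intensity / ring.sum()) + np.sqrt(spec.base_intensity / cyto.sum())
    assert abs(t[ring].mean() - t[cyto].mean()) < 4 * sem


def test_sorting_factor_ratio_of_ratios_exact(single_cell_field):
    stack, _, gt = single_cell_field
    tested, ref = stack.channel("tested"), stack.channel("reference")
    inv = gt.region_masks[1]["invaginations"]
    ring = gt.region_masks[1]["pm_ring"]
    ratio = (tested[inv].mean() / ref[inv].mean()) / (tested[ring].mean() / ref[ring].mean())
    assert ratio == pytest.approx(3.0, rel=1e-12)


def test_poisson_variance_matches_mean():
    # flat cell interior (p = 0) observed at gain 1, no read noise
    spec = fq.CellSpec(center=(80.0, 80.0), radii=(62.0, 60.0), pm_fraction=0.0, n_foci=0)
    noise = fq.NoiseSpec(gain=1.0, read_sigma=0.0, background_level=0.0, seed=9)
    stack, _, gt = fq.generate_field([spec], noise, shape=(160, 160))
    cyto = gt.region_masks[1]["cytoplasm"]
    assert cyto.sum() > 10_000
    vals = stack.channel("tested")[cyto]
    assert vals.var() == pytest.approx(vals.mean(), rel=0.05)


def test_contrast_strictly_increases_with_pm_fraction(noiseless):
    contrasts = []
    for p in (0.0, 0.2, 0.4, 0.6, 0.8):
        spec = fq.CellSpec(center=(50.0, 50.0), pm_fraction=p, n_foci=0)
        _, _, gt = fq.generate_field([spec], noiseless, shape=(100, 100))
        contrasts.append(gt.pm_contrast[1])
    assert np.all(np.diff(contrasts) > 0)


def test_overlapping_placement_rejected():
    specs = [fq.CellSpec(center=(50.0, 50.0)), fq.CellSpec(center=(50.0, 80.0))]
    with pytest.raises(PlacementError):
        fq.generate_field(specs)


def test_border_cell_is_clipped(noiseless):
    spec = fq.CellSpec(center=(0.0, 50.0))
    _, mask, _ = fq.generate_field([spec], noiseless, shape=(100, 100))
    assert mask.cell(1)[0].any() and mask.cell(1).sum() < np.pi * 22 * 20 * 0.8


class TestTimelapse:
    def test_static_limit_identical_frames(self, noiseless):
        spec = fq.CellSpec(center=(50.0, 50.0), n_foci=1)
        kin = fq.KineticsSpec(internalization_rate_per_min=0.0, spike_amplitude=0.0,
                              pm_fraction_end=spec.pm_fraction)
        stack, _, _ = fq.generate_timelapse([spec], kin, noiseless, n_frames=5,
                                            shape=(100, 100))
        for f in range(1, 5):
            assert np.array_equal(stack.data[f], stack.data[0])

    def test_spike_raises_pm_intensity_at_treatment(self, noiseless):
        spec = fq.CellSpec(center=(50.0, 50.0), pm_fraction=0.5, n_foci=0)
        kin = fq.KineticsSpec(t_treat_min=2.0, spike_amplitude=0.3,
                              spike_decay_per_min=0.1,
                              internalization_rate_per_min=5.0, pm_fraction_end=0.5)
        stack, _, gt = fq.generate_timelapse([spec], kin, noiseless, n_frames=5,
                                             shape=(100, 100))
        ring = gt.region_masks[1]["pm_ring"]
        pre = stack.channel("tested", frame=1)[ring].mean()  # t = 1 < t0
        at = stack.channel("tested", frame=2)[ring].mean()  # t = t0
        assert at > pre

    def test_internalization_rate_recovered_from_truth_curve(self):
        kin = fq.KineticsSpec(t_treat_min=5.0, spike_amplitude=0.0,
                              internalization_rate_per_min=0.23, pm_fraction_end=0.15)
        t = np.arange(0.0, 31.0)
        p = pm_fraction_curve(0.7, kin, t)
        after = t >= 5.0
        y = np.log(p[after] - 0.15)
        slope = np.polyfit(t[after] - 5.0, y, 1)[0]
        assert slope == pytest.approx(-0.23, rel=1e-12)

    def test_truth_curve_stored_and_mass_conserving(self, noiseless):
        spec = fq.CellSpec(center=(50.0, 50.0), pm_fraction=0.7, n_foci=2)
        kin = fq.KineticsSpec(t_treat_min=2.0, internalization_rate_per_min=0.5,
                              pm_fraction_end=0.1)
        stack, _, gt = fq.generate_timelapse([spec], kin, noiseless, n_frames=8,
                                             shape=(100, 100))
        assert np.array_equal(gt.pm_fraction_t[1],
                              pm_fraction_curve(0.7, kin, gt.times_min))
        # internalized signal reappears in the foci
        foci = gt.region_masks[1]["foci"]
        first, last = stack.channel("tested", 0), stack.channel("tested", 7)
        assert last[foci].mean() > first[foci].mean()

    def test_frame_interval_validation(self):
        with pytest.raises(ValueError):
            fq.generate_timelapse([fq.CellSpec(center=(50.0, 50.0))],
                                  fq.KineticsSpec(), fq.NoiseSpec(),
                                  n_frames=5, frame_interval_min=0.0)
        with pytest.raises(ValueError):
            fq.generate_timelapse([fq.CellSpec(center=(50.0, 50.0))],
                                  fq.KineticsSpec(), fq.NoiseSpec(), n_frames=1)


class TestDroplets:
    def test_zero_droplets_zero_volume(self, noiseless):
        stack, gt = fq.generate_droplet_stack(0, noise=noiseless)
        assert gt.droplet_volumes_um3 == []
        assert stack.data.max() == 0

    def test_truth_volume_is_voxel_count_times_voxel_volume(self, noiseless):
        stack, gt = fq.generate_droplet_stack(
            1, radii_um=0.3, voxel_size_um=(0.1, 0.1, 0.1), noise=noiseless,
            centers=[(12.0, 48.0, 48.0)],
        )
        painted = int((stack.data > 0).sum())
        assert gt.droplet_volumes_um3[0] == pytest.approx(painted * 0.001)

    def test_separated_spheres_are_two_objects_under_any_connectivity(self, noiseless):
        stack, gt = fq.generate_droplet_stack(
            2, radii_um=0.3, voxel_size_um=(0.1, 0.1, 0.1), noise=noiseless,
            centers=[(8.0, 20.0, 20.0), (8.0, 20.0, 40.0)],
        )
        binary = stack.data > 0
        for conn in (6, 26):
            assert label_components_3d(binary, conn).max() == 2

    def test_droplet_outside_field_rejected(self, noiseless):
        with pytest.raises(ValueError):
            fq.generate_droplet_stack(1, radii_um=0.5, voxel_size_um=(0.1, 0.1, 0.1),
                                      noise=noiseless, centers=[(0.0, 2.0, 2.0)])

    def test_subvoxel_radius_rejected(self, noiseless):
        with pytest.raises(ValueError):
            fq.generate_droplet_stack(1, radii_um=0.05, voxel_size_um=(0.2, 0.1, 0.1),
                                      noise=noiseless)
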