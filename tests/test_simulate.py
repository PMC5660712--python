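"""Forward-model statistics: labeling densities, puncta, noise, barcodes."""

import numpy as np
import pytest
from scipy import stats

from exmtool import optics, simulate as sim
from exmtool.volume import LabelVolume, MembraneMask, extract_membrane


def flat_membrane(n_side: int = 130, voxel: float = 6.0) -> MembraneMask:
    """A single flat membrane patch of n_side^2 voxels (one neuron)."""
    mask = np.zeros((3, n_side, n_side), dtype=bool)
    mask[1] = True
    owner = np.ones((3, n_side, n_side), dtype=np.int64)
    return MembraneMask(mask=mask, owner=owner, voxel_size=voxel)


class TestLabelMembranes:
    def test_zero_density_empty(self, rng):
        f = sim.label_membranes(flat_membrane(16), (0.0, 0.0), rng=rng)
        assert len(f) == 0

    def test_seeded_determinism(self):
        m = flat_membrane(32)
        a = sim.label_membranes(m, rng=np.random.default_rng(5))
        b = sim.label_membranes(m, rng=np.random.default_rng(5))
        assert np.array_equal(a.points, b.points)

    def test_poisson_count_moments(self):
        """Realized counts match density x area (Monte Carlo, 200 seeds)."""
        m = flat_membrane(130)  # 130^2 voxels x (6 nm)^2 = 0.6084 um^2
        area_um2 = 130 * 130 * 36e-6
        density = 4000.0
        counts = [
            len(sim.label_membranes(m, (density, density), rng=np.random.default_rng(s)))
            for s in range(200)
        ]
        expected = density * area_um2
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_jitter_sd_matches_localization_accuracy(self):
        m = flat_membrane(130)
        f = sim.label_membranes(m, (8000.0, 8000.0), jitter_sd=20.0,
                                rng=np.random.default_rng(0))
        # the membrane plane is at z = 9 nm (center of slice 1); jitter is the
        # only source of z scatter
        sd = np.std(f.points[:, 0])
        assert abs(sd - 20.0) < 1.0

    def test_per_neuron_variation_raises_dispersion(self):
        """Per-neuron density draws reproduce dim/bright neuron variability."""
        labels = np.ones((4, 60, 60), dtype=np.uint32)
        for i in range(6):
            labels[:, :, i * 10:(i + 1) * 10] = i + 1
        mask = extract_membrane(LabelVolume(labels, 6.0))
        cvs = {True: [], False: []}
        for per_neuron in (True, False):
            for s in range(30):
                f = sim.label_membranes(mask, (4000.0, 10000.0), per_neuron=per_neuron,
                                        rng=np.random.default_rng(s))
                counts = np.bincount(f.owner, minlength=7)[1:]
                cvs[per_neuron].append(np.std(counts) / np.mean(counts))
        assert np.mean(cvs[True]) > np.mean(cvs[False])


class TestCompartmentLabeling:
    def test_zero_density_and_empty_region(self, rng):
        region = np.ones((10, 10, 10), dtype=bool)
        assert len(sim.label_volume_compartment(region, (0.0, 0.0), 6.0, rng=rng)) == 0
        assert len(sim.label_volume_compartment(~region, (1e4, 1e4), 6.0, rng=rng)) == 0

    def test_poisson_count_moments(self):
        region = np.ones((77, 77, 77), dtype=bool)  # ~0.099 um^3 at 6 nm
        vol_um3 = 77**3 * (6e-3) ** 3
        density = 2000.0
        counts = [
            len(sim.label_volume_compartment(region, (density, density), 6.0,
                                             rng=np.random.default_rng(s)))
            for s in range(200)
        ]
        expected = density * vol_um3
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_points_satisfy_region_predicate(self, rng):
        region = np.zeros((12, 12, 12), dtype=bool)
        region[2:5, 3:9, 1:4] = True
        f = sim.label_volume_compartment(region, (5e4, 5e4), 6.0, rng=rng)
        vox = np.floor(f.points / 6.0).astype(int)
        assert region[vox[:, 0], vox[:, 1], vox[:, 2]].all()


class TestPuncta:
    def test_zero_cluster_sd_gives_delta(self, rng):
        f = sim.FluorophoreField(np.array([[30.0, 30.0, 30.0]]), [1.0], [1], [0.0], [0])
        f = sim.apply_puncta(f, (0.0, 0.0), rng=rng)
        img = sim.rasterize_field(f, (10, 10, 10), 6.0)
        assert img.sum() == pytest.approx(1.0)
        assert (img > 0).sum() <= 8  # trilinear neighborhood of one point

    def test_amplitude_conserved_after_spreading(self, rng):
        # keep all points > 4 sigma_max (192 nm) from the volume faces so no
        # mass is lost to edge truncation
        pts = rng.uniform(200, 280, size=(50, 3))
        f = sim.FluorophoreField(pts, np.ones(50), np.ones(50, int), np.zeros(50), np.zeros(50, int))
        f = sim.apply_puncta(f, (1.0, 48.0), rng=rng)
        img = sim.rasterize_field(f, (80, 80, 80), 6.0)
        assert abs(img.sum() - 50.0) < 50 * 1e-3

    def test_sigma_distribution_uniform(self, rng):
        n = 10_000
        f = sim.FluorophoreField(np.zeros((n, 3)), np.ones(n), np.ones(n, int),
                                 np.zeros(n), np.zeros(n, int))
        f = sim.apply_puncta(f, (1.0, 48.0), rng=rng)
        p = stats.kstest(f.cluster_sigma, stats.uniform(loc=1.0, scale=47.0).cdf).pvalue
        assert p > 0.01


class TestBrainbow:
    def test_pure_mixture_single_channel(self, rng):
        n = 100
        f = sim.FluorophoreField(np.zeros((n, 3)), np.ones(n), np.ones(n, int),
                                 np.zeros(n), np.zeros(n, int))
        out = sim.assign_channels(f, {1: np.array([1.0, 0.0, 0.0])}, rng=rng)
        assert (out.channel == 0).all()

    def test_multinomial_channel_counts(self):
        n = 10_000
        mix = np.array([0.5, 0.3, 0.2])
        f = sim.FluorophoreField(np.zeros((n, 3)), np.ones(n), np.ones(n, int),
                                 np.zeros(n), np.zeros(n, int))
        out = sim.assign_channels(f, {1: mix}, rng=np.random.default_rng(3))
        counts = np.bincount(out.channel, minlength=3)
        p = stats.chisquare(counts, mix * n).pvalue
        assert p > 0.01

    def test_mixtures_on_simplex_and_deterministic(self, small_gt):
        a = sim.assign_brainbow_colors(small_gt, np.random.default_rng(2))
        b = sim.assign_brainbow_colors(small_gt, np.random.default_rng(2))
        assert set(a) == set(np.unique(small_gt.labels[small_gt.labels > 0]))
        for lab in a:
            assert a[lab].sum() == pytest.approx(1.0)
            assert np.array_equal(a[lab], b[lab])


class TestBarcodes:
    def test_zero_density_empty(self, small_gt, rng):
        assert len(sim.place_barcodes(small_gt, 0.0, rng)) == 0

    def test_identity_lookup_oracle(self, small_gt, rng):
        bc = sim.place_barcodes(small_gt, 200.0, rng)
        vox = np.minimum(
            (bc.points / small_gt.voxel_size).astype(int),
            np.array(small_gt.shape) - 1,
        )
        assert np.array_equal(bc.identity, small_gt.labels[vox[:, 0], vox[:, 1], vox[:, 2]])
        assert (bc.identity > 0).all()

    def test_count_moments(self):
        labels = np.ones((100, 100, 100), dtype=np.uint32)  # 0.216 um^3
        vol = LabelVolume(labels, voxel_size=6.0)
        vol_um3 = (0.6**3)
        counts = [
            len(sim.place_barcodes(vol, 30.0, np.random.default_rng(s)))
            for s in range(100)
        ]
        expected = 30.0 * vol_um3
        se = np.sqrt(expected / 100)
        assert abs(np.mean(counts) - expected) < 3 * se


@pytest.fixture(scope="module")
def tiny_psf():
    psf = optics.render_confocal_psf(voxel_pitch=(120.0, 120.0, 120.0))
    return optics.scale_psf(psf, 20.0)


class TestRenderStack:
    def test_pure_read_noise_floor(self, tiny_psf, rng):
        """With no fluorophores the stack is zero-clipped read noise.

        Oracle: closed-form moments of a normal censored at zero
        (mean = sd/sqrt(2 pi), E[X^2] = sd^2/2).
        """
        sd = 2.0
        stack = sim.render_stack(
            sim.FluorophoreField.empty(), tiny_psf, (40, 32, 32),
            snr_poisson_range=None, snr_read_range=(50.0, 100.0),
            read_sd=sd, rng=rng,
        )
        x = stack.data
        assert abs(x.mean() - sd / np.sqrt(2 * np.pi)) < 0.1
        assert abs((x**2).mean() - sd**2 / 2) < 0.2

    def test_impulse_response_matches_psf(self, tiny_psf):
        """A single on-grid punctum renders as the sampled PSF."""
        shape = (40, 33, 33)
        # focal planes at z voxels 10 and 30; center the punctum on one
        pt = np.array([[10 * 6.0 + 3.0, 16 * 6.0 + 3.0, 16 * 6.0 + 3.0]])
        f = sim.FluorophoreField(pt, [1.0], [1], [0.0], [0])
        stack = sim.render_stack(f, tiny_psf, shape, z_step=120.0,
                                 snr_poisson_range=None, snr_read_range=None)
        img = stack.data
        kern = tiny_psf.intensity
        kc = tuple(s // 2 for s in kern.shape)
        plane = img[0]  # z plane 0 is the focal plane containing the punctum
        ratio = plane[16, 16] / kern[kc]
        # compare the lateral neighborhood where the PSF is non-negligible
        for dy in range(-3, 4):
            for dx in range(-3, 4):
                expected = kern[kc[0], kc[1] + dy, kc[2] + dx] * ratio
                assert plane[16 + dy, 16 + dx] == pytest.approx(expected, rel=0.05, abs=1e-6 * ratio)

    def test_poisson_variance_equals_mean(self, tiny_psf):
        """Across repeated renders, bright-pixel variance tracks the mean."""
        shape = (20, 24, 24)
        rng = np.random.default_rng(0)
        pts = rng.uniform(30, 114, size=(40, 3))
        f = sim.FluorophoreField(pts, np.ones(40), np.ones(40, int), np.zeros(40), np.zeros(40, int))
        stacks = [
            sim.render_stack(f, tiny_psf, shape, snr_poisson_range=(10.0, 10.0),
                             snr_read_range=None, rng=np.random.default_rng(1000 + s))
            for s in range(100)
        ]
        data = np.stack([s.data for s in stacks])
        mean = data.mean(axis=0)
        var = data.var(axis=0)
        bright = mean > 0.5 * mean.max()
        ratio = var[bright].sum() / mean[bright].sum()
        assert abs(ratio - 1.0) < 0.1

    def test_linearity_before_noise(self, tiny_psf, rng):
        shape = (20, 24, 24)
        pts = rng.uniform(30, 114, size=(30, 3))
        f1 = sim.FluorophoreField(pts[:15], np.ones(15), np.ones(15, int), np.zeros(15), np.zeros(15, int))
        f2 = sim.FluorophoreField(pts[15:], np.ones(15), np.ones(15, int), np.zeros(15), np.zeros(15, int))
        kw = dict(snr_poisson_range=None, snr_read_range=None)
        a = sim.render_stack(f1, tiny_psf, shape, **kw).data
        b = sim.render_stack(f2, tiny_psf, shape, **kw).data
        both = sim.render_stack(sim.FluorophoreField.concatenate([f1, f2]), tiny_psf, shape, **kw).data
        assert np.allclose(a + b, both, rtol=1e-6, atol=1e-9)

    def test_realized_snrs_within_ranges(self, tiny_psf, rng):
        shape = (20, 24, 24)
        pts = rng.uniform(30, 114, size=(30, 3))
        f = sim.FluorophoreField(pts, np.ones(30), np.ones(30, int), np.zeros(30), np.zeros(30, int))
        stack = sim.render_stack(f, tiny_psf, shape, rng=rng)
        assert 7.0 <= stack.snr_poisson <= 12.0
        assert 50.0 <= stack.snr_read <= 100.0
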