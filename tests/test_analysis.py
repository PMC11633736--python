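"""Unmixing, correlation specificity, ratiometric imaging, droplets, stats."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import inspiresim as ins
from inspiresim.analysis import ProfileFitError


class TestPowerNormalize:
    def test_identity_and_scaling(self):
        img = np.arange(6.0).reshape(2, 3)
        np.testing.assert_array_equal(ins.power_normalize(img, 1.0), img)
        np.testing.assert_array_equal(ins.power_normalize(img, 2.0), img / 2)

    def test_roundtrip_through_power_curve(self):
        # a wavenumber-dependent power curve applied then divided out
        nu = np.linspace(1000, 2000, 11)
        curve = 3.0 + 2.0 * np.sin(nu / 200.0)
        flat = np.ones((4, 4))
        for p in curve:
            np.testing.assert_allclose(ins.power_normalize(flat * p, p), flat)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            ins.power_normalize(np.ones((2, 2)), 0.0)


class TestUnmix:
    def test_pure_pixel_recovers_unit_abundance(self):
        refs = ins.UnmixReferences(
            np.array([[1.0, 0.2], [0.1, 1.0], [0.5, 0.5]]),
            channels=("c0", "c1", "c2"), species=("a", "b"),
        )
        img = refs.matrix[:, 0].reshape(3, 1, 1)
        ab, res = ins.unmix(img, refs)
        assert ab[0, 0, 0] == pytest.approx(1.0)
        assert ab[1, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert res[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_identity_references_clip_channels(self):
        refs = ins.UnmixReferences(np.eye(2), ("c0", "c1"), ("a", "b"))
        imgs = np.array([[[0.3]], [[-0.2]]])
        ab, _ = ins.unmix(imgs, refs)
        assert ab[0, 0, 0] == pytest.approx(0.3)
        assert ab[1, 0, 0] == 0.0  # non-negativity clips the negative channel

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            ins.UnmixReferences(np.ones((3, 2)), ("a", "b", "c"), ("x", "y"))

    def test_error_grows_monotonically_with_noise(self):
        rng = np.random.default_rng(4)
        refs = ins.UnmixReferences(
            np.array([[1.0, 0.1], [0.2, 1.0], [0.4, 0.6]]),
            ("c0", "c1", "c2"), ("a", "b"),
        )
        truth = rng.random((2, 12, 12))
        clean = np.einsum("cs,syx->cyx", refs.matrix, truth)
        errs = []
        for sigma in (0.0, 0.05, 0.25):
            noisy = clean + sigma * rng.standard_normal(clean.shape)
            ab, _ = ins.unmix(noisy, refs)
            errs.append(np.abs(ab - truth).mean())
        assert errs[0] < 1e-10
        assert errs[0] <= errs[1] <= errs[2]


class TestTernaryMixtureImaging:
    """End-to-end four-channel unmixing of the ternary powder phantom."""

    SPECIES = ["palmitic_acid", "diphenylbutadiyne", "triphenylphosphine"]
    CHANNELS = [(1477.0, "ir"), (1593.0, "raman"), (1700.0, "ir"),
                (2216.0, "raman")]

    @pytest.fixture(scope="class")
    def imaged(self, library, psfs, gains):
        psf_r, psf_i = psfs
        train = ins.PulseTrainConfig(dwell=20e-6)
        thermal = ins.ThermalConfig()
        cmap = ins.make_mixture_map(self.SPECIES, 60, 3.0, seed=1,
                                    pixel_size=0.4)
        r_ir, r_raman = ins.channel_unit_response(train, thermal)
        k_srl, k_pt = gains
        stack = []
        with np.errstate(all="ignore"):
            for nu, mod in self.CHANNELS:
                exc = ins.ExcitationConfig(
                    ir_wavenumber=nu if mod == "ir" else 1750.0,
                    raman_wavenumber=nu if mod == "raman" else 2850.0,
                )
                pair = ins.scan_image(cmap, library, psf_r, psf_i, exc, gains,
                                      train=train, thermal=thermal)
                if mod == "ir":
                    stack.append(pair.ir_image / (r_ir * k_pt * exc.p_ir))
                else:
                    stack.append(
                        pair.raman_image
                        / (r_raman * k_srl * exc.p_pump * exc.p_stokes)
                    )
        return cmap, np.array(stack)

    def test_abundance_recovery_noiseless(self, imaged, library):
        cmap, stack = imaged
        refs = ins.references_from_library(library, self.CHANNELS, self.SPECIES)
        ab, _ = ins.unmix(stack, refs)
        for i in range(len(self.SPECIES)):
            assert np.abs(ab[i] - cmap.grid[i]).mean() < 0.02

    def test_unmixed_maps_less_correlated_than_single_modality(
        self, imaged, library
    ):
        cmap, stack = imaged
        refs = ins.references_from_library(library, self.CHANNELS, self.SPECIES)
        ab, _ = ins.unmix(stack, refs)
        pairwise = [
            ins.pcc(ab[i], ab[j])
            for i in range(3) for j in range(i + 1, 3)
        ]
        # shared-band single-modality pairs: both IR channels, both Raman
        pcc_ir = ins.pcc(stack[0], stack[2])
        pcc_raman = ins.pcc(stack[1], stack[3])
        assert max(pairwise) < pcc_ir
        assert max(pairwise) < pcc_raman


class TestPcc:
    def test_identical_and_inverted(self):
        a = np.arange(9.0).reshape(3, 3)
        assert ins.pcc(a, a) == pytest.approx(1.0)
        assert ins.pcc(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_toy(self):
        a = np.array([[0.0, 1.0], [2.0, 3.0]])
        b = np.array([[1.0, 0.0], [3.0, 2.0]])
        assert ins.pcc(a, b) == pytest.approx(0.6)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ins.pcc(np.ones((2, 2)), np.arange(4.0).reshape(2, 2))


class TestRatiometric:
    def test_equal_images_give_unity(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = ins.ratiometric(a, a)
        np.testing.assert_allclose(out, 1.0)

    def test_bounds(self):
        a = np.array([[0.0, 10.0]])
        b = np.array([[10.0, 0.0]])
        out = ins.ratiometric(a, b)
        assert out[0, 0] == pytest.approx(0.5)
        assert out[0, 1] == pytest.approx(2.0)

    def test_hand_computed_recipe(self):
        # background 1; a - 1 = [0, 2, 5] -> /5 = [0, .4, 1];
        # b - 1 = [3, 0, 1.5] -> /3 = [1, 0, .5]; then (x+1)/(y+1)
        a = np.array([[1.0, 3.0, 6.0]])
        b = np.array([[4.0, 1.0, 2.5]])
        out = ins.ratiometric(a, b, background=1.0)
        np.testing.assert_allclose(out[0], [1.0 / 2.0, 1.4 / 1.0, 2.0 / 1.5])

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(0)
        a = rng.random((5, 5))
        b = rng.random((5, 5))
        base = ins.ratiometric(a, b)
        scaled = ins.ratiometric(7.0 * a, 7.0 * b)
        np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_all_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            ins.ratiometric(np.full((2, 2), 3.0), np.ones((2, 2)),
                            background=3.0)


# ---------------------------------------------------------------------------
# Independent droplet-extraction oracle: BFS flood fill + Crofton perimeter
# ---------------------------------------------------------------------------


def _flood_fill_components(binary):
    """8-connected components by breadth-first search (no scipy/skimage)."""
    ny, nx = binary.shape
    labels = np.zeros((ny, nx), dtype=int)
    current = 0
    for sy in range(ny):
        for sx in range(nx):
            if binary[sy, sx] and labels[sy, sx] == 0:
                current += 1
                queue = [(sy, sx)]
                labels[sy, sx] = current
                while queue:
                    y, x = queue.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < ny and 0 <= xx < nx
                                    and binary[yy, xx]
                                    and labels[yy, xx] == 0):
                                labels[yy, xx] = current
                                queue.append((yy, xx))
    return labels, current


def _boundary_perimeter(mask):
    """Polygonal boundary length: edge count with a corner correction.

    Counts exposed pixel edges, then shortens each convex corner by
    (2 - sqrt(2)) to approximate the enclosing polygon (classic
    8-neighbourhood perimeter estimate; independent of any library
    implementation).
    """
    padded = np.pad(mask.astype(int), 1)
    edges = 0
    edges += int(np.sum(padded[1:, :] != padded[:-1, :]))
    edges += int(np.sum(padded[:, 1:] != padded[:, :-1]))
    # convex corners: 2x2 blocks with exactly one foreground pixel
    blocks = (padded[:-1, :-1] + padded[:-1, 1:] + padded[1:, :-1]
              + padded[1:, 1:])
    corners = int(np.sum(blocks == 1)) + int(np.sum(blocks == 3))
    return float(edges) - corners * (2.0 - math.sqrt(2.0))


def brute_force_droplets(image, pixel_size, min_diameter, threshold):
    """Reference extraction: components, measurements and an independent
    circularity estimate (not filtered)."""
    binary = image > threshold
    labels, n = _flood_fill_components(binary)
    rows = []
    for lab in range(1, n + 1):
        mask = labels == lab
        area = mask.sum() * pixel_size**2
        eq_diam = 2.0 * math.sqrt(area / math.pi)
        if eq_diam < min_diameter:
            continue
        perim = _boundary_perimeter(mask) * pixel_size
        circ = 1.05 if perim == 0 else min(4 * math.pi * area / perim**2, 1.05)
        ys, xs = np.nonzero(mask)
        rows.append((
            (xs.mean() + 0.5) * pixel_size,
            (ys.mean() + 0.5) * pixel_size,
            area,
            eq_diam,
            image[mask].mean(),
            circ,
        ))
    return sorted(rows)


class TestExtractDroplets:
    def test_empty_image(self):
        table = ins.extract_droplets(np.zeros((20, 20)), 0.1)
        assert table.empty

    def test_disks_kept_elongated_rejected(self):
        img = np.zeros((120, 120))
        yy, xx = np.mgrid[:120, :120]
        for cy, cx in ((25, 25), (25, 85), (85, 25)):
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 8**2] = 1.0
        img[(((yy - 85) / 20.0) ** 2 + ((xx - 85) / 5.0) ** 2) <= 1.0] = 1.0
        table = ins.extract_droplets(img, 0.1, min_diameter=0.4)
        assert len(table) == 3
        assert (table["circularity"] >= 0.8).all()

    def test_ground_truth_recall_and_shape_filtering(self):
        cmap, truth = ins.make_droplet_field(50, circular_fraction=0.8, seed=3)
        table = ins.extract_droplets(cmap.grid[0], cmap.pixel_size,
                                     min_diameter=0.4)
        found = table[["centroid_x_um", "centroid_y_um"]].to_numpy()
        circ = truth[truth["shape"] == "circular"][["x_um", "y_um"]].to_numpy()
        elong = truth[truth["shape"] == "elongated"][["x_um", "y_um"]].to_numpy()

        def n_matched(gt):
            if not len(found):
                return 0
            d = np.sqrt(((gt[:, None, :] - found[None, :, :]) ** 2).sum(-1))
            return int((d.min(axis=1) < 0.5).sum())

        assert n_matched(circ) >= 0.9 * len(circ)
        assert n_matched(elong) == 0

    def test_matches_brute_force_oracle(self):
        # disk-only images (well inside the circularity band): both
        # pipelines must find identical components with identical
        # measurements, and both circularity estimates must retain them
        rng = np.random.default_rng(12)
        for _trial in range(4):
            img = np.zeros((48, 48))
            yy, xx = np.mgrid[:48, :48]
            placed = []
            while len(placed) < 3:
                cy, cx = rng.uniform(10, 38, 2)
                r = rng.uniform(3.0, 6.0)
                if all(np.hypot(cy - py, cx - px) > r + pr + 2
                       for py, px, pr in placed):
                    placed.append((cy, cx, r))
                    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = (
                        rng.uniform(0.5, 2)
                    )
            got = ins.extract_droplets(
                img, 0.1, min_diameter=0.0, interp_pixel=0.1,
                background=0.0, threshold=0.25,
            )
            want = brute_force_droplets(img, 0.1, 0.0, 0.25)
            got_rows = sorted(map(tuple, got.to_numpy()))
            assert len(got_rows) == len(want)
            for g, w in zip(got_rows, want):
                # centroid, area, diameter, intensity: exact agreement
                np.testing.assert_allclose(g[:5], w[:5], rtol=1e-12)
                assert g[5] >= 0.8 and w[5] >= 0.8  # same keep decision

    def test_elongated_rejected_by_both_pipelines(self):
        img = np.zeros((48, 48))
        yy, xx = np.mgrid[:48, :48]
        img[(((yy - 24) / 16.0) ** 2 + ((xx - 24) / 3.5) ** 2) <= 1.0] = 1.0
        got = ins.extract_droplets(img, 0.1, min_diameter=0.0,
                                   interp_pixel=0.1, background=0.0,
                                   threshold=0.5)
        want = brute_force_droplets(img, 0.1, 0.0, 0.5)
        assert got.empty
        assert len(want) == 1 and want[0][5] < 0.8


class TestDropletStats:
    def test_identical_samples(self):
        t = pd.DataFrame({"equivalent_diameter_um": [1.0, 2.0, 3.0]})
        out = ins.droplet_stats(t, t.copy())
        assert out["t_statistic"] == pytest.approx(0.0)
        assert out["t_pvalue"] == pytest.approx(1.0)
        assert out["variance_pvalue"] == pytest.approx(1.0)
        assert out["t_stars"] == "ns"

    def test_textbook_pooled_t(self):
        a = pd.DataFrame({"equivalent_diameter_um": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"equivalent_diameter_um": [4.0, 5.0, 6.0]})
        out = ins.droplet_stats(a, b)
        assert out["t_statistic"] == pytest.approx(-3.674, abs=1e-3)
        assert out["t_pvalue"] == pytest.approx(0.0213, abs=2e-4)
        assert out["t_stars"] == "*"

    def test_missing_column_rejected(self):
        t = pd.DataFrame({"area_um2": [1.0, 2.0]})
        with pytest.raises(KeyError):
            ins.droplet_stats(t, t, column="equivalent_diameter_um")

    def test_rejection_rate_matches_closed_form_power(self):
        # shift of 1 sd, n = 100 per group: compare the empirical rejection
        # rate at alpha = 0.05 with noncentral-t power
        n, reps, delta = 100, 400, 1.0
        rng = np.random.default_rng(17)
        a = rng.standard_normal((reps, n))
        b = rng.standard_normal((reps, n)) + delta
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        rate = float(np.mean(p < 0.05))
        df = 2 * n - 2
        ncp = delta * math.sqrt(n / 2.0)
        tcrit = stats.t.ppf(0.975, df)
        power = (1.0 - stats.nct.cdf(tcrit, df, ncp)
                 + stats.nct.cdf(-tcrit, df, ncp))
        ci = 3.0 * math.sqrt(power * (1 - power) / reps) + 1.0 / reps
        assert abs(rate - power) <= max(ci, 0.01)


class TestResolution:
    def test_gaussian_profile_self_consistency(self):
        x = (np.arange(200) - 100) * 25.0  # nm
        img = np.exp(-0.5 * (x / (500.0 / 2.3548200450309493)) ** 2)[None, :]
        img = np.repeat(img, 5, axis=0)
        fwhm = ins.fit_profile_fwhm(img, 0.025, axis="x")
        assert fwhm == pytest.approx(500.0, abs=5.0)

    def test_sphere_projection_blur_vs_halfmax_oracle(self, library, psfs,
                                                      gains):
        from scipy.ndimage import gaussian_filter

        cmap = ins.make_bead_map(0.5, 0.01, 2.0)
        sigma_px = 398.0 / 2.3548200450309493 / 10.0
        img = gaussian_filter(cmap.grid[0], sigma_px, mode="reflect")
        fit = ins.fit_profile_fwhm(img, 0.01, axis="x")
        prof = img[img.shape[0] // 2]
        from test_optics import measured_fwhm

        half_max = measured_fwhm(prof, 10.0)
        assert fit == pytest.approx(half_max, rel=0.03)

    def test_flat_image_rejected(self):
        with pytest.raises(ProfileFitError):
            ins.fit_profile_fwhm(np.ones((10, 10)), 0.1)

    def test_deconvolution_algebra(self):
        assert ins.deconvolve_bead(450.0, 0.0) == pytest.approx(450.0)
        assert ins.deconvolve_bead(500.0, 500.0) == 0.0
        meas = math.sqrt(398.0**2 + 500.0**2)
        assert ins.deconvolve_bead(meas, 500.0) == pytest.approx(398.0)
        with pytest.warns(UserWarning):
            assert ins.deconvolve_bead(300.0, 500.0) == 0.0

    def test_scan_fit_deconvolve_round_trip(self, library, psfs, gains):
        # image a bead, fit the profile, remove the bead size in quadrature:
        # recovers each channel's configured PSF within 5%
        psf_r, psf_i = psfs
        bead = ins.make_bead_map(0.5, 0.025, 2.0, profile="gaussian")
        exc = ins.ExcitationConfig(ir_wavenumber=1730.0, raman_wavenumber=2957.0)
        pair = ins.scan_image(bead, library, psf_r, psf_i, exc, gains,
                              train=ins.PulseTrainConfig(dwell=10e-6))
        for img, target in ((pair.raman_image, 398.0), (pair.ir_image, 561.0)):
            meas = ins.fit_profile_fwhm(img, 0.025)
            assert ins.deconvolve_bead(meas, 500.0) == pytest.approx(
                target, rel=0.05
            )
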