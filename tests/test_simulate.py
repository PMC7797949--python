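"""Ground-truth generator and forward imaging model."""

import numpy as np
import pytest

from evcoloc import (
    AcquisitionParams,
    ChannelTransform,
    PopulationSpec,
    generate_population,
    render_bead_fields,
    render_field,
)
from evcoloc.classes import all_classes

from conftest import CHANNELS, HEK_FRACTIONS, make_params


class TestGeneratePopulation:
    def test_degenerate_spec_all_triple(self, default_params):
        spec = PopulationSpec(
            channels=CHANNELS,
            class_fractions={"CD9∙CD63∙CD81": 1.0},
            n_vesicles=50,
        )
        vesicles = generate_population(spec, default_params, seed=0)
        assert len(vesicles) == 50
        assert all(v.labels == frozenset(CHANNELS) for v in vesicles)

    def test_n_zero_gives_empty_list(self, default_params):
        spec = PopulationSpec(
            channels=CHANNELS, class_fractions={"CD9": 1.0}, n_vesicles=0
        )
        assert generate_population(spec, default_params, seed=0) == []

    def test_class_counts_match_independent_multinomial_sampler(self, default_params):
        """Class draws must agree exactly with numpy's multinomial under the
        same seed policy, and lie within 3 multinomial SDs of expectation."""
        spec = PopulationSpec(
            channels=CHANNELS, class_fractions=HEK_FRACTIONS, n_vesicles=10_000
        )
        vesicles = generate_population(spec, default_params, seed=42)
        names = [c for c in all_classes(CHANNELS) if HEK_FRACTIONS.get(c, 0) > 0]
        probs = np.array([HEK_FRACTIONS[c] for c in names])
        counts = {c: 0 for c in names}
        from evcoloc.classes import class_name

        for v in vesicles:
            counts[class_name(v.labels, CHANNELS)] += 1
        observed = np.array([counts[c] for c in names])

        oracle = np.random.default_rng(42).multinomial(10_000, probs / probs.sum())
        assert np.array_equal(observed, oracle)
        expected = 10_000 * probs
        sds = np.sqrt(10_000 * probs * (1 - probs))
        assert np.all(np.abs(observed - expected) <= 3 * sds)

    def test_multinomial_chisquare_at_large_n(self, default_params):
        from scipy.stats import chisquare

        spec = PopulationSpec(
            channels=CHANNELS, class_fractions=HEK_FRACTIONS, n_vesicles=100_000
        )
        vesicles = generate_population(spec, default_params, seed=7)
        from evcoloc.classes import class_name

        names = list(HEK_FRACTIONS)
        counts = {c: 0 for c in names}
        for v in vesicles:
            counts[class_name(v.labels, CHANNELS)] += 1
        obs = [counts[c] for c in names]
        exp = [100_000 * HEK_FRACTIONS[c] for c in names]
        assert chisquare(obs, exp).pvalue > 0.01

    def test_positions_respect_edge_margin(self, default_params):
        spec = PopulationSpec(
            channels=CHANNELS, class_fractions={"CD9": 1.0}, n_vesicles=500
        )
        vesicles = generate_population(spec, default_params, seed=3)
        margin = 5 * default_params.pixel_size_nm
        w, h = default_params.field_bounds_nm()
        for v in vesicles:
            assert margin <= v.x_nm <= w - margin
            assert margin <= v.y_nm <= h - margin

    @pytest.mark.parametrize(
        "fractions",
        [
            {"CD9": 0.5, "CD63": 0.4},  # does not sum to 1
            {"CD9": 0.5, "CD4": 0.5},  # unknown channel
            {"CD9": 1.5, "CD63": -0.5},  # negative fraction
        ],
    )
    def test_invalid_specs_rejected(self, fractions):
        with pytest.raises(ValueError):
            PopulationSpec(channels=CHANNELS, class_fractions=fractions, n_vesicles=10)

    def test_labeling_efficiency_thins_emissions(self, default_params):
        spec = PopulationSpec(
            channels=CHANNELS,
            class_fractions={"CD9∙CD63∙CD81": 1.0},
            n_vesicles=4000,
            labeling_efficiency={"CD9": 1.0, "CD63": 0.5, "CD81": 0.9},
        )
        vesicles = generate_population(spec, default_params, seed=11)
        emitted = {c: sum(c in v.emits for v in vesicles) for c in CHANNELS}
        assert emitted["CD9"] == 4000
        assert abs(emitted["CD63"] / 4000 - 0.5) < 3 * np.sqrt(0.25 / 4000)
        assert abs(emitted["CD81"] / 4000 - 0.9) < 3 * np.sqrt(0.09 / 4000)


class TestRenderField:
    def test_empty_field_no_noise_is_flat_background(self, default_params):
        img = render_field([], default_params, "CD9", seed=0, noise=False)
        assert img.shape == default_params.field_shape
        assert np.all(img == default_params.background_level)

    def test_photon_conservation_single_vesicle(self):
        """Noiseless image integral = brightness x photon_scale + background."""
        params = make_params(background_level=50.0, photon_scale=2.0)
        spec = PopulationSpec(
            channels=CHANNELS,
            class_fractions={"CD9": 1.0},
            n_vesicles=1,
            brightness_mean=3000.0,
            brightness_cv=0.0,
        )
        v = generate_population(spec, params, seed=5)
        img = render_field(v, params, "CD9", seed=0, noise=False)
        excess = img.sum() - 50.0 * img.size
        assert excess == pytest.approx(3000.0 * 2.0, rel=0.01)
        # argmax pixel contains the true position
        i, j = np.unravel_index(np.argmax(img), img.shape)
        assert int(v[0].x_nm / 100) == j
        assert int(v[0].y_nm / 100) == i

    def test_photon_conservation_many_spots(self, default_params, hek_spec):
        vesicles = generate_population(hek_spec, default_params, seed=8)
        img = render_field(vesicles, default_params, "CD63", seed=0, noise=False)
        n = sum("CD63" in v.emits for v in vesicles)
        total_brightness = sum(
            v.brightness["CD63"] for v in vesicles if "CD63" in v.emits
        )
        excess = img.sum() - default_params.background_level * img.size
        assert excess == pytest.approx(total_brightness, rel=1e-4)
        assert n > 0

    def test_seed_determinism(self, default_params, hek_spec):
        v1 = generate_population(hek_spec, default_params, seed=9)
        v2 = generate_population(hek_spec, default_params, seed=9)
        assert [(a.x_nm, a.y_nm, a.labels) for a in v1] == [
            (b.x_nm, b.y_nm, b.labels) for b in v2
        ]
        img1 = render_field(v1, default_params, "CD9", seed=13)
        img2 = render_field(v2, default_params, "CD9", seed=13)
        assert np.array_equal(img1, img2)

    def test_undeclared_channel_rejected(self, default_params):
        with pytest.raises(ValueError):
            render_field([], default_params, "GFP", seed=0)

    def test_out_of_field_vesicle_clipped_and_flagged(self):
        # a large shift pushes the vesicle outside the rendered channel frame
        params = AcquisitionParams(
            field_shape=(64, 64),
            channel_transforms={
                "CD9": ChannelTransform.identity(),
                "CD63": ChannelTransform.translation(100.0, 0.0),
            },
        )
        spec = PopulationSpec(
            channels=("CD9", "CD63"),
            class_fractions={"CD9∙CD63": 1.0},
            n_vesicles=5,
        )
        vesicles = generate_population(spec, params, seed=2)
        render_field(vesicles, params, "CD63", seed=0, noise=False)
        assert all(v.clipped for v in vesicles)


class TestRenderBeadFields:
    def test_identity_transforms_give_coincident_maxima(self, default_params):
        images, _ = render_bead_fields(5, default_params, seed=1, noise=False)
        ref = images["CD9"]
        for c in ("CD63", "CD81"):
            assert np.array_equal(
                np.argwhere(ref > ref.mean() + 50), np.argwhere(images[c] > ref.mean() + 50)
            )

    def test_known_translation_recovered_by_centroiding(self):
        params = make_params(shifts={"CD63": (2.5, -1.25)})
        images, pos = render_bead_fields(6, params, seed=4, noise=False)
        from scipy import ndimage

        def centroids(img):
            mask = img > params.background_level + 100
            lab, n = ndimage.label(mask)
            return np.array(ndimage.center_of_mass(img - params.background_level, lab, range(1, n + 1)))

        c_ref = centroids(images["CD9"])
        c_mov = centroids(images["CD63"])
        assert len(c_ref) == len(c_mov) == 6
        # transform maps raw -> ref, so the moving channel renders each bead
        # at ref - shift; center_of_mass returns (row, col) = (y, x)
        expected = c_ref + np.array([1.25, -2.5])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(c_mov).query(expected)
        # plain masked centroiding carries ~0.1 px truncation bias
        assert np.all(d < 0.15)

    def test_fewer_than_three_beads_rejected(self, default_params):
        with pytest.raises(ValueError):
            render_bead_fields(2, default_params, seed=0)
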