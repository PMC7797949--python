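"""Population profiles, group statistics, clustering and embedding."""

import numpy as np
import pytest

from evcoloc import (
    PopulationProfile,
    build_profile,
    compare_groups,
    distance_cluster,
    embed_tsne,
    linear_correlation,
    match_channels,
    perplexity_sweep,
    venn_counts,
)

from conftest import CHANNELS, make_spot


def records_from(points_by_channel):
    return match_channels(
        {
            c: [make_spot(x, y, channel=c) for x, y in pts]
            for c, pts in points_by_channel.items()
        }
    )


def profile_from_counts(counts: dict, sample_id="s", channels=CHANNELS):
    """Build a profile whose single field holds the given class counts."""
    pts = {c: [] for c in channels}
    records = []
    x = 10.0
    for cls, n in counts.items():
        members = cls.split("∙")
        for _ in range(n):
            for c in members:
                pts[c].append((x, 10.0))
            x += 10.0
    return build_profile({"f0": records_from(pts)}, sample_id, channels)


class TestBuildProfile:
    def test_single_field_fraction_arithmetic(self):
        prof = profile_from_counts({"CD63": 2, "CD9∙CD63∙CD81": 1})
        assert prof.class_fractions["CD63"] == pytest.approx(2 / 3)
        assert prof.class_fractions["CD9∙CD63∙CD81"] == pytest.approx(1 / 3)
        assert prof.class_fractions["CD9"] == 0.0
        assert sum(prof.class_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_identical_fields_have_zero_sd(self):
        recs = records_from({"CD9": [(10, 10), (30, 30)]})
        prof = build_profile({"f0": recs, "f1": recs}, "s", CHANNELS)
        assert all(sd == 0.0 for sd in prof.class_fraction_sd.values())

    def test_empty_field_excluded_with_warning(self):
        recs = records_from({"CD9": [(10, 10)]})
        with pytest.warns(UserWarning):
            prof = build_profile({"f0": recs, "f1": []}, "s", CHANNELS)
        assert len(prof.per_field_class_counts) == 1

    def test_fractions_normalized_across_fields(self, rng):
        fields = {}
        for f in range(5):
            pts = {
                c: [tuple(p) for p in rng.uniform(0, 400, (int(rng.integers(5, 15)), 2))]
                for c in CHANNELS
            }
            fields[f"f{f}"] = records_from(pts)
        prof = build_profile(fields, "s", CHANNELS)
        assert sum(prof.class_fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert prof.total_records == sum(
            sum(c.values()) for c in prof.per_field_class_counts.values()
        )


class TestVennCounts:
    def test_single_class_only(self):
        prof = profile_from_counts({"CD9": 7})
        v = venn_counts(prof)
        assert v["CD9"] == 7
        assert v["CD9∙CD81"] == 0
        assert v["CD9∙CD63∙CD81"] == 0

    def test_marker_totals_and_overlaps_by_hand_summation(self):
        counts = {
            "CD9∙CD81": 34, "CD63": 34, "CD9∙CD63∙CD81": 11,
            "CD9": 9, "CD81": 8, "CD9∙CD63": 2, "CD63∙CD81": 2,
        }
        v = venn_counts(profile_from_counts(counts))
        assert v["CD9"] == 56
        assert v["CD81"] == 55
        assert v["CD63"] == 49
        assert v["CD9∙CD81"] == 45

    def test_nested_hierarchy_structure(self):
        """If every AV+ record is DiI+ and every DiI+ is CTB+, the overlap
        counts collapse onto the totals (AV subset of DiI subset of CTB)."""
        channels = ("CTB", "DiI", "AV")
        counts = {"CTB": 60, "CTB∙DiI": 29, "CTB∙DiI∙AV": 5}
        prof = profile_from_counts(counts, channels=channels)
        v = venn_counts(prof)
        assert v["DiI∙AV"] == v["AV"]  # AV ⊂ DiI
        assert v["CTB∙DiI"] == v["DiI"]  # DiI ⊂ CTB


class TestCompareGroups:
    def test_identical_groups_degenerate(self):
        r = compare_groups([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert r.t == 0.0
        assert r.p == 1.0

    def test_extreme_separation_highly_significant(self):
        r = compare_groups([0.1, 0.101, 0.099], [0.9, 0.899, 0.901])
        assert r.p < 0.01
        assert r.significant_01

    def test_matches_pooled_variance_closed_form(self):
        """Equal-variance two-sample t on a fixed worked dataset agrees
        with the textbook pooled-variance formula to 4 decimals."""
        a = [0.12, 0.15, 0.18, 0.10, 0.14]
        b = [0.22, 0.19, 0.25, 0.21, 0.24]
        r = compare_groups(a, b)
        assert round(r.t, 4) == round(-4.865989, 4)
        assert r.p == pytest.approx(0.0012462949, abs=1e-8)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([0.1], [0.2, 0.3])


class TestLinearCorrelation:
    def test_perfect_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = linear_correlation(x, [2 * v for v in x])
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_r_squared_mean(self, rng):
        """Independent x, y at n=11: E[R^2] = 1/(n-1) = 0.1."""
        r2 = [
            linear_correlation(rng.normal(size=11), rng.normal(size=11)).r_squared
            for _ in range(2000)
        ]
        assert np.mean(r2) == pytest.approx(0.1, abs=0.015)


class TestDistanceCluster:
    def test_identical_profiles_merge_first(self):
        p1 = profile_from_counts({"CD9": 10}, "a")
        p2 = profile_from_counts({"CD9": 10}, "b")
        p3 = profile_from_counts({"CD63": 10}, "c")
        res = distance_cluster([p1, p3, p2])
        assert res.distance_matrix[0, 2] == 0.0
        # first merge joins the two identical profiles (leaves 0 and 2)
        assert set(res.linkage[0, :2].astype(int)) == {0, 2}

    def test_mismatched_class_spaces_rejected(self):
        p1 = profile_from_counts({"CD9": 5})
        p2 = profile_from_counts({"CTB": 5}, channels=("CTB", "DiI", "AV"))
        with pytest.raises(ValueError):
            distance_cluster([p1, p2])

    def test_two_generating_mixes_recovered_at_k2(self, rng):
        """Profiles simulated from two distinct mixes split cleanly when the
        dendrogram is cut at two clusters."""
        from scipy.cluster.hierarchy import fcluster

        def noisy_profile(base, sid):
            pts = {c: [] for c in CHANNELS}
            x = 10.0
            for cls, n in base.items():
                for _ in range(max(1, int(n + rng.integers(-2, 3)))):
                    for c in cls.split("∙"):
                        pts[c].append((x, 10.0))
                    x += 10.0
            return build_profile({"f0": records_from(pts)}, sid, CHANNELS)

        mix_a = {"CD9∙CD81": 30, "CD63": 5}
        mix_b = {"CD63": 30, "CD81": 5}
        profs = [
            noisy_profile(mix_a, "a1"), noisy_profile(mix_b, "b1"),
            noisy_profile(mix_a, "a2"), noisy_profile(mix_b, "b2"),
        ]
        res = distance_cluster(profs)
        groups = fcluster(res.linkage, t=2, criterion="maxclust")
        assert groups[0] == groups[2]
        assert groups[1] == groups[3]
        assert groups[0] != groups[1]


class TestEmbedTsne:
    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.uniform(size=(20, 7))
        a = embed_tsne(X, perplexity=5, seed=3)
        b = embed_tsne(X, perplexity=5, seed=3)
        assert np.array_equal(a.embedding, b.embedding)

    def test_separated_groups_stay_separated(self, rng):
        X = np.vstack(
            [
                rng.normal(0.0, 0.01, size=(9, 7)),
                rng.normal(1.0, 0.01, size=(9, 7)),
            ]
        )
        res = embed_tsne(X, perplexity=4, seed=0)
        from sklearn.metrics import silhouette_score

        labels = [0] * 9 + [1] * 9
        assert silhouette_score(res.embedding, labels) > 0

    def test_degenerate_input_flagged_not_raised(self):
        X = np.ones((10, 7))
        res = embed_tsne(X, perplexity=3, seed=0)
        assert res.degenerate

    def test_perplexity_must_be_below_n(self, rng):
        with pytest.raises(ValueError):
            embed_tsne(rng.uniform(size=(5, 7)), perplexity=5)

    def test_sweep_reports_kl_per_value(self, rng):
        X = rng.uniform(size=(12, 7))
        out = perplexity_sweep(X, perplexities=(2, 4, 30), seed=1)
        assert [r.perplexity for r in out] == [2.0, 4.0]
        assert all(np.isfinite(r.kl_divergence) for r in out)
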