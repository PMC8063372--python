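"""Variant parsing, map projection, distance scores and ROC analysis."""

from __future__ import annotations

import numpy as np
import pytest

from channelscale._resources import variants_resource_path
from channelscale.classify import concordance_auc, optimal_threshold, roc_curve
from channelscale.hydropathy_field import ZeroCrossing
from channelscale.pore_geometry import PorePath, PorePoint
from channelscale.scaling_criticality import CriticalPoint
from channelscale.variant_mapping import (
    MutationSite,
    distance_to_critical_sphere,
    distance_to_hp_boundary,
    label_counts,
    locate_site,
    map_site,
    occupancy,
    parse_variants,
    weighted_score,
)

VARIANT_TSV = """\
residue_number\twt_aa\tmut_aa\tlabel
100\tI\tV\tpain
200\tD\tN\tneutral
100\tI\tT\tpain
300\tS\tP\tpain
"""


class TestParseVariants:
    def test_three_rows_parse_with_labels(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(VARIANT_TSV)
        sites = parse_variants(p)
        # residue 100 collapses to one site holding two substitutions
        assert len(sites) == 3
        site100 = next(s for s in sites if s.residue_number == 100)
        assert site100.n_variants == 2
        assert label_counts(sites) == {"pain": 2, "neutral": 1}

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("residue_number\twt_aa\tlabel\n1\tA\tpain\n")
        with pytest.raises(ValueError):
            parse_variants(p)

    def test_bundled_variant_table_has_published_set_sizes(self):
        sites = parse_variants(variants_resource_path())
        counts = label_counts(sites)
        assert counts == {"pain": 36, "neutral": 48}


class TestLocateSite:
    def test_heavy_centroid_excludes_hydrogens(self, toy_default):
        s = toy_default.structure
        rid = int(s.residue_number[0])
        pos = locate_site(s, rid)
        mask = (s.residue_number == rid) & (s.element != "H")
        assert np.allclose(pos, s.coords[mask].mean(axis=0))

    def test_two_heavy_atoms_centroid(self):
        from tests.test_hydropathy_field import _structure_with

        s = _structure_with([[0, 0, 0], [0, 0, 2]], [0.1, 0.1])
        assert np.allclose(locate_site(s, 1), [0, 0, 0])  # residues are per-atom here

    def test_absent_residue_raises_keyerror(self, toy_default):
        with pytest.raises(KeyError):
            locate_site(toy_default.structure, 77777)


class TestMapSite:
    def test_exhaustive_search_agreement(self, toy_default, rng):
        path, maps = toy_default.path, toy_default.maps
        for _ in range(20):
            site = MutationSite(residue_number=1, label="pain")
            site.site_position = rng.uniform(-20, 20, 3)
            map_site(site, path, maps)
            p_idx, alpha = site.map_coord
            d_all = np.linalg.norm(path.positions - site.site_position, axis=1)
            assert p_idx == int(np.argmin(d_all))
            radii = maps.radii[p_idx]
            expected_alpha = int(np.searchsorted(radii, d_all[p_idx], side="left")) + 1
            assert alpha == min(expected_alpha, len(radii))

    def test_boundary_radius_is_inclusive(self, toy_default):
        path, maps = toy_default.path, toy_default.maps
        p_idx = 10
        l_alpha = maps.radii[p_idx][49]
        pos = path.points[p_idx].position + np.array([0.0, 0.0, 0.0])
        # place the site exactly on the 50th sphere of its nearest pore point
        site = MutationSite(residue_number=1, label="pain")
        site.site_position = pos + np.array([0.0, l_alpha, 0.0])
        map_site(site, path, maps)
        if site.map_coord[0] == p_idx:  # nearest point may shift on a skewed path
            assert site.map_coord[1] == 50

    def test_far_site_clamped_with_warning(self, toy_default, caplog):
        site = MutationSite(residue_number=1, label="pain")
        site.site_position = np.array([500.0, 0.0, 0.0])
        map_site(site, toy_default.path, toy_default.maps)
        assert site.map_coord[1] == toy_default.maps.radii.shape[1]


class TestOccupancy:
    def _sites(self, coords_alphas):
        out = []
        for i, (p_idx, alpha, label) in enumerate(coords_alphas):
            s = MutationSite(residue_number=i, label=label)
            s.map_coord = (p_idx, alpha)
            out.append(s)
        return out

    def test_single_bin_occupancy_is_one(self):
        sites = self._sites([(0, 5, "pain"), (1, 5, "pain")])
        h = occupancy(sites, axis="alpha", bins=np.array([0.0, 10.0]))
        assert h.rates["pain"][0] == 1.0

    def test_counts_conserve_label_totals(self):
        sites = self._sites(
            [(0, 5, "pain"), (0, 50, "pain"), (2, 80, "neutral"), (3, 20, "neutral"), (1, 60, "neutral")]
        )
        h = occupancy(sites, axis="alpha", bins=4)
        assert h.counts["pain"].sum() == 2
        assert h.counts["neutral"].sum() == 3
        assert h.rates["pain"].sum() == pytest.approx(1.0)

    def test_uniform_sites_are_roughly_uniform(self, rng):
        sites = self._sites([(0, int(a), "pain") for a in rng.integers(1, 201, 400)])
        h = occupancy(sites, axis="alpha", bins=4)
        assert np.all(np.abs(h.rates["pain"] - 0.25) < 0.08)  # binomial noise


class TestDistanceScores:
    def _path_at_origin(self):
        return PorePath([PorePoint(0, np.zeros(3), 1, 2, 50)], spacing=1.0)

    def test_single_boundary_element(self):
        site = MutationSite(residue_number=1, label="pain")
        site.site_position = np.array([12.0, 0.0, 0.0])
        omega = [ZeroCrossing(p_index=0, alpha=3, l_star=10.0)]
        d, lo, hi = distance_to_hp_boundary(site, omega, self._path_at_origin())
        assert d == pytest.approx(2.0)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_site_on_every_locus_scores_zero(self):
        site = MutationSite(residue_number=1, label="pain")
        site.site_position = np.array([0.0, 10.0, 0.0])
        omega = [ZeroCrossing(0, 1, 10.0), ZeroCrossing(0, 2, 10.0)]
        d, _, _ = distance_to_hp_boundary(site, omega, self._path_at_origin())
        assert d == 0.0

    def test_median_matches_brute_force(self, toy_default, rng):
        path = toy_default.path
        omega = [
            ZeroCrossing(int(rng.integers(0, len(path))), 5, float(rng.uniform(5, 30)))
            for _ in range(50)
        ]
        site = MutationSite(residue_number=1, label="pain")
        site.site_position = rng.uniform(-10, 10, 3)
        d, _, _ = distance_to_hp_boundary(site, omega, path)
        vals = [
            abs(np.linalg.norm(site.site_position - path.points[c.p_index].position) - c.l_star)
            for c in omega
        ]
        assert d == pytest.approx(np.median(vals))

    def test_critical_sphere_distance_formula(self):
        crit = CriticalPoint(found=True, p_index=0, position=np.zeros(3), xi_crit=33.4)
        site = MutationSite(residue_number=1, label="pain")
        site.site_position = np.array([40.0, 0.0, 0.0])
        assert distance_to_critical_sphere(site, crit) == pytest.approx(6.6)
        site.site_position = np.array([0.0, 33.4, 0.0])
        assert distance_to_critical_sphere(site, crit) == pytest.approx(0.0)

    def test_undefined_without_critical_point(self):
        site = MutationSite(residue_number=1, label="pain")
        site.site_position = np.zeros(3)
        with pytest.raises(ValueError):
            distance_to_critical_sphere(site, CriticalPoint(found=False))

    def test_weighted_score_endpoints_and_midpoint(self):
        assert weighted_score(10.0, 6.0, w=1.0) == 10.0
        assert weighted_score(10.0, 6.0, w=0.0) == 6.0
        assert weighted_score(10.0, 6.0, w=0.5) == 8.0
        with pytest.raises(ValueError):
            weighted_score(1.0, 1.0, w=1.5)


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        scores = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        labels = ["pain"] * 3 + ["neutral"] * 3
        roc = roc_curve(scores, labels)
        assert roc.auc == 1.0
        opt = optimal_threshold(roc)
        assert opt.sensitivity == 1.0 and opt.specificity == 1.0
        assert 3.0 < opt.threshold < 10.0

    def test_trapezoid_equals_pairwise_concordance(self, rng):
        for _ in range(10):
            n = 30
            scores = np.round(rng.normal(size=n), 1)  # ties included
            labels = np.where(rng.uniform(size=n) < 0.4, "pain", "neutral")
            if len(set(labels)) < 2:
                continue
            roc = roc_curve(scores, labels)
            assert roc.auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    def test_random_labels_give_half_auc(self, rng):
        n = 2000
        scores = rng.normal(size=n)
        labels = np.where(rng.uniform(size=n) < 0.5, "pain", "neutral")
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(0.5, abs=0.05)  # Monte-Carlo CI

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = np.where(rng.uniform(size=40) < 0.5, "pain", "neutral")
        a = roc_curve(scores, labels).auc
        b = roc_curve(np.exp(2.0 * scores) + 7.0, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_orientation_reversal_complements_auc(self, rng):
        scores = rng.normal(size=50)
        labels = np.array(["pain"] * 20 + ["neutral"] * 30, dtype=object)
        a = roc_curve(scores, labels, low_predicts_positive=True).auc
        b = roc_curve(scores, labels, low_predicts_positive=False).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], ["pain", "pain"])

    def test_matches_sklearn_on_random_data(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=60)
        labels = np.where(rng.uniform(size=60) < 0.45, "pain", "neutral")
        ours = roc_curve(scores, labels).auc
        # sklearn scores high-predicts-positive; negate for orientation
        ref = roc_auc_score((labels == "pain").astype(int), -scores)
        assert ours == pytest.approx(ref, abs=1e-12)


class TestOptimalThreshold:
    def test_confusion_identities_hold(self, rng):
        scores = rng.normal(size=48)
        labels = np.array(["pain"] * 18 + ["neutral"] * 30, dtype=object)
        roc = roc_curve(scores, labels)
        opt = optimal_threshold(roc)
        assert opt.tp + opt.fn == roc.n_pos
        assert opt.tn + opt.fp == roc.n_neg
        assert opt.sensitivity == pytest.approx(opt.tp / roc.n_pos)
        assert opt.specificity == pytest.approx(opt.tn / roc.n_neg)

    def test_equals_exhaustive_youden_search(self, rng):
        scores = np.round(rng.normal(size=40), 1)
        labels = np.where(rng.uniform(size=40) < 0.5, "pain", "neutral")
        roc = roc_curve(scores, labels)
        opt = optimal_threshold(roc)
        j_best = max(
            (scores[labels == "pain"] <= th).mean() + (scores[labels == "neutral"] > th).mean() - 1.0
            for th in roc.thresholds
        )
        assert opt.youden_j == pytest.approx(j_best, abs=1e-12)

    def test_all_equal_scores_deterministic_degenerate(self):
        roc = roc_curve([5.0] * 6, ["pain"] * 3 + ["neutral"] * 3)
        opt = optimal_threshold(roc)
        assert opt.youden_j == pytest.approx(0.0)
        # tie-break prefers full specificity (nothing predicted positive)
        assert opt.specificity == 1.0
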