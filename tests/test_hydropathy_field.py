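"""Cumulative hydropathic moments and zero-crossing topology."""

from __future__ import annotations

import numpy as np
import pytest

from channelscale.hydropathy_field import (
    detect_topology,
    field_map,
    hp_boundary,
    moment0,
    moment1,
    moment_profile,
)
from channelscale.packing_cdf import SamplingGrid, sampling_radii
from channelscale.pore_geometry import PorePath, PorePoint
from channelscale.structure_io import Structure, StructureError
from tests.conftest import random_cloud


def _point(position=(0.0, 0.0, 0.0), D=1.0, L=40.0, index=0):
    return PorePoint(index, np.asarray(position, dtype=float), D - 0.5, D, L)


def _structure_with(coords, hi):
    n = len(coords)
    s = Structure(
        serial=np.arange(1, n + 1),
        element=np.full(n, "C", dtype=object),
        atom_name=np.full(n, "C1", dtype=object),
        residue_name=np.full(n, "UNK", dtype=object),
        residue_number=np.arange(1, n + 1),
        segment_id=np.full(n, "A", dtype=object),
        coords=np.asarray(coords, dtype=float),
    )
    s.vdw_radius = np.full(n, 1.5)
    s.mass = np.full(n, 12.0)
    s.hi = np.asarray(hi, dtype=float)
    s.hi_noisy = s.hi.copy()  # noise already folded in for these checks
    return s


class TestMoment0:
    def test_opposite_indices_cancel_exactly(self):
        s = _structure_with([[1, 0, 0], [0, 1, 0]], [1.0, -1.0])
        g = SamplingGrid(0, np.array([2.0]))
        h0, m0 = moment0(s, _point(), g)
        assert h0[0] == 0.0
        assert m0[0] == 0.0

    def test_full_sphere_conserves_total_index_sum(self, rng):
        s = random_cloud(rng, 300)
        p = _point(D=0.1, L=100.0)
        g = sampling_radii(p, 30)
        h0, _ = moment0(s, p, g)
        assert h0[-1] == pytest.approx(s.hi_noisy.sum(), abs=1e-10)

    def test_undefined_below_first_atom(self, rng):
        s = random_cloud(rng, 50)
        d = np.linalg.norm(s.coords, axis=1)
        g = SamplingGrid(0, np.array([d.min() * 0.9, d.max() + 1]))
        h0, m0 = moment0(s, _point(), g)
        assert np.isnan(h0[0]) and np.isnan(m0[0])
        assert np.isfinite(h0[1])

    def test_matches_brute_force_masked_sums(self, rng):
        s = random_cloud(rng, 400)
        p = _point(position=(0.5, -1.0, 2.0))
        g = SamplingGrid(0, np.linspace(2.0, 40.0, 50))
        h0, m0 = moment0(s, p, g)
        h1, m1z, _ = moment1(s, p, g)
        d = np.linalg.norm(s.coords - p.position, axis=1)
        for j, l in enumerate(g.radii):
            mask = d <= l
            if not mask.any():
                continue
            assert h0[j] == pytest.approx(s.hi_noisy[mask].sum(), abs=1e-9)
            expected_h1 = (s.hi_noisy[mask, None] * (s.coords[mask] - p.position)).sum(axis=0)
            assert np.allclose(h1[j], expected_h1, atol=1e-9)
            assert m1z[j] == pytest.approx(expected_h1[2] / mask.sum(), abs=1e-9)


class TestMoment1:
    def test_single_atom_axial_moment_and_orientation(self):
        s = _structure_with([[0, 0, 3]], [2.0])
        g = SamplingGrid(0, np.array([5.0]))
        h1, m1z, orient = moment1(s, _point(), g)
        assert np.allclose(h1[0], [0, 0, 6.0])
        assert m1z[0] == pytest.approx(6.0)
        assert orient[0] == "in"  # positive axial component points intracellular

    def test_mirror_pair_cancels_axial_component(self):
        s = _structure_with([[1, 0, 4], [1, 0, -4]], [0.7, 0.7])
        g = SamplingGrid(0, np.array([10.0]))
        _, m1z, _ = moment1(s, _point(), g)
        assert m1z[0] == pytest.approx(0.0, abs=1e-12)

    def test_translation_identity_at_full_radius(self, rng):
        # h1 about p minus h1 about p' equals (p' - p) * h0 once every atom
        # is inside both spheres
        s = random_cloud(rng, 200)
        p1, p2 = _point(position=(0, 0, 0), L=200), _point(position=(2, -1, 3), L=200)
        g = SamplingGrid(0, np.array([150.0]))
        h1_a, _, _ = moment1(s, p1, g)
        h1_b, _, _ = moment1(s, p2, g)
        h0, _ = moment0(s, p1, g)
        assert np.allclose(h1_a[0] - h1_b[0], (p2.position - p1.position) * h0[0], atol=1e-9)


class TestFieldMap:
    def test_single_point_path_reduces_to_moment_profile(self, rng):
        s = random_cloud(rng, 200)
        d = np.linalg.norm(s.coords, axis=1)
        p = _point(D=float(d.min()), L=float(d.max() + s.vdw_radius.max()))
        path = PorePath([p], spacing=1.0)
        maps = field_map(s, path, k_alpha=40)
        prof = moment_profile(s, p, sampling_radii(p, 40))
        assert maps.m0.shape == (1, 40)
        assert np.allclose(maps.m0[0], prof.m0, equal_nan=True)
        assert np.allclose(maps.m1_z[0], prof.m1_z, equal_nan=True)

    def test_requires_noise_assigned(self, rng):
        s = random_cloud(rng, 50)
        s.hi_noisy = np.full(s.n_atoms, np.nan)
        with pytest.raises(StructureError):
            moment_profile(s, _point(), SamplingGrid(0, np.array([10.0])))

    def test_m0_at_outer_radius_identical_across_pore_points(self, toy_default):
        maps = toy_default.maps
        full = maps.m0[:, -1]
        assert np.max(np.abs(full - full[0])) <= 1e-9 * max(abs(full[0]), 1e-30)

    def test_deterministic_under_seed(self, toy_default):
        from channelscale.structure_io import add_index_noise
        from channelscale.synthetic import make_toy_channel
        from tests.conftest import TOY_SEED

        s2, _ = make_toy_channel(toy_default.spec)
        add_index_noise(s2, 0.001, TOY_SEED)
        maps2 = field_map(s2, toy_default.path, k_alpha=maps_k(toy_default))
        assert np.array_equal(
            np.nan_to_num(maps2.m1_z), np.nan_to_num(toy_default.maps.m1_z)
        )


def maps_k(toy) -> int:
    return toy.maps.m0.shape[1]


class TestTopology:
    def test_planted_boundary_found_per_row(self):
        radii = np.tile(np.linspace(1.0, 20.0, 40), (5, 1))
        field = np.sign(radii - 10.0)
        field[field == 0] = 1.0
        topo = detect_topology(field, radii=radii, field_id="m0")
        rows = [c.p_index for c in topo.zero_crossings]
        assert sorted(rows) == list(range(5))
        for c in topo.zero_crossings:
            assert abs(c.l_star - 10.0) <= np.diff(radii[0])[0]
        assert len(topo.domains) == 2

    def test_all_positive_grid_single_domain_no_crossings(self):
        topo = detect_topology(np.ones((4, 6)))
        assert len(topo.domains) == 1
        assert topo.zero_crossings == []
        assert topo.domains[0].area_fraction == 1.0

    def test_crossing_count_matches_brute_force_sign_scan(self, rng):
        field = rng.normal(size=(12, 30)).cumsum(axis=1)  # smooth-ish rows
        topo = detect_topology(field)
        expected = 0
        for i in range(12):
            signs = np.sign(field[i])
            signs[signs == 0] = 1
            expected += int((signs[:-1] != signs[1:]).sum())
        assert len(topo.zero_crossings) == expected

    def test_area_fractions_sum_to_one_and_labels_partition(self, toy_default):
        topo = detect_topology(toy_default.maps.m0, radii=toy_default.maps.radii)
        assert sum(d.area_fraction for d in topo.domains) == pytest.approx(1.0)
        defined = np.isfinite(toy_default.maps.m0)
        assert np.all((topo.labels > 0) == defined)

    def test_boundaries_separate_opposite_signs(self, toy_default):
        topo = detect_topology(toy_default.maps.m1_z, radii=toy_default.maps.radii)
        for c in topo.zero_crossings[::7]:
            s1 = topo.signs[c.p_index, c.alpha]
            s2 = topo.signs[c.p_index, c.alpha + 1]
            assert s1 * s2 == -1


class TestHpBoundary:
    def test_band_edges_recovered_from_low_alpha_sign(self, toy_band):
        maps = toy_band.maps
        topo = detect_topology(maps.m0, radii=maps.radii, field_id="m0")
        z_lo, z_hi = toy_band.truth.band
        spacing = toy_band.path.spacing
        for i, p in enumerate(toy_band.path):
            first = np.nonzero(np.isfinite(maps.m0[i]))[0][0]
            sign = topo.signs[i, first]
            z = p.position[2]
            if z_lo + spacing < z < z_hi - spacing:
                assert sign == 1  # hydrophobic lining inside the band
            elif z < z_lo - spacing or z > z_hi + spacing:
                assert sign == -1  # hydrophilic lining outside

    def test_boundary_restricted_to_pore_touching_hydrophobic_domains(self, toy_band):
        maps = toy_band.maps
        topo = detect_topology(maps.m0, radii=maps.radii, field_id="m0")
        omega = hp_boundary(topo, hydrophobic_sign=1)
        assert omega
        hp_ranks = {
            int(d.label[1:]) for d in topo.domains if d.sign == 1 and d.touches_pore
        }
        for c in omega:
            assert (
                topo.labels[c.p_index, c.alpha] in hp_ranks
                or topo.labels[c.p_index, c.alpha + 1] in hp_ranks
            )

    def test_fully_hydrophilic_structure_has_empty_boundary(self, rng):
        s = random_cloud(rng, 200)
        s.hi_noisy = -np.abs(s.hi_noisy)  # all hydrophilic
        d = np.linalg.norm(s.coords, axis=1)
        p = _point(D=float(d.min()), L=float(d.max() + 2))
        path = PorePath([p], spacing=1.0)
        maps = field_map(s, path, k_alpha=30)
        topo = detect_topology(maps.m0, radii=maps.radii, field_id="m0")
        with pytest.warns(UserWarning):
            omega = hp_boundary(topo, hydrophobic_sign=1)
        assert omega == []

    def test_sign_convention_flip_swaps_domain_roles(self, toy_band):
        maps = toy_band.maps
        topo = detect_topology(maps.m0, radii=maps.radii, field_id="m0")
        om_pos = {(c.p_index, c.alpha) for c in hp_boundary(topo, hydrophobic_sign=1)}
        om_neg = {(c.p_index, c.alpha) for c in hp_boundary(topo, hydrophobic_sign=-1)}
        # flipping the convention selects boundaries of the opposite-sign
        # pore-touching domains; the two selections are distinct
        assert om_pos and om_neg and om_pos != om_neg


def test_radial_component_shrinks_relative_to_axial(toy_default):
    # beyond a lag cut-off, the median (over pore points) ratio of the radial
    # to the axial first-moment magnitude decreases with the sampling scale
    maps = toy_default.maps
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = maps.h1_xy_norm / np.abs(maps.h1_z)
    k = ratio.shape[1]
    med = np.nanmedian(ratio, axis=0)
    upper = med[k // 2 :]
    # robust monotone-trend check: OLS slope of the median ratio is negative
    x = np.arange(len(upper))
    slope = np.polyfit(x, upper, 1)[0]
    assert slope < 0
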