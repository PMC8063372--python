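"""Shared fixtures: toy channels analysed once per session, random clouds."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from channelscale import (
    add_index_noise,
    atomic_cdf,
    field_map,
    fit_sigmoid,
    locate_critical_point,
    pm_vs_transition,
    sampling_radii,
    trace_pore,
)
from channelscale.annotation import SegmentAnnotation
from channelscale.structure_io import Structure
from channelscale.synthetic import make_toy_channel, toy_annotation, toy_spec

TOY_SEED = 4
K_ALPHA = 200


def random_cloud(rng: np.random.Generator, n_atoms: int, box: float = 20.0) -> Structure:
    """Random atom cloud with random vdW radii and hydropathy indices."""
    s = Structure(
        serial=np.arange(1, n_atoms + 1),
        element=np.full(n_atoms, "C", dtype=object),
        atom_name=np.array([f"C{i%9+1}" for i in range(n_atoms)], dtype=object),
        residue_name=np.full(n_atoms, "UNK", dtype=object),
        residue_number=np.arange(1, n_atoms + 1),
        segment_id=np.full(n_atoms, "A", dtype=object),
        coords=rng.uniform(-box / 2, box / 2, (n_atoms, 3)),
    )
    s.mass = rng.uniform(1.0, 32.0, n_atoms)
    s.vdw_radius = rng.uniform(1.0, 2.0, n_atoms)
    s.hi = rng.normal(0.0, 0.3, n_atoms)
    s.hi_noisy = s.hi + rng.normal(0.0, 0.001, n_atoms)
    return s


@dataclass
class ToyAnalysis:
    spec: object
    structure: Structure
    truth: object
    annotation: SegmentAnnotation
    path: object
    grids: list
    cdfs: list
    fits: list
    transitions: list
    maps: object
    crit: object


def _analyse(preset: str, seed: int) -> ToyAnalysis:
    spec = toy_spec(preset, seed=seed)
    structure, truth = make_toy_channel(spec)
    add_index_noise(structure, 0.001, seed)
    annotation = toy_annotation(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path = trace_pore(structure, spacing=1.0, z_range=annotation.pore_z_range(structure, pad=1.0))
        grids = [sampling_radii(p, K_ALPHA) for p in path]
        cdfs = [atomic_cdf(structure, p, g) for p, g in zip(path, grids)]
        fits = [fit_sigmoid(c, g) for c, g in zip(cdfs, grids)]
        roles = annotation.roles(structure)
        transitions = [
            pm_vs_transition(structure, p, g, annotation, roles=roles) for p, g in zip(path, grids)
        ]
        maps = field_map(structure, path, K_ALPHA)
        crit = locate_critical_point(
            path, fits, maps.m1_z, maps.radii, annotation.sf_center(structure)
        )
    return ToyAnalysis(spec, structure, truth, annotation, path, grids, cdfs, fits, transitions, maps, crit)


@pytest.fixture(scope="session")
def toy_default() -> ToyAnalysis:
    """Default toy channel (band + planted scaling break), fully analysed."""
    return _analyse("default", TOY_SEED)


@pytest.fixture(scope="session")
def toy_band() -> ToyAnalysis:
    """Band-only toy channel for hydrophobic-patch topology checks."""
    return _analyse("band", 3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
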