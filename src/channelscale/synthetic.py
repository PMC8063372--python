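"""Fully specified synthetic inputs for every pipeline stage.

The toy channel combines three deterministic-under-seed populations:

* a pore-lining cylinder (pore-module wall) of four-fold pseudo-symmetric
  atom rings around a gently sinusoidal axis,
* a narrow selectivity-filter (SF) ring at the pore midpoint, and
* a voltage-sensor bulk of small atom clusters whose distances from the SF
  center are drawn from the *complement* of a truncated-logistic radial
  density, so that the total atom-packing CDF around the SF is sigmoid by
  construction and its inflection scale is a designed quantity.

Hydropathy is planted by construction: a hydrophobic band lining the pore
and/or an axially antisymmetric pattern around the SF whose sign reverses
on the sphere of the designed inflection radius, producing the power-law
expansion/contraction pattern with a known break.  Each generator emits
its ground truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.stats import norm

from ._resources import load_masses, load_vdw_radii
from .annotation import SegmentAnnotation, SegmentRange, write_annotation
from .packing_cdf import MODEL_FUNCS
from .structure_io import HydropathyTable, Structure, write_structure
from .variant_mapping import MutationSite

_TOY_RESNAME = "TOY"
_TOY_ELEMENT = "C"
# atom-name prefixes encode the planted hydropathy class so that the full
# table-lookup I/O path can reproduce the in-memory indices
CLASS_PREFIXES = {
    "band": "P",
    "philic": "N",
    "soc_in_pos": "S",
    "soc_in_neg": "T",
    "soc_out_pos": "U",
    "soc_out_neg": "V",
    "soc_mid_pos": "W",
    "soc_mid_neg": "X",
}


@dataclass
class ToyChannelSpec:
    """Construction parameters of the toy channel (defaults ~2,900 atoms)."""

    n_slices: int = 31
    z_min: float = -30.0
    z_max: float = 30.0
    lining_radius: float = 9.0
    lining_count: int = 16  # atoms per slice; multiple of 4
    axis_amplitude: float = 0.8
    axis_period: float = 60.0
    z_jitter: float = 0.3
    angle_jitter: float = 0.05
    sf_z: float = 0.0
    sf_ring_radius: float = 6.0
    sf_ring_atoms: int = 40  # split over two staggered rings
    # voltage-sensor bulk: clusters of atoms with SF-centered distances drawn
    # from the complement of a truncated-logistic radial density
    bulk_mu: float = 22.0
    bulk_scale: float = 2.0
    bulk_range: tuple = (12.0, 32.0)
    n_bulk_clusters: int = 1200
    bulk_cluster_size: int = 2
    bulk_cluster_jitter: float = 0.7
    bulk_min_perp: float = 12.0  # keep the bulk clear of the pore lumen
    bulk_halfwidth: float = 15.0  # |z - sf_z| clip, symmetric about the SF
    # clusters closer to the axis than this belong to the pore module, the
    # rest to the voltage sensors — placing the compositional PM-to-VS
    # transition scale nu just above the packing inflection, as in the
    # channel systems the fixture emulates
    bulk_pm_perp: float = 18.0
    # hydrophobic band on the pore lining: (z_lo, z_hi, index value)
    hydrophobic_band: tuple | None = (5.0, 25.0, 0.3)
    hydrophilic_value: float = -0.15
    soc: bool = True
    soc_amplitude: float = 2.0
    # the index magnitude outside the break sphere is softened so the planted
    # contraction is slower than the expansion is fast (the break location
    # stays sharp, the decay does not swamp the pre-break growth interval)
    soc_out_factor: float = 0.3
    # the reversal is blended over a thin shell so the piecewise power-law
    # misfit grows smoothly as the probe point moves away from the SF
    soc_blend: float = 0.8
    soc_mid_factor: float = 0.15
    soc_halfwidth: float | None = 15.0  # slab carrying the pattern; None = everywhere
    seed: int = 7

    def validate(self) -> None:
        if self.lining_count % 4:
            raise ValueError("lining_count must be a multiple of 4 (four-fold pseudo-symmetry)")
        if not (self.z_min < self.sf_z < self.z_max):
            raise ValueError("sf_z must lie inside the z range")
        if not (self.bulk_range[0] < self.bulk_mu < self.bulk_range[1]):
            raise ValueError("bulk_mu must lie inside bulk_range")
        if self.hydrophobic_band is not None:
            z_lo, z_hi, _ = self.hydrophobic_band
            if not (self.z_min <= z_lo < z_hi <= self.z_max):
                raise ValueError("hydrophobic band z-range must lie inside the structure")


def toy_spec(preset: str = "default", seed: int = 7) -> ToyChannelSpec:
    """Named presets: 'default' (band + SF scaling pattern), 'band' (pure
    hydrophobic-band topology), 'soc' (pure scaling pattern everywhere)."""
    if preset == "default":
        return ToyChannelSpec(seed=seed)
    if preset == "band":
        return ToyChannelSpec(hydrophobic_band=(-20.0, 20.0, 0.3), soc=False, seed=seed)
    if preset == "soc":
        return ToyChannelSpec(hydrophobic_band=None, soc=True, soc_halfwidth=None, seed=seed)
    raise ValueError(f"unknown toy-channel preset {preset!r}")


@dataclass
class ToyChannelTruth:
    """Ground truth emitted with the generated structure."""

    axis: np.ndarray  # (n_slices, 3) exact slice centers
    pore_radius: float  # planted lining clearance radius (lining - vdW)
    band: tuple | None  # (z_lo, z_hi) of the hydrophobic lining band
    sf_center: np.ndarray
    sf_ring_radius: float
    soc_break: float | None  # rho*: planted expansion/contraction break (A)
    n_atoms: int
    seed: int
    class_values: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["axis"] = np.asarray(self.axis).tolist()
        d["sf_center"] = np.asarray(self.sf_center).tolist()
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ToyChannelTruth":
        d = json.loads(Path(path).read_text())
        d["axis"] = np.asarray(d["axis"], dtype=float)
        d["sf_center"] = np.asarray(d["sf_center"], dtype=float)
        d["band"] = tuple(d["band"]) if d["band"] is not None else None
        return cls(**d)


def _richards_inflection_of_cdf(r: np.ndarray, counts: np.ndarray) -> float:
    """Inflection scale of a designed CDF via a self-contained Richards fit.

    This is the generator's reference computation (kept independent of the
    analysis module): the inflection of the Richards curve is
    s + (1 + q)/k with k = t/A (1 + q)^(1 + 1/q).
    """

    def richards(l, A, t, s, q):
        with np.errstate(all="ignore"):
            k = t / A * (1.0 + q) ** (1.0 + 1.0 / q)
            b = np.exp(1.0 + q + k * s)
            return A * (1.0 + q * b * np.exp(np.clip(-k * l, -700, 700))) ** (-1.0 / q)

    p0 = [float(counts[-1]), float(np.max(np.gradient(counts, r))), float(r[np.argmax(np.gradient(counts, r))]), 1.0]
    popt, _ = curve_fit(richards, r, counts, p0=p0, maxfev=20000)
    A, t, s, q = popt
    k = t / A * (1.0 + q) ** (1.0 + 1.0 / q)
    return float(s + (1.0 + q) / k)


def make_toy_channel(spec: ToyChannelSpec | None = None) -> tuple[Structure, ToyChannelTruth]:
    """Generate the toy channel and its ground-truth record."""
    spec = spec if spec is not None else ToyChannelSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    z_slices = np.linspace(spec.z_min, spec.z_max, spec.n_slices)
    n_bulk = spec.n_bulk_clusters * spec.bulk_cluster_size

    def axis_xy(z: float) -> tuple[float, float]:
        # sinusoidal lateral offset, phased to be flat at the SF so the
        # filter rings stay coaxial with the local pore direction
        if spec.axis_amplitude == 0:
            return 0.0, 0.0
        return (
            spec.axis_amplitude * (1.0 - np.cos(2 * np.pi * (z - spec.sf_z) / spec.axis_period)),
            0.0,
        )

    sf_center = np.array([*axis_xy(spec.sf_z), spec.sf_z])

    # ---- deterministic layout (no jitter) used for the designed CDF -------
    det_dists = []
    for z0 in z_slices:
        ox, oy = axis_xy(z0)
        for a in range(spec.lining_count):
            theta = 2 * np.pi * a / spec.lining_count + 0.1 * z0
            pos = np.array([ox + spec.lining_radius * np.cos(theta), oy + spec.lining_radius * np.sin(theta), z0])
            det_dists.append(np.linalg.norm(pos - sf_center))
    n_sf = 8 * max(spec.sf_ring_atoms // 8, 1)
    for a in range(n_sf):
        det_dists.append(float(np.hypot(spec.sf_ring_radius, 0.8)))
    det_dists = np.asarray(det_dists)

    # designed total radial density around the SF: truncated-logistic target,
    # bulk sampled from the target minus the lining contribution
    rg = np.arange(0.02, det_dists.max() + 12.0, 0.02)
    lo, hi = spec.bulk_range
    mu, sc = spec.bulk_mu, spec.bulk_scale
    with np.errstate(over="ignore"):
        pdf = np.where(
            (rg >= lo) & (rg <= hi),
            np.exp(-(rg - mu) / sc) / sc / (1.0 + np.exp(-(rg - mu) / sc)) ** 2,
            0.0,
        )
    pdf /= np.trapezoid(pdf, rg)
    lining_rdf = np.zeros_like(rg)
    for d0 in det_dists:
        lining_rdf += norm.pdf(rg, d0, max(spec.z_jitter, 0.3))
    target_scale = brentq(
        lambda C: np.trapezoid(np.maximum(C * pdf - lining_rdf, 0.0), rg) - n_bulk,
        n_bulk / 2.0,
        100.0 * n_bulk,
    )
    residual = np.maximum(target_scale * pdf - lining_rdf, 0.0)
    residual_cdf = np.cumsum(residual)
    residual_cdf /= residual_cdf[-1]

    soc_break = None
    if spec.soc:
        designed_counts = np.cumsum((lining_rdf + residual) * (rg[1] - rg[0]))
        mask = rg > spec.sf_ring_radius - 1.0
        soc_break = _richards_inflection_of_cdf(rg[mask], designed_counts[mask])

    # ---- atom placement ---------------------------------------------------
    coords: list[np.ndarray] = []
    res_numbers: list[int] = []
    is_lining: list[bool] = []
    pm_res = 0
    for k, z0 in enumerate(z_slices):
        ox, oy = axis_xy(z0)
        per_quad = spec.lining_count // 4
        for q in range(4):
            pm_res += 1
            for a in range(per_quad):
                idx = q * per_quad + a
                theta = 2 * np.pi * idx / spec.lining_count + 0.1 * z0 + rng.normal(0.0, spec.angle_jitter)
                coords.append(
                    np.array(
                        [
                            ox + spec.lining_radius * np.cos(theta),
                            oy + spec.lining_radius * np.sin(theta),
                            z0 + rng.normal(0.0, spec.z_jitter),
                        ]
                    )
                )
                res_numbers.append(pm_res)
                is_lining.append(True)
    # the filter is a short two-ring stack with staggered angles, so the
    # constriction has no angular gap for the clearance optimiser to dodge
    per_quad_sf = max(spec.sf_ring_atoms // 8, 1)
    for q in range(4):
        for ring, dz_ring in enumerate((-0.8, 0.8)):
            for a in range(per_quad_sf):
                theta = (
                    np.pi / 2 * q
                    + (a + 0.5) * (np.pi / 2) / per_quad_sf
                    + ring * (np.pi / 4) / per_quad_sf
                )
                coords.append(
                    np.array(
                        [
                            sf_center[0] + spec.sf_ring_radius * np.cos(theta),
                            sf_center[1] + spec.sf_ring_radius * np.sin(theta),
                            spec.sf_z + dz_ring + rng.normal(0.0, 0.15),
                        ]
                    )
                )
                res_numbers.append(9000 + q + 1)
                is_lining.append(False)
    # bulk clusters: inner ones are pore-module material, outer ones belong
    # to the voltage sensors (residue ranges 2001+ and 5001+ respectively)
    cluster_d = np.interp(rng.uniform(size=spec.n_bulk_clusters), residual_cdf, rg)
    vs_res = 5000
    pm_bulk_res = 2000
    for di in cluster_d:
        while True:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            center = sf_center + di * v
            ox, oy = axis_xy(center[2])
            perp = np.hypot(center[0] - ox, center[1] - oy)
            if (
                perp >= spec.bulk_min_perp
                and abs(center[2] - spec.sf_z) <= spec.bulk_halfwidth
                and spec.z_min <= center[2] <= spec.z_max
            ):
                break
        if perp < spec.bulk_pm_perp:
            pm_bulk_res += 1
            resnum = pm_bulk_res
        else:
            vs_res += 1
            resnum = vs_res
        for _ in range(spec.bulk_cluster_size):
            coords.append(center + rng.normal(0.0, spec.bulk_cluster_jitter, 3))
            res_numbers.append(resnum)
            is_lining.append(False)

    xyz = np.vstack(coords)
    res_numbers = np.asarray(res_numbers)
    is_lining = np.asarray(is_lining)
    n = len(xyz)

    # ---- planted hydropathy ----------------------------------------------
    # the scaling pattern lives on the voltage-sensor bulk only: the axial
    # field is near zero until bulk atoms enter the sampling sphere, grows
    # coherently up to the break sphere and decays (softened) beyond it
    classes = np.full(n, "philic", dtype=object)
    if spec.soc:
        is_bulk = (res_numbers > 2000) & (res_numbers < 9000)
        d_sf = np.linalg.norm(xyz - sf_center, axis=1)
        dz = xyz[:, 2] - spec.sf_z
        in_slab = (
            np.abs(dz) <= spec.soc_halfwidth if spec.soc_halfwidth is not None else np.ones(n, bool)
        )
        inside = d_sf <= soc_break - spec.soc_blend
        outside = d_sf > soc_break + spec.soc_blend
        mid = ~inside & ~outside
        pos = dz >= 0
        sel = is_bulk & in_slab
        classes[sel & inside & pos] = "soc_in_pos"
        classes[sel & inside & ~pos] = "soc_in_neg"
        classes[sel & mid & pos] = "soc_mid_pos"
        classes[sel & mid & ~pos] = "soc_mid_neg"
        classes[sel & outside & ~pos] = "soc_out_pos"
        classes[sel & outside & pos] = "soc_out_neg"
    if spec.hydrophobic_band is not None:
        z_lo, z_hi, _ = spec.hydrophobic_band
        in_band = (
            (xyz[:, 2] >= z_lo)
            & (xyz[:, 2] <= z_hi)
            & (is_lining | (res_numbers > 9000))
            & (classes == "philic")
        )
        classes[in_band] = "band"

    class_values = {
        "band": spec.hydrophobic_band[2] if spec.hydrophobic_band is not None else 0.3,
        "philic": spec.hydrophilic_value,
        "soc_in_pos": spec.soc_amplitude,
        "soc_in_neg": -spec.soc_amplitude,
        "soc_out_pos": spec.soc_amplitude * spec.soc_out_factor,
        "soc_out_neg": -spec.soc_amplitude * spec.soc_out_factor,
        "soc_mid_pos": spec.soc_amplitude * spec.soc_mid_factor,
        "soc_mid_neg": -spec.soc_amplitude * spec.soc_mid_factor,
    }

    atom_names = np.empty(n, dtype=object)
    counters: dict[tuple[int, str], int] = {}
    for i in range(n):
        key = (int(res_numbers[i]), str(classes[i]))
        counters[key] = counters.get(key, 0) + 1
        atom_names[i] = f"{CLASS_PREFIXES[str(classes[i])]}{counters[key]}"

    structure = Structure(
        serial=np.arange(1, n + 1),
        element=np.full(n, _TOY_ELEMENT, dtype=object),
        atom_name=atom_names,
        residue_name=np.full(n, _TOY_RESNAME, dtype=object),
        residue_number=res_numbers,
        segment_id=np.full(n, "A", dtype=object),
        coords=xyz,
    )
    masses = load_masses()
    vdw = load_vdw_radii()
    structure.mass = np.full(n, masses[_TOY_ELEMENT])
    structure.vdw_radius = np.full(n, vdw[_TOY_ELEMENT])
    structure.hi = np.array([class_values[str(c)] for c in classes], dtype=float)

    truth = ToyChannelTruth(
        axis=np.column_stack(
            [
                np.array([axis_xy(z)[0] for z in z_slices]),
                np.array([axis_xy(z)[1] for z in z_slices]),
                z_slices,
            ]
        ),
        pore_radius=float(spec.lining_radius - vdw[_TOY_ELEMENT]),
        band=(spec.hydrophobic_band[0], spec.hydrophobic_band[1]) if spec.hydrophobic_band else None,
        sf_center=sf_center,
        sf_ring_radius=spec.sf_ring_radius,
        soc_break=soc_break,
        n_atoms=n,
        seed=spec.seed,
        class_values=class_values,
    )
    return structure, truth


def toy_hydropathy_table(truth: ToyChannelTruth) -> HydropathyTable:
    """Lookup table reproducing the planted per-atom indices via atom names."""
    entries = {
        (_TOY_RESNAME, f"{CLASS_PREFIXES[cls]}*"): float(v)
        for cls, v in truth.class_values.items()
    }
    entries[("*", "@" + _TOY_ELEMENT)] = 0.0
    return HydropathyTable(entries, hydrophobic_sign=1)


def toy_annotation(structure: Structure) -> SegmentAnnotation:
    """Segment annotation matching the generator's residue numbering."""
    res = structure.residue_number
    segments = []
    pm = res[res < 5000]
    vs = res[(res > 5000) & (res < 9000)]
    sf = res[res > 9000]
    if len(pm):
        segments.append(SegmentRange("*", int(pm.min()), int(pm.max()), "PM"))
    if len(vs):
        segments.append(SegmentRange("*", int(vs.min()), int(vs.max()), "VS"))
    if len(sf):
        segments.append(SegmentRange("*", int(sf.min()), int(sf.max()), "SF"))
    return SegmentAnnotation(segments=segments, es_end="low_z", pore_axis_hint=(0.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# curve fixtures
# ---------------------------------------------------------------------------
def make_sigmoid_series(
    family: str,
    params: dict[str, float],
    n: int = 200,
    l_range: tuple[float, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact sigmoid-model series with optional additive Gaussian noise."""
    if family not in MODEL_FUNCS:
        raise ValueError(f"unknown model family {family!r}")
    if l_range is None:
        span = params["A"] / params["t"]
        l_range = (max(params["s"] - 0.5 * span, 0.0), params["s"] + 3.0 * span)
    l = np.linspace(l_range[0], l_range[1], n)
    y = MODEL_FUNCS[family](l, **params)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return l, y


def make_piecewise_powerlaw(
    gamma1: float,
    gamma2: float,
    break_l: float,
    n: int = 100,
    l_range: tuple[float, float] | None = None,
    prefactor: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-exponent power law, continuous at the break, multiplicative noise."""
    if l_range is None:
        l_range = (break_l / 4.0, break_l * 2.0)
    if not (l_range[0] < break_l < l_range[1]):
        raise ValueError("break_l must lie inside l_range")
    l = np.linspace(l_range[0], l_range[1], n)
    y = np.where(
        l <= break_l,
        prefactor * l**gamma1,
        prefactor * break_l ** (gamma1 - gamma2) * l**gamma2,
    )
    if noise_sd > 0:
        y = y * (1.0 + np.random.default_rng(seed).normal(0.0, noise_sd, n))
    return l, y


def make_labeled_sites(
    center: np.ndarray,
    crit_shell_radius: float,
    n_pain: int = 12,
    n_neutral: int = 16,
    jitter_sd: float = 0.0,
    separation: float = 6.0,
    seed: int = 0,
) -> list[MutationSite]:
    """Planted variant sites: pain on the critical shell (± jitter), neutral
    uniformly off-shell (at least ``separation`` from it)."""
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)

    def direction() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    sites = []
    for i in range(n_pain):
        r = crit_shell_radius + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        sites.append(
            MutationSite(
                residue_number=50000 + i,
                label="pain",
                substitutions=[("G", "A")],
                site_position=center + max(r, 0.1) * direction(),
            )
        )
    for i in range(n_neutral):
        while True:
            r = rng.uniform(0.2 * crit_shell_radius, 1.8 * crit_shell_radius)
            if abs(r - crit_shell_radius) >= separation:
                break
        sites.append(
            MutationSite(
                residue_number=60000 + i,
                label="neutral",
                substitutions=[("G", "A")],
                site_position=center + r * direction(),
            )
        )
    return sites


def toy_variant_sites(
    structure: Structure,
    truth: ToyChannelTruth,
    n_pain: int = 12,
    n_neutral: int = 16,
) -> list[tuple[int, str]]:
    """Pick structure residues whose centroids sit on / off the planted
    critical shell: (residue_number, label) pairs for a variants table."""
    if truth.soc_break is None:
        raise ValueError("toy channel has no planted scaling break")
    res_ids = np.unique(structure.residue_number)
    dev = []
    for rid in res_ids:
        centroid = structure.coords[structure.residue_number == rid].mean(axis=0)
        dev.append((abs(np.linalg.norm(centroid - truth.sf_center) - truth.soc_break), int(rid)))
    dev.sort()
    pain = [rid for _, rid in dev[:n_pain]]
    neutral = [rid for _, rid in dev[-n_neutral:]]
    return [(rid, "pain") for rid in pain] + [(rid, "neutral") for rid in neutral]


def write_toy_channel(out_dir: str | Path, spec: ToyChannelSpec | None = None) -> ToyChannelTruth:
    """Materialise a toy-channel data set: structure.pdb, annotation.tsv,
    hydropathy_toy.tsv, truth.json and (when a break is planted) variants.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structure, truth = make_toy_channel(spec)
    write_structure(structure, out / "structure.pdb")
    write_annotation(toy_annotation(structure), out / "annotation.tsv")
    toy_hydropathy_table(truth).to_file(out / "hydropathy_toy.tsv")
    truth.to_json(out / "truth.json")
    if truth.soc_break is not None:
        rows = toy_variant_sites(structure, truth)
        with open(out / "variants.tsv", "w") as fh:
            fh.write("residue_number\twt_aa\tmut_aa\tlabel\n")
            for rid, label in rows:
                fh.write(f"{rid}\tG\tA\t{label}\n")
    return truth
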