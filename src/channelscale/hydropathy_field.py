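"""Cumulative hydropathic moment fields and their zero-crossing topology.

The zero-order moment h0(p, l) is the sum of (noise-perturbed) per-atom
hydropathy indices inside the sampling sphere; the hydropathic density is
m0 = h0/N.  The first-order moment h1(p, l) = sum HI_i (c_i - p) quantifies
the hydropathic imbalance; its axial per-atom component m1_z = h1_z/N is the
axial interaction-strength field whose sign defines the "in" (toward the
intracellular side, m1_z > 0) and "out" orientation states.  Zero crossings
of a field over the (p, alpha) map partition it into sign-consistent domains
(hydrophobic patch vs hydrophilic surroundings for m0; orientation domains
for m1_z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .packing_cdf import SamplingGrid, sampling_radii
from .pore_geometry import PorePath, PorePoint
from .structure_io import Structure, StructureError

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _require_noisy(structure: Structure) -> np.ndarray:
    if np.any(np.isnan(structure.hi_noisy)):
        raise StructureError("hi_noisy not assigned; run add_index_noise first")
    return structure.hi_noisy


def _cumulative(structure: Structure, p: np.ndarray, radii: np.ndarray):
    """Counts and cumulative HI / HI*(c-p) sums inside each sphere."""
    hiw = _require_noisy(structure)
    offsets = structure.coords - p
    d = np.linalg.norm(offsets, axis=1)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    idx = np.searchsorted(d_sorted, radii, side="right")
    cum_h = np.concatenate([[0.0], np.cumsum(hiw[order])])
    cum_m = np.concatenate([np.zeros((1, 3)), np.cumsum(hiw[order, None] * offsets[order], axis=0)])
    return idx, cum_h[idx], cum_m[idx]


@dataclass
class MomentProfile:
    """Moment functions of one pore point along the sampling radii.

    Cells with N = 0 are undefined and carried as NaN (never 0/0).
    """

    p_index: int
    radii: np.ndarray
    counts: np.ndarray
    h0: np.ndarray
    m0: np.ndarray
    h1: np.ndarray  # (K, 3)
    m1_z: np.ndarray

    @property
    def h1_z(self) -> np.ndarray:
        return self.h1[:, 2]

    @property
    def h1_xy_norm(self) -> np.ndarray:
        return np.linalg.norm(self.h1[:, :2], axis=1)

    @property
    def orientation(self) -> np.ndarray:
        """'in' where m1_z > 0 (toward the intracellular side), 'out' where
        m1_z < 0, '' where undefined."""
        out = np.where(self.m1_z > 0, "in", "out").astype(object)
        out[~np.isfinite(self.m1_z)] = ""
        return out


def moment0(structure: Structure, p: PorePoint, grid: SamplingGrid):
    """Zero-order cumulative hydropathic moment h0 and density m0 = h0/N."""
    counts, h0, _ = _cumulative(structure, p.position, grid.radii)
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = np.where(counts > 0, h0 / np.maximum(counts, 1), np.nan)
    h0 = np.where(counts > 0, h0, np.nan)
    return h0, m0


def moment1(structure: Structure, p: PorePoint, grid: SamplingGrid):
    """First-order cumulative moment h1 (vector), axial density m1_z and the
    per-alpha orientation state."""
    counts, _, h1 = _cumulative(structure, p.position, grid.radii)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1_z = np.where(counts > 0, h1[:, 2] / np.maximum(counts, 1), np.nan)
    h1 = np.where(counts[:, None] > 0, h1, np.nan)
    orientation = np.where(m1_z > 0, "in", "out").astype(object)
    orientation[~np.isfinite(m1_z)] = ""
    return h1, m1_z, orientation


def moment_profile(structure: Structure, p: PorePoint, grid: SamplingGrid) -> MomentProfile:
    counts, h0, h1 = _cumulative(structure, p.position, grid.radii)
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = np.where(counts > 0, h0 / np.maximum(counts, 1), np.nan)
        m1_z = np.where(counts > 0, h1[:, 2] / np.maximum(counts, 1), np.nan)
    return MomentProfile(
        p_index=p.index,
        radii=grid.radii,
        counts=counts,
        h0=np.where(counts > 0, h0, np.nan),
        m0=m0,
        h1=np.where(counts[:, None] > 0, h1, np.nan),
        m1_z=m1_z,
    )


@dataclass
class FieldMaps:
    """Rectangular (pore point x alpha) grids of the moment fields."""

    radii: np.ndarray  # (M, K)
    counts: np.ndarray
    h0: np.ndarray
    m0: np.ndarray
    h1_z: np.ndarray
    h1_xy_norm: np.ndarray
    m1_z: np.ndarray
    grids: list[SamplingGrid] = field(default_factory=list)
    profiles: list[MomentProfile] = field(default_factory=list)


def field_map(structure: Structure, path: PorePath, k_alpha: int = 800) -> FieldMaps:
    """Compute m0 and m1_z (plus carriers) over the full (p, alpha) map."""
    grids = [sampling_radii(p, k_alpha) for p in path]
    profiles = [moment_profile(structure, p, g) for p, g in zip(path, grids)]
    stack = lambda attr: np.vstack([getattr(pr, attr) for pr in profiles])
    return FieldMaps(
        radii=np.vstack([g.radii for g in grids]),
        counts=stack("counts"),
        h0=stack("h0"),
        m0=stack("m0"),
        h1_z=np.vstack([pr.h1[:, 2] for pr in profiles]),
        h1_xy_norm=stack("h1_xy_norm"),
        m1_z=stack("m1_z"),
        grids=grids,
        profiles=profiles,
    )


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------
@dataclass
class ZeroCrossing:
    """Sign change between alpha cells (alpha, alpha+1) of row p_index, with
    the linearly interpolated crossing radius l*."""

    p_index: int
    alpha: int  # 0-based index of the left cell
    l_star: float


@dataclass
class Domain:
    label: str
    sign: int
    n_cells: int
    area_fraction: float
    touches_pore: bool


@dataclass
class TopologyMap:
    field_id: str
    signs: np.ndarray  # (M, K): +1 / -1, 0 where undefined
    labels: np.ndarray  # (M, K) int domain ids, 0 where undefined
    domains: list[Domain]
    zero_crossings: list[ZeroCrossing]

    def domain_of(self, label: str) -> Domain:
        for d in self.domains:
            if d.label == label:
                return d
        raise KeyError(label)


def detect_topology(
    grid: np.ndarray,
    radii: np.ndarray | None = None,
    field_id: str = "field",
) -> TopologyMap:
    """Zero-crossing/domain decomposition of a (p, alpha) field.

    Crossings are sign changes between adjacent alpha cells of one row, with
    l* linearly interpolated from the cell radii; domains are 4-connected
    components of same-sign cells, labelled T1, T2, ... by descending area
    (ties by first cell in row-major order).  Undefined (NaN) cells are
    excluded.  Exactly-zero cells side with the positive sign.
    """
    f = np.asarray(grid, dtype=float)
    if f.ndim != 2 or f.shape[0] < 1 or f.shape[1] < 2:
        raise ValueError("field grid must be 2-D with at least 2 alpha columns")
    defined = np.isfinite(f)
    signs = np.zeros(f.shape, dtype=int)
    signs[defined & (f >= 0)] = 1
    signs[defined & (f < 0)] = -1

    crossings: list[ZeroCrossing] = []
    for i in range(f.shape[0]):
        row = signs[i]
        ok = (row[:-1] != 0) & (row[1:] != 0) & (row[:-1] != row[1:])
        for j in np.nonzero(ok)[0]:
            y0, y1 = f[i, j], f[i, j + 1]
            if radii is not None:
                x0, x1 = radii[i, j], radii[i, j + 1]
            else:
                x0, x1 = float(j), float(j + 1)
            frac = y0 / (y0 - y1) if y0 != y1 else 0.5
            crossings.append(ZeroCrossing(p_index=i, alpha=int(j), l_star=float(x0 + frac * (x1 - x0))))

    labels = np.zeros(f.shape, dtype=int)
    comps: list[tuple[int, np.ndarray]] = []  # (sign, mask)
    offset = 0
    for sgn in (1, -1):
        lab, n = ndimage.label(signs == sgn, structure=_FOUR_CONN)
        for k in range(1, n + 1):
            mask = lab == k
            labels[mask] = offset + k
            comps.append((sgn, mask))
        offset += n

    # first defined cell per row marks the pore-lining low-alpha band
    first_defined = np.full(f.shape[0], -1)
    for i in range(f.shape[0]):
        nz = np.nonzero(defined[i])[0]
        if len(nz):
            first_defined[i] = nz[0]

    n_defined = int(defined.sum())
    order = sorted(
        range(len(comps)),
        key=lambda k: (-int(comps[k][1].sum()), int(np.flatnonzero(comps[k][1].ravel())[0])),
    )
    domains: list[Domain] = []
    relabel = np.zeros(offset + 1, dtype=int)
    for rank, k in enumerate(order, start=1):
        sgn, mask = comps[k]
        touches = any(
            first_defined[i] >= 0 and mask[i, first_defined[i]] for i in range(f.shape[0])
        )
        domains.append(
            Domain(
                label=f"T{rank}",
                sign=sgn,
                n_cells=int(mask.sum()),
                area_fraction=float(mask.sum()) / max(n_defined, 1),
                touches_pore=touches,
            )
        )
    # relabel components to match the sorted domain order
    new_labels = np.zeros_like(labels)
    for rank, k in enumerate(order, start=1):
        new_labels[comps[k][1]] = rank
    return TopologyMap(
        field_id=field_id,
        signs=signs,
        labels=new_labels,
        domains=domains,
        zero_crossings=crossings,
    )


def hp_boundary(topology: TopologyMap, hydrophobic_sign: int = 1) -> list[ZeroCrossing]:
    """Boundary elements of the hydrophobic-patch domains.

    Keeps the zero crossings adjacent to hydrophobic domains that touch the
    pore-lining low-alpha band; an empty result (no hydrophobic patch) is
    reported with a warning.
    """
    hp_ranks = {
        int(d.label[1:])
        for d in topology.domains
        if d.sign == np.sign(hydrophobic_sign) and d.touches_pore
    }
    if not hp_ranks:
        warnings.warn("no hydrophobic pore-lining domain found; boundary is empty", stacklevel=2)
        return []
    out = []
    for c in topology.zero_crossings:
        l1 = topology.labels[c.p_index, c.alpha]
        l2 = topology.labels[c.p_index, c.alpha + 1]
        if l1 in hp_ranks or l2 in hp_ranks:
            out.append(c)
    return out
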