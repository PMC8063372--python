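"""Mutation-site placement, map projection and distance scores.

Each variant site (a residue carrying one or more missense substitutions,
labelled pain-related or neutral) is represented structurally by its
wild-type residue's heavy-atom centroid, projected onto the (p, alpha) map
via its nearest pore point, and scored by (a) the median distance from the
hydrophobic-patch boundary treated as a family of spherical loci, (b) the
distance from the critical-sphere surface around the selectivity filter and
(c) their weighted average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydropathy_field import FieldMaps, ZeroCrossing
from .pore_geometry import PorePath
from .scaling_criticality import CriticalPoint
from .structure_io import Structure

logger = logging.getLogger(__name__)

LABELS = ("pain", "neutral")


@dataclass
class MutationSite:
    """A distinct (residue, label) mutation site.

    Multiple substitutions at one residue collapse to a single mapped site;
    the individual substitutions remain listed in ``substitutions``.
    """

    residue_number: int
    label: str
    substitutions: list[tuple[str, str]] = field(default_factory=list)
    site_position: np.ndarray | None = None
    map_coord: tuple[int, int] | None = None  # (p_index, alpha: 1-based)
    dist3d: float = np.nan  # 3-D distance to the mapped pore point

    @property
    def n_variants(self) -> int:
        return len(self.substitutions)


@dataclass
class DistanceScores:
    site: MutationSite
    d_hp: float
    d_hp_lo: float
    d_hp_hi: float
    d_sf: float
    d_weighted: float


@dataclass
class OccupancyHistogram:
    axis: str  # 'alpha' or 'p'
    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]
    rates: dict[str, np.ndarray]


def parse_variants(path) -> list[MutationSite]:
    """Read a variant table (residue_number, wt_aa, mut_aa, label).

    Rows collapse to one site per distinct (residue_number, label); the
    per-site substitution list keeps every row for classification-side
    bookkeeping.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue_number", "wt_aa", "mut_aa", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    sites: dict[tuple[int, str], MutationSite] = {}
    for row in df.itertuples(index=False):
        label = str(row.label).strip().lower()
        if label not in LABELS:
            raise ValueError(f"unknown variant label {row.label!r} (expected one of {LABELS})")
        key = (int(row.residue_number), label)
        site = sites.setdefault(key, MutationSite(residue_number=key[0], label=label))
        site.substitutions.append((str(row.wt_aa).strip(), str(row.mut_aa).strip()))
    out = sorted(sites.values(), key=lambda s: (s.residue_number, s.label))
    counts = label_counts(out)
    logger.info("parsed %d mutation sites (%s)", len(out), counts)
    return out


def label_counts(sites: list[MutationSite]) -> dict[str, int]:
    return {lab: sum(1 for s in sites if s.label == lab) for lab in LABELS}


def locate_site(structure: Structure, residue_number: int, mode: str = "heavy_centroid") -> np.ndarray:
    """Representative structural location of a residue.

    ``heavy_centroid`` (default): geometric center of the heavy atoms;
    ``ca``: the alpha-carbon; ``all_atom``: all-atom centroid.
    """
    mask = structure.residue_number == residue_number
    if not mask.any():
        raise KeyError(f"residue {residue_number} not present in the structure")
    if mode == "ca":
        sel = mask & (structure.atom_name == "CA")
        if not sel.any():
            raise ValueError(f"residue {residue_number} has no CA atom")
        return structure.coords[sel][0].copy()
    if mode == "heavy_centroid":
        sel = mask & (structure.element != "H")
        if not sel.any():
            raise ValueError(f"residue {residue_number} has no heavy atoms")
        return structure.coords[sel].mean(axis=0)
    if mode == "all_atom":
        return structure.coords[mask].mean(axis=0)
    raise ValueError(f"unknown site mode {mode!r}")


def map_site(site: MutationSite, path: PorePath, maps: FieldMaps) -> MutationSite:
    """Project the site onto the (p, alpha) map.

    p* is the nearest pore point; alpha is the smallest sampling index whose
    radius reaches the site (inclusive boundary), clamped to K_alpha with a
    warning when the site lies beyond L(p*).  The 3-D distance to p* is
    recorded for the map-offset diagnostics.
    """
    if site.site_position is None:
        raise ValueError("site has no structural position; call locate_site first")
    pos = np.asarray(site.site_position, dtype=float)
    d = np.linalg.norm(path.positions - pos, axis=1)
    p_idx = int(np.argmin(d))
    dist = float(d[p_idx])
    radii = maps.radii[p_idx]
    j = int(np.searchsorted(radii, dist, side="left"))
    if j >= len(radii):
        logger.warning(
            "site at residue %d lies beyond L(p*) (%.2f > %.2f Å); clamped to K_alpha",
            site.residue_number, dist, radii[-1],
        )
        j = len(radii) - 1
    site.map_coord = (p_idx, j + 1)  # alpha is 1-based
    site.dist3d = dist
    return site


def occupancy(sites: list[MutationSite], axis: str = "alpha", bins: int | np.ndarray = 10) -> OccupancyHistogram:
    """Per-label map occupancy histograms along alpha or along p."""
    if axis not in ("alpha", "p"):
        raise ValueError("axis must be 'alpha' or 'p'")
    values = {
        lab: np.array(
            [s.map_coord[1] if axis == "alpha" else s.map_coord[0] for s in sites if s.label == lab and s.map_coord],
            dtype=float,
        )
        for lab in LABELS
    }
    allv = np.concatenate([v for v in values.values() if len(v)]) if any(len(v) for v in values.values()) else np.array([0.0])
    edges = np.histogram_bin_edges(allv, bins=bins)
    counts = {}
    rates = {}
    for lab, v in values.items():
        c, _ = np.histogram(v, bins=edges)
        counts[lab] = c
        if c.sum() == 0:
            logger.warning("zero mapped sites with label %r; occupancy histogram is all-zero", lab)
            rates[lab] = c.astype(float)
        else:
            rates[lab] = c / c.sum()
    return OccupancyHistogram(axis=axis, bin_edges=edges, counts=counts, rates=rates)


def distance_to_hp_boundary(
    site: MutationSite,
    omega0: list[ZeroCrossing],
    path: PorePath,
) -> tuple[float, float, float]:
    """Median (with 2.5/97.5 percentile band) of the distances from the site
    to each boundary element's spherical locus | ||site - p_j|| - l*_j |."""
    if not omega0:
        raise ValueError("empty hydrophobic-patch boundary; score undefined")
    pos = np.asarray(site.site_position, dtype=float)
    pts = np.array([path.points[c.p_index].position for c in omega0])
    lstar = np.array([c.l_star for c in omega0])
    vals = np.abs(np.linalg.norm(pts - pos, axis=1) - lstar)
    return (
        float(np.median(vals)),
        float(np.percentile(vals, 2.5)),
        float(np.percentile(vals, 97.5)),
    )


def distance_to_critical_sphere(site: MutationSite, crit: CriticalPoint) -> float:
    """| ||site - p_crit|| - xi_crit |: distance from the critical sphere."""
    if not crit.found:
        raise ValueError("no critical point located; score undefined")
    pos = np.asarray(site.site_position, dtype=float)
    return float(abs(np.linalg.norm(pos - crit.position) - crit.xi_crit))


def weighted_score(d_hp: float, d_sf: float, w: float = 0.5) -> float:
    """w * d_hp + (1 - w) * d_sf for w in [0, 1]."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("weight w must lie in [0, 1]")
    return w * d_hp + (1.0 - w) * d_sf


def score_sites(
    sites: list[MutationSite],
    omega0: list[ZeroCrossing],
    crit: CriticalPoint,
    path: PorePath,
    w: float = 0.5,
) -> list[DistanceScores]:
    """All three distance scores for every site with a structural position."""
    out = []
    for site in sites:
        if site.site_position is None:
            logger.warning("site %d has no structural position; excluded from scoring", site.residue_number)
            continue
        d_hp, lo, hi = distance_to_hp_boundary(site, omega0, path)
        d_sf = distance_to_critical_sphere(site, crit)
        out.append(
            DistanceScores(
                site=site, d_hp=d_hp, d_hp_lo=lo, d_hp_hi=hi, d_sf=d_sf,
                d_weighted=weighted_score(d_hp, d_sf, w),
            )
        )
    return out


def scores_to_dataframe(scores: list[DistanceScores]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue_number": [s.site.residue_number for s in scores],
            "label": [s.site.label for s in scores],
            "n_variants": [s.site.n_variants for s in scores],
            "d_hp": [s.d_hp for s in scores],
            "d_hp_lo": [s.d_hp_lo for s in scores],
            "d_hp_hi": [s.d_hp_hi for s in scores],
            "d_sf": [s.d_sf for s in scores],
            "d_weighted": [s.d_weighted for s in scores],
            "dist3d": [s.site.dist3d for s in scores],
        }
    )
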