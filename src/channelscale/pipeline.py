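"""End-to-end orchestration: prepare -> pore -> scan -> mapfield ->
criticality -> score -> classify, with a manifest of every parameter and
seed.  Each stage writes its outputs before the next starts, so a failure
preserves the completed stages and names the failing one."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .annotation import read_annotation
from .classify import optimal_threshold, roc_curve
from .hydropathy_field import detect_topology, field_map, hp_boundary
from .packing_cdf import fit_sigmoid, pm_vs_transition, sampling_radii, atomic_cdf, summarize_profiles
from .pore_geometry import trace_pore
from .scaling_criticality import locate_critical_point
from .structure_io import (
    HydropathyTable,
    add_index_noise,
    assign_properties,
    center_and_align,
    read_structure,
    write_atom_table,
)
from .variant_mapping import (
    label_counts,
    locate_site,
    map_site,
    parse_variants,
    score_sites,
    scores_to_dataframe,
)

logger = logging.getLogger(__name__)

STAGES = ("prepare", "pore", "scan", "mapfield", "criticality", "score", "classify")


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs remain on disk."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Flat run configuration; serialised verbatim into the manifest."""

    structure: str
    annotation: str
    out_dir: str
    variants: str | None = None
    hydropathy_table: str | None = None  # None -> shipped resource
    seed: int = 0
    sigma: float = 0.001
    k_alpha: int = 800
    spacing: float = 1.0
    search_radius: float = 5.0
    sf_window: float = 6.0
    weight: float = 0.5
    hydrophobic_sign: int = 1
    strict_lookup: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` text config."""
        values: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in values:
                continue
            raw = values[f.name]
            if f.name in ("seed", "k_alpha", "hydrophobic_sign"):
                kwargs[f.name] = int(raw)
            elif f.name in ("sigma", "spacing", "search_radius", "sf_window", "weight"):
                kwargs[f.name] = float(raw)
            elif f.name == "strict_lookup":
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = raw if raw.lower() != "none" else None
        return cls(**kwargs)

    def to_manifest(self) -> dict:
        return dataclasses.asdict(self)


def _write_matrix(path: Path, matrix: np.ndarray) -> None:
    np.savetxt(path, matrix, delimiter="\t", fmt="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_manifest(), "version": __version__, "stages": []}
    summary: dict = {}

    def stage_done(name: str) -> None:
        manifest["stages"].append(name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    # ---- prepare ----------------------------------------------------------
    try:
        annotation = read_annotation(config.annotation)
        structure = read_structure(config.structure)
        table = (
            HydropathyTable.from_file(config.hydropathy_table, hydrophobic_sign=config.hydrophobic_sign)
            if config.hydropathy_table
            else HydropathyTable.from_file(hydrophobic_sign=config.hydrophobic_sign)
        )
        assign_properties(structure, table=table, strict=config.strict_lookup)
        add_index_noise(structure, sigma=config.sigma, seed=config.seed)
        center_and_align(structure, pore_axis_hint=annotation.pore_axis_hint, es_end=annotation.es_end)
        write_atom_table(structure, out / "prepared_atoms.tsv")
        manifest["frame_rotation"] = structure.frame_rotation.tolist()
        manifest["frame_translation"] = structure.frame_translation.tolist()
        summary["n_atoms"] = structure.n_atoms
    except Exception as exc:  # noqa: BLE001
        raise StageError("prepare", exc) from exc
    stage_done("prepare")

    # ---- pore -------------------------------------------------------------
    try:
        z_range = annotation.pore_z_range(structure, pad=1.0)
        path = trace_pore(
            structure, spacing=config.spacing, search_radius=config.search_radius, z_range=z_range
        )
        path.to_dataframe().to_csv(out / "pore.tsv", sep="\t", index=False, float_format="%.3f")
        summary["n_pore_points"] = len(path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("pore", exc) from exc
    stage_done("pore")

    # ---- scan -------------------------------------------------------------
    try:
        grids = [sampling_radii(p, config.k_alpha) for p in path]
        cdfs = [atomic_cdf(structure, p, g) for p, g in zip(path, grids)]
        fits = [fit_sigmoid(c, g) for c, g in zip(cdfs, grids)]
        roles = annotation.roles(structure)
        transitions = [
            pm_vs_transition(structure, p, g, annotation, roles=roles)
            for p, g in zip(path, grids)
        ]
        counts = np.vstack([c.counts for c in cdfs])
        _write_matrix(out / "cdf_counts.tsv", counts)
        _write_matrix(out / "cdf_normalized.tsv", counts / structure.n_atoms)
        with open(out / "fits.tsv", "w") as fh:
            fh.write("p_index\tfamily\tA\tt\ts\tq_tilde\txi\to\trss\taic\tconverged\tnu\n")
            for f, t in zip(fits, transitions):
                nu = format(t.nu, ".6g") if t.defined else "nan"
                fh.write(
                    f"{f.p_index}\t{f.family}\t{f.A:.6g}\t{f.t:.6g}\t{f.s:.6g}\t"
                    f"{'' if f.q_tilde is None else format(f.q_tilde, '.6g')}\t{f.xi:.6g}\t{f.o:.6g}\t"
                    f"{f.rss:.6g}\t{f.aic:.6g}\t{int(f.converged)}\t{nu}\n"
                )
        descriptors = summarize_profiles(
            fits, transitions, grids, normalized_cdf=counts / structure.n_atoms
        )
        summary["s_median"] = descriptors.s_median
        summary["xi_median"] = descriptors.xi_median
        summary["o_median"] = descriptors.o_median
        summary["nu_median"] = descriptors.nu_median
    except Exception as exc:  # noqa: BLE001
        raise StageError("scan", exc) from exc
    stage_done("scan")

    # ---- mapfield ---------------------------------------------------------
    try:
        maps = field_map(structure, path, k_alpha=config.k_alpha)
        _write_matrix(out / "m0.tsv", maps.m0)
        _write_matrix(out / "m1z.tsv", maps.m1_z)
        topo0 = detect_topology(maps.m0, radii=maps.radii, field_id="m0")
        topo1 = detect_topology(maps.m1_z, radii=maps.radii, field_id="m1z")
        omega0 = hp_boundary(topo0, hydrophobic_sign=config.hydrophobic_sign)
        for name, topo in (("omega0", topo0), ("omega1", topo1)):
            with open(out / f"{name}.tsv", "w") as fh:
                fh.write("p_index\talpha\tl_star\tfield_id\n")
                for c in topo.zero_crossings:
                    fh.write(f"{c.p_index}\t{c.alpha}\t{c.l_star:.4f}\t{topo.field_id}\n")
        with open(out / "domains.tsv", "w") as fh:
            fh.write("field_id\tlabel\tsign\tn_cells\tarea_fraction\ttouches_pore\n")
            for topo in (topo0, topo1):
                for d in topo.domains:
                    fh.write(
                        f"{topo.field_id}\t{d.label}\t{d.sign}\t{d.n_cells}\t"
                        f"{d.area_fraction:.6f}\t{int(d.touches_pore)}\n"
                    )
        summary["n_hp_boundary"] = len(omega0)
        summary["n_domains_m0"] = len(topo0.domains)
        summary["n_domains_m1z"] = len(topo1.domains)
    except Exception as exc:  # noqa: BLE001
        raise StageError("mapfield", exc) from exc
    stage_done("mapfield")

    # ---- criticality ------------------------------------------------------
    try:
        sf_center = annotation.sf_center(structure)
        crit = locate_critical_point(
            path, fits, maps.m1_z, maps.radii, sf_center, window=config.sf_window
        )
        crit_record = {
            "found": crit.found,
            "reason": crit.reason,
            "p_index": crit.p_index,
            "position": None if crit.position is None else crit.position.tolist(),
            "xi_crit": crit.xi_crit,
            "gamma_part1": crit.gamma_part1,
            "gamma_part2": crit.gamma_part2,
            "marfe_part1": crit.marfe_part1,
            "marfe_part2": crit.marfe_part2,
        }
        (out / "criticality.json").write_text(json.dumps(crit_record, indent=1))
        summary["critical_point"] = crit_record
    except Exception as exc:  # noqa: BLE001
        raise StageError("criticality", exc) from exc
    stage_done("criticality")

    if config.variants is None:
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        return summary

    # ---- score ------------------------------------------------------------
    try:
        sites = parse_variants(config.variants)
        mappable = []
        unmappable = []
        for site in sites:
            try:
                site.site_position = locate_site(structure, site.residue_number)
            except KeyError:
                unmappable.append(site.residue_number)
                continue
            map_site(site, path, maps)
            mappable.append(site)
        if unmappable:
            logger.warning("%d variant residues absent from the structure: %s", len(unmappable), unmappable)
        scores = score_sites(mappable, omega0, crit, path, w=config.weight)
        df = scores_to_dataframe(scores)
        df.to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.4f")
        summary["n_sites"] = label_counts(mappable)
        summary["n_unmappable"] = len(unmappable)
    except Exception as exc:  # noqa: BLE001
        raise StageError("score", exc) from exc
    stage_done("score")

    # ---- classify ---------------------------------------------------------
    try:
        roc_records = {}
        for score_name in ("d_hp", "d_sf", "d_weighted"):
            roc = roc_curve(df[score_name].to_numpy(), df["label"].to_numpy(), score_name=score_name)
            opt = optimal_threshold(roc)
            roc_records[score_name] = {
                "auc": roc.auc,
                "n_pos": roc.n_pos,
                "n_neg": roc.n_neg,
                "optimal_threshold": opt.threshold,
                "sensitivity": opt.sensitivity,
                "specificity": opt.specificity,
                "confusion": {"tp": opt.tp, "fn": opt.fn, "tn": opt.tn, "fp": opt.fp},
            }
            with open(out / f"roc_{score_name}.tsv", "w") as fh:
                fh.write("threshold\tsensitivity\tspecificity\n")
                for th, se, sp in zip(roc.thresholds, roc.sensitivity, roc.specificity):
                    fh.write(f"{th:.6g}\t{se:.6f}\t{sp:.6f}\n")
        (out / "roc_summary.json").write_text(json.dumps(roc_records, indent=1))
        summary["roc"] = roc_records
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc
    stage_done("classify")

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
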