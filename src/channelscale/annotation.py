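"""Segment annotation: residue ranges for pore modules, voltage sensors and
the selectivity filter, plus the extracellular-end convention.

The on-disk form is a TSV with columns (segment_id, res_start, res_end, role)
where role is one of PM (pore-module helices S5-S6), VS (voltage-sensor
helices S1-S4) or SF (selectivity-filter residues).  Directive lines of the
form ``#es_end=low_z`` and ``#pore_axis=x,y,z`` carry the frame hints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ROLES = ("PM", "VS", "SF")


@dataclass
class SegmentRange:
    segment_id: str  # chain or domain label; '*' matches any
    res_start: int
    res_end: int
    role: str


@dataclass
class SegmentAnnotation:
    segments: list[SegmentRange] = field(default_factory=list)
    es_end: str = "low_z"  # which z end of the input frame is extracellular
    pore_axis_hint: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def role_of(self, residue_number: int, segment_id: str | None = None) -> str | None:
        for seg in self.segments:
            if seg.res_start <= residue_number <= seg.res_end and (
                segment_id is None or seg.segment_id == "*" or seg.segment_id == segment_id
            ):
                return seg.role
        return None

    def roles(self, structure) -> np.ndarray:
        """Per-atom role array ('PM'/'VS'/'SF'/'') for a Structure."""
        out = np.empty(structure.n_atoms, dtype=object)
        cache: dict[tuple[str, int], str] = {}
        for i in range(structure.n_atoms):
            key = (str(structure.segment_id[i]), int(structure.residue_number[i]))
            if key not in cache:
                cache[key] = self.role_of(key[1], key[0]) or ""
            out[i] = cache[key]
        return out

    def sf_center(self, structure) -> np.ndarray:
        """Geometric center of the selectivity-filter residues' atoms."""
        mask = self.roles(structure) == "SF"
        if not mask.any():
            raise ValueError("annotation defines no SF residues present in the structure")
        return structure.coords[mask].mean(axis=0)

    def pore_z_range(self, structure, pad: float = 0.0) -> tuple[float, float]:
        """z range covered by pore-lining (PM and SF) residues."""
        roles = self.roles(structure)
        mask = (roles == "PM") | (roles == "SF")
        if not mask.any():
            raise ValueError("annotation defines no pore-module residues present in the structure")
        z = structure.coords[mask, 2]
        return float(z.min() + pad), float(z.max() - pad)


def read_annotation(path: str | Path) -> SegmentAnnotation:
    ann = SegmentAnnotation()
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("es_end="):
                    ann.es_end = body.split("=", 1)[1].strip()
                elif body.startswith("pore_axis="):
                    ann.pore_axis_hint = tuple(float(v) for v in body.split("=", 1)[1].split(","))
                continue
            if not header_seen:
                header_seen = True
                continue
            seg, start, end, role = line.split("\t")
            role = role.strip().upper()
            if role not in ROLES:
                raise ValueError(f"unknown segment role {role!r} (expected one of {ROLES})")
            ann.segments.append(SegmentRange(seg.strip(), int(start), int(end), role))
    if not ann.segments:
        raise ValueError(f"annotation file {path} contains no segment rows")
    return ann


def write_annotation(ann: SegmentAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#es_end={ann.es_end}\n")
        fh.write("#pore_axis=" + ",".join(str(v) for v in ann.pore_axis_hint) + "\n")
        fh.write("segment_id\tres_start\tres_end\trole\n")
        for seg in ann.segments:
            fh.write(f"{seg.segment_id}\t{seg.res_start}\t{seg.res_end}\t{seg.role}\n")
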