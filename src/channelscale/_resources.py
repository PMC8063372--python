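"""Loading of the shipped per-atom property resources (mass, vdW, hydropathy)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def _data_path(name: str) -> Path:
    return Path(resources.files("channelscale").joinpath("data", name))


def load_element_table(name: str, path: str | Path | None = None) -> dict[str, float]:
    """Read an element-keyed value table (``element<TAB>value`` with header)."""
    p = Path(path) if path is not None else _data_path(name)
    table: dict[str, float] = {}
    with open(p) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            key, value = line.split("\t")
            table[key.upper()] = float(value)
    return table


def load_masses(path: str | Path | None = None) -> dict[str, float]:
    return load_element_table("atomic_masses.tsv", path)


def load_vdw_radii(path: str | Path | None = None) -> dict[str, float]:
    return load_element_table("vdw_radii.tsv", path)


def hydropathy_resource_path() -> Path:
    return _data_path("hydropathy_synthetic.tsv")


def variants_resource_path() -> Path:
    return _data_path("scn9a_variants_synthetic.tsv")
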