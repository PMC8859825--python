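"""File formats, packaged data access, run configuration and reporting.

PMF tables travel as whitespace-delimited two-column text with '#'-prefixed
header lines carrying the bead name, facet, units (kT or kJ/mol, converted on
load with kT(300 K) = 2.494 kJ/mol) and cutoff. Material and bead databases
are YAML; reports are CSV/TSV plus a JSON run manifest, written
deterministically so identical inputs yield byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants
from .potentials import HamakerMaterial, SurfacePMFTable

__all__ = [
    "packaged_data_path",
    "read_pmf_table",
    "write_pmf_table",
    "load_materials",
    "load_table1",
    "load_table2",
    "RunConfig",
    "report",
]


def packaged_data_path(name: str):
    """Path to a data file shipped inside the package."""
    return resources.files("uamodel.data") / name


def read_pmf_table(path) -> SurfacePMFTable:
    """Parse a tabulated surface potential file, normalizing units to kT."""
    header: dict[str, str] = {}
    hs: list[float] = []
    vs: list[float] = []
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip().lower()] = val.strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected two columns")
        h, v = float(parts[0]), float(parts[1])
        if not np.isfinite(v) or not np.isfinite(h):
            raise ValueError(f"{path}: line {lineno}: non-finite value")
        if hs and h <= hs[-1]:
            raise ValueError(f"{path}: line {lineno}: grid not strictly increasing")
        hs.append(h)
        vs.append(v)
    for key in ("bead", "facet", "units", "r_c"):
        if key not in header:
            raise ValueError(f"{path}: missing required header key '{key}'")
    units = header["units"].lower()
    values = np.asarray(vs, dtype=float)
    if units in ("kj/mol", "kj_mol", "kjmol"):
        values = values / constants.KT_KJ_PER_MOL_300
    elif units != "kt":
        raise ValueError(f"{path}: unsupported units {header['units']!r}")
    table = SurfacePMFTable(
        bead_name=header["bead"],
        facet=header["facet"],
        grid=np.asarray(hs, dtype=float),
        values=values,
        r_c=float(header["r_c"]),
        zero_ref=header.get("zero_ref", "false").lower() == "true",
    )
    return table


def write_pmf_table(table: SurfacePMFTable, path) -> None:
    lines = [
        f"# bead: {table.bead_name}",
        f"# facet: {table.facet}",
        "# units: kT",
        f"# r_c: {table.r_c:.6g}",
        f"# zero_ref: {str(table.zero_ref).lower()}",
    ]
    for h, v in zip(table.grid, table.values):
        lines.append(f"{h:.9f} {v:.9f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_pmf_dir(pmf_dir, facet: str | None = None) -> dict[str, SurfacePMFTable]:
    """Load every PMF table file (*.dat, *.pmf, *.txt) in a directory.

    Returns tables keyed by bead name, optionally restricted to one facet.
    """
    out: dict[str, SurfacePMFTable] = {}
    for p in sorted(Path(pmf_dir).iterdir()):
        if p.suffix.lower() not in (".dat", ".pmf", ".txt"):
            continue
        table = read_pmf_table(p)
        if facet is not None and table.facet != facet:
            continue
        out[table.bead_name] = table
    return out


def load_materials(path=None) -> dict[str, HamakerMaterial]:
    """Dielectric-material database keyed by material_id."""
    path = path or packaged_data_path("materials.yaml")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    out = {}
    for mid, entry in data["materials"].items():
        out[mid] = HamakerMaterial(
            material_id=mid,
            dielectric=entry.get("dielectric"),
            refractive_index=float(entry["refractive_index"]),
            kind=entry.get("kind", "dielectric"),
            frequency=float(entry["frequency"]),
        )
    return out


def load_table1(path=None) -> pd.DataFrame:
    """Packaged facet hydrophobicity descriptor table (immersion enthalpies)."""
    path = path or packaged_data_path("ag_facet_descriptors.tsv")
    return pd.read_csv(path, sep="\t", dtype={"facet": str})


def load_table2(path=None) -> pd.DataFrame:
    """Packaged protein adsorption benchmark table (ΔG_ads and E_ads columns)."""
    path = path or packaged_data_path("ag_protein_benchmark.tsv")
    return pd.read_csv(path, sep="\t")


@dataclass
class RunConfig:
    """Validated configuration of a screening run."""

    proteins: list[str]
    pmf_dir: str
    shape: str = "sphere"
    radius: float | None = 20.0
    zeta_mV: float = 0.0
    ionic_strength: float = 0.15
    dielectric: float = 78.4
    temperature: float = constants.DEFAULT_TEMPERATURE
    facets: list[str] = field(default_factory=lambda: ["100", "110", "111"])
    facet_weights: dict[str, float] | None = None
    grid_deg: float = 5.0
    out_dir: str = "ua_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in self.proteins:
            if not Path(p).exists():
                raise FileNotFoundError(f"protein file not found: {p}")
        if not Path(self.pmf_dir).is_dir():
            raise FileNotFoundError(f"PMF directory not found: {self.pmf_dir}")
        if self.grid_deg <= 0:
            raise ValueError("grid resolution must be positive")


def _write_heatmap_csv(amap, path) -> None:
    df = pd.DataFrame(
        amap.E,
        index=[f"{np.degrees(t):.1f}" for t in amap.grid.theta_values],
        columns=[f"{np.degrees(p):.1f}" for p in amap.grid.phi_values],
    )
    df.index.name = "theta_deg\\phi_deg"
    df.to_csv(path, float_format="%.6f")


def report(
    out_dir,
    maps: dict[tuple[str, str], "AdsorptionMap"] | None = None,
    rankings: pd.DataFrame | None = None,
    poses: dict[str, str] | None = None,
    contacts: dict[str, list[tuple[str, int, float]]] | None = None,
    manifest: dict | None = None,
) -> list[Path]:
    """Write heatmap CSVs, ranking TSV, pose PDBs and a run manifest.

    Deterministic: identical inputs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (protein_id, facet), amap in sorted((maps or {}).items()):
        p = out / f"heatmap_{protein_id}_{facet}.csv"
        _write_heatmap_csv(amap, p)
        written.append(p)
    if rankings is not None:
        p = out / "ranking.tsv"
        rankings.to_csv(p, sep="\t", index=False, float_format="%.6f")
        written.append(p)
    for protein_id, pdb_text in sorted((poses or {}).items()):
        p = out / f"pose_{protein_id}.pdb"
        p.write_text(pdb_text)
        written.append(p)
    for protein_id, clist in sorted((contacts or {}).items()):
        p = out / f"contacts_{protein_id}.tsv"
        lines = ["residue\tindex\th_nm"]
        lines += [f"{r}\t{i}\t{h:.4f}" for r, i, h in clist]
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    if manifest is not None:
        p = out / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(p)
    return written
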