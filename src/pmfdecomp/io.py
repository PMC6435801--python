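"""Readers and writers for on-disk artifacts.

All artifacts are plain text: free-energy profiles and per-frame energy
tables as TSV with ``#`` metadata headers, conformations as XYZ (bead label,
x, y, z in nm) or CA-only PDB, and run configurations as YAML.  Floats are
written with 17 significant digits so write → read round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fep import PerFrameEnergyTable
from .model import ChainTopology, Conformation
from .wham import FreeEnergyProfile

FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------- profiles

def write_profile(path, profile: FreeEnergyProfile) -> None:
    """Profile TSV: metadata header lines then R_nm / value_kT / stderr_kT."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_K = {profile.temperature:.17g}\n")
        if profile.pressure is not None:
            fh.write(f"# pressure_bar = {profile.pressure:.17g}\n")
        fh.write(f"# component = {profile.component or 'F'}\n")
        if profile.r_ref is not None:
            fh.write(f"# zero_reference_nm = {profile.r_ref:.17g}\n")
        fh.write("R_nm\tvalue_kT\tstderr_kT\n")
        for r, v, e in zip(profile.r, profile.values, profile.errors):
            fh.write(f"{r:.17g}\t{v:.17g}\t{e:.17g}\n")


def read_profile(path) -> FreeEnergyProfile:
    """Parse a profile TSV; malformed headers raise with the line number."""
    meta = {}
    rows = []
    header_seen = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: malformed metadata line {line!r}")
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
                continue
            cols = line.split("\t")
            if not header_seen:
                if cols[:3] != ["R_nm", "value_kT", "stderr_kT"]:
                    raise ValueError(
                        f"{path}:{ln}: expected columns R_nm, value_kT, stderr_kT; got {cols}"
                    )
                header_seen = True
                continue
            if len(cols) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns, got {len(cols)}")
            try:
                rows.append(tuple(float(c) for c in cols))
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric entry in {cols}") from None
    if not header_seen:
        raise ValueError(f"{path}: missing column header line")
    arr = np.array(rows)
    return FreeEnergyProfile(
        r=arr[:, 0], values=arr[:, 1], errors=arr[:, 2],
        r_ref=float(meta["zero_reference_nm"]) if "zero_reference_nm" in meta else None,
        temperature=float(meta.get("temperature_K", 298.0)),
        pressure=float(meta["pressure_bar"]) if "pressure_bar" in meta else None,
        component=meta.get("component", ""),
    )


# ------------------------------------------------------------ energy tables

def write_energy_table(path, table: PerFrameEnergyTable,
                       metadata: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k} = {v}\n")
        table.frame.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_energy_table(path) -> PerFrameEnergyTable:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"cannot parse energy table {path}: {exc}") from exc
    return PerFrameEnergyTable(df)


# ---------------------------------------------------------- histogram sets

def write_histograms(path, hset) -> None:
    """Umbrella histogram TSV: window definitions in the header, counts per bin."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_K = {hset.temperature:.17g}\n")
        for i, w in enumerate(hset.windows):
            fh.write(f"# window_{i} = {w.center:.17g} {w.force_constant:.17g}\n")
        cols = ["bin_left_nm", "bin_right_nm"] + [f"count_{i}" for i in range(len(hset.windows))]
        fh.write("\t".join(cols) + "\n")
        for b in range(hset.counts.shape[1]):
            row = [f"{hset.bin_edges[b]:.17g}", f"{hset.bin_edges[b + 1]:.17g}"]
            row += [f"{c:.17g}" for c in hset.counts[:, b]]
            fh.write("\t".join(row) + "\n")


def read_histograms(path):
    from .sampler import UmbrellaWindow
    from .wham import UmbrellaHistogramSet

    temperature = 298.0
    windows = []
    rows = []
    header_seen = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                key = key.strip()
                if key == "temperature_K":
                    temperature = float(val)
                elif key.startswith("window_"):
                    c, k = val.split()
                    windows.append(UmbrellaWindow(float(c), float(k)))
                continue
            if not header_seen:
                header_seen = True
                continue
            rows.append([float(x) for x in line.split("\t")])
    if not windows or not rows:
        raise ValueError(f"{path}: no windows or counts found")
    arr = np.array(rows)
    edges = np.append(arr[:, 0], arr[-1, 1])
    counts = arr[:, 2:].T
    return UmbrellaHistogramSet(edges, counts, windows, temperature)


# -------------------------------------------------------------- structures

def write_xyz(path, conformations, labels: Optional[Sequence[str]] = None,
              comment: str = "coordinates in nm") -> None:
    """Multi-frame XYZ; one block per conformation, coordinates in nm."""
    if isinstance(conformations, Conformation):
        conformations = [conformations]
    with open(path, "w") as fh:
        for conf in conformations:
            coords = conf.coordinates if isinstance(conf, Conformation) else np.asarray(conf)
            fh.write(f"{len(coords)}\n{comment}\n")
            for i, (x, y, z) in enumerate(coords):
                lab = labels[i] if labels is not None else "CA"
                fh.write(f"{lab} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path) -> list[Conformation]:
    confs = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise ValueError(f"{path}: expected atom count at line {pos + 1}") from None
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame at line {pos + 1}")
        coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        confs.append(Conformation(coords, frame_id=len(confs)))
        pos += 2 + n
    return confs


def write_pdb(path, topology: ChainTopology, conformation: Conformation) -> None:
    """CA-only PDB (one pseudo-residue per bead); coordinates converted to Å."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = conformation.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = conformation.coordinates * 10.0  # nm → Å
    atoms.atom_name = np.array(["CA"] * n)
    atoms.res_name = np.array(["GLY"] * n)
    atoms.res_id = np.arange(1, n + 1)
    atoms.chain_id = np.array(["A"] * n)
    atoms.element = np.array(["C"] * n)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb(path) -> Conformation:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    ca = atoms[atoms.atom_name == "CA"]
    return Conformation(ca.coord / 10.0)  # Å → nm


# ------------------------------------------------------------ configuration

def topology_from_config(cfg: dict) -> ChainTopology:
    """Build a topology from the structured config mapping (see docs)."""
    beads = cfg["beads"]
    bonds = cfg.get("bonds", [])
    angles = cfg.get("angles", [])
    kwargs = dict(
        charges=[b.get("charge", 0.0) for b in beads],
        born_radii=[b["born_radius"] for b in beads],
        lj_sigma=[b.get("lj_sigma", 0.3) for b in beads],
        lj_epsilon=[b.get("lj_epsilon", 0.0) for b in beads],
        surface_tension=[b.get("surface_tension", 0.0) for b in beads],
        bond_atoms=[[b["i"], b["j"]] for b in bonds],
        bond_r0=[b["r0"] for b in bonds],
        bond_k=[b["k"] for b in bonds],
        terminals=tuple(cfg.get("terminals", (0, len(beads) - 1))),
        label=cfg.get("label", "chain"),
    )
    if angles:
        kwargs["angle_atoms"] = [[a["i"], a["j"], a["k"]] for a in angles]
        kwargs["angle_theta0"] = [a["theta0"] for a in angles]
        kwargs["angle_k"] = [a["k_theta"] for a in angles]
    return ChainTopology(**kwargs)


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    # referenced files must exist at validation time
    for key in ("topology_file",):
        if key in cfg and not Path(cfg[key]).exists():
            raise FileNotFoundError(f"{path}: referenced file {cfg[key]!r} does not exist")
    return cfg
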