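"""Coordinate/topology data model and readers/writers for the formats the
pipeline touches: GRO, PDB, XYZ (trajectories), XVG (GROMACS-dialect tables),
CSV topologies.

Unit convention: coordinates are always stored in nm (PDB Ångström are divided
by 10 on read), times in ps, masses in g/mol, charges in units of e. Atom
indexing is 0-based internally and 1-based in file output.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SPECIES = ("protein", "cation", "anion", "water")
AXES = ("LA", "W", "H")


@dataclass
class Topology:
    """Per-atom static attributes of a system.

    Arrays are aligned; ``ids`` are unique 0-based integers. ``marker``
    holds '' or one of 'LA'/'W'/'H'; each axis label, if used at all, must
    occur exactly twice (the two endpoint groups are single atoms) or be
    supplied as groups via :func:`select`.
    """

    ids: np.ndarray
    masses: np.ndarray
    species: np.ndarray
    charges: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    hydrophobic: np.ndarray
    marker: np.ndarray
    elements: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        self.ids = np.asarray(self.ids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        self.charges = np.asarray(self.charges, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.hydrophobic = np.asarray(self.hydrophobic, dtype=bool)
        self.marker = np.asarray(self.marker, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        for name in ("masses", "species", "charges", "resids", "resnames",
                     "hydrophobic", "marker", "elements"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology field {name!r} length mismatch")
        if len(np.unique(self.ids)) != n:
            raise ValueError("atom ids must be unique")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        for ax in AXES:
            cnt = int(np.sum(self.marker == ax))
            if cnt not in (0, 2):
                raise ValueError(
                    f"marker label {ax!r} must occur exactly twice, found {cnt}")

    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    @classmethod
    def simple(cls, n: int, masses=1.0, species="protein", charges=0.0,
               resids=1, resnames="MOL", hydrophobic=False, marker="",
               elements="") -> "Topology":
        """Build a topology broadcasting scalar defaults over n atoms."""
        def bcast(v, dtype=object):
            a = np.asarray(v)
            return np.full(n, v, dtype=dtype) if a.ndim == 0 else np.asarray(v, dtype=dtype)
        return cls(
            ids=np.arange(n),
            masses=bcast(masses, float),
            species=bcast(species),
            charges=bcast(charges, float),
            resids=bcast(resids, int),
            resnames=bcast(resnames),
            hydrophobic=bcast(hydrophobic, bool),
            marker=bcast(marker),
            elements=bcast(elements),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "mass": self.masses, "species": self.species,
            "charge": self.charges, "resid": self.resids,
            "resname": self.resnames, "hydrophobic": self.hydrophobic,
            "marker": self.marker, "element": self.elements,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Topology":
        marker = df.get("marker", pd.Series([""] * len(df))).fillna("")
        elements = df.get("element", pd.Series([""] * len(df))).fillna("")
        return cls(
            ids=df["id"].to_numpy(),
            masses=df["mass"].to_numpy(),
            species=df["species"].to_numpy(),
            charges=df.get("charge", pd.Series(np.zeros(len(df)))).to_numpy(),
            resids=df.get("resid", pd.Series(np.ones(len(df), dtype=int))).to_numpy(),
            resnames=df.get("resname", pd.Series(["MOL"] * len(df))).to_numpy(),
            hydrophobic=df.get("hydrophobic", pd.Series([False] * len(df))).to_numpy(),
            marker=marker.to_numpy(),
            elements=elements.to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "Topology":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class Trajectory:
    """Frames of particle coordinates in a periodic orthorhombic box.

    coords: (n_frames, n_atoms, 3) nm; box: (n_frames, 3) edge lengths nm;
    time: (n_frames,) ps. Raw file coordinates are preserved on read;
    wrapping into the primary box happens only inside operations that need
    minimum-image distances.
    """

    topology: Topology
    coords: np.ndarray
    box: np.ndarray
    time: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords hold {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if self.time is None:
            self.time = np.arange(self.n_frames, dtype=float)
        else:
            self.time = np.asarray(self.time, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class TableSeries:
    """A rectangular numeric table plus provenance metadata."""

    columns: list
    data: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.columns):
            raise ValueError("data width does not match column names")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.columns)


# ---------------------------------------------------------------------------
# coordinate readers / writers


def _detect_format(path, fmt=None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("gro", "pdb", "xyz"):
        return suffix
    raise ValueError(f"cannot auto-detect format from extension of {path!r}")


def read_coordinates(path, fmt: str | None = None,
                     topology: Topology | None = None) -> Trajectory:
    """Read a GRO/PDB/XYZ coordinate file into a Trajectory (nm).

    GRO and PDB go through mdtraj (PDB Å are converted to nm); XYZ uses this
    package's own plain 4-column dialect, which is written in nm. Atom order
    is preserved. If no topology is supplied a minimal one is built (unit
    masses, species 'protein', elements from the file when available).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    if fmt == "xyz":
        return _read_xyz(path, topology)
    if fmt not in ("gro", "pdb"):
        raise ValueError(f"unsupported coordinate format {fmt!r}")
    import mdtraj as md
    try:
        t = md.load(str(path))
    except Exception as exc:  # mdtraj error messages carry the offending record
        raise ValueError(f"malformed {fmt.upper()} file {path}: {exc}") from exc
    coords = np.asarray(t.xyz, dtype=float)  # mdtraj is nm-native
    if t.unitcell_lengths is not None:
        box = np.asarray(t.unitcell_lengths, dtype=float)
    else:
        span = coords.max(axis=(0, 1)) - coords.min(axis=(0, 1))
        box = np.tile(np.maximum(span, 1.0) * 2.0, (t.n_frames, 1))
    if topology is None:
        elements = np.array(
            [a.element.symbol if a.element is not None else ""
             for a in t.topology.atoms], dtype=object)
        masses = np.array(
            [a.element.mass if a.element is not None and a.element.mass > 0
             else 1.0 for a in t.topology.atoms])
        topology = Topology.simple(t.n_atoms)
        topology.elements = elements
        topology.masses = masses
        topology.resids = np.array([a.residue.index + 1 for a in t.topology.atoms])
        topology.resnames = np.array([a.residue.name for a in t.topology.atoms],
                                     dtype=object)
    if topology.n_atoms != t.n_atoms:
        raise ValueError(
            f"topology has {topology.n_atoms} atoms, file has {t.n_atoms}")
    return Trajectory(topology, coords, box, np.asarray(t.time, dtype=float))


def _read_xyz(path, topology=None) -> Trajectory:
    """Plain XYZ series: natoms / comment / element x y z (nm)."""
    frames, names = [], None
    times = []
    with open(path) as fh:
        lines = fh.readlines()
    i, lineno = 0, 0
    n_atoms = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected atom count") from exc
        if n_atoms is None:
            n_atoms = n
        elif n != n_atoms:
            raise ValueError(
                f"{path}:{i + 1}: atom count {n} differs from first frame {n_atoms}")
        comment = lines[i + 1]
        m = re.search(r"t=\s*([-\d.eE+]+)", comment)
        times.append(float(m.group(1)) if m else float(len(frames)))
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}:{i + 2}: truncated frame")
        coords = np.empty((n, 3))
        frame_names = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + j}: malformed XYZ record")
            frame_names.append(parts[0])
            try:
                coords[j] = [float(x) for x in parts[1:4]]
            except ValueError as exc:
                raise ValueError(f"{path}:{i + 3 + j}: non-numeric coordinate") from exc
        names = names or frame_names
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    coords = np.stack(frames)
    span = coords.max(axis=(0, 1)) - coords.min(axis=(0, 1))
    box = np.tile(np.maximum(span, 1.0) * 2.0, (len(frames), 1))
    if topology is None:
        topology = Topology.simple(n_atoms)
        topology.elements = np.asarray(names, dtype=object)
    return Trajectory(topology, coords, box, np.asarray(times))


def write_xyz(traj: Trajectory, path) -> None:
    """Write a Trajectory as a plain XYZ series with coordinates in nm."""
    with open(path, "w") as fh:
        labels = [e if e else "X" for e in traj.topology.elements]
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {f} t= {traj.time[f]:.6f}\n")
            for name, (x, y, z) in zip(labels, traj.coords[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def write_gro(traj: Trajectory, path) -> None:
    """Write a Trajectory as a (possibly multi-frame) GRO file, nm, fixed width."""
    top = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"mabsolkit frame t= {traj.time[f]:.4f}\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            for i in range(traj.n_atoms):
                resid = int(top.resids[i]) % 100000
                resname = str(top.resnames[i])[:5]
                name = (str(top.elements[i]) or str(top.species[i])[:2].upper() or "X")[:5]
                atomid = (int(top.ids[i]) + 1) % 100000  # 1-based in files
                x, y, z = traj.coords[f, i]
                fh.write(f"{resid:5d}{resname:<5s}{name:>5s}{atomid:5d}"
                         f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            bx, by, bz = traj.box[f]
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# XVG (GROMACS dialect)


def read_xvg(path) -> TableSeries:
    """Read an XVG table; '#'/'@' lines are kept as metadata, not data."""
    meta_lines, rows = [], []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#") or s.startswith("@"):
                meta_lines.append(s)
                continue
            parts = s.split()
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ValueError(f"{path}:{lineno}: ragged row "
                                 f"({len(parts)} fields, expected {width})")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    columns = [f"col{i}" for i in range(width)]
    # pull axis labels out of @-metadata when present
    for m in meta_lines:
        if m.startswith("@") and "xaxis" in m and '"' in m:
            columns[0] = m.split('"')[1]
        if m.startswith("@") and "yaxis" in m and '"' in m and width > 1:
            columns[1] = m.split('"')[1]
    return TableSeries(columns, np.array(rows),
                       metadata={"source": str(path), "headers": meta_lines})


def write_xvg(table: TableSeries, path, title: str = "") -> None:
    """Write a TableSeries in the GROMACS pullx XVG dialect."""
    with open(path, "w") as fh:
        fh.write(f"# mabsolkit: {title}\n")
        for key, val in table.metadata.items():
            if key != "headers":
                fh.write(f"# {key}: {val}\n")
        fh.write(f'@    title "{title}"\n')
        fh.write(f'@    xaxis  label "{table.columns[0]}"\n')
        if len(table.columns) > 1:
            fh.write(f'@    yaxis  label "{table.columns[1]}"\n')
        for row in table.data:
            fh.write("  ".join(f"{v:.8g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# selections

_CLAUSE = re.compile(
    r"^\s*(?:(?P<field>species|resname|marker|element)\s*(?:==)?\s*(?P<value>\S+)"
    r"|resid\s+(?P<lo>\d+)(?:\s*(?:to|-)\s*(?P<hi>\d+))?"
    r"|(?:flag\s+)?(?P<flag>hydrophobic)"
    r"|(?P<all>all))\s*$")


def select(topology: Topology, expression: str) -> np.ndarray:
    """Evaluate a predicate over topology fields, returning sorted atom ids.

    Grammar: clauses joined by 'and' / 'or'; clauses are
    ``species <tag>``, ``resname <name>``, ``marker <axis>``,
    ``element <sym>``, ``resid <i> [to <j>]``, ``hydrophobic``, ``all``.
    An empty selection is allowed but warned about.
    """
    tokens = re.split(r"\s+(and|or)\s+", expression.strip())
    masks, ops = [], []
    for tok in tokens:
        if tok in ("and", "or"):
            ops.append(tok)
            continue
        m = _CLAUSE.match(tok)
        if not m:
            unknown = tok.split()[0] if tok.split() else tok
            raise ValueError(f"unknown selection field or clause: {unknown!r}")
        if m.group("all"):
            masks.append(np.ones(topology.n_atoms, dtype=bool))
        elif m.group("flag"):
            masks.append(topology.hydrophobic.copy())
        elif m.group("lo"):
            lo = int(m.group("lo"))
            hi = int(m.group("hi")) if m.group("hi") else lo
            masks.append((topology.resids >= lo) & (topology.resids <= hi))
        else:
            fieldname, value = m.group("field"), m.group("value")
            arr = {"species": topology.species, "resname": topology.resnames,
                   "marker": topology.marker, "element": topology.elements}[fieldname]
            masks.append(np.asarray([str(v) == value for v in arr]))
    mask = masks[0]
    for op, nxt in zip(ops, masks[1:]):
        mask = (mask & nxt) if op == "and" else (mask | nxt)
    ids = np.sort(topology.ids[mask])
    if len(ids) == 0:
        warnings.warn(f"selection {expression!r} matched no atoms")
    return ids
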