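"""Structures, trajectories and tabular output.

All coordinates are stored in nanometres (the GRO convention); PDB input is
converted from angstroms on read.  Boxes are orthorhombic ``(Lx, Ly, Lz)``;
triclinic input raises :class:`UnsupportedFeatureError` because every analysis
in this package relies on orthorhombic minimum-image arithmetic.

Three trajectory dialects are supported:

* repeated GRO blocks, with the frame time read from a ``t=`` token on the
  title line (in ps, converted to ns, matching the GRO convention);
* multi-frame XYZ text whose comment line carries ``t=<ns>`` and
  ``box=<Lx> <Ly> <Lz>`` tokens;
* a simple binary frame stream (magic ``MTRJ``, little-endian: uint32 version,
  uint32 n_atoms, then per frame one float64 time (ns), three float64 box
  lengths (nm) and ``3*n_atoms`` float64 coordinates (nm)).

Atom indices are 0-based internally; the 1-based numbering of the file
dialects is applied only on read/write.
"""

from __future__ import annotations

import io as _io
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "AtomSelection",
    "ParseError",
    "StructureError",
    "UnsupportedFeatureError",
    "read_structure",
    "read_trajectory",
    "iter_frames",
    "write_structure",
    "write_trajectory",
    "write_binary_trajectory",
    "write_tsv",
    "read_tsv",
]

_BINARY_MAGIC = b"MTRJ"
_BINARY_VERSION = 1


class ParseError(ValueError):
    """Malformed record in a structure/trajectory file (carries a line number)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class StructureError(ValueError):
    """File-level inconsistency (e.g. declared atom count != records found)."""


class UnsupportedFeatureError(ValueError):
    """Input uses a feature outside this package's scope (e.g. triclinic box)."""


@dataclass
class Topology:
    """Atom identities shared by every frame of a trajectory.

    Charges (elementary charge e) and masses (amu) are optional and may be
    attached after construction.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    segids: np.ndarray
    charges: np.ndarray | None = None
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype="U8")
        self.resnames = np.asarray(self.resnames, dtype="U8")
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.segids = np.asarray(self.segids, dtype="U8")
        n = len(self.names)
        for attr in ("resnames", "resids", "segids"):
            if len(getattr(self, attr)) != n:
                raise StructureError(f"topology field {attr!r} has wrong length")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if len(self.charges) != n:
                raise StructureError("charges length != atom count")
            if not np.all(np.isfinite(self.charges)):
                bad = np.flatnonzero(~np.isfinite(self.charges))
                raise StructureError(f"non-finite charges at atoms {bad[:5].tolist()}")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if len(self.masses) != n:
                raise StructureError("masses length != atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return self.n_atoms


@dataclass
class Frame:
    """One set of coordinates (nm) with an orthorhombic box and a time stamp (ns)."""

    coords: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,):
            raise StructureError("box must be three orthorhombic lengths")
        if not np.all(self.box > 0):
            raise StructureError(f"box lengths must be positive, got {self.box}")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """A topology plus an ordered sequence of frames with non-decreasing times."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        times = [f.time for f in self.frames]
        for f in self.frames:
            if f.n_atoms != n:
                raise StructureError(
                    f"frame has {f.n_atoms} atoms, topology has {n}"
                )
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise StructureError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


@dataclass(frozen=True)
class AtomSelection:
    """A named, ordered, duplicate-free set of 0-based atom indices."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("selection indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices contain duplicates")
        object.__setattr__(self, "indices", idx)

    @property
    def n_atoms(self) -> int:
        return len(self.indices)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_box_line(line: str, lineno: int) -> np.ndarray:
    parts = line.split()
    try:
        vals = [float(p) for p in parts]
    except ValueError as exc:
        raise ParseError(f"unreadable box line: {exc}", lineno) from None
    if len(vals) not in (3, 9):
        raise ParseError(f"box line needs 3 or 9 numbers, got {len(vals)}", lineno)
    if len(vals) == 9 and any(abs(v) > 1e-12 for v in vals[3:]):
        raise UnsupportedFeatureError(
            "triclinic box detected; only orthorhombic boxes are supported"
        )
    return np.array(vals[:3])


def _time_from_title(title: str) -> float:
    """Extract the time (ps in GRO titles, returned in ns) from a ``t=`` token."""
    if "t=" in title:
        after = title.split("t=", 1)[1].strip()
        first = after.split()[0] if after.split() else ""
        try:
            return float(first) / 1000.0  # GRO titles carry ps
        except ValueError:
            pass
    return 0.0


def _read_gro_block(lines: list[str], start: int) -> tuple[Topology, Frame, int]:
    """Parse one GRO block starting at line index *start*; returns next index."""
    if start >= len(lines):
        raise ParseError("empty GRO block", start + 1)
    title = lines[start].rstrip("\n")
    try:
        n_atoms = int(lines[start + 1].split()[0])
    except (IndexError, ValueError):
        raise ParseError("cannot read atom count", start + 2) from None
    end = start + 2 + n_atoms
    if end + 1 > len(lines):
        raise EOFError(f"truncated GRO block starting at line {start + 1}")
    names, resnames, resids, coords = [], [], [], []
    for k, raw in enumerate(lines[start + 2 : end]):
        lineno = start + 3 + k
        if len(raw.rstrip("\n")) < 44:
            raise ParseError("GRO atom line shorter than 44 columns", lineno)
        try:
            resids.append(int(raw[0:5]))
            resnames.append(raw[5:10].strip())
            names.append(raw[10:15].strip())
            coords.append(
                (float(raw[20:28]), float(raw[28:36]), float(raw[36:44]))
            )
        except ValueError as exc:
            raise ParseError(f"malformed GRO atom record: {exc}", lineno) from None
    box = _parse_box_line(lines[end], end + 1)
    topo = Topology(
        names=np.array(names),
        resnames=np.array(resnames),
        resids=np.array(resids),
        segids=np.array([""] * n_atoms),
    )
    frame = Frame(coords=np.array(coords), box=box, time=_time_from_title(title))
    return topo, frame, end + 1


def _read_pdb(lines: list[str]) -> tuple[Topology, Frame]:
    names, resnames, resids, segids, coords = [], [], [], [], []
    box = None
    for k, raw in enumerate(lines):
        lineno = k + 1
        rec = raw[:6].strip()
        if rec == "CRYST1":
            try:
                a, b, c = float(raw[6:15]), float(raw[15:24]), float(raw[24:33])
                al, be, ga = float(raw[33:40]), float(raw[40:47]), float(raw[47:54])
            except ValueError as exc:
                raise ParseError(f"malformed CRYST1: {exc}", lineno) from None
            if any(abs(ang - 90.0) > 1e-6 for ang in (al, be, ga)):
                raise UnsupportedFeatureError(
                    "triclinic CRYST1 box; only orthorhombic boxes are supported"
                )
            box = np.array([a, b, c]) / 10.0
        elif rec in ("ATOM", "HETATM"):
            if len(raw.rstrip("\n")) < 54:
                raise ParseError("ATOM record shorter than 54 columns", lineno)
            try:
                names.append(raw[12:16].strip())
                resnames.append(raw[17:21].strip())
                segids.append(raw[21].strip())
                resids.append(int(raw[22:26]))
                coords.append(
                    (float(raw[30:38]), float(raw[38:46]), float(raw[46:54]))
                )
            except ValueError as exc:
                raise ParseError(f"malformed ATOM record: {exc}", lineno) from None
    if not names:
        raise StructureError("no ATOM/HETATM records found")
    xyz = np.array(coords) / 10.0  # angstrom -> nm
    if box is None:
        span = xyz.max(axis=0) - xyz.min(axis=0)
        box = span + 1.0  # 1 nm margin
        warnings.warn(
            "PDB file has no CRYST1 record; box set from coordinate extent + 1 nm",
            stacklevel=3,
        )
    topo = Topology(
        names=np.array(names),
        resnames=np.array(resnames),
        resids=np.array(resids),
        segids=np.array(segids),
    )
    return topo, Frame(coords=xyz, box=box)


def read_structure(path: str | Path, dialect: str | None = None) -> tuple[Topology, Frame]:
    """Read a single-frame structure file.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"gro"`` or ``"pdb"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect not in ("gro", "pdb"):
        raise ValueError(f"unknown structure dialect {dialect!r}")
    lines = path.read_text().splitlines(keepends=True)
    if dialect == "pdb":
        return _read_pdb(lines)
    try:
        topo, frame, nxt = _read_gro_block(lines, 0)
    except EOFError as exc:
        raise StructureError(str(exc)) from None
    return topo, frame


def _iter_gro_frames(lines: list[str], topology: Topology) -> Iterator[Frame]:
    pos = 0
    while pos < len(lines) and lines[pos].strip() == "":
        pos += 1
    while pos < len(lines):
        try:
            topo, frame, pos = _read_gro_block(lines, pos)
        except EOFError:
            warnings.warn("truncated final frame dropped", stacklevel=4)
            return
        if topo.n_atoms != topology.n_atoms:
            raise StructureError(
                f"frame atom count {topo.n_atoms} != topology {topology.n_atoms}"
            )
        yield frame
        while pos < len(lines) and lines[pos].strip() == "":
            pos += 1


def _iter_xyz_frames(lines: list[str], topology: Topology) -> Iterator[Frame]:
    pos = 0
    while pos < len(lines):
        if lines[pos].strip() == "":
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].split()[0])
        except ValueError:
            raise ParseError("expected XYZ atom count", pos + 1) from None
        if pos + 2 + n_atoms > len(lines):
            warnings.warn("truncated final frame dropped", stacklevel=4)
            return
        comment = lines[pos + 1]
        if "box=" not in comment:
            raise ParseError("XYZ comment line lacks box= token", pos + 2)
        box_str = comment.split("box=", 1)[1].strip()
        box_vals = box_str.replace(",", " ").split()[:3]
        box = np.array([float(v) for v in box_vals])
        time = 0.0
        if "t=" in comment:
            time = float(comment.split("t=", 1)[1].split()[0])
        coords = []
        for k in range(n_atoms):
            parts = lines[pos + 2 + k].split()
            if len(parts) < 4:
                raise ParseError("short XYZ atom line", pos + 3 + k)
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if n_atoms != topology.n_atoms:
            raise StructureError(
                f"frame atom count {n_atoms} != topology {topology.n_atoms}"
            )
        yield Frame(coords=np.array(coords), box=box, time=time)
        pos += 2 + n_atoms


def _iter_binary_frames(path: Path, topology: Topology) -> Iterator[Frame]:
    with open(path, "rb") as fh:
        header = fh.read(12)
        if len(header) < 12 or header[:4] != _BINARY_MAGIC:
            raise ParseError("not a MTRJ binary frame stream", 1)
        version, n_atoms = struct.unpack("<II", header[4:12])
        if version != _BINARY_VERSION:
            raise UnsupportedFeatureError(f"MTRJ version {version} unsupported")
        if n_atoms != topology.n_atoms:
            raise StructureError(
                f"frame atom count {n_atoms} != topology {topology.n_atoms}"
            )
        frame_bytes = 8 * (4 + 3 * n_atoms)
        while True:
            buf = fh.read(frame_bytes)
            if not buf:
                return
            if len(buf) < frame_bytes:
                warnings.warn("truncated final frame dropped", stacklevel=4)
                return
            vals = np.frombuffer(buf, dtype="<f8")
            yield Frame(
                coords=vals[4:].reshape(n_atoms, 3).copy(),
                box=vals[1:4].copy(),
                time=float(vals[0]),
            )


def iter_frames(path: str | Path, topology: Topology) -> Iterator[Frame]:
    """Lazily yield frames from a trajectory file (GRO-block, XYZ or binary)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == _BINARY_MAGIC:
        yield from _iter_binary_frames(path, topology)
        return
    lines = path.read_text().splitlines(keepends=True)
    first = next((ln for ln in lines if ln.strip()), "")
    # XYZ dialect starts with a bare integer; GRO starts with a title line.
    toks = first.split()
    if len(toks) == 1 and toks[0].isdigit():
        yield from _iter_xyz_frames(lines, topology)
    else:
        yield from _iter_gro_frames(lines, topology)


def read_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read a whole trajectory into memory (see :func:`iter_frames` to stream)."""
    return Trajectory(topology=topology, frames=list(iter_frames(path, topology)))


# ---------------------------------------------------------------------------
# writers


def _write_gro_block(fh, topology: Topology, frame: Frame, title: str) -> None:
    fh.write(f"{title} t= {frame.time * 1000.0:.4f}\n")
    fh.write(f"{topology.n_atoms:5d}\n")
    for i in range(topology.n_atoms):
        resid = int(topology.resids[i]) % 100000
        atomid = (i + 1) % 100000
        x, y, z = frame.coords[i]
        fh.write(
            f"{resid:5d}{topology.resnames[i]:<5.5s}{topology.names[i]:>5.5s}"
            f"{atomid:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )
    fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


def write_structure(path: str | Path, topology: Topology, frame: Frame,
                    title: str = "memtilt structure") -> None:
    """Write a single-frame GRO file."""
    with open(path, "w") as fh:
        _write_gro_block(fh, topology, frame, title)


def write_trajectory(path: str | Path, trajectory: Trajectory,
                     title: str = "memtilt frame") -> None:
    """Write a multi-frame GRO-block trajectory.

    GRO's fixed %8.3f coordinate columns limit the round-trip accuracy to
    5e-4 nm; use :func:`write_binary_trajectory` for full precision.
    """
    with open(path, "w") as fh:
        for frame in trajectory:
            _write_gro_block(fh, trajectory.topology, frame, title)


def write_binary_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write the documented MTRJ binary frame stream (float64, lossless)."""
    with open(path, "wb") as fh:
        fh.write(_BINARY_MAGIC)
        fh.write(struct.pack("<II", _BINARY_VERSION, trajectory.topology.n_atoms))
        for frame in trajectory:
            rec = np.concatenate(
                [[frame.time], frame.box, frame.coords.ravel()]
            ).astype("<f8")
            fh.write(rec.tobytes())


def write_tsv(path: str | Path, table: pd.DataFrame,
              metadata: dict | None = None) -> None:
    """Write a TSV with '#'-prefixed metadata lines then a header row.

    Floats are rendered with repr-round-trip precision so that rewriting the
    same table is byte-identical.
    """
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                     lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping metadata lines."""
    return pd.read_csv(path, sep="\t", comment="#")
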