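"""Coarse-grained topology and trajectory handling.

This module defines the in-memory containers used by every analysis stage
(:class:`BeadTopology`, :class:`Frame`, :class:`Trajectory`,
:class:`Selection`), readers and writers for the standard coarse-grained
file formats (GRO/PDB topologies, XTC/TRR trajectories, via MDAnalysis) and
for a documented plain-text trajectory fallback, plus the periodic-boundary
geometry primitives shared by all downstream modules.

Conventions
-----------
* Coordinates are in nm, times in ns (Martini/GROMACS convention).
  MDAnalysis reports Å and ps; the readers convert on the way in.
* Boxes are rectangular; the membrane normal is the z axis.
* Contact cutoffs used downstream are strict ``< cutoff``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger("lipidprint")

# Recognised molecule classes.
MOLECULE_CLASSES = (
    "protein", "PC", "Chol", "PE", "PS", "SM", "PIP2", "water", "ion",
)
LIPID_CLASSES = ("PC", "Chol", "PE", "PS", "SM", "PIP2")

#: Default Martini residue-name -> molecule-class table, extendable per call.
DEFAULT_NAME_MAP = {
    "POPC": "PC", "DOPC": "PC", "DPPC": "PC",
    "CHOL": "Chol", "CHL1": "Chol",
    "POPE": "PE", "DOPE": "PE",
    "POPS": "PS", "DOPS": "PS",
    "DPSM": "SM", "PSM": "SM",
    "POP2": "PIP2", "PIP2": "PIP2",
    "W": "water", "WF": "water", "PW": "water", "SOL": "water", "HOH": "water",
    "ION": "ion", "NA": "ion", "CL": "ion", "NA+": "ion", "CL-": "ion",
}

_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class FormatError(ValueError):
    """A file does not parse under the named standard."""


class TopologyError(ValueError):
    """Topology/trajectory inconsistency (bead counts, classes, ids)."""


class GeometryError(ValueError):
    """Invalid geometric request (cutoff vs box, triclinic box, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BeadTopology:
    """Static per-bead metadata defining protein and lipid groups.

    All fields are parallel arrays of length ``n_beads``; bead ids are the
    (contiguous, 0-based) array indices.

    Attributes
    ----------
    bead_name : array of str
        Coarse-grained bead names (e.g. ``"BB"``, ``"ROH"``).
    residue_id : int array
        Residue numbers as given in the source file (protein residue ids are
        322-699 for the TRPC3-like systems this package was built around,
        but no constraint is imposed).
    residue_name : array of str
    monomer_id : int array
        Protein chain copy (0..n_monomers-1); 0 for non-protein beads.
    molecule_id : int array
        One id per physical molecule: each protein chain is one molecule,
        each lipid/water/ion residue is one molecule.
    molecule_class : array of str
        One of :data:`MOLECULE_CLASSES`; constant within a molecule.
    """

    bead_name: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    monomer_id: np.ndarray
    molecule_id: np.ndarray
    molecule_class: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.bead_name)
        for f in ("residue_id", "residue_name", "monomer_id", "molecule_id",
                  "molecule_class"):
            if len(getattr(self, f)) != n:
                raise TopologyError(f"field {f!r} length != n_beads")
        bad = set(np.unique(self.molecule_class)) - set(MOLECULE_CLASSES)
        if bad:
            raise TopologyError(f"unknown molecule classes: {sorted(bad)}")
        # all beads of a molecule share a class
        for mol in np.unique(self.molecule_id):
            cls = np.unique(self.molecule_class[self.molecule_id == mol])
            if len(cls) != 1:
                raise TopologyError(f"molecule {mol} spans classes {cls}")

    @property
    def n_beads(self) -> int:
        return len(self.bead_name)

    @property
    def protein_mask(self) -> np.ndarray:
        return self.molecule_class == "protein"

    def lipid_mask(self, lipid_class: str | None = None) -> np.ndarray:
        if lipid_class is None:
            return np.isin(self.molecule_class, LIPID_CLASSES)
        return self.molecule_class == lipid_class

    def molecules_of_class(self, molecule_class: str) -> np.ndarray:
        """Sorted molecule ids belonging to one class."""
        return np.unique(self.molecule_id[self.molecule_class == molecule_class])

    def n_monomers(self) -> int:
        if not self.protein_mask.any():
            return 0
        return int(self.monomer_id[self.protein_mask].max()) + 1

    def equal(self, other: "BeadTopology") -> bool:
        """Field-by-field equality (used by the round-trip contract)."""
        return (
            np.array_equal(self.bead_name, other.bead_name)
            and np.array_equal(self.residue_id, other.residue_id)
            and np.array_equal(self.residue_name, other.residue_name)
            and np.array_equal(self.monomer_id, other.monomer_id)
            and np.array_equal(self.molecule_id, other.molecule_id)
            and np.array_equal(self.molecule_class, other.molecule_class)
        )


@dataclass
class Frame:
    """One trajectory frame: time (ns), positions (nm), box lengths (nm)."""

    time: float
    positions: np.ndarray  # (n_beads, 3)
    box: np.ndarray        # (3,) rectangular box lengths

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or not (self.box > 0).all():
            raise GeometryError("box must be three positive lengths")
        if not np.isfinite(self.positions).all():
            raise GeometryError("non-finite positions")


@dataclass
class Trajectory:
    """Time-ordered frames with a uniform time step.

    Positions are stored as one ``(n_frames, n_beads, 3)`` array; ``frame(i)``
    returns a :class:`Frame` view. A single-frame trajectory is legal but has
    ``dt = None`` and is refused by the kinetic analyses.
    """

    times: np.ndarray       # (n_frames,) ns
    positions: np.ndarray   # (n_frames, n_beads, 3) nm
    box: np.ndarray         # (3,) or (n_frames, 3) nm

    _DT_TOL = 1e-6  # ns, tolerance on uniform spacing

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 3 or len(self.times) != len(self.positions):
            raise TopologyError("positions must be (n_frames, n_beads, 3)")
        if len(self.times) == 0:
            raise TopologyError("empty trajectory")
        d = np.diff(self.times)
        if len(d) and ((d <= 0).any() or np.ptp(d) > self._DT_TOL):
            raise TopologyError(
                "frame times must increase with uniform spacing "
                f"(spread {np.ptp(d):g} ns exceeds {self._DT_TOL:g})"
            )

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float | None:
        """Frame spacing in ns; None for a single-frame trajectory."""
        if self.n_frames < 2:
            return None
        return float(self.times[1] - self.times[0])

    def frame_box(self, i: int) -> np.ndarray:
        return self.box if self.box.ndim == 1 else self.box[i]

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), self.positions[i], self.frame_box(i))

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))


@dataclass(frozen=True)
class Selection:
    """An (ordered, duplicate-free) set of bead indices with a label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.intp))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# Periodic-boundary geometry
# ---------------------------------------------------------------------------

def min_image_vector(p1: np.ndarray, p2: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement ``p2 - p1`` in a rectangular box.

    Broadcasts over leading axes; each component lies in [-L/2, L/2).
    """
    box = np.asarray(box, dtype=float)
    if not (box > 0).all():
        raise GeometryError("box lengths must be positive")
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(p1, p2, box) -> float | np.ndarray:
    """Euclidean distance under the rectangular minimum-image convention."""
    d = min_image_vector(p1, p2, box)
    return np.sqrt((d * d).sum(axis=-1))


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary cell [0, L) per axis."""
    box = np.asarray(box, dtype=float)
    return np.mod(positions, box)


# ---------------------------------------------------------------------------
# Topology I/O
# ---------------------------------------------------------------------------

def _classify_residues(resnames, name_map, strict):
    """Map residue names to molecule classes; unknowns warn (lenient) or raise."""
    table = dict(DEFAULT_NAME_MAP)
    if name_map:
        table.update(name_map)
    classes = []
    unknown = set()
    for rn in resnames:
        key = rn.strip()
        if key in _AMINO3:
            classes.append("protein")
        elif key in table:
            classes.append(table[key])
        elif key.upper() in table:
            classes.append(table[key.upper()])
        else:
            unknown.add(key)
            classes.append("ion")
    if unknown:
        msg = (f"unknown residue names {sorted(unknown)}; supply a name_map "
               "entry or use strict=True to reject")
        if strict:
            raise FormatError(msg)
        warnings.warn(msg + " (classified as inert 'ion')", stacklevel=3)
        logger.warning(msg)
    return np.array(classes)


def _infer_topology_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".gro":
        return "GRO"
    if suffix == ".pdb":
        return "PDB"
    raise FormatError(f"cannot infer topology format from {path!r}")


def read_topology(path, format: str | None = None, *, name_map=None,
                  strict: bool = False) -> tuple[BeadTopology, Frame]:
    """Read a GRO or PDB coarse-grained topology.

    Returns the :class:`BeadTopology` together with the coordinate
    :class:`Frame` stored in the file (GRO and PDB both carry coordinates).

    Lipid classes are inferred from residue names via
    :data:`DEFAULT_NAME_MAP`, extendable through ``name_map``. Unknown
    residue names warn and are classified as inert ``ion`` unless
    ``strict=True``, in which case they are rejected.

    Protein monomers (chain copies) are detected from chain/segment ids when
    present, otherwise from restarts (decreases) in the protein residue-id
    sequence.
    """
    import MDAnalysis as mda

    path = Path(path)
    fmt = (format or _infer_topology_format(path)).upper()
    if fmt not in ("GRO", "PDB"):
        raise FormatError(f"unsupported topology format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MDA guessers are chatty
            u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise FormatError(f"{path}: failed to parse as {fmt}: {exc}") from exc

    atoms = u.atoms
    names = atoms.names.astype(str)
    resids_per_bead = atoms.resids.astype(int)
    resnames_per_bead = atoms.resnames.astype(str)
    resindex = atoms.resindices  # grouping into residues, file order

    res_classes = _classify_residues(u.residues.resnames.astype(str),
                                     name_map, strict)
    classes = res_classes[resindex]

    # chain/segment labels, if informative
    try:
        chain_labels = atoms.chainIDs.astype(str)
    except (AttributeError, mda.exceptions.NoDataError):
        segids = atoms.segids.astype(str)
        chain_labels = segids if len(set(segids)) > 1 else None

    monomer = np.zeros(len(atoms), dtype=int)
    molecule = np.zeros(len(atoms), dtype=int)
    prot = classes == "protein"
    # residue-level walk assigns monomer/molecule ids in file order
    res_first_bead = np.searchsorted(resindex, np.arange(len(u.residues)))
    mono_of_res = np.zeros(len(u.residues), dtype=int)
    mol_of_res = np.zeros(len(u.residues), dtype=int)
    cur_mono, cur_mol = -1, -1
    prev_prot_resid, prev_chain = None, None
    for ri in range(len(u.residues)):
        b0 = res_first_bead[ri]
        if res_classes[ri] == "protein":
            rid = resids_per_bead[b0]
            chain = chain_labels[b0] if chain_labels is not None else None
            new_chain = (
                cur_mono < 0
                or (chain is not None and chain != prev_chain)
                or (chain is None and prev_prot_resid is not None
                    and rid <= prev_prot_resid)
            )
            if new_chain:
                cur_mono += 1
                cur_mol += 1
            mono_of_res[ri] = cur_mono
            mol_of_res[ri] = cur_mol
            prev_prot_resid, prev_chain = rid, chain
        else:
            cur_mol += 1
            mol_of_res[ri] = cur_mol
            mono_of_res[ri] = 0
    monomer = mono_of_res[resindex]
    molecule = mol_of_res[resindex]
    monomer[~prot] = 0

    top = BeadTopology(
        bead_name=names,
        residue_id=resids_per_bead,
        residue_name=resnames_per_bead,
        monomer_id=monomer,
        molecule_id=molecule,
        molecule_class=classes,
    )
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        box = np.array([1.0, 1.0, 1.0])
        warnings.warn(f"{path}: no box in file; using unit box", stacklevel=2)
    else:
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise GeometryError("triclinic boxes are not supported")
        box = dims[:3] / 10.0  # A -> nm
    frame = Frame(0.0, atoms.positions / 10.0, box)
    return top, frame


def write_topology(topology: BeadTopology, frame: Frame, path) -> None:
    """Write a topology + coordinates as a GRO file (round-trips losslessly
    modulo GRO's field widths)."""
    import MDAnalysis as mda

    n = topology.n_beads
    # residue grouping = consecutive runs of (molecule_id, residue_id)
    key = topology.molecule_id.astype(np.int64) * 10_000_000 + topology.residue_id
    boundaries = np.flatnonzero(np.diff(key)) + 1
    starts = np.concatenate([[0], boundaries])
    resindex = np.zeros(n, dtype=int)
    resindex[starts] = 1
    resindex = np.cumsum(resindex) - 1
    n_res = resindex[-1] + 1

    u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=resindex,
                           trajectory=True)
    u.add_TopologyAttr("names", topology.bead_name)
    u.add_TopologyAttr("resids", topology.residue_id[starts])
    u.add_TopologyAttr("resnames", topology.residue_name[starts])
    u.dimensions = np.array([*(np.asarray(frame.box) * 10.0), 90.0, 90.0, 90.0])
    u.atoms.positions = frame.positions * 10.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

TEXT_TRAJ_MAGIC = "# lipidprint-traj v1"


def write_trajectory_text(traj: Trajectory, path) -> None:
    """Write the documented plain-text trajectory format.

    One block per frame: a header line ``t=<ns> box=<Lx> <Ly> <Lz>`` followed
    by one ``x y z`` line (nm) per bead.
    """
    with open(path, "w") as fh:
        fh.write(TEXT_TRAJ_MAGIC + "\n")
        for i in range(traj.n_frames):
            b = traj.frame_box(i)
            fh.write(f"t={traj.times[i]:.6f} box={b[0]:.6f} {b[1]:.6f} {b[2]:.6f}\n")
            np.savetxt(fh, traj.positions[i], fmt="%.6f")


def _read_trajectory_text(path, n_beads, strict):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != TEXT_TRAJ_MAGIC:
        raise FormatError(f"{path}: not a lipidprint text trajectory")
    headers = [i for i, ln in enumerate(lines) if ln.startswith("t=")]
    if not headers:
        raise FormatError(f"{path}: no frames")
    # beads per frame is the block size between headers
    block = (headers[1] - headers[0] - 1) if len(headers) > 1 \
        else len(lines) - headers[0] - 1
    if block != n_beads:
        raise TopologyError(f"{path}: {block} beads per frame but topology "
                            f"has {n_beads}")
    times, frames, boxes = [], [], []
    for h in headers:
        header = lines[h]
        try:
            t_part, box_part = header.split("box=")
            t = float(t_part.split("=")[1])
            box = np.array([float(x) for x in box_part.split()])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{h + 1}: bad frame header "
                              f"{header!r}") from exc
        body = lines[h + 1:h + 1 + n_beads]
        try:
            if len(body) < n_beads:
                raise ValueError("incomplete frame")
            pos = np.array([[float(v) for v in ln.split()] for ln in body])
            if pos.shape != (n_beads, 3):
                raise ValueError("wrong shape")
        except ValueError as exc:
            msg = f"{path}: corrupt frame at t={t} ns ({exc})"
            if strict:
                raise FormatError(msg) from exc
            warnings.warn(msg + "; truncating trajectory", stacklevel=3)
            break
        times.append(t)
        frames.append(pos)
        boxes.append(box)
    if not times:
        raise FormatError(f"{path}: no complete frames")
    return np.array(times), np.array(frames), np.array(boxes)


def read_trajectory(path, topology: BeadTopology, format: str | None = None,
                    *, strict: bool = False) -> Trajectory:
    """Read an XTC/TRR trajectory (via MDAnalysis) or the text fallback.

    The bead count in the file must equal the topology's; frame times must
    be uniformly spaced (tolerance 1e-6 ns). In lenient mode a corrupt text
    frame truncates the trajectory with a warning; strict mode raises.
    """
    path = Path(path)
    if format is None:
        format = {".xtc": "XTC", ".trr": "TRR"}.get(path.suffix.lower(), "text")
    fmt = format.upper() if format.lower() != "text" else "text"

    if fmt == "text":
        times, pos, boxes = _read_trajectory_text(path, topology.n_beads, strict)
    elif fmt in ("XTC", "TRR"):
        from MDAnalysis.coordinates.TRR import TRRReader
        from MDAnalysis.coordinates.XTC import XTCReader

        reader_cls = XTCReader if fmt == "XTC" else TRRReader
        reader = reader_cls(str(path))
        if reader.n_atoms != topology.n_beads:
            raise TopologyError(
                f"{path}: {reader.n_atoms} beads in trajectory but "
                f"{topology.n_beads} in topology")
        times, pos, boxes = [], [], []
        for ts in reader:
            times.append(ts.time / 1000.0)       # ps -> ns
            pos.append(ts.positions / 10.0)      # A -> nm
            if not np.allclose(ts.dimensions[3:], 90.0, atol=1e-3):
                raise GeometryError("triclinic boxes are not supported")
            boxes.append(ts.dimensions[:3] / 10.0)
        reader.close()
        times, pos, boxes = np.array(times), np.array(pos), np.array(boxes)
    else:
        raise FormatError(f"unsupported trajectory format {format!r}")

    if pos.shape[1] != topology.n_beads:
        raise TopologyError(f"{path}: bead count mismatch")
    box = boxes[0] if np.allclose(boxes, boxes[0]) else boxes
    return Trajectory(times=times, positions=pos, box=box)


def write_trajectory(traj: Trajectory, path, format: str = "text") -> None:
    """Write a trajectory as text (default) or XTC."""
    if format.lower() == "text":
        write_trajectory_text(traj, path)
        return
    if format.upper() == "XTC":
        from MDAnalysis.coordinates.XTC import XTCWriter

        with XTCWriter(str(path), n_atoms=traj.n_beads) as w:
            import MDAnalysis as mda

            u = mda.Universe.empty(traj.n_beads, trajectory=True)
            for i in range(traj.n_frames):
                u.atoms.positions = traj.positions[i] * 10.0
                b = traj.frame_box(i) * 10.0
                u.dimensions = np.array([*b, 90.0, 90.0, 90.0])
                u.trajectory.ts.time = traj.times[i] * 1000.0
                u.trajectory.ts.frame = i
                w.write(u.atoms)
        return
    raise FormatError(f"unsupported trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Slicing / selections
# ---------------------------------------------------------------------------

def slice_equilibrated(traj: Trajectory, t_start: float) -> Trajectory:
    """Drop the pre-equilibration part: keep frames with ``time >= t_start``.

    The field convention (and this package's pipeline default) is to discard
    the first portion of a production run before computing any statistics;
    dt is preserved.
    """
    keep = traj.times >= t_start - 1e-9
    if not keep.any():
        raise TopologyError(f"t_start={t_start} ns is beyond the trajectory")
    box = traj.box if traj.box.ndim == 1 else traj.box[keep]
    return Trajectory(traj.times[keep], traj.positions[keep], box)


def slice_frames(traj: Trajectory, start: int, stop: int | None = None) -> Trajectory:
    sl = slice(start, stop)
    box = traj.box if traj.box.ndim == 1 else traj.box[sl]
    return Trajectory(traj.times[sl], traj.positions[sl], box)


def concat_trajectories(a: Trajectory, b: Trajectory) -> Trajectory:
    """Concatenate two contiguous slices of the same system."""
    if a.n_beads != b.n_beads:
        raise TopologyError("bead-count mismatch in concatenation")
    box_a = a.box if a.box.ndim == 2 else np.tile(a.box, (a.n_frames, 1))
    box_b = b.box if b.box.ndim == 2 else np.tile(b.box, (b.n_frames, 1))
    box = np.concatenate([box_a, box_b])
    if np.allclose(box, box[0]):
        box = box[0]
    return Trajectory(np.concatenate([a.times, b.times]),
                      np.concatenate([a.positions, b.positions]), box)


def select(topology: BeadTopology, expr: str) -> Selection:
    """Resolve a selection expression to bead indices.

    Grammar: terms joined by ``+`` (set union); each term is one of
    ``protein``, ``lipid`` (all lipid classes), ``lipid:<class>``,
    ``bead:<name>``, ``resid:<id>``.
    """
    idx = np.zeros(0, dtype=np.intp)
    for term in (t.strip() for t in expr.split("+")):
        if term == "protein":
            mask = topology.protein_mask
        elif term == "lipid":
            mask = topology.lipid_mask()
        elif term.startswith("lipid:"):
            cls = term.split(":", 1)[1]
            if cls not in LIPID_CLASSES:
                raise ValueError(f"unknown lipid class {cls!r}")
            mask = topology.lipid_mask(cls)
        elif term.startswith("bead:"):
            mask = topology.bead_name == term.split(":", 1)[1]
        elif term.startswith("resid:"):
            mask = topology.residue_id == int(term.split(":", 1)[1])
        else:
            raise ValueError(f"cannot parse selection term {term!r}")
        idx = np.union1d(idx, np.flatnonzero(mask))
    return Selection(idx, label=expr)
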