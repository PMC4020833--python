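"""Domain types and I/O: structures, trajectory ensembles and region schemes.

Internal length unit is nanometres everywhere.  PDB files (which are in
Angstrom) are converted on read/write; report tables convert to mixed
presentation units at the presentation layer only.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ArgumentError,
    EmptyInputError,
    FormatError,
    InsufficientDataError,
    IntegrityError,
    SchemeError,
    ShapeError,
)

NM_PER_ANGSTROM = 0.1

#: Maximum heavy-atom--hydrogen distance (nm) used to infer covalent
#: attachment when the file carries no CONECT records.
_H_BOND_INFER_CUTOFF = 0.13

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})
_DONOR_ELEMENTS = frozenset({"N", "O", "S", "F"})
_ACCEPTOR_ELEMENTS = frozenset({"N", "O", "S", "F"})


# ---------------------------------------------------------------------------
# StructureModel
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """A protein structure: atoms, residue identity, positions and H-bond roles.

    Positions are in nm.  ``hbond_roles`` holds one of ``donor-heavy``,
    ``acceptor``, ``hydrogen`` or ``none`` per atom; a donor-heavy atom may
    simultaneously act as acceptor (tracked via :attr:`acceptor_flags`).
    """

    atom_ids: np.ndarray          # (N,) int
    atom_names: list[str]
    elements: list[str]
    residue_numbers: np.ndarray   # (N,) int, author numbering
    residue_names: list[str]
    positions: np.ndarray         # (N, 3) nm
    bonds: list[tuple[int, int]] = field(default_factory=list)  # atom_id pairs
    hbond_roles: np.ndarray | None = None   # (N,) object dtype
    acceptor_flags: np.ndarray | None = None  # (N,) bool

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=int)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.atom_ids), 3):
            raise ShapeError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.atom_ids)} atoms"
            )
        if len(np.unique(self.atom_ids)) != len(self.atom_ids):
            dup = int(self.atom_ids[_first_duplicate(self.atom_ids)])
            raise IntegrityError(f"duplicate atom_id {dup}")
        if np.any(np.diff(self.residue_numbers) < 0):
            raise IntegrityError("residue_number not non-decreasing in atom order")
        if not np.all(np.isfinite(self.positions)):
            raise IntegrityError("non-finite atom position")
        if self.hbond_roles is None:
            self._assign_hbond_roles()
        self._validate_hbond_roles()

    # -- construction helpers ------------------------------------------------

    def _assign_hbond_roles(self) -> None:
        """Derive donor/acceptor/hydrogen flags from elements and bonds.

        Hydrogens are element H; a heavy atom is donor-capable when at least
        one hydrogen is bonded to it (bonds inferred geometrically when the
        file provides none); N/O/S/F heavy atoms are acceptor-capable.
        """
        n = len(self.atom_ids)
        roles = np.array(["none"] * n, dtype=object)
        acceptors = np.zeros(n, dtype=bool)
        elements = [e.upper() for e in self.elements]
        h_idx = [i for i, e in enumerate(elements) if e == "H"]
        if h_idx and not self.bonds:
            self.bonds = self._infer_hydrogen_bonds(h_idx, elements)
        id_to_idx = {int(a): i for i, a in enumerate(self.atom_ids)}
        donor_heavy: set[int] = set()
        for a, b in self.bonds:
            ia, ib = id_to_idx.get(int(a)), id_to_idx.get(int(b))
            if ia is None or ib is None:
                raise IntegrityError(f"bond references unknown atom_id ({a}, {b})")
            for h, heavy in ((ia, ib), (ib, ia)):
                if elements[h] == "H" and elements[heavy] in _DONOR_ELEMENTS:
                    roles[h] = "hydrogen"
                    donor_heavy.add(heavy)
        for i, e in enumerate(elements):
            if i in donor_heavy:
                roles[i] = "donor-heavy"
            if e in _ACCEPTOR_ELEMENTS and e != "H":
                acceptors[i] = True
                if roles[i] == "none":
                    roles[i] = "acceptor"
        self.hbond_roles = roles
        self.acceptor_flags = acceptors

    def _infer_hydrogen_bonds(
        self, h_idx: list[int], elements: list[str]
    ) -> list[tuple[int, int]]:
        bonds: list[tuple[int, int]] = []
        heavy = [
            i for i, e in enumerate(elements)
            if e in _DONOR_ELEMENTS and e != "H"
        ]
        if not heavy:
            return bonds
        heavy_pos = self.positions[heavy]
        for h in h_idx:
            d = np.linalg.norm(heavy_pos - self.positions[h], axis=1)
            j = int(np.argmin(d))
            if d[j] <= _H_BOND_INFER_CUTOFF:
                bonds.append((int(self.atom_ids[h]), int(self.atom_ids[heavy[j]])))
        return bonds

    def _validate_hbond_roles(self) -> None:
        id_to_idx = {int(a): i for i, a in enumerate(self.atom_ids)}
        for i, role in enumerate(self.hbond_roles):
            if role != "hydrogen":
                continue
            partners = [
                other
                for a, b in self.bonds
                for h, other in ((a, b), (b, a))
                if id_to_idx[int(h)] == i
                and self.hbond_roles[id_to_idx[int(other)]] == "donor-heavy"
            ]
            if len(partners) != 1:
                raise IntegrityError(
                    f"H-bond hydrogen atom_id {int(self.atom_ids[i])} bonded to "
                    f"{len(partners)} donor-heavy atoms (expected 1)"
                )

    # -- views ---------------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def atoms(self) -> list[tuple]:
        """Spec-shaped atom tuples (id, name, element, resnum, resname, pos)."""
        return [
            (
                int(self.atom_ids[i]),
                self.atom_names[i],
                self.elements[i],
                int(self.residue_numbers[i]),
                self.residue_names[i],
                self.positions[i].copy(),
            )
            for i in range(self.n_atoms)
        ]

    @property
    def has_hydrogens(self) -> bool:
        return any(e.upper() == "H" for e in self.elements)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue numbers in chain order."""
        _, idx = np.unique(self.residue_numbers, return_index=True)
        return self.residue_numbers[np.sort(idx)]

    def selection_mask(self, name: str) -> np.ndarray:
        if name == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if name == "backbone":
            return np.array([a in _BACKBONE_NAMES for a in self.atom_names])
        if name in ("calpha", "ca"):
            return np.array([a == "CA" for a in self.atom_names])
        if name == "heavy":
            return np.array([e.upper() != "H" for e in self.elements])
        raise ArgumentError(f"unknown selection {name!r}")

    def hydrogen_donor_pairs(self) -> list[tuple[int, int]]:
        """(hydrogen index, donor-heavy index) pairs, atom-array indices."""
        id_to_idx = {int(a): i for i, a in enumerate(self.atom_ids)}
        out = []
        for a, b in self.bonds:
            ia, ib = id_to_idx[int(a)], id_to_idx[int(b)]
            for h, d in ((ia, ib), (ib, ia)):
                if self.hbond_roles[h] == "hydrogen" and self.hbond_roles[d] == "donor-heavy":
                    out.append((h, d))
        return sorted(set(out))


def _first_duplicate(values: np.ndarray) -> int:
    seen: set[int] = set()
    for i, v in enumerate(values):
        if int(v) in seen:
            return i
        seen.add(int(v))
    raise AssertionError("no duplicate present")


# ---------------------------------------------------------------------------
# TrajectoryEnsemble
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryEnsemble:
    """Ordered Cartesian frames (nm) with timestamps (ps), grouped by replica."""

    replicas: list[np.ndarray]          # each (n_frames, n_atoms, 3)
    times: list[np.ndarray]             # each (n_frames,) ps, strictly increasing
    selection_masks: dict[str, np.ndarray] = field(default_factory=dict)
    #: After merging: (replica_index, n_frames) per original replica, in order.
    replica_edges: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.replicas:
            raise EmptyInputError("ensemble needs at least one replica")
        self.replicas = [np.asarray(r, dtype=float) for r in self.replicas]
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        n_atoms = self.replicas[0].shape[1]
        for r, t in zip(self.replicas, self.times):
            if r.ndim != 3 or r.shape[2] != 3:
                raise ShapeError(f"replica has shape {r.shape}, expected (F, N, 3)")
            if r.shape[1] != n_atoms:
                raise ShapeError("atom_count differs between replicas")
            if r.shape[0] == 0:
                raise EmptyInputError("replica with zero frames")
            if len(t) != r.shape[0]:
                raise ShapeError("timestamp count differs from frame count")
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise IntegrityError("timestamps not strictly increasing")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def atom_count(self) -> int:
        return self.replicas[0].shape[1]

    @property
    def n_frames(self) -> int:
        return sum(r.shape[0] for r in self.replicas)

    def frames(self) -> np.ndarray:
        """All frames concatenated over replicas, shape (F, N, 3)."""
        if len(self.replicas) == 1:
            return self.replicas[0]
        return np.concatenate(self.replicas, axis=0)

    def all_times(self) -> np.ndarray:
        return np.concatenate(self.times)

    def frame_spacing_ps(self) -> float:
        t = self.times[0]
        if len(t) < 2:
            raise InsufficientDataError("frame spacing undefined with <2 frames")
        return float(t[1] - t[0])

    def with_masks(self, structure: StructureModel) -> "TrajectoryEnsemble":
        self.selection_masks = {
            "all": structure.selection_mask("all"),
            "backbone": structure.selection_mask("backbone"),
            "calpha": structure.selection_mask("calpha"),
            "heavy": structure.selection_mask("heavy"),
        }
        return self


# ---------------------------------------------------------------------------
# RegionScheme
# ---------------------------------------------------------------------------

REQUIRED_REGIONS = (
    "JMR", "JM-B", "JM-S", "JM-Z", "N-lobe", "C-lobe",
    "A-loop", "C-loop", "Ca-helix", "P-loop", "KID",
)

_REGION_ALIASES = {"Cα-helix": "Ca-helix", "CA-helix": "Ca-helix"}


@dataclass
class RegionScheme:
    """Named inclusive residue-number ranges mapped onto a structure.

    Ranges are inclusive on both ends and use author numbering.  A region may
    consist of several ranges; an empty list is allowed (the name must still
    be present) for regions whose extent is user-configurable.
    """

    regions: dict[str, list[tuple[int, int]]]
    name: str = "custom"

    def __post_init__(self) -> None:
        canonical: dict[str, list[tuple[int, int]]] = {}
        for key, ranges in self.regions.items():
            key = _REGION_ALIASES.get(key, key)
            canonical[key] = [(int(lo), int(hi)) for lo, hi in ranges]
        self.regions = canonical
        missing = [r for r in REQUIRED_REGIONS if r not in self.regions]
        if missing:
            raise SchemeError(f"region scheme missing required regions: {missing}")
        for key, ranges in self.regions.items():
            for lo, hi in ranges:
                if lo > hi:
                    raise SchemeError(f"region {key!r}: invalid range {lo}-{hi}")
        for sub in ("JM-B", "JM-S"):
            if not set(self.residues(sub)) <= set(self.residues("JMR")):
                raise SchemeError(f"{sub} is not a subset of JMR")

    def residues(self, name: str) -> list[int]:
        name = _REGION_ALIASES.get(name, name)
        if name not in self.regions:
            raise SchemeError(f"unknown region {name!r}")
        out: list[int] = []
        for lo, hi in self.regions[name]:
            out.extend(range(lo, hi + 1))
        return sorted(set(out))

    def count_residues(self, name: str) -> int:
        return len(self.residues(name))

    def atom_indices(
        self, structure: StructureModel, name: str, subset: str = "all"
    ) -> np.ndarray:
        members = set(self.residues(name))
        mask = np.array([int(r) in members for r in structure.residue_numbers])
        mask &= structure.selection_mask(subset)
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise SchemeError(f"region {name!r} selects no atoms in this structure")
        return idx

    def validate_against(self, structure: StructureModel) -> None:
        lo = int(structure.residue_numbers.min())
        hi = int(structure.residue_numbers.max())
        for key, ranges in self.regions.items():
            for a, b in ranges:
                if b < lo or a > hi:
                    raise SchemeError(
                        f"region {key!r} range {a}-{b} outside structure span {lo}-{hi}"
                    )


def csf1r_default_scheme() -> RegionScheme:
    """Region scheme for the modeled receptor cytoplasmic segment (543-922).

    JM-Z has no published extent; it defaults to the JMR remainder after
    JM-B and JM-S and should be overridden when a better definition exists.
    C-loop, P-loop, Ca-helix and KID defaults are drawn from the catalytic /
    glycine-rich / helix-C / insert-domain residues named in the analyses and
    are configurable.
    """
    return RegionScheme(
        name="csf1r-543-922",
        regions={
            "JMR": [(543, 580)],
            "JM-B": [(543, 552)],
            "JM-S": [(553, 564)],
            "JM-Z": [(565, 580)],
            "N-lobe": [(582, 664)],
            "C-lobe": [(671, 922)],
            "A-loop": [(796, 825)],
            "C-loop": [(772, 784)],
            "Ca-helix": [(626, 642)],
            "P-loop": [(588, 596)],
            "KID": [(678, 692)],
        },
    )


def csf1r_sequence_scheme() -> RegionScheme:
    """Alternate scheme with the wider JMR used for sequence-level analysis."""
    scheme = csf1r_default_scheme()
    regions = dict(scheme.regions)
    regions["JMR"] = [(538, 580)]
    return RegionScheme(regions=regions, name="csf1r-sequence")


def toy_scheme(n_residues: int) -> RegionScheme:
    """Region scheme laid out proportionally over a toy chain of 1..n residues.

    Mirrors the native layout: JMR head (with JM-B/JM-S/JM-Z split),
    N-lobe middle, C-lobe tail; remaining regions nested inside the lobes.
    """
    n = n_residues
    if n < 20:
        raise ArgumentError("toy scheme needs >= 20 residues")
    jmr_end = max(6, n // 5)
    jmb_end = max(2, jmr_end // 3)
    jms_end = max(jmb_end + 2, 2 * jmr_end // 3)
    nlobe_end = n // 2
    aloop_lo = nlobe_end + (n - nlobe_end) // 3
    aloop_hi = min(n, aloop_lo + max(3, n // 10))
    return RegionScheme(
        name=f"toy-{n}",
        regions={
            "JMR": [(1, jmr_end)],
            "JM-B": [(1, jmb_end)],
            "JM-S": [(jmb_end + 1, jms_end)],
            "JM-Z": [(jms_end + 1, jmr_end)],
            "N-lobe": [(jmr_end + 1, nlobe_end)],
            "C-lobe": [(nlobe_end + 1, n)],
            "A-loop": [(aloop_lo, aloop_hi)],
            "C-loop": [(nlobe_end + 1, min(n, nlobe_end + 3))],
            "Ca-helix": [(max(jmr_end + 1, nlobe_end - 4), nlobe_end)],
            "P-loop": [(jmr_end + 1, min(nlobe_end, jmr_end + 3))],
            "KID": [(min(n, aloop_hi + 1), min(n, aloop_hi + 3))],
        },
    )


# ---------------------------------------------------------------------------
# PDB I/O
#
# A deliberately small fixed-column reader/writer: author numbering is kept
# verbatim, format errors carry the offending line number, and duplicate
# serials are an integrity error -- requirements the generic parsers do not
# surface.  Only ATOM/HETATM/CONECT/TER/END records are interpreted.
# ---------------------------------------------------------------------------

def load_structure(path: str, dialect: str = "pdb") -> StructureModel:
    """Read a structure from ``path``.

    dialect ``pdb`` parses ATOM/HETATM records (Angstrom -> nm); dialect
    ``internal-json`` reads the package's JSON structure container.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "pdb":
        return _read_pdb(path)
    if dialect == "internal-json":
        return _read_json_structure(path)
    raise ArgumentError(f"unknown structure dialect {dialect!r}")


def _read_pdb(path: str) -> StructureModel:
    atom_ids: list[int] = []
    names: list[str] = []
    elements: list[str] = []
    resnums: list[int] = []
    resnames: list[str] = []
    positions: list[list[float]] = []
    bonds: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record in ("ATOM", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    resnum = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: unparsable record: {exc}")
                element = line[76:78].strip() or _element_from_name(name)
                atom_ids.append(serial)
                names.append(name)
                elements.append(element)
                resnums.append(resnum)
                resnames.append(resname)
                positions.append([x * NM_PER_ANGSTROM,
                                  y * NM_PER_ANGSTROM,
                                  z * NM_PER_ANGSTROM])
            elif record == "CONECT":
                fields = line.split()[1:]
                try:
                    serials = [int(f) for f in fields]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: unparsable CONECT: {exc}")
                for other in serials[1:]:
                    bonds.append((serials[0], other))
    if not atom_ids:
        raise EmptyInputError(f"{path}: no ATOM records")
    bonds = sorted({(min(a, b), max(a, b)) for a, b in bonds})
    return StructureModel(
        atom_ids=np.array(atom_ids),
        atom_names=names,
        elements=elements,
        residue_numbers=np.array(resnums),
        residue_names=resnames,
        positions=np.array(positions),
        bonds=bonds,
    )


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def write_pdb(structure: StructureModel, path: str) -> None:
    """Write ATOM records (nm -> Angstrom, %8.3f) plus hydrogen CONECTs."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            x, y, z = structure.positions[i] / NM_PER_ANGSTROM
            name = structure.atom_names[i]
            pdb_name = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                "ATOM  {serial:>5d} {name:4s} {res:<3s} A{resnum:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n".format(
                    serial=int(structure.atom_ids[i]),
                    name=pdb_name,
                    res=structure.residue_names[i][:3],
                    resnum=int(structure.residue_numbers[i]),
                    x=x, y=y, z=z,
                    el=structure.elements[i].upper()[:2],
                )
            )
        for a, b in structure.bonds:
            fh.write(f"CONECT{a:>5d}{b:>5d}\n")
        fh.write("END\n")


def _read_json_structure(path: str) -> StructureModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}:{exc.lineno}: unparsable JSON: {exc.msg}")
    atoms = doc["atoms"]
    return StructureModel(
        atom_ids=np.array([a["id"] for a in atoms]),
        atom_names=[a["name"] for a in atoms],
        elements=[a["element"] for a in atoms],
        residue_numbers=np.array([a["resnum"] for a in atoms]),
        residue_names=[a["resname"] for a in atoms],
        positions=np.array([a["position"] for a in atoms]),
        bonds=[tuple(b) for b in doc.get("bonds", [])],
    )


def write_json_structure(structure: StructureModel, path: str) -> None:
    doc = {
        "atoms": [
            {
                "id": int(structure.atom_ids[i]),
                "name": structure.atom_names[i],
                "element": structure.elements[i],
                "resnum": int(structure.residue_numbers[i]),
                "resname": structure.residue_names[i],
                "position": [float(v) for v in structure.positions[i]],
            }
            for i in range(structure.n_atoms)
        ],
        "bonds": [[int(a), int(b)] for a, b in structure.bonds],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

TRAJ_MAGIC = "# trajcomm-traj 1"


def write_trajectory(frames: np.ndarray, times_ps: np.ndarray, path: str) -> None:
    """Write the plain-text internal trajectory format.

    Layout: a magic header, an ``natoms`` line, then per frame a
    ``frame <index> time <ps>`` line followed by one ``x y z`` line per atom
    (nm, full float precision).
    """
    frames = np.asarray(frames, dtype=float)
    with open(path, "w") as fh:
        fh.write(TRAJ_MAGIC + "\n")
        fh.write(f"natoms {frames.shape[1]}\n")
        for k, frame in enumerate(frames):
            fh.write(f"frame {k} time {float(times_ps[k]):.6f}\n")
            for x, y, z in frame:
                fh.write(f"{x:.9f} {y:.9f} {z:.9f}\n")


def _read_text_trajectory(path: str) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != TRAJ_MAGIC:
            raise FormatError(f"{path}:1: not a trajcomm trajectory file")
        natoms_line = fh.readline().split()
        if len(natoms_line) != 2 or natoms_line[0] != "natoms":
            raise FormatError(f"{path}:2: expected 'natoms <N>'")
        n_atoms = int(natoms_line[1])
        frames: list[np.ndarray] = []
        times: list[float] = []
        lineno = 2
        while True:
            head = fh.readline()
            lineno += 1
            if not head:
                break
            fields = head.split()
            if len(fields) != 4 or fields[0] != "frame" or fields[2] != "time":
                raise FormatError(f"{path}:{lineno}: expected frame header")
            times.append(float(fields[3]))
            block = np.empty((n_atoms, 3))
            for i in range(n_atoms):
                row = fh.readline()
                lineno += 1
                vals = row.split()
                if len(vals) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 'x y z'")
                block[i] = [float(v) for v in vals]
            frames.append(block)
    if not frames:
        raise EmptyInputError(f"{path}: zero frames")
    return np.array(frames), np.array(times)


def _read_binary_trajectory(path: str, stride_ps: float) -> tuple[np.ndarray, np.ndarray]:
    # Adapter for standard binary formats; only used when MDAnalysis is
    # importable and the caller feeds .dcd/.xtc/.trr files.
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ArgumentError(
            f"binary trajectory {path!r} requires the optional MDAnalysis adapter"
        ) from exc
    u = mda.Universe(path)  # pragma: no cover
    frames = np.array([u.atoms.positions * NM_PER_ANGSTROM for _ in u.trajectory])
    times = np.arange(len(frames)) * stride_ps
    return frames, times  # pragma: no cover


def load_trajectory(
    paths: list[str],
    structure: StructureModel,
    stride_ps: float = 1.0,
) -> TrajectoryEnsemble:
    """Load one replica per input file; atom counts must match ``structure``."""
    if not paths:
        raise EmptyInputError("no trajectory files given")
    replicas, times = [], []
    for path in paths:
        ext = os.path.splitext(path)[1].lower()
        if ext in (".dcd", ".xtc", ".trr"):
            frames, t = _read_binary_trajectory(path, stride_ps)
        else:
            frames, t = _read_text_trajectory(path)
        if frames.shape[1] != structure.n_atoms:
            raise ShapeError(
                f"{path}: {frames.shape[1]} atoms but structure has "
                f"{structure.n_atoms}"
            )
        replicas.append(frames)
        times.append(t)
    return TrajectoryEnsemble(replicas=replicas, times=times).with_masks(structure)


def ensemble_from_arrays(
    replicas: list[np.ndarray],
    structure: StructureModel | None = None,
    stride_ps: float = 1.0,
) -> TrajectoryEnsemble:
    """Build an ensemble from in-memory frame arrays with synthesized times."""
    times = [np.arange(len(r)) * stride_ps for r in replicas]
    ens = TrajectoryEnsemble(replicas=[np.asarray(r) for r in replicas], times=times)
    if structure is not None:
        ens.with_masks(structure)
    return ens


# ---------------------------------------------------------------------------
# merge_replicas
# ---------------------------------------------------------------------------

def merge_replicas(
    ens: TrajectoryEnsemble, discard_head_ns: float = 0.0
) -> TrajectoryEnsemble:
    """Concatenate replicas after dropping the first ``discard_head_ns`` of each.

    The returned single-replica ensemble records the original replica
    boundaries in :attr:`TrajectoryEnsemble.replica_edges` so the convergence
    stage can split the merged trajectory back into per-replica halves.
    Frames with ``t - t0 < discard`` are removed (strict: the frame at exactly
    the discard offset is retained).
    """
    discard_ps = discard_head_ns * 1000.0
    kept_frames: list[np.ndarray] = []
    kept_times: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    offset = 0.0
    for k, (frames, t) in enumerate(zip(ens.replicas, ens.times)):
        keep = (t - t[0]) >= discard_ps
        if not np.any(keep):
            raise EmptyInputError(
                f"replica {k}: discard of {discard_head_ns} ns removes all frames"
            )
        kept = frames[keep]
        tk = t[keep]
        kept_frames.append(kept)
        # shift times so the merged axis is contiguous and strictly increasing
        tk = tk - tk[0] + offset
        spacing = tk[1] - tk[0] if len(tk) > 1 else 1.0
        offset = tk[-1] + spacing
        kept_times.append(tk)
        edges.append((k, int(kept.shape[0])))
    merged = TrajectoryEnsemble(
        replicas=[np.concatenate(kept_frames, axis=0)],
        times=[np.concatenate(kept_times)],
        selection_masks=dict(ens.selection_masks),
    )
    merged.replica_edges = edges
    return merged
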