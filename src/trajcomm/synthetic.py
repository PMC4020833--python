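"""Synthetic structures and trajectory ensembles with planted statistics.

Every downstream statistic computed by this package (RMSF, PCA, LFA kernels,
commute times) is a second-moment functional of the displacement field, so
zero-mean Gaussian ensembles with a planted block-correlation structure are
a complete stand-in for MD output: the ground truth of every analysis stage
is known by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import StructureModel, TrajectoryEnsemble
from .errors import ArgumentError

#: Consecutive CA-CA distance in the extended toy chain (nm).
CA_SPACING_NM = 0.38


# ---------------------------------------------------------------------------
# PlantedSpec
# ---------------------------------------------------------------------------

@dataclass
class PlantedSpec:
    """Declarative description of the statistical structure to plant.

    cluster_blocks: (residue_lo, residue_hi, rho, sigma_nm) tuples; atoms of
    a block share per-axis correlation ``rho`` with fluctuation ``sigma``.
    replica_drift: per-replica rigid offsets (3-vectors, nm) applied to the
    residues in ``drift_region``; an empty list means no drift anywhere.
    """

    n_residues: int
    cluster_blocks: list[tuple[int, int, float, float]] = field(default_factory=list)
    background_sigma: float = 0.03
    hbond_schedule: list[tuple[int, int, int, float]] = field(default_factory=list)
    replica_drift: list[np.ndarray] = field(default_factory=list)
    drift_region: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sigma <= 0:
            raise ArgumentError("background_sigma must be > 0")
        spans: list[tuple[int, int]] = []
        for lo, hi, rho, sigma in self.cluster_blocks:
            if not (0.0 <= rho <= 1.0):
                raise ArgumentError(f"block correlation {rho} outside [0, 1]")
            if sigma <= 0:
                raise ArgumentError("block sigma must be > 0")
            if lo > hi:
                raise ArgumentError(f"invalid block range {lo}-{hi}")
            for a, b in spans:
                if lo <= b and hi >= a:
                    raise ArgumentError("cluster blocks overlap")
            spans.append((lo, hi))
        for entry in self.hbond_schedule:
            occ = entry[3]
            if not (0.0 <= occ <= 1.0):
                raise ArgumentError(f"occupancy {occ} outside [0, 1]")


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def make_toy_structure(
    n_residues: int,
    geometry: str = "extended",
    with_hydrogens: bool = True,
    first_residue: int = 1,
) -> StructureModel:
    """Idealized poly-alanine-like backbone chain (N, H, CA, C, O per residue).

    Geometries: ``extended`` places residues along +x with a 0.38 nm CA step;
    ``helix`` uses ideal alpha-helix parameters (0.15 nm rise, 100 deg turn,
    0.23 nm radius); ``coil`` is a deterministic self-avoiding-ish random
    walk seeded from ``n_residues``.  Amide N (with its H when requested) is
    the donor; carbonyl O the acceptor.  Output is fully deterministic.
    """
    if n_residues < 2:
        raise ArgumentError("n_residues must be >= 2")
    if geometry not in ("helix", "extended", "coil"):
        raise ArgumentError(f"unknown geometry {geometry!r}")

    ca = _ca_trace(n_residues, geometry)

    atom_ids, names, elements, resnums, resnames, positions, bonds = (
        [], [], [], [], [], [], [])
    serial = 1
    for i in range(n_residues):
        resnum = first_residue + i
        # local frame along the chain for placing substituent atoms
        ahead = ca[min(i + 1, n_residues - 1)] - ca[max(i - 1, 0)]
        t = ahead / (np.linalg.norm(ahead) or 1.0)
        up = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(t, up)) > 0.9:
            up = np.array([0.0, 1.0, 0.0])
        side = np.cross(t, up)
        side /= np.linalg.norm(side)

        n_pos = ca[i] - 0.145 * t + 0.05 * side
        h_pos = n_pos + 0.10 * side
        c_pos = ca[i] + 0.152 * t - 0.04 * side
        o_pos = c_pos + 0.123 * side

        entries = [("N", "N", n_pos)]
        if with_hydrogens:
            entries.append(("H", "H", h_pos))
        entries += [("CA", "C", ca[i]), ("C", "C", c_pos), ("O", "O", o_pos)]
        n_serial = serial
        for name, element, pos in entries:
            atom_ids.append(serial)
            names.append(name)
            elements.append(element)
            resnums.append(resnum)
            resnames.append("ALA")
            positions.append(pos)
            if name == "H":
                bonds.append((n_serial, serial))
            serial += 1

    return StructureModel(
        atom_ids=np.array(atom_ids),
        atom_names=names,
        elements=elements,
        residue_numbers=np.array(resnums),
        residue_names=resnames,
        positions=np.array(positions),
        bonds=bonds,
    )


def _ca_trace(n: int, geometry: str) -> np.ndarray:
    if geometry == "extended":
        return np.column_stack(
            [np.arange(n) * CA_SPACING_NM, np.zeros(n), np.zeros(n)]
        )
    if geometry == "helix":
        theta = np.deg2rad(100.0) * np.arange(n)
        return np.column_stack(
            [0.23 * np.cos(theta), 0.23 * np.sin(theta), 0.15 * np.arange(n)]
        )
    rng = np.random.default_rng(n)  # coil: deterministic in n
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    ca = np.vstack([np.zeros(3), np.cumsum(CA_SPACING_NM * steps, axis=0)])
    return ca


# ---------------------------------------------------------------------------
# Gaussian ensembles with planted block covariance
# ---------------------------------------------------------------------------

def sample_ensemble(
    structure: StructureModel,
    spec: PlantedSpec,
    n_frames: int,
    n_replicas: int = 1,
    stride_ps: float = 1.0,
) -> TrajectoryEnsemble:
    """Draw frames = reference + Gaussian displacement realizing ``spec``.

    Inside a block every atom's displacement on axis mu is
    ``sigma * (sqrt(rho) * Z_block_mu + sqrt(1-rho) * eps_atom_mu)`` so any
    two block atoms have per-axis correlation exactly ``rho``; atoms outside
    all blocks fluctuate independently with ``background_sigma``.  Replica k
    is additionally offset rigidly by ``replica_drift[k]`` on the atoms of
    ``drift_region``.  Bit-reproducible from ``spec.seed``.
    """
    if n_frames < 1:
        raise ArgumentError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    n_atoms = structure.n_atoms
    resnums = structure.residue_numbers

    block_of_atom = np.full(n_atoms, -1)
    for b, (lo, hi, _rho, _sigma) in enumerate(spec.cluster_blocks):
        block_of_atom[(resnums >= lo) & (resnums <= hi)] = b

    drift_mask = np.zeros(n_atoms, dtype=bool)
    if spec.drift_region is not None:
        lo, hi = spec.drift_region
        drift_mask = (resnums >= lo) & (resnums <= hi)

    replicas = []
    for k in range(n_replicas):
        disp = rng.normal(size=(n_frames, n_atoms, 3)) * spec.background_sigma
        for b, (lo, hi, rho, sigma) in enumerate(spec.cluster_blocks):
            members = np.nonzero(block_of_atom == b)[0]
            shared = rng.normal(size=(n_frames, 1, 3))
            local = rng.normal(size=(n_frames, len(members), 3))
            disp[:, members, :] = sigma * (
                math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * local
            )
        frames = structure.positions[None, :, :] + disp
        if k < len(spec.replica_drift) and np.any(drift_mask):
            frames[:, drift_mask, :] += np.asarray(spec.replica_drift[k], float)
        for entry in spec.hbond_schedule:
            _apply_hbond_schedule(frames, structure, entry, rng)
        replicas.append(frames)

    times = [np.arange(n_frames) * stride_ps for _ in range(n_replicas)]
    ens = TrajectoryEnsemble(replicas=replicas, times=times)
    return ens.with_masks(structure)


def _apply_hbond_schedule(
    frames: np.ndarray,
    structure: StructureModel,
    entry: tuple[int, int, int, float],
    rng: np.random.Generator,
) -> None:
    """Overwrite donor/H/acceptor positions so the triplet satisfies the
    H-bond criteria in a random ``round(occupancy * n_frames)``-frame subset
    (collinear at 3.0 A) and fails them elsewhere (5.0 A).  Donor and
    hydrogen are pinned to their reference positions so sampling noise cannot
    blur the planted geometry."""
    donor_id, hydrogen_id, acceptor_id, occupancy = entry
    id_to_idx = {int(a): i for i, a in enumerate(structure.atom_ids)}
    d, h, a = (id_to_idx[int(donor_id)], id_to_idx[int(hydrogen_id)],
               id_to_idx[int(acceptor_id)])
    n_frames = len(frames)
    n_on = round(float(occupancy) * n_frames)
    on = rng.permutation(n_frames)[:n_on]
    dh = structure.positions[h] - structure.positions[d]
    u = dh / np.linalg.norm(dh)
    frames[:, d] = structure.positions[d]
    frames[:, h] = structure.positions[h]
    frames[:, a] = structure.positions[d] + HBOND_OFF_DISTANCE_NM * u
    frames[on, a] = structure.positions[d] + HBOND_ON_DISTANCE_NM * u


# ---------------------------------------------------------------------------
# Planted hydrogen-bond frames
# ---------------------------------------------------------------------------

#: Planting margins, chosen safely inside/outside the 3.5 A / 120 deg
#: detection cutoffs so float noise can never flip a frame's class.
HBOND_ON_DISTANCE_NM = 0.30
HBOND_OFF_DISTANCE_NM = 0.50


def plant_hbond_frames(
    structure: StructureModel,
    donor_id: int,
    hydrogen_id: int,
    acceptor_id: int,
    occupancy: float,
    n_frames: int,
    seed: int = 0,
    stride_ps: float = 1.0,
) -> TrajectoryEnsemble:
    """Trajectory in which one donor/H/acceptor triplet satisfies the H-bond
    criteria in exactly ``round(occupancy * n_frames)`` uniformly chosen
    frames (collinear D-H...A at 3.0 A) and fails them everywhere else
    (D...A moved to 5.0 A).  All other atoms stay at reference positions.
    """
    if not (0.0 <= occupancy <= 1.0):
        raise ArgumentError(f"occupancy {occupancy} outside [0, 1]")
    if n_frames < 1:
        raise ArgumentError("n_frames must be >= 1")
    id_to_idx = {int(a): i for i, a in enumerate(structure.atom_ids)}
    try:
        d = id_to_idx[int(donor_id)]
        h = id_to_idx[int(hydrogen_id)]
        a = id_to_idx[int(acceptor_id)]
    except KeyError as exc:
        raise ArgumentError(f"unknown atom_id {exc.args[0]}")
    if structure.hbond_roles[d] != "donor-heavy":
        raise ArgumentError(f"atom_id {donor_id} is not a donor-heavy atom")
    if structure.hbond_roles[h] != "hydrogen":
        raise ArgumentError(f"atom_id {hydrogen_id} is not an H-bond hydrogen")
    if not structure.acceptor_flags[a]:
        raise ArgumentError(f"atom_id {acceptor_id} is not an acceptor")

    n_on = round(occupancy * n_frames)
    rng = np.random.default_rng(seed)
    on_frames = set(rng.permutation(n_frames)[:n_on].tolist())

    dh = structure.positions[h] - structure.positions[d]
    norm = np.linalg.norm(dh)
    if norm == 0:
        raise ArgumentError("donor and hydrogen coincide")
    u = dh / norm  # D->H direction; acceptor placed on this ray => DHA 180 deg

    frames = np.repeat(structure.positions[None, :, :], n_frames, axis=0)
    for k in range(n_frames):
        dist = HBOND_ON_DISTANCE_NM if k in on_frames else HBOND_OFF_DISTANCE_NM
        frames[k, a] = structure.positions[d] + dist * u
    ens = TrajectoryEnsemble(
        replicas=[frames], times=[np.arange(n_frames) * stride_ps]
    )
    return ens.with_masks(structure)
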