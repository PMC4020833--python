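"""Regional geometry: superposition, RMSD/RMSF, centroid distances, H-bonds.

Distances are nm internally; the H-bond cutoffs are taken in Angstrom at the
API surface (the convention the criteria are usually quoted in) and converted
internally.  The donor-hydrogen-acceptor angle cutoff is applied at the
hydrogen: a perfectly linear D-H...A geometry scores 180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NM_PER_ANGSTROM, RegionScheme, StructureModel, TrajectoryEnsemble
from .errors import (
    DegenerateError,
    InsufficientDataError,
    PreconditionError,
    SchemeError,
    StrideError,
    TrajcommError,
)

#: Default geometric H-bond criteria (donor...acceptor distance, DHA angle).
DEFAULT_HBOND_DIST_A = 3.5
DEFAULT_HBOND_ANGLE_DEG = 120.0

#: d1/d2 anchor regions: (region pair) resolved through the region scheme.
DISTANCE_ANCHORS = {
    "d1": ("JM-B", "N-lobe"),
    "d2": ("JM-S", "C-lobe"),
}


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------

def superpose(
    frame: np.ndarray,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of ``frame`` onto ``reference``.

    The rotation/translation is fitted on ``fit_selection`` (indices into the
    atom axis; all atoms when None) and applied to the whole frame.  Returns
    the transformed frame and the post-fit RMSD over the fit selection, nm.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_selection is None:
        fit_selection = np.arange(frame.shape[0])
    fit_selection = np.asarray(fit_selection)
    if len(fit_selection) < 3:
        raise DegenerateError("rigid fit needs at least 3 atoms")
    x = frame[fit_selection]
    y = reference[fit_selection]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (frame - xc) @ rot.T + yc
    delta = moved[fit_selection] - y
    rmsd = float(np.sqrt((delta ** 2).sum() / len(fit_selection)))
    return moved, rmsd


def align_frames(
    frames: np.ndarray, reference: np.ndarray, fit_selection: np.ndarray | None = None
) -> np.ndarray:
    """Superpose every frame onto ``reference``; returns the aligned stack."""
    return np.array([superpose(f, reference, fit_selection)[0] for f in frames])


def align_to_mean(
    frames: np.ndarray,
    fit_selection: np.ndarray | None = None,
    n_iter: int = 2,
) -> np.ndarray:
    """Iteratively superpose all frames onto their running mean structure."""
    aligned = align_frames(frames, frames[0], fit_selection)
    for _ in range(n_iter):
        aligned = align_frames(aligned, aligned.mean(axis=0), fit_selection)
    return aligned


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def regional_rmsd(
    ens: TrajectoryEnsemble,
    scheme: RegionScheme,
    structure: StructureModel,
    region: str,
    fit_region: str | None = None,
    subset: str = "backbone",
) -> np.ndarray:
    """Per-frame RMSD of a region's atoms vs the first frame.

    Frames are first globally superposed on ``fit_region`` (default: the
    whole selection); the RMSD is then evaluated on ``region`` without
    re-fitting, so rigid displacements of a sub-region relative to the fit
    frame remain visible.
    """
    frames = ens.frames()
    region_idx = scheme.atom_indices(structure, region, subset)
    if fit_region is None or fit_region == region:
        fit_idx = region_idx
    else:
        fit_idx = scheme.atom_indices(structure, fit_region, subset)
    reference = frames[0]
    out = np.empty(len(frames))
    for k, frame in enumerate(frames):
        moved, _ = superpose(frame, reference, fit_idx)
        delta = moved[region_idx] - reference[region_idx]
        out[k] = np.sqrt((delta ** 2).sum() / len(region_idx))
    return out


def rmsf(
    ens: TrajectoryEnsemble,
    structure: StructureModel,
    selection: str = "backbone",
    by: str = "atom",
) -> tuple[np.ndarray, np.ndarray]:
    """Root-mean-square fluctuation about the time-average structure.

    Frames are superposed on ``selection`` onto the mean structure first.
    Returns ``(labels, values_nm)``: per-atom indices or per-residue numbers
    depending on ``by`` (residue mode averages RMSF over the residue's
    selected atoms).
    """
    frames = ens.frames()
    if len(frames) < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames")
    sel = np.nonzero(structure.selection_mask(selection))[0]
    if len(sel) == 0:
        raise SchemeError(f"selection {selection!r} is empty")
    aligned = align_to_mean(frames[:, sel, :])
    mean = aligned.mean(axis=0)
    msf = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)  # (n_sel,)
    per_atom = np.sqrt(msf)
    if by == "atom":
        return sel, per_atom
    if by == "residue":
        resnums = structure.residue_numbers[sel]
        unique = np.unique(resnums)
        values = np.array([per_atom[resnums == r].mean() for r in unique])
        return unique, values
    raise TrajcommError(f"unknown RMSF aggregation {by!r}")


# ---------------------------------------------------------------------------
# Centroid distances (d1 / d2)
# ---------------------------------------------------------------------------

@dataclass
class DistanceSeries:
    name: str
    values_nm: np.ndarray
    times_ps: np.ndarray
    anchors: tuple[str, str]

    def __post_init__(self) -> None:
        if np.any(self.values_nm < 0):
            raise TrajcommError("distance series has negative entries")


def centroid_distance(
    ens: TrajectoryEnsemble,
    scheme: RegionScheme,
    structure: StructureModel,
    pair: str = "d1",
    stride_ps: float = 10.0,
    subset: str = "heavy",
) -> DistanceSeries:
    """Distance between the unweighted centroids of two anchor regions.

    ``pair`` is ``d1`` (JM-B vs N-lobe), ``d2`` (JM-S vs C-lobe) or
    ``"regionA:regionB"`` for a custom pair.  Frames are sampled every
    ``stride_ps``; the stride must be a multiple of the frame spacing.
    """
    if pair in DISTANCE_ANCHORS:
        region_a, region_b = DISTANCE_ANCHORS[pair]
        name = pair
    elif ":" in pair:
        region_a, region_b = pair.split(":", 1)
        name = "custom"
    else:
        raise SchemeError(f"unknown distance pair {pair!r}")
    idx_a = scheme.atom_indices(structure, region_a, subset)
    idx_b = scheme.atom_indices(structure, region_b, subset)

    frames = ens.frames()
    times = ens.all_times()
    spacing = times[1] - times[0] if len(times) > 1 else stride_ps
    step = stride_ps / spacing
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise StrideError(
            f"stride {stride_ps} ps is not a multiple of frame spacing {spacing} ps"
        )
    step = int(round(step))
    frames = frames[::step]
    times = times[::step]
    ca = frames[:, idx_a, :].mean(axis=1)
    cb = frames[:, idx_b, :].mean(axis=1)
    values = np.linalg.norm(ca - cb, axis=1)
    return DistanceSeries(name=name, values_nm=values, times_ps=times,
                          anchors=(region_a, region_b))


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(
    frame: np.ndarray,
    structure: StructureModel,
    dist_cut_a: float = DEFAULT_HBOND_DIST_A,
    angle_cut_deg: float = DEFAULT_HBOND_ANGLE_DEG,
    allow_intra_residue: bool = False,
) -> set[tuple[int, int, int]]:
    """All (donor_id, hydrogen_id, acceptor_id) triplets satisfying the
    geometric criteria in one frame: donor...acceptor distance <= cutoff and
    D-H...A angle at the hydrogen >= cutoff.

    Donor and acceptor must belong to different residues unless
    ``allow_intra_residue``.  Requires explicit hydrogens on the structure.
    """
    if not structure.has_hydrogens:
        raise PreconditionError("H-bond detection requires explicit hydrogens")
    frame = np.asarray(frame, dtype=float)
    dist_cut = dist_cut_a * NM_PER_ANGSTROM
    cos_cut = np.cos(np.deg2rad(angle_cut_deg))

    hd_pairs = structure.hydrogen_donor_pairs()
    acceptors = np.nonzero(structure.acceptor_flags)[0]
    if len(hd_pairs) == 0 or len(acceptors) == 0:
        return set()
    found: set[tuple[int, int, int]] = set()
    acc_pos = frame[acceptors]
    for h, d in hd_pairs:
        da = np.linalg.norm(acc_pos - frame[d], axis=1)
        near = acceptors[da <= dist_cut]
        for a in near:
            if a == d or a == h:
                continue
            if (not allow_intra_residue
                    and structure.residue_numbers[a] == structure.residue_numbers[d]):
                continue
            hd_vec = frame[d] - frame[h]
            ha_vec = frame[a] - frame[h]
            nh, na = np.linalg.norm(hd_vec), np.linalg.norm(ha_vec)
            if nh == 0 or na == 0:
                continue
            # angle at H between bonds H->D and H->A; cos(angle) <= cos(cutoff)
            if np.dot(hd_vec, ha_vec) / (nh * na) <= cos_cut:
                found.add((
                    int(structure.atom_ids[d]),
                    int(structure.atom_ids[h]),
                    int(structure.atom_ids[a]),
                ))
    return found


@dataclass
class HBondRecord:
    """Residue-level H-bond contact with its per-frame presence series."""

    donor_residue: int
    acceptor_residue: int
    series: np.ndarray  # bool per evaluated frame
    times_ps: np.ndarray

    @property
    def occupancy_percent(self) -> float:
        return 100.0 * float(np.count_nonzero(self.series)) / len(self.series)

    @property
    def label(self) -> str:
        return f"{self.donor_residue}...{self.acceptor_residue}"


def hbond_occupancy(
    ens: TrajectoryEnsemble,
    structure: StructureModel,
    pairs: list[tuple[int, int]],
    stride_ps: float = 100.0,
    dist_cut_a: float = DEFAULT_HBOND_DIST_A,
    angle_cut_deg: float = DEFAULT_HBOND_ANGLE_DEG,
) -> list[HBondRecord]:
    """Residue-level H-bond occupancy over strided frames.

    A (res_a, res_b) pair counts as bonded in a frame when ANY
    donor/hydrogen/acceptor atom pairing between the two residues — in either
    donor->acceptor direction — satisfies the criteria.
    """
    resnums = set(int(r) for r in structure.residue_numbers)
    for a, b in pairs:
        if a not in resnums or b not in resnums:
            raise SchemeError(f"residue pair ({a}, {b}) not in structure")
    frames = ens.frames()
    times = ens.all_times()
    spacing = times[1] - times[0] if len(times) > 1 else stride_ps
    step = stride_ps / spacing
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise StrideError(
            f"stride {stride_ps} ps is not a multiple of frame spacing {spacing} ps"
        )
    step = int(round(step))
    frames = frames[::step]
    times = times[::step]

    id_to_res = {
        int(structure.atom_ids[i]): int(structure.residue_numbers[i])
        for i in range(structure.n_atoms)
    }
    records = []
    per_frame_sets = [
        detect_hbonds(f, structure, dist_cut_a, angle_cut_deg) for f in frames
    ]
    for res_a, res_b in pairs:
        series = np.zeros(len(frames), dtype=bool)
        for k, triplets in enumerate(per_frame_sets):
            for d, _h, a in triplets:
                rd, ra = id_to_res[d], id_to_res[a]
                if {rd, ra} == {res_a, res_b}:
                    series[k] = True
                    break
        records.append(HBondRecord(res_a, res_b, series, times))
    return records
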