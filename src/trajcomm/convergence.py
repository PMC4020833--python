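"""Ensemble-based convergence analysis of merged multi-replica trajectories.

Representative conformations ("references") are drawn at random and every
frame is binned to its nearest reference by global Calpha RMSD.  The merged
trajectory is split into four quarters (two halves per replica); a reference
missing from one quarter ("lone reference") signals non-convergence.  All
frames are pre-aligned once onto the merged average structure, so the
pairwise RMSD is the coordinate RMS difference in that common frame — a
deterministic and O(F) approximation of pairwise optimal fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StructureModel, TrajectoryEnsemble
from .errors import ArgumentError, EmptyInputError, LabelingError
from .geometry import align_to_mean

DEFAULT_R_NM = 0.1


@dataclass
class ConvergenceReport:
    references: list[int]                 # frame indices of reference structures
    reference_times_ps: list[float]
    assignment: np.ndarray                # (F,) reference index per frame
    quarter_labels: np.ndarray            # (F,) quarter id per frame
    populations: np.ndarray               # (n_refs, n_quarters)
    r_nm: float
    seed: int

    def __post_init__(self) -> None:
        if self.r_nm <= 0:
            raise ArgumentError("cutoff r must be > 0")

    @property
    def lone_references(self) -> list[int]:
        """References with at least one empty quarter."""
        empty = (self.populations == 0).any(axis=1)
        return [self.references[i] for i in np.nonzero(empty)[0]]

    @property
    def balance_scores(self) -> np.ndarray:
        """Per-reference min/max population ratio across quarters."""
        mx = self.populations.max(axis=1)
        mn = self.populations.min(axis=1)
        out = np.zeros(len(self.references))
        nonzero = mx > 0
        out[nonzero] = mn[nonzero] / mx[nonzero]
        return out

    @property
    def min_balance(self) -> float:
        return float(self.balance_scores.min()) if len(self.references) else 0.0


def _aligned_calpha(ens: TrajectoryEnsemble, structure: StructureModel) -> np.ndarray:
    ca = np.nonzero(structure.selection_mask("calpha"))[0]
    frames = ens.frames()[:, ca, :]
    return align_to_mean(frames)


def _rmsd_to(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    delta = frames - ref[None]
    return np.sqrt((delta ** 2).sum(axis=(1, 2)) / frames.shape[1])


def pick_references(
    ens: TrajectoryEnsemble,
    structure: StructureModel,
    r_nm: float = DEFAULT_R_NM,
    seed: int = 0,
    _aligned: np.ndarray | None = None,
) -> list[int]:
    """Iterative random cover: draw an unassigned frame uniformly at random,
    make it a reference and absorb every unassigned frame within RMSD < r;
    repeat until all frames are assigned.  Returns reference frame indices
    in pick order; deterministic given ``seed``.
    """
    if r_nm <= 0:
        raise ArgumentError("cutoff r must be > 0")
    aligned = _aligned_calpha(ens, structure) if _aligned is None else _aligned
    n_frames = len(aligned)
    if n_frames == 0:
        raise EmptyInputError("no frames")
    rng = np.random.default_rng(seed)
    unassigned = np.ones(n_frames, dtype=bool)
    references: list[int] = []
    while unassigned.any():
        pool = np.nonzero(unassigned)[0]
        ref = int(pool[rng.integers(len(pool))])
        references.append(ref)
        rmsd = _rmsd_to(aligned[pool], aligned[ref])
        unassigned[pool[rmsd < r_nm]] = False
    return references


def quarter_labels_for(ens: TrajectoryEnsemble) -> np.ndarray:
    """Quarter id per merged frame: each original replica split in two halves.

    Uses :attr:`TrajectoryEnsemble.replica_edges` when present (merged
    ensemble); otherwise each replica of a multi-replica ensemble is split
    in halves directly.
    """
    if ens.replica_edges is not None:
        counts = [n for _, n in ens.replica_edges]
    else:
        counts = [r.shape[0] for r in ens.replicas]
    labels = np.empty(sum(counts), dtype=int)
    offset = 0
    q = 0
    for n in counts:
        half = n // 2
        labels[offset:offset + half] = q
        labels[offset + half:offset + n] = q + 1 if n > 1 else q
        offset += n
        q += 2
    return labels


def bin_by_reference(
    ens: TrajectoryEnsemble,
    structure: StructureModel,
    references: list[int],
    r_nm: float,
    quarter_labels: np.ndarray | None = None,
    seed: int = 0,
    _aligned: np.ndarray | None = None,
) -> ConvergenceReport:
    """Assign every frame to its nearest reference (ties at <1e-9 to the
    earlier-picked one) and tabulate populations per trajectory quarter.

    Frames farther than ``r_nm`` from every reference still bin to the
    nearest one so the binning is an exact partition of the trajectory.
    """
    aligned = _aligned_calpha(ens, structure) if _aligned is None else _aligned
    n_frames = len(aligned)
    if quarter_labels is None:
        quarter_labels = quarter_labels_for(ens)
    quarter_labels = np.asarray(quarter_labels)
    if len(quarter_labels) != n_frames:
        raise LabelingError(
            f"{len(quarter_labels)} quarter labels for {n_frames} frames"
        )
    dists = np.stack(
        [_rmsd_to(aligned, aligned[ref]) for ref in references], axis=1
    )  # (F, n_refs)
    # nearest wins; earlier-picked reference wins near-ties deterministically
    best = dists.min(axis=1, keepdims=True)
    assignment = (dists <= best + 1e-9).argmax(axis=1)
    n_quarters = int(quarter_labels.max()) + 1
    populations = np.zeros((len(references), n_quarters), dtype=int)
    np.add.at(populations, (assignment, quarter_labels), 1)
    times = ens.all_times()
    return ConvergenceReport(
        references=list(references),
        reference_times_ps=[float(times[i]) for i in references],
        assignment=assignment,
        quarter_labels=quarter_labels,
        populations=populations,
        r_nm=r_nm,
        seed=seed,
    )


def convergence_scan(
    ens: TrajectoryEnsemble,
    structure: StructureModel,
    r_nm: float = DEFAULT_R_NM,
    n_runs: int = 5,
    base_seed: int = 0,
) -> tuple[list[ConvergenceReport], int]:
    """Repeat pick+bin with ``n_runs`` seeds; the chosen run maximizes the
    minimum per-reference balance score (a reproducible stand-in for the
    visual 'better represented' judgement).  Returns (reports, chosen index).
    """
    if n_runs < 1:
        raise ArgumentError("n_runs must be >= 1")
    aligned = _aligned_calpha(ens, structure)
    labels = quarter_labels_for(ens)
    reports = []
    for k in range(n_runs):
        seed = base_seed + k
        refs = pick_references(ens, structure, r_nm, seed, _aligned=aligned)
        reports.append(
            bin_by_reference(ens, structure, refs, r_nm, labels, seed,
                             _aligned=aligned)
        )
    chosen = int(np.argmax([rep.min_balance for rep in reports]))
    return reports, chosen
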