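"""Modular communication network: independent dynamic segments from local
feature analysis, proximity/persistent-contact graphs, commute-time matrix
and greedy growth of communication pathways.

Commute time between two residues is implemented as the variance of their
inter-Calpha distance over the ensemble ("communication propensity"): rigidly
co-moving residues have CT = 0 and communicate efficiently, independently
fluctuating ones have large CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .core import NM_PER_ANGSTROM, RegionScheme, StructureModel, TrajectoryEnsemble
from .errors import (
    ArgumentError,
    InsufficientDataError,
    PreconditionError,
    SchemeError,
    ThresholdError,
)
from .modes import ModeSet

DEFAULT_D_CUT_A = 3.6
DEFAULT_CONTACT_DIST_A = 4.0
DEFAULT_PERSISTENCE = 0.5
DEFAULT_KEEP_FRACTION = 0.01
DEFAULT_CT_TARGET_FRACTION = 0.10
DEFAULT_HUB_DEGREE = 5
MIN_IDS_SIZE = 3


# ---------------------------------------------------------------------------
# Distance statistics over the ensemble
# ---------------------------------------------------------------------------

def _residue_atom_groups(
    structure: StructureModel, subset: str = "heavy"
) -> tuple[np.ndarray, list[np.ndarray]]:
    mask = structure.selection_mask(subset)
    residues = structure.residue_ids
    groups = [
        np.nonzero(mask & (structure.residue_numbers == r))[0] for r in residues
    ]
    return residues, groups


def _min_dist_frame(frame: np.ndarray, padded: np.ndarray, width: int) -> np.ndarray:
    """Residue-pair minimum atom distance matrix for one frame, shape (n, n).

    Residues are padded to a common atom count by repeating their first atom
    (the repeat can never win the minimum against a different residue), which
    keeps the reduction fully vectorized.
    """
    n = len(padded)
    pts = frame[padded.ravel()]                          # (n*width, 3)
    d = cdist(pts, pts).reshape(n, width, n, width)
    return d.min(axis=(1, 3))


def _padded_groups(groups: list[np.ndarray]) -> tuple[np.ndarray, int]:
    width = max(len(g) for g in groups)
    padded = np.empty((len(groups), width), dtype=int)
    for i, g in enumerate(groups):
        padded[i, :len(g)] = g
        padded[i, len(g):] = g[0]
    return padded, width


def mean_min_distance(
    ens: TrajectoryEnsemble,
    structure: StructureModel,
    subset: str = "heavy",
) -> np.ndarray:
    """Time-average over frames of the smallest inter-atom distance between
    each residue pair (nm, symmetric, zero diagonal)."""
    _residues, groups = _residue_atom_groups(structure, subset)
    padded, width = _padded_groups(groups)
    frames = ens.frames()
    acc = np.zeros((len(groups), len(groups)))
    for frame in frames:
        acc += _min_dist_frame(frame, padded, width)
    return acc / len(frames)


def neighbor_graph(
    dist_matrix: np.ndarray,
    residues: np.ndarray,
    d_cut_a: float = DEFAULT_D_CUT_A,
) -> nx.Graph:
    """Undirected graph with an edge where the mean smallest distance is
    below ``d_cut_a`` (Angstrom); no self-edges."""
    dist_matrix = np.asarray(dist_matrix)
    if not np.allclose(dist_matrix, dist_matrix.T):
        raise ArgumentError("distance matrix must be symmetric")
    cut_nm = d_cut_a * NM_PER_ANGSTROM
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in residues)
    n = len(residues)
    for i in range(n):
        for j in range(i + 1, n):
            if dist_matrix[i, j] < cut_nm:
                g.add_edge(int(residues[i]), int(residues[j]))
    return g


def contact_graph(
    ens: TrajectoryEnsemble,
    structure: StructureModel,
    contact_dist_a: float = DEFAULT_CONTACT_DIST_A,
    persistence: float = DEFAULT_PERSISTENCE,
) -> nx.Graph:
    """Persistent non-bonded contact graph.

    Edge (a, b) when the fraction of frames in which any inter-residue
    heavy-atom pair lies within ``contact_dist_a`` Angstrom is at least
    ``persistence``; sequence-adjacent residue pairs (covalently linked) are
    excluded.
    """
    residues, groups = _residue_atom_groups(structure, "heavy")
    n = len(residues)
    padded, width = _padded_groups(groups)
    frames = ens.frames()
    cut_nm = contact_dist_a * NM_PER_ANGSTROM
    counts = np.zeros((n, n))
    for frame in frames:
        counts += _min_dist_frame(frame, padded, width) <= cut_nm
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in residues)
    frac = counts / len(frames)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(int(residues[i]) - int(residues[j])) <= 1:
                continue
            if frac[i, j] >= persistence:
                g.add_edge(int(residues[i]), int(residues[j]),
                           persistence=float(frac[i, j]))
    return g


def commute_time(
    ens: TrajectoryEnsemble,
    structure: StructureModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Commute-time matrix: variance of the inter-residue Calpha distance.

    Returns (residues, ct_matrix) with ct in nm^2, symmetric, zero diagonal.
    """
    ca = np.nonzero(structure.selection_mask("calpha"))[0]
    if len(ca) == 0:
        raise SchemeError("structure has no Calpha atoms")
    frames = ens.frames()[:, ca, :]
    if len(frames) < 2:
        raise InsufficientDataError("commute time needs at least 2 frames")
    residues = structure.residue_numbers[ca]
    n = frames.shape[1]
    total = np.zeros((n, n))
    total_sq = np.zeros((n, n))
    for chunk in np.array_split(frames, max(1, len(frames) // 200)):
        diff = chunk[:, :, None, :] - chunk[:, None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=3))  # (f, n, n)
        total += dist.sum(axis=0)
        total_sq += (dist ** 2).sum(axis=0)
    f = len(frames)
    ct = total_sq / f - (total / f) ** 2
    ct = np.clip(ct, 0.0, None)
    np.fill_diagonal(ct, 0.0)
    return residues, ct


def choose_ct_cut(
    ct_matrix: np.ndarray,
    target_fraction: float = DEFAULT_CT_TARGET_FRACTION,
) -> float:
    """Smallest threshold at which the 95th-percentile residue (ranked by
    partner count at that threshold) communicates with
    ceil(target_fraction * N) partners."""
    ct = np.asarray(ct_matrix, dtype=float)
    n = len(ct)
    if n < 2:
        raise ThresholdError("matrix too small")
    off = ct[~np.eye(n, dtype=bool)]
    if np.allclose(off, off[0]):
        raise ThresholdError("degenerate commute-time matrix (all equal)")
    target = int(np.ceil(target_fraction * n))
    candidates = np.unique(off)
    lo, hi = 0, len(candidates) - 1
    # partner count per residue is monotone in the threshold: bisect
    def reaches(thr: float) -> bool:
        counts = (ct <= thr).sum(axis=1) - 1  # exclude self
        return float(np.percentile(counts, 95)) >= target
    if not reaches(candidates[hi]):
        return float(candidates[hi])
    while lo < hi:
        mid = (lo + hi) // 2
        if reaches(candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


# ---------------------------------------------------------------------------
# Local feature analysis -> independent dynamic segments
# ---------------------------------------------------------------------------

def lfa_segments(
    modes: ModeSet,
    structure: StructureModel,
    neighbors: nx.Graph,
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
    min_size: int = MIN_IDS_SIZE,
    max_seeds: int | None = None,
) -> tuple[np.ndarray, float, list[dict]]:
    """Independent dynamic segments from the retained-mode projection kernel.

    The kernel K(a, b) = sum_r v_r(a) . v_r(b) (3-vector dot product per
    residue) is row-normalized into a correlation-like matrix C.  p_cut is
    the (1 - keep_fraction) quantile of off-diagonal |C|.  Seeds are picked
    greedily by residual reconstruction error (diagonal of the deflated
    kernel); each segment is its seed plus the residues with |C| > p_cut
    that connect to the seed through the neighbor graph.  Seeds already
    absorbed into a segment are skipped; segments below ``min_size`` are
    dropped.

    Returns (lfa_corr, p_cut, segments) where each segment is a dict with
    ``seed`` and sorted ``residues``.
    """
    if modes.n_modes == 0:
        raise PreconditionError("no retained modes")
    if not (0.0 < keep_fraction < 1.0):
        raise ArgumentError("keep_fraction must be in (0, 1)")
    vecs = modes.eigenvectors                      # (m, n_res_atoms, 3)
    residues = structure.residue_numbers[modes.atom_indices]
    unique = np.unique(residues)
    if len(unique) != len(residues):
        # collapse multiple atoms per residue by summing their components
        collapsed = np.zeros((modes.n_modes, len(unique), 3))
        for k, r in enumerate(unique):
            collapsed[:, k, :] = vecs[:, residues == r, :].sum(axis=1)
        vecs = collapsed
    res_ids = unique

    # projection kernel onto the retained-mode subspace.  Thresholding uses
    # the unnormalized kernel: cosine-normalizing a rank-m kernel saturates
    # the correlations of low-amplitude residues (any two m-dim feature
    # vectors have a generic cosine) and drowns the planted structure.
    flat = vecs.transpose(1, 0, 2).reshape(len(res_ids), -1)  # (n, 3m)
    kernel = flat @ flat.T
    corr = kernel / np.abs(kernel).max()

    off = np.abs(corr[~np.eye(len(res_ids), dtype=bool)])
    p_cut = float(np.quantile(off, 1.0 - keep_fraction))

    n_seeds = max_seeds if max_seeds is not None else modes.n_modes
    residual = kernel.copy()
    taken: set[int] = set()
    segments: list[dict] = []
    for _ in range(n_seeds):
        err = np.diag(residual).copy()
        if err.max() <= 1e-12:
            break
        seed_idx = int(np.argmax(err))
        # deflate the kernel by the chosen seed's feature (Gram-Schmidt)
        row = residual[seed_idx].copy()
        residual = residual - np.outer(row, row) / row[seed_idx]
        if seed_idx in taken:
            continue
        members = _grow_segment(seed_idx, corr, p_cut, res_ids, neighbors)
        if len(members) < min_size:
            continue
        taken.update(members)
        segments.append({
            "seed": int(res_ids[seed_idx]),
            "residues": sorted(int(res_ids[m]) for m in members),
        })
    return corr, p_cut, segments


def _grow_segment(
    seed_idx: int,
    corr: np.ndarray,
    p_cut: float,
    res_ids: np.ndarray,
    neighbors: nx.Graph,
) -> set[int]:
    candidate = {
        i for i in range(len(res_ids))
        if i == seed_idx or abs(corr[seed_idx, i]) > p_cut
    }
    # keep candidates reachable from the seed through the neighbor graph
    # walking only over candidate residues: a segment is spatially contiguous
    id_of = {int(res_ids[i]): i for i in range(len(res_ids))}
    allowed = {int(res_ids[i]) for i in candidate}
    reached = {seed_idx}
    stack = [int(res_ids[seed_idx])]
    while stack:
        r = stack.pop()
        if r not in neighbors:
            continue
        for nb in neighbors.neighbors(r):
            if nb in allowed and id_of[nb] not in reached:
                reached.add(id_of[nb])
                stack.append(nb)
    return reached


# ---------------------------------------------------------------------------
# Communication pathways
# ---------------------------------------------------------------------------

def grow_cps(
    residues: np.ndarray,
    ct_matrix: np.ndarray,
    ct_cut: float,
    contacts: nx.Graph,
) -> list[list[int]]:
    """Greedy maximal chains of contacting residues whose every pair
    communicates within ``ct_cut``.

    Each contact edge with CT <= ct_cut seeds a chain; the chain is extended
    at either end by the contacting residue with the smallest worst-case CT
    to the current members (ties to the lowest residue number), as long as
    that worst-case CT stays within the cutoff.  Reversed duplicates and
    chains fully contained in a longer one are removed; output sorted by
    decreasing length then first residue.
    """
    idx_of = {int(r): i for i, r in enumerate(residues)}

    def ct(a: int, b: int) -> float:
        return float(ct_matrix[idx_of[a], idx_of[b]])

    chains: list[tuple[int, ...]] = []
    for a, b in sorted(tuple(sorted(e)) for e in contacts.edges):
        if ct(a, b) > ct_cut:
            continue
        chain = [a, b]
        members = {a, b}
        while True:
            best: tuple[float, int, int] | None = None  # (worst_ct, res, end)
            for end, tip in ((0, chain[0]), (1, chain[-1])):
                for cand in contacts.neighbors(tip):
                    if cand in members:
                        continue
                    worst = max(ct(cand, m) for m in chain)
                    if worst <= ct_cut and (best is None or (worst, cand) < best[:2]):
                        best = (worst, cand, end)
            if best is None:
                break
            _, cand, end = best
            if end == 0:
                chain.insert(0, cand)
            else:
                chain.append(cand)
            members.add(cand)
        key = tuple(chain) if chain[0] <= chain[-1] else tuple(reversed(chain))
        chains.append(key)

    unique = sorted(set(chains), key=lambda c: (-len(c), c))
    kept: list[tuple[int, ...]] = []
    kept_sets: list[set[int]] = []
    for chain in unique:
        s = set(chain)
        if any(s <= other for other in kept_sets):
            continue
        kept.append(chain)
        kept_sets.append(s)
    return [list(c) for c in kept]


# ---------------------------------------------------------------------------
# Network container and summary
# ---------------------------------------------------------------------------

@dataclass
class CommunicationNetwork:
    residues: np.ndarray
    retained_modes: int
    lfa_corr: np.ndarray
    p_cut: float
    ids_list: list[dict]
    mean_min_dist: np.ndarray
    neighbors: nx.Graph
    contacts: nx.Graph
    ct_matrix: np.ndarray
    ct_cut: float
    cps: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx_of = {int(r): i for i, r in enumerate(self.residues)}
        for chain in self.cps:
            for x, y in zip(chain, chain[1:]):
                if not self.contacts.has_edge(x, y):
                    raise ArgumentError(f"CP step {x}-{y} not a contact edge")
            for i, x in enumerate(chain):
                for y in chain[i + 1:]:
                    if self.ct_matrix[idx_of[x], idx_of[y]] > self.ct_cut + 1e-12:
                        raise ArgumentError(
                            f"CP pair {x}-{y} exceeds CT cutoff"
                        )
        for seg in self.ids_list:
            if seg["seed"] not in seg["residues"]:
                raise ArgumentError("IDS does not contain its seed")

    def hubs(self, hub_degree: int = DEFAULT_HUB_DEGREE) -> list[int]:
        counts: dict[int, int] = {}
        for chain in self.cps:
            for r in set(chain):
                counts[r] = counts.get(r, 0) + 1
        return sorted(r for r, c in counts.items() if c >= hub_degree)

    def pairwise_paths(self) -> set[tuple[int, int]]:
        """Non-redundant residue pairs co-occurring in at least one CP."""
        pairs: set[tuple[int, int]] = set()
        for chain in self.cps:
            s = sorted(set(chain))
            for i, x in enumerate(s):
                for y in s[i + 1:]:
                    pairs.add((x, y))
        return pairs


def build_network(
    ens: TrajectoryEnsemble,
    structure: StructureModel,
    modes: ModeSet,
    retained_modes: int,
    d_cut_a: float = DEFAULT_D_CUT_A,
    contact_dist_a: float = DEFAULT_CONTACT_DIST_A,
    persistence: float = DEFAULT_PERSISTENCE,
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
    ct_cut: float | None = None,
    ct_target_fraction: float = DEFAULT_CT_TARGET_FRACTION,
) -> CommunicationNetwork:
    """Run the full network construction with auto-chosen thresholds."""
    mmd = mean_min_distance(ens, structure)
    residues = structure.residue_ids
    neighbors = neighbor_graph(mmd, residues, d_cut_a)
    contacts = contact_graph(ens, structure, contact_dist_a, persistence)
    ct_res, ct = commute_time(ens, structure)
    if ct_cut is None:
        ct_cut = choose_ct_cut(ct, ct_target_fraction)
    retained = modes.subset(retained_modes)
    lfa_corr, p_cut, ids_list = lfa_segments(retained, structure, neighbors,
                                             keep_fraction)
    cps = grow_cps(ct_res, ct, ct_cut, contacts)
    return CommunicationNetwork(
        residues=ct_res,
        retained_modes=retained_modes,
        lfa_corr=lfa_corr,
        p_cut=p_cut,
        ids_list=ids_list,
        mean_min_dist=mmd,
        neighbors=neighbors,
        contacts=contacts,
        ct_matrix=ct,
        ct_cut=ct_cut,
        cps=cps,
    )


def network_summary(
    net: CommunicationNetwork,
    scheme: RegionScheme,
    focus_residues: list[int] | None = None,
    region_pairs: list[tuple[str, str]] | None = None,
    hub_degree: int = DEFAULT_HUB_DEGREE,
) -> dict:
    """Path/hub counts in the layout of a variant-comparison table.

    ``paths`` counts non-redundant residue pairs co-occurring in a CP;
    ``hubs`` counts residues on >= hub_degree distinct CPs; region-pair and
    focus-residue entries count the pairwise paths touching those selections.
    """
    pairs = net.pairwise_paths()
    summary: dict = {
        "paths": len(pairs),
        "n_cps": len(net.cps),
        "hubs": len(net.hubs(hub_degree)),
        "hub_degree": hub_degree,
        "ct_cut": net.ct_cut,
        "p_cut": net.p_cut,
        "n_ids": len(net.ids_list),
        "region_pairs": {},
        "focus_residues": {},
    }
    if region_pairs is None:
        region_pairs = [("JM-B", "P-loop"), ("JM-B", "Ca-helix"), ("JMR", "C-loop")]
    for ra, rb in region_pairs:
        try:
            sa, sb = set(scheme.residues(ra)), set(scheme.residues(rb))
        except SchemeError:
            raise
        count = sum(
            1 for x, y in pairs
            if (x in sa and y in sb) or (x in sb and y in sa)
        )
        summary["region_pairs"][f"{ra}|{rb}"] = count
    for r in focus_residues or []:
        summary["focus_residues"][str(r)] = sum(
            1 for x, y in pairs if r in (x, y)
        )
    return summary


def network_to_graphml(net: CommunicationNetwork, scheme: RegionScheme, path: str) -> None:
    """Export residue nodes (with region labels) and the edge sets."""
    g = nx.Graph()
    region_of: dict[int, str] = {}
    for name in scheme.regions:
        for r in scheme.residues(name):
            region_of.setdefault(r, name)
    for r in net.residues:
        g.add_node(int(r), region=region_of.get(int(r), ""))
    for a, b in net.neighbors.edges:
        g.add_edge(a, b, kind="neighbor")
    for a, b in net.contacts.edges:
        if g.has_edge(a, b):
            g[a][b]["kind"] = "neighbor+contact"
        else:
            g.add_edge(a, b, kind="contact")
    for k, chain in enumerate(net.cps):
        for x, y in zip(chain, chain[1:]):
            if g.has_edge(x, y):
                g[x][y]["cp"] = g[x][y].get("cp", "") + f"{k},"
    nx.write_graphml(g, path)
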