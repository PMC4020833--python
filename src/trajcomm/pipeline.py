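"""Configuration-driven end-to-end pipeline for a two-variant comparison.

A single :class:`RunConfig` drives both variants so thresholds are identical
across the comparison.  Every artifact written is listed in a manifest next
to a hash of the configuration; rerunning with the same seeds is
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import communication, convergence, geometry, modes, synthetic
from .core import (
    RegionScheme,
    StructureModel,
    TrajectoryEnsemble,
    csf1r_default_scheme,
    csf1r_sequence_scheme,
    load_structure,
    load_trajectory,
    merge_replicas,
    toy_scheme,
)
from .errors import ComparisonError, SchemeError, TrajcommError


@dataclass
class VariantInput:
    """Either file inputs (structure + trajectories) or a synthetic recipe."""

    name: str
    structure_path: str | None = None
    trajectory_paths: list[str] = field(default_factory=list)
    synthetic: dict | None = None        # kwargs for the synthetic generator


@dataclass
class RunConfig:
    variants: list[VariantInput]
    scheme: str | dict = "toy"
    outdir: str = "trajcomm_out"
    seed: int = 0
    discard_head_ns: float = 0.0
    r_nm: float = convergence.DEFAULT_R_NM
    n_convergence_runs: int = 5
    d_cut_a: float = communication.DEFAULT_D_CUT_A
    contact_dist_a: float = communication.DEFAULT_CONTACT_DIST_A
    persistence: float = communication.DEFAULT_PERSISTENCE
    keep_fraction: float = communication.DEFAULT_KEEP_FRACTION
    ct_cut: float | None = None
    ct_target_fraction: float = communication.DEFAULT_CT_TARGET_FRACTION
    hbond_dist_a: float = geometry.DEFAULT_HBOND_DIST_A
    hbond_angle_deg: float = geometry.DEFAULT_HBOND_ANGLE_DEG
    variance_fraction: float = 0.8
    n_pca_modes: int = 100
    n_overlap_modes: int = 10
    hub_degree: int = communication.DEFAULT_HUB_DEGREE
    d_stride_ps: float = 10.0
    hbond_stride_ps: float = 100.0
    hbond_pairs: list[tuple[int, int]] = field(default_factory=list)
    focus_residues: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.variants:
            raise TrajcommError("config needs at least one variant")
        for name, value in (
            ("r_nm", self.r_nm), ("d_cut_a", self.d_cut_a),
            ("contact_dist_a", self.contact_dist_a),
            ("persistence", self.persistence),
            ("keep_fraction", self.keep_fraction),
            ("hbond_dist_a", self.hbond_dist_a),
            ("variance_fraction", self.variance_fraction),
        ):
            if value <= 0:
                raise TrajcommError(f"threshold {name} must be positive")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        doc["variants"] = [
            VariantInput(**v) if isinstance(v, dict) else v
            for v in doc.get("variants", [])
        ]
        if "hbond_pairs" in doc:
            doc["hbond_pairs"] = [tuple(p) for p in doc["hbond_pairs"]]
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        doc = self.to_dict()
        doc.pop("outdir", None)  # where results land must not change the hash
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def region_scheme(self, n_residues: int | None = None) -> RegionScheme:
        if isinstance(self.scheme, dict):
            return RegionScheme(regions={
                k: [tuple(r) for r in v] for k, v in self.scheme.items()
            })
        if self.scheme == "csf1r":
            return csf1r_default_scheme()
        if self.scheme == "csf1r-sequence":
            return csf1r_sequence_scheme()
        if self.scheme == "toy":
            if n_residues is None:
                raise SchemeError("toy scheme needs the chain length")
            return toy_scheme(n_residues)
        raise SchemeError(f"unknown scheme {self.scheme!r}")


def _toy_atom_ids(residue: int) -> tuple[int, int, int]:
    """(N, H, O) atom ids of a residue in the 5-atom toy chain layout."""
    base = 5 * (residue - 1)
    return base + 1, base + 2, base + 5


def demo_config(outdir: str = "demo_out", seed: int = 0) -> RunConfig:
    """Two-variant synthetic demo: a native-like variant with a strong
    correlated block and high planted H-bond occupancies, and a mutant-like
    variant with doubled block variance and weakened H-bonds."""
    n_res = 60
    d_n, d_h, _ = _toy_atom_ids(5)
    _, _, a_o = _toy_atom_ids(35)
    d2_n, d2_h, _ = _toy_atom_ids(8)
    _, _, a2_o = _toy_atom_ids(38)

    def recipe(block_sigma: float, occ1: float, occ2: float, sub_seed: int):
        return {
            "n_residues": n_res,
            "geometry": "helix",
            "n_frames": 200,
            "n_replicas": 2,
            "background_sigma": 0.02,
            "cluster_blocks": [[20, 28, 0.9, block_sigma]],
            "hbond_schedule": [
                [d_n, d_h, a_o, occ1],
                [d2_n, d2_h, a2_o, occ2],
            ],
            "seed": seed + sub_seed,
        }

    return RunConfig(
        variants=[
            VariantInput(name="native",
                         synthetic=recipe(0.10, 0.82, 0.54, 1)),
            VariantInput(name="mutant",
                         synthetic=recipe(float(0.10 * np.sqrt(2)), 0.19, 0.54, 2)),
        ],
        scheme="toy",
        outdir=outdir,
        seed=seed,
        contact_dist_a=7.0,
        hbond_stride_ps=1.0,
        hbond_pairs=[(5, 35), (8, 38)],
        focus_residues=[24],
    )


# ---------------------------------------------------------------------------
# Per-variant bundle
# ---------------------------------------------------------------------------

@dataclass
class VariantBundle:
    name: str
    structure: StructureModel
    scheme: RegionScheme
    ensemble: TrajectoryEnsemble          # multi-replica
    merged: TrajectoryEnsemble
    rmsd: dict[str, np.ndarray]
    rmsf_residues: np.ndarray
    rmsf_values: np.ndarray
    distances: dict[str, geometry.DistanceSeries]
    hbond_records: list[geometry.HBondRecord]
    modeset: modes.ModeSet
    retained_modes: int
    collectivity: dict[str, list[float]]
    convergence_reports: list[convergence.ConvergenceReport]
    chosen_run: int
    network: communication.CommunicationNetwork
    summary: dict

    @property
    def ids_list(self) -> list[dict]:
        return self.network.ids_list


def _load_variant_ensemble(
    var: VariantInput, config: RunConfig
) -> tuple[StructureModel, TrajectoryEnsemble]:
    if var.synthetic is not None:
        return _synthesize_variant(var, config)
    if var.structure_path is None or not var.trajectory_paths:
        raise TrajcommError(f"variant {var.name}: no inputs configured")
    dialect = "pdb" if var.structure_path.endswith(".pdb") else "internal-json"
    structure = load_structure(var.structure_path, dialect)
    ens = load_trajectory(var.trajectory_paths, structure)
    return structure, ens


def _synthesize_variant(
    var: VariantInput, config: RunConfig
) -> tuple[StructureModel, TrajectoryEnsemble]:
    recipe = dict(var.synthetic or {})
    n_residues = int(recipe.get("n_residues", 40))
    geometry_kind = recipe.get("geometry", "extended")
    structure = synthetic.make_toy_structure(n_residues, geometry_kind, True)
    spec = synthetic.PlantedSpec(
        n_residues=n_residues,
        cluster_blocks=[tuple(b) for b in recipe.get("cluster_blocks", [])],
        background_sigma=float(recipe.get("background_sigma", 0.03)),
        hbond_schedule=[tuple(e) for e in recipe.get("hbond_schedule", [])],
        replica_drift=[np.asarray(d, float) for d in recipe.get("replica_drift", [])],
        drift_region=(tuple(recipe["drift_region"])
                      if recipe.get("drift_region") else None),
        seed=int(recipe.get("seed", config.seed)),
    )
    ens = synthetic.sample_ensemble(
        structure, spec,
        n_frames=int(recipe.get("n_frames", 300)),
        n_replicas=int(recipe.get("n_replicas", 2)),
        stride_ps=float(recipe.get("stride_ps", 1.0)),
    )
    return structure, ens


def analyze_variant(
    var: VariantInput, config: RunConfig
) -> VariantBundle:
    structure, ens = _load_variant_ensemble(var, config)
    n_residues = len(structure.residue_ids)
    scheme = config.region_scheme(n_residues)
    scheme.validate_against(structure)
    for required in ("A-loop", "JMR", "N-lobe", "C-lobe"):
        scheme.residues(required)  # fail fast before any compute
    merged = merge_replicas(ens, config.discard_head_ns)

    rmsd = {
        region: geometry.regional_rmsd(merged, scheme, structure, region, "N-lobe")
        for region in ("JMR", "N-lobe", "C-lobe", "A-loop")
    }
    res_ids, rmsf_vals = geometry.rmsf(merged, structure, "backbone", by="residue")
    spacing = merged.frame_spacing_ps()
    d_stride = config.d_stride_ps if config.d_stride_ps % spacing == 0 else spacing
    h_stride = (config.hbond_stride_ps
                if config.hbond_stride_ps % spacing == 0 else spacing)
    distances = {
        pair: geometry.centroid_distance(merged, scheme, structure, pair, d_stride)
        for pair in ("d1", "d2")
    }
    hbond_records = geometry.hbond_occupancy(
        merged, structure, config.hbond_pairs, h_stride,
        config.hbond_dist_a, config.hbond_angle_deg,
    ) if config.hbond_pairs else []

    modeset = modes.pca_modes(merged, structure, "backbone", config.n_pca_modes)
    retained = modes.modes_for_variance(modeset, config.variance_fraction)
    coll = {
        region: [
            modes.collectivity(
                modeset.eigenvectors[k],
                _subset_in_modes(modeset, scheme, structure, region),
            )
            for k in range(min(config.n_overlap_modes, modeset.n_modes))
        ]
        for region in ("JMR",)
    }

    reports, chosen = convergence.convergence_scan(
        merged, structure, config.r_nm, config.n_convergence_runs, config.seed
    )

    ca_modes = modes.pca_modes(merged, structure, "calpha", config.n_pca_modes)
    ca_retained = modes.modes_for_variance(ca_modes, config.variance_fraction)
    network = communication.build_network(
        merged, structure, ca_modes, ca_retained,
        d_cut_a=config.d_cut_a,
        contact_dist_a=config.contact_dist_a,
        persistence=config.persistence,
        keep_fraction=config.keep_fraction,
        ct_cut=config.ct_cut,
        ct_target_fraction=config.ct_target_fraction,
    )
    summary = communication.network_summary(
        network, scheme, config.focus_residues, hub_degree=config.hub_degree
    )
    return VariantBundle(
        name=var.name, structure=structure, scheme=scheme, ensemble=ens,
        merged=merged, rmsd=rmsd, rmsf_residues=res_ids, rmsf_values=rmsf_vals,
        distances=distances, hbond_records=hbond_records, modeset=modeset,
        retained_modes=retained, collectivity=coll,
        convergence_reports=reports, chosen_run=chosen, network=network,
        summary=summary,
    )


def _subset_in_modes(
    modeset: modes.ModeSet, scheme: RegionScheme, structure: StructureModel,
    region: str,
) -> np.ndarray:
    members = set(scheme.residues(region))
    resnums = structure.residue_numbers[modeset.atom_indices]
    return np.nonzero([int(r) in members for r in resnums])[0]


# ---------------------------------------------------------------------------
# run_pipeline / compare_variants
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run all stages for every configured variant and write the report bundle.

    Returns ``{"bundles": {name: VariantBundle}, "overlap_grid": ...,
    "manifest": [...]}``; artifacts land under ``config.outdir``.
    """
    os.makedirs(config.outdir, exist_ok=True)
    manifest: list[str] = []

    def emit(name: str, writer) -> None:
        path = os.path.join(config.outdir, name)
        writer(path)
        manifest.append(name)

    bundles: dict[str, VariantBundle] = {}
    for var in config.variants:
        try:
            bundle = analyze_variant(var, config)
        except TrajcommError as exc:
            # keep the concrete error type so callers can match on it
            raise type(exc)(f"stage failure for variant {var.name!r}: {exc}") from exc
        bundles[var.name] = bundle
        _write_variant_artifacts(bundle, config, emit)

    if len(bundles) >= 2:
        names = list(bundles)
        a, b = bundles[names[0]], bundles[names[1]]
        grid = _overlap_grid(a.modeset, b.modeset, config.n_overlap_modes)
        emit(
            f"overlap_{names[0]}_vs_{names[1]}.csv",
            lambda p: pd.DataFrame(grid).to_csv(p, float_format="%.6f"),
        )
    else:
        grid = None

    emit("config.yaml", config.to_yaml)
    doc = {"config_hash": config.digest(), "artifacts": sorted(manifest)}
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    return {"bundles": bundles, "overlap_grid": grid, "manifest": manifest}


def _overlap_grid(a: modes.ModeSet, b: modes.ModeSet, n: int) -> np.ndarray:
    n = min(n, a.n_modes, b.n_modes)
    va = a.flat()[:n]
    vb = b.flat()[:n]
    return (va @ vb.T) ** 2  # per-mode-pair squared inner products


def _write_variant_artifacts(bundle: VariantBundle, config: RunConfig, emit) -> None:
    name = bundle.name
    times_ns = bundle.merged.all_times() / 1000.0

    rmsd_df = pd.DataFrame({"time_ns": times_ns, **{
        region: series for region, series in bundle.rmsd.items()
    }})
    emit(f"{name}_rmsd.csv",
         lambda p: rmsd_df.to_csv(p, index=False, float_format="%.6f"))
    emit(f"{name}_rmsf.csv",
         lambda p: pd.DataFrame({
             "residue": bundle.rmsf_residues, "rmsf_nm": bundle.rmsf_values,
         }).to_csv(p, index=False, float_format="%.6f"))
    for dname, series in bundle.distances.items():
        df = pd.DataFrame({
            "time_ns": series.times_ps / 1000.0,
            f"{dname}_nm": series.values_nm,
        })
        emit(f"{name}_{dname}.csv",
             lambda p, df=df: df.to_csv(p, index=False, float_format="%.6f"))
    if bundle.hbond_records:
        df = pd.DataFrame({
            "contact": [r.label for r in bundle.hbond_records],
            "occupancy_percent": [r.occupancy_percent for r in bundle.hbond_records],
        })
        emit(f"{name}_hbonds.csv",
             lambda p, df=df: df.to_csv(p, index=False, float_format="%.2f"))
    emit(f"{name}_pca_eigenvalues.csv",
         lambda p: pd.DataFrame({
             "mode": np.arange(1, bundle.modeset.n_modes + 1),
             "eigenvalue_nm2": bundle.modeset.eigenvalues,
         }).to_csv(p, index=False, float_format="%.9f"))
    emit(f"{name}_collectivity.csv",
         lambda p: pd.DataFrame(bundle.collectivity).to_csv(
             p, index_label="mode", float_format="%.6f"))

    conv = {
        "r_nm": config.r_nm,
        "chosen_run": bundle.chosen_run,
        "runs": [
            {
                "seed": rep.seed,
                "n_references": len(rep.references),
                "lone_references": rep.lone_references,
                "min_balance": rep.min_balance,
                "populations": rep.populations.tolist(),
            }
            for rep in bundle.convergence_reports
        ],
    }
    emit(f"{name}_convergence.json",
         lambda p: json.dump(conv, open(p, "w"), indent=1, sort_keys=True))
    emit(f"{name}_network_summary.json",
         lambda p: json.dump(bundle.summary, open(p, "w"), indent=1, sort_keys=True))
    emit(f"{name}_network.graphml",
         lambda p: communication.network_to_graphml(bundle.network, bundle.scheme, p))


def compare_variants(a: VariantBundle, b: VariantBundle) -> dict:
    """Delta report between two variant bundles from the same region scheme."""
    if a.scheme.regions != b.scheme.regions:
        raise ComparisonError("variant bundles use different region schemes")
    delta: dict = {"a": a.name, "b": b.name}

    occ_a = {r.label: r.occupancy_percent for r in a.hbond_records}
    occ_b = {r.label: r.occupancy_percent for r in b.hbond_records}
    contacts = sorted(set(occ_a) | set(occ_b))
    delta["hbond_occupancy"] = {
        label: {
            "a": occ_a.get(label, 0.0),
            "b": occ_b.get(label, 0.0),
            "difference": occ_a.get(label, 0.0) - occ_b.get(label, 0.0),
            "fold_change": (occ_a.get(label, 0.0) / occ_b[label]
                            if occ_b.get(label) else None),
        }
        for label in contacts
    }

    n = min(10, a.modeset.n_modes, b.modeset.n_modes)
    ev_a, ev_b = a.modeset.eigenvalues[:n], b.modeset.eigenvalues[:n]
    delta["eigenvalue_ratios"] = [
        float(x / y) if y > 0 else None for x, y in zip(ev_b, ev_a)
    ]

    pairs_a = set(a.summary["region_pairs"]) | set(b.summary["region_pairs"])
    delta["region_pair_paths"] = {
        key: {
            "a": a.summary["region_pairs"].get(key, 0),
            "b": b.summary["region_pairs"].get(key, 0),
            "difference": (a.summary["region_pairs"].get(key, 0)
                           - b.summary["region_pairs"].get(key, 0)),
        }
        for key in sorted(pairs_a)
    }
    delta["paths"] = {"a": a.summary["paths"], "b": b.summary["paths"],
                      "difference": a.summary["paths"] - b.summary["paths"]}

    matches = []
    for seg_a in a.ids_list:
        best, best_j = 0.0, None
        for j, seg_b in enumerate(b.ids_list):
            sa, sb = set(seg_a["residues"]), set(seg_b["residues"])
            jac = len(sa & sb) / len(sa | sb) if sa | sb else 0.0
            if jac > best:
                best, best_j = jac, j
        matches.append({"a_seed": seg_a["seed"],
                        "b_seed": (b.ids_list[best_j]["seed"]
                                   if best_j is not None else None),
                        "jaccard": best})
    delta["ids_matching"] = matches
    return delta
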