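# trajcomm

Post-analysis toolkit for molecular-dynamics trajectory ensembles, built for
native-vs-mutant receptor comparisons:

- **Regional geometry** — backbone RMSD/RMSF per named region, centroid
  distance time series between anchor regions (`d1`/`d2`), geometric
  hydrogen-bond detection (donor–acceptor distance + angle at the hydrogen)
  and residue-level occupancy tables.
- **Collective motions** — PCA of positional covariance, an elastic-network
  normal-mode stand-in on the Cα trace, variance-fraction mode counts,
  subspace overlap between mode sets, entropy-based degree of collectivity
  and resultant fragment displacement.
- **Ensemble convergence** — random reference-structure covers, RMSD binning
  of trajectory quarters (two halves per replica), lone-reference detection
  and multi-seed robustness scans.
- **Communication network** — independent dynamic segments from local
  feature analysis of retained PCA modes, mean-smallest-distance neighbor
  graphs, persistent non-bonded contact graphs, a commute-time
  (distance-fluctuation) matrix, greedy communication-pathway growth, and
  pathway/hub summary tables.
- **Synthetic ensembles** — Gaussian trajectory generators with planted
  block correlations, hydrogen-bond schedules and per-replica drift, so
  every analysis stage is testable against known ground truth.

Structures are read from PDB (author numbering preserved verbatim) or an
internal JSON dialect; trajectories from a documented plain-text format
(one coordinate block per frame, nm) with an optional MDAnalysis adapter
for DCD/XTC/TRR. All internal lengths are nm.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: oracle
equivalences (brute-force H-bond scan, per-pair variance commute time,
Frobenius-norm overlap, quaternion superposition), planted-parameter
recovery (correlated-block segments, H-bond occupancies, centroid-distance
shifts, replica-drift detection) and the demo-pipeline budget.

## CLI

```bash
trajcomm simulate --n-residues 40 --n-frames 200 --outdir fixtures/
trajcomm geometry fixtures/structure.pdb fixtures/replica0.trj fixtures/replica1.trj
trajcomm modes fixtures/structure.pdb fixtures/replica0.trj
trajcomm convergence fixtures/structure.pdb fixtures/replica*.trj --r-nm 0.1
trajcomm network fixtures/structure.pdb fixtures/replica*.trj
trajcomm report config.yaml          # full two-variant pipeline from YAML
trajcomm compare config.yaml         # pipeline + native-vs-mutant deltas
```

A ready-made two-variant demo configuration is available from Python:

```python
from trajcomm.pipeline import demo_config, run_pipeline, compare_variants

config = demo_config("demo_out", seed=0)
result = run_pipeline(config)
delta = compare_variants(result["bundles"]["native"],
                         result["bundles"]["mutant"])
```

The pipeline writes CSV/JSON/GraphML artifacts plus a manifest with a config
hash; reruns with the same seeds are byte-identical.

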