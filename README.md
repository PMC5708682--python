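# pbptraj

Trajectory metrics and conformational-event detection for two-domain hinge
proteins (periplasmic binding proteins and friends).

Given an *open* and a *closed* reference structure and one or more
trajectories (as multi-model PDB), `pbptraj` computes seven per-frame
structural metrics — inter-domain distance, angle and dihedral between
domain centers of mass, CA RMSD, heavy-atom radius of gyration, solvent
accessible surface, and two-reference similarity scores Q(NC) and
q(similarity) — then summarises endpoint windows (box/whisker quartiles)
and calls opening/closure events from sustained crossovers of the two
q(similarity) traces, graded by concurrent peaks/valleys in the geometric
metrics.

A fully seeded synthetic generator (`pbptraj.synthetic`) produces two-domain
hinge trajectories with scheduled open/close transitions and ground-truth
event lists, used as the package's benchmark.

## Command line

```sh
# emit synthetic fixtures (multi-model PDB + ground-truth JSON)
pbptraj simulate --out scratch/sim --seed 1 --preset benchmark

# run the full metric/event pipeline
pbptraj analyze \
    --open-ref scratch/sim/benchmark_open.pdb \
    --closed-ref scratch/sim/benchmark_closed.pdb \
    --traj scratch/sim/benchmark_run00.pdb \
    --traj scratch/sim/benchmark_run01.pdb \
    --out scratch/analysis

# CA RMSD between two reference structures over a residue range
pbptraj compare-refs open.pdb closed.pdb --residues 1:238
```

`analyze` writes `metrics.tsv` (per-frame table: run_id, frame, time_ps and
the ten metrics), `endpoint_summary.tsv`, `density_qnc.tsv`
(log10-frequency map of Q(NC)_open vs Q(NC)_closed over [0.4, 1]),
`events.json` and a `manifest.json` carrying the config hash; identical
configurations give byte-identical outputs.  Exit codes: 0 ok, 2 config
error, 3 data error.  Analysis options (cutoffs, smoothing, prominence,
normalisation, ...) can live in one YAML file passed via `--config`; flags
override file keys.

Binary MD formats (DCD/XTC) are not read; convert to multi-model PDB first
(e.g. `mdconvert` or `cpptraj trajout ... pdb`).

## Scoring conventions worth knowing

* **Q(NC)**: Gaussian-weighted native-contact score over CA pairs within
  8 Å (inclusive) at sequence separation ≥ 2; width `sigma_ij = |i-j|^0.15`,
  exponent denominator `2*sigma^2`.
* **q(similarity)**: the same Gaussian over *all* CA pairs at separation
  ≥ 2, no distance cutoff, denominator `sigma^2`.
* **Normalisation**: the default `unit_identity` divides by the number of
  summed terms, so a frame identical to its reference scores exactly 1.0.
  The alternative `printed` mode divides by `(N-1)(N-2)` (N = contact count
  for Q(NC), residue count for q(similarity)); it does *not* score 1 at
  identity (q(similarity) identity = 0.5) and exists only for comparison
  with legacy tooling.
* **ω classification**: |ω| ≤ 30° cis, |ω| ≥ 150° trans, otherwise twisted.
* **SASA**: deterministic Shrake–Rupley with a golden-spiral point set
  (default 960 points, probe 1.4 Å; radii C 1.70 / N 1.55 / O 1.52 /
  S 1.80 Å).

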