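# semirigid

Unsupervised spatio-temporal consensus clustering of molecular-dynamics
trajectories into **semi-rigid domains** — groups of atoms whose mutual
distances fluctuate little over time, so that each group moves approximately
as a rigid body and can serve as a stable fitting reference for downstream
motion analysis.

The method is a three-step procedure:

1. **Spatial clustering per segment.** The trajectory is split into `N_s`
   equal segments of `N_f` frames. For each segment, the matrix of pairwise
   Cα distance standard deviations (STDDV) is computed and the Cα atoms are
   decomposed into `k` crisp clusters by minimising the within-cluster sum
   of distance variabilities, `q = tr(cᵀDc)`, via seeded random single-atom-move
   descent plus exhaustive sweeps, restarted many times.
2. **Time-wise consensus.** Per atom pair, the fraction of segments in which
   the two atoms were *not* co-clustered defines a normalized dissimilarity
   `Δ` (a pseudo-metric). `Δ` is grouped by agglomerative hierarchical
   clustering ("average" or "complete" linkage) and cut into `N_G` groups,
   numbered by descending size.
3. **Cross-trajectory consolidation.** Group partitions from replicate
   trajectories are matched to a reference by the Hungarian algorithm on the
   symmetric-difference loss; the per-group intersections across all
   replicates are the **stable kernels** — the final semi-rigid domains.

The package also ships a synthetic trajectory generator with planted rigid
domains (slow collective rigid-body random walks + fast per-atom jitter +
optional metastable "loop switching"), used as the validation bed.

## Library quick start

```python
import semirigid as sr

# three replicate synthetic trajectories with 3 planted domains
trajs = []
for seed in (1, 2, 3):
    spec = sr.PlantedSpec(n_domains=3, atoms_per_domain=30, n_frames=2500, seed=seed)
    traj, truth = sr.generate_planted_trajectory(spec)
    trajs.append(traj)

config = sr.PipelineConfig(discard_time_ps=0, n_segments=50, k=3,
                           n_trials=10, n_groups=3, seed=42)
result = sr.run_pipeline(trajs, config)
print(result.kernels.coverage)           # fraction of atoms in a stable kernel
print(result.per_trajectory[0].partition.group_of)
```

Defaults of `PipelineConfig` follow the reference protocol: discard the
first 100 ns, `N_s = 500` segments (`N_f = 50` at 20 ps/frame), `k = 7`,
100000 optimisation trials per segment, "average" linkage, `N_G = 24`.

## CLI

Every pipeline stage is a subcommand (`semirigid --help`):

```bash
# generate a synthetic trajectory (multi-model PDB + ground truth)
semirigid simulate --spec spec.json --out t1.pdb --truth truth1.json

# full pipeline over replicates
semirigid run --traj t1.pdb --traj t2.pdb --traj t3.pdb --dt 20 \
    --discard 0 --segments 50 --k 3 --n-groups 3 --seed 7 --out-dir results/

# or stage by stage
semirigid fit --traj traj.pdb --sstable ss.tsv --ref-frame 0 --out fitted.pdb
semirigid stddv --traj fitted.pdb --dt 20 --segments 500 --out-dir mats/
semirigid cluster --matrix mats/stddv_00000.tsv --k 7 --trials 100000 --seed 1 --out l0.json
semirigid consensus l*.json --out-delta delta.tsv
semirigid agglomerate --matrix delta.tsv --n-groups 24 --out-groups groups.json
semirigid edges --matrix delta.tsv --threshold 0.06 --out edges.tsv
semirigid match --ref groupsA.json --others groupsB.json --out match.json
semirigid kernels --ref groupsA.json --others groupsB.json --others groupsC.json --out kernels.json
semirigid export-tcl --groups kernels.json --traj t1.pdb --out color.tcl
```

Inputs are multi-model PDB, or GROMACS XTC plus a GRO/PDB atom list.
Coordinates are handled in nm internally; exports use 1-based continuous
residue numbering. Secondary-structure tables are TSVs with columns
`domain`, `res_start`, `res_end`, `kind`; fixtures for the PD-1/PD-L1
complex (240 residues) are packaged under `semirigid/data/`.

## Layout

| module | contents |
| --- | --- |
| `semirigid.traj_io` | PDB/XTC/GRO reading & writing, trimming, atom selection, SS tables |
| `semirigid.fitting` | Kabsch superposition, trajectory fitting, RMSD profiles |
| `semirigid.stddv` | STDDV matrices, segmentation schemes |
| `semirigid.spatial` | crisp clustering of STDDV matrices (+ brute-force oracle) |
| `semirigid.consensus` | dissimilarity consensus, agglomeration, cuts, circular-plot edges |
| `semirigid.matching` | Hungarian group matching, disparities, stable kernels |
| `semirigid.synthetic` | planted-domain trajectory generator, ARI |
| `semirigid.pipeline` | end-to-end orchestration, manifests, VMD Tcl export |
| `semirigid.cli` | click-based CLI |
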