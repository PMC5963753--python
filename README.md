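# pharmnet

Ligand-based pharmacophore screening and continuous Petri-net simulation of
the IGF-1R / ER-alpha breast-cancer signaling network, as a tested,
reusable pipeline.

The package has two halves:

1. **Cheminformatics** — read SMILES/SDF libraries, perceive typed 3-D
   pharmacophore feature points (aromatic-hydrophobic, hydrophobic,
   H-bond acceptor/donor) on conformers, match them against a 3-feature
   distance-constraint pharmacophore model, and run a screening cascade
   (pharmacophore hit → Lipinski HBD/HBA → rotatable-bond/ring/TPSA
   drug-likeness).  The packaged model (`src/pharmnet/models/igf1r_3pt.yaml`)
   has features HyD/Aro (radius 1.4 Å), HyD (0.8 Å) and HBA (0.9 Å) with
   pairwise distances 3.75 / 4.99 / 6.79 Å.
2. **Systems biology** — a deterministic continuous Petri-net engine
   (mass-action and Michaelis–Menten rate laws, standard and inhibitory
   arcs, flux-gated non-negativity) plus packaged reconstructions of the
   untreated and fulvestrant-treated IGF-1R networks and a qualitative
   untreated-vs-treated comparison table.

A synthetic-data module generates labeled feature-point libraries with
guaranteed ground truth and ships the curated 23-compound training table
(21 active / 2 inactive; activity classes from IC50 thresholds
0.5 / 20 / 60 µM).

## CLI

```sh
pharmnet screen   --library lib.smi --out report.csv [--model model.yaml] \
                  [--lipinski-inclusive] [--tpsa-max 140] [--summary s.json]
pharmnet simulate --net src/pharmnet/models/igf1r_untreated.yaml \
                  --horizon 50 --out traj.csv [--plot traj.png]
pharmnet compare  --out table.csv [--plot-dir panels/]   # packaged nets by default
pharmnet evaluate --library fixtures/synthetic_library.csv [--out eval.json]
pharmnet fixtures --out fixtures/ --seed 42
```

Every command that writes an output file also writes
`<out>.provenance.json` (version, configuration, seed, input hashes); runs
are byte-reproducible for a fixed configuration and seed.

## Library API sketch

```python
from pharmnet import pharmacophore, synthetic_data, igfr_models
from pharmnet.hybrid_petri_net import simulate, fold_change

model = pharmacophore.packaged_model()
spec = synthetic_data.SyntheticLibrarySpec(n_positive=21, n_negative=2,
                                           jitter_sigma=0.2, seed=42)
library = synthetic_data.generate_matching_library(spec, model)
print(pharmacophore.evaluate_model(model, library).accuracy)  # 1.0

traj = simulate(igfr_models.build_untreated(), horizon=50)
print(fold_change(traj, "IGF1R", "peak_over_initial"))  # ~3.33
```

## Notes on scope

* Feature-perception rules are this package's own (documented SMARTS rule
  table, editable as YAML); they are not a reimplementation of any
  commercial tool's perception.
* The two packaged networks encode the interactions named in the source
  narrative with unit rates and unit weights; reconstruction choices are
  listed in the YAML headers.
* Screening of the external drug database behind the original hit list is
  out of scope; the cascade is validated on synthetic and user-supplied
  libraries.
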