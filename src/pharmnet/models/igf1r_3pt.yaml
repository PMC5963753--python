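# Three-feature ligand-based pharmacophore model for IGF-1R inhibitors.
# F1: combined aromatic/hydrophobic feature, F2: aliphatic hydrophobe,
# F3: hydrogen-bond acceptor.  Radii and pairwise distances in Angstrom.
features:
  - {label: F1, type: HYD_ARO, radius: 1.4}
  - {label: F2, type: HYD, radius: 0.8}
  - {label: F3, type: HBA, radius: 0.9}
distances:
  - [0.0, 3.75, 4.99]
  - [3.75, 0.0, 6.79]
  - [4.99, 6.79, 0.0]
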