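# complexqa

Quality assessment of protein–protein complex models.

When a docking program or a deep-learning structure predictor produces a model
of a two-chain complex, two questions follow: *how close is the model to the
experimentally determined structure*, and *could we have known without the
experiment*? `complexqa` answers both for binary (receptor/ligand) complexes:

* **CAPRI-criteria scoring** of a model against a native structure —
  fnat (the fraction of native cross-interface residue contacts reproduced by
  the model, heavy-atom distance ≤ 5 Å), I-RMSD (backbone RMSD over native
  interface residues after superposing those residues; interface = any heavy
  atom within 10 Å of the other chain), and L-RMSD (backbone RMSD over the
  ligand after superposing on the receptor) — combined into the four CAPRI
  accuracy classes:

  | class | condition |
  |---|---|
  | high | fnat ≥ 0.5 and (L-RMSD ≤ 1 or I-RMSD ≤ 1) |
  | medium | fnat ≥ 0.3 and (L-RMSD ≤ 5 or I-RMSD ≤ 2) |
  | acceptable | fnat ≥ 0.1 and (L-RMSD ≤ 10 or I-RMSD ≤ 4) |
  | incorrect | otherwise |

  Model and native are put into residue correspondence by per-chain global
  sequence alignment (never by author numbering, which prediction pipelines
  shift), and residues unresolved in the experiment are pruned from the model
  before any metric is computed. Superposition uses the Kabsch least-squares
  algorithm with a proper rotation.

* **Predictor-confidence interface metrics** — interface pLDDT (mean
  per-residue pLDDT over residues with cross-chain atomic contacts at a
  cutoff, default 4 Å) and interface PAE (mean symmetrized predicted aligned
  error over contacting cross-chain residue pairs). A model with no interface
  contacts scores interface pLDDT 0 and interface PAE 35. pTM/ipTM are read
  and passed through as ranking scores.

* **Complex MSA assembly and depth** — per-chain A3M/FASTA alignments are
  merged into the block-diagonal "unpaired" complex alignment (each row padded
  with gaps equal to the partner-chain length; a 200-residue index shift marks
  the chain junction), optionally with paired ortholog rows and a pre-pairing
  filter (≥ 50% query coverage, ≥ 20% query identity). Depth is measured as
  Neff: the number of clusters under greedy 62%-identity clustering.

* **Score discrimination statistics** — how well any per-model score
  separates the CAPRI classes: ROC AUC (Mann–Whitney with midrank ties),
  95% CIs from 2000 stratified bootstrap replicates, ordinal multiclass AUC,
  optimal cutpoints by maximizing sensitivity + specificity, Wilcoxon
  rank-sum tests, and Pearson correlations.

* **Synthetic benchmark generator** — ideal α-helix toy complexes,
  rigid-body decoy series spanning all four CAPRI classes with analytically
  known L-RMSD, and fabricated confidence maps whose interface signal tracks
  true accuracy with a tunable noise level, so the whole pipeline is testable
  without downloading a single structure.

## Worked example

Generate a small synthetic benchmark and assess one of its decoys:

```
$ complexqa fixtures --n-cases 3 --models-per-case 5 --noise-sd 10 --seed 7 --out fx
$ complexqa assess --model fx/case000_m2.pdb --native fx/case000_native.pdb \
      --receptor-chains A --ligand-chains B
{
  "fnat": 0.4,
  "irmsd": 2.629071763361689,
  "lrmsd": 6.000044718583356,
  "capri_class": "acceptable",
  "n_native_contacts": 15,
  "n_interface_residues": 28
}
```

This decoy reproduces 40% of the 15 native residue contacts, its ligand sits
6.0 Å from the native pose after receptor superposition, and the interface
deviates by 2.6 Å — acceptable accuracy, per the decision table above.

How well does interface pLDDT pick out the good models in that benchmark?

```
$ complexqa roc --table fx/scores.tsv --column interface_plddt \
      --positives medium,high --negatives incorrect --boot 200 --seed 7
{ "auc": 1.0, "ci_low": 1.0, "ci_high": 1.0, "n_pos": 6, "n_neg": 5, ... }

$ complexqa cutpoint --table fx/scores.tsv --column interface_plddt
{ "threshold": 86.16, "sensitivity": 1.0, "specificity": 1.0, "objective": 2.0 }

$ complexqa report --table fx/scores.tsv
{ "t1_medium_or_better_pct": 100.0, "t1_high_or_better_pct": 66.7, ... }
```

At this mild noise level interface pLDDT separates incorrect from
medium/high models perfectly (AUC 1.0; the best threshold, pLDDT ≈ 86,
achieves sensitivity + specificity = 2), and ranking by pTM puts a
medium-or-better model at rank 1 in every case.

All commands are also available as library functions (`complexqa.assess`,
`complexqa.binary_auc`, `complexqa.neff`, ...).

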