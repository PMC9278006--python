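# Methods

This note records the models, conventions and design choices behind
`complexqa`, at the level of detail a maintainer or careful user needs.

## Structure handling and residue correspondence

PDB files are parsed with gemmi. Only amino-acid ATOM records of the named
chains are kept; hydrogens and waters are dropped, and parent-mapped modified
residues (MSE → MET, SEP → SER, ...) are accepted even when written as
HETATM. Alternate locations are resolved per atom name to the
highest-occupancy conformer, ties broken by file order. Residue keys are
`(chain_id, seq_number, insertion_code)` but are never used for
correspondence: model and native chains are matched by global sequence
alignment (identity scoring: match +1, mismatch −1, affine gaps −2/−0.5),
because prediction pipelines renumber chains — notably the 200-residue index
shift used to mark a chain break when two chains are fed to a single-chain
predictor. Within each partner, chain assignment maximizes the summed
alignment score over all pairings (exhaustive; partners in binary complexes
hold at most a few chains), and a best pairing below 30% identity over
aligned columns is treated as a failed correspondence rather than silently
mis-mapped. Aligned positions with identical amino acids become residue
pairs; everything else lands in the model-only/native-only sets. Before any
metric, both structures are pruned to the paired residues and, within each
pair, to the intersection of atom names — this is what removes
experimentally unresolved residues from a predicted model.

## CAPRI metrics

* **Contacts / fnat.** A residue contact is any cross-partner heavy-atom
  pair at ≤ 5 Å. fnat is the fraction of *native* contacts reproduced by the
  model (compared through the mapping); extra non-native contacts in the
  model do not count against it. A native with zero contacts has no
  interface and is an error, not fnat = 0.
* **Superposition.** Kabsch least-squares via SVD with the determinant
  correction, so the rotation is always proper. The backbone atom set is
  {N, CA, C, O}.
* **I-RMSD.** The interface residue set is defined on the native only (any
  heavy atom within 10 Å of the other partner); the model-side interface
  never changes the atom set. Backbone atoms of those residues are
  superposed and the RMSD is read from the same atoms.
* **L-RMSD.** Receptor backbone superposed, ligand backbone RMSD computed
  with no further fitting. A pure ligand translation of magnitude t
  therefore gives L-RMSD = t exactly — a property the tests exploit.
* **Classification.** The standard CAPRI decision table (fnat 0.1/0.3/0.5;
  L-RMSD 10/5/1; I-RMSD 4/2/1) evaluated top-down (high before medium before
  acceptable), which makes boundary triples unambiguous. The contact and
  interface cutoffs (5 Å, 10 Å) are the community-standard values.

## Confidence metrics

pLDDT lives on the 0–100 scale; inputs that look 0–1 scaled are multiplied
by 100 with a logged warning. The PAE matrix is asymmetric (entry (i, j) is
the expected error of residue j when aligned on residue i); interface PAE
averages the symmetrized value (pae[i,j] + pae[j,i])/2 over contacting
cross-partner pairs, which makes the metric independent of which chain is
called receptor. The interface contact cutoff defaults to 4 Å with 4–10 Å
supported; widening the cutoff can only grow the interface set. A model with
no interface contacts at the cutoff is assigned interface pLDDT 0 and
interface PAE 35 — sentinel values that rank such models below any model
with a genuine interface. Confidence JSON key names cover the common
predictor dialects (plddt/pLDDT, pae/predicted_aligned_error, flat or nested
PAE); when only a coordinate file is available, per-residue pLDDT is the
mean B-factor. ipTM is stored and passed through as a score column; it is
never computed here.

## MSA assembly and depth

The unpaired complex alignment is block-diagonal: the query row concatenates
both chain queries; every other chain-A row gets lenB trailing gaps and
every chain-B row lenA leading gaps, so all rows have length lenA + lenB.
The 200-residue junction offset is carried as metadata and applied only when
emitting predictor-ready inputs — internal residue keys never see it.
Paired rows (ortholog pairs concatenated across both chains) can be
appended, including in paired-only mode. The pre-pairing filter keeps rows
with ≥ 50% query coverage and ≥ 20% query identity.

Neff is the cluster count of greedy incremental clustering at 62% identity:
rows are visited longest-first (ungapped length), each joins the first
cluster whose representative shares at least the threshold identity —
matches divided by the shorter ungapped length, the convention of the
standard greedy clustering tools — otherwise it founds a new cluster. The
k-mer prescreen those tools use is an optimization, not part of the
contract, and is omitted. Because it is unclear in general whether depth
should be measured per chain or on the combined alignment, the depth report
computes both (and paired-row depth separately when paired rows exist).

## Discrimination statistics

AUC is computed as the Mann–Whitney probability with midrank tie handling,
oriented by a per-column direction flag (higher-is-better for pTM/pLDDT,
lower-is-better for PAE and energy-like scores) so stored values are never
sign-flipped. CIs are percentile intervals over 2000 stratified bootstrap
replicates (positives and negatives resampled separately, sizes preserved);
on small samples a raw percentile interval can exclude the point estimate,
so the interval is clamped to contain it. The CAPRI classes are ordinal, so
the multiclass AUC binarizes the score at each adjacent class boundary
(incorrect | acceptable-or-better, and so on) and macro-averages the split
AUCs; a micro (size-weighted) variant is exposed as an option. This ordinal
construction — rather than literal one-vs-rest, which cannot score a middle
class perfectly from a single monotone column — is a deliberate choice and a
caveat when comparing against multiclass tools that consume per-class
probabilities. Optimal cutpoints scan observed score values and maximize
sensitivity + specificity (positives: medium/high; negatives: incorrect, by
default), ties broken toward higher specificity then the more permissive
threshold; the reported threshold is an achieved observed value, not a
midpoint. The rank-sum test uses exact enumeration when both samples have
n ≤ 8 with no ties and the tie/continuity-corrected normal approximation
otherwise; Pearson p-values come from the t transform with n − 2 degrees of
freedom. Missing score values exclude a row from that column's analysis
only. All stochastic routines take an explicit seed.

## Synthetic benchmark

The generator builds two-chain natives from ideal poly-alanine α-helices:
backbone N/CA/C/O placed by natural-extension internal coordinates with
Engh–Huber bond lengths and angles and helical torsions (φ = −57°,
ψ = −47°, ω = 180°). The ligand helix is spun by a seed-determined phase,
aligned parallel to the receptor helix, and shifted until the minimum
inter-chain heavy-atom distance reaches the requested gap (default 3.4 Å, a
tight van-der-Waals contact that guarantees a genuine interface at the 4 Å
confidence cutoff). Default sizes are 16 + 12 residues — deliberately small
so brute-force oracles remain exact and fast.

Decoys are rigid-body perturbations of the ligand (rotation about its
centroid, then translation). The graded series slides the ligand along the
helix axis, which degrades fnat and I-RMSD gradually while keeping
L-RMSD = t analytic; a far translated-and-rotated pose supplies an
unambiguous incorrect decoy. Perturbation magnitudes are mapped to class
bands empirically — the assessment itself arbitrates which grid point lands
in which class — not assumed from the thresholds. Two constraints keep the
noiseless confidence construction separable: incorrect decoys must be
clearly wrong (I-RMSD > 4 Å), and better-than-incorrect decoys must retain a
4 Å interface, mirroring real decoy sets where roughly-docked models
genuinely touch.

Fabricated confidence maps anchor interface pLDDT at 95 − 5·I-RMSD (clamped
to [20, 95]; non-interface baseline 92) and cross-chain PAE at
0.25 + 3·I-RMSD (clamped to [0.25, 32]; intra-chain 1.5), with Gaussian
noise of standard deviation `noise_sd` added to pLDDT (0.3 × `noise_sd` to
PAE) and clamping to the legal ranges; pTM and ipTM decrease linearly in
I-RMSD. At `noise_sd` 0 the interface signal is a strictly decreasing
function of true accuracy, so incorrect vs medium/high is perfectly
separable by construction; noise has to reach roughly 20 pLDDT units before
the incorrect/high AUC measurably drops, which is the regime the
degradation tests probe.

What the generator does *not* emulate: real AlphaFold failure modes (chain
clashes, disorder, compensating errors between pLDDT and PAE), side chains,
non-helical folds, or conformational change on binding. Passing tests
therefore demonstrate the correctness of the metrics and statistics, not
predictive performance on real complexes — assessing released predictor
models against deposited structures requires only the `assess`/`confidence`
CLI on those files, but the numbers here make no claim about them.

## Problem sizes and numerical choices

The test suite and the acceptance script run on toy complexes of 20–28
residues, benchmarks of 8–20 cases × 5 models, alignments of ≤ 30 rows, and
2000 bootstrap replicates — sizes chosen so every quantity can be
cross-checked against brute-force enumeration while the whole suite stays in
the one-minute range. Superposition tolerances are 1e-9 Å against the
closed-form quaternion oracle; PDB round-trips are exact to the format's
3-decimal precision; degenerate inputs (no native interface, < 3 backbone
atoms, constant score columns, empty class groups) raise typed errors rather
than returning silent defaults.
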