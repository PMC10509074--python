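# Methods

## The problem the framework addresses

Structure-based virtual-screening models are routinely reported to separate
binders from non-binders with high accuracy, yet much of that accuracy can
come from *ligand-specific bias* — distributional differences between the
active and decoy ligand sets — rather than from recognising favourable
protein–ligand interactions. Telling the two apart on real data is hard
because the true contribution of each ligand atom to binding is not
experimentally measurable at scale. This package sidesteps the problem with
fully synthetic complexes in which the per-atom ground truth is known
exactly, so that any model's per-atom attributions can be scored objectively.

## Generative model

A *synthetic protein* is a point cloud of typed pseudo-residues
`{(x_i, y_i, z_i, t_i)}` sampled around a 3D ligand:

1. The ligand's heavy-atom bounding box is padded by 5 Å per side.
2. `m = round(a_coef · V)` candidate points are sampled uniformly in the box
   (`V` the box volume; `a_coef` defaults to 0.05 residues/Å³, so the
   candidate density is independent of ligand size).
3. Each point receives a type uniformly at random: HBA/HBD under the Polar
   rule, HBA/HBD/Hydrophobic under the Contribution rule.
4. Points within 2 Å of a ligand atom are deleted (clash filter, strict `<`).
5. Points within 3 Å of an already retained point are deleted greedily in
   sampling order.
6. If more than `n_res = floor(n_ops / n_lig)` points survive, survivors are
   subsampled uniformly to `n_res`, with `n_ops = 50`. Scaling the residue
   count inversely with the number of interacting ligand groups removes the
   trivial correlation between ligand polarity and label, which would
   otherwise be a ligand-specific bias by construction.

`n_lig` counts the ligand's interacting functional groups: atoms carrying a
donor and/or acceptor feature (an atom that is both counts once), plus —
under the Contribution rule — the single-atom hydrophobic features.

Two deterministic rules label the complex:

- **Polar**: a record is emitted for every complementary residue/atom pair
  (HBD residue ↔ acceptor atom, HBA residue ↔ donor atom) strictly closer
  than 4 Å; the complex is active iff at least one record exists. Ground
  truth per atom is the binary indicator of participation.
- **Contribution**: every same-type pair (HBA ↔ acceptor, HBD ↔ donor,
  Hydrophobic ↔ hydrophobe) contributes `w · f(d)` where `f` is the
  Gamma(4, 1) probability density of the pair distance (unimodal, mode at
  3 Å, max single-pair hydrogen-bond score 2.2404) and `w` is 10 for
  hydrogen bonds and 3 for hydrophobic contacts. The complex is active iff
  the summed score exceeds 4; no hard distance cutoff is applied (the
  density decays naturally). Ground truth per atom is its summed pair score.

Because no single pair can exceed the threshold, Contribution actives always
require several good contacts, which is what makes the rule hard for
featurizations that only record whether a contact is inside a binary cutoff.

## Pharmacophore perception

Atom types come from RDKit's standard chemical feature definitions
(`BaseFeatures.fdef`): families Donor, Acceptor and — for the Contribution
rule — the single-atom Hydrophobe family. Lumped multi-atom hydrophobic
features (aromatic rings, gem-dimethyl groups) are deliberately *not*
projected onto their member atoms: doing so types nearly every atom of a
drug-like molecule, which both destroys the Contribution rule's class
balance and leaves almost no atoms with zero ground-truth contribution,
whereas these datasets are characterised by near-balanced labels and a
majority of zero-contribution atoms. Hydrogens are implicit throughout; all
geometry is heavy-atom only (residues are points, so there is no hydrogen-
bond geometry to model). Exact donor/acceptor SMARTS sets differ between
toolkit versions; minor typing differences relative to other implementations
are expected and do not affect any of the framework's invariants.

## Fixture ligands

`generate_fixture_ligands` enumerates a combinatorial panel of 34 drug-like
amide/sulfonamide scaffolds × 24² substituent pairs (≈2,800 distinct
admitted molecules), with seeded ETKDG conformers; the same seed reproduces
coordinates bitwise.

Panel admission is deliberately restrictive, because the unbiased datasets
are *defined* by the absence of ligand-specific signal and the binding rules
respond to several whole-ligand quantities. A ligand's marginal probability
of being labelled active rises with smaller padded-box volume (the residue
cloud is denser), with atoms typed both donor and acceptor (they match two
residue types but count once in `n_lig`), and with a higher
polar-to-hydrophobe ratio (hydrogen bonds weigh 10, hydrophobic contacts 3,
yet both occupy `n_lig` slots equally). A combinatorial panel that varies
freely in those quantities therefore hands a ligand-only model real signal.
Admission consequently requires: 20–27 heavy atoms (a catalogue-tranche-like
slice, as vendor collections are binned by molecular weight), no dual
donor/acceptor atoms, exactly three single-atom hydrophobic features, at
least one polar atom, and an interacting-group count between 6 and 9 under
the contribution rule (which narrows the floor-step variation of the
per-ligand residue cap). Under the default generation parameters this
yields active fractions of ≈0.53 (Polar) and ≈0.49 (Contribution) and
ligand-only random-forest accuracies statistically at chance (means over
independent protein draws ≈0.53 and ≈0.49) — the bias-free condition the
benchmark emulates. Because forest predictions are correlated across
chemically similar ligands, the single-draw holdout accuracy has
heavier-than-binomial tails; reported ligand-only accuracies are therefore
means over three independent protein draws of the same ligand pool.

What the fixture does *not* emulate: real vendor chemical diversity (the
panel is combinatorial around a few dozen scaffolds, so inter-ligand
similarity is higher than in a random catalogue slice), conformational
ensembles, protonation states, and any target-dependent structure. Tests
passing on fixture data therefore demonstrate correctness of the machinery
and the qualitative behaviour of models on unbiased data, not performance on
any particular real screening library.

## Featurization

- **Morgan**: RDKit hashed circular substructures, radius 2, 2048 bits.
  Purely 2D; serves as the ligand-only bias probe.
- **PLEC-style**: for every (ligand atom, residue) pair strictly inside the
  distance cutoff, the ligand atom's circular environment identifiers at
  radii 0..3 are each hashed together with the residue type (a residue is a
  single unconnected atom, hence protein depth 0) into a 16,384-bit vector
  via a stable 64-bit blake2b digest folded modulo the length. Collisions
  are tolerated as in any hashed fingerprint. Only behavioural equivalence
  with reference interaction fingerprints is claimed: pair locality, cutoff
  response and determinism, all property-tested.
- **Masking**: an atom is replaced by a typeless dummy that keeps
  coordinates and bonds but has no element identity, produces no
  environments of its own and enters no contact pairs. The same convention
  is used for Morgan and PLEC fingerprints so that masking scores are
  comparable across models and no valence-breaking deletion is needed.

## Models and attribution

Random forests (500 trees, √p features per split, unlimited depth, seeded;
all exposed) on either fingerprint. `RF_PLEC_n` denotes the PLEC model with
cutoff `n` Å. Attribution is by atom masking,
`s_i = score(m) − score(m\i)` with `score` the forest's active-class
probability; all masked variants of a complex are featurized and scored in
one batch.

## Metrics

- **Attribution AUC** (binary ground truth): 1 − inversions/worst-case over
  (binder, non-binder) pairs in the attribution ranking, equivalently the
  pair-concordance fraction. Ties count one half, so uniform random scores
  have expectation exactly 0.5 — this keeps the random baseline centred and
  matches the expected value over random tie-breaking. Complexes with no
  binders or all binders are skipped and counted. The dataset summary is the
  unweighted mean over complexes (a pooled-atom variant would weight large
  ligands more; per-complex averaging is reported).
- **Spearman rho** between attributions and true contributions, mid-ranks
  for ties, per complex; dataset value is the mean with degenerate complexes
  (constant vectors, <3 atoms) skipped and counted.
- **MATR(t)**: atoms are ranked within each complex by attribution
  (descending, mid-ranks); the ranks of all atoms with true contribution
  > t are pooled across the dataset (atom-weighted, since the quantity is a
  mean over qualifying atoms) and averaged. Curves are reported on a grid
  from 0 to 3 in steps of 0.2.
- **RER** = MATR(model)/MATR(ground-truth ranking), optimum 1.00. The
  default threshold 0.96 selects roughly the top tenth of atom scores in a
  typical resampled-active test set; it is configurable because the right
  quantile depends on the contribution distribution of the data at hand.

## Workflows

- *Unbiased build*: one unconditioned complex per ligand, plus a bias
  diagnostic comparing the per-ligand donor/acceptor-count distribution
  between actives and decoys.
- *Bias-matched build*: for externally labelled ligands the protein is
  resampled (up to 100 attempts) until the synthetic label matches the
  external one; unmatched ligands are discarded and logged. This injects
  exactly the ligand-specific bias of the external label assignment.
- *Active-only test set*: candidates are filtered (Tanimoto ≤ 0.8 to every
  reference on 2048-bit Morgan radius-2 fingerprints; ≥ 15 heavy atoms),
  sampled, and resampled-until-active so every example carries meaningful
  ground truth.
- *Benchmark*: seeded random holdout (default 500) for classification
  metrics; attribution metrics on a resampled-until-active set derived from
  test ligands. One row per model (RF_Morgan + one RF_PLEC per cutoff,
  default 2.5–6.0 Å in 0.5 Å steps).
- *Perturbation case study*: starting from a Polar-active complex with
  exactly one interaction, the key residue is moved along the residue→atom
  axis to 50 evenly spaced distances in [1.5, 10] Å (the path is a design
  choice; only the pair distance matters to either rule) and the key atom's
  masking-attribution rank is tracked per model.

## Numerical choices and degenerate inputs

- Distance comparisons at a cutoff are strict (`< 4 Å` interacts; clash and
  separation filters delete at `<` and keep at `≥`).
- All randomness flows from one integer seed through `numpy` SeedSequence
  spawning; every complex records its sub-seed; RDKit embedding seeds are
  folded into [1, 2³¹).
- Ligands with `n_lig = 0` are rejected before generation (an empty
  interaction vocabulary admits no meaningful label); single-atom ligands
  get a valid box of side 2·pad.
- Zero-survivor samplings retry with a fresh sub-seed up to a bounded
  attempt count before raising.
- Residue subsampling preserves sampling order; the pairwise-separation
  filter is greedy in sampling order (the retained set is then not the
  maximum independent set, but the procedure is deterministic and unbiased).

## Problem sizes

The packaged studies use 2,500 fixture ligands with a 500-example holdout
(training on 2,000), 100 resampled-active complexes for attribution
evaluation, and 50 perturbation distances; these sizes reproduce the
qualitative and most quantitative behaviours of the full-scale setting (10k
ligands) while keeping a complete run on a single CPU in minutes. At this
scale the cutoff-matched RF_PLEC_4 typically exceeds 0.95 holdout accuracy
on Polar data and 0.9 mean Attribution AUC, and the ligand-only RF_Morgan
stays within a few points of chance on both rules.

## Known limitations

- No physical realism beyond the 2 Å clash rule: no sterics, directional
  hydrogen bonds, solvation, flexibility or real protein structure.
- One conformer per ligand; no protonation/tautomer enumeration.
- The PLEC-style fingerprint is behaviourally, not bit-for-bit, equivalent
  to other implementations.
- The Contribution rule's class balance depends on the ligand population;
  strongly atypical ligand sets (very small, very apolar) shift it.
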