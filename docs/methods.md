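# Methods

## Model and assumptions

`iterprot` predicts four per-residue properties of a protein chain from
its sequence profile: three-state secondary structure (helix H, sheet E,
coil C), relative solvent accessible surface area (rASA ∈ [0, 1]),
the backbone torsions φ/ψ, and the Cα-geometry angles θ (planar angle
over Cα<sub>i−1</sub>, Cα<sub>i</sub>, Cα<sub>i+1</sub>) and τ (dihedral
over Cα<sub>i−1</sub>…Cα<sub>i+2</sub> about the Cα<sub>i</sub>–Cα<sub>i+1</sub>
bond).  The working assumptions are the classic ones of windowed 1-D
structure prediction: local sequence context (here 17 residues) carries
most of the signal for local structure; evolutionary preferences are
summarized by a PSI-BLAST PSSM row per residue; and the four properties
are mutually informative, so feeding each predictor the previous
round's estimates of *all* properties improves every one of them.  The
three predictors within an iteration are fully independent networks —
no weights are shared — so they may be trained in any order with
identical results.

Angles are handled on the circle throughout: training targets and
feedback features are (sin, cos) pairs, decoding is
`atan2(sin, cos)` into (−180°, 180°], and every angular error is
min(|d|, 360° − |d|).  φ of the first residue, ψ of the last, θ at both
termini and τ at the last two positions are structurally undefined:
they are masked out of the loss, fed back as zeros in both channels,
reported as NaN in memory and as the sentinel `360.0` in files.

## Networks and training

Every head is a feed-forward stack — input → 150 → 150 → 150 → output,
sigmoid units — trained in two phases:

1. **Greedy autoencoder pretraining.**  One sparse autoencoder per
   hidden layer (linear encoder/decoder, L1 activity penalty, weight
   1e−4), 10 epochs at learning rate 0.05.  The reconstruction loss is
   the mean squared error over batch *and* feature entries; defining it
   per-entry keeps the gradient scale independent of the input width
   (a per-sample-summed loss makes a linear autoencoder diverge at this
   rate for 459-wide inputs).  Activations are propagated to the next
   pretraining stage through the sigmoid the assembled network applies,
   so each autoencoder sees inputs on its layer's working scale.
2. **Back-propagation fine-tuning.**  Squared error on sigmoid outputs
   (cross-entropy available via `loss="cross_entropy"`), plain SGD with
   mini-batches of 128 under the stepped rate ladder 1, 0.5, 0.2, 0.05
   with 30 epochs at each rate.  Momentum and weight decay default to 0
   and are config-exposed.

Inputs are min–max normalized to [0, 1] per feature column, with the
column minima/maxima fit on the training corpus only, reused (and
clipped) at prediction time, and stored in the checkpoint.  A
zero-range column maps to the constant 0.5.  Sin/cos targets in
[−1, 1] are affinely mapped into the sigmoid-reachable window
[0.1, 0.9] for training and inverse-mapped (then clipped to [−1, 1]) at
prediction; SS targets are one-hot, and reported class probabilities
are the sigmoid outputs renormalized to sum to 1 (argmax is unaffected).

All randomness — weight initialization and within-epoch shuffling —
flows from a single run seed through a documented fan-out
(`SeedSequence(seed, spawn_key=(iteration, head))`), so training twice
yields byte-identical checkpoints and predictions.

## Iterative scheme

Iteration 1 consumes 17 × (20 PSSM + 7 physicochemical) = 459 features
per residue; iterations ≥ 2 append the previous round's 3 SS
probabilities, 1 rASA and 8 angle channels inside the same window for
17 × 39 = 663.  These dimensions are asserted at train and predict
time.  During training, iteration k's feedback features are the
iteration-(k−1) networks' predictions on the training corpus itself; an
optional out-of-fold mode (`oof_folds > 1`) produces them from
fold-held-out copies instead, guarding against feedback overfitting —
at desk scale direct feedback generalized well, so the default is off.
The fed-back groups are configurable (`feedback_groups`), which
expresses the SS-only ablation; a `base_model` argument lets ablations
reuse the full model's iteration-1 networks so the schemes differ only
in what is fed back.

The ASA head trains on rASA; raw ASA in Å² is recovered by multiplying
with the residue type's theoretical maximum ASA (Tien et al. 2013
values).  Evaluation reports the Pearson correlation on both scales.

## Geometry

Torsion-derived fragments are built by sequential natural-extension
(NeRF) placement of N, Cα, C with fixed covalent geometry
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles C–N–Cα 121.7°,
N–Cα–C 111.2°, Cα–C–N 116.2°) and a trans peptide (ω = 180°), which
forces a constant Cα–Cα spacing of ≈ 3.80 Å.  Cα-angle-derived traces
use a fixed 3.8 Å virtual bond.  Builders start in a canonical frame
(first atom at the origin, second on +x, third in the xy plane); every
measured quantity is rigid-motion invariant, so the frame is
immaterial.  Build → measure round trips close to ≪ 0.01°.  Degenerate
inputs error: interior NaN torsions, collinear θ (0°/180°, where the
dihedral frame vanishes), zero-length bonds.  RMSD is the Kabsch
optimal superposition with the determinant correction, so reflections
are never used and chiral mirror images score > 0.

Because the ideal-geometry Cα spacing (3.80 Å) differs slightly from
the fixed 3.8 Å trace bond, fragments rebuilt from a structure's own
true φ/ψ and true θ/τ agree to < 0.05 Å RMSD rather than exactly —
the cross-representation consistency score is meaningful only above
that idealization floor.

## Synthetic corpus

The generator emulates the full data contract with no downloads.  Per
protein: coil and structured (H/E) segments alternate with
class-specific length ranges (H 4–14, E 3–8, C 2–7); residues are drawn
from class-preferred amino-acid sets with probability `coupling` (else
uniformly); φ/ψ are sampled per class around textbook Ramachandran
centers (H −57°/−47° σ 8°; E −120°/130° σ 15°; C −80°/120° σ 40°/60°);
the backbone is then *built* from those torsions, and θ/τ and the Cα
trace are measured from it, so all geometric labels are mutually
consistent by construction.  rASA is a burial proxy — the min–max
normalized distance of each Cα from the chain centroid — and ASA is its
inverse image under the max-ASA table.  Mock PSSMs are integer-rounded
`7·one-hot(residue) + 2·(class-preference − mean) + N(0, 5²)`.

The default conditions (200 proteins of 30–70 residues, coupling 0.6,
noise σ 5) were chosen so the first-iteration SS task lands in the
realistic ~0.85 Q3 regime — difficult enough that feedback has headroom
— rather than at the ceiling a cleaner corpus produces.  What the
corpus does **not** model: real evolutionary profiles (its PSSM signal
is a caricature), excluded-volume and hydrogen-bonded loop geometry,
β-sheet pairing between distant strands, and true solvent accessibility
physics.  Passing tests therefore demonstrate that the machinery —
feature feedback, periodic regression, geometric self-consistency — is
implemented correctly and that iteration helps when cross-property
signal exists; they do not certify accuracy on real proteins, which
requires real structures and PSI-BLAST profiles.

## Problem sizes and schedules

Unit tests use corpora of 6–8 proteins and a 1 + 2-epoch schedule
(seconds).  The benchmark (`iterprot.benchmark.run_desk_benchmark`)
trains on 200 proteins and scores 60 held-out proteins per seed with a
shortened schedule — 2 autoencoder epochs, 8 epochs per rate, ladder
unchanged — which reproduces the qualitative behaviour of the full
schedule in ~2 minutes per seed on one CPU.  The improvement and
ablation properties are judged across three seeds; single-seed Q3
differences of ~±0.3% are within run-to-run noise at this scale, so the
full-vs-SS-only comparison uses the seed mean.

## Known limitations

* The XOR-style sanity check uses a single hidden layer: 3-layer plain
  SGD sigmoid stacks (including scikit-learn's logistic-SGD MLP) stall
  on 2-D XOR; the production tasks are wide and data-rich, where the
  deep stack trains fine.
* Squared error on sigmoids learns slowly early on (flat spots); the
  reference rate ladder compensates, and cross-entropy is one config
  switch away.
* The PSSM reader supports the PSI-BLAST ASCII log-odds block only; the
  percentage block and other profile dialects are out of scope.
* Full-protein assembly from predicted angles is intentionally not
  attempted — error accumulates over long chains; fragments of ~15
  residues are the supported unit of 3-D validation.
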