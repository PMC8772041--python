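# Methods

## Problem and model

Given a protein chain and per-residue predicted structure (secondary
structure, relative solvent accessibility, phi/psi dihedrals), the task is
to label each residue as binding or not binding a Ca²⁺ or Mg²⁺ ion. The
classifier operates on residue-centred windows of length L = 9: the window
captures the local sequence/structure context that metal coordination
perturbs, and the chain is padded with (L−1)/2 pseudo residues so every
residue — including terminal ones — centers exactly one window. A window's
label is the binding status of its center.

The feature encoding is deliberately low-dimensional (129 at L = 9) and
fully interpretable; see the README for the three blocks. Conventions worth
recording:

* **Pad is a first-class symbol.** The residue alphabet is closed at 21
  symbols (20 amino acids + `X` for pad/unknown) and every structure track
  carries an explicit `PAD` class. This is why the composition sub-blocks
  have 21/4/5/3/4 dimensions and the PWM class counts q are 21, 4, 5, 3, 4:
  the "+1" over the natural class counts is the pad/vacancy class. Windows
  at chain ends therefore differ from interior windows in a way the model
  can see, rather than through imputed values.
* **RSA discretization is clamped at the edges.** The four printed intervals
  leave x = 0 and x ∈ (0.85, 1] uncovered; the mapper assigns them to
  classes I and IV respectively so it is total on [0, 1]. The boundary mass
  is negligible in practice and the synthetic generator never produces it.
* **PWM background p₀.** The log-odds m_ij = ln(p_ij/p₀j) needs a background
  distribution; the default is the empirical class frequency pooled over all
  sites of the combined (positive + negative) training fragments, smoothed
  with the same √N/q pseudo-count as the per-site probabilities so the
  log-odds stay finite when a class never occurs. `background="uniform"`
  (p₀j = 1/q) is available for the alternative reading of "background".
  Natural log for the PWM scores, base-2 log for the entropies.
* **Entropy excludes pads.** Charge and hydropathy are undefined for the pad
  symbol; the entropy denominators count real residues only, keeping the
  class counts at 3 and 6 rather than introducing an artificial pad class.
* **Leakage control.** PWMs and the feature standardizer are refit inside
  every training fold; test fragments are always encoded with matrices they
  did not contribute to.

## Classifier and training

A stack of equal-width ReLU hidden layers with a logistic output unit,
cross-entropy loss, Adam at its default step size (scikit-learn's
`MLPClassifier` under the hood), inputs standardized per feature on the
training rows. Zero-variance training columns are mapped to a constant 0 at
transform time, so a feature that carried no information during training
can never perturb predictions. A predicted probability equal to the 0.5
threshold counts as a positive call.

Early stopping runs an explicit epoch loop: training stops when the epoch's
training accuracy has not risen for 10 consecutive epochs (or at 200
epochs), keeping the last weights. A held-out validation monitor was
considered and rejected: at the balanced training sizes this model sees
(hundreds of rows), a 10% monitor is 20–40 rows whose accuracy saturates
within a few epochs and freezes training far short of convergence, while
the epoch-accuracy monitor has n-row resolution and keeps improving until a
genuine plateau. The patience window also lets the final weights refine
past the last recorded improvement. All randomness (weight init, batch
shuffling) is governed by one integer seed; identical seed and data give
bit-identical predictions.

Hyper-parameter search is coordinate-wise exhaustive: hidden layers
(1–8), then hidden width, then batch size (2, 4, …, 128 each), sweeping one
knob while the others are held fixed — at 32, the mid-grid value, before
they have been optimized. The objective is mean MCC over stratified
validation folds (3 by default); ties break toward the smaller value, so
the search prefers the simplest architecture among equals. Exactly
|grid₁| + |grid₂| + |grid₃| configurations are evaluated. The default
`ModelConfig` (2 × 16, batch 32) is a tuned balanced-protocol setting of
this family of models; re-tune on new data.

## Evaluation protocol

* `metrics` computes Sn/Sp/Acc (percent) and MCC from integer confusion
  counts; a zero factor in the MCC denominator defines MCC = 0 (the
  standard convention where the coefficient is otherwise undefined).
* `kfold_cv` uses stratified fragment-level folds (`group_by_chain=True`
  switches to stratified group folds that keep each chain's fragments
  together). Fold metrics are reported individually and micro-pooled over
  summed confusion counts; every fragment is tested exactly once.
* `undersample_eval` draws |positives| negatives without replacement,
  repeats the draw 10 times, runs the CV on each balanced set and averages
  the four metrics arithmetically across repeats (metric averaging, not
  count pooling — each repeat is a complete experiment).
* `chain_split` assigns whole chains: ⌊0.8·n⌋ to training, the rest to
  test, seeded. `independent_eval` combines both: balanced-undersampling CV
  on the training chains, then, per repeat, a pipeline fitted on one
  balanced draw predicts every fragment of the withheld chains at their
  natural imbalance — the deployment scenario, where MCC drops sharply even
  when Sn/Sp stay high, because false positives scale with the negative
  majority.

## Synthetic data

The generator emulates the joint structure of the three real inputs:
sequences from vertebrate background amino-acid frequencies, binding
positions as per-residue Bernoulli draws (default rate 1%, matching the
order of magnitude of real Ca²⁺/Mg²⁺ imbalance), and structure tracks drawn
per class and then uniformly within each class's continuous interval, so
discretization never clamps. At and within ±1 of a binding position,
`signal_strength` (default 3.0) acts as a log-odds tilt enriching D/E/N
residues, coil secondary structure and buried/intermediate RSA — the
coordination chemistry of real alkaline-earth sites — so all three feature
families carry recoverable signal. `structure_noise` (default 0.1) replaces
the structure tilt with the background draw at that probability, mimicking
predictor error in real structure annotations.

What the generator does **not** emulate: sequence redundancy and family
structure (real datasets need identity clustering; synthetic chains are
i.i.d.), spatial clustering of binding residues into coordinated sites,
long-range conservation signals, and realistic secondary-structure
autocorrelation along the chain. Passing recovery tests therefore shows the
pipeline is correct and sensitive to a signal of this kind and size, not
that the same MCC would be reached on curated experimental data — on the
chain-level independent test at natural imbalance, MCC is markedly lower
than in balanced CV, as with real data.

`worked_example()` freezes a 3-chain, ~190-residue instance of the
generator used throughout the tests, small enough for brute-force oracle
verification of its PWMs, compositions and entropies.

## Problem sizes and numerical choices

The default study (tests and `scripts/acceptance.py`) uses 200 chains of
50–150 residues (~19k fragments, ~200 positives): large enough that the
balanced protocol's pooled MCC is stable to ±0.05 across seeds, small
enough for an end-to-end run in about a minute on one CPU. PWM probability
normalization is exact by construction and asserted to 1e−12. Feature
matrices and structure tables round-trip bit-exactly through their text
formats (shortest-repr decimals, `float_precision="round_trip"` on read).
Degenerate inputs fail loudly: single-class training labels, empty PWM
training sets, out-of-range structure values, ragged feature rows and
non-contiguous residue indices all raise with the offending chain or line
named.

## Known limitations

* Window length is global; per-ligand window tuning is out of scope.
* Training data for the CLI's full-data `cv` subcommand are extremely
  imbalanced; expect the high-Sp/low-Sn regime unless `undersample` is used.
* The saved-model format stores dense weights as JSON text — fine at these
  architecture sizes, not meant for large networks.
* No redundancy filtering: the package trusts its inputs to be
  non-redundant and only enforces the 50-residue minimum chain length.
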