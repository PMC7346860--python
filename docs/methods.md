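# Methods

## Windows and conventions

A splice-site window is a fixed-length string over {A, C, G, T} with the
core dinucleotide pinned at a convention-defined 1-based position:
40 nt windows carry GT at 20–21 (donor) or AG at 19–20 (acceptor);
398 nt windows carry GT at 201–202 or AG at 198–199. Trimming a 398 nt
window to L ∈ {40, 80, 160, 240} relocates the dimer to L/2 (donor) or
L/2 − 1 (acceptor); these derived positions are the unique interpolation
that reproduces both fixed conventions at their endpoints (201 → 20 for
donor, 198 → 19 for acceptor at L = 40). The 398 nt placement is
off-centre by design and is taken at face value. Input is uppercased on
ingest; ambiguity codes are rejected by default (an opt-in mode encodes
any IUPAC code as the uniform 0.25 row) because silently imputing bases
would contaminate training data. All positions reported to users are
1-based.

## One-hot encoding

Each window becomes an N × 4 binary matrix with fixed column order
(A, C, G, T); each row is a unit vector. `decode_one_hot` is the exact
inverse and rejects any row that is not a unit vector, naming the row.

## The synthetic-data generator

The generator emulates the structure of real splice-site corpora so the
whole pipeline is testable without redistributable data. Positives are
drawn column-independently from a position weight matrix (PWM) built
from three ingredients:

* **consensus tables** shaped like the canonical human splice consensus
  — donor (A/C)AG|GTRAGT over offsets −3…+6 around the junction,
  acceptor polypyrimidine tract plus YAG|G over offsets −13…+2. The
  numeric values are a synthetic stand-in with the canonical shape, not
  frequencies estimated from any dataset;
* **flank composition**: positions outside the consensus footprint use
  an exon-like distribution on the exonic side and an intron-like
  (T-richer) distribution on the intronic side. Real windows are exonic
  on one side of the junction and intronic on the other, while decoys
  drawn from bulk sequence have no such asymmetry; without this term a
  consensus-only simulation is substantially easier to saturate with a
  bare PWM scorer than real corpora are to a CNN, i.e. it understates
  the realistic separability of the balanced task;
* a **strength** knob in [0, 1] mixing everything with the background:
  strength 0 is an exact null (positives and negatives identically
  distributed apart from the forced dimer), strength 1 the full signal.

Negatives are i.i.d. background (GC fraction configurable, default 0.42
≈ human genome) with the obligate dimer forced in — the standard decoy
construction. Positives and negatives share the background
distribution, so the PWM columns are the only systematic signal; a PWM
log-odds scorer therefore bounds what any classifier can achieve, and
the generator's separability control (log-odds AUROC ≥ 0.95 at
strength 1, ≈ 0.5 at strength 0) calibrates that downstream CNN
performance is attributable to planted signal, not artifacts.

What the simulator does **not** model: dinucleotide/k-mer dependence,
branch-point signal, distal signal beyond the window that drives the
published window-size effect, duplicated or overlapping sequences
between corpora, and real ClinVar allele-frequency structure. Passing
tests show the machinery recovers planted signal; they say nothing
about performance on real genomes.

Variant sets are drawn from positive windows: *disruptive* records hit
one of the six highest-information non-dimer PWM columns (plus the two
dimer positions themselves by default, since junction-breaking variants
are the canonical pathogenic case) and substitute the lowest-probability
alternative allele (alphabetical tie-break, so mutating the G of GT
gives A); *neutral* records hit the lowest-information columns with a
uniformly random alternative. (window, position) pairs are sampled
without replacement within each class.

## Architectures and training

`CNN_3`, `CNN_4` and `CNN_LSTM` are fixed layer stacks (see
`splicevar.models`). Choices the architecture tables leave open:

* hidden activations are ReLU, the output a 2-way softmax with one-hot
  labels and categorical cross-entropy (not a single sigmoid);
* convolutions are stride-1 and valid (no padding); the first filter
  spans the full 4-channel axis, collapsing it, so all subsequent
  layers are 1-D along the sequence;
* max-pool stride equals pool size, remainder dropped;
* the bidirectional LSTM uses 320 units per direction (concatenated 640
  features per step, the DanQ-style reading of "320 output dimension"),
  returns the full output sequence, and is flattened before the dense
  925 layer;
* weight initialisation is Glorot-uniform with LSTM forget-gate bias 1,
  under a fixed seed.

Training: SGD with Nesterov momentum 0.9 (`v ← μv − ηg`,
`w ← w + μv − ηg`), batch size 64, 30 epochs by default, learning rate
`0.05 · f^⌊epoch/5⌋`. The decay period is read as epochs (the natural
unit for a per-5 schedule); the decay factor is not pinned by the
recipe and defaults to the conventional 0.5, exposed as a parameter.
The networks and the training loop are NumPy with explicit
forward/backward passes; every layer's gradient is checked against
central finite differences in the test suite (relative error < 1e-5).
Inverted dropout is active only during training. A non-finite loss
aborts with a diagnostic rather than silently continuing.

The public surface is a scikit-learn-style estimator
(`SpliceSiteClassifier`: `fit`/`predict`/`predict_proba`, `get_params`,
fitted attributes with trailing underscores) so the models compose with
sklearn model selection; `build_model`/`train`/`predict_proba` remain
as thin functional wrappers.

## Evaluation

Probabilities are binarized with a strict `> 0.5` rule (0.5 itself is
negative). AUPRC uses step-wise (average-precision) integration rather
than trapezoidal PR interpolation, which is optimistic; AUROC equals
the Mann–Whitney pair statistic with ties at 1/2 — both verified
against exhaustive enumeration oracles on all small instances.
Undefined precision (no positive predictions) is reported as 0 with a
warning, MCC with a zero denominator as 0, so imbalance sweeps never
produce NaNs. Cross-validation re-declares a fresh model per fold;
folds are stratified by label to stabilise AUPRC on imbalanced data.
Group comparisons use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom, one-sided.

## Imbalance protocol

`subsample_ratio` takes ⌊0.8·P⌋ positives and exactly `n` times that
many negatives (n ∈ {1, 3, 5, 7} in the standard sweep) for training,
without replacement; the holdout keeps the remaining 20% of positives
and *all* remaining negatives, so holdout prevalence falls as the
training ratio rises — deliberately mimicking deployment, where decoys
vastly outnumber true sites.

## Variant scoring

`Score(m) = log10(PM(ref)/PM(alt))` with both probabilities clamped to
[1e-6, 1 − 1e-6]; clamping keeps the score finite when the model
saturates and preserves antisymmetry under a ref/alt swap. The analysis
filter keeps variants whose reference window scores strictly above 0.8
("over 80%"), read as a strict inequality and exposed as a parameter.
Variants falling on the core dinucleotide are scored (they pass through
the model even though the mutated window no longer satisfies the dimer
invariant); generators can exclude them via `include_dimer=False`. The
one-sided alternative is "disruptive/pathogenic scores greater", the
direction implied by the score's sign convention. Variant input is
window-relative; genome-anchored VCF ingestion is out of scope to avoid
a reference-genome dependency.

## Problem sizes

The package's standard desk-scale experiment — used by the test suite
and `scripts/acceptance.py` — trains CNN_4 for 5 epochs on 2,000
windows per class of strength-1 donor data, evaluates on 500 per class,
runs 5-fold cross-validation at 1,000 per class with 4 epochs, and
scores 200 disruptive plus 200 neutral variants. These sizes recover
the planted signal with comfortable margins (holdout AUPRC ≈ 0.97,
shuffled-label null AUROC ≈ 0.5, disruptive-vs-neutral Welch p ≪ 0.01)
while a full run stays in the minutes range on a single CPU.

## Determinism

All randomness flows through `numpy.random.default_rng` seeded from the
caller: generator configs carry a seed, the estimator's `random_state`
seeds initialisation, batch shuffling and dropout streams, and derived
sub-seeds are fixed functions of the stage. Identical seeds give
byte-identical datasets and bit-identical training histories on the
same NumPy backend.

## Known limitations

* Column-independent PWM positives cannot represent higher-order motif
  dependence; CNN filter widths > 1 therefore add less here than on
  real data.
* The simulator places no signal in the long flanks of 398 nt windows,
  so the published long-window advantage is not reproduced (and not
  asserted anywhere).
* Published corpus-level numbers (combined-dataset sizes, real AUPRC
  values, ClinVar p-values) depend on external data and an unpublished
  merge rule; they are out of scope.
* Training is CPU-bound NumPy; it is intended for desk-scale
  experiments, not genome-scale training.
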