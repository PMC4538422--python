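# Methods

## Labels from structure

**Accessible surface area.** ASA is computed with a rolling-probe
(Shrake–Rupley) point-sampling algorithm rather than by calling an external
program: every heavy atom is covered with a deterministic golden-spiral
lattice of test points on a sphere of radius r_atom + r_probe; a point is
accessible when it lies outside every other atom's probe-expanded sphere, and
the atom's area is the exposed fraction times 4π(r+probe)². Residue ASA sums
its heavy atoms. Defaults: probe 1.4 Å, 960 points per atom (per-residue
agreement with a 10 000-point evaluation is better than 2 % on test
structures), heavy-atom radii C 1.76 / N 1.65 / O 1.40 / S 1.85 Å, unknown
elements 1.80 Å with a warning. The point set is deterministic, so ASA is a
pure function of coordinates. A parser for precomputed DSSP output (the ACC
column, chain-break rows skipped) is provided as an equivalent input path.

**RSA and 3-state burial.** RSA divides ASA by the residue type's maximum
accessibility in an extended Gly-X-Gly tripeptide (values 75 Å² for Gly up to
255 Å² for Trp). RSA may exceed 1 for termini and distorted conformations;
it is kept unclipped by default (optional clipping to 1). The three burial
states use half-open bins [0, 0.10) → B, [0.10, 0.40) → I, [0.40, ∞) → E.
The 10 %/40 % cutoffs make the three states roughly equipopulated on globular
monomers; boundary membership is a convention choice (the upper bin is
closed below), applied consistently everywhere.

**Contact number.** CN of residue i counts residues j with |i−j| > 5 whose
Cβ lies within 7.5 Å of residue i's Cβ. "5 nearest neighbours" is read as 5
on each side; the exclusion is configurable. Counts above 14 collapse onto
the cap, giving 15 classes — raw counts are also reported. Glycine (and any
residue missing Cβ) gets a virtual Cβ built from N/CA/C with the standard
ideal-geometry linear combination (tetrahedral carbon, 1.53 Å bond), falling
back to CA when the backbone is incomplete.

**Dataset filters.** Chains shorter than 50 residues or with fewer than 10 %
buried (B) residues are rejected, with a per-chain report of the rule that
fired. Oligomer detection, membrane screening and sequence-identity
clustering need external databases and are out of scope.

## Features

Three per-residue blocks, concatenated to d = 109 dimensions, then windowed:
position i's model input stacks rows i−k … i+k (k = 5 default, zero padding
beyond the termini), giving (2k+1)·d = 1199 inputs.

* **Evolution (40).** From an HHsuite `.hhm` profile: the 20 match-emission
  probabilities (2^(−score/1000); `*` floors at 2⁻²⁰) plus 20 log₂-odds of
  emission versus a fixed background frequency vector (Robinson–Robinson).
  The companion-column composition is a design choice — profile formats do
  not fix it — so a plain 40-column TSV dialect is accepted verbatim as an
  escape hatch.
* **Structure (11).** Predicted 8-class and 3-class secondary-structure
  probabilities, concatenated [ss8 | ss3]; rows must sum to 1 within 1e−3.
  A uniform ss8 fallback covers inputs lacking an 8-class prediction.
* **Amino acid (58).** Position-independent tables: 7 physicochemical
  properties, 11 SS-segment-endpoint propensities, 40 correlated contact
  potentials. The packaged file `data/aa_tables_synthetic.json` fills the 7
  physicochemical columns with standard public scales (Kyte–Doolittle
  hydropathy, residue volume, molecular weight, pI, Chou–Fasman helix/sheet
  propensity, net charge) and the 11- and 40-column tables with seeded
  synthetic stand-ins of the right shape; real property tables can be
  supplied through `load_aa_tables(path)` — shapes (20×7 / 20×11 / 20×40)
  are enforced either way. Letter X maps to the table column means with a
  warning.

Features are standardised per dimension (mean 0, sd 1) on the training set;
the scaler is stored inside the model and applied at prediction time.

## The conditional neural field

Node potentials pass the windowed input through H hidden sigmoid neurons
(tanh available by config; H defaults to 100 and should be shrunk for small
synthetic problems): φ(a, f(i)) = Σⱼ U[a,j]·σ(Wⱼ·f(i)+bⱼ) + cₐ, with
transition potentials ψ(a,b) = T[a,b]. All inference is exact and in log
space with log-sum-exp stabilisation (no scaling-factor variant), safe for
chains of ~1000 residues: forward–backward yields the log-partition, unary
and pairwise posteriors; Viterbi yields the MAP labeling with ties broken
toward the lower label index. Gradients are empirical-minus-expected
sufficient statistics for U and T, backpropagated through the gate for W;
they are verified against central finite differences (max relative error
< 1e−4) and all inference against exhaustive enumeration at small L.

Labels are 1-based in documentation and TSVs, 0-based contiguous internally;
contact-number class c (0…14) is class index c.

## Training

Stochastic gradient ascent on log P(Y|X) − λ‖θ‖² (λ = 1e−4 on weights, not
biases). Initialisation is Glorot-uniform for W and U, zero for biases and T.
Learning rate 0.01 by default, ×0.9 per epoch; pure SGD (minibatch 1) with
optional minibatch averaging. A held-out fraction (10 %) monitors validation
log-likelihood with patience-5 early stopping; the best-validation snapshot
is returned. Everything — initialisation, splits, task and example
sampling — draws from one seeded generator, so a config seed reproduces the
final parameters bit-for-bit.

Multitask training samples the task uniformly (proportional-to-size
sampling available), then an example of that task: one shared W is updated by
every task, each head (U_t, T_t) only by its own. The returned per-task
models hold the same W array object.

The consensus stage stacks first-level models: per residue, their posterior
vectors are concatenated and windowed with the same k, and a fresh CNF is
trained on those inputs. The intended first-level set is the four
feature-class combinations (evolution-only, structure-only, amino-acid-only,
combined); the implementation accepts any list of models for the task.

## Synthetic data

`make_helix_chain` builds an ideal α-helix (radius 2.3 Å, twist 100°/residue,
rise 1.5 Å — consecutive CA–CA chords ≈ 3.8 Å) with N/C placed off-axis at
~1.46 Å in the local frame and Cβ by ideal geometry; optional seeded jitter
roughens it so contact counts and surface areas vary.

`make_two_task_dataset` plants a known CNF and samples labels exactly from it
(forward filtering, backward sampling — empirical marginals converge to the
forward–backward posteriors). Features are AR(1) along the chain (ρ = 0.8),
mimicking the local correlation of windowed profile features. A shared
hidden layer drives both tracks; each head is ordinal — class scores are
−γ(s−μ_c)² in a latent depth s, which expands to scores linear in the hidden
vector, so the construction is an exact CNF. The `coupling` knob mixes the
shared latent direction with an independent one for the 15-class track
(coupling 1 = one common driver, 0 = disjoint hidden units). Score scales
(γ₃ = 25, γ₁₅ = 60, hidden pre-activation scale 2.5, diagonal transition 0.4)
were chosen so the generating model's own predictions sit in the realistic
operating regime for this problem — about 0.67 three-state accuracy, 0.28
fifteen-state accuracy and 0.87 expected-vs-true contact-number correlation —
and the three burial states are near 1:1:1.

What the generator does *not* emulate: real profile statistics, long-range
(non-chain) label dependencies, class imbalance of extreme contact numbers,
and structural noise in label generation. Passing the planted-recovery and
multitask tests therefore demonstrates correctness of the estimator and the
benefit of sharing under the model's own assumptions, not performance on real
proteins — headline numbers on real corpora require the external profile
tools and structure databases this package deliberately does not depend on.

## Verification sizes

The test suite checks inference against exhaustive enumeration (200 random
instances, L ≤ 6, M ≤ 4, tolerance 1e−8), geometry against dense-point and
all-pairs brute-force oracles, posterior recovery after training on 500
planted chains of length 30 (mean total-variation distance < 0.1 on held-out
chains), and a 10-paired-seed multitask-versus-single comparison at coupling
0.9 and 30 training chains (multitask not worse by more than 0.01 mean
accuracy; measured gain ≈ +0.017). These sizes keep the full suite to a few
minutes while leaving each check statistically meaningful.

## Known limitations

* ASA uses a fixed four-element radius table; exotic heteroatoms fall back to
  a default radius (the labelers only accept standard amino acids anyway).
* The consensus stage trains per task; a joint multi-task consensus is not
  implemented.
* SGD is single-threaded and in pure numpy; at H = 100 and D = 1199 training
  on thousands of real chains would be slow — the design favours exactness
  and reproducibility over throughput.
* The packaged 11- and 40-column amino-acid tables are synthetic stand-ins;
  supply measured tables for real-data work.
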