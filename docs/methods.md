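# Methods

## Reaction representation

A reaction is parsed from `reactants>agents>products` SMILES with RDKit.
Every atom must carry a map number ≥ 1, unique within its side; the agents
field is tokenized and discarded (nothing downstream consumes it, and no
convention exists for folding agents into the reaction graph). Map number
0 is rejected rather than auto-mapped: the representation is only
meaningful under a complete, correct mapping, and silently inventing one
would hide data problems. Explicit hydrogens written as `[H:n]` atoms are
kept in the graph when `keep_explicit_h` is set (datasets with explicit-H
mappings) and folded into implicit H counts otherwise.

The condensed graph of reaction (CGR) is the superposition of the two
sides: vertices keyed by map number, edges by unordered map-number pairs,
each carrying separate reactant and product attribute blocks plus
presence flags. Imbalance — atoms present on one side only, e.g.
unreported leaving groups — is legal and flagged, never "fixed" by
automatic completion: missing fragments can rearrange, so autocompletion
can silently corrupt a dataset. An element mismatch between sides at one
map number is a hard error.

## Features

Molecular atom vectors are 133 long: one-hot atomic number (slots for
Z = 1..100 plus a catch-all), total degree (0–5 + catch-all), formal
charge (−2..+2 + catch-all), chirality tag (4 + catch-all), H count
(0–4 + catch-all), hybridization (sp, sp², sp³, sp³d, sp³d² + catch-all),
an aromaticity flag, and mass/100. Molecular bond vectors are 14 long:
a null-bond flag, bond-type one-hot (single/double/triple/aromatic),
conjugation, ring membership, and stereo one-hot (6 + catch-all). The
edge-initialization input cat(x_v, e_vw) is therefore 147 for molecules.

Reaction graphs use dual blocks. The atom vector concatenates one side's
full 133 features with a 32-wide difference block that drops the
atomic-number one-hot — elements cannot change in a reaction — but keeps
the scaled mass, so isotope information survives imbalance; total 165.
Bond vectors concatenate two 14-blocks (28). Three combination modes are
exposed: `reac_diff` (reactant + product-minus-reactant difference, the
default and empirically strongest), `prod_diff`, and `reac_prod`. All
three produce equal-length vectors, so models are mode-portable.

For atoms/bonds present on one side only, `imbalance_mode` chooses the
substitute for the missing side, applied *before* differences are taken:

* `zero` (default): the zero vector. A vanished atom's diff block is thus
  −x̃^reac, which lets the network see the disappearance.
* `copy`: the present side's block is imputed. Atom blocks are copied
  unconditionally; a one-sided *bond* is copied only when one of its
  endpoints is absent on that side (the bond is missing because of
  imbalance), never when both endpoints exist there (the bond is genuinely
  made or broken). The stricter reading — impute every one-sided bond —
  is available behind `copy_all_bonds=True`; the default was chosen
  because imputing a deliberately broken bond erases the reaction's own
  signal. For balanced reactions the two modes coincide exactly.

## Encoder

Hidden states live on directed edges; the reverse edge is excluded from
the incoming sum, which prevents immediate echo ("tottering") of a
message back along the bond it arrived on. With τ = ReLU:

* h⁰_vw = τ(W_i · cat(x_v, e_vw)), W_i bias-free;
* h^{t+1}_vw = τ(h⁰_vw + W_h · Σ_{k∈N(v)\w} h^t_kv) for T steps
  (T = 3 default; T = 0 is well-defined and reads out the initial
  states);
* h_v = τ(W_o · cat(x_v, Σ_{w∈N(v)} h^T_wv));
* mean (default) or sum aggregation over atoms, then concatenation of
  the optional descriptor vector f.

Bias placement: W_h and W_o carry biases, W_i does not. The architecture
family's equations are usually printed bias-free; one 300-wide bias
beyond the conventional output/readout set is required to make the
default model's trainable-scalar count come out at 378,601, and it is
fixed on W_h for determinism. The closed-form counter and the enumerated
weights of instantiated models agree by construction and by test.

Batches are encoded as one disjoint union graph with per-graph
aggregation segments; results are identical to per-graph encoding (an
asserted contract, not an approximation).

## Numerics and training

No deep-learning framework is used: forward pass, hand-derived
backpropagation and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) are
implemented in NumPy, in float64 throughout. The gradient implementation
is verified against central finite differences to ~1e-6 relative error;
biases are shifted off zero in that test, since a pre-activation sitting
exactly on the ReLU kink has an ambiguous subgradient and a finite
difference straddling it reports the average slope.

The per-step learning rate rises linearly from 1e-4 to 1e-3 across the
first two epochs, then decays exponentially with a constant per-step
factor chosen to land exactly on 1e-4 at the last step. A total step
budget not exceeding the warmup is a configuration error. Losses are
mean-squared error on standardized targets (regression; standardization
fitted on the training partition only, predictions de-standardized) and
softmax cross-entropy (multiclass). The loss choices follow the
convention of this architecture family; only the evaluation metrics (MAE
for regression, accuracy for classification) drive checkpoint selection:
the epoch with the best validation metric is returned. Training is
bit-reproducible for a fixed seed. A non-finite loss aborts immediately
with a diagnostic rather than training through NaNs.

Dropout (default 0) sits after each hidden FFN activation with inverted
scaling. Weight matrices are Glorot-uniform; biases start at zero.
Warm-starting from an earlier result or checkpoint file supports the
pretrain-then-fine-tune workflow.

The five-fold protocol (`cross_validate`) re-splits and re-trains at
seeds `base`, `base+1`, … and reports per-fold metrics with mean and
standard deviation, giving a split-independent performance estimate.

## Splits

* `random`: uniform; partition sizes within one record of the 80/10/10
  fractions.
* `random_grouped`: random over unique condition-free reactions
  (canonical `reactants>>products`, maps and agents stripped), so one
  reaction measured under several solvents/enzymes never leaks across
  partitions.
* `directed_scaffold`: records are first grouped by the unordered pair of
  canonical sides — a reaction and its reverse share the key and can
  never straddle partitions — then bucketed by the generic Murcko
  framework of the lexicographically smaller side (direction-independent)
  with multi-molecule sides using sorted, dot-joined component
  frameworks. Buckets go largest-first to training, then validation, then
  test; ties break randomly under the split seed. The scaffold operator
  and assignment order are design choices; with fewer than three buckets
  no scaffold split exists, so the splitter warns and falls back to a
  grouped random split that still keeps pairs together.
* `predefined`: three plain-text index files, one integer per line, for
  externally published splits.

## Baselines

The dummy baseline predicts the training-target mean; by the definition
of R², it scores exactly 0 on its own training targets and sets the error
floor. Morgan reaction fingerprints are *count*-based (radius 3, width
1024): counts make the product-minus-reactant "diff" variant informative
where folded bits would saturate, and the diff of a reverse reaction is
exactly the negation of the forward one. Atom maps are stripped before
hashing, because RDKit's environment hashes would otherwise encode the
mapping itself. Whether the original baselines hashed with or without
maps is not documented; without is the conservative choice. The
fingerprint models reuse the identical feed-forward readout and training
loop as the graph model — one readout stack, two front ends.

## Synthetic fixtures

The generator emulates the *structure* of curated reaction datasets —
valid complete mappings, explicit hydrogens, balanced/imbalanced
mixtures, regression or class targets — without any claim to realistic
thermochemistry. Four templates over twelve small C/H/O/N skeletons:
homolysis of a heavy-atom single bond (radical pair), SN2 substitution of
a C–O bond by amide ion, E2 elimination by hydroxide, and proton transfer
to water. Each alters at most two bonds, so the regression target

    y = 10·(bonds broken) − 4·(bonds formed) + 2·Δ(formal charge sum) + ε

is exactly computable from the generated record's own CGR (bond-change
counts are recomputed from the final, possibly fragment-dropped record,
keeping targets and graphs consistent). The coefficients were fixed once
at magnitudes that separate the templates clearly; ε is Gaussian with
σ = 0 by default, since the fixtures' role is to test whether the
architecture can recover an exactly learnable rule. Imbalanced variants
drop the smallest product fragment. Multiclass fixtures use the template
id as the label, mirroring name-reaction classification at toy scale.

Because targets are a linear function of three CGR summary statistics,
passing the learnability tests shows the encoder extracts bond-change
information from raw graphs — it does not show performance on real
activation energies or yields, whose targets depend on chemistry far
beyond bond counts.

## Problem sizes

The test suite trains on 20–500 toy reactions (10–20 atoms each) at
hidden sizes 12–300; the learnability check uses 500 fixtures at the full
default architecture for 30 epochs, chosen as the point where the fitted
model's test MAE is far inside the acceptance margin. The acceptance
script itself is purely structural (weight enumeration) and runs in
seconds.

## Known limitations

* Correct, complete atom mapping is assumed; the package validates
  uniqueness and element consistency but cannot detect a chemically wrong
  mapping.
* Multi-bonds between one atom pair are unsupported (bond identity is the
  unordered map-number pair) — not expressible in the supported SMILES
  chemistry anyway.
* Only ReLU, mean/sum aggregation, and per-step LR decay are implemented;
  attention-style readouts and atom-level targets are out of scope.
* The NumPy engine targets CPU and desk-scale datasets (10²–10⁵
  reactions); it has no GPU path.
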