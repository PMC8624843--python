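# Methods

## Scope and model family

`ribocontact` predicts the full residue–base contact map of a protein–RNA
pair from sequences and predicted secondary structures. The model is a
sparse linear scorer over local context features, decoded exactly by integer
programming and trained as a structured SVM. Everything is deterministic
given its seeds: the same corpus, hyperparameters and seed reproduce the
same weights bit for bit.

## Inputs and their derived representations

A pair consists of a protein record (sequence over the 20 canonical amino
acids plus an equal-length 8-state secondary-structure string over
H/G/I/E/B/T/S/−) and an RNA record (sequence over ACGU plus a balanced,
non-crossing dot-bracket string). Non-canonical letters are rejected rather
than remapped: every feature alphabet is canonical-only, so an X or N would
silently create feature keys the model can never share across records.

From the dot-bracket we derive a 6-state loop profile. Paired bases are
stacks (S). Each unpaired base belongs to exactly one loop — the innermost
base pair enclosing it, or the exterior — and is labelled by that loop's
kind: no enclosing pair → external (E); a closing pair with no inner pairs →
hairpin (H); one inner pair with unpaired bases on both the 5′ and 3′ gaps →
internal (I), on exactly one gap → bulge (B); two or more inner pairs →
multibranch (M). Unpaired bases between two exterior stems remain E: without
a closing pair there is no multibranch. Pseudoknots are outside the model
(only `(`, `)`, `.` are accepted), which matches the non-crossing output of
the intended structure predictors. The implementation is a single-pass loop
decomposition; the test suite checks it against an independent classifier
that explicitly searches for each base's innermost enclosing pair.

## Features

Feature keys are (type, context) pairs with integer counts; all stores are
sparse because the nominal key spaces (e.g. 20⁵ × 4⁵ paired windows) are
intractable densely. The rows are:

* residue features, counted once per binding residue: sequence k-mers
  (k = 3, 5); k-mers of the 10-group (LVIM, C, A, G, ST, P, FYW, EDNQ, KR, H)
  and 4-group (LVIMC, AGSTP, FYW, EDNQKRH) simplified alphabets (k = 5, 7);
  8-state structure k-mers (k = 3, 5);
* base features, once per binding base: sequence and loop-profile k-mers
  (k = 3, 5);
* contact features, once per contact: equal-length paired windows combining
  a residue-side string (sequence, either simplified alphabet, or 8-state
  structure) with a base-side string (sequence or profile), at k = 3 and 5.
  Structure pairs with structure and sequence-like strings with sequence,
  giving 12 rows. The simplified alphabets use k = 3, 5 here even though
  their unary rows use k = 5, 7; both choices are deliberate and independent.

Windows are centred and padded with a sentinel `^`, so every position yields
a full-length context. This keeps exactly one key per (position, row) and
makes the per-variable scores position-independent precomputations. Each
simplified-alphabet letter maps to the first letter of its group; any
injective labelling would be equivalent.

## Decoding

With precomputed scores `u_i` (residue), `v_j` (base) and `w_ij` (contact),
decoding maximizes `Σ u_i x_i + Σ v_j y_j + Σ w_ij z_ij` over binary
variables subject to: `x_i + y_j ≥ 2 z_ij`; `x_i ≤ Σ_j z_ij`;
`y_j ≤ Σ_i z_ij`; `y_{j−1} + (1−y_j) + y_{j+1} ≥ 1` (no isolated binding
base); and per-residue/per-base caps `Σ_j z_ij ≤ X_i`, `Σ_i z_ij ≤ Y_j`
(default 8, `None` = unbounded). The isolated-base constraint is enforced at
the RNA termini with out-of-range neighbour terms read as 0: a bound
terminal base therefore needs its single inward neighbour bound, and a
length-1 RNA can never bind. The exhaustive-enumeration oracle implements
the identical convention, so the equivalence tests pin the boundary
semantics down rather than averaging over them.

The backend is HiGHS branch-and-cut via `scipy.optimize.milp`, run with a
zero MIP gap so optima are proven rather than approximated; the empty map is
always feasible, so the optimum is never below 0. Returned indicator values
are re-derived from the contact variables, and the reported objective is
re-evaluated on the returned map. Among co-optimal maps the solver's choice
is implementation-defined; the enumeration oracle breaks ties by the
lexicographically smallest contact set, so cross-checks compare objective
values, never contact sets.

## Loss and loss-augmented decoding

The training loss charges `δFN = 0.5` per false-negative binding residue,
binding base and contact, and `δFP = 0.005` per false positive of each kind.
These six penalties set the sensitivity/specificity trade-off: misses are
100× more expensive than spurious predictions, which is what makes a sparse
prediction the safe default. Loss-augmented decoding shifts each variable's
score by `−δFN` where the true variable is 1 and `+δFP` where it is 0, and
carries the constant `δFN · (#true positives)` in an explicit offset so that
the augmented objective of *every* candidate map equals `f(ẑ) + Δ(z, ẑ)`
exactly (the tests verify this identity exhaustively on small instances).
The shift on `w_ij` is conditioned on the true contact `z_ij`, which is the
only reading under which the identity holds.

## Training

The regularized structured hinge is minimized by stochastic subgradient
descent: per instance, decode `ẑ` under loss-augmented scores and update
each touched key by `φ_k(ẑ) − φ_k(z) + C sgn(λ_k)` (with `sgn 0 = 0`),
scaled per key by AdaGrad: `λ_k ← λ_k − η/√(G_k + ε) · g_k`, `G_k` the
running sum of squared subgradients. Defaults: `η = 1`, `ε = 10⁻⁸`,
`C = 10⁻⁵`, at most 100 epochs (50 in the acceptance experiments),
convergence declared when the largest per-epoch weight change falls below
`10⁻⁶`. Instances are visited in a per-epoch shuffled order drawn from the
training seed; updates within an epoch are per-key independent, so runs are
bitwise reproducible. The ℓ1 subgradient is applied lazily to the keys
touched by the current instance only — an exact dense ℓ1 step over the
unbounded key space of a sparse model is not defined. Gold maps that violate
the decoding constraints (an isolated bound base, or a cap overflow) are
rejected up front with a data error naming the instance, since the hinge
would otherwise compare against an unreachable target.

## Evaluation

PPV = TP/(TP+FP), SEN = TP/(TP+FN) and their harmonic mean F are computed at
three levels: contacts (entries of z), binding residues (derived x) and
binding bases (derived y). A metric with a zero denominator is reported as 0
and flagged undefined — required for empty predictions. Datasets aggregate
macro (mean of per-pair metrics; a pair is excluded from a level only when
tp = fp = fn = 0 there) or micro (metrics of pooled counts); macro is the
default and the mode is recorded in every output.

## Contact maps from coordinates

A residue and a base are in contact when any two of their non-hydrogen atoms
lie within 4.0 Å. This single heavy-atom criterion also covers
hydrogen-bond-range contacts (3.5 Å < 4.0 Å) without modelling donor/acceptor
geometry, which would require hydrogen positions that X-ray structures
usually lack. PDB extraction takes one protein chain and one RNA chain per
instance, skips non-standard residues/nucleotides with a warning and
compacts indices; resolution and redundancy filtering are the caller's
responsibility.

## Synthetic corpus

The generator emulates the full input stack and produces labels that are
*realizable by construction*: random protein sequences with run-favouring
8-state structure strings (first-order Markov chain, stay probability 0.75);
random RNA sequences with well-formed dot-brackets from a recursive
stem-loop sampler (stems ≥ 3 bp; hairpin, internal-loop, bulge and
multibranch motifs); sparse planted weights drawn Normal(0, scale) on a
random fraction of the feature keys realizable in the corpus; labels decoded
exactly under the planted weights and the configured caps. Defaults: 10
pairs, protein lengths 15–30, RNA lengths 20–40, sparsity 0.1, scale 1.0,
caps (8, 8). The RNA range is chosen so all six loop states occur with
positive probability (multibranch loops need roughly 17+ nt); the protein
range keeps a 50-epoch training run around a minute on one CPU while leaving
dozens of contacts per pair. The problem sizes in the acceptance experiments
(10 training pairs, instances up to 30 × 40, 200 oracle instances up to
4 × 4) are scaled-down study conditions chosen for exactness of verification,
not estimates of real-corpus accuracy.

What the generator does *not* emulate: real binding-site composition biases,
correlation between RNA sequence and its structure (sequence and dot-bracket
are sampled independently), structure-prediction errors, multi-chain
complexes, and the redundancy structure of a PDB-derived corpus. Passing the
synthetic tests therefore demonstrates correctness of the machinery —
decoding exactness, the loss-augmentation identity, trainability and
reproducibility — not expected accuracy on real protein–RNA pairs.

## Identifiability of planted weights

Within a finite corpus many feature keys are exactly collinear: the 12
contact rows of one (i, j) cell always fire together, and rare windows occur
at a single position. Collinear keys receive identical subgradients, so the
learner distributes weight mass across a whole co-firing group regardless of
which member was planted. Per-key sign recovery is therefore assessed only
on keys that carry a planted weight — among those, the top decile by
recovered magnitude agrees in sign with the planted values well above 80% —
while the absolute placement of mass within a collinear group is
unidentifiable in principle.

## Known limitations

* Decoding cost grows with |P|·|R| binary variables; there is no
  approximate/heuristic mode, so very long pairs are expensive.
* The loop profile discards base-pairing partners (a stack's pairing
  distance is invisible), a known information loss of profile encodings.
* One protein chain × one RNA chain per instance; no multi-chain complexes.
* The ℓ1 treatment is the plain lazy subgradient; proximal methods would
  produce exact zeros more aggressively.
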