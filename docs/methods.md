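# Methods

This note documents the models, algorithms and parameter choices behind
`rnadecoy`, including the places where the design was genuinely open and
what the synthetic benchmark does and does not demonstrate.

## Folding engine

Secondary structures are pseudoknot-free sets of canonical pairs (A-U, C-G,
G-U) with hairpin loops of at least 3 unpaired residues. The energy model is
deliberately minimal: one stability term per pair type (defaults
CG/GC −3.0, AU/UA −2.0, GU/UG −1.0 kcal/mol-equivalents) plus a stacking
bonus of −1.0 whenever a pair directly encloses another, converted to
Boltzmann weights with β = 1/RT at 37 °C (RT = 0.6163 kcal/mol). It is not
a nearest-neighbor parameterization and its free energies are not
comparable to experimental ones; what the pipeline consumes is *relative*
information — probability distributions within a sequence and free-energy
differences within a group — which this model supplies while remaining
exactly testable. When fidelity to a production thermodynamic engine
matters, per-sequence probability matrices computed externally can be
ingested instead (`i j prob` text files plus an alignment), bypassing the
internal fold entirely.

Pair probabilities are exact: an inside recursion over intervals with a
paired-interval table (the stacking term makes the recursion two-level) and
an outside recursion over enclosing pairs, both rescaled per position so
that long or very stable sequences stay inside float64 range. The
brute-force oracle enumerates every legal structure (sequences ≤ 20 nt),
Boltzmann-weights each, and must agree with the dynamic program to 1e-9;
this equivalence is asserted over 200 random sequences in the test suite.

The ensemble free energy is −(1/β)·ln Q including the empty structure
(hence always ≤ 0). It stands in for a loop-decomposition evaluation of a
single predicted structure: it is deterministic and requires no structure
choice, and only its spread within a group matters (the Z-score feature).

MEA structures maximize Σ 2γ·P(i,j) over chosen pairs plus Σ Po(i) over
unpaired positions (γ = 1 by default), with deterministic tie-breaks
(prefer unpaired, then the smaller partner index).

## Consensus iteration

Pairwise alignments use a three-state pair HMM (match, two insert states;
gap open 0.05, gap extend 0.4) in an odds-ratio formulation: match
emissions are a substitution odds ratio (3.0 identical / 0.5 different)
times the structural match score raised to β_align (default 1.0). Iteration
0 aligns from sequence alone and folds each sequence intrinsically. Each of
the 3 refinement iterations recomputes, per sequence, the extrinsic
information

E(i,j) = mean over other sequences n of Σ_{k<l} π(i,k)·π(j,l)·Pⁿ(k,l),

refolds with each pair weight multiplied by (1 + γ·E(i,j)), then recomputes
match scores and realigns. The final alignment is built progressively —
one round of triplet consistency on the posteriors, a neighbor-joining
guide tree on posterior-expected identity (lexicographic tie-breaks for
determinism), and profile–profile alignment maximizing summed posterior
match probability with free gaps.

**The extrinsic weight γ.** The multiplicative form keeps the extrinsic
term off when a group has one sequence and makes the all-zero bonus an
exact identity. Because E ≤ 1, the multiplier must be large enough for
group evidence to compete with intrinsic pair weights of order e^±5;
γ = 50 (ln(1 + 50·E) spans roughly 0–4 k_BT) was calibrated so that the
documented consensus effect is actually expressed: with it, homologs'
recovery of the family consensus structure rises from ≈0.56 to ≈0.86 mean
overlap across seeded trials, and a shuffled decoy's structure is pulled
toward the consensus in >90% of trials. Small values (≲1) leave the
iteration numerically inert. γ is exposed in the configuration.

## Features

PS/US scores are computed per alignment column for each sequence from the
final probability matrices: PS averages the products of upstream-pairing
probabilities plus downstream-pairing products against every other
sequence; US does the same for unpaired probabilities; a gapped position
contributes the all-zero marginal triple, and gap columns of the target
score zero. Since PS + US ≤ 1, the 2-D histogram (bin width 1/30) keeps
only the lower-triangular 465 bins; a score of exactly 1.0 clamps into the
last bin; counts are normalized by the number of non-gap columns.

The KL score compares the target's histogram q with the bin-wise mean r of
the others' histograms: both receive a pseudocount of 1/465 per bin and are
renormalized, then Σ q·ln(q/r). Interpretive choices, fixed here: the
pseudocount is applied to the *normalized* distributions (scale-free), the
mean of others is taken before pseudocounting, and the logarithm is
natural — any base change only rescales the feature, which the classifier
absorbs.

The Z-score uses the mean and *population* standard deviation of the other
sequences' free energies; zero spread yields 0 with a warning. The mean
sequence Shannon entropy is (1/A)·Σ p·log₁₀ p of the target's own symbol
frequency per column, gaps counting as a fifth symbol; it is kept with its
natural sign (≤ 0, bounded below by −log₁₀5) — the classifier is invariant
to the sign convention. The structural Shannon entropy is
−(1/N)·Σ_{i<j} P·log₁₀P with 0·log 0 = 0, computed on the iteration-0 and
final matrices; the difference (initial − final) captures how much the
consensus iteration reshaped a sequence's folding landscape.

## Decoys and synthetic families

Shuffled decoys permute a uniformly chosen subset of positions (the
permutation is uniform; a residue may land on its own position), keeping
round((1−keep)·L) positions mobile where keep is the family's mean pairwise
identity — so decoys match the family's length, composition and typical
identity while their structure is disrupted (mean structure overlap with
the original < 0.5 across seeded trials). Cross-family decoys are drawn
uniformly from another family. Rounding is half-up; both generators are
seeded and reproducible.

Synthetic families emulate small structured-RNA families: a random nested
consensus (2–4 helices of ≥3 stacked pairs, hairpins ≥3, 30–60% of
residues paired, optionally one enclosing helix), lengths 40–120 nt, target
mean pairwise identities 0.5–0.8. A seed sequence realizes the consensus
with GC-biased stems and A-rich loops (as in natural RNAs; this also limits
spurious competing helices) and is redrawn up to 15 times until its own MEA
fold recovers the consensus. Members evolve from the seed by point
mutations — compensatory at paired positions with probability 0.9 (the
pair switches to another canonical type) — at a rate inverted from the
target identity via t ≈ (1−f)² + f²/3; candidates whose fold drifts off the
consensus are redrawn (up to 8 tries, best kept), emulating the purifying
selection that conserves real family structures. Realized identities land
within ±0.05 of target; the modal single-sequence MEA structure of a family
recovers ≥ 60% of consensus pairs (asserted in tests).

What the generator does *not* emulate: insertions/deletions within a family
(members of one family share a length, so the within-family alignment is
exact and ungapped), covariation statistics of specific natural families,
non-canonical or pseudoknotted structure, and base modification. Passing
benchmarks on this corpus therefore demonstrate that the pipeline's
features separate structure-sharing groups from composition-matched
contaminants under controlled conditions — not performance on curated
natural families, where alignment ambiguity and family-specific length
variation make the problem harder.

## Classifier and evaluation

Features feed an AdaBoost ensemble of depth-1 decision trees. Two variants
are exposed: *discrete-vote* (scikit-learn's AdaBoostClassifier) and
*probability-weighted* (the default; real-valued stump contributions
½·ln(p/(1−p)), implemented locally over scikit-learn stumps because recent
scikit-learn releases dropped that algorithm). The decoy probability of the
probability-weighted variant is the logistic of the mean stump
contribution — monotone in the decision function, so ROC analysis is
unaffected by the squashing choice. Hyperparameters (estimators 20–2000,
learning rate 0.5–20, both variants — a logarithmic subsample of the wider
ranges, with the full ranges available by configuration) are selected by
grouped cross-validated grid search maximizing AUC; all sequences of a
group stay in one fold, since group members are not independent. The
benchmark and the reproduction script train with the defaults
(500 estimators, learning rate 1.0, probability-weighted) rather than a
per-run grid search, keeping the headline numbers a function of the
features rather than of hyperparameter luck.

ROC curves sweep all score thresholds; AUC is trapezoidal; the operating
point reported is the (linearly interpolated) sensitivity at a 5%
false-positive rate. The bundled example threshold of 0.4971 on the decoy
probability corresponds to that operating point for one particular trained
model and should be re-derived from the ROC whenever the model is
retrained.

## Problem sizes and determinism

The default corpus is 13 families (8 train / 5 test, disjoint), 210
training groups (60 each with 1, 2, 3 mixed-kind decoys, 30 clean) and 70
testing groups (10 per decoy count for cross-family and shuffled decoys
separately, 10 clean), each group holding 5–20 homologs — a deliberately
desk-scale corpus an order of magnitude smaller than a full curation
campaign, sized so the whole benchmark reruns in minutes on one core.
Every stochastic component (structure, family, group, shuffle, corpus,
classifier) takes an explicit seed, and the deterministic stages (folding,
alignment, features, ROC) are bit-reproducible unconditionally; ties in
the guide tree and dynamic programs are broken by fixed rules, never by
float noise or dictionary order.

## Known limitations

- The energy model's absolute free energies are not physical; only
  within-group comparisons are meaningful.
- The pair HMM has fixed, uncalibrated gap/substitution parameters;
  severely length-mismatched pairs rely on the insert states heavily.
- Groups smaller than 3 cannot be scored (the Z-score needs two other
  sequences); a single-sequence "group" degenerates to an intrinsic fold.
- O(S²·L²) alignment and O(L³)–O(L⁴) folding per iteration make the
  pipeline comfortable up to roughly 20 sequences × 200 nt; it is not a
  genome-scan tool.
- Paralogous families that genuinely share part of their structure are
  expected to remain hard: the features measure structural coherence with
  the group, which partial homology partially satisfies.
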