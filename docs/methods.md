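# Methods

This note documents the model, the numerical and design choices behind
`sulfsite`, and what its tests do and do not establish.

## Problem and model

Given a protein sequence, every cysteine is a candidate S-sulfenylation
site. The unit of prediction is a 21-residue window centered on the
cysteine (10 residues up- and downstream, `X`-padded at termini). The
choice of ±10 follows the observation that experimentally mapped peptides
carry short flanks (on the order of 6 ± 4.6 residues), so a ±10 window
captures essentially all sequence context such data can provide.

Classification is a soft-margin SVM with RBF kernel. Defaults are
γ = 0.005 and C = 1.0; γ is the published operating point of this predictor
family, C is unpublished and left at the library default, and both are
exposed in `ModelConfig`. Probabilities come from Platt-sigmoid
calibration fitted on internal cross-validated decision values
(`CalibratedClassifierCV(SVC(...), method="sigmoid", ensemble=False)`).
We deliberately use the wrapper rather than LIBSVM's internal
`probability=True` implementation: on small, weakly separable training
sets the internal fit can invert the probability ordering relative to the
SVM margin (we measured held-out decision-value AUC 0.68 against
probability AUC 0.30 on a 128-sample planted benchmark), while sigmoid
fitting on pooled out-of-fold decision values keeps the ordering
consistent. The calibration uses up to 5 internal folds, reduced to the
size of the smaller class; training therefore requires at least two
examples per class. A site is called modified when its probability
strictly exceeds the cutoff (default 0.5), so a probability exactly at the
cutoff is a negative call.

### Class imbalance

Negative windows outnumber positives roughly 7:1 in realistic benchmarks.
Each training round draws a uniform random negative subset equal in size to
the positive class (without replacement, seed-deterministic).
`repeated_balanced_cv` repeats the whole procedure (default 20 repeats of
stratified 10-fold CV), pools held-out probabilities within a repeat into
one metrics report, and summarizes across repeats as mean ± sample SD.
AUCs are averaged as scalars per repeat rather than averaging ROC curves.
The deployable model (`train_ensemble`) averages the probabilities of B
(default 20) SVMs trained on independent balanced draws, so all negatives
inform the served predictor even though each member sees a balanced set.

### Leakage control

All trainable artifacts are fitted inside the training folds only: the
PSAAP matrix is re-estimated per fold from training-fold positives, and
encoding held-out windows never updates it. The property table used by the
`aaindex` encoder is a fixed external constant (not data-dependent), so its
min-max scaling introduces no leakage.

## Encoders

- **binary** — per flanking position, a 21-length one-hot block in fixed
  residue order (A first, C second, …, X last); 20 × 21 = 420 dims. The
  flanks are exactly recoverable from the vector.
- **psaap** — a 21 × 20 matrix of positional residue frequencies estimated
  from positive training windows only (propensity of the modified class);
  encoding looks up the frequency of the window's residue at each flanking
  position (20 dims). Plain relative frequency, no smoothing; the
  difference-matrix variant (positive minus negative frequencies) can be
  supplied as a custom matrix.
- **aaindex** — 14 physicochemical scales per residue (280 dims):
  hydrophobicity (Kyte–Doolittle), solvent-accessible surface area
  (Chothia tripeptide), polarity (Grantham), polarizability
  (Charton–Charton), mean fractional buried area (Rose), α-amino and
  α-carboxyl pK, melting point, molecular weight, optical rotation, net
  charge index of side chains, entropy of formation, heat capacity and
  absolute entropy (Hutchens). `X` is defined as 0 in every scale. The
  shipped TSV (`src/sulfsite/data/physicochemical_properties.tsv`) is one
  representative choice per named property; users can load and substitute
  their own table. Rows are min-max scaled to [0, 1] over the 20 amino
  acids by default (`normalize_properties`, idempotent; constant rows are
  an error) because raw units differ by four orders of magnitude
  (molecular weight ~10², net charge index ~10⁻²) and would otherwise
  dominate the RBF distance.

## Redundancy filter

Pairwise identity between two 21-mers is the fraction of equal characters
(`X` = `X` counts; denominator fixed at 21). The filter is a greedy scan in
input order that drops any window with ≥ 40% identity to an already kept
one — CD-HIT-style representative keeping, because removing *both* members
of every similar pair would annihilate whole clusters. Positives and
negatives are filtered jointly. The scan is vectorized over the kept set
(uint8 matrix comparison), so the full ~8k-window benchmark filters in
seconds.

## Metrics

SN, SP, ACC and MCC are computed exactly from integer confusion counts;
when a factor of the MCC denominator is zero, MCC is reported as 0 with a
warning (standard convention, keeps summaries finite). The ROC is a
threshold sweep with tied scores grouped into a single step and trapezoidal
area, which makes AUC identical to the pairwise concordance probability
(Mann–Whitney U / n₊n₋, ties counted half) — a property the test suite
verifies against brute-force enumeration on score sets up to 200 points.
Internally everything is a fraction; percent formatting happens only in
report rendering.

## Composition contrast

Per-position residue frequencies exclude the padding residue `X` from
denominators so short flanks do not dilute composition. The two-sample
contrast tests each (flanking position, residue) pair with a pooled
two-proportion z-test, switching to Fisher's exact test whenever a pooled
expected count falls below 5; both tests are symmetric under swapping the
classes, which gives the anti-symmetry property (swapped inputs flip every
direction and preserve p-values). Results are reported at a fixed
significance threshold (default p < 0.01) without multiple-testing
correction, matching the convention of two-sample logo tools; the output
TSV is consumable by external logo renderers.

## Synthetic benchmark generator

`MotifSpec` describes a draw: class sizes, a background residue
distribution, and enrichment rules (position, residue, probability). Each
generated protein carries exactly one cysteine; positive-site flanks emit
the rule residue with its stated probability and otherwise draw from the
background restricted to non-rule residues, so the planted frequency equals
the rule probability exactly. The default background is uniform over the
19 non-cysteine amino acids (~5.3% each); excluding cysteine keeps the
planted site the only cysteine per protein, which makes window
re-extraction a bijection onto the planted windows and keeps class counts
exact. The default rule set plants K/R/E at 35% at the upstream and
downstream positions characteristic of S-sulfenylated peptides
(K at −6, −5, −4, −2, +7, +8; R at −4, −2; E at −3, +1, +3, +4, +5).

Flank lengths default to the full 10 residues. This is a deliberate
choice: the generator's primary job is signal-recovery testing, and
sampling realistic short flanks truncates about a third of the planted
positions to `X`, which confounds encoder power with missing data (we
measured the physicochemical encoder at CV AUC 0.88 under truncation vs
0.94 with full flanks at identical planted signal). The short-flank regime
of mapped peptides (upstream ~5.8 ± 4.7, downstream ~7.0 ± 4.5, clipped to
0…10) is available as `MotifSpec.short_flanks()` / `simulate
--short-flanks` and is what the padding-path and round-trip tests use.

What the generator does *not* emulate: proteome-wide residue correlations,
homology structure (generated windows are near-independent draws, so the
redundancy filter removes only chance near-duplicates), multiple sites per
protein, and realistic background composition. Passing tests on synthetic
data therefore demonstrate correct mechanics and recoverability of planted
signal, not real-data performance.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the full protocol at
moderate sizes chosen as the package's own defaults for quick, stable
estimates: 500 + 500 planted windows with 10-fold CV over 2–3
balanced-subsampling repeats, 200 + 200 for null calibration. The null
check expects AUC in [0.4, 0.6]; the planted-motif check expects AUC > 0.9
for the binary and physicochemical encoders. Every random draw
(generation, subsampling, fold shuffling) is seeded; identical seeds give
byte-identical generator output, identical subsample indices and identical
CV summaries.

## Known limitations

- The 14 shipped property scales are representative choices for the named
  properties, not a canonical set; results depend modestly on this choice.
- The PSAAP encoder uses raw positional frequencies; with few positives,
  unseen (residue, position) pairs get propensity 0 rather than a
  smoothed estimate.
- The redundancy filter's greedy order-dependence means a reordered input
  can retain a different (equally valid) representative set.
- Reproduction of the published benchmark numbers (CV AUC ≈ 0.72
  physicochemical, ≈ 0.62 propensity; independent-test AUC ≈ 0.73)
  requires the externally supplied curated peptide spreadsheet and exact
  agreement is limited by the unpublished random subsamples and split of
  the original study; `scripts/benchmark_reproduction.py` implements the
  full protocol for users who have the file.
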