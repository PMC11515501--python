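# Methods

## The problem

Cavity-detection tools such as Fpocket enumerate candidate binding
pockets on a protein surface and rank them by general ligandability, not
by allosteric potential. Allosteric sites — pockets topographically
distinct from the orthosteric site whose occupancy modulates activity at
a distance — are rare (a few percent of detected pockets) and poorly
captured by the 19 structural descriptors Fpocket reports per pocket.
`allopocket` reranks Fpocket's pockets by allosteric likelihood, using
the structural descriptors together with a large family of
amino-acid-based descriptors of the pocket's residue content, and a
multimodel ensemble feature-selection scheme designed for the very small
number of known allosteric protein-pocket pairs.

## Pipeline

1. **Structure preparation.** PDB structures are parsed (first MODEL
   only; for alternate locations the first-listed conformer, i.e. the
   lowest atom serial, is kept) and cleaned: waters, free ions, free
   atoms and bound ligands are removed so the cavity detector sees only
   polymer. Residue kinds (standard amino acid, nucleotide, water, ion,
   other hetero) are assigned purely from residue names against bundled
   tables; selenomethionine (MSE) is treated as methionine.
2. **Pocket assembly.** An Fpocket run directory is parsed into pockets:
   the per-pocket atom file gives the residue set (canonically ordered
   by chain, residue number, insertion code — a fixed order makes
   order-sensitive descriptors reproducible), and the descriptor report
   gives the 19 structural values. Pocket residues are then *completed*:
   each residue's atom list is replaced by the parent structure's full
   atom list, so sequence descriptors see whole residues while the 19
   Fpocket values are preserved verbatim from before completion.
   Pockets consisting solely of nucleotides are discarded (they cannot
   be protein allosteric sites); pocket ids are never renumbered.
3. **Labelling.** A pocket is positive iff it shares at least one
   residue (matched on chain id + residue number) with the annotated
   allosteric-site residues. Proteins without any positive pocket are
   excluded from training. Two chain-selection modes exist for
   evaluation: keep only the chains carrying annotated residues (the
   chain-resolved setting) or keep the whole complex (the realistic
   setting).
4. **Redundancy and quality filters.** A precomputed TM-score table may
   be supplied; proteins whose maximum TM-score against the reference
   set is strictly greater than 0.5 (the same-fold convention) are
   excluded. An optional resolution ceiling reads REMARK 2. Every
   exclusion is logged once with a machine-readable reason code.
5. **Featurization** (below), then per-protein undersampling: all
   positive pockets are kept and negatives are sampled without
   replacement down to 5 per positive (larger proteins would otherwise
   dominate the negative class).
6. **Multimodel selection, training, elimination, evaluation** (below).

## Descriptor families

Each pocket contributes one row: 19 Fpocket descriptors plus sequence
descriptors of its amino-acid string `R_1..R_N` (canonical order,
nucleotides skipped). With the default configuration the vector has
1151 named features, recorded in a manifest.

* **Amino-acid composition** — 20 fractions, summing to 1.
* **CTD** over seven three-class physicochemical groupings
  (hydrophobicity, normalized van der Waals volume, polarity,
  polarizability, charge, secondary structure, solvent accessibility;
  the standard three-class tables):
  - *Composition*: fraction of residues per class;
  - *Transition*: frequency of adjacent-position class changes per
    unordered class pair, normalized by N−1;
  - *Distribution*: relative position (percent of N) of the first,
    25th-, 50th-, 75th-percentile and last occurrence of each class,
    where the q-th percentile occurrence is occurrence number
    ⌈q·count⌉ (at least 1); absent classes give five zeros.
* **Sequence-order coupling numbers** τ_d = Σ_i d(R_i, R_{i+d})² for
  lags d = 1..30 under two amino-acid distance matrices: the Grantham
  matrix (generated from Grantham's published composition / polarity /
  volume scales and distance formula, rounded to integers; D(A,C)=195)
  and a Schneider–Wrede-style normalized physicochemical distance built
  from standardized hydrophobicity, hydrophilicity and side-chain-mass
  scales, scaled to [0,1]. The latter is computed, not transcribed from
  the 1994 publication, so its entries differ from other codebases;
  all uses here are self-consistent.
* **Quasi-sequence-order**: with f_r the residue counts, w = 0.1 and
  T = Σ_d τ_d,
  X_r = f_r / (N + wT) for the 20 residues and
  X_{20+d} = w·τ_d / (N + wT) for each lag; the 20+30 values sum to 1
  and reduce to the normalized composition at w = 0. Pocket sequences
  are short, so lags are clamped to N−1 and missing lags emitted as
  zeros, keeping vector width fixed.
* **k-gap dipeptide composition** for k ∈ {1, 2}: frequencies of ordered
  residue pairs at positions (i, i+k+1), normalized by the N−k−1
  windows; all zeros when no window exists.
* **Global properties** via Biopython ProtParam: average molecular
  weight (residue masses plus one water), aromaticity (fraction F/W/Y),
  isoelectric point (root of the Henderson–Hasselbalch net charge on
  pH ∈ [0,14], tolerance 1e−3 — a wider bracket than ProtParam's own
  bisection, which fails for extreme compositions), Guruprasad
  instability index, and net charge at pH 7.

Non-canonical letters raise an error by default (a config flag drops
them); silent imputation would distort compositions.

## Multimodel ensemble feature selection

Eight candidate feature sets are generated: for each of four
tree-ensemble classifiers (gradient boosting, random forest, extra
trees, AdaBoost),

* a **Boruta** set: in each of `n_iterations` (default 100) iterations a
  permuted shadow copy of every feature is appended, the classifier is
  fit, and a real feature scores a *hit* if its impurity importance
  exceeds the maximum shadow importance. Hit counts are tested against
  Binomial(n_iter, ½) with a two-sided Bonferroni-corrected level
  α/(2·n_features), α = 0.05. Significantly-high features are
  confirmed; undecided features count as rejected (conservative). If
  nothing is confirmed the set falls back to the classifier's top-20
  importance ranking, flagged in the set's provenance.
* a **model-based** set: features are ranked by impurity importance
  (ties broken by name for determinism), and ranking prefixes are scored
  by mean validation average precision over a small grouped split plan;
  the shortest prefix attaining the best mean is kept, with early stop
  after 3 consecutive non-improving prefixes.

One base model is trained per set. The default backend is a small bagged
committee of gradient-boosted tree classifiers (bootstrap resamples,
averaged probabilities, deterministic given the seed); any object with
the same `fit`/`predict_proba` surface can be plugged in.

**Backward elimination.** Starting from all base models with equal
coefficients, each round evaluates the ensemble's mean validation
average precision without each single member, over every split of a
grouped plan (default 51 random splits holding out 20% of proteins;
pockets of one protein never straddle a split). Members are refit on
each split's training side, so no member is ever scored on pockets it
trained on; because the ensemble score is the mean of member
probabilities, each member's per-split validation predictions are
computed once and reused across removal candidates. The removal with
the largest strict improvement (tolerance 1e−6; ties broken by removing
the member with the larger feature set, then by name) is applied;
elimination stops when no removal improves the mean or one member
remains, so the mean metric along the trace is non-decreasing by
construction. Surviving members predict with equal weights — the final
pocket score is the arithmetic mean of their probabilities — and
pockets are reranked per protein by that score, ties broken by the
cavity detector's own rank.

## Evaluation and statistics

* **Average precision**: step interpolation, AP = Σ_k (R_k − R_{k−1})·P_k
  over descending-score thresholds (undefined without positives).
* **ROC AUC**: probability a random positive outranks a random negative,
  ties counted ½.
* **Top-n classification**: each protein's n top-ranked pockets are
  declared predicted-positive, all pockets are pooled, and
  precision/recall/F1 computed; *proportion-top-n* is the fraction of
  proteins whose top n contains a true allosteric pocket.
* **Comparisons** between per-split metric distributions: two-sample
  pooled-variance Student t with a one-sided p (p = 0.5 by convention
  for identical degenerate samples), and Cohen's d with the pooled
  (n−1) standard deviation, labelled small/medium/large at |d| ≥
  0.5/0.8. A paired test would also be defensible since the
  distributions share a split plan; the unpaired pooled test is used
  and this choice is deliberately conservative.
* **Intervals**: mean via the t-interval; median via the box-plot notch
  convention, median ± 1.57·IQR/√n.
* **Feature analysis**: per-feature one-way ANOVA F between the label
  groups (equal to the squared pooled two-sample t for two groups;
  zero within-group variance with differing means yields +inf, flagged)
  and a Pearson correlation matrix (constant features' undefined
  entries emitted as 0 with a warning, diagonal kept at 1).

## Synthetic study conditions

The synthetic generator stands in for curated training data: 90
proteins, each with a uniform random 3–41 pockets and exactly one
allosteric pocket (real training proteins mostly carry a single
annotated site and a similar spread of cavity counts), five informative
features distributed N(effect·label, 1) with a standardized shift of
2.0 between classes, 45 N(0,1) noise features, optional label noise.
Everything is a pure function of the spec and seed.

What it deliberately does **not** emulate: real descriptor
distributions (heavy tails, inter-feature correlation, scale
differences), correlated pockets within a protein, annotation noise
structure, or any geometry. Passing tests on these conditions therefore
demonstrate that the selection and elimination machinery recovers a
planted signal under class imbalance and grouped splitting — not that
the method attains any particular accuracy on real structures.

## Numerical choices and problem sizes

* Strict-improvement tolerance in backward elimination: 1e−6 on the
  mean metric. Forward-stepwise patience: 3 prefixes.
* Splits with a single-class validation side are skipped with a warning
  and recorded; a degenerate single-class training side makes the
  backend predict the prevalence.
* Library defaults mirror the full-scale procedure (Boruta 100
  iterations, 51 validation splits, 20% held-out proteins, 1:5
  undersampling, classifier library defaults). The test suite and the
  acceptance script run the same procedures at desk scale — Boruta
  15–30 iterations, 3–10 splits, 25–30-tree classifiers, two-member
  boosted committees — chosen once as sizes at which the statistical
  decisions remain well-posed (e.g. 30 Boruta iterations still allow a
  Bonferroni-corrected confirmation at α = 0.05 with 50 features).
* All randomness flows from user-supplied integer seeds through
  `numpy.random.default_rng`; derived seeds stay below 2³¹.

## Known limitations

* The Fpocket descriptors are parsed, never recomputed; a run directory
  with a missing key fails loudly rather than imputing.
* TM-scores are consumed from a precomputed table; no structural
  alignment is performed.
* Ensemble coefficients are fixed at 1 (learning non-uniform weights is
  an explicit non-goal here).
* The Schneider–Wrede-style matrix is a computed stand-in with the same
  structure but not the same numbers as the historical table.
* mmCIF input, hydrogen addition and figure-quality plotting are out of
  scope.
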