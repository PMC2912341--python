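# Methods

This note documents the statistical model behind `tmaudit`, the defaults
and why they hold, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## 1. Consensus detection of SP/TM segments in alignments

### Model

Per-residue binary calls from D independent predictors are the only
input; native predictor scores are deliberately ignored, since the
predictors are heterogeneous closed tools and only their binary verdicts
are comparable.  For alignment column *j* and predictor *d*, the calls
over the `n_j` non-gap rows form a binomial sample `k_dj ~ Bin(n_j, p)`.
The test asks whether the column looks like an SP/TM residue more often
than chance:

- H0: p = 1/2, H1: p > 1/2; one-sided exact binomial tail
  `P(K >= k_dj)` compared with α.
- On rejection, the expected positive count is taken as the observed
  `Ê = k` (the natural estimator n·p̂) and the column probability is
  `p̂ = max(Ê/n, ε)`; without rejection `Ê = 0`, so `p̂ = ε`.
- Column score `L_j = Σ_d ln p̂_dj ∈ [D·ln ε, 0]` (natural log; the sum,
  not the mean, over predictors).
- A column is *positive* when at least one predictor rejects
  (equivalently `L_j > D·ln ε`); maximal runs of positive columns are
  candidate segments.

Columns with `n_j = 0` (all-gap) are never positive and carry the floor
score `D·ln ε`, which matters only when they fall inside an SP span
average.

### Segment assembly

- **TM fragment merging.**  Gaps can split one helix into several runs.
  Per predictor, a union indicator marks columns where *any* row carries
  a positive call; inside each maximal run of the OR over predictors, a
  composite indicator keeps the columns where *every* predictor
  contributing to that run agrees.  Raw segments overlapping the same
  composite run are fragments of one segment, and the columns between
  them are restored to the segment span.  The union preserves continuity
  within a helix; the intersection keeps adjacent helices apart (a
  predictor that calls two separate helices vetoes the bridge).
- **Scoring.**  A single fragment scores the arithmetic mean of its
  `L_j`; a multi-fragment segment the weighted mean with weights
  `N_f`, the predicted-column count per fragment.
- **SP span rule.**  Signal-peptide fragments are assumed to come from
  one N-terminal peptide: the segment spans column 1 through the end of
  the most C-terminal fragment and scores the plain mean of `L_j` over
  that whole span (unpredicted columns sit at the ε floor, penalising
  scattered SP fragments).
- **Cutoffs.**  Segments are retained when `ψ >= −12` (TM) or
  `ψ >= −1` (SP); ties retained (the calibration that produced these
  values quotes them as `>=` thresholds with 4.67% / 4.02% FP rates).
- **TM regions.**  Retained helices separated by fewer than 40 columns
  are concatenated: the smallest globular domains are ~40+ residues, so
  shorter spacers are linkers, not domains.  The count is in alignment
  columns, which for seed alignments differs from residues only by
  gaps; columns keep the rule deterministic per domain.

### Parameters

| parameter | default | units | rationale |
|-----------|---------|-------|-----------|
| α | 0.05 | — | conventional level; makes depth 5 the smallest testable alignment (min tail (1/2)^4 = 0.0625 > α) |
| ε | 1e-4 | probability | keeps `D·ln ε` finite and far below both cutoffs (−46 at D=5); results are insensitive to ε within a decade |
| TM cutoff | −12 | nat-log prob. | calibrated: FP 4.67% on labelled structural helices |
| SP cutoff | −1 | nat-log prob. | calibrated: FP 4.02% on labelled non-SP sequences |
| linker_max | 40 | columns | smallest-globular-domain argument above |
| D_TM, D_SP | 5, 2 | predictors | the reference predictor battery sizes |

The log base is natural throughout; the cutoffs are treated as
natural-log quantities.  Summing (not averaging) over predictors means a
different D rescales scores by roughly D/D_ref; recalibrate cutoffs if
the roster changes.

### Single sequences

When only one sequence is available (e.g. benchmarking against labelled
sequence sets) there is nothing to test: `p̂_dj` is the raw call floored
at ε and everything downstream (delineation, merging, span rule, ψ,
cutoffs) is unchanged.  `calibration.single_sequence_scores` implements
this path and `calibration.rate_table`/`select_cutoff` reproduce the
cutoff-determination workflow: at candidate cutoff c a negative scoring
`ψ >= c` is a false positive (matching the retention `>=`), a positive
scoring below is a false negative, rates are percentages to two
decimals, and the selected cutoff is the most permissive one with FP
rate below the target (5%).

## 2. Profile HMM and score partition

### The model

A plan7-like profile: M nodes with match/insert emission log-odds (bits)
over the 20 amino acids plus a neutral X scoring 0, per-node transitions
(m→m, m→i, m→d, i→m, i→i, d→m, d→d), entry (B→M1, B→D1) and exit
(M_M→E, D_M→E) scores, a gathering threshold GA, and Gumbel EVD
parameters (μ, λ) taken as inputs.  There is no multi-hit (J) state and
no null2 correction.  Viterbi is hmmls-style: every path traverses nodes
1..M (global in the model) but may start and end anywhere in the query
(local in the sequence; flanking residues are null-emitted at zero
cost).  Ties in the DP prefer match over delete over insert and earlier
sequence positions, purely for determinism.

Two formats are read: a native JSON profile (canonical, exact
round-trip, `*` encodes forbidden transitions) and a best-effort subset
of the HMMER2 ASCII save format (NAME/LENG/ALPH/GA/EVD headers plus the
three per-node integer score lines; integers are bits × 1000).

### Score decomposition

Because the Viterbi score is a linear combination of path terms, each
term is attributed to a model node: emissions to the emitting node,
transitions to the node they depart from, begin/entry and end/exit to a
position-independent constant.  With a set of flagged SP/TM nodes this
yields `S = S_NG + S_TM + S_const` *exactly* (the departure-node rule
makes the split additive and local to the mask; the attribution of
boundary transitions is the one genuinely free choice here, and moving
a boundary transition across the flag line shifts at most one term).

### Gathering-threshold partition and triage

Assuming the seed sequences' proportion between globular and SP/TM score
parts also holds for true hits scoring near GA, each seed yields
`c_i = (GA − S_const_i)/(S_NG_i + S_TM_i)` (seeds with vanishing
denominator are excluded with a warning), and

    G_TM = mean_i(c_i · S_TM_i),   G_NG = GA − G_TM .

`c` is treated as a random variable over seeds, so the expectation is
the sample mean; the standard error of the `c_i·S_TM_i` sample is
reported as a diagnostic.  An empty flag set gives `G_NG = GA` exactly.
Hits are classified by the (S ≥ GA) × (S_NG ≥ G_NG) quadrant:
true positive / unjustified / false negative / no call, with inclusive
inequalities on both axes.

### Rescoring without the region

The cleanup counterpart on the model side: flagged nodes are excised and
consecutive survivors re-joined using the upstream node's original
outgoing transitions (the minimal-perturbation splice; insert states of
removed nodes are dropped).  E-values for rescored hits use the original
model's EVD parameters, mirroring a re-computation "without the SP/TM
segments" under unchanged statistics.

## 3. Synthetic data

The generators emulate the *statistical* features the method depends on
and nothing else:

- `make_alignment` — planted TM/SP spans drawn from an I/L/V/F/A/M-
  enriched categorical composition (~89% hydrophobic inside vs ~37%
  background), gaps i.i.d. outside planted spans.  No phylogeny, no
  indel process, no per-family conservation structure.
- `make_masks` — per predictor and residue, independent Bernoulli calls
  with the spec's sensitivity inside planted spans and false-positive
  rate outside.  Real predictors err in runs, not i.i.d.; i.i.d. noise
  is *harder* on the binomial test at segment boundaries and easier in
  the nulls, so null-false-flag results here are optimistic relative to
  a predictor with systematically correlated errors.  SP false positives
  are not forced to be N-terminal.
- `make_profile` — a model with an information-rich globular block (one
  favoured motif residue per node, 3.2 bits) followed by a flagged
  hydrophobic block (2.2 bits for any of I/L/V/F/A/M).  Members match
  both blocks with fidelity 0.85; decoys carry only a hydrophobic run
  (80% hydrophobic draws) over random background, reproducing the
  failure mode where the Viterbi path deletes the entire globular block
  cheaply and the hydrophobic match carries the score over GA = 25 bits.

Everything is a pure function of (spec, seed).  Passing tests on these
fixtures demonstrates the statistics and the score algebra, not the
field performance of any real predictor battery or domain library.

### Study conditions used in the tests

Planted-recovery and null-rate checks run at 25 rows, 5 TM + 2 SP
predictors, sensitivity 0.9, per-residue FP rate 0.05, gap rate 0.05.
The row count matters: at depth 25 rejection needs k ≥ 18 calls, so a
true column (k ≈ 22.5 expected) rejects with probability ≈ 0.998 per
predictor and per-column scores sit near `D·ln 0.9`, comfortably above
both cutoffs, while a noise column (k ≈ 1.25 expected) essentially never
rejects.  At the 10-row minimum the same test needs 9/10 calls, and with
sensitivity 0.9 enough predictors fail per column that the SP span
average can drift below the strict −1 cutoff — a real small-alignment
limitation of the method, not an implementation artefact.  Accuracy
sweeps use models of M ≤ 8 and short sequences; the Viterbi oracle
comparison enumerates all paths, which is only feasible at M ≤ 4,
sequence ≤ 8.

## 4. Numerical choices and degenerate inputs

- Exact binomial tails via `scipy.stats.binom.sf`; verified against
  rational summation for n ≤ 20.
- Score additivity is exact by construction; tests bound the residual at
  1e-9 (observed ~1e-15, pure float re-association).
- `-inf` transition scores are legal everywhere; the DP guards against
  all-forbidden models by raising when no valid path exists.
- Empty columns, empty masks, empty flag sets, all-flagged models,
  all-gap rows after cleanup, and zero-denominator seeds all have
  defined behaviour (documented per function) rather than silent
  defaults.
- Cutoff ties retain; FP counting at calibration uses the same `>=`.

## 5. Known limitations

- The two-round signal-peptide confirmation against full-length
  sequences (retrieving full sequences for alignment fragments) is out
  of scope; callers must supply masks computed on whatever sequence
  form they trust.  `MaskSet.validate_sp_nterminal` is provided but off
  by default because domain fragments legitimately start inside an SP.
- Running the third-party predictors themselves, database-scale scans,
  and rebuilding/calibrating HMMs from cleanup alignments are outside
  the package; the run-list mask TSV and the cleanup alignment are the
  interchange points.
- The HMMER2 reader is a tolerant subset, not a validator, and the
  native JSON profile is the canonical format.
- G_NG rests on the proportionality assumption above; for models whose
  seeds have wildly heterogeneous SP/TM content the per-seed `c_i`
  spread (reported in the seed table) should be inspected before
  trusting the triage.
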