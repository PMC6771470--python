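# Methods

## The assembly problem

A SWATH/DIA assay library is built by merging many DDA search-result
exports: per-batch libraries are combined into tissue-specific libraries,
and tissue libraries are combined, one by one, into a multi-tissue
consensus. Two things make this more than a concatenation. First, each
export carries its own error structure (search-engine confidence scale,
decoys, modified and non-proteotypic peptides), so each file must be
filtered to a common standard *before* merging. Second, each export lives
in its own chromatographic time coordinate; add-on retention times must be
mapped into the base library's coordinate, and portions of an add-on whose
RT relationship to the base cannot be established should be excluded rather
than force-fitted, since a wrong RT coordinate silently corrupts downstream
DIA scoring.

`swathlib` implements this assembly as a deterministic pipeline:
clean → pair shared peptides → fit RT map → gate → transform → union.

## Data model

One *entry* is a peptide precursor keyed by
`(stripped_sequence, modified_sequence, precursor_charge)`, carrying its
fragment-ion list (m/z, relative intensity, b/y series annotation), RT in
minutes, protein accession (treated as an opaque string), identification
confidence in [0, 1], decoy and shared-peptide flags, and a set of
provenance labels. The protein is deliberately not part of the key: a
peptide matching several proteins is one entry with `shared=True`, which is
what the proteotypic filter removes. For counting, a *peptide* is a
distinct `(stripped, modified)` pair — charge states collapse — because
published library sizes describe peptides, not precursors
(`count_precursors=True` gives the precursor-level alternative).

## Cleaning

Filters, in fixed order for report attribution (survival itself is
order-independent): decoys → modified → confidence → fragment count →
shared. Defaults: FDR threshold 0.01, at least 5 fragment ions,
unmodified and proteotypic required.

* **FDR cutoff.** The confidence cutoff is derived per file as the smallest
  observed confidence `c` with `#decoys(≥c) / #targets(≥c) ≤ 0.01` — the
  plain target–decoy ratio without π₀ correction, since the upstream search
  engine's calibration is unknown and the criterion is a simple 1% gate. If
  no observed value satisfies the bound, the cutoff is placed just above
  the maximum observed confidence (the filter then removes everything, a
  signal that the file is unusable at that FDR). Explicit per-file cutoffs
  can be supplied to reproduce upstream decisions.
* **Unmodified.** An entry is unmodified when its modified sequence, after
  removing fixed-modification tags and terminal markers, equals the
  stripped sequence. Carbamidomethyl-C (`[CAM]`) is fixed by default:
  cysteine alkylation is part of standard sample preparation, and counting
  it as a modification would remove essentially every cysteine peptide.
  The tag set is configurable (`CleanConfig.fixed_modification_tags`).
* The ≥ 5 fragment rule is applied to the fragment rows as exported, with
  no prior fragment-quality pruning.

## Piecewise-linear RT alignment

RT pairs are taken from entry keys present in both libraries (at least 20
by default). The map from add-on to base RT is ordinary least squares; its
quality gate is R² > 0.90, strictly. When the full-range fit fails the
gate, the add-on RT axis is segmented by recursive binary splitting:

1. Fit OLS on the current segment; if its R² ≥ 0.90, retain it.
2. Otherwise, if the segment holds ≥ 2 × `min_segment_pairs` points and the
   segment budget (`max_segments`, default 6) allows, split at the
   breakpoint minimising the summed residual sum of squares of the two
   sub-fits (prefix-sum scan, O(n) per candidate set; RSS ties break to the
   earliest breakpoint for determinism) and recurse.
3. Terminal segments still failing the gate become *discarded ranges* —
   non-alignable portions of the add-on whose entries are removed rather
   than transformed. If everything is discarded the library is not
   alignable and the merge step records a rejection.

Segment intervals are half-open `[lo, hi)` on the add-on axis with
boundaries at midpoints between neighbouring points; the last retained
interval is closed at the top; retained and discarded ranges partition the
shared-peptide RT span exactly. The global R² reported for the gate is
computed on the retained pairs after per-segment transformation. Entries
beyond the shared-peptide span are dropped by default; `extrapolate=
"nearest"` extends the nearest retained segment instead (opt-in, because
extrapolated coordinates are unverified).

This automates what is otherwise a manual division of the gradient by
visual inspection; the exhaustive-search oracle in the tests pins the
breakpoint choice, and the gate thresholds are ordinary config.

Numerical notes: segments with zero response variance count as R² = 1
(nothing left to explain); a segment with zero regressor variance cannot be
fitted and is discarded; `fit_linear` sorts pairs by add-on RT before the
regression so that the single-segment piecewise fit and the plain fit are
bit-identical.

## Merging

Sequential, order-as-given. The first cleaned library seeds the base and
defines the consensus RT coordinate; a retained base entry's RT is never
modified by later merges. Duplicate keys resolve by `keep_base` (default —
first-seen wins, matching the base/add-on asymmetry of sequential
workflows) or `best_confidence`; either way the survivor's source-label set
becomes the union, which is what the tissue-sharing statistics read. A
gate failure is a recorded rejection, not an exception, so one bad add-on
does not abort a long build. Consequences worth knowing: the final entry
*key set* is order-invariant when all gates pass and nothing is dropped by
alignment, but entry *content* (which duplicate's RT/fragments survive) can
depend on order under `keep_base`.

## Statistics

Composition histograms satisfy the conservation identities
Σ counts(peptides-per-protein) = #proteins and Σ k·count(k) = #peptides,
which the tests assert on arbitrary fixtures. Inter-library overlap is
reported relative to the *second* library (the external or tissue-specific
one), stated explicitly in the output since the convention matters.
Quantification consistency is the squared Pearson correlation of log10
intensities over peptides shared by two tables, excluding non-positive
intensities; the log scale makes the metric invariant to global scaling,
the standard treatment for intensity data.

## The simulator

`simulate_library` emulates the structure such a library actually has, with
a per-entry ground-truth record so that every downstream claim is checkable
by recounting:

* **Proteins/peptides.** Peptides per protein follow a truncated geometric
  with P(X = 1) = 0.23 (so ~77% of generated proteins are multi-peptide, a
  realistic long-tailed shape for a deep library); sequences are random
  tryptic-looking strings (7–25 residues, ending K/R).
* **Fragments.** 3 + Poisson(4) fragment ions per precursor (mean ≈ 7),
  b/y with valid ordinals; intensities Dirichlet-drawn and scaled so the
  top fragment is 10 000 — only relative values matter downstream.
* **Masses.** Q1/Q3 are monoisotopic values computed from residue masses
  (pyteomics constants), including modification deltas, so simulated files
  re-verify by independent mass summation to < 0.001 Th.
* **Tissues.** Each peptide belongs to 1, 2 or 3+ tissues with
  probabilities 0.55/0.25/0.20 over three labels; `tissue_view` extracts
  the sub-library one tissue would contribute.
* **Decoys** are pseudo-reversed sequences (terminal residue fixed), drawn
  per entry with probability 0.30; target and decoy confidences come from
  Beta(5, 1) and Beta(1.2, 4), giving realistic score overlap for cutoff
  derivation. 15% of entries carry a variable `[Oxi]` modification (mass
  shift applied); cysteines always carry fixed `[CAM]`, exercising the
  fixed-modification rule.
* **RT** is uniform over a 2–62 min gradient.

`distort_library` warps RTs through a piecewise-linear map plus Gaussian
noise and returns the exact inverse map as the recovery oracle. The
canonical nonlinear scenario (`nonlinear_distortion_spec`) uses slopes
1.0/1.4/0.8 with the three pieces' add-on windows offset so the overall
correlation is far from linear (single-fit R² ≈ 0.3) — the situation that
forces segmentation — plus a contiguous uniform-noise block holding the
top 10% of the gradient, emulating a locally failed gradient segment. Of
note, a *mild* smooth distortion keeps the full-range R² above 0.90 and is
deliberately left unsegmented: the gate, not curvature per se, decides
whether division is needed.

What the simulator does **not** emulate: real fragmentation chemistry
(intensity patterns are random, not predicted), score distributions of any
particular search engine, correlated RT drift within a run, missing
fragment annotations, or protein inference ambiguity beyond a binary
shared flag. Passing tests therefore demonstrate the correctness of the
bookkeeping, the estimator and the gating logic — not that any particular
instrument's data will align with any particular R².

## Problem sizes and verification

The test suite and the acceptance script run on generated data: cleaning
is verified exactly against the truth record on a ~10,000-entry library;
the FDR cutoff against an exhaustive scan on 100 random target/decoy
mixtures; piecewise recovery on 50 seeded distortions (~900 shared pairs
each, success = every segment's slope and intercept within 3 standard
errors of truth and ≥ 80% of the noisy block discarded); consensus
building against direct ground-truth set union on 3-tissue plans of a few
hundred proteins. These sizes make the whole suite run in well under a
minute while keeping binomial/OLS uncertainties far smaller than the
effects being checked.

## Known limitations

* Extra (non-canonical) columns of a PeakView export are preserved at
  entry level (taken from the entry's first fragment row); row-level
  variation within an entry is not kept.
* The OpenSWATH dialect has no columns for decoy/shared/confidence; these
  are lost on conversion, and `Tr_recalibrated` values are passed through
  unchanged (no iRT calibration).
* The PeakView `score` column is written as a mirror of `confidence`; the
  canonical model keeps a single [0, 1] confidence.
* No spline/LOESS RT models: the method linearizes by design, and the
  discard-don't-extrapolate policy is the conservative complement.
* FDR estimation is the simple decoy/target ratio; no π₀ correction, no
  protein-level FDR, no rescoring.
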