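# Methods

This note documents the models, conventions and design decisions behind
`tapemeasure`, in the order the pipeline runs them. Coordinates are
1-based and inclusive at every interface; any 0-based indexing is private
to an implementation.

## Reference architecture

The reference layout models a 937-residue TP901-1-like tape measure
protein:

| element | span | size |
|---|---|---|
| N-terminal essential region | 1–154 | 154 aa |
| hydrophobic region 1 (Tm1–3) | 390–460 | 71 aa |
| cytoplasmic loop | 461–590 | 130 aa |
| hydrophobic region 2 (Tm4–6) | 591–679 | 89 aa |
| repeat region (29 repeats) | 461–807 | 347 aa |
| C-terminal essential region | 878–937 | 60 aa |

Two boundary conventions deserve comment. First, the loop between the
two hydrophobic regions is 130 residues by inclusive counting (461–590),
although it is sometimes quoted as 129; the generator exposes the loop
span explicitly rather than deriving it. Second, the repeat region
overlaps hydrophobic region 2 by construction: the repeats run without
interruption from the residue after hydrophobic region 1 to position 807
(the C-terminal deletion series starts at residue 810), straight through
the second hydrophobic stretch. Repeat coordinates are never measured
directly, so the region start (461) is an inference from the membrane
spans "directly preceding" the repeats, and is exposed as a parameter.

Membrane sub-span boundaries inside region 1 follow from the deletion
arithmetic (Tm3 = 442–460 from its 19-aa deletion, Tm2–3 = 43 aa, so
Tm2 = 418–441, Tm1–3 = 71 aa, so Tm1 = 390–417). In region 2 only
Tm4 = 591–613 (23 aa) is constrained; the even 614–646 / 647–679 split of
Tm5/Tm6 is a documented convention.

## Per-repeat length inference

Each repeat is 11 or 18 residues. The deletion tables give linear
equations over the repeat lengths: a row deleting repeats *a..b* plus *k*
extra residues (or half of the next repeat, `floor(len/2)`) removed an
observed total. `solve_repeat_lengths` enumerates all satisfying
assignments by branch-and-bound (left-to-right assignment; every
constraint is checked the moment its last variable is bound, and partial
sums are bounded by the extreme admissible lengths). The empty constraint
list returns a symbolic `UNCONSTRAINED` sentinel instead of enumerating
2^29 tuples; an inconsistent system returns the empty tuple.

For the packaged tables, 27 single-range rows constrain the system
(multi-range rows such as "repeats 1–9 plus 20–26" are used as
downstream accounting checks, not solver inputs). The solution set has
six members; all have 25 elevens and 4 eighteens (total 347), which is
also forced algebraically: 11·n₁₁ + 18·n₁₈ = 347 with n₁₁ + n₁₈ = 29 has
the unique solution n₁₈ = 4. The residual ambiguity is the position of
one 18-mer within repeats {1,2} and one within {24,25,26}. The reference
assignment is selected by placing 18-mers as early as the constraints
allow (lexicographically smallest list of 18-mer indices), giving 18-mers
at repeats 1, 5, 8 and 24; all six solutions stay available through the
solver. Repeat 19's length is individually unconstrained without the
full-region row; with it, it resolves to 11.

## Synthetic-sequence generator

The generator is the package's study-condition definition, not a
convenience fixture: it emulates a 937-residue TMP with the full
reference architecture planted, under a single integer seed
(`numpy.random.default_rng`; no global state). Its defaults are the
reference conditions used by every recovery test:

* **Background** (inter-domain segments, repeat interiors): drawn from a
  hydrophilic-biased composition that excludes the anchor residues (W, F)
  and the strongly hydrophobic residues reserved for membrane spans
  (I, L, V, M, C). This emulates the polar character of the inter-domain
  regions and guarantees that at zero noise every anchor is a planted
  anchor and no background window crosses the hydropathy threshold.
* **Anchors**: each repeat opens with Trp (18-mers) or Phe (11-mers).
* **Membrane spans**: filled with isoleucine. A single-residue fill keeps
  the planted hydropathy signal deterministic at the region boundaries.
* **Junction linkers**: a windowed scanner cannot separate two membrane
  spans that abut as identical hydrophobic blocks, so each hydrophobic
  region is planted as hydrophobic segments separated by 7-residue
  arginine linkers (real membrane helices are likewise separated by short
  polar connectors). Linker positions are chosen so that the default
  caller sees one span per planted sub-segment, each ≥ 15 residues.
* **Interface shoulders**: ten deterministic tyrosines immediately before
  each region (the "aromatic belt" residue of membrane interfaces) and
  ten prolines immediately after. Their Kyte–Doolittle scores (−1.3 and
  −1.6) are tuned so that the default caller's thresholded runs begin and
  end exactly at the architectural region bounds — the windowed mean at
  the first region residue just clears 1.6 and at the residue before it
  just misses.
* **Aromatic noise**: with probability `aromatic_noise_rate` per
  background position, a W or F is emitted (default 0; recovery under
  noise is reported at 0.05 across 20 seeds in the test suite).

What the generator does **not** emulate: real amino-acid composition of
any particular protein, repeat-internal sequence similarity, indel drift
between repeat copies, genuinely amphipathic membrane helices, or any
DNA-level feature beyond the fixed-codon back-translation used for oligo
design. Passing recovery tests therefore demonstrate the callers'
correctness on cleanly planted structure, not their performance on
arbitrary natural TMPs — on real sequences the repeat caller handles
exact spacings only (a `tolerance` parameter admits small deviations),
and the hydropathy scanner is a transparent stand-in for HMM-based
topology predictors, with no claim of reproducing their output.

## Repeat caller

Anchors are all W/F positions (configurable). The caller maximises the
number of anchors chainable with consecutive spacings in {11, 18} (±
`tolerance`, default 0), then the spanned length, and returns the
leftmost chain among remaining ties — an exact dynamic program over the
DAG of admissible anchor pairs, verified in the tests against an
independent longest-path oracle. Interior noise anchors are simply
skipped, without penalty.

Chain anchors become element starts; element *i* ends one residue before
anchor *i*+1. The terminal anchor has no successor, so its element is
closed by anchor identity (W → 18, F → 11, clipped at the sequence end);
setting `require_closing_anchor` drops the terminal element instead.
Chains shorter than `min_repeats` (default 3) are suppressed.

## Hydropathy scanner

Kyte–Doolittle per-residue scores (as shipped with Biopython), smoothed
by a centred moving average (window 19). Terminal windows are truncated
rather than discarded, keeping the profile the length of the sequence and
making it exactly reversal-symmetric. Spans are maximal runs with
smoothed score ≥ 1.6; runs shorter than 15 residues are discarded; spans
separated by ≤ 30 residues are grouped into one hydrophobic region
(wide enough to bridge the planted inter-helix linkers, far narrower than
the 130-residue loop separating the two reference regions). Raising the
threshold can only shrink coverage (tested as a property).

## Mutant conventions

* Residue ranges are inclusive of both named endpoints (validated by the
  30/13/33/80-residue control rows of the tables).
* The fractional notations are disambiguated in the grammar: `+k` deletes
  the first *k* residues of the next repeat (0 ≤ k ≤ its length, so the
  11-residue step series can end on a whole repeat), `+half` deletes
  `floor(len/2)` of it (9 for an 18-mer, matching the 100-residue
  half-repeat row).
* Two table rows print a deletion size one residue short of the inclusive
  count (their first named residue, F31, is evidently retained at the
  junction). The fixture stores the printed values with a per-row
  convention flag; accounting reports the discrepancy and never silently
  corrects it.
* Membrane-span deletions resolve to the **union** of the named sub-span
  intervals: deleting Tm1–6 removes 71 + 89 = 160 residues (two disjoint
  intervals), not the 290-residue bounding stretch.
* Applying a mutant splices the edit intervals out of the sequence
  (replacements splice residues in), rejects any edit touching the
  initiator Met, and lifts the annotation: features losing all residues
  are flagged destroyed, partially hit features are truncated to their
  surviving residues. Sequence length plus net residues deleted always
  equals the reference length (tested as a property).
* Oligo design back-translates the protein with one fixed codon per
  residue, maps the single contiguous edit to CDS coordinates, and
  concatenates the 45-nt (configurable 40–45) homology arms immediately
  flanking the deletion, with any replacement back-translated in
  between. Arms truncated by a CDS end are flagged with a warning. The
  oligo is written on the coding strand by fixed convention.

## Tail-length calibration

Unweighted ordinary least squares of tail length (nm) on TMP residue
count (937 minus residues deleted, insertions added back), in closed form
via the centred normal equations; the fit is checked against an
independent implementation at 10⁻¹⁰ relative tolerance. Weighted or
robust alternatives were considered and rejected as defaults: the source
measurements are means of 10–18 virions with no per-point uncertainty
published. The fit requires ≥ 3 points and positive x-variance, and
refuses a non-positive slope (a calibration in which tails do not
lengthen with TMP size is meaningless).

On the eight packaged points the fit gives slope 0.1440 nm/aa
(R² = 0.994, max |residual| 2.6 nm) and an x-intercept of 136 aa. The
published extrapolation quotes 127 aa; that line was read off a plotted
figure and is not exactly recoverable from the tabulated points, so the
package reports its own fit and the published value side by side rather
than forcing agreement.

Derived constants use the published intercept: 937 − 127 = 810
tail-contributing residues; 118 nm / 810 aa = 0.1457 nm per residue,
quoted as 0.145 (reported values are truncated toward zero at the third
decimal, matching the convention of quoting only supported digits; the
exact quotient is available separately). 810 residues × 1.47 Å (extended
α-helix rise) = 1190 Å to three significant figures.

Parameter recovery: simulating the real design (eight mutant sizes,
Gaussian measurement noise of σ = 1.5 nm) over 100 seeds recovers the
true slope with a mean error well under 5%.

## Problem sizes and numerical notes

The validation suite runs at the scale of the system itself: one
937-residue protein per seed, 29 repeats, 58 table rows, 8 calibration
points; oracle comparisons use 200 random anchor instances (≤ 25 anchors)
and 100 simulation seeds. The whole suite completes in a few seconds.
Floating-point margins at the planted hydropathy boundaries are ≥ 0.026
score units, far above double-precision rounding. Solver enumeration
order is lexicographic over length tuples; all tie-breaks (reference
assignment selection, leftmost chain, nearest-period labels with the
smaller period on ties) are deterministic and documented above.

## Known limitations

* The hydropathy caller recovers planted architecture; it is not a
  topology predictor and reports no membrane orientation.
* The repeat caller assumes exact (or near-exact) periodicity and a
  single anchor class per element; diverged repeats without aromatic
  anchors are invisible to it.
* Phenotypes (plaquing efficiency, lysogeny, particle morphology) are
  consumed as data and audited descriptively; the package makes no
  phenotype predictions — the single-residue deletion series shows no
  simple sequence-to-phenotype rule to model.
* The packaged tables transcribe the printed source data, including its
  censored (≤) bounds and the two convention-flagged rows.
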