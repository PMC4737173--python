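# Methods

## The stop-process model and the reactivity estimator

A targeted probing experiment interrogates a panel of known RNAs. Each RNA
has a probed region of n nucleotides (1-based, position 1 = transcription
start) lying strictly 5′ of the reverse-transcription (RT) primer site. RT
initiates at the primer and walks 3′→5′; at modification site k it
terminates with probability

* `gamma_k` — natural drop-off, active in both channels;
* `theta_true_k` — reagent-induced termination (the polymerase halts one
  nucleotide before a 2′-O-adduct), active only in the (+) channel, applied
  after surviving drop-off at that site.

A walk that survives all n sites yields a full-length cDNA. The observed
data per channel are therefore multinomial over n + 1 outcomes with

```
P(stop at k) = s_k * prod_{j>k} (1 − s_j),     P(full) = prod_j (1 − s_j)
```

where `s_k = gamma_k` in the (−) channel and
`s_k = gamma_k + (1 − gamma_k)·theta_true_k` in the (+) channel.

Because the likelihood factorises over sites given the arrival counts, the
MLE of each per-encounter stop probability is the arrival-frequency ratio
`X_k / (sum_{i<=k} X_i + X_full)`. The subtraction in log-survival space,
`raw_k = ln(1 − gamma_k) − ln(1 − beta_k) = −ln(1 − m_k)`, removes drop-off
exactly and, in the single-hit (Poisson) regime, is proportional to the
modification rate. The test suite enforces this optimality claim directly: a
dense grid search over the explicit stop-process likelihood (an independent
oracle sharing no code with the estimator) must land on the same theta to
within 1e−3 on hundreds of random small count tables, so any silent change
to the estimator surfaces as a failure rather than drift.

Numerical conventions:

* negative `raw_k` values (control stops exceeding treated stops, a common
  finite-depth fluctuation) are truncated to 0 *before* simplex
  normalisation;
* a site where every surviving transcript stops (frequency exactly 1) is
  clamped to 1 − 1e−6 with a warning, so the log stays finite; the grid
  oracle maximises over the same bounded domain [0, 1 − 1e−6];
* sites never reached by RT (zero arrivals) are flagged unobserved and
  written with the −999 sentinel in all text outputs;
* an all-zero signal produces a *degenerate* flagged profile (all zeros)
  rather than an error — orthogonal-pair controls legitimately produce
  near-null signal.

## Normalisation and classes

`theta` is normalised to the probability simplex and `rho = n·theta`, so a
non-degenerate profile has mean reactivity exactly 1 over probed positions.
This mean-1 convention is what centres the conventional class thresholds:
rho > 1.25 high, 0.5 ≤ rho ≤ 1.25 moderate, rho < 0.5 weak. The boundary
values 0.5 and 1.25 are assigned to "moderate"; both thresholds are
arguments of `classify_reactivity` for users who need different cut-offs.
Replicate profiles are combined positionwise with the arithmetic mean and
the sample (n−1) standard deviation, and conditions are compared per
position with a one-sided Welch t-test (Satterthwaite degrees of freedom;
scipy implementation, validated in tests against the textbook formulas and
calibrated under the null to a 10% ± 1% rejection rate at p < 0.10 with
three replicates per group).

## Read geometry and processing

The read-level conventions (shared by the simulator and the pipeline):

* **read 1** = channel handle + target-derived sequence in sense
  orientation starting at the 5′-most position the cDNA covers + adapter
  read-through when the fragment is shorter than the read (2×35 bp reads by
  default); read 2 carries the opposite end and is not needed for stop
  inference, so single-end input is accepted.
* **stop coordinate**: with p the 1-based position of the first covered
  base, the modification site is p − 1; p = 1 is a full-length extension.
* **handles**: the (+)/(−) barcodes are run configuration, defaulting to
  the degenerate patterns plus = RRRY, minus = YYYR (disjoint at the first
  base, so demultiplexing is unambiguous); a read matching both patterns is
  counted as ambiguous, not force-assigned.
* **alignment**: targets are few and short, so placement is a direct
  substring/Hamming scan over the panel (exact-match fast path). Reads must
  place uniquely; multi-mapping reads are discarded rather than fractionally
  assigned, because orthogonally designed targets should never share
  35-mers and ambiguity signals a configuration error. Adapter trimming
  cannot remove read-through remnants shorter than its minimum overlap
  (5 nt), so up to 4 trailing bases may be clipped during placement; the 3′
  end never informs the stop coordinate. The aligner is checked against a
  brute-force all-offsets Hamming oracle.
* **ligation dimers**: an RT primer ligated directly to the sequencing
  adapter carries no target insert and — since the handle enters a read only
  through cDNA that copied the RNA — no handle; a read is classified as a
  dimer when it is a primer-site sequence immediately followed by adapter
  (≤ 1 mismatch per segment). Dimers are excluded before alignment and
  reported as a QC fraction; a fragment that genuinely stops at site n and
  therefore contains only primer-derived sequence remains distinguishable by
  its leading handle.

The round trip simulate → trim → demux → align → tabulate is required to be
*exact* (zero lost or misassigned reads) at zero noise, and remains exact in
tests at a 40% dimer rate.

## Folding

The pseudo-free-energy term `dG_i = m·ln(rho_i + 1) + b` (defaults m = 1.1,
b = −0.3 kcal/mol) is applied through the ViennaRNA (2.7.x, Turner 2004
parameters) SHAPE-restraint mechanism, which adds the term per stacked base
pair; missing positions are passed as −999 and contribute nothing. The
engine name/version is recorded on every `StructureModel`. Predicted
energies are cross-checked in tests by independent re-evaluation of the
returned structure. Published values computed with other nearest-neighbour
engines or parameter vintages can differ by a few tenths of a kcal/mol;
comparisons across engines should allow ±0.5 kcal/mol. Subsequence energies
(`subsequence_mfe_energy`) fold the extracted interval in isolation and are
invariant to flanking sequence by construction. Pseudoknots are out of
scope, as in any nearest-neighbour MFE treatment.

## Structure–function statistics

Expression is read out as `(FL − FL_blank)/(OD − OD_blank)` minus the
FL/OD of a reporter-free autofluorescence control; fold changes are ratios
of replicate *means* (not means of ratios), with percent repression
`100·(1 − mean_A/mean_B)`. The Shine-Dalgarno scan sums reactivities over a
six-nucleotide sliding window in the ON and OFF states and reports the
window with the largest ON−OFF difference (ties to the smallest start
index), using the sense RNA's transcription start as position 1. Missing
reactivities contribute 0 to window sums by default; a stricter
`missing_policy="skip"` drops any window containing a missing value. The
window is an explicit parameter of `window_fold_change`, since the most
informative hexamer and the sub-window with the strongest per-nucleotide
changes need not coincide.

## Cleavage spike QC

Reagent-induced stops appear in the (+) channel only; an RNase cleavage of
the RNA itself truncates both channels coincidently. `detect_spikes` flags
positions whose robust z-score ((count − median)/1.4826·MAD, the MAD
resisting the heavy right tail genuine reactivity creates) is ≥ 5 *and*
whose read fraction is ≥ 5%, in both channels. Full-length counts are
excluded from the background statistics. The MAD scale is floored at one
count so a perfectly flat background cannot divide by zero. The thresholds
are engineering defaults validated by simulation: on flat-Poisson null
backgrounds (λ = 10, 50 sites, 1000 simulations) the per-target false-call
rate is below 1%, and a planted dual-channel spike carrying ≥ 20% of reads
is always called.

## The simulator and what it does not emulate

`simulate_stop_counts` draws multinomial counts from the closed-form stop
distribution above — exactly the process the estimator inverts — and
`simulate_reads` expands counts into FASTQ-ready read pairs with handles,
adapter read-through and a configurable ligation-dimer fraction. Defaults
were chosen once to represent the single-hit probing regime: per-site
modification propensities uniform on [0, 0.05] over a 50–72 nt probed
region (≈ one modification per molecule), natural drop-off uniform on
[0, 0.01] per site, 10⁴–10⁶ reads per channel, 2×35 bp reads. All
randomness flows from a single integer seed through numpy Generators, so
runs are bit-reproducible.

The simulator does **not** model PCR amplification bias,
fragment-length-dependent ligation efficiency, sequence-dependent reagent
preferences, base-quality errors (a uniform substitution rate exists purely
to stress the aligner and is off by default), or carrier effects between
targets. Passing recovery tests therefore demonstrate correctness of the
inference given the stop-process model, not robustness to every artefact of
real libraries; the (−) channel subtraction is the only bias correction the
estimator performs.

## Problem sizes used in the checks

The automated checks run at: 500 random count tables (n ≤ 5, ≤ 200 reads
per channel) for the grid-oracle comparison; n = 50 with 10⁴/10⁵/10⁶ reads
per channel for parameter recovery (max error < 0.01 at 10⁵, strictly
decreasing across depths); 10⁴ reads for the exact round trip; 1000 random
profile pairs for the window-scan enumeration check; 1000 null simulations
for spike specificity; and 10⁴ null trials for Welch calibration. These
sizes were chosen as the smallest that make the statistical assertions
sharp.

## Known limitations and open choices

* The ρ = n·θ (mean-1) normalisation is one of two conventions in use for
  drop-off-corrected profiles; it is the one consistent with class
  thresholds centred near 1, and it is applied uniformly on output and
  input tables.
* DMS-mode analysis is supported by masking non-A/C positions
  (`mask_by_base`), not by a base-specific error model; masked positions are
  missing, never zero.
* The published sequences of the riboregulator antisense RNAs used in the
  original structure–function study live in that study's supplementary
  material and are not redistributed here; the hairpin-stability
  reproduction check in the acceptance suite therefore requires the user to
  supply those sequences and fails (honestly) without them.
* Reactivity estimation is maximum-likelihood only; no posterior
  uncertainty is attached to theta beyond replicate standard deviations.
* The aligner is intentionally specialised to small panels of short,
  orthogonal targets; it is not a general transcriptome aligner.
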