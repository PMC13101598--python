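# Methods

## Overview

`editquant` estimates per-position base-editing fractions from analyzed
Sanger chromatograms. The pipeline is: read the sample trace → build a
per-base signal table → apply a Phred quality filter → locate the gRNA
motif → align the control → fit a background-noise null → score every
wild-type-base position inside the motif.

## Signal model

Each called base contributes the four channel intensities at its peak
location, normalised to percent signals (rows whose total height is
zero are flagged invalid and excluded downstream). Working on the
percent scale makes the analysis invariant to run-to-run intensity
differences between capillaries and instruments.

The "phred cutoff" (default 0.001 ⇔ Q30) is an error-*probability*
threshold: a base passes when 10^(−Q/10) ≤ cutoff. The longest
contiguous head and tail of failing bases are trimmed — Sanger quality
degrades at read ends — while interior failing bases are only masked
from noise fitting. Motif rows are never dropped: a motif row failing
quality is scored anyway and carries a warning. N calls are kept in the
table but excluded from noise fitting.

## Motif location and orientation

The motif is the protospacer 5′→3′. `motif_fwd` states whether the gRNA
and the sequencing primer read the same strand; when false the motif is
searched as its reverse complement and protospacer numbering (1–20,
position 20 PAM-adjacent) runs antiparallel to the read, so the
wild-type/edit bases are supplied on the read strand (ABE: A→G forward,
T→C reverse). The search tolerates up to ⌈20% of motif length⌉
mismatches so heavily edited samples still locate; two loci tying at
the minimal mismatch count are reported as ambiguous rather than
silently choosing one, since scoring the wrong locus is worse than
failing loudly.

Sample and control are aligned locally (match +2, mismatch −3, gap open
−5, gap extend −2 — conservative values for high-quality Sanger reads)
in both orientations; the higher-scoring orientation wins, which is how
control orientation is matched automatically. A control is rejected
when identity over the aligned columns falls below 0.5 *or* the aligned
span covers less than half of the shorter sequence — local alignments
of unrelated sequences are short but locally perfect, so an identity
floor alone cannot reject them.

## Candidate positions

A motif position is a candidate when the *control* base aligned to it
equals the wild-type base; where the control is unaligned (gap,
truncation, or no control given) the motif string decides. Anchoring on
the control keeps fully converted positions visible: at 100% editing
the sample's called base is already the edit base. The reported
`edit_percent` is the percent signal of the edit-base channel — not
1 − wt percent — so bystander substitutions at the same position do not
inflate it. All wild-type positions across the whole motif are
reported, not only the canonical window: detection is window-agnostic,
the window is a guide-design concept (`editquant.guides`).

## Noise model

Background observations are the three non-called channel percents at
every quality-passing, valid, non-N position outside the motif (within
the kept range). When the control is a trace, its background (outside
the region aligned to the sample motif) is pooled with the sample's;
a FASTA control carries no signal, so the model must be fittable from
the sample alone. At least 50 background positions are required.

The null is a zero-adjusted gamma. The zero mass ν is the fraction of
exact zeros (zero integer peak height); the gamma component, in the
mean/dispersion parameterisation (mean μ, variance σ²μ²), is fitted to
the nonzero observations by two-parameter maximum likelihood
(`scipy.stats.gamma.fit` with location fixed at 0). All off-channel
observations are pooled into one model; per-channel nulls would triple
the parameter count on the same data and are left as an extension.
Observations are sorted before fitting so the fit is independent of
collection order (this is what makes strand-reversal exactly
reproducible). Degenerate inputs: all-zero observations return a ν = 1
sentinel under which any positive signal has p = 0 (flagged in the fit
log); fewer than five distinct nonzero values fall back to a moment fit
with dispersion floored at 0.5.

The edit p-value is the one-sided upper tail P(X ≥ x): 1 at x = 0
(the point mass belongs to the tail), (1 − ν)·S_gamma(x; μ, σ) for
x > 0. P-values are raw; significance is p < threshold (default 0.01)
with no multiple-testing correction, so users wanting stringency should
lower the threshold to 0.001 or 0.0001 rather than expect an FDR.

## Synthetic data generator

`editquant.simulate` emulates an *analyzed* trace: one Gaussian peak
per base (default spacing 12 trace points, peak SD 2 — peaks fully
resolved), called-channel amplitude 2000 with ~10% lognormal jitter
(run-to-run peak-height variation), edited positions splitting the
amplitude (1−f)/f between template and edit channels, and every other
channel drawing zero-adjusted-gamma background scaled by the amplitude.
Defaults ν = 0.2, μ = 0.02, σ = 0.5 describe a clean run with ~2% mean
bleed, the regime in which Sanger-based quantification is credible
above ~5% editing. Qualities default to flat Q40 decaying linearly to
Q10 over the last 10% of bases, exercising the end-trimming path.
Intensities are floored to integers and capped at the int16 range of
ABIF DATA tags; files written through `write_abif` therefore round-trip
exactly.

What the generator does **not** emulate: dye blobs, mobility shifts,
primer peaks, heteroduplex/indel trace decomposition, basecaller
miscalls correlated across channels. A green synthetic test therefore
establishes correctness of the statistics and bookkeeping, not
robustness to every real-trace pathology.

Known small bias: at an edited position the two off-channels add noise
to the denominator, so the recovered fraction is ≈ f/(1 + 2μ) — about
4% low at f = 1 with default noise. This is inherent to percent-signal
quantification, matches what the recovery tolerance (±0.05) allows, and
is not corrected for.

## File formats

ABIF reading uses Biopython's `abi` parser; required tags are DATA9–12
(analyzed channels, mapped to bases via FWO_), PLOC, PBAS, PCON, with
descriptive errors naming any missing tag. Unknown tags are ignored.
The bundled writer emits exactly that minimal tag set (big-endian
directory, version 1.01) — enough for this package and for Biopython to
re-read, not a general ABIF library. Controls may be `.ab1` or FASTA
(first record, with a warning if more follow). Batch parameters are
`.xlsx` (openpyxl) or `.csv`; header names are snake_case; blank
cutoff cells receive the defaults.

## Numerical conventions

- Coordinates are 0-based internally; every user-facing protospacer
  position is 1-based.
- Percent sums are exact to 1e-9 on valid rows.
- `significant` is a strict inequality (p < threshold).
- Batch rows run independently and deterministically; re-running a
  batch bit-reproduces the combined table.

## Limitations

Indels are out of scope: an insertion or deletion upstream of the motif
corrupts the trace downstream and should be analysed with
decomposition-based tools. Quantification below ~5% editing approaches
the background-noise floor even with a control. The p-value treats
positions independently; correlated noise (e.g. dye blobs spanning
several peaks) can produce clustered false positives.
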