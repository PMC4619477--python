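# Methods

This note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Signal model and denoising

A chromatogram is four non-negative intensity arrays (one per nucleotide)
with called bases anchored to scan positions. Denoising is a multilevel
orthonormal Haar decomposition, f(t) = A_n + Σ D_i, computed with
PyWavelets in periodized mode; the detail sub-signals are discarded outright
(no soft/hard thresholding) and the level-n approximation is kept, clipped
at zero. Defaults and consequences:

- **levels = 3** (configurable). The level-3 approximation is piecewise
  constant over 8-scan blocks. With a typical inter-peak spacing of ~12
  scans this means peak apices arrive as plateaus and apex positions are
  quantized to ±4 scans. Every consumer downstream is plateau-aware and no
  stage relies on sub-block apex accuracy.
- Signals whose length is not a multiple of 2^levels are symmetric-padded
  and the pad dropped after reconstruction, so output length always equals
  input length and peak scan indices stay valid.
- The orthonormal (÷√2) filter convention makes the per-level energy
  partition ‖a‖² = ‖cA‖² + ‖cD‖² exact, which the tests exploit.

## Peak location and the three features

At a called base, channels are ranked by their denoised intensity **at the
called peak scan**; the strongest channel is the primary peak and the
runner-up is the secondary when it clears `floor_fraction` of the primary.
Ranking by at-scan intensity rather than by tallest in-window wave is
deliberate: the rising tail of a neighbouring base's peak can be the tallest
thing in a ±half-spacing window while contributing almost nothing at the
scan where this base actually migrates.

Wave geometry (L, M, R) is the highest local-maximum plateau in the search
window (default half-width: half the median inter-peak spacing), with each
flank walked down to the nearest local minimum; the walk may leave the apex
window (up to twice the half-width) because a wave's support is wider than
the window used to find its apex. When consecutive identical bases merge a
peak into a broad shoulder with no interior maximum, a window-spanning
fallback geometry is used and flagged unresolved.

Features per position: horizontal apex distance; height ratio (primary over
secondary, ≥ 1 by construction); half-wave width ratio computed from the
vertical half-extents (|y₁−y₂|+|y₁−y₃|)/(|y₄−y₅|+|y₄−y₆|) — the printed
formula uses y-differences, and that is what is implemented. When either
geometry is unresolved the width ratio is unmeasurable; since Gaussian waves
of equal width rising from baseline have half-extent proportional to
height, the height ratio substitutes for it in that case.

**Noisy waves.** A wave within ±2 called positions counts as noisy when its
height exceeds 70 % of the secondary peak's height **and** its half-extent
exceeds 50 % of the secondary's (conjunctive). Each position's own primary
wave is the legitimate sequence signal and is never counted — counting
neighbour primaries would make every real SNP "noisy" since a normal base
peak always dwarfs a secondary peak. A prominence filter (half-extent ≥ 25 %
of height) keeps noise bumps riding on peak tails from counting as waves.

## SNP scoring network

Architecture: 3 inputs → 10 logistic hidden units → 1 linear output; 51
trainable parameters (thresholds stored as bias weights). Feature
normalization to [0, 1] (0 = ideal double peak): distance divided by the
trace's median inter-peak spacing; each ratio r folded to max(r, 1/r) and
mapped by (r−1)/(r_max−1) with r_max = 5; all clamped. Scores are the raw
output × 100, clamped to [1, 100].

**Training targets** come from a Mamdani fuzzy system, since no labelled
corpus of double-peak features exists. Each normalized feature has three
triangular memberships (good/fair/poor peaking at 0/0.5/1). The 27-rule
base maps the sum of quality indices (good = 0 … poor = 2) to four output
classes — 0 → true, 1–2 → vague, 3–4 → false, ≥ 5 → strongly-false — whose
symmetric triangular supports sit exactly on the reporting score bands
([75, 100], [60, 75], [20, 60], [1, 19]), so a single fully-fired rule
defuzzifies to its class centroid (87.5 / 67.5 / 40 / 10). Aggregation is
max, defuzzification is the centroid over a 0.01-resolution grid. The rule
base is monotone on the crisp quality grid; pointwise monotonicity across
the whole cube is not guaranteed (a known property of max-aggregated
Mamdani systems) and not relied on.

**Optimisation** is Levenberg–Marquardt on the summed squared residuals
V(w) = Σ (d_k − y_k)² with targets on the [0, 1] scale:
Δw = −[JᵀJ + μI]⁻¹ Jᵀe, J the analytic residual Jacobian. μ₀ = 0.01,
β = 10: an accepted step (V decreased) divides μ by β; a rejected one
multiplies it and recomputes the step from the same Jacobian, aborting if μ
overflows 1e12. Stopping: V < ε = 0.1 (on the normalized scale) or 110
iterations. With 443 training samples V rarely reaches 0.1 in the budget,
so runs typically end non-converged by that flag while the model is
excellent; quality is governed by the returned best-validation snapshot
(early stopping). Weights initialise uniform (0, 1) from the seed, and
training is bit-reproducible: the shipped default model (seed 20151024,
443/147 samples, best validation MSE ≈ 7.1e-4 at iteration 68) is
regenerated bit-identically by `scripts/build_default_model.py`.

**Grades.** score ≥ 75 → 1; 60 ≤ score < 75 → 2/3/4 for ≤ 1 / = 2 / > 2
noisy waves; 20 ≤ score < 60 → 5; < 20 → 6. Grades 1–2 are a strict
calling threshold, 3–4 a relaxed one; 5–6 label rejected candidates, so
"no calls on a clean trace" means no calls at grade ≤ 4.

## InDel detection

The double-peak region is the chain of positions with a secondary peak
above a region-specific floor of **0.40** of the primary (the SNP path keeps
the permissive 0.10 floor: its grade bands absorb weak candidates, whereas
region marking must separate genuine allele peaks from block-leak
artefacts, which stay below ~0.31 of the primary at the default noise).
Positions where the two alleles share a base show a single peak, so chains
tolerate single-peak gaps of ≤ 4 positions; gaps enter the secondary stream
as 'N' and are skipped during scoring. A region needs ≥ 8 double-peak
positions (min_run).

Matchability at offset m is the identity fraction over scored overlap
positions (minimum 5). Transposition tolerance: a mismatch may be repaired
by swapping the primary/secondary calls at one trace position involved in
the comparison, provided the previous scored comparison still matches, no
earlier comparison involving that position breaks, and no adjacent position
was already swapped — miscalled positions are isolated events, and the
adjacency bar prevents repairs from cascading into wholesale stream
exchange (which would score any pair of streams perfectly). The search
scans m = ±1..±30, ties broken toward smaller |m| then '+'; the call is
accepted at matchability ≥ 0.80. Sign convention: '+' = the primary
(top-peak) allele carries the extra bases. Allele reconstruction merges the
two streams under the winning offset; the long and short alleles differ by
exactly |m| bases, and the shared prefix before the region is taken from
the called sequence.

## Synthetic traces

The simulator renders each allele as a train of Gaussian peaks (height 1000
split 50:50 between alleles, σ = 4 scans, spacing 12 scans), one peak per
base on the channel of that base, both alleles co-migrating by base count.
A heterozygous SNP scales the variant channel of the second allele by the
allele ratio; a heterozygous InDel shifts the second allele's downstream
bases by the InDel size, producing the continuous double-peak tail. Linear
crosstalk (2 %) and uniform baseline noise (U(0, 50), i.e. 5 % of a full
peak — the "moderate noise" condition) are added; base calls and peak scans
come from the noise-free primary-allele grid. InDel traces carry an
amplification imbalance (second allele at 0.8): with exact 50:50 mixing the
primary/secondary labelling downstream of an InDel would be an arbitrary
per-position tie-break, destroying the stream identity the alignment needs,
and real amplifications are never exactly balanced.

Not modelled: mobility shifts, dye blobs, polymerase slippage, basecaller
miscalls, quality-dependent peak broadening. Passing benchmarks therefore
demonstrate the algorithmic machinery — feature recovery, scoring,
alignment — under controlled conditions, not performance on degraded
real-world traces; the published detection rates on real amplicons are not
reproducible without those trace files and are out of scope here.

Benchmark problem sizes (also used by `scripts/acceptance.py`): 120-base
traces; 50-trace SNP benchmarks (three SNPs per trace, ratios cycling
0.5–1.0); 200 InDel traces spanning sizes 1–30 and both signs; 100 random
regions for the brute-force search check. These sizes give stable rate
estimates while keeping a full run in seconds.

## I/O

ABI (.ab1) files are read through Biopython's abi parser using the analyzed
data channels (DATA9–12), with the channel→base mapping taken from the
FWO_1 field-order record; base calls from PBAS, peak scans from PLOC;
non-ACGT calls become 'N'. SCF v2/v3 is decoded directly (no installed
library reads SCF): v3 sample blocks are double-delta decoded modulo 2¹⁶,
v2 interleaved records parsed per the format. Readers either return a trace
satisfying every container invariant or raise a typed error. The SCF writer
emits standards-conformant v3 (16-bit samples) and round-trips losslessly
up to integer quantization of intensities.

Reports are deterministic TSV (LF endings, fixed float formatting, 1-based
positions, sorted calls); identical inputs always produce byte-identical
bytes. A JSON sidecar with the same content is available behind a flag.

## Known limitations

- One InDel per trace (the dominant double-peak region); compound or nested
  InDels are not resolved.
- SNPs inside an InDel's double-peak tail are not scored separately.
- Detection degrades when a variant sits inside a run of identical bases —
  the merged-peak fallback recovers the height feature but the width
  feature is then a proxy.
- The 0.40 region floor assumes the default noise regime; heavily degraded
  traces need the exposed configuration knobs.
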