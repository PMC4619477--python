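# sangerhet

Reference-free detection of **heterozygous SNPs and InDels in a single
direct-Sanger amplicon trace** of a diploid sample.

When a diploid PCR amplicon is sequenced directly (no sub-cloning), both
alleles run in the same capillary. A heterozygous SNP shows up as two
superimposed fluorescence peaks at one base position; a heterozygous
insertion/deletion frame-shifts the two alleles against each other, so
nearly every position downstream shows a double peak. Neither variant can be
found by alignment because there is only one trace and, often, no reference
sequence — the signal itself has to be deconvolved. That is what this
package does. It is aimed at marker development and candidate-gene
resequencing workflows (EST amplicons, mapping-population parents) where
traces come one at a time.

## Method

Four stages, each exposed as library functions and as a CLI subcommand:

1. **Noise filtering** (`sangerhet.wavelet`). Each channel f(t) is
   decomposed with the orthonormal Haar filter bank into
   f(t) = A_n + Σᵢ Dᵢ; the detail sub-signals D₁..D₃ carry the
   high-frequency noise and are discarded, keeping the level-3
   approximation A₃ at full length.
2. **Feature extraction** (`sangerhet.peaks`). At every called base the
   primary (top) and secondary (lower) waves are located and three features
   computed from their (L, M, R) geometries: the horizontal apex distance
   |x₁−x₄|, the height ratio |y₁|/|y₄|, and the half-wave width ratio
   (|y₁−y₂|+|y₁−y₃|)/(|y₄−y₅|+|y₄−y₆|).
3. **SNP scoring** (`sangerhet.snpnet`). A 3-10-1 back-propagation network
   (logistic hidden units, linear output) maps the normalized features to a
   score in [1, 100]. It is trained with the Levenberg–Marquardt update
   Δw = −[JᵀJ + μI]⁻¹ Jᵀe on 443 + 147 synthetic samples whose targets come
   from a Mamdani fuzzy system, μ adapted by a factor β = 10 on step
   acceptance/rejection. Scores map to six grades:
   ≥ 75 → 1 (true SNP); [60, 75) → 2/3/4 by the number of nearby noisy
   waves (≤1 / =2 / >2); [20, 60) → 5 (false); < 20 → 6 (strongly false).
4. **InDel sizing** (`sangerhet.indel`). The region of continuous double
   peaks is split into primary and secondary base-call streams, which are
   slid against each other over offsets m ∈ ±1..±30 with tolerance for
   isolated primary/secondary basecall transpositions. The m maximising the
   matchability (identity fraction over the scored overlap) is the InDel
   size; '+' means the top-peak allele carries the extra bases. The two
   full-length allele sequences are reconstructed for downstream alignment.

A simulator (`sangerhet.simulate`) renders diploid traces as Gaussian peak
trains with planted variants, crosstalk and baseline noise, plus truth
manifests and an SCF v3 writer, so the whole pipeline is testable without
any sequencing data.

## Worked example

```bash
python examples/call_snps.py
```

```
planted SNPs (index, ref, alt, allele ratio):
   (30, 'G', 'A', 0.8)
   (60, 'G', 'C', 0.6)
   (90, 'A', 'G', 0.5)

calls (1-based position, primary/secondary base, score, grade):
    31  G/A  score= 78.3  grade=1  noisy=0
    61  G/C  score= 79.7  grade=1  noisy=0
    91  A/G  score= 77.6  grade=1  noisy=0
```

All three planted heterozygous sites — down to a 0.5 allele ratio — are
recovered at grade 1 (score ≥ 75, a true SNP) with no false calls. The InDel
counterpart:

```bash
python examples/call_indel.py
```

```
planted: 3-base insertion on the primary allele at index 40
double-peak region: bases 40-115
call: m=+3 (|m|=3 bases), matchability=0.983
```

From the shell, the same analyses over trace files (.scf or .ab1):

```bash
sangerhet simulate --n-traces 10 --seed 1 --out bench/
sangerhet snps bench/*.scf --max-grade 4 -o reports/
sangerhet indels bench/*.scf -o reports/
```

Each trace gets a deterministic TSV report (optionally a JSON sidecar with
`--json`); positions are 1-based in reports.

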