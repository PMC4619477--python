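"""Generate a reproducible synthetic benchmark of SCF traces.

Writes a directory of SCF v3 files — homozygous nulls, heterozygous-SNP
traces across allele ratios, and heterozygous-InDel traces across sizes
1..30 — plus a truth manifest for scoring caller sensitivity and false
positives. The same seed always produces byte-identical files.
"""

from sangerhet.simulate import make_benchmark

manifest = make_benchmark(20, "benchmark_scf", seed=1)
print(manifest[["trace", "kind", "snp_indices", "indel_size", "indel_sign"]]
      .to_string(index=False))
print(f"\n{len(manifest)} traces written to benchmark_scf/ "
      "(SCF v3 + manifest.tsv)")
# Feed the .scf files to `sangerhet snps` / `sangerhet indels` and compare
# the reports against manifest.tsv to measure sensitivity and FDR.
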