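# varcons

Multi-caller somatic variant consensus toolkit.

Somatic variant callers disagree: each produces systematic ("deterministic")
false positives of its own plus random noise, and each misses real variants.
`varcons` combines the VCFs of several callers and accepts a variant when at
least *k* of the *n* callers report it. It ships everything needed to use
and evaluate that strategy:

- **Normalized cross-caller matching** — allele trimming, multi-allelic and
  MNV decomposition, and reference-based indel left-alignment, so the same
  event is recognized across caller-specific VCF representations.
- **Dialect-aware support extraction** — per-caller FORMAT conventions
  (`AD` pairs, scalar `AD`+`RD`, `AF`/`FA`, `FREQ` percent strings, Strelka
  tier counts, `DP4`) resolved through ordered strategy plans; presets for
  MuSE, Mutect, Mutect2, Pindel, SomaticSniper, VarDict, VarScan and
  Strelka, overridable from an INI file.
- **Low-stringency pre-filter** — retain records with FILTER `PASS`/`.`,
  ALT-supporting depth > 3 and VAF > 0.02 (all configurable).
- **k-of-n consensus** — union (k=1) through full intersection (k=n), with
  symbolic thresholds `n`, `n-1`, `majority`. Recommended defaults: `n-1`
  for SNVs, `n` (both callers) for indels.
- **Benchmarking** — precision / sensitivity / F1 against a truth VCF, for
  every caller subset at every threshold, plus support histograms and
  summary statistics (median/max F1 by subset size and by relative
  threshold).
- **Amplicon noise analysis** — partition germline panel calls into
  germline-consistent (VAF in [0.4, 0.6] or [0.9, 1.0]) vs noise, count
  consensus-accepted noise per sample and threshold, optionally after
  dropping the noisiest caller.
- **Synthetic fixtures** — a seeded generator producing per-caller VCFs
  (in each caller's native dialect) with known truth, independent misses,
  private and correlated false positives, and germline-mode samples, plus
  an exact bookkeeping manifest.

## CLI

All functionality is under a single `varcons` entry point
(equivalently `python -m varcons.cli`):

```bash
# generate a 6-caller synthetic dataset with truth + manifest
varcons simulate --seed 1 -o fixtures/

# consensus VCF at the default SNV threshold (n-1)
varcons combine --vcf fixtures/mutect2.vcf --vcf fixtures/varscan.vcf \
    --vcf fixtures/vardict.vcf --threshold n-1 -o consensus.vcf

# evaluate against a truth set
varcons evaluate --vcf ... --truth fixtures/truth.vcf -o metrics.tsv

# full subset x threshold sweep
varcons sweep --vcf ... --truth fixtures/truth.vcf -o sweep.tsv

# germline amplicon noise table (one directory of caller VCFs per sample)
varcons simulate --germline --seed 2 --n-samples 10 -o gl/
varcons noise --sample-dir 'gl/*' --drop-caller auto -o noise.tsv
```

Caller identity is taken from each VCF's file name (`mutect2.vcf` uses the
Mutect2 dialect preset; unknown names get a generic plan). Exit codes:
0 success, 1 usage/configuration error, 2 data/format error. Outputs are
written atomically; a failed run leaves no partial files.

## Library use

```python
from varcons import (
    SimulationConfig, simulate_dataset, combine_at_threshold,
    low_stringency_filter, threshold_sweep, evaluate_keys,
)

ds = simulate_dataset(SimulationConfig(seed=0))
callsets = [low_stringency_filter(cs) for cs in ds.callsets]
table = combine_at_threshold(callsets, k=5)
print(evaluate_keys(table.accepted, ds.truth_keys))
```
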