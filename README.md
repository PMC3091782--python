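# fsvkit

Low-coverage (~5X) resequencing of **pooled DNA** is a cheap way to find
SNPs in two populations — say, two lines divergently selected for a trait —
but a hard way to tell which of those SNPs are *informative*, i.e. strongly
differentiated between the populations. At 5X most truly variable sites are
covered by a handful of reads, so a site's own read counts are a noisy
frequency estimate, and many variable sites look fixed.

`fsvkit` implements and evaluates a flanking-window remedy, the **Flanking
SNPs Value (FSV)**. For each SNP called in a line's pool, let
*S* ∈ [0, 1] be the proportion of that line's reads agreeing with the
reference; where a line shows no call the SNP is assumed fixed for the
reference allele there (*S* = 1). For a focal position and a total window
of *W* bp centred on it (*W*/2 each side, focal SNP removed), with *H* and
*L* the flanking SNPs detected in the high and low line,

    FSV = ( Σ_{i∈H} |S_iH − S_iL| / N_H ) × ( Σ_{j∈L} |S_jL − S_jH| / N_L )

Each factor is a mean of unit-interval values, so FSV ∈ [0, 1]; it is large
only when *both* lines' flanking SNPs show systematic between-line score
differences — a signature of local divergence, e.g. opposite selective
sweeps. SNPs with no reference-supporting read in either line are excluded
from the sums, and a window is only trusted when each line contributes
strictly more than 1 flanking SNP per kb.

Because the original chicken data (two body-weight-selected lines, SOLiD
pools at 5.19X/5.53X plus a 60 K chip on 20 birds/line) were never
deposited, the package ships a first-class **synthetic-data generator**:
divergence blocks with exponential lengths carry Balding–Nichols
line-frequency draws (so neighbouring SNPs have correlated divergence),
individual chip genotypes are binomial dosages with no-calls, and pooled
pileups are finite-pool binomial resampling + Poisson depth + binomial
read splits with a per-read error. Everything downstream — the 3-read pool
caller, chip summaries, the FSV scan, and the evaluation layer
(detection sensitivity by frequency bin, Δp-stratified FSV means, Pearson
correlation per chromosome size class and window size) — runs on the
generator's output or on your own TSV tables.

## Worked example

```python
from fsvkit import SimulationConfig, run_pipeline

cfg = SimulationConfig(rng_seed=42)       # 20 Mb genome, defaults as above
res = run_pipeline(cfg)

print("detected SNPs:", len(res.calls))
print(res.density.to_string(index=False))
pooled = res.sensitivity.query("line == 'pooled'")
print(pooled[["bin", "n_chip_snps", "fraction_detected"]].to_string(index=False))
scan = res.correlation
best = scan[scan["best"] & (scan["stratum"] == "all")].iloc[0]
print(f"best window: {best.window_total//1000} kb, "
      f"r = {best.pearson_r:.3f} (n = {best.n}, P = {best.p_value:.2e})")
```

prints

```
detected SNPs: 63125
     stratum  n_snps  length_kb  snps_per_kb
     overall   63125    20000.0      3.15625
intermediate   18546     6000.0      3.09100
       macro   33004    10000.0      3.30040
       micro   11575     4000.0      2.89375
    bin  n_chip_snps  fraction_detected
0.0-0.1          420           0.007143
0.1-0.2          131           0.106870
...
0.9-1.0          385           0.877922
best window: 14 kb, r = 0.474 (n = 102, P = 4.84e-07)
```

Reading this: of ~100,000 true SNPs on the 20 Mb genome, ~63,000 reach the
3-non-reference-read threshold in at least one pool (≈3.2 called SNPs/kb —
detection is lossy at 5X). The redetection fraction of chip SNPs climbs
from under 1% for rare non-reference alleles to ~88% above frequency 0.9,
and FSV correlates with the chip-measured between-line frequency
difference (r ≈ 0.47 for SNPs with Δp > 0.4), most strongly at an
intermediate window size — the scale of the simulated divergence blocks.

The same stages are scriptable from a shell:

```sh
fsvkit run --seed 42 --out-dir out/            # everything at once
fsvkit simulate --out-dir sim/                 # or stage by stage
fsvkit call --pileup sim/pileup.tsv --threshold 3 --out calls.tsv
fsvkit chip --genotypes-high sim/chip_genotypes_high.tsv \
            --genotypes-low  sim/chip_genotypes_low.tsv  --out chip.tsv
fsvkit fsv  --calls calls.tsv --focal focal.tsv --out fsv.tsv
fsvkit evaluate correlate --chip-summary chip.tsv --fsv fsv.tsv \
            --class-map classes.tsv --out scan.tsv
```

All interchange files are headered TSV; `fsvkit run` also writes a JSON
manifest (config snapshot, seed, output digests) and the run is
byte-reproducible from its seed.

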