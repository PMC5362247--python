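# screensift

Analysis toolkit for inducible-toxicity siRNA rescue screens: plate
normalization and robust Z scoring, threshold hit calling, reporter
counter-screen and expression filtering, siRNA pool deconvolution
(on-target vs single-siRNA-dominated), decay-kinetics half-life estimation,
and a fully seeded synthetic-screen generator with known ground truth.

## Package layout

| module                    | responsibility |
|---------------------------|----------------|
| `screensift.io`           | TSV schemas, validation, cross-referenced screen bundles, score/expression table ingestion with column mapping |
| `screensift.scoring`      | per-plate sample-median normalization, experiment-wide median/MAD robust Z per replicate, triplicate summary (mean/min/max Z, fold rescue) |
| `screensift.filtering`    | hit calling (enhancers `Z >= t`, sensitizers `Z < t`), counter-screen elimination (`Z <=` cutoff derived as the minimum scrambled-control Z), expression filter (`FPKM > 0.5` in either condition), cascade report, Spearman screen-correlation diagnostic |
| `screensift.deconvolution`| classify pools from per-siRNA fold rescues (>= 2 rescuing at 2-fold → on-target; 1 → single-dominant, promotable to synergy via the pooled non-rescuing siRNAs) |
| `screensift.kinetics`     | comparative-Ct relative quantification, semi-log (log-linear OLS) decay fits, `t1/2 = ln 2 / k` |
| `screensift.simulate`     | seeded synthetic screens (lethal induction, planted rescuers / off-target / induction-inhibitor pools, plate scale factors, lognormal well noise), deconvolution and time-course simulators, recovery metrics |
| `screensift.pipeline`     | glue: raw bundles → scores → cascade report |

## CLI

```bash
screensift simulate --seed 17 --out simdir/           # synthetic screen + truth
screensift ingest --layout L.tsv --measurements M.tsv --library Lib.tsv --out bundle/
screensift score --bundle bundle/ --mode multiplicative --out scores.tsv
screensift filter --scores scores.tsv --counter luci.tsv --expression expr.tsv \
    --z-min 3.0 --counter-cut auto --min-fpkm 0.5 --out report.json
screensift deconv --folds deconv.tsv --rescue-fold 2.0 --out deconv_report.tsv
screensift halflife --timecourse tc.tsv --mode qpcr --out fits.tsv
```

All inputs are tab-separated UTF-8 with a header row; well addresses accept
leading zeros on input ("A01") and are written without them. A YAML config
may supply thresholds and column-name mappings; CLI flags override it.

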