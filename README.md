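# msapdiv

Band-based genetic and epigenetic diversity analysis for dominant-marker
fingerprints: AFLP (amplified fragment length polymorphism) and dual-enzyme
MSAP (methylation-sensitive amplified polymorphism).

`msapdiv` is aimed at population geneticists and ecological epigeneticists
who score anonymous presence/absence markers in non-model organisms and want
a reproducible route from raw 0/1 fingerprint tables to a statistical
comparison of genetic vs epigenetic diversity — in particular for paired
designs that contrast restricted-endemic species with widespread congeners.

## What it computes

**Methylation scoring.** MSAP runs the isoschizomers HpaII and MspI (both
cut `CCGG`, with different methylation sensitivity) in parallel. The joint
band pattern at each epilocus encodes a methylation state:

| HpaII | MspI | state |
|------:|-----:|-------|
| 1 | 1 | unmethylated |
| 1 | 0 | hemi-methylated CHG |
| 0 | 1 | hemi-/fully methylated CG |
| 0 | 0 | uninformative |

The Mix1 scoring scheme converts each epilocus into two dominant markers:
U-MSAP (unmethylated condition scored 1) and M-MSAP (either methylated
condition scored 1). Loci are then filtered per species dataset
(monomorphic-locus deletion and a minimum minority count, `MinPoly = 2` by
default).

**Diversity indices.** For every population × marker type:

- PPOL — proportion of polymorphic fragments;
- SI — Shannon's index per locus, `SI = −Σ pᵢ ln pᵢ` over band
  presence/absence frequencies, averaged over loci (max `ln 2`);
- PPRIV — proportion of the population's bands private to it;
- RI — frequency-down-weighted marker value
  `RI_x = Σᵢ s_ix / Σⱼ s_ij` (rarity index), averaged over individuals.

**Replicate QC.** Technical replicates give a per-locus mismatch fraction;
irreproducible bands are eliminated and the overall scoring error rate
(mismatches / (pairs × retained loci)) is reported.

**Comparison stage.** Each index is modelled with Markers × Distribution
fixed effects and random intercepts for species and population-in-species:
binomial mixed models (logit link, Laplace approximation) for PPOL/PPRIV,
weighted linear mixed models for SI/RI. Terms are tested with
likelihood-ratio tests; estimated marginal means with Tukey-adjusted
pairwise marker contrasts are reported per distribution class, and Pearson
correlations relate genetic to epigenetic index values per class.

**Synthetic data.** A seeded hierarchical generator (genus → species →
population → individual) emulates the paired 7-genus sampling design,
including enzyme-rule-generated HpaII/MspI band pairs and noisy technical
replicates, so the full pipeline is testable without any raw data.

## Worked example

```python
from msapdiv import SynthConfig, fit_index_model, correlate_groups
from msapdiv.calibration import synthetic_diversity_table

table = synthetic_diversity_table(SynthConfig(
    seed=7, n_genera=7, individuals_per_population=12,
    n_aflp_loci=120, n_msap_epiloci=100, replicate_fraction=0.0))
print(table.groupby("marker_type")[["PPOL", "SI", "PPRIV", "RI"]].mean().round(3))

res = fit_index_model(table, "SI")
for row in res.lrt:
    print(f"{row['term']:22s} chi2={row['chi_square']:7.2f} df={row['df']} p={row['p']:.4g}")
```

prints

```
              PPOL     SI  PPRIV     RI
marker_type
AFLP         0.707  0.340  0.146  2.262
M_MSAP       0.859  0.451  0.013  2.135
U_MSAP       0.850  0.448  0.025  1.812
Markers                chi2= 215.08 df=2 p=1.98e-47
Distribution           chi2=   0.19 df=1 p=0.6622
Markers:Distribution   chi2=   2.01 df=2 p=0.3655
```

Read: both MSAP marker sets are more diverse than AFLP in this simulated
dataset (the strong Markers effect), while the two distribution classes do
not differ and the marker pattern is the same in both classes — the
expected answer here, because the generator was run with
`restricted_effect=0`, i.e. exchangeable classes.

The same stages are scriptable from the shell:

```bash
msapdiv simulate --seed 2 --out-dir sim/
msapdiv qc --in sim/genus01_restricted_aflp.csv --report qc.json --out aflp_qc.csv
msapdiv epigenotype --hpa sim/genus01_restricted_hpa.csv \
    --msp sim/genus01_restricted_msp.csv --out-u u.csv --out-m m.csv
msapdiv run-all --config pipeline.yaml
```

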