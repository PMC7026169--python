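# edura

Joint structural and functional analysis of how a bacterial transcriptional
regulatory network (TRN) is embedded in its circular chromosome.

Bacterial gene regulation runs on two coupled channels: **digital** control
through discrete transcription-factor → target links, and **analog** control
through the spatial organisation of the chromosome (supercoiling, nucleoid
structure), which acts on chromosomal neighbourhoods. This package
implements three analyses that probe their interplay, plus the synthetic
generators needed to validate every stage without external downloads:

1. **EDURA** (Edge Distribution Under Rotation of an Axis). For a candidate
   Ori–Ter axis at position *a* on a circle of *g* bp, every directed edge
   falls into one of six categories — r₊, r₋, l₊, l₋, rl, lr (along each
   chromosomal arm away from / toward Ori, or across the arms). From the
   counts *n*(·) two asymmetries are formed,

       A±ʳ = (n(r₊) − n(r₋)) / (n(r₊) + n(r₋) + n(rl))

   (mirrored for the left arm) and the cross–along asymmetry
   A↔ = (n(lr)+n(rl) − Σ along)/(Σ all). Because an edge migrates through a
   fixed cycle of categories as the axis rotates, A±ʳ and A±ˡ are strongly
   correlated at generic positions; a *drop* in their windowed correlation
   (after subtracting switch-randomized baselines) marks an axis against
   which the embedding is systematic. `detect_axis` returns the curve's
   minimiser.

2. **Control strengths.** For one expression contrast, genes with
   |logFC| > T_FC induce an *effective network* in the TRN and in the gene
   proximity network (GPN: genes linked when their centres are within
   T_GPN bp on the circle). With R = N_connected/N_isolated, the control
   type confidence CTC is the z-score of R against 10,000 equally sized
   random gene sets — digital CTC on the TRN, analog CTC on the GPN.

3. **Decision-tree feature importances.** Nine per-gene features (distance
   to Ori; CRP/H-NS/FIS binding-site densities in ±50 kbp; called GPN
   neighbours; called TRN regulators; direct-target flags for hns/fis/crp)
   feed an impurity-based tree classifying called vs uncalled genes.
   Importances are shuffle-corrected (mean importance over 100 label
   permutations subtracted) and correlated with the CTCs across contrasts.

## Worked example

Generate a synthetic dataset whose differentially expressed gene sets are a
50/50 mixture of network-spreading (digital) and chromosomal-neighbourhood
(analog) events, then measure both control strengths:

```bash
edura simulate --preset mixed --lambda 0.5 --n-contrasts 12 --seed 7 --out-dir demo
edura ctc --genome demo/genes.tsv --trn demo/edges.tsv \
          --contrasts demo/contrasts.tsv --g 2000000 \
          --n-null 2000 --seed 7 --out-dir demo/run
```

which prints (abridged; full tables land in `demo/run/control_absdge.csv`):

```
{
  "absdge": {
    "spearman": -0.6223776223776225,
    "n_contrasts": 12
  }
}
```

The negative Spearman coefficient between digital and analog CTC across
contrasts is the signature of the two control modes buffering one another:
contrasts dominated by regulator perturbations score high digital / low
analog CTC, and neighbourhood-driven contrasts the reverse. Individual rows
of the CSV carry each contrast's call size, R, CTC pair, and null moments.

Planting and recovering an Ori–Ter axis:

```bash
edura simulate-systematic --n 400 --counts 120,30,120,30,20,20 \
      --axis 0.25g --g 1000000 --seed 1 --out-prefix demo/toy
edura scan --genome demo/toy_genes.tsv --trn demo/toy_edges.tsv \
      --g 1000000 --seed 2 --out-dir demo/scan
```

```
{
  "detected_ori_bp": 257499.38310869428,
  "detected_ter_bp": 757499.3831086943,
  "correlation_minimum": 0.5275356808495344
}
```

The planted axis at 250,000 bp is recovered to 0.75% of the genome length;
the correlation minimum (0.53 against a generic-position baseline near 1)
is the detection signal.

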