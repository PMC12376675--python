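# secircuit

Discovery of super-enhancer-driven transcription-factor circuits in
two-condition epigenomes — for example a drug-resistant cancer cell line
against its sensitive parent — packaged as a tested, reusable pipeline with a
planted-truth synthetic data generator, so every inference stage can be
validated end to end without access to restricted sequencing data.

It is aimed at computational biologists who have H3K27ac/H3K4me1/H3K4me3 and
TF peak calls plus coverage tracks, RNA-seq count matrices, patient survival
tables, and drug dose-response measurements, and who want the standard chain
of analyses those inputs support:

1. **Peak-set comparison** — shared vs condition-specific H3K27ac peaks
   (≥1 bp overlap, BED 0-based half-open coordinates throughout).
2. **Super-enhancer (SE) calling** — ROSE-style: stitch enhancer peaks within
   a 12 kb gap, quantify input-subtracted coverage per stitched element, rank
   by ascending signal, rescale the rank/signal curve to the unit square, and
   cut at the smallest rank where the discrete tangent slope reaches 1 and
   stays ≥ 1 through the top; elements above the cutoff signal are SEs.
3. **Regulatory-element stratification** — promoters (H3K4me3 + TSS-window
   co-occupancy) vs enhancers (H3K4me1), nearest-TSS gene assignment, and
   Trio/Dual/Solo/None groups by how many of three TFs co-bind each element,
   with expression linkage, Welch pairwise tests, and SE-overlap fractions.
4. **Differential expression** — FPKM normalization and a clearly labeled
   Welch-on-log2(FPKM+1) stand-in honoring |log2FC| > 0.584, p < 0.05 calls
   (external DE tables import through the same schema).
5. **Circuit nomination** — candidate TFs = SE-driven ∩ upregulated ∩ TF
   catalog; pairwise Pearson network across patient samples; candidate
   circuits are maximal cliques whose every edge has r ≥ r_min and
   p ≤ p_max (defaults 0.5 / 0.05).
6. **Enrichment and survival** — preranked GSEA (weighted KS running sum,
   gene-label permutation null), per-sample ssGSEA signature scores, the
   maximally selected log-rank statistic for an optimal survival cutpoint
   with a selection-adjusted permutation p, and the log-rank test.
7. **Drug synergy** — median-effect fits fa/(1−fa) = (D/Dm)^m and the
   Chou-Talalay combination index CI = d1/Dx1 + d2/Dx2 (CI = 1 additive,
   < 1 synergistic, > 1 antagonistic); Dm doubles as the IC50 estimate.

A position-weight-matrix scanner and a minimal motif-span statistic (the
tightest window containing one motif hit of each of the three TFs) support
co-binding analyses at base-pair resolution.

## Worked example

Fit two drugs and score their fixed-ratio combination (here on synthetic
curves with Hill slopes 1.5/1.2, median-effect doses 9.3/2.0 µM and a planted
CI of 0.6):

```bash
secircuit synergy --drug1 abi.tsv --drug2 bi3802.tsv \
    --combo combo.tsv --out ci.tsv
# drug1 m=1.5 Dm=9.3 uM; drug2 m=1.2 Dm=2 uM; mean CI 0.6
```

`ci.tsv` then holds one row per combination observation, e.g.

```
fa        d1_uM  d2_uM   Dx1_uM  Dx2_uM  ci
0.0938    0.5    0.1075  2.0496  0.3020  0.6000
0.2043    1.0    0.2151  3.7572  0.6442  0.6000
```

— at each observed fraction affected, the single-agent iso-effective doses
Dx1/Dx2 are derived from the fits and the CI of 0.6 < 1 reports synergy.

A full synthetic study (simulate → SE call → stratify → DE → circuit →
survival → synergy) runs in a few seconds:

```bash
secircuit run --outdir demo --seed 1
# simulate: 2.7s ... synergy: 0.002s
# top circuit: ['G1080', 'G1460', 'G1720', 'G4181']
```

Here the planted mutually-correlated trio (G1080, G1460, G1720) is recovered
inside the top nominated clique; `demo/report.json` records per-stage
parameters, timings, and SHA-256 output digests (identical config + seed
reproduces identical digests).

## Layout

- `src/secircuit/intervals.py` — interval model, BED/bedGraph I/O, overlap
  and stitching algebra, peak-set comparison
- `src/secircuit/se_caller.py` — signal quantification, stitch/rank,
  inflection cutoff
- `src/secircuit/element_annotation.py` — promoter/enhancer classification,
  co-binding groups, motif scan/span
- `src/secircuit/expression_de.py` — FPKM, DE stand-in, BH adjustment
- `src/secircuit/circuit_finder.py` — candidate selection, Pearson network,
  maximal-clique nomination
- `src/secircuit/enrichment_survival.py` — preranked GSEA, ssGSEA, maxstat
  cutpoint, log-rank
- `src/secircuit/drug_response.py` — median-effect fit, IC50, combination
  index
- `src/secircuit/synthetic_data.py` — the planted-truth generator
- `src/secircuit/pipeline.py`, `cli.py` — orchestration and the `secircuit`
  command

See `docs/methods.md` for the models, defaults, and known limitations.
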