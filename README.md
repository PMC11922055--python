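# stallkit

Loss of N4-acetylcytidine (ac4C) at position C12 in the D-arm of tRNA-Leu
and tRNA-Ser — the modification deposited by NAT10 with its tRNA adapter
THUMPD1 — lowers the levels of the affected isodecoders, slows ribosomes at
the codons those tRNAs decode, promotes ribosome collisions, and feeds into
GCN2/eIF2α stress signaling. `stallkit` is a tested, synthetic-data-driven
re-implementation of the computational analyses behind that chain of
evidence, for computational biologists who want to study, stress-test, or
extend these methods at desk scale:

* **Chemical-probing site calling** (`stallkit.acseq`): reduced-vs-mock
  sequencing libraries in which borohydride-reduced ac4C reads as a C→T
  misincorporation or an RT stop. Reads are adapter-trimmed, deduplicated on
  the full sequence including UMIs, exhaustively ungapped-aligned, and piled
  up; for each reference cytidine the net misincorporation rate
  `T/(C+T)_reduced − T/(C+T)_mock` (floored at 0) is filtered at depth
  strictly greater than 100 reads and net rate at least 2%, annotated with
  the 5'-CCG-3' consensus, and classified for knockout sensitivity.
* **Isodecoder quantification** (`stallkit.trnaquant`): modification-tolerant
  counting (mismatches at annotated C12 positions are forgiven), fractional
  multimapper weights, proportions per replicate, pooled-variance t tests on
  log proportions with Benjamini–Hochberg adjustment, and anticodon-level
  aggregation.
* **Ribosome and disome occupancy** (`stallkit.riboprof`): monosome
  ([25,40) nt) and disome ([40,80] nt) footprints, length-dependent A-site
  offsets (disome offsets target the leading ribosome), per-codon occupancy
  `occ(c) = mean over occurrences of (count / gene-mean density)` rescaled to
  mean 1 over the 61 sense codons, KO/WT occupancy ratios, meta-codon
  profiles, per-gene tracks, and translation-efficiency (TE) gene sets.
* **Codon-bias statistics** (`stallkit.codonbias`): codon usage against a
  global background, within-amino-acid-family skew
  `r_set(c) − r_background(c)` with `r(c) = f(c)/Σ_family f`, the U/A- vs
  C/G-rich Leu/Ser codon classes, and dipeptide enrichment.
* **Closed-form assays** (`stallkit.assays`): Sanger misincorporation
  `100·T/(C+T)` with water-control subtraction, periodate-protection qPCR
  charged fraction `2^(−ΔΔCt)`, relative expression `2^(−ΔΔCt)`, Pearson
  chi-square goodness of fit against Mendelian ratios, Fisher exact
  comparison of knockout proportions across Gcn2 backgrounds, and
  densitometry normalization.
* **Synthetic data** (`stallkit.synthetic`): first-class generators for every
  input above, encoding the study conditions — 26 Ser/Leu substrate
  isodecoders over 9 anticodons, the knockout depletion profile (4-fold for
  Leu-UAA-2, 1.5-fold for four others), stall-codon dwell models, and a
  dihybrid-cross cohort model whose viabilities are calibrated to 13%/22%
  Thumpd1-null offspring by Gcn2 stratum.

## Worked example

```python
import pandas as pd
import stallkit as sk
from stallkit.synthetic import DEFAULT_ADAPTER, AcetylationProfile

# 26 substrate isodecoders over 9 anticodons, plus 10 decoys
ref = sk.make_trna_reference(seed=1, n_decoys=10)
profile = AcetylationProfile.default(ref)

pileups = {}
for name, seed in (("reduced", 3), ("mock", 4)):
    raw = sk.simulate_ac4cseq_reads(ref, profile, name, depth=1000, seed=seed,
                                    adapter=DEFAULT_ADAPTER,
                                    umi_5p_len=6, umi_3p_len=3)
    clean = sk.preprocess_reads(raw, DEFAULT_ADAPTER, umi_5p_len=6, umi_3p_len=3)
    alns = sk.align_ungapped(clean, ref)
    pileups[name] = sk.build_pileup(alns, clean, ref)

sites = sk.call_sites(pileups["reduced"], pileups["mock"], ref)
print(sites[sites.passes][["ref_id", "pos", "net_rate",
                           "stop_fraction", "is_ccg"]].head())
```

prints exactly the 26 substrate C12 sites (0-based position 11), e.g.:

```
   ref_id  pos  net_rate  stop_fraction  is_ccg
Leu-AAG-1   11  0.434586       0.333667    True
Leu-AAG-2   11  0.493719       0.336336    True
Leu-AAG-3   11  0.491535       0.329329    True
Leu-CAA-1   11  0.481253       0.312312    True
Leu-CAA-2   11  0.468278       0.320000    True
```

`net_rate` is the mock-subtracted C→T misincorporation rate (stoichiometry
times chemistry), `stop_fraction` the share of cDNAs terminating adjacent to
C12 — higher for Leu than Ser genes under the default chemistry — and
`is_ccg` the 5'-CCG-3' consensus flag. Running the tRNA-seq arm of the
pipeline (2 replicates × 200,000 reads per condition) and the differential
test ranks the depleted isodecoders first:

```
  gene_id    log2fc  p_value  p_adjusted
Leu-UAA-2 -1.885951 0.000351    0.004559
Leu-AAG-3 -0.482756 0.001583    0.006859
Ser-AGA-3 -0.458067 0.001395    0.006859
Leu-UAA-3 -0.451868 0.000334    0.004559
Ser-UGA-4 -0.450622 0.001301    0.006859
```

so the recovered Leu-UAA-2 depletion is `2^1.886 ≈ 3.7`-fold on the
proportion scale (the injected 4-fold drop, slightly compressed by
renormalization over the tRNA pool).

A command-line surface mirrors the library: `stallkit simulate
<reference|ac4c|trnaseq|transcriptome|footprints|qpcr|cohort|sanger>`,
`stallkit ac4c-call`, `stallkit trna-quant`, `stallkit trna-diff`,
`stallkit ribo-occupancy`, `stallkit metacodon`, `stallkit te`,
`stallkit codon-bias`, and `stallkit assay <...>`. See `stallkit --help`.

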