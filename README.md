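# cernet

**lncRNA-centred competing-endogenous-RNA (ceRNA) network inference for
two-group expression cohorts.**

Long non-coding RNAs can act as molecular sponges: by carrying binding
sites for the same microRNAs as a protein-coding gene (PCG), a lncRNA
competes for the shared miRNA pool and thereby de-represses the PCG. The
signature of such a circuit in expression data is a positive lncRNA–mRNA
correlation combined with negative correlations of both transcripts with
the shared miRNA. `cernet` implements the full discovery chain used in
case/control transcriptome studies (e.g. psoriatic vs healthy skin
biopsies profiled by RNA-seq and small RNA-seq), starting from expression
matrices:

1. **Differential expression** — counts are normalized by
   median-of-ratios size factors and tested with a negative-binomial Wald
   test; miRNA TPM with a Wilcoxon rank-sum test. A feature is called DE
   when its Benjamini–Hochberg adjusted *p* < .05 **and**
   |log₂ fold change| ≥ 2.
2. **Co-expression network** — Pearson correlation across samples, soft
   thresholded as *a₍ᵤᵥ₎ = |r₍ᵤᵥ₎|^β* with β chosen by scale-free-topology
   fit; edges kept when *a₍ᵤᵥ₎* > 0.02 and at least one endpoint is a
   lncRNA, with DE-lncRNA-anchored subnetwork extraction.
3. **miRNA target scanning** — Smith–Waterman complementarity alignment
   of each miRNA against lncRNA full-length and mRNA 3′UTR sequences
   (match +5, G:U wobble +1, mismatch −3, gaps −9/−4, seed positions 2–8
   scaled ×4, score cutoff 140), with canonical seed-class annotation
   (8mer / 7mer-m8 / 7mer-A1 / 6mer).
4. **ceRNA triplet inference** — a (lncRNA, miRNA, mRNA) triplet is
   admitted when (1) both miRNA–target arms have a scan hit supported by
   the interaction whitelist, (2) the lncRNA and mRNA share the miRNA,
   (3) both correlate negatively with it, and (4) positively with each
   other (Pearson on log₂(x+1), two-sided *p* < .05). Triplets assemble
   into a tripartite network; 3-node motifs can be extracted around an
   anchor gene (e.g. STAT1).
5. **Enrichment** — hypergeometric over-representation against GMT gene
   sets and preranked GSEA on the log₂-fold-change ranking.

Because the original cohorts and interaction databases are external, the
package ships a first-class **synthetic cohort generator** that plants DE
features, block co-expression, real binding sites in the sequences, and
ceRNA circuits with known ground truth — so the entire chain is testable
end to end.

## Worked example

```python
from cernet.synthdata import CohortConfig, generate_cohort, write_fixture
from cernet.pipeline import PipelineConfig, run_pipeline

cohort = generate_cohort(CohortConfig(seed=7))        # 300 mRNA, 80 lncRNA,
write_fixture(cohort, "cohort7")                      # 60 miRNA, 50 vs 50
cfg = PipelineConfig.for_fixture("cohort7", "results7", seed=7,
                                 anchors=["PCG0183"])
result = run_pipeline(cfg)
print(result.log["stages"]["cerna"])
```

prints

```
{'n_triplets': 10, 'n_lncrna': 10, 'n_mirna': 10, 'n_mrna': 10, 'n_edges': 20}
```

i.e. ten triplets survived all four criteria, forming a tripartite
network of 10 lncRNAs, 10 miRNAs and 10 mRNAs joined by 20
lncRNA–miRNA / miRNA–mRNA edges. The triplet table
(`results7/triplets.tsv`) carries the three correlations per circuit:

```
lncrna_id mirna_id mrna_id  r_lnc_mrna  r_mir_lnc  r_mir_mrna
  LNC0002  MIR0018 PCG0183    0.930603  -0.748870   -0.760125
  LNC0013  MIR0002 PCG0054    0.953514  -0.852947   -0.839331
  ...
```

— strongly positive lncRNA–mRNA coupling with both arms anti-correlated
with the shared miRNA, exactly the ceRNA signature. On this cohort all
10 planted circuits are recovered with no false positives. The same
pipeline is available from the shell:

```bash
cernet synth --out cohort7 --seed 7
cernet run --config pipeline.yaml --seed 7
```

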