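# atacmotif

From chromatin-accessibility counts to transcription-factor motif
activities.

`atacmotif` is a reusable, tested implementation of the analysis chain
used to study regulatory change between two cell states with ATAC-seq —
the motivating setting is postnatal pancreatic-islet maturation, where
accessible chromatin sites (ACS) in immature (P10) and mature (adult)
rat islets are compared to find the transcription-factor motifs that
drive sites to open or close.  It is aimed at computational biologists
who have peak regions, fragment intervals (or a count table), motif
matrices and a gene fold-change table, and want the downstream
statistics without re-assembling five tools.

The pipeline:

1. **Quantify** — each sequenced fragment implies two Tn5 insertion
   events (its ends); insertions are counted per ACS per sample.
2. **Differential accessibility** — negative-binomial counts with TMM
   normalization, a common dispersion φ (variance μ + φμ²) estimated by
   conditional maximum likelihood, an exact conditional test per site,
   BH adjustment, and Up/Down/Stable classes at p < 0.05, FDR < 0.2.
3. **Motif scan** — JASPAR PFMs become log-odds PSSMs; p-values come
   from the exact null score distribution (sparse DP over attainable
   scores, equal to exhaustive enumeration); both strands are scanned at
   p ≤ 1e-4 into a binary ACS × motif match matrix N.
4. **Enrichment** — preranked GSEA of ACS ranked by log2 fold-change
   against each motif's match set: weighted KS enrichment score,
   permutation null, NES, BH-adjusted p.
5. **Activity** — the elastic net `log2FC ~ N β` (cyclic coordinate
   descent, 10-fold cross-validated λ, α = 0.5): the coefficient β_m is
   motif m's *activity*; β < 0 is the repressor-like, closing-site
   signature (e.g. SCRT1 in maturing islets).
6. **Integrate** — nearest-TSS gene links with TSS (±1 kb) / proximal
   (1–10 kb) / distal classes, enhancer/repressor calls by fold-change
   concordance, hypergeometric motif-target enrichment, and Pearson
   comparison of fold-change signatures.

A synthetic-data module generates complete studies with known ground
truth (planted motif instances, true activities, NB counts, concordant
gene tables), so every stage is testable without downloading anything.

## Worked example

```python
from atacmotif import DifferentialAccessibility, MotifActivityModel, PrerankedGSEA
from atacmotif.simulate import simulate_study
from atacmotif.motifscan import build_match_matrix, empirical_background, pfm_to_pssm
from atacmotif.enrichment import sets_from_match_matrix

study = simulate_study(n_acs=1000, n_motifs=20, n_active=6, seed=42)

diff = DifferentialAccessibility(study["counts"],
                                 study["counts"].attrs["groups"]).fit()
print(diff.summary())

bg = empirical_background(s for _, s in study["sequences"])
pssms = [pfm_to_pssm(p, background=bg) for p in study["pwms"]]
mm = build_match_matrix(study["sequences"], pssms, threshold_p=1e-4)

activity = MotifActivityModel(mm, diff.table["log2fc"], alpha=0.5).fit(seed=0)
print(activity.summary())

gsea = PrerankedGSEA(diff.significant()["log2fc"],
                     sets_from_match_matrix(mm)).fit(n_perm=2000, seed=0)
print(gsea.summary())
```

prints

```
Differential accessibility (NB exact test, common dispersion)
  sites: 1000   contrast: adult vs P10
  common dispersion: 0.2024
  TMM factors: P10_1=1.028, P10_2=1.041, P10_3=1.033, adult_1=0.972, adult_2=0.971, adult_3=0.958
  thresholds: p < 0.05, FDR < 0.2
  Up: 3.3%   Down: 3.5%   Stable: 93.2%

Motif activity (elastic net on motif-match matrix)
  ACS: 1000   motifs: 20   alpha: 0.5   lambda (min): 0.0276
  selected motifs (activity != 0): 10
    motif_009: activity=+0.542
    motif_011: activity=-0.433
    motif_019: activity=+0.371
    motif_004: activity=-0.315
    motif_007: activity=-0.277
    motif_017: activity=+0.271
    ...

Preranked GSEA: 20 sets, ranking of 68 items, 2000 permutations
  significant at adj_p < 0.05: 5
    motif_011: NES=-2.86 adj_p=0.0056
    motif_007: NES=-2.63 adj_p=0.0056
    motif_004: NES=-2.65 adj_p=0.0056
    motif_009: NES=+2.62 adj_p=0.0056
    motif_019: NES=+1.93 adj_p=0.04
```

Reading the output: the generator planted six active motifs in this
study — motif_004 (−0.62), motif_007 (−0.48), motif_009 (+0.79),
motif_011 (−0.78), motif_017 (+0.36), motif_019 (+0.81).  The simulated
counts recover the dispersion that generated them (0.20), the six
largest |activity| estimates are exactly the six planted motifs with the
correct signs, and the enrichment analysis independently flags five of
them — negative NES for the motifs enriched in closing sites, positive
for the opening ones.

The same stages are available from a shell:

```bash
atacmotif run-all --fixture --outdir results --seed 0
atacmotif diff --counts counts.tsv --samples samples.tsv --p 0.05 --fdr 0.2 --out diff.tsv
atacmotif scan --fasta acs.fasta --motifs jaspar.pfm --out matrix.tsv
atacmotif activity --matrix matrix.tsv --logfc diff.tsv --alpha 0.5 --out activity.tsv
```

`run-all` executes simulate → quantify → diff → scan → enrich →
activity → integrate into one directory with a manifest (seed, applied
thresholds, per-file checksums, run hash); reruns with the same config
and seed are byte-identical, and `--resume` recomputes only missing
stages.

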