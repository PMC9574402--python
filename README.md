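# apmsquant

Label-free quantification and interactome inference for affinity-purification
mass spectrometry (AP-MS), built for bait-versus-control co-purification
studies such as native neurotransmitter-receptor pull-downs (e.g. GABA_A
receptor subtypes purified from brain plasma membrane with subunit-specific
antibodies against non-immune IgG controls).

## What it computes

Starting from peptide-spectrum-match (PSM) tables — one row per identified
spectrum with run, condition, protein, peptide, modifications, intensity —
the pipeline produces:

1. **SI_GI quantification.** Per run, a protein's spectral index is the sum
   of its PSM intensities; the *spectral index normalized to global
   intensity* is

   SI_GI(p) = Σ_i I_i(p) / Σ_q Σ_i I_i(q),

   a compositional abundance in [0, 1] whose per-run values sum to 1, making
   amounts comparable within and between runs.

2. **Enrichment vs IgG control.** For every protein seen in a bait
   replicate, Welch's unequal-variance t-test of bait SI_GI values against
   control values (undetected entries zero-filled), two-tailed, raw
   per-protein p at α = 0.05; plus a detected-in-all-replicates flag. The
   `enriched` flag restricts significance to the bait direction, since a
   strong pull-down compositionally depletes everything else.

3. **Stoichiometry summaries.** Subunit-class fractions of summed mean
   SI_GI over the significant class members (so shares total 100%);
   relative-abundance pies with sub-2% slices merged into "Other"; and
   pooled-variance unpaired t-tests between purifications, computable
   directly from printed mean ± SEM summaries.

4. **Phosphosite occupancy.** Localized phospho-peptides are mapped onto
   reference-protein coordinates (site labels like S408); occupancy at a
   site is (phospho PSMs at the site) / (all PSMs covering the site) per
   run, compared across conditions with the unpaired t-test.

5. **Network & PCA.** Interaction networks over proteins passing the triple
   filter (significant, detected in all replicates, mean SI_GI > 0.0005)
   using local interaction/GO snapshot tables; replicate-level PCA of
   z-transformed SI_GI profiles over the significantly enriched
   all-replicate proteins.

6. **Synthetic experiments.** A ground-truth generator emulating the study
   design (5 bait + 5 IgG replicates, graded bait complex, fold-enriched
   interactors, log-normal intensities, per-run dropout, planted phosphosite
   occupancies) so every stage is testable without raw data.

## Worked example

```sh
apmsquant simulate --seed 3 --out demo        # psms.tsv, reference.fasta, truth.tsv
apmsquant run --psms demo/psms.tsv --fasta demo/reference.fasta --out demo/out
apmsquant report --out demo/out
```

prints (numbers from this exact command):

```
apmsquant report (version 0.1.0)
  Gabra1-IP: 139 proteins tested, 122 significant, 103 significant in all replicates
  PCA over 103 features: PC1/PC2 variance 32.13%, 27.62%
```

139 proteins were seen in at least one bait replicate; 122 reach p < 0.05
against the IgG controls. Most of those are *depleted* background (the bait
complex and interactors crowd them out of the bait-run composition) — the
`enriched` column in `demo/out/enrichment_Gabra1-IP.tsv` marks the 38
bait-elevated calls: the 9 receptor-complex subunits and 29 of the 30
planted interactors (one interactor dropped out of a bait replicate and
lands at p = 0.0502). 103 significant proteins were also detected in all
five bait replicates and become PCA features. Stage outputs
(`quant/si_gi.tsv`, `enrichment_*.tsv`, `pie_*.tsv`, `network_*.tsv`,
`pca_*.tsv`, `report.json`) are plain TSV/JSON.

The same analyses are available as library calls:

```python
from apmsquant import (SimulationConfig, simulate_experiment,
                       build_quant_matrix, enrich_proteins, score_recovery)

exp = simulate_experiment(SimulationConfig(seed=3))
matrix = build_quant_matrix(exp.psms)          # columns sum to 1
records = enrich_proteins(matrix, "Gabra1-IP") # Welch t per protein
print(score_recovery(exp.truth, records))      # sensitivity / FPR vs truth
```

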