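# ribomethdiff

Differential analysis of ribosomal RNA 2′-O-methylation from RiboMeth-seq
fragment end counts.

2′-O-methylation of the ribose, deposited by fibrillarin under the guidance
of box C/D snoRNAs, is the most abundant modification of human rRNA (104
catalogued sites on 18S/5.8S/28S). Because the methyl group protects the
phosphodiester bond 3′ of the modified ribose from alkaline hydrolysis,
RiboMeth-seq infers the methylated fraction of molecules at a site from the
local depletion of fragment ends at that bond. `ribomethdiff` is for groups
studying methylation *plasticity* — e.g. how proliferating (P), quiescent
(Q) and stress-induced senescent (SIPS) primary fibroblasts from several
donors differ — starting from per-position end-count tables (alignment is
upstream and out of scope).

## What it computes

- **RMS score** per site and sample: `score = clip(1 − n_site / n̄_flank, 0, 1)`
  with a ±2-bond flank window (catalogued neighbour sites excluded from the
  flanks), after summing technical replicates; 0 = unmethylated,
  1 = fully methylated. Low-coverage sites are masked, not guessed.
- **Donor-blocked differential testing**: per site, the additive two-factor
  fixed-effects model `y = μ + donor + state + ε` with
  `F = MS_state / MS_residual` on `(a−1), (a−1)(b−1)` degrees of freedom,
  Benjamini–Hochberg q-values across sites (default cutoff q < 0.1), and
  Tukey studentized-range pairwise state contrasts using the blocked model's
  residual mean square. Sites are classified as `variable`,
  `constitutive_high` (mean score > 0.9) or `substoichiometric_stable`.
- **Sample embedding** (t-SNE, PCA fallback) of the score matrix, before and
  after *eliminating the donor factor* (donor-mean centring), plus a
  silhouette-based optimal cluster count.
- **Downstream quantification**: ΔCt relative snoRNA expression (vs 5.8S
  rRNA, P-state mean pinned to 1), northern band normalization (loading
  control SNORD57), Pearson/Spearman correlation of site methylation with
  guide-snoRNA expression, and pre-rRNA processing ratios (47S:28S, 21S:47S,
  18S-E:47S, 30S:41S, 30S:47S, 41S:47S) with two-tailed one-sample t-tests
  against 1.
- **A ground-truthed simulator** of the whole measurement process (Poisson
  end counts with methylation-dependent cleavage protection, donor batch
  offsets, planted state effects, technical replicates, coupled snoRNA
  expression, band intensities) so every stage is testable end to end.

## Worked example

```python
import ribomethdiff as rmd
from ribomethdiff.stats import fit_blocked_anova, bh_adjust, tukey_pairwise

catalog = rmd.default_catalog()            # 104 sites
design = rmd.default_design()              # 3 donors x 3 states x 2 tech reps
truth = rmd.build_truth(catalog, design, seed=1, **rmd.growth_arrest_preset())
profiles = rmd.simulate_end_counts(truth, rmd.FragmentationParams(seed=1), catalog)
merged = rmd.merge_technical_replicates(profiles, design)
scores = rmd.compute_rms_scores(merged, catalog)

results = fit_blocked_anova(scores, design)
q = bh_adjust([r.p_state for r in results])
hits = sorted(r.site for r, qv in zip(results, q) if qv < 0.1)
print(len(catalog), rmd.site_distance(catalog, "LSU-G3723", "LSU-C3680"))
print(hits)
print(round(tukey_pairwise(scores, design, "LSU-G3723")[("Q", "SIPS")], 5))
```

prints

```
104 43
['LSU-A2388', 'LSU-G1303', 'LSU-G2411', 'LSU-G3723', 'LSU-G4588',
 'SSU-C1272', 'SSU-C797', 'SSU-G436', 'SSU-G867']
0.00045
```

i.e. the catalog holds 104 sites, the two senescence-linked sites LSU-G3723
(guide SNORD87) and LSU-C3680 (guide SNORD88A/B/C) are 43 nt apart, the
donor-blocked test recovers exactly the nine planted differential sites at
q < 0.1, and the Q-vs-SIPS Tukey contrast at LSU-G3723 is significant
(P ≈ 4.5 × 10⁻⁴).

The same pipeline is available from a shell:

```sh
ribomethdiff all --out-dir run1 --seed 1        # simulate + score + diff + quant
ribomethdiff score --out-dir run1               # individual stages
```

Each run directory holds plain TSV tables and a `manifest.json` with the
config hash and seed; identical config and seed reproduce the TSVs
byte-for-byte.

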