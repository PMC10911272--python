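# Methods

## Scope and data model

The pipeline starts from per-position fragment end-count tables (one TSV per
sequencing library, columns `subunit  position  count5p`), a site catalog of
104 human rRNA 2′-O-methylation positions, and a study design of donors ×
growth states × technical replicates. Read trimming and alignment are
upstream of this package.

Coordinates are 1-based on the mature rRNA species (18S = 1869 nt,
5.8S = 157 nt, 28S = 5070 nt). A site at position *p* protects the bond
between positions *p* and *p + 1*; end counts are indexed by bond
(1 … L − 1). Site labels follow the field convention `SSU-`/`LSU-` +
nucleotide + position (18S/28S); 5.8S sites keep the species name as prefix.
The bundled catalog is a documented, partly schematic fixture: only the
positions and guide assignments printed in the underlying study (e.g.
SNORD87 → LSU-G3723, SNORD88A/B/C → LSU-C3680, SNORD57 → SSU-A99) are real;
the remaining entries exist so the pipeline runs at the catalogued total of
104 sites and carry invented `SNORD2xx` guide names precisely so they cannot
be mistaken for biological annotations.

## RMS scoring

For site bond *b* with count `n_b`, the score is

    score = clip(1 − n_b / mean(flank counts), 0, 1)

with flanks the ≤ 2w bonds within ±w of *b* (default w = 2), excluding bonds
that are themselves catalogued sites: a protected neighbour would deflate
the local cleavage baseline and inflate scores at clustered sites. Under
the measurement model below, E[n_site]/E[n_flank] = 1 − m·π, so with full
protection (π = 1) the score is an asymptotically unbiased estimator of the
methylated fraction m.

Numerical conventions:

- Technical replicates are merged by summing counts before scoring
  (score-level averaging is the other defensible choice; count summing keeps
  the Poisson statistics exact).
- If the flank mean falls below `min_flank_mean` (default 10 counts, a QC
  threshold, configurable) or a site has no eligible flank bond (terminal
  positions), the score is missing (NaN) and masked — never extrapolated.
- Sites near a reference end are scored from the one-sided flanks that
  exist; a site at the last position (no 3′ bond) is masked.
- Scores are invariant to uniform rescaling of a library's counts
  (sequencing depth) and monotonically decreasing in the site-bond count.

## Differential testing

Each site's merged scores over the donor × state grid (default 3 × 3, one
biological sample per cell) are fitted with the additive two-factor
fixed-effects model y = μ + donor + state + ε. Blocking on donor removes
the dominant inter-individual batch effect of primary cells before the
state comparison. For the balanced design the decomposition is exact:

    F_state = (SS_state / (a−1)) / (SS_resid / ((a−1)(b−1)))

with a states and b donors. Only balanced complete crossings are accepted;
sites with missing cells are skipped with a reason rather than silently
switching sums-of-squares types. A residual SS below 1e-12 of the total is
treated as zero: with a nonzero state effect the site is flagged
`zero_residual` and reported at p = 0; with no effect, F = 0 and p = 1.

Omnibus p-values are adjusted with the Benjamini–Hochberg step-up
(q-values; discovery cutoff q < 0.1). Missing p-values propagate as missing
and do not count toward the number of tests. Pairwise state contrasts use
Tukey's studentized-range test with the blocked model's MS_residual and
(a−1)(b−1) degrees of freedom; Tukey results are meant to be read after a
significant omnibus test. Sites are classified as `variable` (q below
cutoff), otherwise `constitutive_high` if the grand mean score exceeds 0.9,
otherwise `substoichiometric_stable`.

"Eliminating the donor factor" for visualisation subtracts each site's
donor-level mean and adds back the grand mean (NaN-aware, idempotent,
mask-preserving). Embeddings use t-SNE (perplexity 3 for nine samples,
clamped below n; fixed seed; PCA initialisation) with a PCA fallback for
very small n. The silhouette-optimal cluster count scans seeded k-means
over k = 2…5, breaking ties toward smaller k; a best silhouette ≤ 0.5 is
flagged as weak structure, following the usual silhouette-width reading
that values in that range may reflect artificial partitions (an
unstructured blob partitions at ≈ 0.3–0.45, separated groups well above
0.7).

## Downstream quantification

- **qPCR**: ΔCt = Ct_target − Ct_reference with 5.8S rRNA as reference and
  assay efficiency fixed at 2. Linear abundances 2^−ΔCt are divided by the
  arithmetic mean of the P-state samples, so the P-group mean is exactly 1
  per target; adding a constant to both Ct values of a sample cancels.
  Tests are run on linear-scale normalized values.
- **Northern blots**: per-lane division by a loading-control band (SNORD57
  for snoRNA blots); lanes with unusable control signal are excluded with a
  warning; P normalization as above.
- **Correlation**: Pearson r (Spearman as secondary) between a site's scores
  and its guide snoRNA's expression across shared samples; guide groups that
  the assay cannot resolve (SNORD88A/B/C) are one aggregate series; fewer
  than 3 pairs yields an `insufficient_data` record, not an error.
- **Processing ratios**: per-sample ratios of pre-rRNA intermediates
  (47S:28S, 21S:47S, 18S-E:47S, 30S:41S, 30S:47S, 41S:47S; 30S and 41S are
  specific to processing pathways B and A respectively). Normalization to P
  is donor-paired when every donor contributes a P sample (each sample is
  divided by its donor's P ratio), else by the P mean. Q and SIPS groups are
  tested with two-tailed one-sample t-tests against 1; a zero-variance group
  is an explicit error, not ±∞.

## Simulator

The generator emulates alkaline hydrolysis followed by size selection and
single-end sequencing, at the level the scoring consumes: per-bond end
counts. Count at bond b ~ Poisson(λ · (1 − m_b·π)) independently per
library, with λ the expected cleavage events per unmethylated bond
(default 3000), π the protection of a fully methylated site (default 1),
and m_b the site's methylated fraction (0 off catalogued sites). The truth
decomposes additively, m = clip(base + donor_offset + state_offset, 0, 1):
donor offsets are drawn once per (site, donor) from N(0, donor_sd²), state
offsets are fixed so the planted differential sites are unambiguous, and
technical replicates share m exactly. All randomness flows from one root
seed via named substreams, so outputs are bit-identical across runs.

The default **growth-arrest scenario** places 95 sites at base 0.97 and
plants substoichiometric bases (0.60–0.90) with state offsets of 0.04–0.12
at nine sites — SSU G436/C797/G867/C1272 and LSU G1303/A2388/G2411/G3723/
G4588 — such that P differs from the arrested states at eight of them and
only LSU-A2388, LSU-G3723 and LSU-G4588 differ between Q and SIPS;
donor_sd = 0.01. At λ = 3000 per library (two replicates merged) the
per-score counting noise is ≈ 0.007, so planted effects are comfortably
detectable while null sites stay calibrated. The **donor-dominant
scenario** keeps the same planted truth but raises donor_sd to 0.06, the
regime in which inter-donor variability dominates the 104-site profile and
raw embeddings cluster by donor until the donor factor is eliminated —
under the default scenario's small batch effects, the strong P-versus-
arrested signal, not the donor, dominates sample distances, which is why
the donor-clustering demonstrations use this scenario.

Guide-snoRNA expression is simulated per variable site as
coupling·m + (1 − coupling)·mean(m) + N(0, noise_sd²) (defaults 0.9 and
0.01), emulating the co-regulation of a site with its limiting guide.
Band intensities are state means times mean-one lognormal noise with a
given CV; the default state means encode a 30S:41S increase in Q/SIPS
(pathway-B preference) and reduced 21S and 18S-E in SIPS (slowed late SSU
processing).

What the simulator does **not** model — and what passing tests therefore do
not establish about real data: sequence- or structure-dependent cleavage
bias, fragment size selection effects on per-bond end frequencies, ligation
bias, partial protection heterogeneity across sites, alignment artefacts at
clustered or repeated positions, and any coupling between snoRNA abundance
and methylation beyond a fixed linear term.

## Problem sizes and determinism

The test suite and the acceptance script run the full design (104 sites,
18 libraries, ≈ 7,100 bonds per library). Calibration checks use 2,000
simulated null tables for the type-I rate (exact binomial 99% band around
α = 0.05) and 200 full-pipeline replicates for the realized false-discovery
proportion at q < 0.1 (mean ≈ 0.085 against the BH bound of
(95/104)·0.1 ≈ 0.091); both complete in seconds. Every stochastic routine
takes an explicit seed, and pipeline runs write a manifest (config, hash,
seed, per-stage counts) from which all outputs are regenerable.

## Known limitations

- The scoring formula is the simple flank-normalized protection score; the
  window (±2) and the coverage threshold are configurable but the
  score-variant family is fixed.
- Only balanced complete donor × state crossings are testable; unbalanced
  studies need a different (e.g. mixed-model) engine.
- The catalog's non-printed coordinates are placeholders (see above); users
  with a curated catalog should load their own TSV.
- Tukey contrasts assume the blocked model's homoscedastic residuals; with
  2–4 residual df the studentized-range tail is conservative for very small
  effects.
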