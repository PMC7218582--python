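# Methods

This note documents the models behind `lbqc`: the cleaning workflow itself,
the statistical contaminant classifier, the synthetic-cohort generator used
to validate both, and the numerical choices that a user changing defaults
should understand.

## The cleaning workflow

The pipeline operates on an OTU × sample count table with per-sample
metadata (role: specimen / NTC / mock; qPCR biomass in 16S rRNA gene
copies/μl; age at collection; run, plate well, repeat group, storage
buffer, extraction kit). Stages run in a fixed order:

1. **Spurious-OTU removal.** An OTU is spurious iff its grand total across
   *all* samples — specimens of every biomass plus controls — is < 5 reads.
   Totals are computed before any sample exclusion, so reads in
   soon-to-be-gated specimens still count; `denoise_and_gate` enforces this
   order and a test pins it. The boundary is strict: a total of exactly 5
   survives.
2. **Biomass gate.** Specimens are retained iff copies/μl > 500 (strict;
   exactly 500 is excluded). NTCs and mocks are never gated — they are
   controls, not specimens. Specimens without a biomass measurement are
   excluded and listed separately rather than silently dropped.
3. **Contaminant identification and subtraction** (below), performed on
   proportions computed from the denoised, gated table.

## Contaminant identification

Two routes, sharing one removal operator:

* **NTConly**: flag any OTU with count > 0 in at least one NTC *and* at
  least one specimen. An OTU present only in NTCs is not flagged (there is
  nothing to remove from specimens).
* **Statistical classifier**: per OTU,
  * *frequency evidence* uses the specimen columns where the OTU frequency
    and the measured concentration are both positive (at least 4 required,
    otherwise the evidence is missing). In (ln c, ln f) space two
    one-parameter least-squares fits are compared — ln f = β₀ versus the
    fixed-slope contaminant model ln f = −ln c + β₀′ — through the F-ratio
    tail p = Pr(F₍n−1,n−1₎ ≥ SSR₀/SSR₁). The fixed slope makes the test
    invariant to rescaling all concentrations (units cancel into β₀′). A
    numerically perfect contaminant fit (SSR₁ ≤ 10⁻¹² SSR₀) returns p = 0.
  * *prevalence evidence* is the one-sided Fisher exact (hypergeometric
    tail) test of presence enriched in NTCs versus specimens.
  * the *combined* score is Fisher's method, p = Pr(χ²₄ ≥ −2(ln p_f +
    ln p_p)), with pass-through when one input is missing. Both inputs are
    conservative under their nulls (the F-ratio concentrates below 1 for
    biomass-independent OTUs; the exact test is discrete), so the combined
    score is conservative too.
  * decision rule: contaminant iff p < threshold, default 0.1, strict.
    The threshold is a named parameter in the library, CLI and pipeline
    config because no principled universal value exists.

**Subtraction.** For each flagged OTU j with maximum NTC proportion m_j,
specimen proportions become q_ij = max(0, p_ij − m_j); unflagged OTUs are
untouched. By default each specimen column is then re-closed to sum 1
(ratios among survivors preserved); `renormalize=False` keeps the raw
subtracted values (the resulting table is marked unclosed) for shift
reporting. A column emptied by subtraction is flagged degenerate and left
all-zero. All NTC columns form a single control pool by default.

`shift_report` summarizes the effect per genus (member-OTU proportions
summed): the fraction of initially-positive specimens whose post-method
proportion is exactly zero ("complete removal") plus mean before/after
abundances.

## QC statistics

* **Shannon diversity** uses the natural logarithm, H = −Σ p ln p over
  positive entries; count vectors are closed internally; an all-zero vector
  is an error, and a single-OTU sample scores 0.
* **Repeat reproducibility** is the squared Pearson correlation of two
  repeats' proportion vectors over the union of OTUs (zeros included) —
  identical to the OLS-with-intercept coefficient of determination and
  symmetric in the pair, which the phrase "linear regression R²" alone
  would not guarantee. Zero-variance profiles yield an explicit
  `undefined` flag, never a silent NaN. A repeat group of size k produces
  k(k−1)/2 records.
* **Correlations** of biomass with age, reads and diversity are Pearson on
  ln(copies/μl + 1) (Spearman available via flag); incomplete records are
  dropped pairwise, and fewer than 3 pairs or zero variance gives an
  undefined (None) result.
* **Beta diversity**: Bray-Curtis on proportions (counts accepted with a
  warning). PCoA is Gower double-centering with eigendecomposition;
  negative eigenvalues are dropped with their magnitudes reported — no
  Cailliez/Lingoes correction, the simplest defensible policy. PERMANOVA
  partitions Σd²/n and estimates p as (1 + #{F_perm ≥ F_obs})/(1 + n_perm)
  with a seeded generator, so p is never exactly zero and is reproducible.
  Complete-linkage clustering delegates to scipy's implementation; cut
  heights 0.99 (primary) and 0.90 (secondary) are defaults on the
  Bray-Curtis dendrogram scale.
* **Compositional tools**: count-based Bayesian-multiplicative zero
  replacement (per column, zeros become δ = α/(N + αD) with α = 0.5 by
  default; nonzero parts rescaled so ratios are preserved), ilr pivot
  coordinate z = √((D−1)/D)·ln(x_pivot/gm(others)), and one-way ANOVA with
  Tukey HSD simultaneous 95% intervals; the studentized-range quantile
  comes from scipy's numerical CDF inversion and is cached (tolerance of
  the inversion ≈ 1e−6). Significance of a pair means its interval
  excludes zero.
* **Mock evaluation** matches OTUs to reference taxa by genus+species
  through the taxonomy map; grouped reference entries
  ("Staphylococcus aureus/epidermidis") match any member species, and a
  genus-only match is accepted where the reference gives no species. The
  background proportion is the summed abundance of OTUs matching no
  reference taxon; expected-but-undetected taxa report observed 0 (log2
  ratio −∞), not an error.

## The synthetic cohort generator

`generate_cohort(SimConfig)` produces a count table, metadata, taxonomy and
a `SyntheticTruth` labelling every OTU's origin (`true_taxon`,
`reagent_contaminant`, `spillover` = mock-community taxa, which reach
specimen/NTC wells only through well-to-well transfer, and `spurious`) and
every sample's latent state (true biomass B, mixing weight w, realized
spill-over fraction).

Per sample, the expected composition is

    profile = w·(kit-biased true composition)
            + (1−w)·(reagent background realization)
            + ε·(biomass-weighted mean profile of other wells on the plate)

closed to 1, with reads drawn multinomially at a lognormal depth.

* **Contamination mixture.** w = B/(B+κ): the reagent background behaves as
  a fixed pseudo-biomass κ (copies/μl equivalents), so its read share 1−w
  grows as specimen biomass falls — the simplest model with that
  qualitative behavior. κ is buffer-specific and calibrated so diluted
  mocks reproduce the observed background levels: with mock-high biomass
  2×10⁶ copies/μl and a 1-in-10⁴ dilution (mock-low B = 200),
  κ_stgg = 21.0 gives 21/221 ≈ 9.5% and κ_primestore = 3.05 gives ≈ 1.5%.
  Biological specimens additionally carry κ_specimen = 60 copies/μl of
  collection-matrix background (swab/skin/environment) on top of the
  buffer term; without it, gated specimens would be ~99.4% clean and the
  empirically observed signatures of low biomass — NTC-like diversity,
  depressed repeat reproducibility, co-clustering with NTCs — could not
  arise. NTCs have B = 0, hence w = 0: pure background.
* **Reagent background realization.** Each buffer has a base contaminant
  profile (Dirichlet over 20 kitome taxa, drawn once per cohort); each
  sequenced column draws its own realization ~ Dirichlet(25 × base),
  emulating aliquot/lot variability between library preparations. This
  draw is per column by design: technical repeats share the underlying
  specimen state (age, B, true composition, w) but see independent reagent
  aliquots, which is precisely why low-biomass repeats reproduce worse.
  Within-run repeats additionally share their spill-over rate and depth;
  between-run repeats redraw both.
* **True compositions.** Each specimen belongs to one of six
  dominance clusters (Moraxella, Corynebacterium, Haemophilus,
  Streptococcus, Staphylococcus, Dolosigranulum) and draws its composition
  from Dirichlet(0.04 + boost), where the boost (15, split across the
  dominant genus' OTUs) produces the strong single-genus dominance of
  infant nasopharyngeal profiles (Shannon ≈ 1 for clean high-biomass
  samples, versus ≈ 2.3 for the background profile).
* **Biomass vs age.** ln B = 4.5 + 1.0·ln(age+1) + N(0, 1.5); ages are a
  mixture of an early-life mass (25% uniform on 0–14 days) and a lognormal
  (median 90 days). These defaults put most first-two-weeks specimens
  below the 500 copies/μl gate while ~85% of older specimens pass.
  Reported copies/μl multiply B by lognormal(0, 0.2) qPCR-like noise; the
  exact B is kept in the truth object.
* **Kit lysis bias.** Gram-positive taxa are down-weighted before closure
  (multiplier 0.85 for the gentler kit, 0.5 for the harsher one), so
  gram-negative members of the mock are over-represented relative to
  theory.
* **Spill-over.** ε·(donor profile) with donors weighted by biomass share
  within the same 96-well plate, ε ~ Gamma(2, rate/2) around the default
  rate 0.002 — a free parameter; no quantitative spill-over rate is
  available to calibrate against.
* **Spurious OTUs.** Per sample, count ~ Poisson(λ₀(B+1)^−γ) with λ₀ = 4,
  γ = 0.15 (≈ 4 per NTC, ≈ 1 per high-biomass specimen); each spurious OTU
  carries 1–2 reads, appears in at most two samples, and always totals
  < 5 reads so the denoising rule removes it by construction.
* **Determinism.** One master seed; every sample's draws come from a
  sub-stream keyed by a CRC32 hash of its identifier, so a sample's data do
  not depend on cohort size or ordering, and equal seeds give bit-identical
  outputs.

**What the generator does not emulate**: read-level artifacts (chimeras,
index hopping, PCR-cycle effects), taxonomy misassignment, batch effects
beyond run-wise repeats, biomass-dependent sequencing depth (depth is
independent of B here), and cross-genus shared OTUs. Passing tests
therefore demonstrate that the pipeline recovers the *modeled* mechanisms —
biomass-scaled reagent contamination, spill-over, spurious rare OTUs —
not that it is robust to every failure mode of real amplicon data.

## Validation design

The acceptance suite checks, on ten cohorts at the default conditions
(~113 gated specimen repeats, 10 NTCs each): combined-classifier
sensitivity ≥ 0.8 with false-positive rate ≤ 0.05 at threshold 0.1, versus
the NTConly route's full sensitivity but materially higher false-positive
rate; both rates are computed over OTUs detected in at least one specimen,
since an OTU absent from specimens can neither corrupt nor be removed from
them. Directional findings (negative biomass–diversity correlation,
positive age–biomass correlation, lower repeat R² and more NTC
co-clustering below 500 copies/μl, STGG > Primestore mock backgrounds) are
asserted across all ten seeds. The PERMANOVA size check uses 1000
exchangeable datasets at 200 permutations each; the mock high-vs-low
separation test stratifies to a single buffer and kit (six replicates per
biomass level) so the lysis-bias nuisance factor does not inflate the
within-group spread. Exact operations (Bray-Curtis, Shannon, ilr, Fisher
tests, R²) are pinned to independent brute-force evaluations, and PCoA /
PERMANOVA / Tukey intervals are cross-checked against scikit-bio and
statsmodels.

## Known limitations

* The frequency model assumes the measured copies/μl is an unbiased
  concentration proxy; heavy qPCR noise (σ ≫ 0.2 on the log scale) will
  dilute frequency evidence toward the prevalence test.
* Max-proportion subtraction is deliberately aggressive for abundant
  contaminants and can zero a genuinely mixed OTU; the shift report exists
  to make that visible rather than to prevent it.
* With very few NTCs the prevalence test saturates (its minimum attainable
  p grows), and with none the statistical route refuses to run.
* Complete-linkage cut heights 0.99/0.90 are meaningful on the Bray-Curtis
  scale only; clustering other distances requires choosing new cuts.
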