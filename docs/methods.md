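# Methods

This note records the models, rules, and numerical choices behind `mrdflow`,
and what the synthetic validation does and does not establish.

## LAIP rules

- **Eligibility.** Only aberrant lineage markers (CD4, CD7, CD56, CD25) define
  a LAIP. The eligibility threshold is *inclusive*: expression ≥ 20% of AML
  cells at diagnosis qualifies. Inclusivity is forced by the packaged cohort
  itself — two patients carry a marker at exactly 20% that is counted in
  their published LAIP number — and the boundary convention is tested there.
- **Tracking marker.** The qualifying marker with maximal diagnostic
  expression. Ties (which do not occur in the packaged cohort) break by
  specificity, CD25 > CD56 > CD7 > CD4: CD25 and CD56 assessments are the
  most reliable against the molecular reference, CD4 the least. The rule is
  validated in aggregate — it reproduces the 33/59/11/11 split of
  partial-class samples across CD7/CD4/CD56/CD25 — not per patient, since the
  published table's per-patient marker highlighting is typographic.
- **Expression class.** Tracking expression ≥ 90% is *total* (LAIP-method
  only; the DfN filter would be a no-op), 20–90% *partial* (both methods run).
  The ≥ 90% boundary is likewise pinned by the cohort: exactly 4 patients
  (11 samples) classify as total.
- CD123 overexpression and asynchronous CD15/CD11b aberrancies are recorded
  but never eligible for tracking: CD123's background in leukemia-free marrow
  exceeds the interpretive threshold, and lineage aberrancies are the
  specific ones.

## Gating model

All fluorescence geometry lives on an asinh scale with cofactor 150; scatter
channels stay linear. The cofactor is a display-scale convention, not a claim
about any instrument: 150 puts autofluorescence (~40 a.u.) in the quasi-linear
region and stained signal (~1200 a.u.) around 2.8.

- **Doublets** (P1): a through-origin relation FSC-A = s·FSC-H is fitted
  robustly on each sample (s = median ratio); events outside 3 robust SDs
  (1.4826·MAD) of the ratio are flagged. A floor of 1e-6·s on the band width
  guards the degenerate zero-spread case.
- **Debris**: FSC-A < 30,000 and SSC-A < 40,000 (generator units). Flags are
  stored, never dropped, so preprocessing is auditable.
- **CD45⁺ leukocytes** (P2): cutoff = median + 3.5 robust SDs of the debris
  region's CD45. A robust rule, not a high percentile, because intact cells
  leak into the scatter-defined debris region at the fraction of a percent
  and an extreme percentile chases them. Fallback when the sample has no
  debris: the valley between the two dominant CD45 density modes.
- **Internal negative control** (C1): the CD45-brightest 4% of leukocytes
  with below-median side scatter. Purity matters more than size here: CD117⁺
  progenitors sit only ~1 asinh unit below lymphocytes in CD45, and 1%
  contamination of the control moves a 99th-percentile marker cutoff from the
  negative into the positive component.
- **Marker cutoffs**: 99th percentile of the control's transformed intensity
  (per sample, so follow-ups use their own internal control). Controls under
  100 events warn and fall back to a global percentile.
- **Blast gate** (P3): located from CD117⁺ CD45⁺ non-control seed events. The
  upper CD45/SSC edges use a one-sided robust rule (median + 4.5·1.4826·lower
  MAD) so CD117-dim tail events from mature populations cannot stretch the
  gate; lower edges are the 0.1% quantile with a 10% margin. A template fit
  fails when seeds are < 50 events or < 2% of leukocytes — a marrow without a
  discernible blast population cannot anchor a template (the packaged
  cohort's minimum diagnostic burden is 14%).
- **Phenotype gates** (P4–P8): axis-aligned quantile boxes (0.1–99.9% plus a
  10% margin) over *all* events inside P3 — not only the CD117⁺ seeds — so
  that partial or absent expression of any marker, including CD34/CD117
  themselves, stays inside the template. This is what makes the template a
  container for the whole leukemic clone rather than for one marker-positive
  subset.
- Follow-up samples replay the stored geometry verbatim. Gate adjustment is
  deliberately not automatic; it would be an explicit manual override.
- The two-tube cross-check is a relative comparison of terminal fractions
  (≤ 20% difference passes); the generator simulates a single tube, so the
  check is exposed as a QC helper only.

Template gates nest by construction (each mask is ANDed with its parent), and
templates serialize to JSON (gate ids, channels, vertex lists, transform
spec) for lossless replay.

## Quantification and calls

`MRD% = 100 · counted / N(CD45⁺)`. Every cutoff in the package is strict
("positive" means strictly above): the molecular threshold is defined as
ratio > 0.01, and the 0–0.034% leukemia-free background range must fall below
the 0.035% interpretive threshold, which only a strict comparison guarantees
at the boundary. Values are stored at full precision; rounding to the
3-decimal granularity of the thresholds happens at display.

Therapy-specific mode applies 0.034% (post-chemotherapy) and 0.095%
(post-Ven+HMA). Post-transplant samples have no published dedicated cut-off
and fall back to the default 0.035%. Samples under the 500,000-event
acquisition target are quantified anyway and carry a `low_events` QC flag.

Molecular: arithmetic replicate means, no outlier rejection (replicate CV
above 50% warns only), exclusion strictly below 10,000 mean ABL1 copies.
Copy numbers are assumed already quantified against standard curves.

## Validation statistics

The molecular call is the reference. Concordance = (TP+TN)/n; the identity
concordance + FP% + FN% = 100 is a tested invariant. Method comparison is a
Pearson chi-square without continuity correction on the 2×2
method × concordant/discordant table; the choice of test construction is an
assumption (a paired McNemar variant would also be defensible), so printed
p-values are comparative, not confirmatory. ROC is empirical over observed
values with the strict ">" rule; AUC is the tie-corrected Mann–Whitney
statistic (equal to the trapezoidal area and cross-checked in tests against
brute-force pair counting and scikit-learn); SE and 95% CI follow Hanley &
McNeil; the null p-value uses the normal approximation without tie
correction. The operating point maximizes Youden's J — the criterion is the
standard default, chosen here as an assumption since cut-offs are usually
published with paired sensitivity/specificity but without naming a criterion
— with ties resolved toward higher specificity. "True MRD" restriction strata
are value filters: CD117⁺ share of leukocytes < 1% and molecular ratio < 1.

## Synthetic cohort generator

The generator produces what the analysis needs to be honest about its own
claims: populations with the right topology, not a physical instrument model.

- **Populations** (lymphocytes, granulocytes, CD117⁺ normal progenitors,
  blasts, debris) with per-channel log-normal intensities on the raw scale.
  Locations/spreads are free parameters with documented defaults (e.g. blasts
  CD45 median 500 vs lymphocytes 5000, progenitors 2000 — the CD45-dim
  ordering the gating strategy relies on), not measurements of any cytometer.
- **Marker positivity** is a latent per-event Bernoulli; positives draw from
  a stained component (median 1200, σ 0.40), negatives from autofluorescence
  (median 40, σ 0.45). Truth labels retain the Bernoulli draws. Diagnosis
  samples take blast positive fractions directly from the patient's
  diagnostic expression percentages.
- **Background**: progenitors carry aberrant-marker positivity calibrated so
  the marrow-wide LAIP⁺ frequency matches the defaults CD4 0.020 / CD7 0.010 /
  CD56 0.005 / CD25 0.002 percent of leukocytes — inside the 0–0.034% range
  observed in leukemia-free marrow, ordered by the markers' reported
  specificity. The per-sample progenitor burden varies log-uniformly
  (0.05–0.8% of leukocytes) to emulate regeneration.
- **Doublets** sum two singlets' area signals and keep FSC-H near the larger
  one — the simplest construction the FSC-A/FSC-H gate separates. Debris is
  low-scatter, CD45-negative. Doublets never count as truth blasts.
- **Molecular coupling**: expected NPM1-mutant copies = 30,000 × true
  leukemic fraction against a mean 100,000 ABL1 copies, i.e. expected
  ratio% = 0.3 × true MRD%, placing the 0.035% flow threshold just above the
  0.01% molecular threshold so the two assays agree in expectation near the
  decision boundary. Replicates carry log-normal error (CV 15%) on top of
  Poisson counting noise; a truly negative sample yields exactly zero mutant
  copies.
- **Cohort**: 25 patients (the packaged diagnosis profiles) × 5 follow-ups =
  125 samples; true levels are 0 with probability 0.32 (the molecular
  negativity rate of the study cohort) and otherwise log-uniform over
  0.01–2% of leukocytes; therapies draw from the 62/58/5 mix. Per-sample
  seeds derive from the master seed via a counter scheme
  (`SeedSequence([master, patient, sample])`), so any sample regenerates in
  isolation.
- **Problem sizes.** Follow-ups use 120,000 events and diagnoses 80,000 —
  enough for ~40 events at the interpretive threshold and stable template
  quantiles, while keeping the full 125-sample study under a minute. The
  500,000-event acquisition target is retained as the QC default, so
  synthetic samples carry the `low_events` flag, exactly as under-acquired
  clinical samples would.

**What the generator omits**, hence what passing tests do *not* show about
real data: no compensation/spillover error, no instrument drift or batch
effects, no immunophenotypic shift between diagnosis and follow-up (a known
blind spot of template-based tracking), no monocytic differentiation, and
lymphocytes are negative for all panel markers (real CD4⁺ T cells would
serve as an internal *positive* control; the negative-control logic is
unaffected). Populations are stationary between diagnosis and follow-up, so
template replay is easier than in the clinic; synthetic concordances are
accordingly optimistic. The reproducible content is structural: DfN ≤ LAIP
always; equality under total expression; the DfN background sitting below the
interpretive threshold on leukemia-free marrow; the
sensitivity/specificity ordering of the two methods; and a DfN Youden cut-off
that lands at the interpretive threshold while the LAIP-method's sits an
order of magnitude higher, because the LAIP count carries the template
background (progenitors plus rare mature-cell leakage, ~0.3–0.7% of
leukocytes with these defaults).

## Known limitations

- Gate geometry is axis-aligned boxes; real templates use hand-drawn convex
  polygons. The `GateNode` container accepts arbitrary convex polygons; only
  the automatic fitter is box-shaped.
- The blast-region heuristics (robust trims, quantile boxes) are this
  package's own placement rules; published workflows place these gates by
  eye and give no numerical definition.
- Multi-LAIP patients are tracked by the single highest-expression marker;
  OR-logic over several aberrant markers exists behind the API (apply the
  DfN filter per marker) but is not a default, since the published filter is
  single-marker.
- No limit-of-detection/limit-of-quantification machinery and no
  relapse/outcome modeling.
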