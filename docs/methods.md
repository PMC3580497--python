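# Methods

## Fitness scoring

The chronic readout is the area under each well's OD600-versus-time curve,
computed by trapezoidal integration on the recorded grid. By default each
well's initial OD is subtracted before integration (negative values floored
at zero): the inoculum contributes `OD0 × duration` to a raw AUC, and
subtracting it makes growth ratios invariant to plate-to-plate inoculum
differences and to any multiplicative rescaling of a plate's readings.
Integrating raw OD is available as `baseline="raw"`; the window defaults to
the full recorded run, which extends past control saturation, with an
explicit `[t_start, t_end]` option because no saturation-detection rule is
imposed.

The per-plate control AUC is the arithmetic mean over that plate's
solvent-control wells (layouts must carry at least four on any plate with
compounds). A control coefficient of variation above 20% (configurable)
flags the plate as a QC warning rather than an error: the scores are still
produced, the flag travels with them. Replicate aggregation uses the sample
(n−1) standard deviation — triplicates are a sample, not a population — and
the hit call applies to the replicate mean. The hit threshold compares
inclusively (ratio ≤ 0.65 is a hit, 0.651 is not); `1 − threshold` is the
minimum fractional growth inhibition, 35% at the default.

## Acute phenotypes

Phototaxis scores arrive pre-categorized (`toward_light`, `away_from_light`,
`no_movement`, `lysed`); untreated cells are negatively phototactic, so the
control direction defaults to `away_from_light` and movement toward light is
a sign reversal. Lysed wells are counted as motility-inhibited — they show
no response to directional light. Because plates are photographed twice with
light from opposite sides, two scores per well are accepted and reconciled
by agreement; disagreement yields a missing call, since no principled
tie-break exists for contradictory images.

The photosynthesis readout is a fluorescence ratio against the in-plate
control mean; elevated fluorescence indicates reduced photosystem II
efficiency. No published hit threshold exists for this assay, so the default
(ratio ≥ 1.35) mirrors the 35% effect-size convention of the fitness screen.
This symmetry is an assumption, exposed as configuration, not a measured
property of the assay.

Cytotoxicity: a growth-inhibited compound whose culture regrows after
transfer to compound-free medium is cytostatic, one that does not is
cytocidal, and non-inhibited compounds are reversible. Overlap accounting
across assays is inclusion–exclusion on compound-id sets and is computed on
raw acute calls, before any fitness filtering.

## Fingerprints and the similarity network

Fingerprints are sparse sets of hashed circular-substructure identifiers
(Morgan radius 2, diameter 4) using the standard connectivity invariants —
element, degree, charge, H count, ring membership — with stereochemistry
ignored by default. Sets rather than folded bit vectors avoid a folding-
length choice and collision artefacts; a folded 2048-bit mode exists for
interoperability. Hash values are implementation-defined, so cross-
implementation comparisons must be made at the similarity level, never on
raw feature identifiers; the test suite freezes feature-set *sizes* from a
reference run for regression only.

The network joins compounds at Tanimoto strictly greater than the cutoff
(default 0.5). Structural families are the connected components of this
graph — single-linkage clustering at the cutoff. Isolated nodes are kept and
flagged rather than dropped, since displays typically show only the
connected subset. Node colour encodes acute activity (green = both
phenotypes, red = photosynthesis, blue = motility/phototaxis, white =
neither) and shape encodes fitness (circle = hit, diamond = not).

## Naive Bayes model

Each feature's weight is the Laplacian-corrected log-ratio
`log[(A_F + 1) / ((T_F + 1/P_a)·P_a)]`. The correction shrinks low-count
features toward zero evidence: a feature never seen in training contributes
exactly `log 1 = 0`, which is also the score of features absent from the
model, so unfamiliar chemistry is neutral rather than penalised. Features
are presence/absence — set semantics match the fingerprint definition.
Scores are sums of log-weights and are relative ranks only; no calibrated
probability is exposed. Ranking sorts by descending score with ties broken
by compound id, making every downstream cut deterministic. A Bernoulli
naive Bayes (scikit-learn) serves as an independent cross-check of the
ranking in the test suite, not as the implementation.

## Evaluation

Five-fold repeated holdout: train on four-fifths, rank the held-out fifth,
read EF at the top 10% (`m = ceil(f·n)`; the ceil choice and the tie rule
are recorded in output metadata). Folds are stratified by label — whether
the original scheme stratified is unknowable from its description, but
stratification stabilises per-fold EF and matches the intent of using each
fifth as the comparison set. The summary is the mean EF with standard error
`sd / sqrt(k)`. EF is bounded by `min(m, n_active) / (m·n_active/n)`,
attained by a perfect ranking, and equals 1 at fraction 1 for any ranking.
Seeded generators drive every random choice; the default evaluation seed is
20121118 and is recorded in output metadata.

## Synthetic data

Plates: logistic growth `OD(t) = OD0 + K/(1 + e^{−r(t−t_m)})` plus Gaussian
noise clipped at zero. Defaults OD0 = 0.1, K = 0.9, r = 0.15 h⁻¹,
t_m = 30 h, σ = 0.005 OD, sampled every 0.5 h for 80 h in triplicate with
eight controls per 96-well plate — a sigmoidal curve family resembling algal
microtiter growth at OD600 ≈ 0.1 inoculum read every 30 minutes over an
80-hour assay. Logistic is the simplest saturating family; no growth model
is fitted anywhere in the pipeline, so only the curve's shape matters. A
compound's inhibition factor φ ∈ [0, 1] multiplies K by φ and r by
(0.5 + 0.5φ): partial inhibitors change curve shape, not just scale, which
exercises the integration-window logic. The closed-form AUC ratio implied by
φ (via the analytic logistic antiderivative) is exported as an oracle;
noise-free simulated plates reproduce it to the trapezoid discretization
error, which at the default 0.5 h sampling is ≈ 10⁻⁵ relative and below
10⁻⁶ at 0.02 h sampling — exact-recovery tests therefore run at the fine
interval, noise-recovery tests at the assay interval.

Libraries: compounds are assembled from a fragment grammar — scaffold
templates (benzene, pyridine, furan, cyclohexane, piperidine, naphthalene)
filled with substituent fragments — which guarantees RDKit-valid SMILES;
invalid combinations are resampled and counted. A planted pharmacophore
(sulfonamide or chloro-benzamide fragment) occurs in 30% of compounds and
raises activity probability from p0 = 0.1 to p1 = 0.8, for an expected hit
rate of 0.31. These defaults give the ranking model a strong but imperfect
signal: the attainable EF@10% is capped near 1/0.31 ≈ 3.2 and the model
reaches ≈ 2.6, while p0 = p1 gives a null library calibrating EF to 1.

Acute readouts: photosynthesis-mechanism compounds emit 1.8× control
fluorescence (safely above the 1.35 hit ratio with σ = 3 a.u. noise),
motility compounds score `no_movement` on both image sides, sign-reversal
compounds `toward_light`; regrowth is Bernoulli(1 − cytocidal fraction) for
inhibited compounds.

What the generator does *not* emulate: edge effects and spatial gradients on
plates, evaporation, compound uptake or degradation kinetics, fluorescence
induction transients, correlated replicate failures, and real chemical
diversity (the grammar spans a few scaffold families, far narrower than a
screening collection). Passing tests therefore demonstrate that the pipeline
recovers planted effects under its stated noise model, not that real screens
meet these error rates.

## Pipeline

The campaign runner executes simulate → fitness → acute → network → train →
evaluate → rank into one directory. Each stage records a hash of its
configuration slice and input files; an unchanged stage with existing
outputs is skipped, and any upstream change re-triggers downstream stages.
No timestamps enter result files, so identical seeds give byte-identical
outputs. The network stage builds the graph over active compounds only
(fitness hits plus acute actives), matching how screen networks are
visualised and keeping the O(n²) similarity computation on the relevant
subset. Default campaign sizes (600-compound library in the runner's
default, 400 in the acceptance script, 2,000 for model evaluation) were
chosen as the smallest sizes at which the binomial noise on recovered rates
and enrichment factors is comfortably inside the documented tolerances.

## Known limitations

- The AUC integration window and baseline mode change absolute AUCs; only
  the default configuration is covered by the recovery oracles.
- The photosynthesis hit threshold is a convention, not a measured cut.
- Sparse fingerprint feature ids are not portable across fingerprint
  implementations; persist similarities or SMILES, not feature ids.
- The naive Bayes model assumes feature independence; correlated
  substructures (as the fragment grammar necessarily produces) make scores
  over-confident, which affects calibration but not ranking quality here.
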