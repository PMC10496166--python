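# Methods

## The measurement problem

An 18-item knee questionnaire is conventionally reported as a single 0–100
score, which presumes the items measure one construct. Structural validity
asks whether the item covariance matrix is consistent with that
unidimensional scoring, with a small number of correlated subscales, or with
a *bifactor* structure — one general factor loaded by every item plus
orthogonal specific factors that absorb the extra covariance among item
clusters that share wording, response format or content. The bifactor
reading matters clinically: it can reconcile visible multidimensionality
with a defensible single total score ("essential unidimensionality").

promstruct implements the complete workflow on either real respondent CSVs
or synthetic cohorts: scoring and completeness filtering → exploratory
factor analysis with a retention rule → confirmatory fitting of candidate
structures → fit-index battery and nested tests → bifactor reliability
indices.

## Instrument and scoring

The built-in instrument has 19 items; item 10a (pre-injury function) is
collected but excluded from scoring and from every factor model. Codes are
stored 0-based, worst→best (a `one_based` switch accepts 1-based files).
The total score is the linear transform `100·(raw − min_raw)/(max_raw −
min_raw)` of the summed scored codes (`max_raw` = 87 for the built-in
instrument, i.e. point values linear in category rank — the official scoring
key). Default scoring is complete-case, matching the validation-study
convention; the official mean-substitution rule for rows with ≥ 16 of 18
answers sits behind an explicit `allow_partial` flag, default off.

## Synthetic cohorts

The generator draws respondents from a continuous latent factor model
`y* = Λη + ε`, η ~ N(0, Φ), ε ~ N(0, Θ), and discretizes each `y*` through
its item's ordered thresholds. The default population is standardized
(per-item `λ_g² + λ_s² + θ = 1`) with:

- general loading 0.6 on all 18 items;
- specific loadings by content cluster: symptoms 0.35, activity 0.40,
  ADLs 0.45, sport 0.55 (sport is the tightest cluster on this instrument,
  symptoms the loosest); the published path diagram gives no
  machine-readable loadings, so these are declared plausible rather than
  matched to any dataset;
- equal-probability thresholds `Φ⁻¹(j/C)` per item's category count
  (2/5/11), giving near-uniform category use; a `symptomatic_population`
  preset shifts thresholds upward to mimic the low, right-censored score
  distributions of post-injury cohorts.

Randomness policy: one `numpy` generator per `simulate` call, factor draws
before residual draws, items in questionnaire order — a fixed seed yields a
bit-identical matrix.

What the generator does *not* emulate: non-normal latents, missingness
mechanisms beyond row deletion, longitudinal correlation, item-specific
response styles. Consequently, passing recovery tests demonstrates that the
estimation machinery is correct under the stated model, not that the model
describes any particular clinical population. One consequence is built in
deliberately: coarse ordinal scales attenuate product-moment correlations
relative to the latent model (≈ 12% for these category counts), exactly the
attenuation accepted when ordinal items are analyzed as continuous.
Recovery tests therefore compare estimates either to the latent truth (where
the criterion tolerates the attenuation) or to the ordinal-scale population
limit approximated by a very large cohort.

## Exploratory analysis

ML extraction uses the classical profile likelihood: for fixed uniquenesses
Ψ the optimal loadings come from the leading eigenvectors of
`Ψ^(-1/2) R Ψ^(-1/2)`, leaving `F(Ψ) = Σ_{j>m}(θ_j − ln θ_j − 1)` over the
trailing eigenvalues, minimized over log-uniquenesses with the envelope
gradient (box-bounded below at 1e-4; hitting the bound raises a Heywood
warning). EFA operates on the correlation matrix; ML factor analysis is
scale invariant, so the m = 1 discrepancy equals the one-factor confirmatory
fit on the covariance matrix — an identity the tests enforce to 1e-6 on the
χ² scale.

Factor retention is Horn's parallel analysis: per-rank percentiles of
eigenvalues from null data of the same N×p shape (independent normal by
default; an in-place column-permutation null is available). The suggested
count is the length of the *leading* run of observed eigenvalues exceeding
the reference — the sequential stopping rule; counting exceedances at all
ranks would make the null error rate grow with p. The reference percentile
defaults to 99 (Glorfeld's conservative variant) rather than the classical
95: with the 95th percentile the first-rank over-extraction rate on pure
noise is the nominal ~5% (measured 4.5% over 200 noise batteries), whereas
the 99th keeps it near 1% at no measurable cost in power for the effect
sizes that matter here (a real second factor with loadings 0.7 at N = 1000
has an eigenvalue near 3.7 against a reference near 1.25). Defaults: 500
replicates.

Oblique rotation is delegated to the gradient-projection algorithm, with a
geomin criterion (ε = 0.01, five deterministic starts to dodge local minima
of the rotation criterion) by default and quartimin/oblimin as the
alternative. Rotation leaves the fitted correlation matrix, and hence every
fit statistic, unchanged.

## Confirmatory engine

Models are declared as loading patterns with a factor covariance structure
(free / orthogonal / bifactor) and optional correlated residuals. Four
fixtures cover the instrument's candidate structures (df = 135, 134, 129,
117 over the 18 scored items; the two-factor exploratory counterpart has
df = 118). In the two-factor fixture, item 3 (pain severity) sits with the
symptom items: the published exploratory item lists leave it unassigned, and
content plus the prior two-factor literature place it there; this choice is
what yields the fixture's df of 134.

Estimation minimizes `F_ML` by L-BFGS-B with analytic gradients
(`∂F = tr[Σ⁻¹(Σ−S)Σ⁻¹ ∂Σ]`). Numerical choices:

- identification: factor variances fixed at 1 (standardized reporting); the
  marker-loading convention (first loading fixed, factor variances free) is
  available and df-equivalent — the two agree in `F_ML` to 1e-8 by test;
- residual variances log-parameterized, box-bounded in `[1e-4, 1e3]·s_ii`;
  an estimate at the lower bound is a Heywood case, reported with a warning,
  never silently;
- factor correlations box-bounded at ±0.99; a non-PD Σ during a line search
  returns a penalty value;
- start values: loadings `0.7·sd` (split 0.6/0.3 general/specific for
  bifactor patterns), residual variances `0.5·s_ii`, factor correlations 0;
- convergence: projected-gradient max-norm below 5e-7, otherwise a
  `ConvergenceWarning` and `converged=False` on the result;
- sign convention: each loading column flipped so its sum is positive;
- χ² multiplier: `(N−1)·F_ML` (Wishart convention) by default, `N·F_ML`
  via the `chisq_dialect` switch, since software dialects differ.

Missing data are complete-case only; moments require `N > p`.

Modification indices are univariate score tests: for each fixed residual
covariance or cross-loading, `MI = (N−1)·g_t²/(2·c_tt)` with
`g_t = tr[Σ⁻¹(Σ−S)Σ⁻¹ ∂Σ_t]` and `c_tt` the candidate's expected-information
diagonal partialled for the free parameters. The tests verify the statistic
against the actual χ² drop from refitting with the parameter freed.

The nested Δχ² test requires the same data, dialect and item set, df
ordering, and a non-negative difference up to convergence noise.

## Fit indices

With model and independence-baseline χ² (baseline: diagonal Σ, closed form
`F = −ln|R|`, df = p(p−1)/2):

- `CFI = 1 − max(χ²_m − df_m, 0)/max(χ²_b − df_b, χ²_m − df_m, 0)`, clamped
  to [0, 1] by construction;
- `TLI = [(χ²_b/df_b) − (χ²_m/df_m)]/[(χ²_b/df_b) − 1]`, deliberately not
  clamped;
- `RMSEA = sqrt(max(χ²_m − df_m, 0)/(df_m·(N−1)))`, 90% CI by root-finding
  the noncentrality at which the observed χ² sits at the 0.95/0.05 quantiles
  of the noncentral χ² (Brent's method, tolerance 1e-8, search bounded at
  10·χ²);
- SRMR on the correlation metric (residuals standardized by observed SDs, so
  it is invariant to rescaling any variable), including diagonal terms by
  default with the off-diagonal-only dialect available.

df = 0 renders RMSEA and TLI as undefined (`None`), not as 0. Adequacy
verdicts apply the published thresholds exactly: CFI and TLI > 0.9, RMSEA
and SRMR < 0.08, standardized loadings > 0.3, factor correlations < 0.85.
Robust (mean/variance-corrected) index variants are out of scope;
conventional ML indices are the only path.

## Bifactor indices

All indices are computed on the standardized solution of an orthogonal
bifactor fit (anything else is a usage error):

- `ω = [(Σλ_g)² + Σ_k(Σλ_k)²] / [(Σλ_g)² + Σ_k(Σλ_k)² + Σθ]`, with
  subscale versions restricting sums to one group's items;
- `ω_H = (Σλ_g)²/denominator of ω` (specifics: own numerator over the
  subscale denominator);
- `ω_R = ω_H/ω`, undefined at ω = 0;
- `ECV_f = Σλ_f²/Σ_all λ²` (sums to 1 by construction);
- `PUC = 1 − Σ_k p_k(p_k−1)/[p(p−1)]`, structure-only: 0.778 for the
  built-in partition (groups of 4/5/6/3 over 18 items);
- `FD = sqrt(diag(Φ Λ' Σ⁻¹ Λ Φ))`, the correlation between regression
  factor-score estimates and the factors.

`variance_decomposition` splits total-score variance into `100·ω_H` (general),
`100·(ω − ω_H)` (specific) and `100·(1 − ω)` (error). The "essentially
unidimensional" flag (general ω_H > 0.8 and general FD > 0.9) is an
interpretive heuristic, labeled as such — the conventional bar for using
factor scores individually is FD > 0.9. Reports render at 3 decimals; full
precision is retained in JSON.

## Pipeline and determinism

`run_structural_validity` chains the stages, fits the requested model
fixtures (non-convergent fits are flagged in the table, not dropped),
defaults the nested comparison to four-factor vs bifactor, and writes
`report.json`, `fit_table.csv`, `indices_table.csv`, per-model loading
tables and a run log recording seed, dialect, rotation and
parallel-analysis settings. Identical config and seed produce byte-identical
JSON. An end-to-end run on a 600-respondent simulated cohort takes a few
seconds on one CPU; the test and validation batteries use cohorts between
600 and 5000 respondents (100k only to approximate a population limit),
sizes chosen to keep sampling error well inside the stated tolerances.

## Validation strategy

Every numerical path is checked against an independent route: hand-computed
covariances and index arithmetic on small fixtures; closed forms
(equicorrelation eigenvalues, the baseline determinant identity); the
EFA≡CFA identity; statsmodels' ML factor analysis as an external oracle for
the one-factor model; a deliberately naive numeric-gradient minimizer for
the bifactor model; recovery of known generating parameters from simulated
cohorts; and exact algebraic identities (ω_R·ω = ω_H, ECV summing to 1)
over random admissible parameterizations.

## Known limitations

- Ordinal items are analyzed as continuous; no WLSMV/polychoric path, so all
  loadings inherit the discretization attenuation described above.
- Complete-case analysis only; no full-information ML for missing data.
- No robust fit-index corrections, no AIC/BIC, no measurement-invariance or
  multi-group models.
- Exploratory bifactor (Schmid–Leiman) rotation is not provided; the
  bifactor path is confirmatory.
- The one-factor-plus-19-correlated-residuals variant that can be built by
  iterating modification indices is representable but intentionally not
  bundled as a fixture: which residuals get freed is data-dependent, and
  such a model is overfitted by construction.
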