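# Methods

## Model and assumptions

The package treats a lake food web as a two-endmember carbon system:
littoral/benthic basal resources (δ¹³C-enriched) and pelagic basal
resources (δ¹³C-depleted), each represented by the arithmetic mean of
sampled baseline organisms. A consumer's littoral carbon use (LCU) is its
linear position between those means; the model assumes δ¹³C changes
negligibly (< 1 ‰) across trophic steps, that the chosen baselines span the
isotopic range the consumers actually draw on, and that consumers and
baselines are in isotopic equilibrium over comparable time windows.
Trophic position converts the consumer's δ¹⁵N excess over a baseline into
trophic steps of fixed size Δn, anchored at the baseline's assumed trophic
position λ. All isotope values are per-mil deltas (δ¹³C vs VPDB, δ¹⁵N vs
air); no unit conversion happens anywhere.

Each of those assumptions fails in recognizable ways, and the package's
structure follows the failures:

* **Bracketing failure.** Fish δ¹³C often extends past the baseline means
  (ontogenetic shifts, unsampled carbon sources, a δ¹³C trophic
  discrimination larger than assumed). Raw LCU then leaves [0, 1]. Clipping
  (`LCU_adj`) restores the bounds at the price of truncation bias — the
  recovery simulations show a systematic negative bias whenever true α > 1
  — while min-max rescaling (`LCU_R`) re-expresses each fish relative to
  the empirically observed δ¹³C range, preserving ordering and variability
  but abandoning the absolute proportion interpretation.
* **Spatial heterogeneity.** Basin-scale offsets in baseline isotopes make
  lake-wide endmembers wrong for every basin; the grouping screens detect
  this and the `GroupingPolicy` matches fish to same-stratum endmembers.
* **Turnover mismatch.** Fast-turnover tissues (liver) track seasonal
  baseline movement; slow tissues (muscle, fin) integrate across it. The
  per-tissue season policy matches liver to same-season baselines and
  pools seasons for muscle/fin.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| Δn (`delta_n`) | 3.4 | ‰ per trophic step | conventional freshwater δ¹⁵N diet–tissue discrimination |
| λ (`lambda_default`) | 2 | — | baseline taxa treated as strict primary consumers in TP₁/TP₂ |
| λ per taxon | mayfly 2.25, mussel 2.0, oligochaete 2.5 | — | macroinvertebrate omnivory places real baselines between 2 and 3; used by TP₂abs |
| `violation_threshold` | 0.05 | fraction | more than 5 % of a population outside [0, 1] switches the recommendation to `LCU_R` |
| `alpha_level` | 0.05 | probability | shared by every screen and post hoc test |
| `rescale_scope` | per_system | — | min/max over all consumers in the analysis; `per_stratum` restricts to each basin |

Boundary convention: LCU values exactly 0 or 1 count as inside bounds (the
violation rule is strict inequality). Out-of-bounds α is deliberately
propagated unclipped into the two-source TP equations — only the `_adj`
variants clip — so the TP suite exposes rather than masks bracketing
failure. The min-max range for `LCU_R` is computed over consumers only, not
baseline organisms (configurable by passing a different cohort); including
baselines would tie the rescaling to taxa the metric is not about.
`TP₁‑LBP` pools all individual baseline specimens with equal weight; a
habitat-mean-of-means option exists for designs with very unbalanced
baseline sampling.

## Statistics

All inference is nonparametric: isotope groups routinely fail Shapiro-Wilk
normality and Levene variance screens, which are provided as advisory
diagnostics only (they log, never branch). The two-sample habitat and
season tests are two-sided Wilcoxon rank-sum tests — exact null enumeration
when both groups have ≤ 8 observations and no ties, otherwise the normal
approximation with tie correction and no continuity correction (so
exchangeable samples give p = 1 exactly). Multi-level screens use
Kruskal–Wallis with tie correction followed by Dunn's pairwise z-tests on
the pooled mid-ranks, Bonferroni-adjusted; Bonferroni is applied uniformly
across every pairwise family for consistency, though it is configurable.
Dunn's test is implemented in `isofoodweb._stats` (z = rank-mean difference
over the tie-corrected null SE) and validated against closed-form values
(H = 32/7 ≈ 4.571 and |z| = 4/√3.5 ≈ 2.138 on the three two-point groups).

The equation-variant comparison treats each variant's per-individual values
as independent groups, which is the field's convention despite the implicit
pairing (every variant is computed from the same fish); a Friedman-style
paired omnibus is available behind `paired=True` but off by default, as the
faithful-to-convention choice. When δ¹³C is distinct but δ¹⁵N is not, the
decision engine still takes the two-source path and logs a caution — the
two δ¹⁵N baselines then contribute little beyond a pooled one, but the
carbon mixing model remains identified.

Degenerate inputs are explicit errors, not NaNs: equal endmember δ¹³C means
raise `DegenerateEndmembersError` carrying the one-source recommendation;
an all-equal LCU collection raises `DegenerateRangeError` from the
rescaler; an all-identical pooled sample short-circuits the rank-sum test
to p = 1.

## Synthetic systems

The generator runs the estimation model forwards. Baselines are Gaussian
around their habitat means (SD 0.5 ‰ within scope); each consumer receives
a true α from a per-species uniform range and a true TP, then
δ¹³C = α·δ¹³C_L + (1−α)·δ¹³C_P + ε and
δ¹⁵N = α·δ¹⁵N_L + (1−α)·δ¹⁵N_P + (TP − λ_weighted)·Δn + ε, with
ε ~ N(0, `noise_sd`), independent across isotopes. The default
`noise_sd` = 0.2 ‰ mirrors typical instrument precision. Basin offsets
shift baselines and consumers together; season offsets reach baselines and
liver only, with muscle/fin seeing the season average; tissue offsets are
fixed shifts (liver −1.0 ‰ δ¹³C, −0.5 ‰ δ¹⁵N vs muscle — generator
conventions sized to make the screens' expected outcomes unambiguous, not
field estimates, since quantitative seasonal/tissue shifts vary by system).

Because δ¹⁵N is generated through the same Δn used in estimation, noise-free
systems are recovered exactly (the package's core correctness oracle);
mismatched-Δn scenarios can be built by changing either side. What the
generator does **not** emulate: δ¹³C trophic discrimination (assumed 0),
scaled (δ¹⁵N-dependent) discrimination, isotopic turnover kinetics,
within-individual tissue correlation of noise, and covariance between α and
TP. Passing recovery tests therefore demonstrates the estimators invert
their own model correctly and degrade gracefully with noise — not that the
model is right for any particular lake.

Three presets mirror common study designs: `simple` (one stratum, season,
tissue; one species' α range extends past 1), `spatial` (three basins, 2 ‰
baseline steps ≫ 0.5 ‰ SD, strongly under-bracketing consumers), and
`temporal_tissue` (two seasons × three tissues with liver-only season
sensitivity). Preset cohort sizes (30–36 fish/species, 15–30
baselines/habitat/scope) are typical field-study sizes and keep every
simulation-based check well under a minute.

## Numerical choices

Equality tolerances: algebraic identities are asserted to 1e−12 (pure
float arithmetic) or 1e−9 (values that pass through aggregation);
statistical check values to the precision of their closed forms. Min-max
rescaling maps the minimum to exactly 0 and maximum to exactly 1;
`clip_lcu` is idempotent and order-preserving. Output CSVs are written at 4
decimal places, exceeding the 1-decimal convention of field reporting so
that round-tripping loses nothing material. The pipeline is fully
deterministic given (input file, config); the generator is deterministic
given its seed (NumPy `default_rng`).

## Known limitations

Two-endmember mixing only — no Bayesian multi-source models, no lipid
correction, no δ³⁴S benthic-sediment metric, no scaled discrimination
factors. The decision engine's rule chain covers the diagnostics it is
given (habitat distinctness, violation rate, λ equality); it does not
choose among α sources beyond that chain or perform model selection. Highly
mobile species can violate basin matching in ways no grouping policy fixes;
the policy is user-controlled for exactly that reason.
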