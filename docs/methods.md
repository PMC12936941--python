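# Methods

## The exchange model

An auxotroph surrounded entirely by producing (wildtype) cells grows at a
rate limited by its internal pool of the missing amino acid.  Relative to
the wildtype rate,

    r = (1 + s) · î / (K_M + î)

with `s = (μ_max,aux − μ_wt)/μ_wt` the fitness benefit of dropping the
biosynthetic pathway (μ_max,aux is the auxotroph's rate when the amino acid
is not limiting, μ_wt the wildtype rate on minimal medium) and `K_M` the
Monod half-saturation constant for growth on the internal concentration î.
At steady state î solves the uptake/leakage balance

    ((1+s) + ľ)·x² − (ϵL − ľ)·x − ϵL = 0,   x = î/K_M,

whose non-negative root has the closed form implemented in
`auxleak.model.internal_concentration`.  The drivers are dimensionless:

- `L = l_wt·I_C/(μ_wt·K_M)` — wildtype relative leakage flux, leaked vs.
  growth-invested amino acid.  `I_C` is the producers' internal
  concentration; we assume producers grow near their maximum rate and set
  `I_C = 20·K_M` (`i_c_factor`).
- `ľ = l_aux/μ_max,aux` — the auxotroph's own leakage relative to its
  maximum growth rate.
- `ϵ` — auxotroph/wildtype ratio of combined uptake+leakage rates; 1 when
  transporters are unchanged by the deletion.

Only `î/K_M` matters for r, so all concentrations are expressed in units of
K_M (`k_m = 1` default).  Defaults `μ_wt = 0.70 h⁻¹` and
`μ_max,aux = 0.90 h⁻¹` are the measured unsupplemented wildtype and
supplemented auxotroph rates, giving `s = 2/7 ≈ 0.286`.

**Critical leakage.**  `critical_leakage` solves r(L) = 1 (where î = K_M/s)
by bracketed Brent root-finding on the monotone map, to relative tolerance
1e-14.  Two couplings are supported.  With ľ held fixed the solution is
effectively closed-form (`L* = ((1+s+ľ)/s + ľ)/(ϵ(1+s))`; the algebraic
case s = 0.2, ľ = 0.1 gives L* = 5.5 exactly) and a threshold exists for
every s > 0.  With a *shared* leakage rate (`l_aux = l_wt = l`, the
convention used for inference and for the heatmap's benefit axis), the
auxotroph's own leakage grows with the supply and r saturates at
`(1+s)·î∞/(K_M+î∞)` with `î∞ = ϵ·I_C·(1+s)`.  A break-even point then only
exists for growth benefits above `(1 + √(1 + 4K_M/(ϵ·I_C)))/2` (≈ 1.048 at
I_C = 20·K_M); `critical_leakage` raises a no-solution error below this
floor and the contour written by the pipeline starts there.  The measured
benefit (≈ 1.29) is far above the floor.

**Leakage inference.**  The maximum auxotroph growth rate is estimated by
OLS extrapolation of auxotroph growth rate on local wildtype fraction
(1 − auxotroph fraction, lifetime mean at the 5 µm radius) to a wildtype
frequency of 1, with the standard error of the predicted mean.  Because
r(l) is strictly monotone, the shared leakage rate reproducing the
extrapolated value is found by bisection (relative tolerance 1e-12);
`fold_to_threshold = L*/L_fit` states how far leakage sits below
break-even.  Uncertainty is propagated by inverting at μ_max ± 1 SE — an
interval, not a posterior, which matches the order-of-magnitude character
of the estimate.  The linear extrapolation of a mildly convex μ(f) response
carries a small bias (a few percent on recovered l in end-to-end synthetic
tests), which is negligible against the ~tens-fold distance to threshold.

## Growth-rate estimation

Cell length (major axis) proxies for biomass; assuming exponential
elongation, the specific growth rate of a track is the OLS slope of
ln(length in µm) against time in hours over the track's full lifetime
(birth to division or loss; daughters are new tracks).  Filters, in order:

1. **Jump filter** — a track is dropped entirely if any consecutive-frame
   pair changes length by more than ±15% relative to the earlier frame
   (segmentation/tracking artifacts).  Evaluated on observed lengths.
2. **Minimum length** — at least 5 consecutive frames.
3. **Fit quality** — after fitting, records with R² ≤ 0.8 are dropped
   (strict inequality).  A zero-variance (constant-length) response is
   assigned R² = 0: such a fit carries no rate information.

Doubling times are `t_d = 60·ln 2/μ` minutes.  Summaries report mean ± SEM
(sd/√n, missing for n = 1) per replicate and strain, plus pooled values.
Pixel-unit tables are converted at ingest with 0.065 µm/pixel.

## Neighborhood composition

The local auxotroph fraction of a focal cell is the auxotroph area divided
by total cell area within a circular neighborhood of the focal centroid,
excluding the focal cell.  The default geometry rule counts a neighbor's
full area iff its centroid lies inside the radius (exact for the synthetic
rods); `rasterized_aux_fraction` provides the pixel-counting variant for
segmented masks and converges to the geometric rule as the pixel shrinks.
Growth is a track-level quantity, so the default covariate is the
lifetime-mean fraction (frames with an empty neighborhood are skipped;
tracks with no defined frame are dropped from correlations, with counts
logged).  The default radius is 5 µm — the scale over which amino-acid
exchange acts — with a 5/9/13 µm sweep for robustness.

Associations use Spearman's ρ (Pearson on mid-ranks, tie-corrected).
Significance comes from permutation: growth rates are shuffled against
fractions n_perm = 10,000 times and the two-sided p is the plain fraction
of permutations with |ρ_perm| ≥ |ρ_obs| (resolution floor 1/n_perm; p = 0
is reported when no permutation reaches the observed value).  Correlations
pool cells across replicates; per-replicate values are also available.
Quartile/fixed-width binning of growth by fraction is provided for
visualization only — inference always uses the continuous data.

Strain comparisons are made at the replicate level: paired t-tests on the
per-replicate mean growth rates (n = replicates), never on cells, because
cells within a chamber are not independent.  Kruskal–Wallis (tie-corrected,
χ² reference) serves for multi-group distributional comparisons.  Raw
p-values are reported without multiplicity correction; stars follow
p < 0.05 (*), < 0.01 (**), < 0.001 (***).

## The synthetic generator

`auxleak.simulate` emulates the statistical structure of chamber
time-lapse data, not cell mechanics.  Defaults are the study conditions:
40 × 40 µm chambers, 60 seed cells with Bernoulli(0.10) auxotroph labels,
μ_wt = 0.70 h⁻¹, 5-minute frames for 12 h, five replicates (wildtype-rate
offsets ~ Normal(0, 0.01 h⁻¹)) with five chambers each, division at 4 µm
into two equal daughters, birth near 2 µm.

Geometry is a deliberate simplification: 1 µm-wide rods stacked in fixed
vertical columns, touching; growth pushes everything toward the open side
(y = 0, the feeding channel), and cells whose centroid crosses it wash
out.  This shoving rule is an invention — the experiment gives no
quantitative description of in-chamber motion — chosen because it
reproduces two load-bearing features: lineages stay contiguous (mutant
clusters form by clonal growth) and slow-growing cells are passively
advected out.  An 8 µm strip nearest the open side is excluded from the
output, as in the imaging analysis.

Observed lengths are true lengths times lognormal noise (CV 2%); with
probability 0.005 per frame a spurious jump multiplies the observation by
a factor in [1.16, 1.5] (either direction), giving the ±15% filter real
work.  Auxotroph growth couples to the local auxotroph fraction f,
recomputed each frame with the same 5 µm centroid rule the analysis uses
(generator and analyzer agree by construction):

- **linear** (default): rate = μ_wt·max(0, r0 + β·f) with r0 = 0.23/0.70
  (the observed auxotroph rate in wildtype-dominated surroundings relative
  to wildtype) and β = −0.5, matching the observed ~10% growth loss per
  10% increase in local auxotroph fraction;
- **model**: rate = μ_wt·r from the exchange model with the wildtype
  leakage flux scaled by the local wildtype fraction (1 − f).

A ground-truth table records each track's lifetime-mean true rate, mean f
(for auxotrophs; wildtype rates do not depend on it) and parent track,
enabling exact recovery tests.

What the generator does **not** emulate: wildtype growth does not respond
to auxotroph neighbors (the measured wildtype effect, ρ ≈ −0.1, has no
synthetic counterpart); amino acids do not diffuse — the coupling is a
direct function of composition, so correlations are far stronger
(ρ ≈ −0.9) than in real data (ρ ≈ −0.2 to −0.3); no cell mechanics,
3-D effects, fluorescence or segmentation imagery.  Passing recovery tests
therefore demonstrates that the *pipeline* detects and quantifies coupling
of the assumed form at experimental sample sizes — not that real data are
this clean.  Because clustering depresses auxotroph growth below the f = 0
anchor r0, the realized pooled auxotroph rate (~0.17–0.20 h⁻¹) sits below
0.23 h⁻¹; the extrapolated maximum (~0.23 h⁻¹) is the quantity comparable
across pipelines.

## Numerical choices and scales

- OLS fits use closed-form normal equations (grouped sums), identical to
  the single-track path to ≤1e-12; the extrapolation uses statsmodels OLS
  with the prediction-mean SE.
- Root-finding is Brent's method with expanding brackets; tolerances 1e-12
  to 1e-14 relative.
- Permutations vectorize one rank transform and shuffle centered ranks; a
  1e-12 comparison slack absorbs round-off when a permutation re-creates
  the observed ordering.
- Type-I-error calibration uses 1000 independent-pair datasets (n = 100,
  1000 permutations each); the pooled-recovery study uses 100 seeds of
  five replicates × two chambers (~300 retained auxotroph tracks per
  dataset, matching the experimental per-strain n).  The no-coupling null
  sets β = 0 *and* zero between-replicate rate variation: replicate
  offsets couple growth and composition through replicate identity, a real
  (nuisance) association that pooled correlations legitimately detect.
- The default full experiment (25 chambers, ~775k observations) simulates
  in seconds and analyzes in about a minute on one CPU.

## Known limitations

- The shoving geometry ignores lateral rearrangement; neighborhoods are
  therefore more column-structured than real chamber packings.
- The leakage inference inherits the model's assumptions (ϵ = 1,
  I_C = 20·K_M, shared leakage rate); it is an order-of-magnitude
  positioning of the system in parameter space, not a biochemical
  measurement.
- Lifetime-mean pairing of growth and composition is one of several
  defensible conventions (per-frame pairing is available); results at the
  5 µm radius are insensitive to this choice in synthetic data.
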