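# Methods

This note documents the models implemented in `capnet`, the parameter
choices, the synthetic-data generator's assumptions, and the numerical
decisions taken where the underlying procedures were genuinely open.

## Vascular graph model

A traced capillary field is represented as a directed multigraph whose
nodes are vessel segments and whose edges are induced by three-way
junctions. A junction carries a *kind* and exactly three distinct incident
segments: at a `BIFURCATION` the major (parent) vessel supplies two minor
daughters; at a `CONFLUENCE` two minor tributaries drain into the major
collector. Crossings — vessels that overlap in the en-face projection
without connecting — are recorded but never traversed.

**Feeders.** A feeding arteriole is a segment with lumen diameter
strictly greater than 8 µm and no upstream parent within the field.
Analyses that need a flow origin (branch order, feeder distance) raise an
error when no segment qualifies.

**Branch order** is 1 for the feeder and increases by one at each
bifurcation along the upstream path. Confluences do not increment the
order: the convention counts *branching* points, and whether a merge
should also count is ambiguous; we chose bifurcations only and flag the
choice here rather than guess.

**Feeder distance** of a vessel is the summed full length of every
strictly-upstream segment (feeder included) plus half the vessel's own
length, i.e. the along-flow path from the feeder's upstream end to the
vessel's center. When loops, anastomoses or multiple feeders admit several
upstream paths, the path minimizing summed length is used, with exact ties
broken by the lexicographically smallest id sequence (deterministic and
implementation-independent). The shortest path is found by a Dijkstra
search whose heap keys are (cost, id-path), so the tie-break is built into
the ordering.

**Capillary taxonomy.** Each vessel is classified by the junction kinds at
its two ends: AC (bifurcation → bifurcation), VC (confluence →
confluence), TC (bifurcation → confluence), WC ("unorthodox", confluence →
bifurcation), and UNCLASSIFIED when either end's junction is absent from
the field. The classification is total: every segment receives exactly one
label.

**Validation** is report-only. Role conflicts (a segment fed or drained by
two junctions) are detected from the global role table; junctions whose
kind flip removes more conflicts than it creates are reported as kind
mismatches, resolved greedily (flip the most-beneficial junction, retract
its claims, repeat). Sending flow into a feeder counts as a conflict, which
anchors the direction sense when two junctions are otherwise symmetric.

## Junction exponents

At a junction with major radius $R_p$ and minors $R_1, R_2$ (radii = lumen
diameters / 2, no wall correction), the exponent $x$ solves
$R_p^x = R_1^x + R_2^x$. The fit evaluates, for every candidate $x$ on the
grid $\{0.01, \dots, 10.00\}$ (step 0.01), the squared prediction error
$(R_p - (R_1^x + R_2^x)^{1/x})^2$ and returns the minimizing $x$, ties to
the smallest. The step 0.01 makes two-decimal exponents exactly
representable; $x = 0$ is excluded because the $1/x$ root is undefined.
The power mean is evaluated as $R_{max}(1 + (R_{min}/R_{max})^x)^{1/x}$
for numerical stability at large $x$.

Admissibility: a junction is fittable only when all three radii are
available and the classical parent (upstream vessel at a bifurcation,
collector at a confluence) is the widest — the power-mean form cannot
yield a parent narrower than the widest daughter. "Widest" uses a 0.01 µm
margin: radii equal within measurement precision count as not-widest.

Per vessel of interest, an UPSTREAM record is fitted at its supplying
junction (always a bifurcation/arteriolar junction) and a DOWNSTREAM
record at its collecting junction (always a confluence/venular junction).
No exclusion is applied at fit time; outliers (exponent > 4) are handled
only by the report's sensitivity rerun.

## Depth profiles

The OCTA stack holds en-face slabs of 40 µm thickness labelled by distance
above the PR1 band (outer-edge convention), 60–220 µm in 20 µm steps by
default (step configurable). For each vessel ROI the per-slab mean, min,
max and SD of gray values are extracted; the vessel depth is the label of
the slab with the maximal mean — a discrete argmax, matching the
stack-position readout convention. No sub-slab interpolation is applied by
default; a 3-point parabolic refinement is available but off. Exact ties
resolve to the smallest depth and set an explicit `ambiguous` flag; an
all-flat profile raises. Peak quality (peak mean / median of means)
accompanies each readout. Depth histograms for reporting use 25 µm bins
centred on multiples of 25.

## Lumen diameters

The straightened division image has rows = cross-sections, columns =
transverse position, with a known centerline column. Lumen pixels are
isolated by an automatic threshold: an Otsu split seeds a *half-height*
refinement — background level = median below the Otsu threshold, band
amplitude = median of the columns straddling the centerline, final
threshold halfway between. Pure Otsu sits below half height on blurred
bands and above it on noisy ones, biasing widths by up to ~0.4 µm at
capillary calibres; the half-height edge is the unbiased boundary under
the blurred-band model below.

Masked pixels are expressed by their signed distance from the centerline
and fit by maximum likelihood under the generative model *uniform
occupancy on $[-D/2, +D/2]$ convolved with a Gaussian edge blur*
($\sigma$ = `blur_sd`, a nuisance). The likelihood integrates the model
density over each pixel's extent (via the closed-form antiderivative
$H(z) = z\Phi(z) + \phi(z)$), so an unblurred integer-pixel band is
recovered exactly. A $10^{-4}$ uniform contamination keeps stray
thresholded pixels from dominating (they widen the bootstrap CI instead of
dragging the fit). Because the likelihood ridge at $\sigma \to 0$ is
non-smooth, the optimizer is a vectorized coarse-to-fine grid search
(160 × 13 coarse grid, two refinement rounds, ~10⁻⁴ µm final resolution)
rather than a gradient method.

Identifiability caveat: with zero image noise the thresholded mask has
deterministic sharp edges regardless of optical blur, so `blur_sd` is not
identifiable and the fit returns ~0 while still recovering the diameter;
the blur nuisance takes meaningful values only in the noisy regime. Under
realistic blur (0.75 µm) and noise (15 % of band amplitude) the diameter
bias is below 0.11 µm across 3–8 µm vessels (mean over seeds, 200 rows).

**Bootstrap CI.** Rows are resampled with replacement B = 1000 times
(explicit seed; warning below B = 100) and the diameter re-fit on each
resample; the 95 % interval is the 2.5/97.5 percentile of the
re-estimates, expanded if necessary to bracket the point estimate. The
interval form (percentile vs normal-approximation) was unspecified
upstream; percentile was chosen for its simplicity and range-respecting
behaviour. A full-width-at-half-maximum estimator is provided for
comparison.

## Flow metrics

A velocity trace is sampled at 200 or 300 Hz for at most 3.4 s. The raw
parameters are the trace extrema ($V_{max}$, $V_{min}$), the arithmetic
mean ($V_{ave}$) and pulsatility $(V_{max}-V_{min})/(V_{max}+V_{min})$,
computed on the unsmoothed trace by default (an optional odd-width
moving-median window is available for spike suppression; the mean is
always over raw samples). Per-cardiac-cycle segmentation is deliberately
not attempted: acquisitions are not cardiac-gated. Velocities are treated
as mm/s throughout (the convention of the kymograph-based velocimetry this
package consumes).

## Statistics

Pearson correlations are complete-case per variable pair, two-tailed, at
significance level 0.05 (flags also at 0.01), with p from the t statistic
$r\sqrt{(n-2)/(1-r^2)}$ on $n-2$ df (delegated to `scipy.stats.pearsonr`;
the test suite cross-checks the closed form to 1e-12). Strength categories
by |r|: [0, 0.30) negligible, [0.30, 0.50) low, [0.50, 0.70) moderate,
[0.70, 0.90) high, ≥ 0.90 very high (left-closed bins; the scale upstream
stops at 0.90, the extra label covers the remainder). No multiple-testing
correction is applied, matching the exploratory design. The sensitivity
rerun drops vessels with downstream junction exponent above a threshold
(default 4) and re-correlates JE_downstream with $V_{ave}$ and $V_{min}$,
reporting how many vessels were removed.

## Synthetic data: the stated world

The generator realizes the cohort structure the analysis assumes, with
full ground truth. Defaults (one place, never tuned per-test):

| parameter | default | rationale |
|---|---|---|
| capillary diameter | 4.33 ± 0.9 µm | measured capillary calibre of the cohort |
| feeder diameter | > 8 µm (derived) | feeder definition; radius back-computed from the capillary target through the exponent identity, ≥ 8.8 µm |
| tree depth | 3 bifurcation generations | yields terminal calibres near 4.3 µm from a ~10 µm feeder at exponent ≈ 2.2 |
| true exponents | N(2.2, 0.7) clipped to [1.0, 4.5] | observed junction-exponent distribution centre ~2.2 |
| segment lengths | N(75, 25) µm, floor 15 µm | feeder distances spanning a few hundred µm |
| depth mixture | 150 ± 10 (w = 2/3), 200 ± 10 (w = 1/3) µm, clipped to [70, 215] | bimodal depth distribution, deep peak ~2× the superficial one |
| sampling | 200 Hz × 3.0 s = 600 samples | standard acquisition; 300 Hz option |
| cardiac frequency | 1.0 Hz | 60 bpm, healthy young adults; integer cycles over 3 s make the sampled mean exact |
| mean velocity | 2.0 ± 0.3 mm/s | capillary RBC velocity scale |
| pulsatility at feeder | 0.55, linear decay 5·10⁻⁴ /µm | cardiac imprint dampens over a few hundred µm (exponential option) |
| trace noise | 0.05 mm/s per sample | velocimetry jitter |
| depth stack | signal 50, noise SD 10 gray levels (SNR 5), background 20, bell σ = 20 µm | σ ≈ half the 40 µm slab thickness, the bell-shaped slab response |

**Network construction.** Each feeder bifurcates top-down for
`tree_depth` generations; at every bifurcation an exponent is drawn and
the parent's $R^x$ mass is split with a U(0.35, 0.65) share, so the
junction identity holds *exactly* at the drawn exponent. Terminal
capillaries then merge pairwise through confluences whose collector radius
is computed from the identity (the collector is necessarily widest), up to
a single venule. An optional `unorthodox_fraction` converts first-level
collectors into WC segments by giving them a downstream bifurcation.
Ground-truth branch orders and feeder distances are computed during
construction with the same shortest-path rule the analysis uses, so
recovery tests can assert exact equality.

**Velocity traces** are raised cosines
$v(t) = V_{ave}\,(1 + P\cos(2\pi f t + \phi))$ plus Gaussian noise,
clamped positive. The raised cosine is the simplest periodic form whose
pulsatility is analytic ($(V_{max}-V_{min})/(V_{max}+V_{min}) = P$
exactly); the true pulse shape is not specified by the measurements this
emulates. Phases are drawn on the sample lattice so the sampled extrema
hit $V_{min}/V_{max}$ exactly in the noiseless case. Pulsatility follows
the configured decay with feeder distance; $V_{min}$ then rises with
distance through $V_{min} = V_{ave}(1-P)$, or via an explicit
`vmin_slope`. A calibration mode embeds a *target* Pearson r between a
covariate and a response by converting it to a regression slope,
$b = \frac{r}{\sqrt{1-r^2}} \cdot \frac{\sigma_{noise}}{\sigma_x}$, using
the realized covariate SD over the analyzed cohort (the terminal
capillaries); the slope is fixed before any response is drawn.

**What the generator does not emulate**, and hence what a green recovery
test does not establish: adaptive-optics image formation, eye motion and
aliasing, leukocyte/plasma gaps, pressure–resistance hemodynamics,
vessel-wall thickness, correlated measurement error between radii at a
junction, and the spatial layout of real capillary beds (ROIs are placed
on a grid; traces are independent across vessels given the embedded
effects). Determinism is absolute: every generator is a pure function of
(config, seed) with its own `numpy` Generator stream.

## Pipeline and IO

CSV dialect: comma, header row, UTF-8, '.' decimal. The depth stack is a
multi-page float TIFF (pages in increasing depth) with a JSON sidecar of
depth labels; masks are an integer label TIFF with a JSON label map. The
supplementary-workbook importer takes an explicit column map (field →
header, optional sheet) because no workbook schema is standardized.
`simulate` + `analyze` under fixed seeds are byte-identical across reruns;
the manifest records seeds, versions and outputs and contains no
timestamps. CLI exit codes: 0 success, 2 schema/configuration error,
3 analysis error.

## Known limitations

- Branch order at confluences is a convention (not incremented); data with
  many merges would be sensitive to it.
- Multiple-feeder assignment uses nearest-by-path; the field practice when
  two arterioles supply one region is not standardized.
- The diameter model assumes a symmetric straight band; curved or tapering
  vessels must be straightened upstream.
- `blur_sd` is a nuisance, under-estimated when thresholding truncates the
  profile shoulders; only the diameter is a calibrated output.
- Depth readout is quantized to the slab grid (20 µm); reported depth
  ranges finer than the grid cannot be resolved without interpolation.
- Correlations treat vessels as independent; subject-level clustering is
  not modelled (no mixed effects), matching the exploratory scope.
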