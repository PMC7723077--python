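# Methods

## Ratiometric model and correction chain

The measurement model treats each scene as three co-registered channel
images. Net signals are obtained by subtracting per-channel mean
backgrounds estimated from a sensor-free reference; negative
post-subtraction pixels are clamped to zero and counted (the count is a QC
output, never silently discarded), since mean-background subtraction
under-determines how negatives should propagate. Bleedthrough
coefficients are through-origin least-squares slopes over single-
fluorophore reference framesets — α from DA vs DD on a donor-only
specimen, β from DA vs AA on an acceptor-only specimen — with the top and
bottom 1% of per-pixel ratios trimmed as a hot-pixel guard when enough
pixels are available. ROI emission ratios are intensity-weighted
(ΣF_sens/ΣDD_net) rather than means of per-pixel ratios: the weighted form
is unbiased under shot noise at low counts, while per-pixel ratio maps
remain available for display. Pixels whose net donor signal falls below an
intensity floor (default 3× the read-noise SD) are excluded; an ROI with
no admissible pixels returns a flagged, ratio-free measurement rather than
an error value.

## Calibration

The isotherm R(C) = R_min + (R_max − R_min)·C/(K_d + C) is fitted by
nonlinear least squares (scipy `curve_fit`) with grid-seeded starts: K_d
is profiled over a log-spaced grid on which the model is linear in
(R_min, R_max), and the best grid point seeds the full three-parameter
refinement with tight (1e-14) convergence tolerances so that noiseless
data are recovered to better than 1e-9 relative. Raw replicate tables are
fitted point-wise and unweighted (replicates share one noise scale);
aggregated tables are weighted by the standard error of each level mean.
K_d ± SE comes from the scaled parameter covariance. Long-run calibration
of the ±2·SE interval was measured at 94.9% over 1000 simulated designs
(7 levels, 8 replicates, ratio noise SD 0.05), indistinguishable from the
95.4% nominal value; a log-K_d parameterization gives identical coverage.

Concentration estimates are gated to a fractional-saturation window,
default 20–80%, computed from the fitted isotherm as
C = K_d·S/(1 − S) (giving 1.85 and 29.6 mM at K_d = 7.4 mM). Published
summaries sometimes quote window bounds that do not satisfy this identity
(e.g. bounds derived from observed in vivo ratio limits); such bounds are
honored only as explicit configuration overrides, stored verbatim with
`source="config"`, never inferred. Out-of-window estimates are retained
and censor-flagged rather than dropped so zone summaries can report
censoring rates; ratios at or beyond the fitted asymptotes map to the
corresponding bound with a censor flag instead of 0/∞. Concentration
uncertainty is reported under the uniform-relative-error convention
(the K_d relative error applied across the window) with the full
delta-method propagation attached as a per-estimate diagnostic.

## Volumetry

Cytosolic volume is the count of above-threshold voxels times the voxel
volume (default 0.06 µm³ from a 0.5 µm z-step). Thresholds are computed
per optical slice with Otsu's method (a fixed-threshold mode exists for
reproducibility tests). Because Otsu on a single-class slice simply splits
the noise, a bimodality guard rejects a slice's threshold unless the two
classes separate by more than four times their internal spread; rejected
and zero-contrast slices contribute nothing and are recorded as NaN
thresholds (empty slices warn, they do not raise). No morphological
cleanup is applied by default — regions of interest are assumed drawn
around single cells — and a sphere phantom at default voxel size recovers
its analytic volume within 5% for radii ≥ 3 µm (discretization bound).
Unit conventions are fixed package-wide: 1 µm³ = 1 fL, 1 pL = 1000 µm³,
1 mM × 1 µm³ = 10⁻³ fmol.

## Kinetics and flux decomposition

The cyanide assay is modeled as a saturating exponential: cytosolic Pi
rises from its baseline by Δ·(1 − e^(−t/τ)) after treatment at t = 0,
where Δ is the recycling delta under CN alone and the recycling delta plus
(1 − sequestration fraction) times the uptake delta under CN with external
Pi. The plateau statistic is the mean of the top-3 points of the smoothed
(5-point moving average) post-treatment trace minus the pre-treatment
baseline mean; a raw maximum would be biased upward by shot noise. The
plateau time is the first crossing of the smoothed trace into the 5%
neighborhood of the plateau level. The crossing is anchored on the tail
mean of the smoothed trace rather than on the top-3 maximum: the top-3
statistic is biased upward by about 1.5σ, and anchoring the crossing on it
was measured to delay detected plateau times by 10–20% past the generated
8–10 s window, whereas the tail mean is unbiased once the trace has
converged. Negative uptake deltas are reported with a QC flag, not
truncated, so zones with no resolvable uptake remain distinguishable from
clamped artifacts. The uptake amount uses an 8-s assay duration
(configurable) and is summarized under both aggregation orders — mean of
per-cell Δ·V products and product of zone means — because the two differ
whenever Δ and V co-vary and published summaries do not always state the
order. The concentration detection floor defaults to 0.4 mM, one standard
error below the smallest uptake delta the assay design resolves.
Sequestration is a difference of genotype means with errors propagated in
quadrature; per-plant pairing across genotypes is impossible. Depletion
series conserve mass by construction: cumulative uptake per seedling is
(C₀ − C(t))·V_well/n_seedlings, clamped at zero, with a QC flag when a
well's concentration rises above its initial value beyond tolerance.

## Synthetic data generator

The forward model renders the three channels from a Pi field, a sensor
model, and an acquisition model. In the default (`responsive`) mode the
net donor emission is constant and all concentration dependence sits in
the sensitized component, making the corrected ratio exactly
isotherm-shaped; `null` renders a Pi-insensitive control sensor (constant
midpoint ratio); `physical` quenches the donor with FRET efficiency
proportional to occupancy, so the ratio is hyperbolic in occupancy and
deviates from the pure isotherm between its endpoints — a robustness probe
for the fitting stage. Noise is Poisson on the expected photon signal
(including background) plus Gaussian read noise; disabling both gives
exact renders used by closed-loop identity tests. Defaults: photon scale
5000 counts per unit fluorophore signal (bright EMCCD regime), background
100 counts, read noise 5 counts, α = 0.3 and β = 0.1 (typical
CFP/YFP-class values; real instruments must estimate their own), pixel
size √0.12 µm and z-step 0.5 µm so the voxel volume is 0.06 µm³. Every
dataset carries a ground-truth record and regenerates bit-identically from
its seed.

Study-condition defaults mirror the experimental design being emulated:
steady-state zone means of 4 (MZ), 10 (TZ), 7 (EZ), 6 (DZ), 4 (MR), and
5 (LRC) mM under replete growth, scaled by 0.75 under starvation;
recycling deltas of ~0.5 mM in the apical zones and ~1.2 mM in the basal
zones; uptake deltas drawn from 0.78 ± 0.07 (LRC), 0.84 ± 0.02 (MZ), and
0.47 ± 0.07 (TZ) mM; per-zone cytosolic volumes drawn from the reference
table in `rootpi.reference`; kinetic plateau times uniform in 8–10 s with
τ = t_plateau/ln 20 so the noiseless trace reaches its 5% neighborhood
exactly at the drawn time; calibration series of 7 levels spanning
0–30 mM with 8 replicates and ratio noise SD 0.05; depletion wells of
0.5 mL and 12 seedlings starting at 0.25 mM. The in vitro converter
sensor for medium assays uses a synthetic K_d of 0.08 mM with a typical
ratio range; its real counterpart's parameters are not published.

What the generator does not emulate: optics (no PSF convolution,
scattering, or depth-dependent spectral effects), photobleaching,
registration error, root growth or movement, and biological covariance
between cells of one plant. Passing recovery tests therefore demonstrates
correctness of the analysis chain under the stated noise model, not
robustness to these real-data effects.

## Statistics and orchestration

Zone comparisons use one-way ANOVA with Tukey's HSD (statsmodels) and a
compact letter display computed by the insert-and-absorb algorithm,
cross-checked in tests against brute-force pairwise significance;
two-group designs use Student's t or the two-sample Kolmogorov–Smirnov
test; α = 0.05 throughout. Statistics are computed on per-cell values
with plant identity retained, and zone letters are emitted for both
per-cell and per-plant aggregations since nesting conventions vary.
Zone boundaries along the root axis (MZ [0, 200), TZ [200, 350),
EZ [350, 700), DZ [700, 1500), MR [1500, ∞) µm) are configuration
placeholders — plausible for a young primary root, not measured values —
and are config-mandatory for non-synthetic data; assignment uses half-open
intervals, so a boundary point belongs to the distal zone. Pipeline runs
are deterministic given their seed and write resolved configuration
alongside outputs. The kinetic time-lapse renderer emits single-slice 2-D
framesets, matching the acquisition geometry of fast ratio imaging
(volumes come from separate Z-stacks); recovery studies run the full
chain — reference framesets, background, coefficients, ratio, inversion,
plateau, volumetry — per cell.

## Problem sizes

Recovery studies default to 100 cells per apical zone (LRC, MZ, TZ) for
flux recovery, a 10-point sequestration-fraction grid with 6 cells per
genotype, 200 seeded calibration designs, and 30 replica-study seeds with
20 cells per zone. The basal zones (EZ, DZ, MR) are exercised through the
detectability arithmetic rather than uptake recovery, since their true
uptake deltas sit below the assay's concentration detection floor and a
relative recovery error is undefined at zero truth.
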