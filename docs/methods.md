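# Methods

## 1. Measurement model

A nucleus with DNA content `c` (in "N units": G1 = 2, G2/M = 4) stained
with a DNA-intercalating dye and imaged for `t` milliseconds yields an
expected integrated signal

    S(c) = gain · t · sat(c),        sat(c) = c·K / (c + K),

where `gain` is detector counts per N unit per millisecond and `K` (N
units) is the half-saturation constant of the staining response. `K → ∞`
is the linear regime; decreasing `K` emulates increasing dye
concentration, compressing the 4N:2N signal ratio from 2 toward 1
(`sat(4)/sat(2) = 2(2+K)/(4+K)`), which is exactly the mechanism that
destroys the two-peak histogram when staining is over-concentrated. The
mapping from dye concentration to `K` is monotone but otherwise
unspecified — no quantitative staining curve is available, so `K` is the
simulator knob and concentrations are only labels.

### Population model

Per-cell DNA content is drawn from a five-component mixture:

| component | content law | meaning |
|-----------|-------------|---------|
| G1        | `2(1+ε)`    | pre-replication, 2N |
| S         | `U(2,4)·(1+ε)` | replicating, uniform through the band |
| G2/M      | `4(1+ε)`    | post-replication, 4N |
| debris    | `U(0.5, 1.8)` | sub-G1 fragments |
| doublet   | sum of two independent cycling draws | two adjacent cells quantified as one object |

with `ε ~ N(0, cv)`. The content CV (default **0.06**) lumps biological
and staining/measurement spread; 6% is a typical G1-peak CV for imaging
cytometry of adherent cells (flow instruments do better, image-based
quantification rarely does). Note the spread is applied to content
*before* saturation: under strong saturation the rendered clusters narrow
together with their spacing, so in this model the two-peak collapse is
driven by peak-ratio compression rather than by cluster overlap.

### Rendering

Each nucleus is a radially symmetric 2-D Gaussian disk, σ = radius/3,
truncated at the radius (3σ) and discretely normalised so the stamped
mass equals `S(c)` exactly — that makes integrated-intensity oracles
analytic. Radii are `N(5.0, 0.5)` px by default; magnification maps onto
radius (up) and cells per field (down). Noise: Poisson shot noise on
expected signal counts, Gaussian read noise/offset as background
(default 100 ± 1 counts), rounding, and hard clipping at `detector_max`
(default 65535; set 4095 to emulate a 12-bit camera). Non-clumped nuclei
keep a ≥ 4 px rim gap; with probability `clump_prob` a nucleus is placed
touching a previous one at centre distance 0.7–0.9 of the summed radii,
so the thresholded masks genuinely merge. All randomness derives from a
single integer seed; identical configuration gives bit-identical output.

## 2. Quantification

- **Threshold**: default is background-anchored — `median + 3·(1.4826·MAD)`
  of the whole field. Otsu is available as an option, but its threshold
  tracks foreground amplitude, which makes mask size grow with nucleus
  brightness; that both biases integrated-intensity ratios (a 4N nucleus
  captures a larger fraction of its profile than a 2N one) and lets
  area-based clump flagging catch bright singletons. The
  background-anchored threshold keeps every mask at essentially the full
  truncated disk whenever nuclei are bright relative to read noise, so
  area is a pure geometry signal.
- **Post-processing**: hole filling, components with area < 30 px
  removed, labels grown 2 px (`expand_labels`, which never merges
  neighbours) to recover the dim rim below threshold.
- **Background**: median of pixels outside the segmentation (median of
  the sub-threshold class when no mask is available) — robust for fields
  up to roughly half-covered by nuclei.
- **Integrated intensity**: Σ(pixel − background) over the label,
  clamped at 0.
- **Flags**: `edge` (label touches the border; partial nuclei bias
  content low), `saturated` (> 5% of pixels at `detector_max`), `clump`
  (area > **1.4** × median area). Flagged records are excluded from
  cytometry. The 1.4 factor sits > 2σ above singleton area variation
  (radius CV 10% ⇒ area CV ≈ 20%) yet below the ≈ 1.5–1.9× area of two
  merged disks; a 1.8–2.0 cut-off would miss most true mergers because
  the overlap lens keeps a merged pair's union well under twice a single
  disk. No watershed splitting is attempted — mergers carry the summed
  DNA of two cells, so they are discarded, not repaired.

## 3. Cytometry

- **Histogram**: fixed interval of 60 counts on raw integrated
  intensities (binned first, axes normalised afterwards), half-open bins
  `[origin + i·60, origin + (i+1)·60)`. The absolute meaning of "60"
  depends on the camera/software intensity units, so the interval is a
  parameter; the reference optics place the G1 peak near bin 60, which
  resolves the 2N/4N structure without starving bins of counts.
- **Peaks**: local maxima of a 3-bin centred moving average (rounded to
  collapse float jitter so smoothed plateaus have a well-defined
  midpoint). Candidate pairs must satisfy `1.6 ≤ g2/g1 ≤ 2.4`; among
  qualifying pairs the score is combined height down-weighted by
  `|ratio − 2|/1.2`. DNA doubling makes 2 the expected spacing; the
  down-weighting matters on strongly G1-arrested populations, where the
  small 4N mode must beat noise bumps on the S shelf. No admissible pair
  ⇒ `UnimodalHistogramError`, the saturation failure mode.
- **Gates**: automatic gates are multiplicative bands `peak·(1 ± w)`
  around each peak with S the residual band between them; manual gates
  from config take precedence. Default **w = 0.15**. With S uniform on
  (2,4), a window factor `w` sends a fraction `2w` of S-phase cells into
  the G2/M window while the S window keeps `1 − 3w`; at `w = 0.2` the S
  spill alone can exceed the entire G2/M gate content of a strongly
  G1-arrested population (e.g. gated S ≈ 15%, G2/M ≈ 12%), making such
  populations unrepresentable. `w = 0.15` keeps all reference conditions
  representable while still covering ±2.5 content CVs around each peak.
- **Fractions**: every event lands in exactly one of G1/S/G2M/ungated
  (`[lo, hi)` semantics ⇒ deterministic ties); fractions sum to 1.
- **Two-peak score**: `1 − valley/(smaller peak)` on smoothed counts,
  clamped to [0,1], 0 when peak pairing fails. In this generator the
  score stays high while two peaks are resolvable and drops to 0 at the
  pairing collapse (see §1 on why the valley barely fills first).

## 4. QC

Over-exposure: fraction of in-nucleus pixels at `detector_max` > 1%
("flat peaks"). Under-exposure: median over nuclei of
`(peak − background)/background σ` < 3 ("missing peaks"); a field with no
detectable nuclei is under-exposed by definition. Surfaces for visual
inspection use block-**maximum** downsampling so clipped plateaus survive.
Both thresholds are configurable; the defaults encode the qualitative
criteria ("flat" and "missing" peaks) as conservative numbers.

## 5. Statistics

Replicate summaries are per-phase mean ± sample SD (n−1). Significance
across conditions is classical one-way ANOVA per phase with (k−1, N−k)
degrees of freedom; degenerate zero-within-variance inputs resolve to the
limits (p = 1 identical, p = 0 separated). No multiple-testing correction
is applied across phases — per-phase tests are reported as-is, matching
standard practice for this experiment type; treat marginal p-values
accordingly.

## 6. Calibrated recovery experiments

Reported results of this kind are *gated* fractions, so the benchmark
generator must be steered in gated terms. Because S spans the whole 2N–4N
band, S cells leak into the G1 and G2/M windows, debris leaks into G1,
and doublets (mostly 2N+2N = 4N) land in the G2/M window; the mixture
producing a target set of gated fractions therefore differs from the
targets themselves. `mixture_for_gated_fractions` estimates the
phase-to-gate assignment matrix by Monte Carlo (200k draws per phase,
fixed internal seed so study conditions never drift with run seeds) and
solves the 3×3 linear system for the cycling fractions, holding doublets
at 3% (a typical residual clump rate after flagging) with debris taking
the remainder; the doublet composition is fixed-pointed over 3
iterations. Targets that would need a negative component raise
`InfeasibleMixtureError` rather than being silently clipped.

The end-to-end experiment (`recover_phase_fractions`) renders ~2000
nuclei per replicate at 150 cells per 900×900 px field in the bright
linear regime (gain 360 counts/N/ms, 5 ms, 16-bit detector, no clumps),
runs the full pipeline, and compares recovered to target percentages.
Three replicates of 2000 nuclei put the per-phase standard error of the
mean near 0.6 pp, comfortably inside the ±2.5 pp band used by the
acceptance tests; those problem sizes are also what keeps the whole
suite in the minutes range.

## 7. What the generator does and does not emulate

Emulated: proportionality of integrated signal to DNA content, staining
saturation, shot/read noise, detector clipping, debris and doublets,
touching nuclei, exposure and magnification effects, field-of-view edge
truncation. Not emulated: optical PSF and defocus, photobleaching,
z-structure, uneven illumination, chromatin texture, cytoplasmic
autofluorescence, cell-to-cell staining heterogeneity beyond a single CV,
and any real staining chemistry (the K-to-concentration mapping is
qualitative). Passing recovery tests therefore demonstrates correctness
of the measurement and gating chain under a faithful noise model — not
robustness to every artefact of real microscopy; on real data the manual
gate pathway and the QC screens carry correspondingly more weight.

## 8. Known limitations

- Peak location is histogram-mode based; on ~2000-cell samples its
  jitter (±1–2 bins) is the dominant noise source in the S fraction.
- Clump flagging is purely area-based; mergers of a small pair can slip
  under 1.4× median, and it assumes nucleus size is roughly
  content-independent (true here, approximately true for real nuclei).
- The background estimator assumes nuclei occupy well under half the
  field.
- `sat()` is a single-site binding curve; real DAPI binding kinetics are
  more complex.
- No model-based histogram deconvolution (Watson / Dean–Jett–Fox): S is
  gated geometrically, so S fractions depend on the gate width
  convention, exactly as with manual flow-cytometry gating.
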