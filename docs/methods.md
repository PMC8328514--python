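# Methods

This note documents the models, defaults, and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## SEC deconvolution and the oligomer level

A size-exclusion trace of a receptor preparation is modeled as a sum of
Gaussian elution peaks over a slowly varying baseline. Species elute in
order of hydrodynamic size: high-molecular-weight (HMW) oligomer first,
then dimer, then monomer.

**Baseline.** The default method fits a straight line through two flank
anchors (first and last 5% of the trace, configurable). Each anchor is
the 5th percentile of the detrended flank plus 1.645 σ̂, where the flank
slope comes from split-half medians and σ̂ from first differences
(σ̂ = sd(Δy)/√2). The percentile makes the anchor robust to a peak tail
leaking into the flank; the additive term removes the percentile's
downward bias under Gaussian noise, so for a clean flank the anchor
equals the local baseline mean. An iterative asymmetric-least-squares
baseline (Eilers-style, λ = 1e10, p = 0.001) is available for curved
baselines; it hugs the lower noise envelope and therefore biases areas
upward by roughly 1.5 σ of the noise — use it only when the baseline is
visibly nonlinear.

**Fitting.** `fit_peaks` fits n Gaussians (default 3, at most 6) by
bounded least squares (lmfit). Initialization: peak candidates from
local maxima of a Savitzky–Golay smoothed trace, ranked by prominence;
amplitude from trace height; width from the half-width at half maximum.
If fewer candidates than requested peaks are found, the fit falls back
to the detected count with a warning. Non-convergence triggers up to 5
restarts with centers jittered by 2% of the elution span (seeded, so the
whole procedure is deterministic for a given input and seed). A manual
elution window and fixed or shared per-peak widths are available for
low-signal traces where automatic initialization is unreliable. Areas
are integrals of the fitted analytic Gaussians (A = amp·σ·√2π), never
numeric integrals of the raw grid, and the elution axis is used as
given, never resampled.

**Species assignment.** The default ordinal rule maps peaks by ascending
elution: last peak monomer, second-to-last dimer, anything earlier
pooled into HMW (a broad HMW population is routinely fit with two
Gaussians). Two peaks read as dimer + monomer. One peak is ambiguous
under this rule and requires the calibrated-window policy, which assigns
each peak to the elution window containing its center and rejects peaks
straddling two windows.

**Levels and uncertainty.** With species areas A_H, A_D, A_M, the levels
are A_D/A_M, A_H/A_M and their sum. Variances come from the fitted area
covariance via the delta method; reported intervals are ±1.96 SE (95%,
fit variance only). Levels are invariant under absorbance rescaling and
elution-axis shifts; on noiseless input the summed fitted areas match
the trapezoidal integral of the corrected trace within 1%.

## Blot densitometry

Lane profiles are 1-D (position, intensity) series; lane extraction from
images is out of scope. The default background is a straight line
between noise-robust flank anchors (same estimator as the SEC baseline),
exact for offset and drift backgrounds. A morphological opening
(rolling minimum then rolling maximum, window 30% of the lane) is
available for curved backgrounds; it is exact on flat backgrounds but
biased under bands when the background drifts, which is why it is not
the default. Bands are integrated trapezoidally over user-supplied
windows (band selection was interactive in the original workflow);
dimer level = dimer area / monomer area. Ladder calibration
(position → kDa, monotone log-linear interpolation) labels bands and
never enters quantification.

## Interface geometry

Protomers are ordered residues (1-based receptor numbering, 1–412) with
labeled coordinate sites: charged (+/−), polar donor (with attached
hydrogen), polar acceptor, nonpolar, backbone. Region labels (TM1–TM7,
loops, H8, CTERM) ship as an editable annotation file; the default
boundaries are approximate except the C-terminus start (residue 291),
which downstream scoping relies on.

Conventions, fixed and tested at the boundaries:

* dimer criterion: minimum over cross-protomer residue pairs of the
  center-of-mass distance, strictly `< 5 Å` (whole-protomer COMs can
  never approach 5 Å for intact receptors, so residue-level COMs are
  the meaningful reading); minimum-image applied under an orthorhombic
  box;
* contact cutoffs are inclusive (`≤`): electrostatic 5.0 Å between
  oppositely charged sites; hydrogen bond donor–acceptor ≤ 3.5 Å with
  the D–H···A angle within 20° of linearity, restricted to C-terminal
  residues by default (H-bond geometry needs atomistic-style sites;
  coarse sites without hydrogens are rejected explicitly);
* nonpolar contacts use 5.0 Å by default — chosen for consistency with
  the electrostatic cutoff, as no separate value is established —
  configurable;
* interacting helices: TM–TM minimum site distance strictly `< 7 Å`; an
  empty list certifies a non-transmembrane interface;
* helix tilt: angle between the leading eigenvector of the backbone
  coordinate covariance and the membrane normal, folded into [0°, 90°];
  the normal defaults to the fixed z-axis rather than an instantaneous
  bilayer normal.

**Interface classification.** With region-labeled contacts, the call is
*symmetric* when CTERM↔CTERM contacts form the plurality (tail-to-tail),
*asymmetric* when the C-terminus of exactly one protomer contacting
non-CTERM regions of the other forms the plurality (tail-to-loop; the
direction is reported), and *none* without contacts. Ties between the
two asymmetric directions are reported as symmetric, which keeps the
call invariant under protomer relabeling.

**Daura clustering.** Pairwise backbone RMSD after optimal rigid
superposition (own Kabsch implementation; a no-fit mode exists), then
iteratively: the frame with the most neighbors within the cutoff
(default 1.5 Å) seeds a cluster of itself plus neighbors, all are
removed, repeat. Ties on neighbor count go to the lowest frame index;
clusters are ordered by decreasing size, then smallest member. Frames
from multiple replicas may be pooled.

**Contact averaging.** Per sequence segment (e.g. residues 291–334 and
335–394), the mean over frames of the number of *distinct residues*
(either protomer) participating in ≥ 1 contact, with standard deviation.
Whether to count distinct residues or contact events is genuinely open;
the distinct-residue reading is the default and an event-counting mode
is exposed.

## Solution biophysics

* Ionic strength I = ½ Σ cᵢzᵢ² assuming full dissociation; phosphates
  count as drawn in the buffer recipe (H₂PO₄⁻ monovalent, HPO₄²⁻
  divalent), no pKa speciation. The 49 mM Na₂HPO₄ component contributes
  147 mM by this arithmetic and is reported as computed.
* Debye length κ⁻¹ = √(ε₀ εr(T) kB T / (2 NA e² ·10³ I)), with εr(T)
  from the Malmberg–Maryott pure-water equation (a constant override is
  available). At 25 °C this reproduces the κ⁻¹ ≈ 0.304/√I nm rule within
  1%; at 0.34 M and 4 °C it gives 5.27 Å, i.e. electrostatic bonds
  longer than ~5 Å are screened out under cold-room high-salt
  conditions. `is_screened` uses a strict inequality at κ⁻¹.
* Hydropathy: sliding-window mean of Kyte–Doolittle values (default
  window 3, odd); positions without a full window are omitted.
* DSF: fluorescence is smoothed with a 5-point centered moving average
  (odd-reflection padding, so a linear ramp stays exactly linear at the
  edges) and differentiated with central differences. Tm is the global
  derivative maximum above a prominence floor (5% of the dynamic range
  per °C by default). The quench onset is the first temperature after Tm
  where the derivative stays below −20% of the Tm peak for ≥ 3 samples,
  shifted by half the smoothing window to undo the smoothing's edge
  advance. Both thresholds are configuration; the defaults are
  conservative because only an approximate quench temperature (~65 °C)
  is established. Ramp metadata (0.5 °C per 30 s) is stored, not used.
* Turbidity: two A450 thresholds (defaults 0.05 / 0.3) map readings to
  soluble / slight / aggregated; the state is monotone in A450.

## Synthetic data

Generators are pure functions of (seed, parameters) and write the same
external formats the readers consume (CSV, multi-model PDB + annotation
TOML), with every planted quantity in a JSON manifest.

* Chromatograms: Gaussian peaks over a linear baseline with additive
  i.i.d. Gaussian noise; SNR is defined as tallest peak amplitude over
  noise σ (default 50; no noise model is established for the
  instrument, so i.i.d. Gaussian is assumed). Default peaks emulate a
  Superdex-200-style separation (HMW 9.0, dimer 11.0, monomer 13.2 mL,
  σ 0.35–0.45 mL, sampled every 0.01 mL) and the default composition
  plants the wild-type levels (dimer 1.14, HMW 0.20, monomer 1);
  presets for the N359 (0.81/0.28) and P354 (0.19/0.43) truncation
  variants reproduce the reported variant levels.
* Lanes: two Gaussian bands over a linear background, band amplitudes
  two orders of magnitude above the background, default dimer level
  1.14 (the untreated wild-type blot).
* Dimers: protomers are labeled point scaffolds — idealized helices for
  TM regions (1.5 Å rise, 1.0 Å coil radius, 100°/residue) and a
  bounded random walk for loops and the disordered tail — *not*
  physically plausible receptors; only the geometric predicates are
  under test. Planted contacts are realized exactly at their target
  distances at well-separated docking slots (25 Å apart, protomer bulks
  150 Å apart), so planted counts are exact and every non-planted pair
  is far beyond any cutoff. A residue may appear in only one planted
  contact; conflicting requirements raise a generation error. Frame
  series displace backbone sites with a per-cluster random field
  (between-cluster RMSD ≫ cutoff) plus per-frame jitter (within-cluster
  RMSD ≈ √6·jitter), leaving side-chain sites — and hence planted
  contacts — fixed across frames.
* Melt curves: rising sigmoid (default midpoint 55 °C, width 2 °C) with
  an optional exponential collapse from the quench temperature (default
  65 °C, τ = 1 °C), sampled at 0.5 °C; turbidity series step from
  soluble through slight (0.25–0.5 M) to aggregated above 1 M NaCl.

What passing tests on these data do **not** show: robustness to
correlated detector noise, peak asymmetry (tailing/fronting), blot
saturation, lane distortion, or physically realistic protein geometry —
none of which the generators emulate.

## Problem sizes and reproducibility

The parameter-recovery suites use 50 seeded replicates per claim
(three-peak traces of ~1000 points at SNR ≥ 30 for levels; planted
contact plans and tilts on 412-residue scaffolds; 100-point melt
curves), sizes at which the whole suite runs in a few minutes on one
CPU. Every random choice flows from an explicit integer seed;
identical inputs, configuration and seed give byte-identical reports
(the CLI embeds a provenance block with the package version, a
configuration hash, and the seed).

## Known limitations

* Gaussian peak shapes only; strongly tailed SEC peaks would need an
  exponentially modified Gaussian, which the fit does not implement.
* The delta-method CIs assume the fit covariance is well conditioned;
  heavily overlapped peaks inflate it honestly but the normal
  approximation may then be poor.
* The ALS baseline's lower-envelope bias (above) makes it a second
  choice for quantitative areas.
* The morphological lane background is biased under bands on drifting
  backgrounds (documented above).
* Periodic-image handling applies to the residue-COM dimer search only;
  contact operators assume the dimer has been unwrapped.
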