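# Methods

This note documents the models, parameter choices and numerical decisions
behind `tandemgc`, and what the synthetic validation does and does not show
about real data.

## The synthetic instrument

The generator emulates a GC×GC-TOF MS platform with tandem ionization: a 5 s
modulation period at 50 Hz per channel (250 spectra per modulation column),
integer-binned m/z over a configurable range (default 45–500 Da; the region
below 500 Da carries all diagnostic fragments of the curated metabolites),
and two parallel ionization channels per run.

**Peak model.** Each compound elutes as a 2D Gaussian blob with default
widths σ₁ = 1 modulation (¹D) and σ₂ = 0.05 s (²D). The ¹D position comes
from the compound's linear retention index, interpolated on an n-alkane
C7–C30 time grid derived from a piecewise-linear oven program (70 °C hold,
10 °C/min to 120 °C, 4 °C/min to 320 °C) rescaled to the simulated run
length; this reproduces the near-linear carbon-number/time relation of
temperature-programmed separations without modelling thermodynamics. The ²D
position is a per-compound elution time within the modulation period. Blobs
eluting across the modulation boundary may split (no wrap-around handling) —
a documented limitation.

**Dual-energy spectra.** 70 eV spectra are dominated by low-m/z TMS-type
fragments (73, 75, 117, 129, 147, 204 ...); 12 eV spectra re-weight intensity
toward compound-specific high-m/z fragments (attenuating the low set to
8–25%), with the per-compound 12 eV TIC response drawn 8–15× below the 70 eV
response — one order of magnitude, matching the channel asymmetry of real
tandem acquisition. Spectra are constructed, not predicted: no ionization
physics is modelled.

**Noise and baseline.** The background is a monotone column-bleed ramp
(0.6→1.4 × the channel level; defaults 23,000 counts TIC at 70 eV, 1,840 at
12 eV) distributed over a polysiloxane bleed spectrum, plus per-pixel
Gaussian TIC noise (σ 5,000 / 50 counts) carried on the bleed profile, plus
Poisson shot noise on blob counts. The σ defaults are chosen so that the
S/N 100 gate maps to 500,000 counts at 70 eV and 5,000 at 12 eV. Because the
Gaussian background noise rides on the bleed spectrum rather than being
drawn independently per voxel, the cube stays internally consistent
(TIC = Σ m/z) at a fraction of the cost; apex-spectrum noise then comes from
shot noise and bleed contamination.

**Retention jitter.** Per-run multiplicative Gaussian jitter with 0.20% RSD
in ¹t_R and 1.90% in ²t_R; a calibration test confirms the empirical RSD over
60 runs matches the configuration.

**Abundance structure.** Per-compound abundances combine a subject-level
lognormal (sd 0.10), a process-replicate lognormal (0.10) shared between the
analytical replicates of a preparation, and an analytical lognormal (0.05) —
reproducing response repeatability around 12% RSD. MUO subjects additionally
scale selected compounds by configured MUO:MHO ratios; with the convention
%Diff = (mean_MUO − mean_MHO)/mean_MHO × 100, a +325.2% difference is the
ratio 4.252. The subject-level sd is deliberately subordinate to the
replicate noise: with only 3-vs-5 subjects and four pseudo-replicates each,
a larger biological variance makes chance subject imbalance statistically
indistinguishable from a class effect for *any* method — a property of such
designs, not of this pipeline.

## Processing decisions

* **Background subtraction** is a grey-scale opening with a flat disk
  (default radius 13 px ≈ 5× the ²D peak width): the rolling ball's intensity
  radius is effectively infinite because TIC scales (10³–10⁶ counts) dwarf
  the spatial extent. The image is Gaussian-smoothed (σ 2 px) before rolling
  so noise pits do not drag the ball down, padded by 2× the radius with edge
  replication (otherwise both morphological passes clip at the border and
  leave a slope × radius residual), and the background is capped at the
  input. Negative residuals are clipped to zero, since downstream volume
  integration assumes non-negative signal. Subtraction operates on the TIC
  image only; apex spectra are read from the raw cube.
* **Noise** is 1.4826 × MAD of (optionally masked) pixels — robust to the
  sparse peaks occupying a small image fraction.
* **Peak detection** uses h-maxima suppression (h = 3 × noise) to merge
  shoulder maxima, then watershed on the inverted TIC restricted to pixels
  above the noise level. Gates: footprint volume ≥ the absolute count
  threshold AND apex/noise ≥ the S/N threshold. Equal-apex ties break toward
  the lower ¹D, then ²D index. The same gates (scaled by the number of runs)
  delineate peak regions on the composite; the apex-S/N gate there is what
  keeps summed background basins from becoming spurious regions.
* **Match factors** implement the weighted cosine with Stein–Scott identity
  exponents (intensity^0.6 · m/z³, configurable); the composite NIST score's
  ratio-of-adjacent-peaks term is deliberately not implemented. m/z are
  aligned by exact integer (nominal mass) equality. Scores are rounded to
  integers in [0, 999]; DMF(s, s) = 999 exactly by Cauchy–Schwarz.
* **Template matching** is greedy one-to-one in descending DMF (ties to the
  nearest RT), windows default to ±1.5 modulations and ±0.15 s — about 3σ of
  the configured jitter at mid-run. The template seeds from the run with the
  highest total TIC; one re-match pass follows transform fitting. The
  retention transform is affine per dimension (least squares); non-rigid
  warping is out of scope.
* **Quantification** warps each run's background-subtracted TIC into
  template space (bilinear) and integrates the region footprints there, so a
  region is the same chemical feature in every run. Regions mapping outside
  a run yield volume 0 with a warning.
* **Statistics.** % response normalization per run; PCA on mean-centered
  % response including QC runs; KW with Dunn's z-tests and Bonferroni over
  pairs (for two groups the KW p gates directly — Dunn degenerates);
  across-features Bonferroni is exposed as an option but off by default.
  PLS-DA uses NIPALS (scikit-learn) on autoscaled features with a binary
  response and 2 components by default; VIP_j = √(p Σ_a SSY_a (w_aj/‖w_a‖)² /
  Σ_a SSY_a), so mean(VIP²) = 1 identically. QC runs are excluded from the
  KW/PLS-DA contrast and retained for PCA.
* **Identification** requires DMF ≥ 900, RMF ≥ 950 and |ΔI^T| ≤ 10, all
  boundaries inclusive; I^T uses ¹D time only (van den Dool–Kratz). Library
  spectra are clipped to the acquisition m/z range before scoring, so
  fragments the detector never saw cannot penalize a match.
* **Fuzzy ratio.** Both composites are divided by their own total response;
  each is max-filtered over the tolerance window (default 3 × 3 px) before
  the per-pixel log2 quotient, which absorbs ≤ 1 px residual misalignment
  and makes the operator exactly antisymmetric under swapping the classes.
  Pixels whose windowed maximum falls below the floor (default 3 × the
  composite noise) are masked to avoid background blow-ups.

## Validation studies and their scope

The reference validation (in `tandemgc.benchmarks`) runs the full pipeline
on five replicate simulations of the 48-run design with 30 compounds on a
400 × 250 grid and 200 m/z bins — sizes chosen to keep a replicate under a
minute while preserving the full study structure. Eight compounds carry
|%Diff| ≥ 50 effects in both directions; the carriers are chosen by seeded
search so the up- and down-regulated total response balances, mirroring the
reported bidirectional pattern (up-regulated saccharides against strongly
down-regulated lactose isomers). Without that balance, % response closure
imposes a systematic apparent class shift on every null compound — a real
hazard of closed compositional data that users should keep in mind when
interpreting selections on real runs.

Pooled over the batch the pipeline flags ≥ 80% of effect compounds by the
joint KW + VIP gate with ≤ 10% of null compounds, and ≥ 90% of compounds
detectable in every run become reliable peaks; a separate 1,000-feature null
simulation checks that the two-group KW selection rate stays inside the
binomial band around α = 0.05, and a 16-run study with 30% of compounds
below the 12 eV gate reproduces the reliable-count ordering
fused ≥ 70 eV ≥ 12 eV. These numbers are recomputed, not stored — see
`scripts/acceptance.py`.

Passing these tests shows the pipeline recovers what the generator injects
under its noise, jitter and closure model. It does not show performance on
real chromatograms, which add wrap-around elution, detector saturation,
co-elution far denser than 30 compounds, derivatization multiplets,
non-affine retention drift, and library spectra measured on other
instruments.

## Known limitations

* Apex-pixel spectra only; no deconvolution of co-eluting spectra. Co-eluting
  compounds can merge into one region (observed as sugar pairs in the worked
  example).
* No wrap-around handling at the modulation boundary.
* The NIST composite similarity (with the adjacent-peak ratio term) is not
  implemented; gate thresholds operate on the pure weighted cosine.
* KW on replicate runs treats replicates as independent (as in the emulated
  workflow); with strong subject-level heterogeneity this inflates
  significance — aggregate per subject before testing if that matters.
* ANDI-MS/netCDF support targets classic NetCDF-3 scan-based layouts written
  by this package; vendor files with scan-dependent m/z axes are not parsed.
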