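# Methods

## Spectral phasor segmentation

Each pixel's spectrum I_k over N wavenumber channels is reduced to the
normalized first-harmonic discrete Fourier pair

    g = Σₖ Iₖ cos(2π h k / N) / Σₖ Iₖ,   s = Σₖ Iₖ sin(2π h k / N) / Σₖ Iₖ

with harmonic h = 1 by default. Two consequences drive the design: any
nonnegative spectrum maps into the closed unit disc, and the map is
invariant to global intensity scaling of a pixel, so segmentation depends
on spectral *shape* only. Pixels with non-positive total intensity are
flagged and excluded from densities; they are never assigned a class.

Chemical classes are selected by polygonal gates in (g, s). Historically
gates are drawn by hand on the phasor density and reused across images; the
`default_gates` constructor automates this by centering a regular hexagon
(circumradius 0.12 by default) on the phasor point of each class reference
spectrum, shrinking hexagons to at most 0.49× the inter-point distance so
gates are always pairwise disjoint, and erroring if two reference points
fall within one gate radius of each other (then only manual gates make
sense). Point-in-polygon uses the even-odd rule with boundary points
counted inside (implemented as a tiny outward tolerance of 1e-9).
Disjointness is enforced at segmentation time, which makes pixel labels
independent of gate order. Manual gates round-trip through a JSON format.

The wavenumber axis defaults to 40 channels from 2800 cm⁻¹ at 5 cm⁻¹
steps. A 2800–3050 cm⁻¹ sweep at 5 cm⁻¹ would imply 51 channels; the
40-channel frame count was kept as the default and the axis is fully
configurable, so either convention is available.

## Percentage steatosis and droplet morphometry

Percentage steatosis is intensity-weighted by definition: the summed lipid
SRS signal over the summed lipid + protein + DNA signal, ×100, with
unassigned signal excluded from the denominator. A pixel-count variant is
available behind a flag for sensitivity checks; on synthetic tissue the two
differ because pure lipid is brighter per pixel than cytoplasm.

Droplets are 8-connected components of the lipid mask (diagonal contact
merges; border-touching components are kept). Equivalent diameter is
2·√(area/π) scaled by pixel size, and the microvesicular/macrovesicular
cutoff sits at 1 µm. Components below `min_area_px` (default 1, i.e. no
filtering) can be suppressed.

Group comparison uses a paired two-tailed Student's t-test with samples
paired by manifest index, mirroring the cohort's paired design even though
the donors are unrelated; an unpaired Welch option exists behind a flag.
Zero-variance paired differences yield an undefined (NaN) p-value with an
explicit degenerate-variance flag rather than a fabricated significance
call.

## cIEF isoform quantification

Electropherograms are peak-normalized (max → 1), then baseline-subtracted.
The default baseline is a running minimum over a quarter-trace window
followed by an equal-width mean smooth, which recovers a constant offset to
within 5 % of its level next to an isolated peak; a linear
endpoint-fit alternative exists. Peak detection runs on a
Savitzky–Golay-smoothed copy (9-point window, order 2) so single-point
noise excursions never seed a peak, with a prominence threshold of 5 % of
the trace maximum; the Gaussian mixture is then refined against the
*unsmoothed* trace by bounded nonlinear least squares. Fitted widths are
constrained to ≤ 0.3 pI units — isoform peaks on a pH 5–8 gradient are
narrow, and the bound prevents a spurious component from absorbing the
noise floor as one huge Gaussian — and components whose refined amplitude
falls below a quarter of the detection threshold are dropped.

PTM assignment is rule-based on the shift from the unmodified peak
(defaulting to the highest-pI peak with ≥ 10 % of the maximum AUC):
shift ≤ −0.35 → acetyl; −0.35 < shift ≤ −0.05 → phospho; shift ≥ +0.05 →
glycosyl; otherwise unmodified. The thresholds are configuration values;
only the directions and the acetyl ≫ phospho magnitude ordering are fixed
by the chemistry. Peaks within a quarter threshold of a rule boundary are
flagged ambiguous. Relative concentrations are fitted-Gaussian AUCs per PTM
class over total AUC — fitted rather than raw trapezoid areas so
overlapping peaks decompose cleanly (raw integration of the whole trace is
available for parity checks at the caller level via the fitted components).

Phosphatase sensitivity is the phospho relative concentration lost between
a paired untreated/treated profile, clipped to [0, 1], with a sensitivity
call at ≥ 0.1. Replicate CV is SD/mean (ddof = 1) of one isoform's share
across replicates, NaN when the mean is zero.

## Synthetic data: what it emulates

**Tissue phantoms.** A frame is protein cytoplasm everywhere, DNA-class
nucleus discs (4 per 100×100 px, radius 3.5 µm), and lipid droplet discs
stamped until the lipid share of total noiseless signal reaches the target
fraction (group means 0.28 NASH / 0.09 normal); a droplet that would
overshoot the +0.03 band is rejected and resampled, with a bounded retry
budget before erroring. Every pixel carries exactly one class spectrum
(Gaussian mixtures: lipid 2850 cm⁻¹ with a 2930 shoulder; protein 2930;
DNA 2960 with a 2930 shoulder), scaled by a smooth log-normal brightness
mottle (σ = 0.10) and per-class amplitudes (lipid 1.8, protein 1.0, DNA
1.2 — lipid CH₂ is brighter per volume). Noise is additive Gaussian at 5 %
of the mean signal; lock-in detection is approximately Gaussian, so shot
noise is omitted. Pixel size defaults to 0.5 µm/px (a 400×400 px frame is
then a 200 µm field and sub-micrometre droplets occupy ~1 px, keeping them
detectable).

Droplet diameters are truncated log-normal. The microvesicular law is
median 0.6 µm, σ_log 0.4, truncated at 2 µm. The macrovesicular law is
median 0.8 µm, σ_log 1.0, truncated at 50 µm: the heavy tail places most
of the lipid *signal* in large droplets (macrovesicular appearance, spans
sub-micrometre to tens of µm) while the median keeps the *detected* mean
diameter close to twice the microvesicular mode's — the two-fold contrast
the analysis is expected to resolve. Detected means are inflated in both
modes by the merging of touching droplets into one connected component,
which is why the law medians are not themselves in a 2:1 ratio.

What the phantoms do **not** model: optical physics (spectral-focusing
chirp, cross-phase modulation backgrounds, stitching artifacts), partial-
volume pixels mixing two classes, 3-D droplet sectioning effects, and
spatial correlation of droplets with hepatocyte anatomy. Passing recovery
tests therefore demonstrates correctness of the segmentation arithmetic
and its noise robustness, not robustness to every real-tissue artifact.

**Electropherograms.** A trace is a constant baseline (0.05) plus Gaussian
isoform peaks (σ = 0.05 pI) with areas proportional to relative
concentrations, peak-scaled to ~1, plus Gaussian noise at 1 % of the peak
maximum — consistent with an assay whose replicate CV specification is
≤ 0.1. Default PTM shifts are −0.15 (phospho), −0.50 (acetyl), and
positive for glycosyl. The λ-phosphatase operator transfers phospho mass
to the unmodified isoform with configurable efficiency (default 1.0,
complete dephosphorylation), conserving total concentration exactly.
Six protein presets (AKT, 4EBP1, BID, HMGCS2, FABP1, FABP5) encode the
NASH-vs-normal perturbation directions (phospho-AKT up in NASH; phospho
down for 4EBP1/BID/HMGCS2/FABP1; FABP5 mainly acetylated in NASH) with
synthetic nominal pI placements; the cohort generator jitters each sample's
mix (σ = 0.03, renormalized) and writes four replicates per protein.

## Cohort report

The cohort table is protein × isoform rows (proteins alphabetical,
isoforms in canonical order with explicit zeros, so per-protein column
blocks sum to 1) by manifest-ordered samples. The differential table
reports group means/SDs, the NASH/normal mean ratio (NaN-flagged for a
zero normal mean), and paired t p-values; no multiple-testing correction
is applied by default (Benjamini–Hochberg behind a flag). The ratio heat
map is drawn on a symmetric log₂ scale with undefined cells greyed out;
the CSV twins carry raw values at 17 significant digits and round-trip
losslessly. `full_report` JSON output is deterministic: sorted keys,
floats rounded to 10 decimals, NaN mapped to null.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale frames (120–400 px square,
40 channels, 1–3 frames per sample) — large enough that a frame holds
hundreds to thousands of droplets and segmentation percentages stabilize
to well under a percentage point, while the whole suite runs in well under
a minute. Determinism everywhere: generators take explicit integer seeds,
per-item seeds derive from a SHA-256 hash of (base seed, index) truncated
to 31 bits, and identical seeds reproduce stacks, traces and manifests
byte for byte.

## Known limitations

- Gates are convex hexagons by default; strongly elongated phasor clusters
  (e.g. from graded lipid/protein mixing) would need manual polygons.
- The 1 µm micro/macro cutoff and the pI-shift thresholds are nominal
  conventions, not fitted quantities.
- Overlapping isoform peaks closer than ~2σ are resolved only as well as
  the Gaussian mixture fit allows; closer peaks merge.
- The paired t-test across unrelated donors is reproduced as the cohort's
  stated design; the Welch option is the statistically safer default for
  genuinely unpaired groups.
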