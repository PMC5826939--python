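# hepatoquant

Quantitative, label-free assessment of non-alcoholic fatty liver disease
(NAFLD) from two complementary measurements:

1. **Hyperspectral stimulated-Raman-scattering (SRS) imaging.** Liver tissue
   imaged across the C–H stretch region (40 channels, 2800 cm⁻¹ in 5 cm⁻¹
   steps) carries a Raman spectrum at every pixel. The **spectral phasor
   transform** maps each pixel's spectrum I_k to normalized first-harmonic
   Fourier coordinates

       g = Σₖ Iₖ cos(2πk/N) / Σₖ Iₖ ,   s = Σₖ Iₖ sin(2πk/N) / Σₖ Iₖ ,

   so chemically similar pixels cluster in the (g, s) plane. Polygonal gates
   around the lipid (2850 cm⁻¹), protein (2930 cm⁻¹) and DNA (2960 cm⁻¹)
   clusters back-project to a per-pixel segmentation. **Percentage
   steatosis** is the lipid SRS signal over the combined lipid + protein +
   DNA signal (×100), and lipid droplets — 8-connected components of the
   lipid mask — are characterized by their equivalent circular diameter,
   split into microvesicular (< 1 µm) and macrovesicular (≥ 1 µm) classes.

2. **Capillary isoelectric focusing (cIEF) immunoassays.** Protein isoforms
   produced by post-translational modification separate along a pH 5–8
   gradient by isoelectric point: phospho- and acetyl-isoforms shift to
   lower pI (acetyl much farther), glycosyl-isoforms to higher pI. Each
   electropherogram is peak-normalized, baseline-subtracted, fitted with a
   Gaussian mixture, and each peak assigned a PTM identity from its pI
   shift; the **relative concentration** of an isoform is its fitted area
   under the curve (AUC) over the total AUC. λ-phosphatase treatment, which
   collapses phospho peaks into the unmodified peak, provides the
   phosphorylation control, scored by the phospho share lost.

Cohorts of normal vs NASH samples are compared with paired two-tailed
t-tests (significance at p ≤ 0.05) and summarized as dual heat maps:
isoform relative concentrations per sample, and NASH/normal differential
ratios.

Because the underlying human biopsies are not publicly available, the
package ships a first-class **synthetic-data module**: ground-truthed liver
phantoms (microvesicular normal mode, macrovesicular NASH mode with
droplets from sub-micrometre to 50 µm) and cIEF traces with known isoform
composition, so every stage of the pipeline is testable end to end.

## Worked example

```python
from hepatoquant import (TissuePhantomSpec, generate_phantom, make_reference_spectra,
                         phasor_transform, default_gates, segment_by_gates,
                         percentage_steatosis, detect_droplets, DEFAULT_AXIS)

spec = TissuePhantomSpec(height_px=200, width_px=200, mode="nash", seed=42)
stack, truth = generate_phantom(spec)
gates = default_gates(DEFAULT_AXIS, make_reference_spectra(DEFAULT_AXIS))
seg = segment_by_gates(phasor_transform(stack), gates)
comp = percentage_steatosis(seg)
droplets = detect_droplets(seg, spec.pixel_size)

print(f"ground-truth lipid fraction: {truth.true_lipid_fraction:.4f}")
print(f"recovered percentage steatosis: {comp.percent_steatosis:.2f}%")
print(f"droplets detected: {len(droplets)}")
print(f"mean equivalent diameter: {droplets.equivalent_diameter_um.mean():.2f} um")
print(f"macrovesicular droplets: {(droplets.droplet_class == 'macro').sum()}")
```

prints

```
ground-truth lipid fraction: 0.2800
recovered percentage steatosis: 28.00%
droplets detected: 435
mean equivalent diameter: 1.47 um
macrovesicular droplets: 183
```

i.e. the full phasor pipeline recovers the phantom's true lipid signal
share essentially exactly, and the NASH-mode droplet population mixes
sub-micrometre and large droplets. The cIEF side works the same way from
the shell:

```sh
$ hepatoquant simulate-cief --out akt.csv --protein AKT --mode nash --seed 3
wrote akt.csv; ground truth {'unmodified': 0.5, 'phospho': 0.5}
$ hepatoquant quantify-cief --trace akt.csv --protein AKT --unmodified-pi 6.2
{
 "phospho": 0.49720628243843734,
 "unmodified": 0.5027937175615627
}
```

recovering the simulated 50/50 phospho split to 0.3 % absolute. Other CLI
commands: `simulate-stack`, `simulate-cohort`, `segment`,
`quantify-steatosis`, and `report` (full cohort analysis with heat maps).

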