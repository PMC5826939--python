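"""Ground-truthed synthetic data: hyperspectral SRS liver phantoms and cIEF traces.

Real SRS liver stacks and capillary isoelectric focusing (cIEF) immunoassay
electropherograms of human biopsies are not publicly deposited, so this module
generates phantoms with the statistical structure the downstream analysis
assumes:

* **Tissue phantoms** — an H x W x C intensity cube over a C-H-stretch Raman
  axis (default 40 channels from 2800 cm^-1 in 5 cm^-1 steps).  Each pixel
  carries the spectrum of exactly one chemical class: hepatocyte cytoplasm is
  *protein* (CH3 stretch, 2930 cm^-1), nuclei are *dna* discs (2960 cm^-1),
  and lipid droplets are *lipid* discs (CH2 stretch, 2850 cm^-1).  Droplet
  diameters follow a truncated log-normal law: a *normal*-liver mode with
  sub-micrometre (microvesicular) droplets and a *nash* mode with droplets up
  to 50 um (macrovesicular).  Droplets are placed until the lipid share of the
  total noiseless SRS signal hits a target fraction, which becomes the ground
  truth the segmentation pipeline is scored against.

* **Electropherograms** — chemiluminescence traces on a pI 5-8 axis built
  from Gaussian isoform peaks.  Post-translational modifications shift the
  isoelectric point: phosphorylation and acetylation toward lower pI (acetyl
  much farther than phospho), glycosylation toward higher pI.  A lambda
  phosphatase operator transfers phospho mass back to the unmodified peak,
  emulating the wet-lab dephosphorylation control.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile

__all__ = [
    "SpectralAxis",
    "ReferenceSpectrum",
    "HyperspectralStack",
    "DropletLaw",
    "TissuePhantomSpec",
    "PhantomGroundTruth",
    "IsoformSpec",
    "ElectropherogramSpec",
    "Electropherogram",
    "make_reference_spectra",
    "generate_phantom",
    "generate_electropherogram",
    "apply_phosphatase",
    "generate_cohort",
    "PROTEIN_PRESETS",
    "DEFAULT_AXIS",
    "CLASS_AMPLITUDES",
]

ClassLabel = Literal["lipid", "protein", "dna"]
PTMType = Literal["unmodified", "phospho", "acetyl", "glycosyl"]

# integer codes used in label images
LABEL_CODES = {"unassigned": 0, "lipid": 1, "protein": 2, "dna": 3}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


# --------------------------------------------------------------------------
# spectral axis and reference spectra
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralAxis:
    """Calibrated wavenumber axis of a hyperspectral stack.

    Parameters
    ----------
    start_wavenumber : float
        First channel position in cm^-1.
    step : float
        Channel spacing in cm^-1 (must be positive).
    n_channels : int
        Number of channels (>= 2).
    """

    start_wavenumber: float = 2800.0
    step: float = 5.0
    n_channels: int = 40

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if self.n_channels < 2:
            raise ValueError(f"n_channels must be >= 2, got {self.n_channels}")

    @property
    def values(self) -> np.ndarray:
        """Axis values in cm^-1, strictly increasing."""
        return self.start_wavenumber + self.step * np.arange(self.n_channels)

    @property
    def stop_wavenumber(self) -> float:
        return float(self.values[-1])

    def to_dict(self) -> dict:
        return {
            "start_wavenumber": self.start_wavenumber,
            "step": self.step,
            "n_channels": self.n_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralAxis":
        return cls(d["start_wavenumber"], d["step"], int(d["n_channels"]))


DEFAULT_AXIS = SpectralAxis(2800.0, 5.0, 40)


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Gaussian-mixture reference spectrum of one chemical class.

    The mixture is evaluated on a :class:`SpectralAxis` and peak-normalized so
    its maximum on the axis equals 1.
    """

    class_label: ClassLabel
    peak_centers: tuple[float, ...]
    peak_widths: tuple[float, ...]  # Gaussian sigma, cm^-1
    peak_weights: tuple[float, ...]  # relative amplitudes

    def __post_init__(self) -> None:
        n = len(self.peak_centers)
        if not (len(self.peak_widths) == len(self.peak_weights) == n):
            raise ValueError("peak_centers/widths/weights must have equal length")
        w = np.asarray(self.peak_weights, dtype=float)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 and not all zero")
        for c in self.peak_centers:
            if not (2700.0 <= c <= 3100.0):
                raise ValueError(f"peak center {c} cm^-1 outside [2700, 3100]")

    def evaluate(self, axis: SpectralAxis) -> np.ndarray:
        """Peak-normalized (max = 1) nonnegative spectrum on ``axis``."""
        x = axis.values
        y = np.zeros_like(x, dtype=float)
        for c, s, w in zip(self.peak_centers, self.peak_widths, self.peak_weights):
            y += w * np.exp(-0.5 * ((x - c) / s) ** 2)
        m = y.max()
        if m <= 0:
            raise ValueError("reference spectrum vanishes on this axis")
        return y / m


#: Dominant peak of each class plus minor shoulders; the shoulders create the
#: realistic partial overlap seen between lipid/protein/DNA phasor clusters.
_DEFAULT_REFERENCES: dict[str, ReferenceSpectrum] = {
    "lipid": ReferenceSpectrum("lipid", (2850.0, 2930.0), (12.0, 25.0), (1.0, 0.25)),
    "protein": ReferenceSpectrum("protein", (2930.0,), (18.0,), (1.0,)),
    "dna": ReferenceSpectrum("dna", (2960.0, 2930.0), (15.0, 20.0), (1.0, 0.35)),
}

#: Relative per-pixel SRS brightness of pure-class pixels.  Lipid CH2 signal
#: in fat is stronger per volume than cytoplasmic protein CH3 signal.
CLASS_AMPLITUDES: dict[str, float] = {"lipid": 1.8, "protein": 1.0, "dna": 1.2}


def make_reference_spectra(
    axis: SpectralAxis = DEFAULT_AXIS,
) -> tuple[ReferenceSpectrum, ReferenceSpectrum, ReferenceSpectrum]:
    """Return the (lipid, protein, dna) reference spectra for ``axis``.

    Lipid peaks at 2850 cm^-1, protein at 2930 cm^-1, DNA at 2960 cm^-1 —
    the three CH-stretch spectral clusters used to decompose liver tissue.

    Raises
    ------
    ValueError
        If the axis does not cover one of the dominant peak centers.
    """
    lo, hi = axis.start_wavenumber, axis.stop_wavenumber
    for ref in _DEFAULT_REFERENCES.values():
        c = ref.peak_centers[0]
        if not (lo <= c <= hi):
            raise ValueError(
                f"axis [{lo}, {hi}] cm^-1 does not cover the {ref.class_label} "
                f"peak center {c} cm^-1"
            )
    return (
        _DEFAULT_REFERENCES["lipid"],
        _DEFAULT_REFERENCES["protein"],
        _DEFAULT_REFERENCES["dna"],
    )


# --------------------------------------------------------------------------
# hyperspectral stack container + TIFF I/O
# --------------------------------------------------------------------------

@dataclass
class HyperspectralStack:
    """H x W x C SRS intensity cube with its wavenumber axis and pixel size."""

    data: np.ndarray  # (H, W, C) float
    axis: SpectralAxis
    pixel_size: float  # um / px

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (H, W, C)")
        if self.data.shape[2] != self.axis.n_channels:
            raise ValueError(
                f"stack has {self.data.shape[2]} channels, axis has "
                f"{self.axis.n_channels}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def save(self, path: str | Path) -> None:
        """Write a multi-page float32 TIFF (page k = channel k) + sidecar JSON."""
        path = Path(path)
        pages = np.moveaxis(self.data.astype(np.float32), 2, 0)
        tifffile.imwrite(path, pages)
        sidecar = {"axis": self.axis.to_dict(), "pixel_size": self.pixel_size}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "HyperspectralStack":
        path = Path(path)
        pages = tifffile.imread(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        data = np.moveaxis(np.asarray(pages, dtype=float), 0, 2)
        return cls(data, SpectralAxis.from_dict(sidecar["axis"]), sidecar["pixel_size"])


# --------------------------------------------------------------------------
# tissue phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DropletLaw:
    """Truncated log-normal lipid-droplet diameter distribution (um)."""

    median_um: float
    sigma_log: float  # sigma of log(diameter)
    max_um: float

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            d = float(np.exp(np.log(self.median_um) + self.sigma_log * rng.standard_normal()))
            if d <= self.max_um:
                return d
        return self.max_um


#: Microvesicular mode: sub-micrometre droplets only (truncated at 2 um).
NORMAL_DROPLET_LAW = DropletLaw(median_um=0.6, sigma_log=0.4, max_um=2.0)
#: Macrovesicular mode: highly variable diameters, sub-micrometre up to 50 um.
#: The heavy log-normal tail puts most of the lipid *signal* in large droplets
#: while keeping the detected mean diameter ~2x the microvesicular mode.
NASH_DROPLET_LAW = DropletLaw(median_um=0.8, sigma_log=1.0, max_um=50.0)

#: Group-mean ground-truth lipid signal fractions used by the cohort generator.
MODE_LIPID_FRACTION = {"normal": 0.09, "nash": 0.28}


@dataclass(frozen=True)
class TissuePhantomSpec:
    """Specification of one synthetic liver frame.

    ``target_lipid_fraction`` is the ground-truth lipid share of the total
    noiseless SRS signal; droplet placement iterates until the realized share
    is within +/-0.03 of it.
    """

    height_px: int = 400
    width_px: int = 400
    pixel_size: float = 0.5  # um / px
    mode: Literal["normal", "nash"] = "normal"
    target_lipid_fraction: float | None = None  # default: mode group mean
    droplet_law: DropletLaw | None = None  # default: mode law
    nucleus_density: float = 4.0  # nuclei per 100x100 px
    nucleus_radius_um: float = 3.5
    noise_sigma: float = 0.05  # fraction of mean noiseless signal
    texture_sigma: float = 0.10  # log-amplitude mottle of tissue brightness
    axis: SpectralAxis = DEFAULT_AXIS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("normal", "nash"):
            raise ValueError(f"mode must be 'normal' or 'nash', got {self.mode!r}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        f = self.lipid_fraction
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"target_lipid_fraction must be in [0, 1], got {f}")
        if self.law.max_um > 50.0:
            raise ValueError("droplet diameters must not exceed 50 um")

    @property
    def lipid_fraction(self) -> float:
        if self.target_lipid_fraction is not None:
            return self.target_lipid_fraction
        return MODE_LIPID_FRACTION[self.mode]

    @property
    def law(self) -> DropletLaw:
        if self.droplet_law is not None:
            return self.droplet_law
        return NASH_DROPLET_LAW if self.mode == "nash" else NORMAL_DROPLET_LAW


@dataclass
class PhantomGroundTruth:
    """Ground truth shipped with a phantom: true labels, droplets, lipid share."""

    label_image: np.ndarray  # (H, W) int codes, see LABEL_CODES
    droplets: list[tuple[tuple[float, float], float]]  # ((row, col) px, diameter um)
    true_lipid_fraction: float


def _disc_pixels(
    center: tuple[float, float], radius_px: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels whose centers lie within the disc.

    Sub-pixel discs always claim the pixel nearest their center so that
    sub-micrometre droplets remain detectable (they occupy ~1 px at the
    default 0.5 um/px sampling).
    """
    r0, c0 = center
    lo_r = max(int(np.floor(r0 - radius_px)), 0)
    hi_r = min(int(np.ceil(r0 + radius_px)) + 1, shape[0])
    lo_c = max(int(np.floor(c0 - radius_px)), 0)
    hi_c = min(int(np.ceil(c0 + radius_px)) + 1, shape[1])
    if lo_r >= hi_r or lo_c >= hi_c:
        return np.array([], int), np.array([], int)
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    r_idx, c_idx = rr[inside], cc[inside]
    if r_idx.size == 0:
        r_n = min(max(int(round(r0)), 0), shape[0] - 1)
        c_n = min(max(int(round(c0)), 0), shape[1] - 1)
        return np.array([r_n]), np.array([c_n])
    return r_idx, c_idx


def _smooth_texture(shape: tuple[int, int], sigma_log: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative brightness mottle, mean ~1."""
    if sigma_log <= 0:
        return np.ones(shape)
    from scipy.ndimage import gaussian_filter

    field_ = rng.standard_normal(shape)
    field_ = gaussian_filter(field_, sigma=8.0, mode="reflect")
    field_ /= max(field_.std(), 1e-12)
    return np.exp(sigma_log * field_ - 0.5 * sigma_log**2)


def generate_phantom(
    spec: TissuePhantomSpec,
) -> tuple[HyperspectralStack, PhantomGroundTruth]:
    """Generate one synthetic liver frame and its ground truth.

    The noiseless cube is ``sum_class abundance_map x reference_spectrum``;
    each pixel belongs to exactly one class, so every pixel's noiseless
    spectrum is proportional to a single reference.  Gaussian read noise with
    standard deviation ``noise_sigma x mean(noiseless signal)`` is then added.

    Raises
    ------
    RuntimeError
        If the target lipid fraction cannot be realized within +/-0.03 after
        a bounded number of droplet rejections.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px
    axis = spec.axis
    lipid_ref, protein_ref, dna_ref = make_reference_spectra(axis)
    spectra = {
        "lipid": lipid_ref.evaluate(axis),
        "protein": protein_ref.evaluate(axis),
        "dna": dna_ref.evaluate(axis),
    }
    # per-pixel integrated signal of a unit-texture pixel of each class
    area = {k: CLASS_AMPLITUDES[k] * spectra[k].sum() for k in spectra}

    labels = np.full((H, W), LABEL_CODES["protein"], dtype=np.int8)
    texture = _smooth_texture((H, W), spec.texture_sigma, rng)

    # nuclei: dna-class discs scattered over the cytoplasm
    n_nuclei = rng.poisson(spec.nucleus_density * H * W / 1e4)
    nucleus_r_px = spec.nucleus_radius_um / spec.pixel_size
    for _ in range(n_nuclei):
        center = (rng.uniform(0, H), rng.uniform(0, W))
        rr, cc = _disc_pixels(center, nucleus_r_px, (H, W))
        labels[rr, cc] = LABEL_CODES["dna"]

    # per-pixel noiseless signal given current labels
    code_area = np.array(
        [0.0, area["lipid"], area["protein"], area["dna"]]
    )
    sig_px = texture * code_area[labels]
    class_sum = {
        k: float(sig_px[labels == LABEL_CODES[k]].sum()) for k in ("lipid", "protein", "dna")
    }

    def lipid_frac() -> float:
        total = class_sum["lipid"] + class_sum["protein"] + class_sum["dna"]
        return class_sum["lipid"] / total

    # droplet placement: stamp discs until the lipid signal share reaches the
    # target; droplets that would overshoot the +0.03 band are rejected and
    # resampled (bounded retries)
    target = spec.lipid_fraction
    droplets: list[tuple[tuple[float, float], float]] = []
    rejections = 0
    max_rejections = 2000
    while lipid_frac() < target:
        d_um = spec.law.sample(rng)
        center = (rng.uniform(0, H), rng.uniform(0, W))
        rr, cc = _disc_pixels(center, d_um / 2.0 / spec.pixel_size, (H, W))
        # signal delta if these pixels convert to lipid
        old = sig_px[rr, cc]
        old_labels = labels[rr, cc]
        new = texture[rr, cc] * area["lipid"]
        gain_lipid = float(new[old_labels != LABEL_CODES["lipid"]].sum())
        lost = {
            k: float(old[old_labels == LABEL_CODES[k]].sum()) for k in ("protein", "dna")
        }
        new_lipid = class_sum["lipid"] + gain_lipid
        new_total = (
            new_lipid
            + class_sum["protein"]
            - lost["protein"]
            + class_sum["dna"]
            - lost["dna"]
        )
        if new_lipid / new_total > target + 0.03:
            rejections += 1
            if rejections > max_rejections:
                raise RuntimeError(
                    f"target lipid fraction {target} unreachable with droplet law "
                    f"{spec.law} on a {H}x{W} field after {max_rejections} rejections"
                )
            continue
        labels[rr, cc] = LABEL_CODES["lipid"]
        sig_px[rr, cc] = new
        class_sum["lipid"] = new_lipid
        class_sum["protein"] -= lost["protein"]
        class_sum["dna"] -= lost["dna"]
        droplets.append(((center[0], center[1]), d_um))

    # assemble the cube: pure-class pixels, amplitude = texture x class amp
    amp = np.zeros((H, W))
    stack = np.zeros((H, W, axis.n_channels))
    for k in ("lipid", "protein", "dna"):
        mask = labels == LABEL_CODES[k]
        amp[mask] = texture[mask] * CLASS_AMPLITUDES[k]
        stack[mask] = amp[mask, None] * spectra[k][None, :]

    true_fraction = lipid_frac()
    if abs(true_fraction - target) > 0.03:
        raise RuntimeError(
            f"realized lipid fraction {true_fraction:.4f} misses target {target} by "
            f"more than 0.03"
        )

    if spec.noise_sigma > 0:
        sigma = spec.noise_sigma * stack.mean()
        stack = stack + rng.normal(0.0, sigma, stack.shape)

    gt = PhantomGroundTruth(
        label_image=labels.copy(), droplets=droplets, true_lipid_fraction=true_fraction
    )
    return HyperspectralStack(stack, axis, spec.pixel_size), gt


# --------------------------------------------------------------------------
# cIEF electropherograms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IsoformSpec:
    """One isoform population: PTM identity, pI shift, share, peak width."""

    ptm_type: PTMType
    pI_shift: float
    relative_concentration: float
    peak_sigma: float = 0.05  # pI units


@dataclass(frozen=True)
class ElectropherogramSpec:
    """Specification of one simulated cIEF electropherogram.

    pI-shift conventions: phospho and acetyl isoforms shift toward lower pI
    (acetyl much farther than phospho), glycosyl isoforms toward higher pI;
    the unmodified isoform sits at ``unmodified_pI`` (shift 0).
    """

    unmodified_pI: float = 6.4
    isoforms: tuple[IsoformSpec, ...] = (IsoformSpec("unmodified", 0.0, 1.0),)
    pI_min: float = 5.0
    pI_max: float = 8.0
    n_points: int = 601
    baseline_level: float = 0.05  # constant chemiluminescence background
    noise_sigma: float = 0.01  # fraction of the max noiseless peak signal
    seed: int = 0

    def __post_init__(self) -> None:
        concs = np.array([i.relative_concentration for i in self.isoforms])
        if np.any(concs < 0):
            raise ValueError("relative concentrations must be >= 0")
        if abs(concs.sum() - 1.0) > 1e-9:
            raise ValueError(f"relative concentrations must sum to 1, got {concs.sum()}")
        phospho = [i.pI_shift for i in self.isoforms if i.ptm_type == "phospho"]
        acetyl = [i.pI_shift for i in self.isoforms if i.ptm_type == "acetyl"]
        for s in phospho + acetyl:
            if s >= 0:
                raise ValueError("phospho and acetyl shifts must be negative")
        if phospho and acetyl and max(acetyl) >= min(phospho):
            raise ValueError("acetyl shifts must be more negative than phospho shifts")
        for i in self.isoforms:
            if i.ptm_type == "glycosyl" and i.pI_shift <= 0:
                raise ValueError("glycosyl shifts must be positive")
            center = self.unmodified_pI + i.pI_shift
            if not (self.pI_min <= center <= self.pI_max):
                raise ValueError(
                    f"{i.ptm_type} isoform center {center:.3f} outside pI axis "
                    f"[{self.pI_min}, {self.pI_max}]"
                )

    def ground_truth(self) -> dict[str, float]:
        """Per-PTM relative concentrations (summing identical shifts)."""
        out: dict[str, float] = {}
        for i in self.isoforms:
            out[i.ptm_type] = out.get(i.ptm_type, 0.0) + i.relative_concentration
        return out


@dataclass
class Electropherogram:
    """A cIEF trace: strictly increasing pI axis + chemiluminescence intensity."""

    pI: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.pI = np.asarray(self.pI, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.pI.shape != self.intensity.shape or self.pI.ndim != 1:
            raise ValueError("pI and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(self.pI) <= 0):
            raise ValueError("pI axis must be strictly increasing")

    def save_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.pI, self.intensity])
        np.savetxt(path, arr, delimiter=",", header="pI,intensity", comments="", fmt="%.9g")

    @classmethod
    def load_csv(cls, path: str | Path) -> "Electropherogram":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1])


def generate_electropherogram(
    spec: ElectropherogramSpec,
) -> tuple[Electropherogram, dict[str, float]]:
    """Simulate a cIEF trace; returns the trace and its ground-truth profile.

    The noiseless trace is ``baseline + sum_isoform Gaussian(center =
    unmodified_pI + shift, area proportional to relative concentration)``,
    peak-scaled so the tallest noiseless isoform peak is ~1.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(spec.pI_min, spec.pI_max, spec.n_points)
    signal = np.zeros_like(x)
    for iso in spec.isoforms:
        c = spec.unmodified_pI + iso.pI_shift
        signal += (
            iso.relative_concentration
            / (iso.peak_sigma * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((x - c) / iso.peak_sigma) ** 2)
        )
    peak = signal.max()
    if peak > 0:
        signal = signal / peak
    trace = spec.baseline_level + signal
    if spec.noise_sigma > 0:
        trace = trace + rng.normal(0.0, spec.noise_sigma, x.shape)
    return Electropherogram(x, trace), spec.ground_truth()


def apply_phosphatase(
    spec: ElectropherogramSpec, efficiency: float = 1.0
) -> ElectropherogramSpec:
    """Lambda-phosphatase operator: move phospho mass to the unmodified peak.

    ``efficiency`` is the dephosphorylated fraction (default 1.0, i.e.
    complete dephosphorylation).  Acetyl and glycosyl isoforms are untouched
    and total concentration is conserved exactly.
    """
    if not (0.0 <= efficiency <= 1.0):
        raise ValueError("efficiency must be in [0, 1]")
    released = 0.0
    sigmas = [i.peak_sigma for i in spec.isoforms]
    new_isoforms: list[IsoformSpec] = []
    for iso in spec.isoforms:
        if iso.ptm_type == "phospho":
            moved = efficiency * iso.relative_concentration
            released += moved
            remaining = iso.relative_concentration - moved
            if remaining > 0:
                new_isoforms.append(dataclasses.replace(iso, relative_concentration=remaining))
        else:
            new_isoforms.append(iso)
    unmod_idx = [i for i, iso in enumerate(new_isoforms) if iso.ptm_type == "unmodified"]
    if unmod_idx:
        i = unmod_idx[0]
        iso = new_isoforms[i]
        new_isoforms[i] = dataclasses.replace(
            iso, relative_concentration=iso.relative_concentration + released
        )
    elif released > 0:
        new_isoforms.append(
            IsoformSpec("unmodified", 0.0, released, float(np.median(sigmas)))
        )
    return dataclasses.replace(spec, isoforms=tuple(new_isoforms))


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

def _preset(unmod: float, phospho: float = 0.0, acetyl: float = 0.0) -> tuple[IsoformSpec, ...]:
    isoforms = [IsoformSpec("unmodified", 0.0, unmod)]
    if phospho > 0:
        isoforms.append(IsoformSpec("phospho", -0.15, phospho))
    if acetyl > 0:
        isoforms.append(IsoformSpec("acetyl", -0.50, acetyl))
    return tuple(isoforms)


#: Six liver proteins with group-dependent isoform mixes emulating the
#: NASH-vs-normal perturbation directions: phospho-Akt up in NASH; phospho
#: 4EBP1/BID/HMGCS2/FABP1 down in NASH; FABP5 mainly acetylated in NASH.
#: Nominal pI values are synthetic placements on the pH 5-8 gradient.
PROTEIN_PRESETS: dict[str, dict] = {
    "AKT": {"pI": 6.2, "normal": _preset(0.75, phospho=0.25), "nash": _preset(0.50, phospho=0.50)},
    "4EBP1": {"pI": 5.9, "normal": _preset(0.30, phospho=0.70), "nash": _preset(0.75, phospho=0.25)},
    "BID": {"pI": 5.6, "normal": _preset(0.55, phospho=0.45), "nash": _preset(0.80, phospho=0.20)},
    "HMGCS2": {"pI": 7.2, "normal": _preset(0.50, phospho=0.50), "nash": _preset(0.80, phospho=0.20)},
    "FABP1": {"pI": 6.8, "normal": _preset(0.60, phospho=0.40), "nash": _preset(0.85, phospho=0.15)},
    "FABP5": {"pI": 6.5, "normal": _preset(0.80, acetyl=0.20), "nash": _preset(0.35, acetyl=0.65)},
}


def _sample_seed(base_seed: int, k: int) -> int:
    """Deterministic, disjoint per-item seeds derived from a base seed."""
    h = hashlib.sha256(f"{base_seed}:{k}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def generate_cohort(
    n_normal: int,
    n_nash: int,
    base_seed: int,
    out_dir: str | Path,
    *,
    frames_per_sample: int = 9,
    frame_shape: tuple[int, int] = (400, 400),
    replicates: int = 4,
    proteins: Sequence[str] | None = None,
    noise_sigma: float = 0.05,
    conc_jitter: float = 0.03,
) -> dict:
    """Write a full synthetic cohort to disk and return its manifest.

    Per sample: ``frames_per_sample`` hyperspectral frames (TIFF + sidecar
    JSON) and, per protein, ``replicates`` cIEF electropherogram CSVs
    (default 4, emulating the minimum-four-repeats assay design).  Sample
    isoform mixes are jittered around the group preset by ``conc_jitter``
    (Dirichlet-style, per sample) so replicates of one sample share a
    biological mean while samples vary.  The manifest records every seed and
    every ground truth; identical ``base_seed`` reproduces it byte for byte.
    """
    if n_normal < 1 or n_nash < 1:
        raise ValueError("cohort needs at least one sample per group")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if proteins is None:
        proteins = list(PROTEIN_PRESETS)
    groups = [("normal", i) for i in range(n_normal)] + [("nash", i) for i in range(n_nash)]

    samples = []
    for k, (mode, i) in enumerate(groups):
        sample_id = f"{mode}_{i + 1:02d}"
        sample_seed = _sample_seed(base_seed, k)
        sdir = out_dir / sample_id
        sdir.mkdir(exist_ok=True)
        frames = []
        for f in range(frames_per_sample):
            spec = TissuePhantomSpec(
                height_px=frame_shape[0],
                width_px=frame_shape[1],
                mode=mode,  # type: ignore[arg-type]
                noise_sigma=noise_sigma,
                seed=_sample_seed(sample_seed, f),
            )
            stack, gt = generate_phantom(spec)
            fname = f"frame_{f:02d}.tif"
            stack.save(sdir / fname)
            frames.append(
                {
                    "file": f"{sample_id}/{fname}",
                    "seed": spec.seed,
                    "true_lipid_fraction": gt.true_lipid_fraction,
                    "n_droplets": len(gt.droplets),
                }
            )
        srng = np.random.default_rng(_sample_seed(sample_seed, 10_000))
        traces = {}
        for protein in proteins:
            preset = PROTEIN_PRESETS[protein]
            base = preset[mode]
            concs = np.array([iso.relative_concentration for iso in base])
            jittered = np.clip(concs + conc_jitter * srng.standard_normal(len(concs)), 0.02, None)
            jittered = jittered / jittered.sum()
            isoforms = tuple(
                dataclasses.replace(iso, relative_concentration=float(c))
                for iso, c in zip(base, jittered)
            )
            rep_entries = []
            for r in range(replicates):
                espec = ElectropherogramSpec(
                    unmodified_pI=preset["pI"],
                    isoforms=isoforms,
                    seed=_sample_seed(sample_seed, 20_000 + 100 * proteins.index(protein) + r),
                )
                trace, truth = generate_electropherogram(espec)
                fname = f"cief_{protein}_rep{r + 1}.csv"
                trace.save_csv(sdir / fname)
                rep_entries.append({"file": f"{sample_id}/{fname}", "seed": espec.seed})
            traces[protein] = {
                "unmodified_pI": preset["pI"],
                "true_profile": {iso.ptm_type: iso.relative_concentration for iso in isoforms},
                "replicates": rep_entries,
            }
        samples.append(
            {
                "sample_id": sample_id,
                "group": mode,
                "mode": mode,
                "seed": sample_seed,
                "frames": frames,
                "cief": traces,
            }
        )

    manifest = {
        "base_seed": base_seed,
        "n_normal": n_normal,
        "n_nash": n_nash,
        "frames_per_sample": frames_per_sample,
        "replicates": replicates,
        "proteins": list(proteins),
        "pixel_size": 0.5,
        "samples": samples,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
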