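"""Spectral phasor transform, gating, and back-projection to a segmentation.

Each pixel's Raman spectrum I_k (k = 0..N-1 channels) maps to a point in the
phasor plane via normalized first-harmonic discrete Fourier coefficients

    g = sum_k I_k cos(2 pi h k / N) / sum_k I_k
    s = sum_k I_k sin(2 pi h k / N) / sum_k I_k

(h = harmonic, default 1).  Spectrally similar pixels cluster together, and
any nonnegative spectrum lands inside the closed unit disc.  Chemical classes
are then selected by polygonal *gates* drawn in (g, s) space and the gated
pixels are projected back to the image, yielding a lipid/protein/DNA
segmentation with per-class summed SRS signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon

from .synthetic import (
    CODE_LABELS,
    LABEL_CODES,
    HyperspectralStack,
    ReferenceSpectrum,
    SpectralAxis,
)

__all__ = [
    "PhasorField",
    "Gate",
    "SegmentationMap",
    "phasor_transform",
    "phasor_coordinates",
    "phasor_density",
    "default_gates",
    "segment_by_gates",
    "save_gates",
    "load_gates",
]


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates of a hyperspectral stack."""

    g: np.ndarray  # (H, W)
    s: np.ndarray  # (H, W)
    total_intensity: np.ndarray  # (H, W) sum over channels
    harmonic: int = 1
    valid: np.ndarray | None = None  # pixels with positive total intensity

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = self.total_intensity > 0


@dataclass(frozen=True)
class Gate:
    """A labeled simple polygon in (g, s) phasor space.

    Membership uses the even-odd rule with boundary points counted inside.
    """

    label: str
    polygon: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("gate polygon needs >= 3 vertices")
        if not self.as_shapely().is_valid:
            raise ValueError(f"gate {self.label!r} polygon is self-intersecting")

    def as_shapely(self) -> Polygon:
        return Polygon(self.polygon)

    def contains(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Vectorized point-in-polygon test (boundary counts as inside)."""
        pts = np.column_stack([np.ravel(g), np.ravel(s)])
        path = MplPath(np.asarray(self.polygon))
        # tiny positive radius expands the polygon so boundary points test True
        inside = path.contains_points(pts, radius=1e-9)
        return inside.reshape(np.shape(g))


@dataclass
class SegmentationMap:
    """Per-pixel class labels plus per-class summed SRS signal.

    ``class_signal`` maps each gate label (plus ``"unassigned"``) to the sum
    of pixel total intensities over its member pixels; the values add up to
    the total stack intensity.
    """

    labels: np.ndarray  # (H, W) int codes per LABEL_CODES
    class_signal: dict[str, float]
    label_codes: dict[str, int] = field(default_factory=lambda: dict(LABEL_CODES))

    def mask(self, label: str) -> np.ndarray:
        return self.labels == self.label_codes[label]

    def percent(self, label: str) -> float:
        assigned = sum(v for k, v in self.class_signal.items() if k != "unassigned")
        return 100.0 * self.class_signal[label] / assigned if assigned > 0 else np.nan


def phasor_coordinates(spectra: np.ndarray, harmonic: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Phasor (g, s) of spectra along the last axis; zero-total rows get (0, 0)."""
    spectra = np.asarray(spectra, dtype=float)
    n = spectra.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 channels")
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    k = np.arange(n)
    phase = 2.0 * np.pi * harmonic * k / n
    total = spectra.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(total != 0, spectra @ np.cos(phase) / total, 0.0)
        s = np.where(total != 0, spectra @ np.sin(phase) / total, 0.0)
    return g, s


def phasor_transform(stack: HyperspectralStack | np.ndarray, harmonic: int = 1) -> PhasorField:
    """Transform a hyperspectral stack to its per-pixel phasor field.

    Pixels with total intensity <= 0 are flagged invalid and assigned (0, 0).

    Raises
    ------
    ValueError
        If the stack contains non-finite values (reports how many pixels).
    """
    data = stack.data if isinstance(stack, HyperspectralStack) else np.asarray(stack, float)
    if data.ndim != 3:
        raise ValueError("expected an (H, W, C) cube")
    bad = ~np.isfinite(data).all(axis=-1)
    if bad.any():
        raise ValueError(f"stack contains non-finite values in {int(bad.sum())} pixels")
    g, s = phasor_coordinates(data, harmonic)
    total = data.sum(axis=-1)
    return PhasorField(g=g, s=s, total_intensity=total, harmonic=harmonic, valid=total > 0)


def phasor_density(
    phasors: PhasorField, bins: int = 256
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of valid pixels over the phasor square [-1, 1]^2.

    Returns ``(counts, g_edges, s_edges)``; counts sum to the number of valid
    (positive-intensity) pixels.
    """
    if bins < 8:
        raise ValueError("bins must be >= 8")
    v = phasors.valid
    counts, ge, se = np.histogram2d(
        phasors.g[v], phasors.s[v], bins=bins, range=[[-1, 1], [-1, 1]]
    )
    return counts, ge, se


def _hexagon(center: tuple[float, float], radius: float) -> tuple[tuple[float, float], ...]:
    ang = np.pi / 3 * np.arange(6)
    return tuple((center[0] + radius * np.cos(a), center[1] + radius * np.sin(a)) for a in ang)


def default_gates(
    axis: SpectralAxis,
    references: Sequence[ReferenceSpectrum],
    radius: float = 0.12,
    harmonic: int = 1,
) -> list[Gate]:
    """Construct disjoint hexagonal gates around each reference phasor point.

    Automates the manual gating workflow: each reference spectrum is mapped to
    its phasor point and surrounded with a regular hexagon of circumradius
    ``radius``, shrunk where necessary so gates stay pairwise disjoint.

    Raises
    ------
    ValueError
        If two reference phasor points lie closer than the gate radius —
        the clusters are then not separable by centered gates and manual
        polygons should be supplied instead.
    """
    points = []
    for ref in references:
        spec = ref.evaluate(axis)
        g, s = phasor_coordinates(spec[None, :], harmonic)
        points.append((ref.class_label, float(g[0]), float(s[0])))
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d = np.hypot(points[i][1] - points[j][1], points[i][2] - points[j][2])
            if d <= radius:
                raise ValueError(
                    f"reference phasor points of {points[i][0]!r} and {points[j][0]!r} "
                    f"are {d:.3f} apart (< gate radius {radius}); supply manual gates"
                )
    gates = []
    for label, g0, s0 in points:
        r = radius
        for label2, g1, s1 in points:
            if label2 == label:
                continue
            d = np.hypot(g0 - g1, s0 - s1)
            r = min(r, 0.49 * d)
        gates.append(Gate(label=label, polygon=_hexagon((g0, s0), r)))
    return gates


def _check_disjoint(gates: Sequence[Gate]) -> None:
    for i in range(len(gates)):
        for j in range(i + 1, len(gates)):
            inter = gates[i].as_shapely().intersection(gates[j].as_shapely())
            if inter.area > 1e-12:
                raise ValueError(
                    f"gates {gates[i].label!r} and {gates[j].label!r} overlap "
                    f"(intersection area {inter.area:.2e})"
                )


def segment_by_gates(phasors: PhasorField, gates: Sequence[Gate]) -> SegmentationMap:
    """Assign each pixel the label of the gate containing its (g, s) point.

    Pixels outside every gate — and invalid (zero-intensity) pixels — are
    ``unassigned``.  Per-class signal accumulates pixel total intensity, so
    class signals plus the unassigned signal equal the total stack intensity.

    Raises
    ------
    ValueError
        If gates overlap (assignment would depend on gate order).
    """
    _check_disjoint(gates)
    label_codes = dict(LABEL_CODES)
    next_code = max(label_codes.values()) + 1
    for gate in gates:
        if gate.label not in label_codes:
            label_codes[gate.label] = next_code
            next_code += 1
    labels = np.zeros(phasors.g.shape, dtype=np.int16)  # 0 = unassigned
    for gate in gates:
        inside = gate.contains(phasors.g, phasors.s) & phasors.valid & (labels == 0)
        labels[inside] = label_codes[gate.label]
    class_signal = {}
    for gate in gates:
        class_signal[gate.label] = float(
            phasors.total_intensity[labels == label_codes[gate.label]].sum()
        )
    class_signal["unassigned"] = float(phasors.total_intensity[labels == 0].sum())
    return SegmentationMap(labels=labels, class_signal=class_signal, label_codes=label_codes)


# ----------------------------------------------------------------------
# gate JSON I/O (parity with manually drawn gates)
# ----------------------------------------------------------------------

def save_gates(gates: Sequence[Gate], path: str | Path) -> None:
    payload = [{"label": g.label, "polygon": [list(v) for v in g.polygon]} for g in gates]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_gates(path: str | Path) -> list[Gate]:
    payload = json.loads(Path(path).read_text())
    return [Gate(label=d["label"], polygon=tuple(map(tuple, d["polygon"]))) for d in payload]
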