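"""Tissue phantoms: compartment geometry and ground-truth elemental maps.

The phantom emulates a 2-um tumor tissue section as seen by a scanning
nano-beam: tumor cells (P-rich membrane and nucleus, Zn-rich nucleoli)
embedded in S-rich stroma, with thin string-like structures in the stroma
carrying co-localized Pt and Br — the signature of extracellular cisplatin
accumulation. Ground-truth concentration maps are built from per-compartment
weights, multiplied by lognormal within-compartment heterogeneity, and
renormalized so each element's map mean hits its target exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .constants import SUPPORTED_ELEMENTS


class Label(IntEnum):
    STROMA = 0
    CYTOPLASM = 1
    MEMBRANE = 2
    NUCLEUS_MATRIX = 3
    NUCLEOLUS = 4
    PT_STRING = 5


CELL_LABELS = (Label.CYTOPLASM, Label.MEMBRANE, Label.NUCLEUS_MATRIX, Label.NUCLEOLUS)
EXTRACELL_LABELS = (Label.STROMA, Label.PT_STRING)


class PhantomSizeError(ValueError):
    """Raised when the requested map cannot hold a single cell."""


@dataclass(frozen=True)
class Geometry:
    """Compartment-geometry parameters, lengths in nm."""

    cell_radius_nm: float = 1800.0
    cell_radius_jitter: float = 0.25
    membrane_width_nm: float = 150.0
    nucleus_radius_frac: float = 0.55
    nucleolus_count: int = 3
    nucleolus_radius_nm: float = 180.0
    cell_area_range: tuple[float, float] = (0.30, 0.60)
    string_density: float = 1.0       # strings per 4096 px of map area
    string_width_px: tuple[int, int] = (2, 4)
    string_length_px: int = 150
    mode: str = "tissue"              # "tissue" | "nucleus_detail"

    def __post_init__(self):
        if self.cell_radius_nm <= 0 or self.membrane_width_nm <= 0:
            raise ValueError("cell radius and membrane width must be positive")
        if self.nucleolus_count < 0 or self.nucleolus_radius_nm <= 0:
            raise ValueError("nucleolus parameters must be positive")
        if self.string_density < 0:
            raise ValueError("string density must be nonnegative")


@dataclass
class LabelMap:
    labels: np.ndarray          # 2-D int array of Label values
    pixel_size_nm: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def fraction(self, members) -> float:
        members = [int(m) for m in np.atleast_1d(members)]
        return float(np.isin(self.labels, members).mean())

    def cell_fraction(self) -> float:
        return self.fraction(CELL_LABELS)


@dataclass(frozen=True)
class TissueProfile:
    """Per-element compartment weights and target map-mean concentrations.

    ``weights[el][label]`` are dimensionless relative levels; ``cbar[el]`` is
    the target map-mean in wt fraction. Pt weights outside the cells are
    rescaled at assignment time so the area-weighted stroma:cell contrast
    equals ``pt_contrast``; Br follows Pt's (rescaled) weights.
    """

    weights: dict = field(default_factory=dict)
    cbar: dict = field(default_factory=dict)
    cv: float = 0.2
    pt_contrast: float = 2.0
    fe_independent: bool = True

    def __post_init__(self):
        for el, w in self.weights.items():
            vals = np.array([w.get(lab, 0.0) for lab in Label], dtype=float)
            if (vals < 0).any():
                raise ValueError(f"negative weight for {el}")
            if not vals.any():
                raise ValueError(f"all-zero weights for {el}")

    @staticmethod
    def default_weights() -> dict:
        L = Label
        return {
            "P":  {L.MEMBRANE: 5, L.NUCLEUS_MATRIX: 4, L.NUCLEOLUS: 4,
                   L.CYTOPLASM: 2, L.STROMA: 1, L.PT_STRING: 1},
            "S":  {L.STROMA: 1.5, L.PT_STRING: 2.0, L.CYTOPLASM: 1,
                   L.MEMBRANE: 1, L.NUCLEUS_MATRIX: 1, L.NUCLEOLUS: 1},
            "Ca": {L.MEMBRANE: 4, L.NUCLEUS_MATRIX: 4, L.NUCLEOLUS: 5,
                   L.CYTOPLASM: 2, L.STROMA: 1, L.PT_STRING: 1},
            "Mn": {L.NUCLEOLUS: 6, L.NUCLEUS_MATRIX: 4, L.CYTOPLASM: 1.5,
                   L.MEMBRANE: 1, L.STROMA: 1, L.PT_STRING: 1},
            "Fe": {lab: 1.0 for lab in L},
            "Zn": {L.NUCLEOLUS: 10, L.NUCLEUS_MATRIX: 4, L.CYTOPLASM: 1,
                   L.MEMBRANE: 1, L.STROMA: 0.5, L.PT_STRING: 0.5},
            # Pt: cells at 1, strings 5x stroma; stroma/string levels are
            # rescaled jointly to hit pt_contrast. Br mirrors Pt.
            "Pt": {L.CYTOPLASM: 1, L.MEMBRANE: 1, L.NUCLEUS_MATRIX: 1,
                   L.NUCLEOLUS: 1, L.STROMA: 1, L.PT_STRING: 5},
            "Br": {L.CYTOPLASM: 1, L.MEMBRANE: 1, L.NUCLEUS_MATRIX: 1,
                   L.NUCLEOLUS: 1, L.STROMA: 1, L.PT_STRING: 5},
        }

    # group-level map means and between-sample SDs (wt fraction): the
    # measured cohort composition per treatment protocol
    GROUP_TABLE = {
        "untreated":    {"P": (2.46e-2, 1.04e-2), "S": (5.03e-2, 0.73e-2),
                         "Zn": (2.5e-4, 2.2e-4), "Pt": (0.0, 0.0)},
        "hyperthermic": {"P": (2.91e-2, 1.08e-2), "S": (6.48e-2, 1.25e-2),
                         "Zn": (4.5e-4, 1.5e-4), "Pt": (1.6e-4, 0.2e-4)},
        "normothermic": {"P": (2.21e-2, 0.61e-2), "S": (4.68e-2, 1.10e-2),
                         "Zn": (3.6e-4, 1.4e-4), "Pt": (1.8e-4, 0.7e-4)},
    }
    TRACE_MEANS = {"Ca": 1.0e-4, "Mn": 5.0e-6, "Fe": 5.0e-5, "Br": 1.0e-5}

    @staticmethod
    def preset(group: str, **overrides) -> "TissueProfile":
        """Profile whose map means equal the measured group means.

        ``group`` is one of ``untreated | hyperthermic | normothermic``.
        P/S/Zn/Pt means are group-specific; Ca, Mn, Fe, Br means are common
        trace levels. Untreated tissue carries no Pt (and trace Br only).
        """
        if group not in TissueProfile.GROUP_TABLE:
            raise ValueError(f"unknown group {group!r}")
        cbar = dict(TissueProfile.TRACE_MEANS)
        cbar.update({el: m for el, (m, _)
                     in TissueProfile.GROUP_TABLE[group].items()})
        prof = TissueProfile(weights=TissueProfile.default_weights(), cbar=cbar)
        return replace(prof, **overrides) if overrides else prof

    @staticmethod
    def sample_group(group: str, seed: int, **overrides) -> "TissueProfile":
        """One cohort member: map means drawn from the group's mean +/- SD.

        Between-sample (tumor-to-tumor) variability is what group SDs in a
        cohort table measure; per-sample draws are truncated at 10% of the
        group mean to stay physical.
        """
        if group not in TissueProfile.GROUP_TABLE:
            raise ValueError(f"unknown group {group!r}")
        rng = np.random.default_rng(seed)
        cbar = dict(TissueProfile.TRACE_MEANS)
        for el, (m, sd) in TissueProfile.GROUP_TABLE[group].items():
            cbar[el] = max(rng.normal(m, sd), 0.1 * m) if m > 0 else 0.0
        prof = TissueProfile(weights=TissueProfile.default_weights(), cbar=cbar)
        return replace(prof, **overrides) if overrides else prof


@dataclass
class GroundTruthMaps:
    conc: dict                # element -> 2-D wt-fraction field
    label_map: LabelMap
    profile: TissueProfile

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def stroma_cell_ratio(self, element: str = "Pt") -> float:
        labels = self.label_map.labels
        out = np.isin(labels, [int(l) for l in EXTRACELL_LABELS])
        cell = np.isin(labels, [int(l) for l in CELL_LABELS])
        return float(self.conc[element][out].mean() / self.conc[element][cell].mean())


@dataclass(frozen=True)
class ReferenceSample:
    """Reference standard with certified concentrations (wt fraction)."""

    certified: dict
    thickness_um: float = 100.0
    density: float = 1.0

    def __post_init__(self):
        if not self.certified:
            raise ValueError("certified table is empty")
        for el, c in self.certified.items():
            if c <= 0:
                raise ValueError(f"nonpositive certified concentration for {el}")
        if self.thickness_um <= 0 or self.density <= 0:
            raise ValueError("thickness and density must be positive")


def make_reference_standard(certified: dict, thickness_um: float = 100.0,
                            density: float = 1.0) -> ReferenceSample:
    return ReferenceSample(dict(certified), thickness_um, density)


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _paint_cell(labels, center, radius_px, geom: Geometry, mem_px, nol_px, rng):
    outer = _disk_mask(labels.shape, center, radius_px)
    inner = _disk_mask(labels.shape, center, radius_px - mem_px)
    labels[outer] = Label.MEMBRANE
    labels[inner] = Label.CYTOPLASM
    nuc_r = geom.nucleus_radius_frac * (radius_px - mem_px)
    off = rng.uniform(-0.15, 0.15, 2) * radius_px
    nuc_center = (center[0] + off[0], center[1] + off[1])
    nucleus = _disk_mask(labels.shape, nuc_center, nuc_r)
    nucleus_region = nucleus & inner
    labels[nucleus_region] = Label.NUCLEUS_MATRIX
    # nucleoli strictly inside the nucleus matrix (eroded region keeps a
    # one-pixel matrix rim around every nucleolus)
    from scipy.ndimage import binary_erosion
    interior = binary_erosion(nucleus_region, iterations=2)
    nol_r = nol_px
    for _ in range(geom.nucleolus_count):
        max_off = nuc_r - nol_r - 1.5
        if max_off <= 0:
            break
        ang = rng.uniform(0, 2 * math.pi)
        d = max_off * math.sqrt(rng.uniform())
        c = (nuc_center[0] + d * math.sin(ang), nuc_center[1] + d * math.cos(ang))
        nol = _disk_mask(labels.shape, c, nol_r)
        labels[nol & interior] = Label.NUCLEOLUS


def _walk_string(labels, rng, width_range, n_steps):
    """Correlated random walk stamped onto STROMA pixels only."""
    stroma = np.argwhere(labels == Label.STROMA)
    if len(stroma) == 0:
        return 0
    start = stroma[rng.integers(len(stroma))]
    pos = start.astype(float)
    heading = rng.uniform(0, 2 * math.pi)
    width = rng.integers(width_range[0], width_range[1] + 1)
    half = width / 2.0
    painted = 0
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.25)
        pos += np.array([math.sin(heading), math.cos(heading)])
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
            break
        r0, r1 = max(0, int(r - half)), min(labels.shape[0], int(r + half) + 1)
        c0, c1 = max(0, int(c - half)), min(labels.shape[1], int(c + half) + 1)
        patch = labels[r0:r1, c0:c1]
        hit = patch == Label.STROMA
        patch[hit] = Label.PT_STRING
        painted += int(hit.sum())
    return painted


def generate_label_map(shape_px, pixel_size_nm: float = 50.0,
                       geometry: Geometry | None = None,
                       seed: int = 0) -> LabelMap:
    """Generate a compartment label map.

    Tissue mode places jittered-radius cells until the cell-area fraction
    reaches a target drawn inside ``geometry.cell_area_range``, then threads
    string-like paths through the stroma. Deterministic for a fixed seed.
    """
    geom = geometry or Geometry()
    dims = [int(s) for s in np.atleast_1d(shape_px)]
    shape = (dims[0], dims[1]) if len(dims) >= 2 else (dims[0], dims[0])
    if min(shape) < 32:
        raise PhantomSizeError(f"map shape {shape} below the 32-px minimum")
    rng = np.random.default_rng(seed)

    mem_px = max(1.0, geom.membrane_width_nm / pixel_size_nm)
    nol_px = max(1.2, geom.nucleolus_radius_nm / pixel_size_nm)

    labels = np.full(shape, int(Label.STROMA), dtype=np.int16)

    if geom.mode == "nucleus_detail":
        labels[:] = Label.CYTOPLASM
        center = (shape[0] / 2 + rng.uniform(-2, 2), shape[1] / 2 + rng.uniform(-2, 2))
        nuc_r = 0.42 * min(shape)
        nucleus = _disk_mask(shape, center, nuc_r)
        labels[nucleus] = Label.NUCLEUS_MATRIX
        nol_r = nol_px
        for _ in range(max(geom.nucleolus_count, 6)):
            ang = rng.uniform(0, 2 * math.pi)
            d = (nuc_r - nol_r - 2) * math.sqrt(rng.uniform())
            c = (center[0] + d * math.sin(ang), center[1] + d * math.cos(ang))
            labels[_disk_mask(shape, c, nol_r) & nucleus] = Label.NUCLEOLUS
        return LabelMap(labels, pixel_size_nm)

    base_r = geom.cell_radius_nm / pixel_size_nm
    min_r = mem_px + 4
    if 2 * base_r * (1 - geom.cell_radius_jitter) > min(shape) or base_r < min_r:
        raise PhantomSizeError(
            f"cell radius {geom.cell_radius_nm} nm does not fit a {shape} map "
            f"at {pixel_size_nm} nm pixels")

    area = shape[0] * shape[1]
    lo, hi = geom.cell_area_range
    target = rng.uniform(lo + 0.05, hi - 0.05)
    n_placed = 0
    centers: list[tuple[float, float, float]] = []   # (row, col, radius)
    for _ in range(300):
        frac = float(np.isin(labels, [int(l) for l in CELL_LABELS]).mean())
        if frac >= target:
            break
        r = base_r * (1 + rng.uniform(-geom.cell_radius_jitter, geom.cell_radius_jitter))
        # shrink the candidate if it would overshoot the upper bound
        if frac + math.pi * r**2 / area > hi - 0.02:
            r = math.sqrt(max((hi - 0.05 - frac), 0.02) * area / math.pi)
        if r < min_r:
            break
        center = (rng.uniform(0.3 * r, shape[0] - 0.3 * r),
                  rng.uniform(0.3 * r, shape[1] - 0.3 * r))
        # cells never overlap: an overlap would overwrite an earlier cell's
        # compartments and break nucleolus containment
        if any((center[0] - c0) ** 2 + (center[1] - c1) ** 2 < (r + r0 + 2) ** 2
               for c0, c1, r0 in centers):
            continue
        _paint_cell(labels, center, r, geom, mem_px, nol_px, rng)
        centers.append((center[0], center[1], r))
        n_placed += 1
    if n_placed == 0:
        raise PhantomSizeError("could not place a single cell")

    n_strings = int(round(geom.string_density * area / 4096))
    for _ in range(n_strings):
        for _attempt in range(5):
            if _walk_string(labels, rng, geom.string_width_px, geom.string_length_px) > 0:
                break
    if geom.string_density > 0 and not (labels == Label.PT_STRING).any():
        _walk_string(labels, rng, geom.string_width_px, geom.string_length_px)

    return LabelMap(labels, pixel_size_nm)


def assign_concentrations(label_map: LabelMap, profile: TissueProfile,
                          seed: int = 0) -> GroundTruthMaps:
    """Turn a label map into per-element ground-truth concentration fields.

    Base levels come from the profile's compartment weights; Pt's
    extracellular weights are rescaled so the area-weighted stroma:cell mean
    ratio equals ``profile.pt_contrast`` exactly before noise (Br inherits
    the rescaled Pt weights). Lognormal heterogeneity with the configured CV
    multiplies each pixel; Fe is drawn as a label-independent field when
    ``fe_independent`` is set. Each map is renormalized to its target mean.
    """
    labels = label_map.labels
    rng = np.random.default_rng(seed)
    missing = [el for el in profile.cbar if el not in profile.weights]
    if missing:
        raise KeyError(f"profile weights missing for elements: {missing}")

    out_mask = np.isin(labels, [int(l) for l in EXTRACELL_LABELS])
    cell_mask = np.isin(labels, [int(l) for l in CELL_LABELS])

    def base_field(el):
        w = profile.weights[el]
        lut = np.array([float(w.get(Label(i), 0.0)) for i in range(len(Label))])
        return lut[labels]

    # Pt contrast rescaling shared by Pt and Br
    scale = 1.0
    if "Pt" in profile.weights:
        pt_base = base_field("Pt")
        if out_mask.any() and cell_mask.any() and pt_base[cell_mask].mean() > 0 \
                and pt_base[out_mask].mean() > 0:
            scale = (profile.pt_contrast * pt_base[cell_mask].mean()
                     / pt_base[out_mask].mean())

    sigma = math.sqrt(math.log(1 + profile.cv**2)) if profile.cv > 0 else 0.0
    conc = {}
    for el, target in profile.cbar.items():
        if el == "Fe" and profile.fe_independent:
            base = np.ones_like(labels, dtype=float)
        else:
            base = base_field(el).astype(float)
            if el in ("Pt", "Br"):
                base = base.copy()
                base[out_mask] *= scale
        if sigma > 0:
            # mean-one lognormal, truncated at +/-2 sigma so matrix-level
            # elements (P, S at wt% scale) cannot push a pixel's summed
            # mass fraction toward the organic-matrix bound
            xi = np.clip(rng.normal(0.0, sigma, size=labels.shape),
                         -2 * sigma, 2 * sigma)
            field_ = base * np.exp(-sigma**2 / 2 + xi)
        else:
            field_ = base
        m = field_.mean()
        conc[el] = field_ * (target / m) if (m > 0 and target > 0) else np.zeros_like(field_)
    return GroundTruthMaps(conc, label_map, profile)
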