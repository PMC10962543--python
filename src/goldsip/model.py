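"""Shared domain types for the gold-labelled single-cell isotope probing pipeline.

The pipeline works on multilayer secondary-ion count images: each acquisition
cycle of a NanoSIMS measurement yields one 2-D count raster per detected ion
species, split over two half-cycles recorded at distinct magnetic field
strengths.  Half-cycle 1 carries ¹²C⁻, ¹²C¹⁴N⁻ and ¹⁹⁷Au⁻(1); half-cycle 2
carries ¹²C₂⁻, ¹²C¹⁵N⁻, ³¹P⁻ and ¹⁹⁷Au⁻(2).  Secondary-electron (SE) images
are recorded in both half-cycles.

Conventions
-----------
* pixel coordinates are 0-based, row-major, origin at the top-left;
* acquisition cycles are numbered 1-based in every user-facing interface
  (internally planes are stored 0-based along the first axis);
* count rasters are non-negative; raw acquisitions are integer, corrected
  stacks may be real-valued.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesLabel",
    "IonSpecies",
    "IonImageStack",
    "DriftTrace",
    "AcquisitionSession",
    "RoiCategory",
    "Roi",
    "ControlStats",
    "EnrichmentResult",
    "CellTruth",
    "SimulationTruth",
    "default_species_table",
    "NATURAL_ABUNDANCE_ATPCT",
]

#: Natural ¹⁵N abundance of biomass, in at% (isotope fraction × 100).
NATURAL_ABUNDANCE_ATPCT = 0.366


class SpeciesLabel(str, enum.Enum):
    """Identifiers for the detected secondary-ion species."""

    C12 = "C12"            # ¹²C⁻, half-cycle 1
    C12N14 = "C12N14"      # ¹²C¹⁴N⁻, half-cycle 1
    AU197_1 = "AU197_1"    # ¹⁹⁷Au⁻ recorded in half-cycle 1
    C12_2 = "C12_2"        # ¹²C₂⁻, half-cycle 2
    C15N = "C15N"          # ¹²C¹⁵N⁻, half-cycle 2
    P31 = "P31"            # ³¹P⁻, half-cycle 2
    AU197_2 = "AU197_2"    # ¹⁹⁷Au⁻ recorded in half-cycle 2
    SE = "SE"              # secondary electrons, both half-cycles

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: half_cycle value meaning "recorded in both half-cycles" (secondary electrons).
BOTH_HALF_CYCLES = 0


@dataclass(frozen=True)
class IonSpecies:
    """One detected species: its half-cycle slot and QSA sensitivity factor.

    ``detector_beta`` is the dimensionless QSA (quasi-simultaneous arrival)
    sensitivity factor; it is defined only for the carbon-bearing species and
    ``None`` for Au⁻, P⁻ and SE (those pass through QSA correction unchanged).
    """

    label: SpeciesLabel
    half_cycle: int  # 1, 2 or BOTH_HALF_CYCLES
    detector_beta: float | None = None

    def __post_init__(self) -> None:
        if self.half_cycle not in (1, 2, BOTH_HALF_CYCLES):
            raise ValueError(f"half_cycle must be 1, 2 or 0 (both), got {self.half_cycle}")
        if self.detector_beta is not None and self.detector_beta < 1.0:
            raise ValueError(f"detector_beta must be >= 1, got {self.detector_beta}")

    @property
    def half_cycles(self) -> tuple[int, ...]:
        return (1, 2) if self.half_cycle == BOTH_HALF_CYCLES else (self.half_cycle,)

    def in_half_cycle(self, half: int) -> bool:
        return half in self.half_cycles


def default_species_table() -> list[IonSpecies]:
    """The eight detected species with half-cycle slots and default β values.

    β = 1.1 for C⁻, 1.06 for C₂⁻ and 1.05 for CN⁻ ions (both ¹²C¹⁴N⁻ and
    ¹²C¹⁵N⁻); Au⁻, P⁻ and SE carry no β and pass through QSA unchanged.
    """
    return [
        IonSpecies(SpeciesLabel.C12, 1, 1.1),
        IonSpecies(SpeciesLabel.C12N14, 1, 1.05),
        IonSpecies(SpeciesLabel.AU197_1, 1, None),
        IonSpecies(SpeciesLabel.C12_2, 2, 1.06),
        IonSpecies(SpeciesLabel.C15N, 2, 1.05),
        IonSpecies(SpeciesLabel.P31, 2, None),
        IonSpecies(SpeciesLabel.AU197_2, 2, None),
        IonSpecies(SpeciesLabel.SE, BOTH_HALF_CYCLES, None),
    ]


def species_by_label(label: SpeciesLabel | str) -> IonSpecies:
    label = SpeciesLabel(label)
    for sp in default_species_table():
        if sp.label == label:
            return sp
    raise KeyError(label)  # pragma: no cover - table covers the enum


@dataclass
class IonImageStack:
    """Multilayer count images of one species: ``planes[cycle-1]`` is a 2-D raster.

    Raw stacks hold non-negative integers (one registered ion per count);
    corrected stacks may hold non-negative reals.
    """

    species: IonSpecies
    planes: np.ndarray  # (n_cycles, rows, cols), counts >= 0
    dwell_time: float = 5e-3  # seconds per pixel
    raster_extent: float = 50.0  # micrometers per side

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise ValueError(f"planes must be 3-D (cycle, row, col), got {self.planes.ndim}-D")
        if self.planes.size and self.planes.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")

    @property
    def n_cycles(self) -> int:
        return self.planes.shape[0]

    @property
    def pixel_shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def cycle_planes(self, first: int, last: int) -> np.ndarray:
        """Planes for the inclusive 1-based cycle range ``first..last``."""
        if not (1 <= first <= last <= self.n_cycles):
            raise ValueError(
                f"invalid cycle range ({first}, {last}) for {self.n_cycles}-cycle stack"
            )
        return self.planes[first - 1 : last]


@dataclass
class DriftTrace:
    """Integer drift offsets recovered during alignment.

    ``half1``/``half2`` hold per-cycle (row, col) shifts that were applied to
    each half-cycle's planes; ``inter_half_cycle`` is the single extra shift
    applied to half-cycle-2 planes to register them onto half-cycle 1.
    ``clipped`` flags cycles whose estimated offset hit the search radius.
    """

    half1: np.ndarray  # (n_cycles, 2) int
    half2: np.ndarray  # (n_cycles, 2) int
    inter_half_cycle: tuple[int, int] = (0, 0)
    clipped: list[int] = field(default_factory=list)  # 1-based cycle numbers
    manual_inter_half_cycle: bool = False

    @classmethod
    def identity(cls, n_cycles: int) -> "DriftTrace":
        z = np.zeros((n_cycles, 2), dtype=int)
        return cls(half1=z.copy(), half2=z.copy())


class RoiCategory(str, enum.Enum):
    """Classification ladder of a region of interest (monotone: each level
    requires every level below it)."""

    AU_ONLY = "AU_ONLY"    # gold hotspot on the Au⁻:C⁻ ratio map
    AU_P = "AU_P"          # gold hotspot confirmed by the P⁻:C⁻ biomass signal
    AU_P_N15 = "AU_P_N15"  # additionally significantly enriched in ¹⁵N

    @property
    def rank(self) -> int:
        return [RoiCategory.AU_ONLY, RoiCategory.AU_P, RoiCategory.AU_P_N15].index(self)


@dataclass
class Roi:
    """A connected pixel set delineating one cell (or small cell cluster)."""

    id: str
    pixels: np.ndarray  # (n_px, 2) int array of (row, col)
    category: RoiCategory = RoiCategory.AU_ONLY
    cycle_counts: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        if self.pixels.size == 0:
            raise ValueError("ROI pixel set must be non-empty")
        if self.pixels.shape[1] != 2:
            raise ValueError("pixels must be (n, 2) (row, col) pairs")

    @property
    def area_px(self) -> int:
        return int(self.pixels.shape[0])

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    def bbox_key(self) -> tuple[int, int]:
        """Deterministic ordering key: top-left-most pixel (row, then col)."""
        rows = self.pixels[:, 0]
        top = rows.min()
        return int(top), int(self.pixels[rows == top, 1].min())


@dataclass
class ControlStats:
    """Natural-abundance baseline fitted on unlabeled control cells.

    The enrichment threshold is always derived, never stored:
    ``threshold_atpct = mean + k_sigma × sd``.
    """

    mean_atpct: float
    sd_atpct: float
    k_sigma: float = 6.0
    n_cells: int | None = None

    def __post_init__(self) -> None:
        if self.sd_atpct < 0:
            raise ValueError("sd_atpct must be non-negative")
        if self.k_sigma < 0:
            raise ValueError("k_sigma must be non-negative")

    @property
    def threshold_atpct(self) -> float:
        return self.mean_atpct + self.k_sigma * self.sd_atpct


@dataclass
class EnrichmentResult:
    """Per-ROI isotope quantification over a cycle range."""

    roi_id: str
    atpct_raw: float
    sigma_poisson: float
    enriched: bool
    cycle_range: tuple[int, int]
    atpct_corrected: float | None = None
    n15_counts: float = 0.0
    n14_counts: float = 0.0
    valid: bool = True
    category: RoiCategory | None = None
    area_px: int | None = None
    analysis_area: str = ""

    def __post_init__(self) -> None:
        if self.valid:
            if not (0.0 <= self.atpct_raw <= 100.0):
                raise ValueError(f"atpct_raw out of [0, 100]: {self.atpct_raw}")
            if self.sigma_poisson < 0:
                raise ValueError("sigma_poisson must be non-negative")
            if self.atpct_corrected is not None and self.atpct_corrected > 100.0:
                raise ValueError("corrected at% exceeds 100 (non-physical)")


@dataclass
class CellTruth:
    """Ground truth for one planted cell in a synthetic acquisition."""

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]    # semi-axes in pixels
    orientation_deg: float
    true_atpct: float
    gold_labeled: bool
    n15_onset_cycle: int  # 1-based; natural abundance before this cycle
    pixels: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    # per-cycle expected CN counts summed over the cell's pixel mask, so
    # estimates can be checked against the exact expectation for any range
    expected_n15: np.ndarray = field(default_factory=lambda: np.empty(0))
    expected_n14: np.ndarray = field(default_factory=lambda: np.empty(0))

    def expected_atpct(self, cycle_range: tuple[int, int]) -> float:
        """Expected measured at% over an inclusive 1-based cycle range
        (accounts for the pre-onset natural-abundance cycles and background
        CN inside the mask)."""
        first, last = cycle_range
        e15 = self.expected_n15[first - 1 : last].sum()
        e14 = self.expected_n14[first - 1 : last].sum()
        return 100.0 * e15 / (e15 + e14)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        if self.pixels.size:
            m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class SimulationTruth:
    """Manifest of everything the simulator planted, for truth-conditional tests."""

    cells: list[CellTruth]
    drift_schedule: np.ndarray            # (n_cycles, 2) int, half-cycle-1 offsets
    half_cycle_offset: tuple[int, int]    # extra offset of half-cycle 2
    excluded_region_mask: np.ndarray      # bool raster of planted low-signal topography
    seed: int = 0
    expected_totals: dict = field(default_factory=dict)  # species -> E[total counts]


@dataclass
class AcquisitionSession:
    """A full measurement: one stack per species plus alignment state.

    ``validity`` holds one boolean raster stack per half-cycle; pixels shifted
    out of frame during alignment become invalid and are excluded from every
    downstream sum.  A freshly simulated or loaded session is fully valid.
    """

    stacks: dict[SpeciesLabel, IonImageStack]
    metadata: dict = field(default_factory=dict)
    alignment: DriftTrace | None = None
    validity: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stacks:
            raise ValueError("session needs at least one stack")
        shapes = {s.planes.shape for s in self.stacks.values()}
        if len(shapes) != 1:
            raise ValueError(f"all stacks must share (n_cycles, rows, cols); got {shapes}")
        for half in (1, 2):
            if half not in self.validity:
                self.validity[half] = np.ones(self.plane_shape3, dtype=bool)

    @property
    def n_cycles(self) -> int:
        return next(iter(self.stacks.values())).n_cycles

    @property
    def pixel_shape(self) -> tuple[int, int]:
        return next(iter(self.stacks.values())).pixel_shape

    @property
    def plane_shape3(self) -> tuple[int, int, int]:
        return next(iter(self.stacks.values())).planes.shape

    @property
    def has_se(self) -> bool:
        return SpeciesLabel.SE in self.stacks

    def stack(self, label: SpeciesLabel | str) -> IonImageStack:
        label = SpeciesLabel(label)
        try:
            return self.stacks[label]
        except KeyError:
            raise KeyError(f"species {label.value} not present in session") from None

    def validity_for(self, label: SpeciesLabel | str) -> np.ndarray:
        """Per-cycle validity rasters applying to the given species' half-cycle.

        SE (recorded in both half-cycles) follows half-cycle 1.
        """
        sp = self.stack(label).species
        half = 1 if sp.half_cycle in (1, BOTH_HALF_CYCLES) else 2
        return self.validity[half]

    def copy(self) -> "AcquisitionSession":
        return AcquisitionSession(
            stacks={
                k: IonImageStack(v.species, v.planes.copy(), v.dwell_time, v.raster_extent)
                for k, v in self.stacks.items()
            },
            metadata=dict(self.metadata),
            alignment=self.alignment,
            validity={h: v.copy() for h, v in self.validity.items()},
        )
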