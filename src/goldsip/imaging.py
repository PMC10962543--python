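"""Accumulated images, elemental ratio maps and at% ¹⁵N maps.

Ratio maps normalize a species to ¹²C⁻ (the matrix element), which largely
cancels topography-driven intensity variation; the at% ¹⁵N map is the isotope
fraction 100·¹⁵N/(¹⁴N+¹⁵N) computed from the two ¹²CN⁻ molecular-ion signals.

Division by zero is handled by validity masking, never by adding an epsilon:
an epsilon would bias at% estimates at low counts.  The display floor (0.63
at%, the enrichment threshold) is rendering metadata only — stored values are
never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from matplotlib import colormaps

from .model import AcquisitionSession, IonImageStack, SpeciesLabel

__all__ = ["RatioMap", "accumulate", "ratio_map", "atpercent_map", "render"]

#: default lower bound of the at% ¹⁵N false-color scale (control mean + 6 SD)
DEFAULT_DISPLAY_FLOOR = 0.63


@dataclass
class RatioMap:
    """A per-pixel ratio image with an explicit validity raster.

    ``values`` are defined only where ``validity`` is True (elsewhere 0 is
    stored but carries no meaning); validity is False wherever the
    accumulated denominator is zero or the pixel was invalidated by
    alignment.
    """

    values: np.ndarray
    numerator: str
    denominator: str
    cycle_range: tuple[int, int]
    validity: np.ndarray
    units: str = ""  # "" for dimensionless ratios, "at%" for isotope maps
    display_floor: float | None = None
    meta: dict = field(default_factory=dict)

    def valid_values(self) -> np.ndarray:
        return self.values[self.validity]


def accumulate(
    stack: IonImageStack,
    cycle_range: tuple[int, int],
    validity: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel sum of counts over an inclusive 1-based cycle range.

    Pixels invalid in a given cycle (per the alignment validity stack)
    contribute nothing in that cycle.
    """
    first, last = cycle_range
    planes = stack.cycle_planes(first, last)
    if validity is not None:
        planes = planes * validity[first - 1 : last]
    return planes.sum(axis=0)


def _accumulated(session: AcquisitionSession, label, cycle_range) -> np.ndarray:
    label = SpeciesLabel(label)
    return accumulate(session.stack(label), cycle_range, session.validity_for(label))


def _any_valid(session: AcquisitionSession, label, cycle_range) -> np.ndarray:
    first, last = cycle_range
    v = session.validity_for(SpeciesLabel(label))
    return v[first - 1 : last].any(axis=0)


def ratio_map(
    session: AcquisitionSession,
    numerator_species: SpeciesLabel | str,
    denominator_species: SpeciesLabel | str,
    cycle_range: tuple[int, int],
) -> RatioMap:
    """Ratio of accumulated counts, e.g. ¹⁹⁷Au⁻:¹²C⁻ or ³¹P⁻:¹²C⁻.

    Validity is False where the accumulated denominator is zero; a zero
    numerator over a positive denominator is a valid ratio of 0.
    """
    num = _accumulated(session, numerator_species, cycle_range)
    den = _accumulated(session, denominator_species, cycle_range)
    validity = (den > 0) & _any_valid(session, numerator_species, cycle_range) \
        & _any_valid(session, denominator_species, cycle_range)
    values = np.zeros_like(den, dtype=float)
    np.divide(num, den, out=values, where=validity)
    return RatioMap(
        values=values,
        numerator=str(SpeciesLabel(numerator_species)),
        denominator=str(SpeciesLabel(denominator_species)),
        cycle_range=tuple(cycle_range),
        validity=validity,
        meta={"numerator_counts": num, "denominator_counts": den},
    )


def atpercent_map(
    session: AcquisitionSession,
    cycle_range: tuple[int, int],
    display_floor: float = DEFAULT_DISPLAY_FLOOR,
) -> RatioMap:
    """Per-pixel at% ¹⁵N map: 100·n15/(n14+n15) on accumulated counts.

    ``display_floor`` (default 0.63 at%) is recorded for rendering only; the
    stored values are unclipped.  Invariant under any common positive scaling
    of both CN channels, so topography effects largely cancel.
    """
    for lab in (SpeciesLabel.C12N14, SpeciesLabel.C15N):
        if lab not in session.stacks:
            raise KeyError(f"at% map needs the {lab.value} stack")
    n14 = _accumulated(session, SpeciesLabel.C12N14, cycle_range)
    n15 = _accumulated(session, SpeciesLabel.C15N, cycle_range)
    total = n14 + n15
    validity = total > 0
    values = np.zeros_like(total, dtype=float)
    np.divide(100.0 * n15, total, out=values, where=validity)
    return RatioMap(
        values=values,
        numerator=str(SpeciesLabel.C15N),
        denominator="C12N14+C15N",
        cycle_range=tuple(cycle_range),
        validity=validity,
        units="at%",
        display_floor=display_floor,
    )


#: color used below the display floor / outside validity (dark background)
_BELOW_FLOOR_RGB = (18, 18, 56)
_INVALID_RGB = (0, 0, 0)


def render(
    rmap: RatioMap,
    path,
    scale: tuple[float, float] | None = None,
    colormap: str = "inferno",
) -> "str":
    """Write a false-color PNG of a ratio map.

    Values at or above ``scale[0]`` (default: the map's display floor, else
    the valid minimum) render through a warm colormap up to ``scale[1]``;
    values below the floor render dark, invalid pixels black.  Output bytes
    are deterministic for fixed inputs.
    """
    if scale is None:
        lo = rmap.display_floor
        if lo is None:
            lo = float(rmap.valid_values().min()) if rmap.validity.any() else 0.0
        hi = float(rmap.valid_values().max()) if rmap.validity.any() else lo + 1.0
        if hi <= lo:
            hi = lo + 1.0
        scale = (lo, hi)
    lo, hi = float(scale[0]), float(scale[1])
    if lo >= hi:
        raise ValueError(f"scale min must be < max, got ({lo}, {hi})")

    cmap = colormaps[colormap]
    norm = np.clip((rmap.values - lo) / (hi - lo), 0.0, 1.0)
    rgb = (cmap(norm)[..., :3] * 255).astype(np.uint8)
    rgb[rmap.values < lo] = _BELOW_FLOOR_RGB
    rgb[~rmap.validity] = _INVALID_RGB
    img = Image.fromarray(rgb, mode="RGB")
    img.save(str(path), format="PNG")
    return str(path)
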