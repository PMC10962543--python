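"""Stepwise single-cell ROI definition on gold/phosphorus/¹⁵N co-localization.

The funnel mirrors the evaluation workflow for gold-hybridized cells on root
surfaces:

1. exclude low-signal topography (low ¹²C⁻ and secondary-electron areas);
2. detect candidate hotspots on the ¹⁹⁷Au⁻:¹²C⁻ ratio map from the early
   measurement window (surface-near material), dropping components that are
   smaller than a cell fragment or large enough to be a biofilm patch;
3. confirm cellular biomass by the ³¹P⁻:¹²C⁻ ratio inside each candidate;
4. screen the confirmed ROIs for significant ¹⁵N enrichment.

Category counts are monotone by construction: AU_P_N15 ⊆ AU_P ⊆ candidates.
ROI masks are frozen at candidate definition; later cycles never reshape
them, so per-cycle profiles always refer to the same pixel set.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, Field
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage import measure, morphology

from .imaging import RatioMap, accumulate
from .model import AcquisitionSession, Roi, RoiCategory, SpeciesLabel
from . import enrichment_stats as es

__all__ = [
    "RoiConfig",
    "exclusion_mask",
    "detect_candidates",
    "classify_rois",
    "funnel_counts",
    "roi_cycle_profile",
    "first_detection_cycle",
    "early_window",
]

#: Cs⁺ fluence bound (ions·cm⁻²) delimiting the surface-near early window
EARLY_FLUENCE_LIMIT = 3.7e16


class RoiConfig(BaseModel):
    """Tunables of the ROI funnel.

    Auto thresholds: the Au:C detection threshold defaults to mean + 3·SD of
    the valid, non-excluded map; the P:C confirmation threshold to the
    background median + 3·MAD (robust to hotspot skew).  Area bounds default
    to 4–400 px — single cells up to small clusters at 512×512 over ~50 μm
    fields; larger components are dropped as candidate biofilms.
    """

    au_ratio_threshold: float | Literal["auto"] = "auto"
    au_auto_k: float = 3.0
    au_min_counts: int | Literal["auto"] = "auto"
    count_gate_alpha: float = Field(default=0.01, gt=0.0, lt=1.0)
    p_ratio_threshold: float | Literal["auto"] = "auto"
    p_auto_k: float = 3.0
    min_area_px: int = Field(default=4, ge=1)
    max_area_px: int = Field(default=400, ge=2)
    connectivity: Literal[4, 8] = 8
    closing_radius: int = Field(default=2, ge=0)
    trim_radius: int = Field(default=1, ge=0)
    c_quantile: float = Field(default=0.05, gt=0.0, lt=1.0)
    se_quantile: float = Field(default=0.05, gt=0.0, lt=1.0)
    early_fluence_cycles: int | None = None
    late_rescan: bool = False
    overlap_dedup: float = 0.5
    detect_m_consecutive: int = Field(default=2, ge=1)

    def model_post_init(self, __context) -> None:
        if self.min_area_px >= self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")


def early_window(session: AcquisitionSession, config: RoiConfig) -> tuple[int, int]:
    """1-based cycle range used for candidate definition.

    Uses cycles with cumulative Cs⁺ fluence ≤ 3.7×10¹⁶ ions·cm⁻² when the
    session metadata carries a per-cycle fluence schedule, else the first
    third of cycles (at least one).
    """
    n = session.n_cycles
    if config.early_fluence_cycles is not None:
        return (1, min(config.early_fluence_cycles, n))
    fluence = session.metadata.get("cs_fluence_per_cycle")
    if fluence is not None:
        cum = np.cumsum(np.asarray(fluence, dtype=float))
        k = int(np.searchsorted(cum, EARLY_FLUENCE_LIMIT, side="right"))
        return (1, max(1, min(k, n)))
    return (1, max(1, n // 3))


def exclusion_mask(session: AcquisitionSession, config: RoiConfig) -> np.ndarray:
    """True where a pixel is excluded from ROI analysis.

    A pixel is excluded when its accumulated ¹²C⁻ falls below the
    ``c_quantile`` quantile or (when an SE image exists) its accumulated
    secondary-electron signal below the ``se_quantile`` quantile — both
    signatures of strong topography.
    """
    full = (1, session.n_cycles)
    c_acc = accumulate(session.stack(SpeciesLabel.C12), full,
                       session.validity_for(SpeciesLabel.C12))
    mask = c_acc < np.quantile(c_acc, config.c_quantile)
    if session.has_se:
        se_acc = accumulate(session.stack(SpeciesLabel.SE), full,
                            session.validity_for(SpeciesLabel.SE))
        mask |= se_acc < np.quantile(se_acc, config.se_quantile)
    # topographic lows are spatially coherent; opening removes the isolated
    # quantile-tail pixels that Poisson scatter alone puts below threshold
    return morphology.opening(mask, morphology.disk(1))


def _auto_threshold(rmap: RatioMap, excl: np.ndarray, k: float) -> float:
    """Background mean + k·SD of the ratio map, with the background moments
    estimated by iterative sigma clipping so that the hotspots being sought
    do not inflate their own detection threshold."""
    vals = rmap.values[rmap.validity & ~excl]
    if vals.size == 0:
        return np.inf
    thr = vals.mean() + k * vals.std()
    for _ in range(20):
        kept = vals[vals <= thr]
        if kept.size == vals.size or kept.size == 0 or kept.max() == 0:
            break  # stop before the clip degenerates to the zero-count mass
        vals = kept
        thr = vals.mean() + k * vals.std()
    return float(thr)


def _count_gate(rmap: RatioMap, excl: np.ndarray, config: RoiConfig) -> np.ndarray | None:
    """Minimum-numerator-count gate for hotspot detection.

    On sparse channels like ¹⁹⁷Au⁻ the ratio of one or two stray background
    counts over a low denominator can exceed any ratio threshold, so hotspot
    pixels must additionally carry more numerator counts than background
    Poisson scatter explains.  The "auto" bound is the smallest count level
    whose family-wise (Bonferroni over pixels) false-positive probability
    under the sigma-clipped background rate stays below
    ``count_gate_alpha``.
    """
    counts = rmap.meta.get("numerator_counts")
    if counts is None or config.au_min_counts == 0:
        return None
    if config.au_min_counts != "auto":
        return counts >= int(config.au_min_counts)
    bg = counts[rmap.validity & ~excl].astype(float)
    if bg.size == 0:
        return None
    zero_frac = (bg == 0).mean()
    if zero_frac > 0.5:
        # sparse channel: the zero fraction pins the Poisson rate and is
        # insensitive to the (rarely zero) hotspot pixels
        lam = -np.log(zero_frac)
    else:
        for _ in range(20):
            kept = bg[bg <= bg.mean() + 3 * bg.std()]
            if kept.size in (bg.size, 0):
                break
            bg = kept
        lam = bg.mean()
    lam = max(lam, 1e-12)
    c_star = int(sps.poisson.isf(config.count_gate_alpha / counts.size, lam)) + 1
    return counts >= c_star


def _components(binary: np.ndarray, connectivity: int) -> list[np.ndarray]:
    labels = measure.label(binary, connectivity=1 if connectivity == 4 else 2)
    return [np.argwhere(labels == lab) for lab in range(1, labels.max() + 1)]


def detect_candidates(
    au_c_map: RatioMap,
    excl: np.ndarray,
    config: RoiConfig,
    late_map: RatioMap | None = None,
) -> list[Roi]:
    """Candidate gold hotspots (category AU_ONLY) on the Au:C ratio map.

    Thresholds the map, labels connected components under the configured
    connectivity, drops components touching the exclusion mask, and applies
    the area filter (too small: noise speck; too large: candidate biofilm,
    logged in provenance).  With ``config.late_rescan`` and a later-window
    map, hotspots emerging late are added, deduplicated against existing
    masks at ≥ ``overlap_dedup`` fractional overlap.  Ordering is
    deterministic: by top-left-most pixel (row, then col).
    """
    rois: list[Roi] = []
    dropped_large = 0

    def scan(rmap: RatioMap, window: str) -> None:
        nonlocal dropped_large
        thr = (
            _auto_threshold(rmap, excl, config.au_auto_k)
            if config.au_ratio_threshold == "auto"
            else float(config.au_ratio_threshold)
        )
        binary = (rmap.values > thr) & rmap.validity
        gate = _count_gate(rmap, excl, config)
        if gate is not None:
            binary &= gate
        if config.closing_radius > 0:
            # gold sits on the cell envelope, so hotspots are rings; closing
            # and hole-filling turn a ring into a cell-covering component
            binary = morphology.closing(
                binary, morphology.disk(config.closing_radius)
            )
            binary = ndi.binary_fill_holes(binary)
        if config.trim_radius > 0:
            # trim the halo of background pixels the envelope signal + closing
            # adds around a cell, so in-ROI medians reflect the cell interior
            binary = morphology.erosion(binary, morphology.disk(config.trim_radius))
        for pix in _components(binary, config.connectivity):
            if excl[pix[:, 0], pix[:, 1]].any():
                continue
            if pix.shape[0] > config.max_area_px:
                dropped_large += 1
                continue
            if pix.shape[0] < config.min_area_px:
                continue
            if window == "late":
                new = set(map(tuple, pix))
                dup = False
                for r in rois:
                    inter = len(new & set(map(tuple, r.pixels)))
                    if inter / min(len(new), r.area_px) >= config.overlap_dedup:
                        dup = True
                        break
                if dup:
                    continue
            rois.append(
                Roi(
                    id="",
                    pixels=pix,
                    category=RoiCategory.AU_ONLY,
                    provenance={"threshold": thr, "window": window},
                )
            )

    scan(au_c_map, "early")
    if config.late_rescan and late_map is not None:
        scan(late_map, "late")

    rois.sort(key=Roi.bbox_key)
    for i, r in enumerate(rois, start=1):
        r.id = f"roi_{i:04d}"
        r.provenance["dropped_large_clusters"] = dropped_large
    return rois


def classify_rois(
    cands: list[Roi],
    p_c_map: RatioMap,
    enrichment: dict[str, "es.EnrichmentResult"],
    control,
    config: RoiConfig,
) -> list[Roi]:
    """Promote candidates up the category ladder.

    AU_P: the median ³¹P⁻:¹²C⁻ ratio inside the ROI exceeds the phosphorus
    threshold (auto: background median + 3·MAD over valid non-ROI pixels).
    AU_P_N15: additionally, the ROI's at% passes the two-clause significance
    rule (carried in ``enrichment[roi.id].enriched``).
    """
    if config.p_ratio_threshold == "auto":
        bg = p_c_map.validity.copy()
        for r in cands:
            bg[r.pixels[:, 0], r.pixels[:, 1]] = False
        vals = p_c_map.values[bg]
        if vals.size:
            med = float(np.median(vals))
            mad = float(np.median(np.abs(vals - med)))
            p_thr = med + config.p_auto_k * mad
        else:
            p_thr = np.inf
    else:
        p_thr = float(config.p_ratio_threshold)

    out: list[Roi] = []
    for r in cands:
        rows, cols = r.pixels[:, 0], r.pixels[:, 1]
        inside = p_c_map.values[rows, cols][p_c_map.validity[rows, cols]]
        category = RoiCategory.AU_ONLY
        if inside.size and float(np.median(inside)) > p_thr:
            category = RoiCategory.AU_P
            res = enrichment.get(r.id)
            if res is not None and res.valid and res.enriched:
                category = RoiCategory.AU_P_N15
        out.append(
            Roi(id=r.id, pixels=r.pixels, category=category,
                cycle_counts=r.cycle_counts,
                provenance={**r.provenance, "p_threshold": p_thr})
        )
    return out


def funnel_counts(rois: list[Roi]) -> dict[str, int]:
    """Monotone funnel {candidates ≥ au_p ≥ au_p_n15} for the run log."""
    au_p = sum(r.category.rank >= RoiCategory.AU_P.rank for r in rois)
    au_p_n15 = sum(r.category is RoiCategory.AU_P_N15 for r in rois)
    return {"candidates": len(rois), "au_p": au_p, "au_p_n15": au_p_n15}


def roi_cycle_profile(
    roi: Roi,
    session: AcquisitionSession,
    species: list[SpeciesLabel | str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-cycle summed counts per species inside the ROI, plus the
    cycle-wise at% ¹⁵N series (NaN where the cycle's CN total is zero)."""
    if species is None:
        species = [SpeciesLabel.AU197_1, SpeciesLabel.C12N14, SpeciesLabel.C15N]
    full = (1, session.n_cycles)
    profile: dict[str, np.ndarray] = {}
    for sp in species:
        label = SpeciesLabel(sp)
        profile[label.value] = es.roi_counts(roi, session, label, full)
    need = {SpeciesLabel.C12N14.value, SpeciesLabel.C15N.value}
    have = {k: profile.get(k) for k in need}
    for k in need - set(profile):
        have[k] = es.roi_counts(roi, session, SpeciesLabel(k), full)
    n14, n15 = have[SpeciesLabel.C12N14.value], have[SpeciesLabel.C15N.value]
    totals = n14 + n15
    atpct = np.full(session.n_cycles, np.nan)
    ok = totals > 0
    atpct[ok] = 100.0 * n15[ok] / totals[ok]
    profile["atpct"] = atpct
    roi.cycle_counts.update({k: v for k, v in profile.items() if k != "atpct"})
    return profile


def first_detection_cycle(
    series: np.ndarray, threshold: float, m_consecutive: int = 2
) -> int | None:
    """First 1-based cycle where ``series`` exceeds ``threshold`` for
    ``m_consecutive`` consecutive cycles; ``None`` if it never does.
    NaN entries never count as exceeding."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series must be non-empty")
    above = np.where(np.isnan(series), False, series > threshold)
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= m_consecutive:
            return i - m_consecutive + 2  # 1-based start of the run
    return None
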