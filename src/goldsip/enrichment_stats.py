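"""Single-cell isotope statistics.

The quantity of interest is the ¹⁵N isotope fraction of a cell,
at% ¹⁵N = 100·¹⁵N/(¹⁴N+¹⁵N), measured from the ¹²C¹⁵N⁻ and ¹²C¹⁴N⁻ count
totals inside a ROI.  Its counting uncertainty follows from Poisson
statistics of the two independent count totals by first-order propagation:

    σ_at% = 100 · sqrt( n15 · n14 / (n15 + n14)³ )

A ROI is called significantly enriched only if BOTH clauses of the 6σ rule
hold: (1) its at% exceeds the unlabeled-control mean plus six control
standard deviations, and (2) six times its own Poisson σ is smaller than its
deviation from the control mean.  The two-clause form guards against low-
count ROIs whose large counting error could mimic enrichment.

Gold-FISH chemistry dilutes the isotopic label (permeabilization plus
deposition of natural-abundance compounds); measured values are corrected by
the multiplicative factor 1/(1−loss), with the loss fraction estimated from
labeled cells measured with and without the treatment.  The factor is
carried at full precision; rounding happens only in display columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .model import (
    AcquisitionSession,
    ControlStats,
    EnrichmentResult,
    Roi,
    SpeciesLabel,
)

__all__ = [
    "atpercent",
    "poisson_sigma",
    "fit_control",
    "is_enriched",
    "roi_enrichment",
    "DilutionModel",
    "dilution_factor",
    "correct_dilution",
    "estimate_label_loss",
    "AreaSummary",
    "summarize_area",
    "compare_areas",
]


def atpercent(n15: float, n14: float) -> float:
    """at% ¹⁵N = 100·n15/(n14+n15).  Total must be positive (callers mask
    zero-total pixels/ROIs instead of calling this)."""
    total = n15 + n14
    if total <= 0:
        raise ValueError("at% undefined for zero total CN counts")
    return 100.0 * n15 / total


def poisson_sigma(n15: float, n14: float) -> float:
    """Poisson counting error of the at% estimate, in at%.

    First-order propagation through p = n15/(n15+n14) with independent
    Poisson totals: σ_p = sqrt(n15·n14/(n15+n14)³).  Zero when either count
    is zero (the estimate sits on the boundary).
    """
    total = n15 + n14
    if total <= 0:
        raise ValueError("σ undefined for zero total CN counts")
    return 100.0 * np.sqrt(n15 * n14 / total**3)


def fit_control(values, k_sigma: float = 6.0) -> ControlStats:
    """Fit the natural-abundance baseline from unlabeled single-cell values.

    Sample mean and SD (n−1 denominator); the enrichment threshold is the
    mean plus ``k_sigma`` standard deviations (default 6).
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError(f"control fit needs at least 2 cells, got {values.size}")
    spread = float(values.std(ddof=1)) if values.min() < values.max() else 0.0
    return ControlStats(
        mean_atpct=float(values.mean()),
        sd_atpct=spread,
        k_sigma=k_sigma,
        n_cells=int(values.size),
    )


def is_enriched(atpct: float, sigma: float, control: ControlStats) -> bool:
    """Two-clause significance rule for ¹⁵N enrichment.

    (1) at% above the control mean + k·SD threshold, and (2) k·σ_Poisson
    smaller than the deviation of the value from the control mean.
    """
    clause1 = atpct > control.threshold_atpct
    clause2 = control.k_sigma * sigma < (atpct - control.mean_atpct)
    return bool(clause1 and clause2)


def roi_counts(
    roi: Roi, session: AcquisitionSession, species: SpeciesLabel | str,
    cycle_range: tuple[int, int],
) -> np.ndarray:
    """Per-cycle summed counts of one species inside the ROI mask, honoring
    per-cycle validity."""
    label = SpeciesLabel(species)
    first, last = cycle_range
    planes = session.stack(label).cycle_planes(first, last)
    validity = session.validity_for(label)[first - 1 : last]
    rows, cols = roi.pixels[:, 0], roi.pixels[:, 1]
    vals = planes[:, rows, cols] * validity[:, rows, cols]
    return vals.sum(axis=1)


def roi_enrichment(
    roi: Roi,
    session: AcquisitionSession,
    cycle_range: tuple[int, int],
    control: ControlStats,
    method: str = "sum",
    analysis_area: str = "",
) -> EnrichmentResult:
    """Quantify a ROI's ¹⁵N content over an inclusive 1-based cycle range.

    ``method="sum"`` (default) computes at% from the cycle-summed counts —
    the Poisson-optimal estimate matching the "total counts within each ROI"
    error definition.  ``method="cycle_mean"`` instead averages per-cycle at%
    values over cycles with non-zero CN totals; both agree for homogeneous
    signals.  σ and the significance flag always use the summed counts.
    """
    n14_series = roi_counts(roi, session, SpeciesLabel.C12N14, cycle_range)
    n15_series = roi_counts(roi, session, SpeciesLabel.C15N, cycle_range)
    n14, n15 = float(n14_series.sum()), float(n15_series.sum())
    if n14 + n15 <= 0:
        return EnrichmentResult(
            roi_id=roi.id, atpct_raw=0.0, sigma_poisson=0.0, enriched=False,
            cycle_range=tuple(cycle_range), valid=False,
            category=roi.category, area_px=roi.area_px, analysis_area=analysis_area,
        )
    if method == "sum":
        value = atpercent(n15, n14)
    elif method == "cycle_mean":
        totals = n14_series + n15_series
        ok = totals > 0
        value = float(np.mean(100.0 * n15_series[ok] / totals[ok]))
    else:
        raise ValueError(f"unknown method {method!r}")
    sigma = poisson_sigma(n15, n14)
    return EnrichmentResult(
        roi_id=roi.id,
        atpct_raw=value,
        sigma_poisson=sigma,
        enriched=is_enriched(value, sigma, control),
        cycle_range=tuple(cycle_range),
        n15_counts=n15,
        n14_counts=n14,
        category=roi.category,
        area_px=roi.area_px,
        analysis_area=analysis_area,
    )


# ---------------------------------------------------------------------------
# label dilution


@dataclass(frozen=True)
class DilutionModel:
    """Multiplicative correction for isotope-label dilution by the
    hybridization chemistry: factor = 1/(1 − loss_fraction)."""

    loss_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.loss_fraction < 1.0):
            raise ValueError(f"loss_fraction must be in [0, 1), got {self.loss_fraction}")

    @property
    def factor(self) -> float:
        return 1.0 / (1.0 - self.loss_fraction)


def dilution_factor(loss_fraction: float) -> DilutionModel:
    """Build the dilution model for a given label-loss fraction."""
    return DilutionModel(loss_fraction=float(loss_fraction))


def correct_dilution(result: EnrichmentResult, model: DilutionModel) -> EnrichmentResult:
    """Apply the dilution factor to a ROI's raw at% (full precision).

    Raises if the corrected value would exceed 100 at% (non-physical).
    """
    if not result.valid:
        raise ValueError(f"cannot dilution-correct invalid result {result.roi_id}")
    corrected = result.atpct_raw * model.factor
    if corrected > 100.0:
        raise ValueError(
            f"corrected at% {corrected:.3f} exceeds 100 for ROI {result.roi_id}"
        )
    return replace(result, atpct_corrected=corrected)


def estimate_label_loss(treated, untreated) -> float:
    """Label-loss fraction from labeled cells with vs without the treatment:
    1 − mean(treated)/mean(untreated), clipped to [0, 1)."""
    treated = np.asarray(list(treated), dtype=float)
    untreated = np.asarray(list(untreated), dtype=float)
    if treated.size == 0 or untreated.size == 0:
        raise ValueError("both treated and untreated lists must be non-empty")
    mu_u = untreated.mean()
    if mu_u == 0:
        raise ValueError("untreated mean is zero; loss undefined")
    loss = 1.0 - treated.mean() / mu_u
    return float(np.clip(loss, 0.0, np.nextafter(1.0, 0.0)))


# ---------------------------------------------------------------------------
# per-area summaries and cross-area comparison


@dataclass
class AreaSummary:
    """Distribution summary of ROI at% values within one analysis area."""

    area_id: str
    n_rois: int
    mean: float
    median: float
    max: float
    q1: float
    q3: float
    mean_corrected: float | None = None
    median_corrected: float | None = None
    max_corrected: float | None = None


def summarize_area(results: list[EnrichmentResult], area_id: str) -> AreaSummary:
    """Mean / median / max / quartiles of raw (and, when present, corrected)
    at% over the valid ROIs of one analysis area."""
    raw = np.array([r.atpct_raw for r in results if r.valid], dtype=float)
    if raw.size == 0:
        raise ValueError(f"no valid results to summarize for area {area_id}")
    corr = np.array(
        [r.atpct_corrected for r in results if r.valid and r.atpct_corrected is not None],
        dtype=float,
    )
    q1, med, q3 = np.percentile(raw, [25, 50, 75])
    return AreaSummary(
        area_id=area_id,
        n_rois=int(raw.size),
        mean=float(raw.mean()),
        median=float(med),
        max=float(raw.max()),
        q1=float(q1),
        q3=float(q3),
        mean_corrected=float(corr.mean()) if corr.size else None,
        median_corrected=float(np.median(corr)) if corr.size else None,
        max_corrected=float(corr.max()) if corr.size else None,
    )


def compare_areas(groups: dict[str, list[float]]) -> dict:
    """One-way ANOVA plus Tukey HSD across analysis areas.

    Pure report — no pipeline behavior depends on its outcome.  Returns
    ``{"anova": {"F", "p"}, "tukey": [{"a", "b", "p_adj", "diff"}, ...]}``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k} needs at least 2 values")
    names = sorted(arrays)
    f, p = sps.f_oneway(*(arrays[k] for k in names))
    tukey = sps.tukey_hsd(*(arrays[k] for k in names))
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append(
                {
                    "a": names[i],
                    "b": names[j],
                    "diff": float(arrays[names[i]].mean() - arrays[names[j]].mean()),
                    "p_adj": float(tukey.pvalue[i, j]),
                }
            )
    return {"anova": {"F": float(f), "p": float(p)}, "tukey": pairs}
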