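"""End-to-end orchestration: corrections → imaging → ROI funnel → statistics."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .corrections import CorrectionConfig, DriftTrace, preprocess
from .enrichment_stats import DilutionModel, correct_dilution, roi_enrichment
from .imaging import RatioMap, atpercent_map, ratio_map
from .model import AcquisitionSession, ControlStats, EnrichmentResult, Roi, SpeciesLabel
from .roi_analysis import (
    RoiConfig,
    classify_rois,
    detect_candidates,
    early_window,
    exclusion_mask,
    funnel_counts,
)

__all__ = ["PipelineResult", "process_session"]


@dataclass
class PipelineResult:
    """Everything one processing run produces."""

    session: AcquisitionSession
    trace: DriftTrace
    rois: list[Roi]
    results: list[EnrichmentResult]
    funnel: dict[str, int]
    maps: dict[str, RatioMap] = field(default_factory=dict)


def process_session(
    session: AcquisitionSession,
    control: ControlStats,
    correction_config: CorrectionConfig | None = None,
    roi_config: RoiConfig | None = None,
    cycle_range: tuple[int, int] | None = None,
    method: str = "sum",
    dilution: DilutionModel | None = None,
    analysis_area: str | None = None,
) -> PipelineResult:
    """Run the full evaluation chain on one acquisition.

    Candidates are detected on the early-window ¹⁹⁷Au⁻:¹²C⁻ ratio map (with
    an optional late-window rescan), confirmed on ³¹P⁻:¹²C⁻, quantified over
    ``cycle_range`` (default: all cycles) and screened with the two-clause
    significance rule against ``control``.  When a dilution model is given,
    every valid ROI also gets a corrected at% value.
    """
    correction_config = correction_config or CorrectionConfig()
    roi_config = roi_config or RoiConfig()
    area = analysis_area or str(session.metadata.get("analysis_area", ""))

    processed, trace = preprocess(session, correction_config)
    n = processed.n_cycles
    cycle_range = cycle_range or (1, n)

    early = early_window(processed, roi_config)
    excl = exclusion_mask(processed, roi_config)
    au_map = ratio_map(processed, SpeciesLabel.AU197_1, SpeciesLabel.C12, early)
    late_map = None
    if roi_config.late_rescan and early[1] < n:
        late_map = ratio_map(processed, SpeciesLabel.AU197_1, SpeciesLabel.C12,
                             (early[1] + 1, n))
    cands = detect_candidates(au_map, excl, roi_config, late_map=late_map)

    enrichment = {
        r.id: roi_enrichment(r, processed, cycle_range, control,
                             method=method, analysis_area=area)
        for r in cands
    }
    p_map = ratio_map(processed, SpeciesLabel.P31, SpeciesLabel.C12, cycle_range)
    rois = classify_rois(cands, p_map, enrichment, control, roi_config)

    results = []
    for roi in rois:
        res = replace(enrichment[roi.id], category=roi.category)
        if dilution is not None and res.valid:
            res = correct_dilution(res, dilution)
        results.append(res)

    maps = {
        "au_c_early": au_map,
        "p_c": p_map,
        "atpct": atpercent_map(processed, cycle_range,
                               display_floor=control.threshold_atpct),
    }
    return PipelineResult(
        session=processed,
        trace=trace,
        rois=rois,
        results=results,
        funnel=funnel_counts(rois),
        maps=maps,
    )
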