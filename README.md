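# goldsip

Quantitative NanoSIMS image evaluation for **gold-labelled single-cell stable
isotope probing**: identify hybridization-labelled bacterial cells on complex
surfaces (e.g. root surfaces) in multilayer secondary-ion count images, and
measure their ¹⁵N enrichment with rigorous counting statistics.

## Who this is for

NanoSIMS users who combine gold-based in situ hybridization (gold-FISH) with
stable-isotope incubations to ask *which individual cells were metabolically
active*. The instrument delivers per-pixel, per-cycle ion counts for several
species; turning those stacks into defensible per-cell enrichment values
requires detector corrections, drift alignment, a reproducible cell-finding
funnel and Poisson-aware significance screening. This package implements that
chain as a tested library plus a small CLI, together with a synthetic
acquisition simulator so every stage can be validated against known ground
truth without instrument data.

## The measurement model

An acquisition consists of cycles split into two half-cycles recorded at
distinct magnetic fields: half-cycle 1 detects ¹²C⁻, ¹²C¹⁴N⁻, ¹⁹⁷Au⁻(1);
half-cycle 2 detects ¹²C₂⁻, ¹²C¹⁵N⁻, ³¹P⁻, ¹⁹⁷Au⁻(2); secondary-electron
images are recorded in both.

**Corrections.** Counts are corrected for detector dead time,
n′ = n / (1 − (n/T)·τ) with dwell time T and τ = 44 ns (configurable), and
for quasi-simultaneous arrival, n′ = n·(1 + βK), with sensitivity factors
β = 1.1 (C⁻), 1.06 (C₂⁻) and 1.05 (CN⁻). Per-cycle drift is compensated by
integer-pixel cross-correlation tracking on the ¹⁹⁷Au⁻ signals, and
half-cycle 2 is registered onto half-cycle 1 with a single offset estimated
from the two accumulated Au images.

**ROI funnel.** Candidate cells are connected hotspots of the ¹⁹⁷Au⁻:¹²C⁻
ratio in the early measurement window (surface-near material), excluding
low-¹²C⁻/low-SE topography, with a size filter that rejects specks and
biofilm-scale clusters. Candidates are confirmed as cellular by the
³¹P⁻:¹²C⁻ ratio, then screened for ¹⁵N enrichment — a monotone funnel
`candidates → Au+P → Au+P+¹⁵N`.

**Isotope statistics.** For each ROI the isotope fraction is computed from
cycle-summed counts,

    at% ¹⁵N = 100 · n15 / (n14 + n15),
    σ_at%  = 100 · sqrt( n15 · n14 / (n15 + n14)³ )   (Poisson),

and a ROI counts as significantly enriched only if (1) its at% exceeds the
unlabeled-control mean + 6 SD (0.362 + 6·0.045 → 0.63 at%) **and** (2) six
times its own Poisson σ is smaller than its deviation from the control mean.
Because hybridization chemistry dilutes the label (measured loss: 39 %),
corrected values are obtained with the factor 1/(1 − 0.39) ≈ 1.64 carried at
full precision. Per-area summaries and an ANOVA + Tukey comparison report
complete the analysis.

## Worked example

```python
import goldsip as g

control = g.ControlStats(mean_atpct=0.362, sd_atpct=0.045, k_sigma=6.0)
print(f"enrichment threshold: {control.threshold_atpct:.2f} at% 15N")

session, truth = g.simulate_session(g.paper_like_scenario(seed=1))
result = g.process_session(session, control, dilution=g.dilution_factor(0.39))
print("ROI funnel:", result.funnel)

enriched = [r for r in result.results if r.enriched]
summary = g.summarize_area(enriched, "SIM")
print(f"enriched ROIs: n={summary.n_rois}, "
      f"mean={summary.mean:.2f}, median={summary.median:.2f}, "
      f"max={summary.max:.2f} at% (raw)")
print(f"dilution-corrected mean: {summary.mean_corrected:.2f} at%")
```

prints

```
enrichment threshold: 0.63 at% 15N
ROI funnel: {'candidates': 36, 'au_p': 30, 'au_p_n15': 28}
enriched ROIs: n=28, mean=1.45, median=1.36, max=3.28 at% (raw)
dilution-corrected mean: 2.37 at%
```

The simulated field contains 30 gold-labelled cells (10 % at natural
abundance) plus non-specific gold specks: the funnel finds 36 gold
candidates, confirms 30 as cells by phosphorus, and flags 28 as
significantly ¹⁵N-enriched — the specks fail the phosphorus screen and the
unlabelled cell fails the 6σ rule, exactly as intended. The raw mean of the
enriched population reflects the planted lognormal enrichment; the corrected
mean undoes the simulated 39 % label loss.

The same pipeline is available from the shell:

```bash
goldsip simulate out/sim --seed 1
goldsip process out/sim out/run --loss-fraction 0.39
goldsip summarize out/run/roi_table.csv out/summary
```

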