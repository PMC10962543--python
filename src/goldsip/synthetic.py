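"""Synthetic NanoSIMS acquisitions with known ground truth.

The simulator emulates the features of a real rhizoplane measurement that
the pipeline has to cope with, at desk scale:

* per-pixel, per-cycle, per-species Poisson counting noise on top of smooth
  expected-rate fields;
* elliptical cells whose CN⁻ emission splits into ¹²C¹⁴N⁻ and ¹²C¹⁵N⁻ as a
  binomial thinning at the cell's isotope fraction — exactly the statistical
  structure the at% estimator assumes;
* gold rendered as a membrane shell (hybridization deposits nanoparticles in
  and on the cell envelope), present from cycle 1, while the ¹⁵N signal of a
  cell only emerges at its onset cycle — reproducing the depth delay between
  gold and ¹⁵N detection as the beam erodes into the cell lumen;
* inter-cycle stage drift (integer random walk) plus a constant half-cycle
  mis-registration;
* low-signal topography trenches and sparse non-specific gold specks
  (auto-nucleation background) to exercise exclusion and false-positive
  handling.

Everything is driven by one seed; a fixed seed reproduces the session
bit-exactly.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field

from .corrections import shift_plane
from .model import (
    BOTH_HALF_CYCLES,
    AcquisitionSession,
    CellTruth,
    IonImageStack,
    NATURAL_ABUNDANCE_ATPCT,
    SimulationTruth,
    SpeciesLabel,
    default_species_table,
)

__all__ = [
    "ScenarioConfig",
    "simulate_session",
    "paper_like_scenario",
    "distort_counts",
    "simulate_single_cells",
]

_NAT_F = NATURAL_ABUNDANCE_ATPCT / 100.0


class ScenarioConfig(BaseModel):
    """Everything that defines one synthetic acquisition.

    Rates are expected counts per pixel per cycle.  ``cell_*_rate`` values
    add to the background inside a cell; the gold shell multiplies the Au
    rate within a ring of ``gold_shell_px`` around each gold-labelled cell's
    boundary.
    """

    pixel_shape: tuple[int, int] = (256, 256)
    raster_extent: float = 50.0  # micrometers per side
    n_cycles: int = Field(default=30, ge=1)
    dwell_time: float = 5e-3

    n_cells: int = Field(default=30, ge=0)
    cell_axis_px: tuple[float, float] = (3.0, 7.0)  # semi-axis range
    fraction_gold: float = Field(default=1.0, ge=0.0, le=1.0)
    fraction_unlabeled: float = Field(default=0.1, ge=0.0, le=1.0)
    enrichment_dist: str = "lognormal"  # or "point"
    enrichment_median_atpct: float = 1.6
    enrichment_sigma_log: float = 0.5
    enrichment_point_atpct: float = 3.0
    enrichment_max_atpct: float = 30.0
    onset_cycle_range: tuple[int, int] = (2, 8)

    background_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "C12": 20.0, "CN": 8.0, "AU": 0.02, "C12_2": 6.0,
            "P31": 0.2, "SE": 30.0,
        }
    )
    cell_c12_rate: float = 60.0
    cell_cn_rate: float = 60.0
    cell_c2_rate: float = 25.0
    cell_p_rate: float = 8.0
    cell_se_rate: float = 40.0
    gold_shell_px: float = 1.5
    gold_shell_rate: float = 8.0

    n_gold_specks: int = 8
    speck_size_px: int = 4
    speck_rate: float = 4.0

    drift_max_step: int = Field(default=1, ge=0)
    drift_max_total: int = Field(default=6, ge=0)
    half_cycle_offset: tuple[int, int] = (0, 0)

    n_trenches: int = 2
    trench_size_px: tuple[int, int] = (10, 40)
    trench_attenuation: float = 0.03

    seed: int = 0


def paper_like_scenario(seed: int = 0) -> ScenarioConfig:
    """Desk-scale default scenario for end-to-end tests.

    256×256 pixels over 30 cycles with ~30 gold-labelled cells, lognormal
    enrichment (median ≈ 1.6 at%), 10 % unlabeled cells at natural
    abundance, ¹⁵N onset delayed by a few cycles, a ≤ 1 px/cycle drift walk
    and a small constant half-cycle mis-registration.
    """
    return ScenarioConfig(seed=seed, half_cycle_offset=(2, -1))


def _ellipse_pixels(
    center: tuple[float, float], axes: tuple[float, float], theta_deg: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Integer pixel coordinates inside a rotated ellipse."""
    cy, cx = center
    a, b = axes
    t = np.deg2rad(theta_deg)
    r = max(a, b) + 1.0
    r0, r1 = int(max(0, np.floor(cy - r))), int(min(shape[0], np.ceil(cy + r) + 1))
    c0, c1 = int(max(0, np.floor(cx - r))), int(min(shape[1], np.ceil(cx + r) + 1))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    u = (yy - cy) * np.cos(t) + (xx - cx) * np.sin(t)
    v = -(yy - cy) * np.sin(t) + (xx - cx) * np.cos(t)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.column_stack([yy[inside], xx[inside]])


def _shell_pixels(center, axes, theta_deg, thickness, shape) -> np.ndarray:
    outer = _ellipse_pixels(center, (axes[0] + thickness, axes[1] + thickness),
                            theta_deg, shape)
    inner = {tuple(p) for p in _ellipse_pixels(
        center, (max(axes[0] - thickness, 0.5), max(axes[1] - thickness, 0.5)),
        theta_deg, shape)}
    keep = [p for p in outer if tuple(p) not in inner]
    return np.asarray(keep, dtype=int) if keep else outer


def _place_cells(cfg: ScenarioConfig, rng: np.random.Generator) -> list[CellTruth]:
    shape = cfg.pixel_shape
    cells: list[CellTruth] = []
    margin = cfg.cell_axis_px[1] + cfg.gold_shell_px + 2
    tries = 0
    max_tries = 400 * max(cfg.n_cells, 1)
    while len(cells) < cfg.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place non-overlapping cells; use fewer or smaller cells"
            )
        cy = rng.uniform(margin, shape[0] - margin)
        cx = rng.uniform(margin, shape[1] - margin)
        a = rng.uniform(*cfg.cell_axis_px)
        b = rng.uniform(cfg.cell_axis_px[0], a)
        theta = rng.uniform(0.0, 180.0)
        clearance = max(a, b) + cfg.gold_shell_px + 1
        ok = all(
            np.hypot(cy - c.center[0], cx - c.center[1])
            > clearance + max(c.axes) + cfg.gold_shell_px + 1
            for c in cells
        )
        if not ok:
            continue
        gold = rng.random() < cfg.fraction_gold
        unlabeled = rng.random() < cfg.fraction_unlabeled
        if unlabeled:
            atpct = NATURAL_ABUNDANCE_ATPCT
        elif cfg.enrichment_dist == "point":
            atpct = cfg.enrichment_point_atpct
        else:
            atpct = float(np.exp(rng.normal(np.log(cfg.enrichment_median_atpct),
                                            cfg.enrichment_sigma_log)))
            atpct = float(np.clip(atpct, NATURAL_ABUNDANCE_ATPCT,
                                  cfg.enrichment_max_atpct))
        onset = int(rng.integers(cfg.onset_cycle_range[0],
                                 cfg.onset_cycle_range[1] + 1))
        cells.append(
            CellTruth(
                center=(cy, cx), axes=(a, b), orientation_deg=theta,
                true_atpct=atpct, gold_labeled=gold, n15_onset_cycle=onset,
                pixels=_ellipse_pixels((cy, cx), (a, b), theta, shape),
            )
        )
    return cells


def _drift_walk(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    offsets = np.zeros((cfg.n_cycles, 2), dtype=int)
    for k in range(1, cfg.n_cycles):
        step = rng.integers(-cfg.drift_max_step, cfg.drift_max_step + 1, size=2)
        offsets[k] = np.clip(offsets[k - 1] + step,
                             -cfg.drift_max_total, cfg.drift_max_total)
    return offsets


def simulate_session(cfg: ScenarioConfig) -> tuple[AcquisitionSession, SimulationTruth]:
    """Draw one acquisition from a scenario; returns the session and truth.

    Expected-rate fields are composed in the reference frame of cycle 1,
    shifted by the cycle's true drift (half-cycle 2 additionally by the
    half-cycle offset), then Poisson counts are drawn independently per
    pixel, cycle and species.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.pixel_shape
    cells = _place_cells(cfg, rng)
    for cell in cells:
        cell.expected_n15 = np.zeros(cfg.n_cycles)
        cell.expected_n14 = np.zeros(cfg.n_cycles)
    drift = _drift_walk(cfg, rng)

    # low-signal topography trenches (axis-aligned rectangles)
    atten = np.ones(shape, dtype=float)
    trench_mask = np.zeros(shape, dtype=bool)
    for _ in range(cfg.n_trenches):
        h = int(rng.integers(*cfg.trench_size_px))
        w = int(rng.integers(*cfg.trench_size_px))
        r0 = int(rng.integers(0, max(shape[0] - h, 1)))
        c0 = int(rng.integers(0, max(shape[1] - w, 1)))
        atten[r0 : r0 + h, c0 : c0 + w] = cfg.trench_attenuation
        trench_mask[r0 : r0 + h, c0 : c0 + w] = True

    bg = cfg.background_rates
    base = {
        SpeciesLabel.C12: np.full(shape, bg["C12"]),
        SpeciesLabel.C12_2: np.full(shape, bg["C12_2"]),
        SpeciesLabel.P31: np.full(shape, bg["P31"]),
        SpeciesLabel.SE: np.full(shape, bg["SE"]),
        SpeciesLabel.AU197_1: np.full(shape, bg["AU"]),
        SpeciesLabel.AU197_2: np.full(shape, bg["AU"]),
    }
    cn_base = np.full(shape, bg["CN"])

    for cell in cells:
        rr, cc = cell.pixels[:, 0], cell.pixels[:, 1]
        base[SpeciesLabel.C12][rr, cc] += cfg.cell_c12_rate
        base[SpeciesLabel.C12_2][rr, cc] += cfg.cell_c2_rate
        base[SpeciesLabel.P31][rr, cc] += cfg.cell_p_rate
        base[SpeciesLabel.SE][rr, cc] += cfg.cell_se_rate
        if cell.gold_labeled:
            shell = _shell_pixels(cell.center, cell.axes, cell.orientation_deg,
                                  cfg.gold_shell_px, shape)
            for au in (SpeciesLabel.AU197_1, SpeciesLabel.AU197_2):
                base[au][shell[:, 0], shell[:, 1]] += cfg.gold_shell_rate

    # non-specific gold auto-nucleation specks (false-positive bait)
    w = cfg.speck_size_px
    for _ in range(cfg.n_gold_specks):
        r = int(rng.integers(1, shape[0] - w))
        c = int(rng.integers(1, shape[1] - w))
        for au in (SpeciesLabel.AU197_1, SpeciesLabel.AU197_2):
            base[au][r : r + w, c : c + w] += cfg.speck_rate

    for k in base:
        base[k] = base[k] * atten
    cn_base = cn_base * atten
    cell_cn_scale = atten  # per-pixel attenuation applied to cell CN too

    species_table = {sp.label: sp for sp in default_species_table()}
    planes: dict[SpeciesLabel, np.ndarray] = {
        lab: np.zeros((cfg.n_cycles,) + shape, dtype=np.uint32)
        for lab in list(base) + [SpeciesLabel.C12N14, SpeciesLabel.C15N]
    }
    expected_totals: dict[str, float] = {lab.value: 0.0 for lab in planes}

    order = sorted(planes, key=lambda l: l.value)
    for k in range(cfg.n_cycles):
        off1 = tuple(drift[k])
        off2 = (drift[k][0] + cfg.half_cycle_offset[0],
                drift[k][1] + cfg.half_cycle_offset[1])
        # CN split for this cycle
        rate15 = cn_base * _NAT_F
        rate14 = cn_base * (1.0 - _NAT_F)
        for cell in cells:
            f = _NAT_F if (k + 1) < cell.n15_onset_cycle else cell.true_atpct / 100.0
            rr, cc = cell.pixels[:, 0], cell.pixels[:, 1]
            add = cfg.cell_cn_rate * cell_cn_scale[rr, cc]
            rate15[rr, cc] += f * add
            rate14[rr, cc] += (1.0 - f) * add
            cell.expected_n15[k] = float(rate15[rr, cc].sum())
            cell.expected_n14[k] = float(rate14[rr, cc].sum())
        cycle_rates = dict(base)
        cycle_rates[SpeciesLabel.C12N14] = rate14
        cycle_rates[SpeciesLabel.C15N] = rate15
        for lab in order:
            sp = species_table[lab]
            off = off1 if sp.half_cycle in (1, BOTH_HALF_CYCLES) else off2
            rate, _ = shift_plane(cycle_rates[lab], off)
            planes[lab][k] = rng.poisson(rate).astype(np.uint32)
            expected_totals[lab.value] += float(rate.sum())

    stacks = {
        lab: IonImageStack(species_table[lab], planes[lab],
                           dwell_time=cfg.dwell_time,
                           raster_extent=cfg.raster_extent)
        for lab in planes
    }
    session = AcquisitionSession(
        stacks=stacks,
        metadata={"scenario_seed": cfg.seed, "simulated": True,
                  "analysis_area": "SIM"},
    )
    truth = SimulationTruth(
        cells=cells,
        drift_schedule=drift,
        half_cycle_offset=tuple(cfg.half_cycle_offset),
        excluded_region_mask=trench_mask,
        seed=cfg.seed,
        expected_totals=expected_totals,
    )
    return session, truth


def distort_counts(
    session: AcquisitionSession,
    dead_time: float,
    qsa_k: dict[str, float] | None = None,
) -> AcquisitionSession:
    """Apply the exact inverse of the QSA and dead-time corrections.

    Treats the session's counts as true rates and produces the count field a
    detector with the given dead time / QSA parameters would report, so that
    ``correct_dead_time`` then ``correct_qsa`` recover the originals.  The
    output is real-valued (no re-discretization; this is a test harness for
    the correction chain, not a noise model).
    """
    qsa_k = qsa_k or {}
    out = session.copy()
    for label, stack in out.stacks.items():
        if label is SpeciesLabel.SE:
            continue
        true = stack.planes.astype(float)
        beta = stack.species.detector_beta
        k = qsa_k.get(label.value, 0.0)
        if beta is not None and k > 0:
            true = true / (1.0 + beta * k)  # inverse of n' = n(1+βK)
        if dead_time > 0:
            T = stack.dwell_time
            # inverse of n' = n/(1 − (n/T)τ): observed = t/(1 + tτ/T)
            true = true / (1.0 + true * dead_time / T)
        out.stacks[label] = IonImageStack(
            stack.species, true, stack.dwell_time, stack.raster_extent
        )
    return out


def simulate_single_cells(
    n_cells: int,
    atpct: float,
    cn_total: float,
    rng: np.random.Generator,
    atpct_sd: float = 0.0,
) -> np.ndarray:
    """Measured at% of single cells from pure culture, at the count level.

    Each cell's true fraction is ``atpct`` (optionally jittered by a normal
    biological spread ``atpct_sd``); its ¹⁵N and ¹⁴N totals are independent
    Poisson draws at that split of ``cn_total`` expected CN counts.  Returns
    the per-cell measured at% values.
    """
    f_true = np.clip(
        (np.full(n_cells, atpct)
         + (rng.normal(0.0, atpct_sd, n_cells) if atpct_sd > 0 else 0.0))
        / 100.0,
        0.0, 1.0,
    )
    n15 = rng.poisson(f_true * cn_total)
    n14 = rng.poisson((1.0 - f_true) * cn_total)
    total = n15 + n14
    total = np.where(total == 0, 1, total)
    return 100.0 * n15 / total
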