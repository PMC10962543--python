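"""Detector corrections and image alignment.

Preprocessing mirrors the standard NanoSIMS evaluation chain, in this fixed
order: detector dead-time correction, QSA (quasi-simultaneous arrival)
correction, per-cycle drift auto-tracking, then inter-half-cycle alignment.

Dead time: after each registered ion the electron-multiplier detector is
blind for τ seconds, undercounting at high rates.  With per-pixel dwell time
T and observed counts n, the corrected count is the non-paralyzable form

    n' = n / (1 − (n/T)·τ)

QSA: multiple secondary ions sputtered by one primary ion can arrive within
a single detection event.  The correction used here is the linear form
n' = n·(1 + β·K), with β the species' sensitivity factor and K the
secondary-to-primary ion ratio.  K defaults to 0 (no-op) unless supplied in
the configuration, because K depends on instrument conditions not carried in
the archives.

Alignment is integer-pixel only: sub-pixel resampling would break Poisson
count semantics downstream.  Shifting never alters count values — pixels
moved out of frame are marked invalid and excluded from all later sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .model import (
    BOTH_HALF_CYCLES,
    AcquisitionSession,
    DriftTrace,
    IonImageStack,
    SpeciesLabel,
)

__all__ = [
    "CorrectionConfig",
    "DriftTrace",
    "correct_dead_time",
    "correct_qsa",
    "correct_session",
    "autotrack",
    "align_half_cycles",
    "preprocess",
]


class SaturationError(ValueError):
    """Count rate at or beyond the dead-time saturation limit (rate·τ ≥ 1)."""


class CorrectionConfig(BaseModel):
    """Configuration of the correction and alignment stages.

    dead_time
        Detector dead time τ in seconds.  Default 44 ns, conventional for
        the electron multipliers of this detector family; configurable.
    qsa_k
        Per-species secondary/primary ion ratio K used by the linear QSA
        correction; species not listed use 0 (correction is then a no-op).
    drift_reference_species
        Species tracked for per-cycle drift; its half-cycle-2 counterpart
        tracks half-cycle 2.  Default the ¹⁹⁷Au⁻(1) signal.
    reference_cycle
        "first" registers every cycle onto cycle 1; "sum" onto the running
        accumulated image (for low-signal data).
    """

    dead_time: float = Field(default=44e-9, ge=0.0)
    qsa_enabled: bool = True
    qsa_k: dict[str, float] = Field(default_factory=dict)
    drift_reference_species: str = "AU197_1"
    drift_search_radius: int = Field(default=10, ge=1)
    reference_cycle: str = "first"
    manual_half_cycle_offset: tuple[int, int] | None = None

    @field_validator("qsa_k")
    @classmethod
    def _k_nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for label, k in v.items():
            if k < 0:
                raise ValueError(f"QSA K for {label} must be >= 0, got {k}")
        return v


def correct_dead_time(
    counts: np.ndarray, dwell_time: float, dead_time: float
) -> np.ndarray:
    """Apply the non-paralyzable dead-time correction per pixel.

    Monotone non-decreasing and convex in the observed counts; identity for
    τ = 0.  Raises :class:`SaturationError` naming the worst pixel when any
    count rate reaches 1/τ.
    """
    counts = np.asarray(counts, dtype=float)
    if dwell_time <= 0:
        raise ValueError("dwell_time must be positive")
    if dead_time < 0:
        raise ValueError("dead_time must be non-negative")
    if dead_time == 0:
        return counts.copy()
    loss = counts / dwell_time * dead_time
    if np.any(loss >= 1.0):
        idx = np.unravel_index(int(np.argmax(loss)), counts.shape)
        rate = counts[idx] / dwell_time
        raise SaturationError(
            f"count rate {rate:.3e} s⁻¹ at pixel {idx} saturates dead time "
            f"τ={dead_time:.3e} s (rate·τ ≥ 1)"
        )
    return counts / (1.0 - loss)


def correct_qsa(
    counts: np.ndarray, beta: float | None, K: float | np.ndarray
) -> np.ndarray:
    """Linear QSA correction n' = n·(1 + β·K); pass-through when β is absent."""
    counts = np.asarray(counts, dtype=float)
    if beta is None:
        return counts.copy()
    if beta < 1.0:
        raise ValueError(f"beta must be >= 1, got {beta}")
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("QSA K must be non-negative")
    return counts * (1.0 + beta * K)


def correct_session(
    session: AcquisitionSession, config: CorrectionConfig | None = None
) -> AcquisitionSession:
    """Dead-time- then QSA-correct every ion stack of a session.

    The SE stack is an electron image, not an ion count, and passes through.
    """
    config = config or CorrectionConfig()
    out = session.copy()
    for label, stack in out.stacks.items():
        if label is SpeciesLabel.SE:
            continue
        planes = correct_dead_time(stack.planes, stack.dwell_time, config.dead_time)
        if config.qsa_enabled:
            K = config.qsa_k.get(label.value, 0.0)
            planes = correct_qsa(planes, stack.species.detector_beta, K)
        out.stacks[label] = IonImageStack(
            stack.species, planes, stack.dwell_time, stack.raster_extent
        )
    out.metadata.setdefault("processing", []).append(
        {"stage": "corrections", "dead_time_s": config.dead_time,
         "qsa_enabled": config.qsa_enabled, "qsa_k": dict(config.qsa_k)}
    )
    return out


# ---------------------------------------------------------------------------
# alignment


def shift_plane(plane: np.ndarray, offset: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Shift a raster by an integer (row, col) offset with zero fill.

    Returns the shifted plane and a validity raster that is False where the
    output pixel has no source inside the frame.  Count values are never
    altered, only repositioned.
    """
    dy, dx = int(offset[0]), int(offset[1])
    out = np.zeros_like(plane)
    valid = np.zeros(plane.shape, dtype=bool)
    h, w = plane.shape
    src_r = slice(max(0, -dy), min(h, h - dy))
    dst_r = slice(max(0, dy), min(h, h + dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_c = slice(max(0, dx), min(w, w + dx))
    if src_r.start < src_r.stop and src_c.start < src_c.stop:
        out[dst_r, dst_c] = plane[src_r, src_c]
        valid[dst_r, dst_c] = True
    return out, valid


def estimate_shift(
    reference: np.ndarray, image: np.ndarray, radius: int
) -> tuple[tuple[int, int], bool]:
    """Integer shift of ``image`` relative to ``reference`` by cross-correlation.

    Maximizes the circular cross-correlation of the mean-subtracted images
    over shifts within ±radius; ties break toward the smallest displacement
    (then row, then col) so results are deterministic.  Returns the shift and
    whether the unconstrained peak lay outside the search window (clipped).
    """
    a = reference.astype(float) - reference.mean()
    b = image.astype(float) - image.mean()
    corr = np.real(np.fft.ifft2(np.conj(np.fft.fft2(a)) * np.fft.fft2(b)))
    h, w = corr.shape
    # global (unconstrained) peak, for the clipped flag
    gi = np.unravel_index(int(np.argmax(corr)), corr.shape)
    g = (gi[0] - h if gi[0] > h // 2 else gi[0], gi[1] - w if gi[1] > w // 2 else gi[1])
    best, best_val = (0, 0), -np.inf
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            val = corr[dy % h, dx % w]
            key = (val, -(abs(dy) + abs(dx)), -dy, -dx)
            if key > (best_val, -(abs(best[0]) + abs(best[1])), -best[0], -best[1]):
                best, best_val = (dy, dx), val
    clipped = max(abs(g[0]), abs(g[1])) > radius and g != best
    return best, clipped


def _counterpart_reference(label: str) -> dict[int, SpeciesLabel]:
    """Map half-cycle → tracking species for a configured reference signal."""
    ref = SpeciesLabel(label)
    pair = {SpeciesLabel.AU197_1: SpeciesLabel.AU197_2,
            SpeciesLabel.AU197_2: SpeciesLabel.AU197_1}
    if ref in pair:
        one, two = (ref, pair[ref]) if ref is SpeciesLabel.AU197_1 else (pair[ref], ref)
        return {1: one, 2: two}
    # non-Au reference: track only its own half-cycle, reuse for the other
    half = 1 if ref in (SpeciesLabel.C12, SpeciesLabel.C12N14) else 2
    return {1: ref if half == 1 else ref, 2: ref}


def autotrack(
    session: AcquisitionSession, config: CorrectionConfig | None = None
) -> tuple[AcquisitionSession, DriftTrace]:
    """Compensate primary-beam / stage drift cycle by cycle.

    Each half-cycle is tracked on its ¹⁹⁷Au⁻ signal: the integer offset
    maximizing the cross-correlation of each cycle's reference plane against
    cycle 1 (or the running sum) is estimated, and all of that half-cycle's
    planes are shifted by its negation.  Out-of-frame pixels become invalid.
    """
    config = config or CorrectionConfig()
    refs = _counterpart_reference(config.drift_reference_species)
    out = session.copy()
    n = out.n_cycles
    trace = DriftTrace.identity(n)

    for half in (1, 2):
        ref_label = refs[half]
        if ref_label not in out.stacks:
            continue
        ref_stack = out.stacks[ref_label].planes
        totals = ref_stack.reshape(n, -1).sum(axis=1)
        zero = np.nonzero(totals == 0)[0]
        if zero.size:
            raise ValueError(
                f"drift reference {ref_label.value} has zero total counts in "
                f"cycle {int(zero[0]) + 1}"
            )
        reference = ref_stack[0].astype(float)
        offsets = np.zeros((n, 2), dtype=int)
        for k in range(1, n):
            off, clipped = estimate_shift(reference, ref_stack[k], config.drift_search_radius)
            offsets[k] = off
            if clipped and (k + 1) not in trace.clipped:
                trace.clipped.append(k + 1)
            if config.reference_cycle == "sum":
                shifted, _ = shift_plane(ref_stack[k], (-off[0], -off[1]))
                reference = reference + shifted
        if half == 1:
            trace.half1 = offsets
        else:
            trace.half2 = offsets
        _apply_cycle_shifts(out, half, offsets)

    out.alignment = trace
    out.metadata.setdefault("processing", []).append({"stage": "autotrack"})
    return out, trace


def _apply_cycle_shifts(session: AcquisitionSession, half: int, offsets: np.ndarray) -> None:
    """Shift every plane of ``half`` by minus its cycle offset, in place."""
    labels = [
        lab for lab, st in session.stacks.items()
        if st.species.half_cycle == half
        or (st.species.half_cycle == BOTH_HALF_CYCLES and half == 1)
    ]
    validity = session.validity[half]
    for k in range(offsets.shape[0]):
        dy, dx = offsets[k]
        if dy == 0 and dx == 0:
            continue
        valid_k = None
        for lab in labels:
            planes = session.stacks[lab].planes
            planes[k], valid_k = shift_plane(planes[k], (-dy, -dx))
        if valid_k is not None:
            validity[k] &= valid_k


def align_half_cycles(
    session: AcquisitionSession, config: CorrectionConfig | None = None
) -> tuple[AcquisitionSession, tuple[int, int]]:
    """Register half-cycle 2 onto half-cycle 1 using the two ¹⁹⁷Au⁻ images.

    A single integer offset maximizing the cross-correlation between the
    accumulated ¹⁹⁷Au⁻(1) and ¹⁹⁷Au⁻(2) images is applied to every
    half-cycle-2 plane.  ``config.manual_half_cycle_offset`` overrides the
    estimate (the manual-alignment path) and is recorded as such.
    """
    config = config or CorrectionConfig()
    out = session.copy()
    if config.manual_half_cycle_offset is not None:
        off = tuple(int(v) for v in config.manual_half_cycle_offset)
        manual = True
    else:
        for lab in (SpeciesLabel.AU197_1, SpeciesLabel.AU197_2):
            if lab not in out.stacks:
                raise ValueError(f"half-cycle alignment needs both Au stacks; {lab.value} missing")
        acc1 = out.stacks[SpeciesLabel.AU197_1].planes.sum(axis=0)
        acc2 = out.stacks[SpeciesLabel.AU197_2].planes.sum(axis=0)
        off, _ = estimate_shift(acc1, acc2, config.drift_search_radius)
        manual = False

    n = out.n_cycles
    offsets = np.tile(np.asarray(off, dtype=int), (n, 1))
    _apply_cycle_shifts(out, 2, offsets)

    trace = out.alignment or DriftTrace.identity(n)
    trace.inter_half_cycle = (int(off[0]), int(off[1]))
    trace.manual_inter_half_cycle = manual
    out.alignment = trace
    out.metadata.setdefault("processing", []).append(
        {"stage": "align_half_cycles", "offset": list(off), "manual": manual}
    )
    return out, (int(off[0]), int(off[1]))


def preprocess(
    session: AcquisitionSession, config: CorrectionConfig | None = None
) -> tuple[AcquisitionSession, DriftTrace]:
    """Full correction chain: dead-time → QSA → auto-tracking → half-cycle
    alignment.  Returns the corrected, aligned session and its drift trace."""
    config = config or CorrectionConfig()
    out = correct_session(session, config)
    out, trace = autotrack(out, config)
    out, _ = align_half_cycles(out, config)
    return out, out.alignment
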