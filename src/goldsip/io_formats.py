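"""Reading and writing acquisition archives, ROI tables and control tables.

A session archive is a directory (or ``.zip`` of the same layout) holding one
multi-page TIFF per ion species — one page per acquisition cycle — plus a
``session.json`` sidecar with the semantics: species table, dwell time,
raster extent, cycle count and alignment state.  Keeping semantics in JSON
rather than TIFF tags leaves the rasters viewable in any image tool.

Tables are plain CSV (comma-separated, UTF-8, ``.`` decimal): ROI results
with full-precision value columns plus rounded 2-decimal display columns,
and unlabeled-control single-cell at% ¹⁵N tables.
"""

from __future__ import annotations

import json
import tempfile
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .model import (
    AcquisitionSession,
    DriftTrace,
    EnrichmentResult,
    IonImageStack,
    IonSpecies,
    SpeciesLabel,
)

SIDECAR_NAME = "session.json"

ROI_TABLE_COLUMNS = [
    "roi_id",
    "analysis_area",
    "category",
    "area_px",
    "atpct_raw",
    "sigma_poisson",
    "enriched",
    "atpct_corrected",
    "first",
    "last",
    "atpct_raw_display",
    "atpct_corrected_display",
]


class SessionFormatError(ValueError):
    """Raised when an archive violates the session layout contract."""


def _raster_name(label: SpeciesLabel) -> str:
    return f"{label.value}.tif"


def write_session(session: AcquisitionSession, path: str | Path) -> Path:
    """Write ``session`` as a TIFF-per-species archive under ``path``.

    Integer stacks are stored as the narrowest unsigned width that holds
    their maximum (16- or 32-bit); corrected real-valued stacks as float32.
    The byte layout is deterministic for fixed inputs.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    species_meta = {}
    for label, stack in sorted(session.stacks.items(), key=lambda kv: kv[0].value):
        planes = stack.planes
        if np.issubdtype(planes.dtype, np.integer):
            dtype = np.uint16 if planes.max(initial=0) < 2**16 else np.uint32
        else:
            dtype = np.float32
        tifffile.imwrite(path / _raster_name(label), planes.astype(dtype),
                         photometric="minisblack")
        species_meta[label.value] = {
            "half_cycle": stack.species.half_cycle,
            "detector_beta": stack.species.detector_beta,
            "dwell_time_s": stack.dwell_time,
            "raster_extent_um": stack.raster_extent,
            "dtype": np.dtype(dtype).name,
        }
    alignment = None
    if session.alignment is not None:
        tr = session.alignment
        alignment = {
            "half1": tr.half1.tolist(),
            "half2": tr.half2.tolist(),
            "inter_half_cycle": list(tr.inter_half_cycle),
            "clipped": list(tr.clipped),
            "manual_inter_half_cycle": tr.manual_inter_half_cycle,
        }
    sidecar = {
        "n_cycles": session.n_cycles,
        "pixel_shape": list(session.pixel_shape),
        "species": species_meta,
        "alignment": alignment,
        "metadata": session.metadata,
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def _resolve_archive(path: Path) -> Path:
    if path.is_file() and path.suffix == ".zip":
        tmp = Path(tempfile.mkdtemp(prefix="goldsip_session_"))
        with zipfile.ZipFile(path) as zf:
            zf.extractall(tmp)
        # archives may nest the layout in a single top-level directory
        if not (tmp / SIDECAR_NAME).exists():
            subdirs = [p for p in tmp.iterdir() if p.is_dir()]
            if len(subdirs) == 1 and (subdirs[0] / SIDECAR_NAME).exists():
                return subdirs[0]
        return tmp
    return path


def read_session(path: str | Path) -> AcquisitionSession:
    """Load a session archive written by :func:`write_session`.

    Raises :class:`SessionFormatError` naming the species when a declared
    raster is missing, or reporting both counts on a page/cycle mismatch.
    A missing optional SE raster yields ``metadata['no_se_available'] = True``.
    """
    path = _resolve_archive(Path(path))
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise SessionFormatError(f"no {SIDECAR_NAME} sidecar under {path}")
    sidecar = json.loads(sidecar_path.read_text())
    n_cycles = int(sidecar["n_cycles"])

    stacks: dict[SpeciesLabel, IonImageStack] = {}
    metadata = dict(sidecar.get("metadata", {}))
    for name, meta in sidecar["species"].items():
        label = SpeciesLabel(name)
        raster = path / _raster_name(label)
        if not raster.exists():
            if label is SpeciesLabel.SE:
                metadata["no_se_available"] = True
                continue
            raise SessionFormatError(f"missing raster for declared species {name}")
        planes = tifffile.imread(raster)
        if planes.ndim == 2:  # single-page stacks load as 2-D
            planes = planes[None]
        if planes.shape[0] != n_cycles:
            raise SessionFormatError(
                f"species {name}: {planes.shape[0]} pages but sidecar declares "
                f"{n_cycles} cycles"
            )
        species = IonSpecies(label, int(meta["half_cycle"]), meta["detector_beta"])
        stacks[label] = IonImageStack(
            species,
            planes,
            dwell_time=float(meta["dwell_time_s"]),
            raster_extent=float(meta["raster_extent_um"]),
        )

    alignment = None
    if sidecar.get("alignment"):
        a = sidecar["alignment"]
        alignment = DriftTrace(
            half1=np.asarray(a["half1"], dtype=int),
            half2=np.asarray(a["half2"], dtype=int),
            inter_half_cycle=tuple(a["inter_half_cycle"]),
            clipped=list(a["clipped"]),
            manual_inter_half_cycle=bool(a.get("manual_inter_half_cycle", False)),
        )
    return AcquisitionSession(stacks=stacks, metadata=metadata, alignment=alignment)


def write_roi_table(results: list[EnrichmentResult], path: str | Path) -> Path:
    """Write per-ROI enrichment results as CSV (full precision + 2-dp display)."""
    path = Path(path)
    rows = []
    for r in results:
        rows.append(
            {
                "roi_id": r.roi_id,
                "analysis_area": r.analysis_area,
                "category": r.category.value if r.category else "",
                "area_px": r.area_px if r.area_px is not None else "",
                "atpct_raw": repr(float(r.atpct_raw)),
                "sigma_poisson": repr(float(r.sigma_poisson)),
                "enriched": r.enriched,
                "atpct_corrected": (
                    repr(float(r.atpct_corrected)) if r.atpct_corrected is not None else ""
                ),
                "first": r.cycle_range[0],
                "last": r.cycle_range[1],
                "atpct_raw_display": _display(r.atpct_raw),
                "atpct_corrected_display": (
                    _display(r.atpct_corrected) if r.atpct_corrected is not None else ""
                ),
            }
        )
    df = pd.DataFrame(rows, columns=ROI_TABLE_COLUMNS)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _display(value: float) -> str:
    """Half-even rounding to 2 decimals, as used in all display columns."""
    return format(float(np.round(value, 2)), ".2f")


def read_roi_table(path: str | Path) -> pd.DataFrame:
    """Read a ROI table back; full-precision columns parse to exact floats."""
    df = pd.read_csv(path)
    missing = set(ROI_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SessionFormatError(f"ROI table missing columns: {sorted(missing)}")
    return df


def read_control_table(path: str | Path) -> list[float]:
    """Read an unlabeled-control table (columns ``cell_id, atpct``) to a list.

    Non-numeric at% entries raise a parse error citing the offending row
    (1-based data row number, excluding the header).
    """
    df = pd.read_csv(path, dtype={"atpct": str}, keep_default_na=False)
    if "atpct" not in df.columns:
        raise SessionFormatError("control table must have an 'atpct' column")
    values = []
    for i, raw in enumerate(df["atpct"], start=1):
        try:
            values.append(float(raw))
        except (TypeError, ValueError):
            raise SessionFormatError(
                f"control table row {i}: non-numeric atpct value {raw!r}"
            ) from None
    return values


def write_control_table(values: list[float], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"cell_id": [f"cell_{i:04d}" for i in range(1, len(values) + 1)],
         "atpct": [repr(float(v)) for v in values]}
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
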