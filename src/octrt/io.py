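"""Reading and writing OCT volumes, boundary tables, and overlay images.

Volumes come in as multi-page TIFFs or directories of equally sized
grayscale frames (lexicographic order), with physical pixel spacing supplied
by a JSON sidecar (``axial_um_per_px``, ``lateral_um_per_px``,
``bscan_spacing_um``).  Embedded TIFF resolution tags are used only as a
fallback for the in-plane spacings; explicit metadata beats inferred
calibration.  Results go out as plain CSV/JSON plus optional per-B-scan
overlay PNGs with the detected boundary curves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .segmentation import BoundaryTrace, FormatError

__all__ = [
    "OCTVolume",
    "ConfigurationError",
    "load_volume",
    "write_volume",
    "write_results",
]

SIDECAR_KEYS = ("axial_um_per_px", "lateral_um_per_px", "bscan_spacing_um")

#: fixed decimal precision for all tabular output (round-trip stable as text)
CSV_FLOAT_FORMAT = "%.4f"


class ConfigurationError(ValueError):
    """Spacing or run metadata is missing or contradictory."""


@dataclass
class OCTVolume:
    """A stack of B-scans with physical spacing metadata.

    ``frames`` has shape (n_bscans, n_depth, n_ascans); intensities are
    finite, non-negative floats in arbitrary linear units.  Spacings are in
    um per pixel (``bscan_spacing`` um between consecutive B-scans).
    """

    frames: np.ndarray
    axial_spacing: float
    lateral_spacing: float
    bscan_spacing: float
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise FormatError("frames must form a non-empty 3D stack")
        if not np.isfinite(self.frames).all():
            raise FormatError("intensities must be finite")
        if self.frames.min() < 0:
            raise FormatError("intensities must be non-negative")
        if self.axial_spacing <= 0 or self.lateral_spacing <= 0:
            raise ConfigurationError("axial and lateral spacings must be > 0")
        if self.bscan_spacing < 0:
            raise ConfigurationError("bscan_spacing must be >= 0")

    @property
    def n_bscans(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# loading


def _to_grayscale(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        frame = frame[..., :3].mean(axis=-1)
    if frame.ndim != 2:
        raise FormatError(f"expected 2D grayscale frames, got shape {frame.shape}")
    return frame.astype(np.float64)


def _read_stack(path: Path) -> np.ndarray:
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff", ".bmp")
        )
        if not files:
            raise FormatError(f"no image frames found in {path}")
        frames = [_to_grayscale(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise FormatError(f"frames have mixed sizes: {sorted(shapes)}")
        return np.stack(frames)

    import tifffile

    data = np.asarray(tifffile.imread(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4 and data.shape[-1] in (3, 4):
        data = data[..., :3].mean(axis=-1)
    if data.ndim != 3 or data.shape[0] == 0:
        raise FormatError(f"cannot interpret {path} as a stack of 2D frames")
    return data.astype(np.float64)


def _tiff_resolution_fallback(path: Path) -> Dict[str, float]:
    """In-plane spacings (um/px) from TIFF resolution tags, where present."""
    import tifffile

    unit_to_um = {2: 25400.0, 3: 10000.0}  # inch, cm
    out: Dict[str, float] = {}
    try:
        with tifffile.TiffFile(path) as tf:
            tags = tf.pages[0].tags
            unit = tags.get("ResolutionUnit")
            scale = unit_to_um.get(getattr(unit, "value", None) and int(unit.value))
            if scale is None:
                return out
            for tag_name, key in (("YResolution", "axial_um_per_px"),
                                  ("XResolution", "lateral_um_per_px")):
                tag = tags.get(tag_name)
                if tag is not None:
                    num, den = tag.value
                    if num:
                        out[key] = scale * den / num
    except Exception:
        return {}
    return out


def load_volume(
    path: Union[str, Path],
    sidecar: Optional[Union[str, Path]] = None,
) -> OCTVolume:
    """Read a volume from a multi-page TIFF or a directory of frames.

    Spacing metadata is taken from the JSON ``sidecar`` (default: a ``.json``
    file next to the stack, or ``metadata.json`` inside a frame directory);
    TIFF resolution tags serve only as a fallback for in-plane spacings.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such input: {path}")
    frames = _read_stack(path)

    if sidecar is None:
        candidate = path / "metadata.json" if path.is_dir() else path.with_suffix(".json")
        sidecar = candidate if candidate.exists() else None
    metadata: Dict[str, float] = {}
    if sidecar is not None:
        sidecar = Path(sidecar)
        if not sidecar.exists():
            raise ConfigurationError(f"sidecar not found: {sidecar}")
        try:
            metadata = json.loads(sidecar.read_text())
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"sidecar {sidecar} is not valid JSON: {exc}") from exc
    if not path.is_dir():
        fallback = _tiff_resolution_fallback(path)
        for key, value in fallback.items():
            metadata.setdefault(key, value)
    if frames.shape[0] == 1:
        metadata.setdefault("bscan_spacing_um", 0.0)

    missing = [k for k in SIDECAR_KEYS if k not in metadata]
    if missing:
        raise ConfigurationError(
            f"missing spacing metadata {missing}; provide a JSON sidecar with keys {SIDECAR_KEYS}"
        )
    values = {}
    for key in SIDECAR_KEYS:
        try:
            values[key] = float(metadata[key])
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"sidecar key {key} is not numeric") from exc
        if not math.isfinite(values[key]):
            raise ConfigurationError(f"sidecar key {key} is not finite")

    meta = {k: v for k, v in metadata.items() if k not in SIDECAR_KEYS}
    meta["source"] = str(path)
    return OCTVolume(
        frames=frames,
        axial_spacing=values["axial_um_per_px"],
        lateral_spacing=values["lateral_um_per_px"],
        bscan_spacing=values["bscan_spacing_um"],
        meta=meta,
    )


def write_volume(volume: OCTVolume, path: Union[str, Path]) -> Path:
    """Write a volume as a float32 multi-page TIFF with a JSON sidecar."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.frames.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "axial_um_per_px": volume.axial_spacing,
                "lateral_um_per_px": volume.lateral_spacing,
                "bscan_spacing_um": volume.bscan_spacing,
            },
            indent=2,
        )
    )
    return path


# ---------------------------------------------------------------------------
# results


def _boundaries_frame(traces: Sequence[BoundaryTrace]) -> pd.DataFrame:
    rows = []
    for b, tr in enumerate(traces):
        rows.append(
            pd.DataFrame(
                {
                    "bscan": b,
                    "ascan": np.arange(tr.n_ascans),
                    "sclera_um": tr.sclera_um,
                    "orl_um": tr.orl_um,
                    "irl_um": tr.irl_um,
                    "thickness_um": tr.thickness_um,
                    "valid": tr.valid,
                    "reason": tr.reason,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _overlay_png(frame: np.ndarray, trace: BoundaryTrace, axial_spacing: float, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    ax.imshow(frame, cmap="gray", aspect="auto", interpolation="nearest")
    x = np.arange(trace.n_ascans)
    for depths, color, label in (
        (trace.irl_um, "tab:purple", "IRL"),
        (trace.orl_um, "tab:red", "ORL"),
        (trace.sclera_um, "gold", "sclera"),
    ):
        ax.plot(x, depths / axial_spacing, color=color, lw=1.0, label=label)
    ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel("A-scan")
    ax.set_ylabel("depth (px)")
    fig.savefig(out, dpi=100)
    plt.close(fig)


def write_results(
    traces: Sequence[BoundaryTrace],
    summaries: Sequence,
    volume_summary,
    outdir: Union[str, Path],
    volume: Optional[OCTVolume] = None,
    overlays: bool = True,
) -> Dict[str, List[Path]]:
    """Write boundary CSV, B-scan summary CSV, volume JSON, optional overlays.

    ``summaries`` is the full list of per-B-scan summaries (retained flags
    set) and ``volume_summary`` the corresponding volume-level aggregate.
    Overlays are drawn only when the source ``volume`` is supplied.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    written: Dict[str, List[Path]] = {"csv": [], "json": [], "png": []}

    boundaries = outdir / "boundaries.csv"
    _boundaries_frame(traces).to_csv(boundaries, index=False, float_format=CSV_FLOAT_FORMAT)
    written["csv"].append(boundaries)

    bscan_csv = outdir / "bscan_summary.csv"
    pd.DataFrame(
        [
            {
                "bscan": s.index,
                "mean_um": s.mean,
                "sd_um": s.sd,
                "n_valid": s.n_valid,
                "n_total": s.n_total,
                "pct_error": s.pct_error,
                "summarizable": s.summarizable,
                "retained": s.retained,
            }
            for s in summaries
        ]
    ).to_csv(bscan_csv, index=False, float_format=CSV_FLOAT_FORMAT)
    written["csv"].append(bscan_csv)

    summary_json = outdir / "volume_summary.json"
    summary_json.write_text(
        json.dumps(
            {
                "weighted_mean_um": volume_summary.weighted_mean,
                "se_um": volume_summary.se,
                "n_retained": volume_summary.n_retained,
                "retained_indices": list(volume_summary.retained_indices),
                "reason": volume_summary.reason,
            },
            indent=2,
        )
    )
    written["json"].append(summary_json)

    if overlays and volume is not None:
        for b, (frame, trace) in enumerate(zip(volume.frames, traces)):
            out = outdir / f"overlay_b{b:02d}.png"
            _overlay_png(frame, trace, volume.axial_spacing, out)
            written["png"].append(out)
    return written
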