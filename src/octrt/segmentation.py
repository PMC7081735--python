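"""Two-stage retinal boundary detection on SD-OCT B-scans.

The segmentation anchors on the sclera, which is the brightest structure in
a rodent B-scan: after coarse Gaussian smoothing the per-A-scan intensity
maximum marks the scleral center.  Boundaries are then read off the axial
intensity slope (first depth derivative of a lightly smoothed A-scan
profile): the outer retinal boundary (ORL) is the first slope valley above
the scleral center, and the inner retinal boundary (IRL) is the highest
slope peak more than ``min_irl_offset_um`` above the ORL.  Retinal thickness
is the axial distance between IRL and ORL.

All scales are specified in micrometres and converted to pixels through the
volume's spacing metadata, so the detector is resolution independent.
Depth index 0 is the vitreous side (top of the B-scan); depth increases
toward the sclera, and "above" means smaller depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationParams",
    "BoundaryTrace",
    "ParameterError",
    "FormatError",
    "smooth_coarse",
    "locate_sclera",
    "axial_slope",
    "detect_orl",
    "detect_irl",
    "segment_bscan",
    "segment_volume",
]


class ParameterError(ValueError):
    """A tuning parameter is outside its valid domain."""


class FormatError(ValueError):
    """Input data violate a structural precondition."""


#: validity flags attached to each A-scan
REASON_OK = "none"
REASON_NO_VALLEY = "no_valley"
REASON_NO_PEAK = "no_peak"
REASON_OUT_OF_FRAME = "out_of_frame"


@dataclass(frozen=True)
class SegmentationParams:
    """Algorithm constants, all in physical units.

    Parameters
    ----------
    sigma_coarse_um
        Gaussian smoothing scale used to localize the sclera (default 20 um).
    sigma_slope_um
        Axial Gaussian smoothing applied before differentiation (default 2 um).
    min_irl_offset_um
        Minimum ORL-to-IRL separation; slope peaks closer to the ORL than
        this are excluded from IRL candidacy (default 120 um).
    pct_error_threshold
        B-scans whose within-scan coefficient of variation (in percent)
        exceeds this are discarded from the volume average (default 25).
    min_valid_fraction
        Minimum fraction of successfully segmented A-scans for a B-scan to
        be summarizable at all (default 0.5).
    coarse_2d
        If True (default) the coarse smoothing acts on both image axes at
        the same physical sigma; if False it is axial only.
    """

    sigma_coarse_um: float = 20.0
    sigma_slope_um: float = 2.0
    min_irl_offset_um: float = 120.0
    pct_error_threshold: float = 25.0
    min_valid_fraction: float = 0.5
    coarse_2d: bool = True

    def __post_init__(self) -> None:
        if self.sigma_coarse_um <= 0:
            raise ParameterError("sigma_coarse_um must be > 0")
        if self.sigma_slope_um <= 0:
            raise ParameterError("sigma_slope_um must be > 0")
        if self.min_irl_offset_um <= 0:
            raise ParameterError("min_irl_offset_um must be > 0")
        if self.pct_error_threshold <= 0:
            raise ParameterError("pct_error_threshold must be > 0")
        if not (0 < self.min_valid_fraction <= 1):
            raise ParameterError("min_valid_fraction must be in (0, 1]")

    def with_overrides(self, **kwargs) -> "SegmentationParams":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


@dataclass
class BoundaryTrace:
    """Per-A-scan boundary depths (um from the top of the frame) for one B-scan.

    Invalid A-scans carry NaN depths/thickness and a failure reason.
    """

    sclera_um: np.ndarray
    orl_um: np.ndarray
    irl_um: np.ndarray
    thickness_um: np.ndarray
    valid: np.ndarray
    reason: np.ndarray  # str per A-scan

    @property
    def n_ascans(self) -> int:
        return self.sclera_um.size

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


# ---------------------------------------------------------------------------
# smoothing and slope


def smooth_coarse(
    bscan: np.ndarray,
    sigma_um: float,
    axial_spacing: float,
    lateral_spacing: float,
    two_dimensional: bool = True,
) -> np.ndarray:
    """Gaussian smoothing at physical scale ``sigma_um`` (reflective borders)."""
    if sigma_um <= 0:
        raise ParameterError("sigma_um must be > 0")
    if axial_spacing <= 0 or lateral_spacing <= 0:
        raise ParameterError("pixel spacings must be > 0")
    bscan = np.asarray(bscan, dtype=np.float64)
    if two_dimensional:
        sigma_px = (sigma_um / axial_spacing, sigma_um / lateral_spacing)
        return ndimage.gaussian_filter(bscan, sigma_px, mode="reflect")
    return ndimage.gaussian_filter1d(bscan, sigma_um / axial_spacing, axis=0, mode="reflect")


def locate_sclera(smoothed_bscan: np.ndarray, axial_spacing: float) -> np.ndarray:
    """Depth (um) of the per-column absolute intensity maximum.

    Ties resolve to the smallest depth (``argmax`` returns the first index).
    """
    idx = np.argmax(np.asarray(smoothed_bscan), axis=0)
    return idx.astype(np.float64) * axial_spacing


def axial_slope(bscan: np.ndarray, sigma_slope_um: float, axial_spacing: float) -> np.ndarray:
    """Axial intensity slope (intensity per um) after 1D axial smoothing.

    Central differences in the interior, one-sided at the borders; positive
    where intensity increases with depth.
    """
    if sigma_slope_um <= 0:
        raise ParameterError("sigma_slope_um must be > 0")
    bscan = np.asarray(bscan, dtype=np.float64)
    if bscan.shape[0] < 3:
        raise FormatError("need at least 3 depth samples to differentiate")
    smoothed = ndimage.gaussian_filter1d(
        bscan, sigma_slope_um / axial_spacing, axis=0, mode="reflect"
    )
    return np.gradient(smoothed, axial_spacing, axis=0)


# ---------------------------------------------------------------------------
# extrema bookkeeping

def _plateau_extrema(profile: np.ndarray):
    """Strict local minima/maxima of a 1D profile with plateau collapsing.

    Runs of equal values are compressed; an interior run strictly below
    (above) both neighbouring runs is a valley (peak) located at the run's
    midpoint index, which may be half-integral.

    Returns ``(min_idx, min_val, max_idx, max_val)`` as float arrays.
    """
    y = np.asarray(profile, dtype=np.float64)
    change = np.flatnonzero(np.diff(y) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [y.size - 1]))
    vals = y[starts]
    mid = (starts + ends) / 2.0
    if vals.size < 3:
        empty = np.empty(0)
        return empty, empty, empty, empty
    inner = vals[1:-1]
    is_min = (inner < vals[:-2]) & (inner < vals[2:])
    is_max = (inner > vals[:-2]) & (inner > vals[2:])
    return mid[1:-1][is_min], inner[is_min], mid[1:-1][is_max], inner[is_max]


# ---------------------------------------------------------------------------
# boundary rules


def detect_orl(
    slope_column: np.ndarray, sclera_depth: float, axial_spacing: float
) -> Optional[float]:
    """First slope valley above the scleral center, or None if absent.

    Scans from the scleral center toward decreasing depth and returns the
    depth (um) of the first strict local minimum of the slope profile.
    """
    slope_column = np.asarray(slope_column, dtype=np.float64)
    max_depth = (slope_column.size - 1) * axial_spacing
    if not (0 <= sclera_depth <= max_depth):
        raise ParameterError(
            f"sclera_depth {sclera_depth} um outside column extent [0, {max_depth}]"
        )
    min_idx, _, _, _ = _plateau_extrema(slope_column)
    depths = min_idx * axial_spacing
    above = depths[depths < sclera_depth]
    if above.size == 0:
        return None
    return float(above.max())


def detect_irl(
    slope_column: np.ndarray,
    orl_depth: float,
    min_irl_offset_um: float,
    axial_spacing: float,
) -> Optional[float]:
    """Highest slope peak more than ``min_irl_offset_um`` above the ORL.

    Among strict local maxima at depths d with ``orl_depth - d`` strictly
    greater than the offset, returns the depth of the largest-valued peak;
    equal amplitudes resolve to the candidate closest to the ORL.  None if
    no admissible peak exists.
    """
    if min_irl_offset_um <= 0:
        raise ParameterError("min_irl_offset_um must be > 0")
    slope_column = np.asarray(slope_column, dtype=np.float64)
    _, _, max_idx, max_val = _plateau_extrema(slope_column)
    depths = max_idx * axial_spacing
    admissible = (orl_depth - depths) > min_irl_offset_um
    if not admissible.any():
        return None
    depths = depths[admissible]
    vals = max_val[admissible]
    best = np.flatnonzero(vals == vals.max())
    return float(depths[best].max())


# ---------------------------------------------------------------------------
# per-B-scan driver


def segment_bscan(
    bscan: np.ndarray,
    params: SegmentationParams,
    axial_spacing: float,
    lateral_spacing: float,
) -> BoundaryTrace:
    """Run the full boundary detection on every A-scan of one B-scan.

    Per-A-scan failures never abort the B-scan; they are flagged with a
    reason and excluded from downstream statistics.
    """
    bscan = np.asarray(bscan, dtype=np.float64)
    if bscan.ndim != 2:
        raise FormatError("a B-scan must be a 2D array (depth x A-scans)")
    n_depth, n_ascans = bscan.shape

    coarse = smooth_coarse(
        bscan, params.sigma_coarse_um, axial_spacing, lateral_spacing,
        two_dimensional=params.coarse_2d,
    )
    sclera = locate_sclera(coarse, axial_spacing)
    slope = axial_slope(bscan, params.sigma_slope_um, axial_spacing)

    orl = np.full(n_ascans, np.nan)
    irl = np.full(n_ascans, np.nan)
    thickness = np.full(n_ascans, np.nan)
    valid = np.zeros(n_ascans, dtype=bool)
    reason = np.full(n_ascans, REASON_OK, dtype=object)

    for j in range(n_ascans):
        o = detect_orl(slope[:, j], sclera[j], axial_spacing)
        if o is None:
            # includes the suspicious case of a maximum at depth index 0,
            # which leaves no room for a retina above it
            reason[j] = REASON_NO_VALLEY
            continue
        orl[j] = o
        if o - params.min_irl_offset_um <= 0:
            # the admissible IRL region lies entirely above the frame
            reason[j] = REASON_OUT_OF_FRAME
            continue
        i = detect_irl(slope[:, j], o, params.min_irl_offset_um, axial_spacing)
        if i is None:
            reason[j] = REASON_NO_PEAK
            continue
        irl[j] = i
        thickness[j] = o - i
        valid[j] = True

    return BoundaryTrace(
        sclera_um=sclera, orl_um=orl, irl_um=irl,
        thickness_um=thickness, valid=valid, reason=reason,
    )


def segment_volume(volume, params: Optional[SegmentationParams] = None) -> list:
    """Segment every B-scan of an :class:`~octrt.io.OCTVolume`."""
    params = params or SegmentationParams()
    return [
        segment_bscan(frame, params, volume.axial_spacing, volume.lateral_spacing)
        for frame in volume.frames
    ]
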