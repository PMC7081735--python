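"""Synthetic rodent SD-OCT phantoms with exact ground-truth boundaries.

An A-scan is modelled as a piecewise-constant layer profile along depth z —
dark vitreous, brighter retina, darker choroid — with logistic transitions
at the inner (IRL) and outer (ORL) retinal boundaries, plus a narrow bright
Gaussian scleral band below the choroid (the brightest structure in the
frame, as in rodent B-scans).  The IRL and ORL depths vary smoothly across
the volume as low-order polynomial surfaces of lateral position and B-scan
index.  Ground truth is defined at the logistic transition midpoints, which
coincide with the axial-slope extrema the detector targets, so sub-pixel
accuracy statements are well defined.

Noise emulates a frame-averaged acquisition: each acquired frame carries
fully developed multiplicative speckle, gamma distributed with unit mean and
shape ``speckle_k``, and the stored B-scan is the mean of ``art_frames``
such frames (drawn exactly as a single gamma with shape
``speckle_k * art_frames``), optionally plus additive Gaussian read noise.
The default geometry follows a Spectralis-style rodent volume scan: 7
B-scans 240 um apart, 768 A-scans each, ART 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import OCTVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "SpecificationError",
    "generate_ascan",
    "generate_volume",
    "inject_distractor",
]


class SpecificationError(ValueError):
    """The phantom specification violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic OCT volume.

    Boundary surfaces are polynomials in normalized coordinates
    x, b in [-1, 1] (lateral position, B-scan index):
    ``depth(x, b) = sum_ij coeffs[i][j] * x**i * b**j`` (um from frame top).
    ``thickness_coeffs`` gives ORL depth as IRL depth plus a thickness
    surface, which keeps the retina positive-thickness by construction.
    The scleral band center tracks the ORL at ``choroid_gap_um`` below it.
    """

    # geometry
    n_bscans: int = 7
    n_ascans: int = 768
    n_depth: int = 496
    axial_um_per_px: float = 3.87
    lateral_um_per_px: float = 11.0
    bscan_spacing_um: float = 240.0
    # layer surfaces (um)
    irl_coeffs: Tuple[Tuple[float, ...], ...] = ((750.0, 5.0), (0.0, 0.0), (15.0, 0.0))
    thickness_coeffs: Tuple[Tuple[float, ...], ...] = ((220.0,),)
    choroid_gap_um: float = 50.0
    sclera_sigma_um: float = 12.0
    # intensity levels (arbitrary linear units); sclera must be brightest
    vitreous_level: float = 4.0
    retina_level: float = 60.0
    choroid_level: float = 25.0
    sclera_level: float = 150.0
    banding_amplitude: float = 0.0
    banding_period_um: float = 40.0
    transition_scale_um: float = 5.0
    # noise model
    speckle_k: Optional[float] = 50.0
    art_frames: int = 100
    read_noise: float = 0.0
    # distractors: (offset above ORL in um, slope-peak amplitude in intensity/um)
    distractors: Tuple[Tuple[float, float], ...] = ()
    seed: int = 0

    # -- derived geometry -------------------------------------------------

    def _poly(self, coeffs, x: np.ndarray, b: np.ndarray) -> np.ndarray:
        out = np.zeros(np.broadcast(x, b).shape)
        for i, row in enumerate(coeffs):
            for j, c in enumerate(row):
                if c:
                    out = out + c * x**i * b**j
        return out

    def _norm_coords(self):
        x = np.linspace(-1, 1, self.n_ascans) if self.n_ascans > 1 else np.zeros(1)
        b = np.linspace(-1, 1, self.n_bscans) if self.n_bscans > 1 else np.zeros(1)
        return x, b

    def irl_depth(self, x: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self._poly(self.irl_coeffs, x, b)

    def orl_depth(self, x: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self.irl_depth(x, b) + self._poly(self.thickness_coeffs, x, b)

    def sclera_center_depth(self, x: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self.orl_depth(x, b) + self.choroid_gap_um

    def validate(self) -> None:
        if self.n_bscans < 1 or self.n_ascans < 1 or self.n_depth < 3:
            raise SpecificationError("degenerate volume geometry")
        if min(self.axial_um_per_px, self.lateral_um_per_px) <= 0 or self.bscan_spacing_um < 0:
            raise SpecificationError("pixel spacings must be positive")
        if self.transition_scale_um <= 0 or self.sclera_sigma_um <= 0:
            raise SpecificationError("transition and band scales must be positive")
        others = (self.vitreous_level, self.retina_level, self.choroid_level)
        if not all(self.sclera_level > lvl for lvl in others):
            raise SpecificationError("sclera must be the brightest layer")
        if min(others) < 0:
            raise SpecificationError("intensity levels must be non-negative")
        x, b = self._norm_coords()
        xg, bg = np.meshgrid(x, b)
        irl, orl, sc = self.irl_depth(xg, bg), self.orl_depth(xg, bg), self.sclera_center_depth(xg, bg)
        if not np.all(irl + 120.0 < orl):
            raise SpecificationError("need irl + 120 um < orl everywhere")
        if not np.all(orl < sc):
            raise SpecificationError("need orl < sclera center everywhere")
        frame_um = (self.n_depth - 1) * self.axial_um_per_px
        if not (np.all(irl > 0) and np.all(sc + 3 * self.sclera_sigma_um < frame_um)):
            raise SpecificationError("layer depths must lie inside the frame")
        for offset, _amp in self.distractors:
            edge = orl - offset
            if not np.all((edge > irl) & (edge < orl)):
                raise SpecificationError(
                    f"distractor offset {offset} um places the edge outside the retina"
                )
        if self.speckle_k is not None and self.speckle_k <= 0:
            raise SpecificationError("speckle_k must be positive or None")
        if self.art_frames < 1:
            raise SpecificationError("art_frames must be >= 1")

    # -- (de)serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        data = json.loads(text)
        for key in ("irl_coeffs", "thickness_coeffs"):
            if key in data:
                data[key] = tuple(tuple(row) for row in data[key])
        if "distractors" in data:
            data["distractors"] = tuple(tuple(d) for d in data["distractors"])
        return cls(**data)


@dataclass
class GroundTruth:
    """True boundary depths (um) per (B-scan, A-scan)."""

    irl_um: np.ndarray
    orl_um: np.ndarray
    sclera_um: np.ndarray

    @property
    def thickness_um(self) -> np.ndarray:
        return self.orl_um - self.irl_um

    def to_frame(self):
        import pandas as pd

        nb, na = self.irl_um.shape
        bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
        return pd.DataFrame(
            {
                "bscan": bb.ravel(),
                "ascan": aa.ravel(),
                "irl_um": self.irl_um.ravel(),
                "orl_um": self.orl_um.ravel(),
                "sclera_um": self.sclera_um.ravel(),
                "thickness_um": self.thickness_um.ravel(),
            }
        )


def _logistic(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(u, -60, 60)))


def _clean_profiles(spec: PhantomSpec, irl: np.ndarray, orl: np.ndarray) -> np.ndarray:
    """Noise-free intensity profiles for boundary surfaces of shape (...,).

    Returns an array of shape irl.shape + (n_depth,).
    """
    z = np.arange(spec.n_depth) * spec.axial_um_per_px
    irl = np.asarray(irl)[..., None]
    orl = np.asarray(orl)[..., None]
    s = spec.transition_scale_um
    sclera_c = orl + spec.choroid_gap_um

    profile = (
        spec.vitreous_level
        + (spec.retina_level - spec.vitreous_level) * _logistic((z - irl) / s)
        + (spec.choroid_level - spec.retina_level) * _logistic((z - orl) / s)
        + (spec.sclera_level - spec.choroid_level)
        * np.exp(-0.5 * ((z - sclera_c) / spec.sclera_sigma_um) ** 2)
    )
    if spec.banding_amplitude:
        inside = _logistic((z - irl) / s) * (1.0 - _logistic((z - orl) / s))
        profile = profile + (
            spec.banding_amplitude
            * inside
            * np.cos(2 * np.pi * (z - irl) / spec.banding_period_um)
        )
    for offset, slope_amp in spec.distractors:
        step = slope_amp * 4.0 * s  # logistic step height giving that slope peak
        profile = profile + step * _logistic((z - (orl - offset)) / s)
    return profile


def _apply_noise(spec: PhantomSpec, profile: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if spec.speckle_k is not None:
        k_eff = spec.speckle_k * spec.art_frames
        profile = profile * rng.gamma(k_eff, 1.0 / k_eff, size=profile.shape)
    if spec.read_noise > 0:
        profile = profile + rng.normal(0.0, spec.read_noise, size=profile.shape)
    return np.maximum(profile, 0.0)


def generate_ascan(
    spec: PhantomSpec,
    x_index: int,
    b_index: int,
    rng: Optional[np.random.Generator] = None,
):
    """One synthetic A-scan and its ground-truth row.

    Returns ``(profile, truth)`` where ``truth`` is a dict with the true
    ``irl_um``, ``orl_um``, ``sclera_um`` and ``thickness_um`` at this
    (A-scan, B-scan) position.
    """
    spec.validate()
    if not (0 <= x_index < spec.n_ascans and 0 <= b_index < spec.n_bscans):
        raise SpecificationError("A-scan/B-scan index out of range")
    x, b = spec._norm_coords()
    irl = spec.irl_depth(x[x_index], b[b_index])
    orl = spec.orl_depth(x[x_index], b[b_index])
    profile = _clean_profiles(spec, irl, orl)
    rng = rng or np.random.default_rng(spec.seed)
    profile = _apply_noise(spec, profile, rng)
    truth = {
        "irl_um": float(irl),
        "orl_um": float(orl),
        "sclera_um": float(orl + spec.choroid_gap_um),
        "thickness_um": float(orl - irl),
    }
    return profile, truth


def generate_volume(spec: PhantomSpec) -> Tuple[OCTVolume, GroundTruth]:
    """Full synthetic volume plus paired ground truth, deterministic per seed.

    The geometry (hence the ground truth) depends only on the spec; the seed
    affects the noise realization alone.
    """
    spec.validate()
    x, b = spec._norm_coords()
    xg, bg = np.meshgrid(x, b)  # (n_bscans, n_ascans)
    irl = spec.irl_depth(xg, bg)
    orl = spec.orl_depth(xg, bg)
    profiles = _clean_profiles(spec, irl, orl)  # (n_bscans, n_ascans, n_depth)

    rng = np.random.default_rng(spec.seed)
    profiles = _apply_noise(spec, profiles, rng)
    # reorder to (n_bscans, depth, A-scans)
    frames = np.ascontiguousarray(np.moveaxis(profiles, -1, 1))

    volume = OCTVolume(
        frames=frames,
        axial_spacing=spec.axial_um_per_px,
        lateral_spacing=spec.lateral_um_per_px,
        bscan_spacing=spec.bscan_spacing_um,
        meta={"source": "phantom", "seed": spec.seed},
    )
    truth = GroundTruth(irl_um=irl, orl_um=orl, sclera_um=orl + spec.choroid_gap_um)
    return volume, truth


def inject_distractor(spec: PhantomSpec, offset_um: float, amplitude: float) -> PhantomSpec:
    """Spec with an extra intensity edge ``offset_um`` above the ORL.

    The edge is a logistic step scaled so its axial-slope peak has the given
    amplitude (intensity per um); it is used to probe the IRL exclusion zone.
    """
    if offset_um <= 0:
        raise SpecificationError("offset_um must be > 0")
    new = replace(spec, distractors=spec.distractors + ((offset_um, amplitude),))
    new.validate()
    return new
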