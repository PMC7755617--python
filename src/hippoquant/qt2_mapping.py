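"""Voxel-wise quantitative T2 from two effective-echo images.

With exactly two echoes the monoexponential model S(TE) = S0 exp(-TE/T2) has
the closed-form solution

    T2 = (te2 - te1) / ln(s1 / s2),        S0 = s1 * exp(te1 / T2),

identical to a two-point least-squares fit and exact on noise-free data. A
voxel's fit is flagged invalid (T2 and S0 set to NaN, valid = 0) when the
signal is at or below the noise floor, non-decaying (s2 >= s1, implying an
infinite or negative T2), or when the fitted T2 falls outside the configured
physical clamp range. Invalid voxels are never silently filled: downstream
summaries must mask on the validity flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import LabelMask, Volume3D, assert_same_grid

__all__ = [
    "FitConfig",
    "T2Map",
    "FitQC",
    "fit_two_point_t2",
    "compute_t2_map",
    "qc_fit",
]


@dataclass(frozen=True)
class FitConfig:
    """Noise floor and physical clamp range of the two-point fit.

    ``t2_min``/``t2_max`` (ms) bound physically interpretable fits; ``eps``
    is the signal noise floor below which a voxel is not fit at all.
    """

    eps: float = 1e-6
    t2_min: float = 1.0
    t2_max: float = 2000.0


@dataclass
class T2Map:
    """Voxel-wise T2 (ms) and S0 with a validity flag per voxel.

    Where ``valid`` is 0, ``t2`` and ``s0`` hold NaN; ``clamped`` marks the
    subset of invalid voxels whose fit succeeded but fell outside the clamp
    range.
    """

    t2: Volume3D
    s0: Volume3D
    valid: np.ndarray
    clamped: np.ndarray
    config: FitConfig = field(default_factory=FitConfig)


@dataclass
class FitQC:
    """Fit quality-control summary over an ROI."""

    n_voxels_fit: int
    frac_nonphysical: float
    frac_clamped: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "n_voxels_fit": self.n_voxels_fit,
            "frac_nonphysical": self.frac_nonphysical,
            "frac_clamped": self.frac_clamped,
            "note": self.note,
        }


def fit_two_point_t2(s1, s2, te1: float, te2: float, config: FitConfig | None = None):
    """Closed-form two-point T2 fit, vectorised over array inputs.

    Returns ``(t2, s0, valid, clamped)`` with NaN sentinels wherever
    ``valid`` is 0. ``te1 >= te2`` is a programming error and raises.
    """
    if te1 >= te2:
        raise ValueError(f"need te1 < te2, got te1={te1}, te2={te2}")
    config = config or FitConfig()
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)

    fittable = (s2 > config.eps) & (s1 > s2)
    t2 = np.full(np.broadcast(s1, s2).shape, np.nan)
    s0 = np.full_like(t2, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fittable, s1 / s2, np.nan)
        t2_raw = (te2 - te1) / np.log(ratio)
    in_range = fittable & (t2_raw >= config.t2_min) & (t2_raw <= config.t2_max)
    clamped = fittable & ~in_range
    t2[in_range] = t2_raw[in_range]
    s0[in_range] = s1[in_range] * np.exp(te1 / t2[in_range])
    return t2, s0, in_range, clamped


def compute_t2_map(
    echo1: Volume3D,
    echo2: Volume3D,
    roi: LabelMask | np.ndarray | None = None,
    config: FitConfig | None = None,
) -> T2Map:
    """Apply the two-point fit per voxel, optionally restricted to an ROI.

    Echo times are taken from each volume's ``meta['te_ms']``. Restricting to
    an ROI never changes values at voxels shared with an unrestricted run.
    """
    assert_same_grid(echo1, echo2)
    config = config or FitConfig()
    try:
        te1 = float(echo1.meta["te_ms"])
        te2 = float(echo2.meta["te_ms"])
    except KeyError as exc:
        raise KeyError("both echoes need meta['te_ms']") from exc
    if te1 >= te2:
        raise ValueError(f"need te1 < te2, got te1={te1}, te2={te2}")

    if roi is None:
        sel = np.ones(echo1.shape, dtype=bool)
    else:
        if isinstance(roi, LabelMask):
            assert_same_grid(echo1, roi)
            sel = roi.data > 0
        else:
            sel = np.asarray(roi) > 0

    t2 = np.full(echo1.shape, np.nan)
    s0 = np.full(echo1.shape, np.nan)
    valid = np.zeros(echo1.shape, dtype=bool)
    clamped = np.zeros(echo1.shape, dtype=bool)
    t2_v, s0_v, valid_v, clamp_v = fit_two_point_t2(
        echo1.data[sel], echo2.data[sel], te1, te2, config
    )
    t2[sel], s0[sel], valid[sel], clamped[sel] = t2_v, s0_v, valid_v, clamp_v

    meta = {"te1_ms": te1, "te2_ms": te2}
    return T2Map(
        t2=Volume3D(data=t2, affine=echo1.affine.copy(), meta={**meta, "description": "qT2 ms"}),
        s0=Volume3D(data=s0, affine=echo1.affine.copy(), meta={**meta, "description": "S0"}),
        valid=valid,
        clamped=clamped,
        config=config,
    )


def qc_fit(t2map: T2Map, roi: LabelMask | np.ndarray) -> FitQC:
    """Exact fit-failure fractions over the ROI (hippocampal mask union)."""
    if isinstance(roi, LabelMask):
        assert_same_grid(t2map.t2, roi)
        sel = roi.data > 0
    else:
        sel = np.asarray(roi) > 0
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty ROI")
    n_invalid = int((~t2map.valid[sel]).sum())
    n_clamped = int(t2map.clamped[sel].sum())
    return FitQC(
        n_voxels_fit=n - n_invalid,
        frac_nonphysical=n_invalid / n,
        frac_clamped=n_clamped / n,
        note=f"{n - n_invalid}/{n} voxels with physically interpretable fits",
    )
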