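"""Landmark-based overlay of light-microscopy sections onto EM sections.

Correlative registration here is a per-section 2D affine fit to paired
landmarks plus bookkeeping between the optical z step and the (typically
60 nm) block-face section thickness, including k-to-1 collapsing of EM
sections into optical-thickness projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LandmarkSet:
    """Paired 2D landmarks (light microscopy vs EM) in micrometres."""

    lm_xy: np.ndarray   # (n, 2)
    em_xy: np.ndarray   # (n, 2)
    lm_section: np.ndarray | None = None
    em_section: np.ndarray | None = None
    lm_step_nm: float | None = None
    em_step_nm: float = 60.0

    def __post_init__(self) -> None:
        lm = np.asarray(self.lm_xy, dtype=float)
        em = np.asarray(self.em_xy, dtype=float)
        if lm.shape != em.shape or lm.ndim != 2 or lm.shape[1] != 2:
            raise ValueError("lm_xy and em_xy must both be (n, 2)")
        if len(lm) < 3:
            raise ValueError("an affine fit needs at least 3 landmark pairs")

    @staticmethod
    def read_csv(path) -> "LandmarkSet":
        df = pd.read_csv(path)
        return LandmarkSet(
            lm_xy=df[["x_lm", "y_lm"]].to_numpy(),
            em_xy=df[["x_em", "y_em"]].to_numpy(),
            lm_section=df["z_lm"].to_numpy() if "z_lm" in df else None,
            em_section=df["z_em"].to_numpy() if "z_em" in df else None,
        )


@dataclass(frozen=True)
class AffineTransform2D:
    """x_em = A @ x_lm + b with the RMS landmark residual in micrometres."""

    matrix: np.ndarray   # (2, 2)
    offset: np.ndarray   # (2,)
    rms_residual_um: float

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) @ self.matrix.T + self.offset


def fit_affine(landmarks: LandmarkSet) -> AffineTransform2D:
    """Least-squares 2D affine mapping LM landmarks onto EM landmarks.

    Collinear (rank-deficient) landmark sets raise, since the affine is
    then not determined.
    """
    lm = np.asarray(landmarks.lm_xy, dtype=float)
    em = np.asarray(landmarks.em_xy, dtype=float)
    design = np.column_stack([lm, np.ones(len(lm))])
    if np.linalg.matrix_rank(design) < 3:
        raise np.linalg.LinAlgError("landmarks are collinear; affine transform is degenerate")
    params, *_ = np.linalg.lstsq(design, em, rcond=None)
    matrix = params[:2].T
    offset = params[2]
    resid = design @ params - em
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform2D(matrix=matrix, offset=offset, rms_residual_um=rms)


def match_sections(lm_z_step_nm: float, em_z_step_nm: float, lm_index: int) -> range:
    """EM section indices overlapping one LM optical section.

    Sections occupy half-open z intervals [k*step, (k+1)*step). With a
    240 nm optical step over 60 nm EM sections, optical section 0 maps to
    EM sections 0-3 (four block-face sections per optical slice).
    """
    if lm_z_step_nm <= 0 or em_z_step_nm <= 0:
        raise ValueError("section steps must be positive")
    z0 = lm_index * lm_z_step_nm
    z1 = (lm_index + 1) * lm_z_step_nm
    first = int(np.floor(z0 / em_z_step_nm))
    # EM section j overlaps iff j*em < z1 and (j+1)*em > z0
    if first * em_z_step_nm + em_z_step_nm <= z0:
        first += 1
    last = int(np.ceil(z1 / em_z_step_nm)) - 1
    if last * em_z_step_nm >= z1:
        last -= 1
    return range(first, last + 1)


def collapse_sections(stack: np.ndarray, k: int, mode: str = "mean") -> np.ndarray:
    """Collapse each run of k consecutive sections into one projection.

    ``mode='sum'`` conserves total intensity; ``mode='mean'`` conserves
    the mean. Trailing sections that do not fill a full group are
    averaged/summed over the sections present.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    n = stack.shape[0]
    groups = [stack[i : i + k] for i in range(0, n, k)]
    op = np.mean if mode == "mean" else np.sum
    return np.stack([op(g.astype(np.float64), axis=0) for g in groups])
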