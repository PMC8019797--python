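"""SSIM/PSNR agreement metrics between frame selections.

Used to quantify how close algorithm-selected frames are to frames a
human rater would pick at the same scan locations: structural
similarity (single-scale SSIM, Gaussian 11x11 window with sigma 1.5,
stability constants K1 = 0.01, K2 = 0.03 on the 8-bit dynamic range)
and peak signal-to-noise ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .frames import check_same_shape, validate_frame

_DATA_RANGE = 255.0


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean single-scale structural similarity between two 8-bit frames."""
    a = validate_frame(a)
    b = validate_frame(b)
    check_same_shape(a, b)
    return float(
        structural_similarity(
            a.astype(np.float64),
            b.astype(np.float64),
            data_range=_DATA_RANGE,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB: 10*log10(255^2 / MSE).

    Identical frames have zero MSE; +inf is returned as the sentinel.
    """
    a = validate_frame(a).astype(np.float64)
    b = validate_frame(b).astype(np.float64)
    check_same_shape(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(_DATA_RANGE**2 / mse)


@dataclass
class SimilarityReport:
    """Per-location SSIM/PSNR table between two frame selections."""

    table: pd.DataFrame  # columns: location, ssim, psnr_db

    @property
    def mean_ssim(self) -> float:
        return float(self.table["ssim"].mean())

    @property
    def mean_psnr_db(self) -> float:
        return float(self.table["psnr_db"].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_selections(
    algorithm_frames: list[np.ndarray],
    subjective_frames: list[np.ndarray],
    locations: list[str] | None = None,
) -> SimilarityReport:
    """SSIM and PSNR between paired frame selections, one row per location.

    The pairing is positional: frame i of each list was taken at the
    same scan location (named in ``locations`` if given).
    """
    if len(algorithm_frames) != len(subjective_frames):
        raise ValueError(
            f"selections differ in length: {len(algorithm_frames)} vs {len(subjective_frames)}"
        )
    if not algorithm_frames:
        raise ValueError("selections are empty")
    if locations is None:
        locations = [f"position {i + 1}" for i in range(len(algorithm_frames))]
    if len(locations) != len(algorithm_frames):
        raise ValueError("locations length must match the selections")
    rows = [
        {"location": loc, "ssim": ssim(a, b), "psnr_db": psnr(a, b)}
        for loc, a, b in zip(locations, algorithm_frames, subjective_frames)
    ]
    return SimilarityReport(table=pd.DataFrame(rows, columns=["location", "ssim", "psnr_db"]))
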