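"""Image-quality features for B-mode ultrasound frames.

Three features summarise the quality of a frame ``I_k`` relative to a
"no-contact" reference ``I_nc`` (the arc-pattern image the machine shows
when the probe is not acoustically coupled to tissue):

* a *contact gate*: the Pearson correlation of the frame with the
  no-contact reference, thresholded at ``t_corr`` — a frame that looks
  like the no-contact reference carries no tissue signal;
* a *compression feature* ``f_c``: the depth extent of supra-threshold
  pixels relative to frame height, a proxy for tissue deformation under
  probe force;
* a *noise feature* ``f_n``: mean plus standard deviation of the
  residual between the frame and its adaptive-Wiener-filtered version.

All operations are deterministic and act on the native 8-bit intensity
scale [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .frames import check_same_shape, validate_frame

#: denominator guard for the Wiener gain when the local variance vanishes
_WIENER_EPS = 1e-12


class DegenerateFrameError(ValueError):
    """Correlation is undefined: one of the frames has zero variance."""


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds and window for feature extraction.

    Parameters
    ----------
    t_corr:
        Contact-gate correlation threshold in [0, 1]; a frame whose
        correlation with the no-contact reference is >= ``t_corr`` is
        deemed not in contact. Default 0.7.
    t_comp:
        Intensity threshold on the 8-bit scale for the compression
        feature. Default 20.
    wiener_window:
        Odd (rows, cols) neighborhood of the adaptive Wiener filter.
    """

    t_corr: float = 0.7
    t_comp: float = 20.0
    wiener_window: tuple[int, int] = (5, 5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_corr <= 1.0:
            raise ValueError(f"t_corr must be in [0, 1], got {self.t_corr}")
        if not 0.0 <= self.t_comp <= 255.0:
            raise ValueError(f"t_comp must be in [0, 255], got {self.t_comp}")
        p, q = self.wiener_window
        if p < 1 or q < 1 or p % 2 == 0 or q % 2 == 0:
            raise ValueError(f"wiener_window sides must be odd and >= 1, got {(p, q)}")


@dataclass(frozen=True)
class LocalStatistics:
    """Per-pixel local moments and the global noise-variance estimate."""

    mu: np.ndarray
    sigma2: np.ndarray
    nu2: float


@dataclass(frozen=True)
class FeatureVector:
    """Quality features of one frame.

    ``contact`` is the binary gate (1 = frame resembles the no-contact
    reference, i.e. insufficient contact). ``correlation_raw`` is NaN
    when correlation was undefined (a zero-variance frame), in which
    case the gate is forced to 1 — a blank frame carries no tissue
    signal. ``no_signal`` flags a frame with no pixel above ``t_comp``.
    """

    contact: int
    correlation_raw: float
    compression: float
    noise: float
    no_signal: bool


def compute_correlation(frame: np.ndarray, reference: np.ndarray) -> float:
    """Pearson correlation between two frames over all pixels.

    Symmetric in its arguments and invariant under positive affine
    intensity transforms of either one.

    Raises
    ------
    ShapeMismatchError
        If the frames differ in shape.
    DegenerateFrameError
        If either frame has zero intensity variance.
    """
    a = validate_frame(frame).astype(np.float64)
    b = validate_frame(reference).astype(np.float64)
    check_same_shape(a, b)
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(np.sum(da * da))
    nb = np.sqrt(np.sum(db * db))
    if na == 0.0 or nb == 0.0:
        raise DegenerateFrameError("correlation undefined for a constant frame")
    return float(np.sum(da * db) / (na * nb))


def contact_gate(correlation_raw: float, t_corr: float) -> int:
    """1 when the frame is at least as correlated with the no-contact
    reference as ``t_corr`` (inclusive boundary), else 0."""
    return 1 if correlation_raw >= t_corr else 0


def compute_compression(frame: np.ndarray, t_comp: float) -> tuple[float, bool]:
    """Depth extent of bright pixels relative to frame height.

    Scans for rows containing any pixel >= ``t_comp``; with U and L the
    largest and smallest such (0-based) row indices, returns
    ``f_c = (U - L) / M``. A frame with no supra-threshold pixel yields
    ``(0.0, no_signal=True)``.
    """
    arr = validate_frame(frame)
    rows = np.nonzero((arr >= t_comp).any(axis=1))[0]
    if rows.size == 0:
        return 0.0, True
    m = arr.shape[0]
    return float(rows[-1] - rows[0]) / m, False


def wiener_filter(
    frame: np.ndarray, window: tuple[int, int] = (5, 5)
) -> tuple[np.ndarray, LocalStatistics]:
    """Adaptive (locally adaptive minimum-mean-square) Wiener filter.

    Per pixel, the mean ``mu`` and variance ``sigma2`` are taken over a
    P x Q neighborhood (reflect padding at the borders). The scalar
    noise variance ``nu2`` is estimated as the mean of all local
    variances. The output pixel is

        mu + max(sigma2 - nu2, 0) / max(sigma2, eps) * (I - mu)

    so flat regions collapse to their local mean while high-variance
    structure is preserved. The non-negativity clamp and denominator
    guard handle neighborhoods whose variance falls below the noise
    floor.
    """
    arr = validate_frame(frame).astype(np.float64)
    p, q = int(window[0]), int(window[1])
    if p < 1 or q < 1 or p % 2 == 0 or q % 2 == 0:
        raise ValueError(f"window sides must be odd and >= 1, got {(p, q)}")
    if p > arr.shape[0] or q > arr.shape[1]:
        raise ValueError(
            f"window {(p, q)} exceeds frame dimensions {arr.shape}"
        )
    padded = np.pad(arr, ((p // 2, p // 2), (q // 2, q // 2)), mode="reflect")
    # contiguous window axis so each neighborhood reduces in C order
    win = sliding_window_view(padded, (p, q)).reshape(arr.shape[0], arr.shape[1], p * q)
    mu = win.mean(axis=-1)
    sigma2 = np.maximum(np.square(win).mean(axis=-1) - mu * mu, 0.0)
    nu2 = float(sigma2.mean())
    gain = np.maximum(sigma2 - nu2, 0.0) / np.maximum(sigma2, _WIENER_EPS)
    filtered = mu + gain * (arr - mu)
    return filtered, LocalStatistics(mu=mu, sigma2=sigma2, nu2=nu2)


def compute_noise_feature(
    frame: np.ndarray, window: tuple[int, int] = (5, 5)
) -> float:
    """Mean plus standard deviation of the Wiener residual.

    The residual ``I_n = I_k - I_{k,f}`` keeps its sign; its mean and
    (population) standard deviation are summed. A constant frame passes
    through the filter unchanged and scores exactly 0.
    """
    arr = validate_frame(frame).astype(np.float64)
    filtered, _ = wiener_filter(arr, window)
    residual = arr - filtered
    return float(residual.mean() + residual.std())


def extract_features(
    frame: np.ndarray,
    reference: np.ndarray,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Compute the full feature vector for one frame.

    A degenerate (zero-variance) frame makes the correlation undefined;
    such frames are treated as not in contact (gate = 1) with
    ``correlation_raw`` recorded as NaN.
    """
    cfg = config or FeatureConfig()
    arr = validate_frame(frame)
    ref = validate_frame(reference)
    check_same_shape(arr, ref)
    try:
        corr = compute_correlation(arr, ref)
        contact = contact_gate(corr, cfg.t_corr)
    except DegenerateFrameError:
        corr = float("nan")
        contact = 1
    compression, no_signal = compute_compression(arr, cfg.t_comp)
    noise = compute_noise_feature(arr, cfg.wiener_window)
    return FeatureVector(
        contact=contact,
        correlation_raw=corr,
        compression=compression,
        noise=noise,
        no_signal=no_signal,
    )


def write_feature_table(rows: list[tuple[str, FeatureVector]], path) -> None:
    """Dump features as CSV with columns
    frame_id, correlation_raw, contact, compression, noise, no_signal."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "frame_id": frame_id,
                "correlation_raw": fv.correlation_raw,
                "contact": fv.contact,
                "compression": fv.compression,
                "noise": fv.noise,
                "no_signal": fv.no_signal,
            }
            for frame_id, fv in rows
        ]
    )
    df.to_csv(path, index=False)
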