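"""Independent brute-force oracles used to pin expected values.

Each oracle enumerates its computation explicitly (per-pixel loops,
two-pass statistics) so it shares no code path with the vectorized
implementations it checks.
"""

import numpy as np


def pearson_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation via the textbook formula on flattened pixels."""
    x = a.astype(np.float64).ravel()
    y = b.astype(np.float64).ravel()
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = float(np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
    return num / den


def compression_oracle(frame: np.ndarray, t_comp: float) -> tuple[float, bool]:
    """Exhaustive row scan for the bright-pixel depth extent."""
    m, n = frame.shape
    bright_rows = []
    for i in range(m):
        for j in range(n):
            if frame[i, j] >= t_comp:
                bright_rows.append(i)
                break
    if not bright_rows:
        return 0.0, True
    return (max(bright_rows) - min(bright_rows)) / m, False


def wiener_oracle(frame: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Per-pixel double-loop adaptive Wiener filter with reflect padding."""
    arr = frame.astype(np.float64)
    p, q = window
    padded = np.pad(arr, ((p // 2, p // 2), (q // 2, q // 2)), mode="reflect")
    m, n = arr.shape
    mu = np.empty((m, n))
    sigma2 = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            patch = padded[i : i + p, j : j + q].copy()
            mean = patch.mean()
            mu[i, j] = mean
            sigma2[i, j] = max(np.square(patch).mean() - mean * mean, 0.0)
    nu2 = sigma2.mean()
    out = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            gain = max(sigma2[i, j] - nu2, 0.0) / max(sigma2[i, j], 1e-12)
            out[i, j] = mu[i, j] + gain * (arr[i, j] - mu[i, j])
    return out


def mean_plus_std_oracle(residual: np.ndarray) -> float:
    """Two-pass mean + population standard deviation."""
    flat = residual.ravel()
    n = flat.size
    mean = float(sum(flat) / n)
    var = float(sum((v - mean) ** 2 for v in flat) / n)
    return mean + var**0.5


def ssim_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Sliding-window single-scale SSIM with an 11x11 Gaussian window
    (sigma 1.5), evaluated at every fully supported position."""
    sigma, radius = 1.5, 5
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    w = np.outer(g, g)
    c1 = (0.01 * 255.0) ** 2
    c2 = (0.03 * 255.0) ** 2
    fa = a.astype(np.float64)
    fb = b.astype(np.float64)
    m, n = fa.shape
    size = 2 * radius + 1
    vals = []
    for i in range(m - size + 1):
        for j in range(n - size + 1):
            pa = fa[i : i + size, j : j + size]
            pb = fb[i : i + size, j : j + size]
            ux = float((w * pa).sum())
            uy = float((w * pb).sum())
            vx = float((w * pa * pa).sum()) - ux * ux
            vy = float((w * pb * pb).sum()) - uy * uy
            vxy = float((w * pa * pb).sum()) - ux * uy
            vals.append(
                ((2 * ux * uy + c1) * (2 * vxy + c2))
                / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))
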