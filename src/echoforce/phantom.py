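"""Synthetic B-mode phantom: frames with the statistical structure the
quality-assessment method relies on.

The generator emulates, phenomenologically, what a linear-array probe
shows while a robot presses it into a soft phantom:

* **no contact** — a dark field crossed by bright arc-shaped
  reverberation bands (the probe "ringing" against air or gel);
* **contact** — a speckled tissue band starting just below the probe
  face whose depth extent grows with applied force as the tissue is
  compressed and more of it fills the field of view, and whose noise
  level (multiplicative speckle plus force-dependent additive noise)
  grows with force;
* a *quality band* of forces whose frames a sonographer would call
  high quality: enough contact for tissue to be visible, not enough to
  deform it badly. Frames rendered inside the band are labeled
  ``high``, frames from the no-contact, light-contact and
  over-compressed regimes are labeled ``low``.

There is no acoustic wave simulation; the generator reproduces the
feature-level phenomenology (correlation with the no-contact reference,
monotone compression and noise responses) rather than physics.
All renders are pure functions of (config, seed, force).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .classifier import LabeledEntry, LabeledFrameSet
from .frames import save_frame

#: Rayleigh scale with unit mean, used for the multiplicative speckle
_RAYLEIGH_UNIT_MEAN_SCALE = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, tissue response and class structure of the phantom.

    Forces are in newtons on the 1–20 N scanning range. The compression
    response is a saturating exponential: the tissue-band extent (as a
    fraction of frame height) rises from ``extent_min`` at first contact
    toward ``extent_max`` with force constant ``extent_tau_n``. The
    additive noise inside the band grows linearly with force.
    ``quality_band_n`` is the force interval whose frames are labeled
    high quality; low-quality in-contact forces are sampled from two
    lobes of width ``lobe_width_n`` whose inner edges sit ``class_gap_n``
    newtons outside the band.
    """

    shape: tuple[int, int] = (96, 128)
    background: float = 8.0
    background_noise_std: float = 2.0
    # no-contact arc pattern
    n_arcs: int = 4
    arc_brightness: float = 150.0
    arc_width_rows: float = 1.5
    arc_curvature_rows: float = 9.0
    arc_decay: float = 0.8
    # contact / compression response
    contact_force_n: float = 1.5
    band_top_frac: float = 0.04
    extent_min: float = 0.35
    extent_max: float = 0.95
    extent_tau_n: float = 6.0
    extent_jitter_std: float = 0.02
    # tissue echogenicity and noise response
    tissue_intensity: float = 120.0
    speckle_strength: float = 0.5
    noise_std_base_8bit: float = 2.0
    noise_std_slope_8bit_per_n: float = 0.9
    # class structure
    quality_band_n: tuple[float, float] = (4.0, 10.0)
    class_gap_n: float = 2.0
    lobe_width_n: float = 2.0
    force_max_n: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        m, n = self.shape
        if m < 2 or n < 2:
            raise ValueError(f"shape must be at least 2x2, got {self.shape}")
        f_lo, f_hi = self.quality_band_n
        if not 0.0 < f_lo < f_hi <= self.force_max_n:
            raise ValueError(
                f"quality band must satisfy 0 < F_lo < F_hi <= {self.force_max_n}, "
                f"got {self.quality_band_n}"
            )
        for name in ("extent_min", "extent_max", "band_top_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.extent_min >= self.extent_max:
            raise ValueError("extent_min must be below extent_max")
        if self.contact_force_n <= 0:
            raise ValueError("contact_force_n must be positive")


class VirtualPhantom:
    """Deterministic synthetic phantom with a cached no-contact reference.

    The reference frame — the correlation template for the contact
    gate — is the no-contact render at the config seed and is
    reproducible from ``(config, seed)`` alone.
    """

    def __init__(self, config: PhantomConfig | None = None):
        self.config = config or PhantomConfig()
        self._arc_image = self._build_arc_image()
        self.reference = self.render_no_contact(seed=self.config.seed)

    # -- deterministic structural layers -------------------------------

    def _build_arc_image(self) -> np.ndarray:
        """Bright arc bands of the no-contact pattern (noise-free)."""
        cfg = self.config
        m, n = cfg.shape
        rows = np.arange(m, dtype=np.float64)[:, None]
        cols = np.arange(n, dtype=np.float64)[None, :]
        lateral = (cols - (n - 1) / 2.0) / ((n - 1) / 2.0)
        img = np.zeros((m, n))
        for i in range(cfg.n_arcs):
            center = (i + 1) / (cfg.n_arcs + 2) * m
            arc_row = center + cfg.arc_curvature_rows * lateral**2
            amplitude = cfg.arc_brightness * cfg.arc_decay**i
            img += amplitude * np.exp(
                -0.5 * ((rows - arc_row) / cfg.arc_width_rows) ** 2
            )
        return img

    def band_extent(self, force: float) -> float:
        """Noise-free tissue-band extent (fraction of frame height)."""
        cfg = self.config
        rise = 1.0 - math.exp(-(force - cfg.contact_force_n) / cfg.extent_tau_n)
        return cfg.extent_min + (cfg.extent_max - cfg.extent_min) * rise

    def noise_std(self, force: float) -> float:
        """Additive in-band noise standard deviation at a given force."""
        cfg = self.config
        return cfg.noise_std_base_8bit + cfg.noise_std_slope_8bit_per_n * (
            force - cfg.contact_force_n
        )

    # -- rendering ------------------------------------------------------

    def render_no_contact(self, seed: int | None = None) -> np.ndarray:
        """Dark frame with the arc pattern plus light background speckle."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        img = (
            cfg.background
            + self._arc_image
            + rng.normal(0.0, cfg.background_noise_std, cfg.shape)
        )
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    def render_contact(self, force: float, seed: int | None = None) -> np.ndarray:
        """Frame under an applied probe force.

        Below the contact threshold the probe is uncoupled and the
        no-contact pattern is returned. Above it, a speckled tissue band
        replaces the arcs; its extent follows the compression response
        and its noise statistics the noise response.
        """
        cfg = self.config
        if force < 0:
            raise ValueError(f"force must be non-negative, got {force}")
        if force < cfg.contact_force_n:
            return self.render_no_contact(seed=seed)
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        m, n = cfg.shape
        img = cfg.background + rng.normal(0.0, cfg.background_noise_std, (m, n))
        extent = self.band_extent(force) + rng.normal(0.0, cfg.extent_jitter_std)
        extent = float(np.clip(extent, 0.05, 0.99))
        top = int(round(cfg.band_top_frac * m))
        bottom = min(m, top + max(2, int(round(extent * m))))
        speckle = rng.rayleigh(_RAYLEIGH_UNIT_MEAN_SCALE, (bottom - top, n))
        tissue = cfg.tissue_intensity * (
            1.0 - cfg.speckle_strength + cfg.speckle_strength * speckle
        )
        tissue += rng.normal(0.0, self.noise_std(force), (bottom - top, n))
        img[top:bottom] = tissue
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # -- class structure and dataset generation ------------------------

    def sample_force(self, rng: np.random.Generator, label: str) -> float:
        """Draw a probe force for a frame of the given quality label.

        High-quality forces are uniform over the quality band. Low
        forces come from three regimes in equal proportion: no contact,
        the light-contact lobe below the band and the over-compressed
        lobe above it (lobes clipped to the physical 0–20 N range).
        """
        cfg = self.config
        f_lo, f_hi = cfg.quality_band_n
        if label == "high":
            return float(rng.uniform(f_lo, f_hi))
        if label != "low":
            raise ValueError(f"unknown label {label!r}")
        regime = int(rng.integers(3))
        if regime == 0:  # no contact
            return float(rng.uniform(0.0, 0.8 * cfg.contact_force_n))
        if regime == 1:  # light contact
            hi = f_lo - cfg.class_gap_n
            lo = hi - cfg.lobe_width_n
            lo = max(lo, cfg.contact_force_n + 0.05)
            if hi <= lo:  # lobe squeezed out; fall back to no contact
                return float(rng.uniform(0.0, 0.8 * cfg.contact_force_n))
            return float(rng.uniform(lo, hi))
        lo = f_hi + cfg.class_gap_n
        hi = min(lo + cfg.lobe_width_n, cfg.force_max_n)
        lo = min(lo, cfg.force_max_n - 0.05)
        return float(rng.uniform(lo, hi))

    def generate_dataset(
        self,
        n_per_class: int,
        seed: int,
        out_dir: str | Path | None = None,
        force_sampler: Callable[[np.random.Generator, str], float] | None = None,
    ) -> LabeledFrameSet:
        """Render a balanced labeled frame collection.

        ``n_per_class`` frames are sampled inside the quality band and
        labeled ``high``; the same number are sampled from the
        no-contact, light-contact and over-compressed regimes and
        labeled ``low``. With ``out_dir`` given, frames are written as
        PNG plus a ``manifest.csv`` (frame_id, path, label); otherwise
        the frames stay in memory on the returned set. Fully
        reproducible from ``seed``.
        """
        if n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        sampler = force_sampler or self.sample_force
        rng = np.random.default_rng(seed)
        render_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class)
        entries = []
        labels = ["high"] * n_per_class + ["low"] * n_per_class
        for i, label in enumerate(labels):
            force = sampler(rng, label)
            frame = self.render_contact(force, seed=int(render_seeds[i]))
            frame_id = f"frame_{i:05d}"
            path = ""
            if out_dir is not None:
                path = f"{frame_id}.png"
                save_frame(frame, Path(out_dir) / path)
                frame_stored = None
            else:
                frame_stored = frame
            entries.append(
                LabeledEntry(frame_id=frame_id, path=path, label=label, frame=frame_stored)
            )
        fs = LabeledFrameSet(entries=entries, root=Path(out_dir) if out_dir else None)
        if out_dir is not None:
            fs.to_manifest(Path(out_dir) / "manifest.csv")
        return fs


class FrozenNoContactPhantom(VirtualPhantom):
    """A phantom whose probe never couples: every render, at any force,
    is a no-contact frame. Models scanning over an air gap."""

    def render_contact(self, force: float, seed: int | None = None) -> np.ndarray:
        if force < 0:
            raise ValueError(f"force must be non-negative, got {force}")
        return self.render_no_contact(seed=seed)


def in_band_force_sampler(config: PhantomConfig) -> Callable[[np.random.Generator, str], float]:
    """Force sampler with zero class separation: every force, for either
    label, is drawn from the quality band, so the two classes are
    identically distributed in feature space. Used to probe how
    classifier accuracy collapses toward chance as separation vanishes."""
    f_lo, f_hi = config.quality_band_n

    def sampler(rng: np.random.Generator, label: str) -> float:
        return float(rng.uniform(f_lo, f_hi))

    return sampler
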