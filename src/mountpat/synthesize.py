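"""Synthetic multichannel EEG generator for end-to-end testing.

The extractor's features are functions of per-timepoint channel rankings,
so the generator builds classes that differ exactly in their channel-
ordering dynamics: channel ``c`` of a class-``k`` epoch is a sinusoid with
a class-specific per-channel phase and amplitude,

    x[t, c] = A_kc * sin(2*pi*f_k*t/L + theta_kc) + eps,   eps ~ N(0, sigma^2)

with phases drawn uniformly on [0, 2*pi) and amplitudes on [0.5, 1.5] once
per class from the seeded generator.  Distinct phase/amplitude patterns
give distinct rank trajectories, which is the one statistic the features
can see — a class difference that is rank-invariant would correctly be
indistinguishable.  Optional subjects multiply each channel by a
subject-specific random gain in [0.8, 1.2], emulating cross-subject shift
for leave-one-subject-out tests.

Everything is deterministic under a fixed seed, and datasets are exactly
class-balanced.  No physiological realism (1/f spectra, artifacts) is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EEGSegment

__all__ = ["SyntheticConfig", "generate_segment", "generate_dataset"]


@dataclass
class SyntheticConfig:
    """Generation parameters.

    noise_sigma is the additive Gaussian noise s.d. in the same (unit)
    amplitude scale as the sinusoids; n_subjects, when set, spreads the
    epochs round-robin over subjects with per-subject channel gains.
    """

    n_classes: int = 2
    nc: int = 14
    L: int = 512
    n_per_class: int = 50
    noise_sigma: float = 0.05
    seed: int = 1
    sampling_rate_hz: float = 128.0
    n_subjects: int | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.nc < 2:
            raise ValueError("need at least two channels")
        if self.L < 5:
            raise ValueError("epoch length must be >= 5")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _class_params(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class frequencies, phases and amplitudes (drawn once, seeded)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    freqs = 3.0 + np.arange(cfg.n_classes)  # cycles per epoch, distinct per class
    phases = rng.uniform(0, 2 * np.pi, size=(cfg.n_classes, cfg.nc))
    amps = rng.uniform(0.5, 1.5, size=(cfg.n_classes, cfg.nc))
    return freqs, phases, amps


def _subject_gains(cfg: SyntheticConfig) -> np.ndarray | None:
    if cfg.n_subjects is None:
        return None
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    return rng.uniform(0.8, 1.2, size=(cfg.n_subjects, cfg.nc))


def generate_segment(
    class_id: int,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    subject_id: int | None = None,
) -> EEGSegment:
    """One labelled epoch of class ``class_id``.

    ``rng`` supplies the additive noise only; class structure comes from
    the deterministic per-class parameters.
    """
    if not 0 <= class_id < cfg.n_classes:
        raise ValueError(f"class_id {class_id} outside [0, {cfg.n_classes})")
    freqs, phases, amps = _class_params(cfg)
    t = np.arange(cfg.L)[:, None]
    clean = amps[class_id] * np.sin(
        2 * np.pi * freqs[class_id] * t / cfg.L + phases[class_id]
    )
    if subject_id is not None:
        gains = _subject_gains(cfg)
        if gains is None:
            raise ValueError("subject_id given but n_subjects not configured")
        clean = clean * gains[subject_id % cfg.n_subjects]
    noise = rng.normal(0.0, cfg.noise_sigma, size=clean.shape) if cfg.noise_sigma else 0.0
    return EEGSegment(
        data=clean + noise,
        label=class_id,
        subject_id=subject_id,
        sampling_rate_hz=cfg.sampling_rate_hz,
    )


def generate_dataset(
    cfg: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[list[EEGSegment], pd.DataFrame]:
    """Class-balanced labelled dataset (optionally written to disk).

    Returns the segments and a manifest frame with columns
    ``path`` (empty unless written), ``label`` and ``subject``.  When
    ``out_dir`` is given each segment is written as a headerless CSV
    (rows = time, columns = channels) plus ``manifest.csv``.
    """
    segments: list[EEGSegment] = []
    rows = []
    # Independent child streams per segment: regeneration order-independent.
    children = np.random.SeedSequence([cfg.seed, 2]).spawn(
        cfg.n_classes * cfg.n_per_class
    )
    idx = 0
    for class_id in range(cfg.n_classes):
        for rep in range(cfg.n_per_class):
            subject = (
                idx % cfg.n_subjects if cfg.n_subjects is not None else None
            )
            seg = generate_segment(
                class_id, cfg, np.random.default_rng(children[idx]), subject
            )
            segments.append(seg)
            rows.append({"path": "", "label": class_id, "subject": subject})
            idx += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, seg in enumerate(segments):
            path = out / f"segment_{i:04d}.csv"
            np.savetxt(path, seg.data, delimiter=",", fmt="%.10g")
            manifest.loc[i, "path"] = str(path)
        manifest.to_csv(out / "manifest.csv", index=False)
    return segments, manifest
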