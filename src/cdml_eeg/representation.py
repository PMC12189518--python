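"""Channel-dependent multilayer time-frequency representation (CDML-EEG-TFR).

The per-channel scalogram images of one trial are stacked along a depth axis —
the three electrodes playing the role the R/G/B planes play in a colour
photograph — giving the 250 x 250 x 3 tensor the convolutional classifier
consumes. Channel order is fixed to the spatial left-midline-right order
(C3, Cz, C4) so that depth position always means the same electrode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import CHANNEL_ORDER, PipelineConfig
from .eeg_io import ChannelError, TrialSegment
from .preprocess import apply_bandpass, FilterSpec
from .tfr import TFRImage, compute_scale_grid, cwt, render_tfr

__all__ = ["CDMLTensor", "stack_channels", "unstack_channels", "build_dataset",
           "save_dataset", "load_dataset"]


@dataclass
class CDMLTensor:
    """One trial's stacked 250 x 250 x 3 time-frequency representation."""

    layers: np.ndarray  # H x W x 3, float32 in [0, 1]
    label: str
    subject_id: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.layers, dtype=np.float32)
        if a.ndim != 3 or a.shape[2] != 3:
            raise ValueError("layers must be H x W x 3")
        self.layers = a


def stack_channels(imgs: dict[str, TFRImage],
                   order: tuple[str, str, str] = CHANNEL_ORDER,
                   label: str = "left", subject_id: str = "",
                   trial_index: int = 0) -> CDMLTensor:
    """Depth-stack per-channel images in canonical electrode order."""
    if set(imgs) != set(order):
        raise ChannelError(f"need exactly channels {set(order)}, got {set(imgs)}")
    shapes = {imgs[c].pixels.shape for c in order}
    if len(shapes) != 1:
        raise ValueError(f"mismatched image shapes: {shapes}")
    layers = np.stack([imgs[c].pixels for c in order], axis=-1)
    return CDMLTensor(layers=layers, label=label, subject_id=subject_id,
                      trial_index=trial_index)


def unstack_channels(tensor: CDMLTensor,
                     order: tuple[str, str, str] = CHANNEL_ORDER
                     ) -> dict[str, TFRImage]:
    """Inverse of :func:`stack_channels` (exact)."""
    return {c: TFRImage(pixels=tensor.layers[:, :, i], channel_label=c)
            for i, c in enumerate(order)}


def build_tensor(seg: TrialSegment, cfg: PipelineConfig) -> CDMLTensor:
    """filter -> CWT -> render -> stack for a single trial."""
    seg = apply_bandpass(seg, FilterSpec(order=cfg.filter.order,
                                         band=cfg.filter.band, fs=seg.fs,
                                         phase_mode=cfg.filter.phase_mode))
    grid = compute_scale_grid(cfg.morlet, seg.fs, cfg.band[0], cfg.band[1],
                              cfg.n_scales)
    imgs: dict[str, TFRImage] = {}
    for row, ch in enumerate(CHANNEL_ORDER):
        scal = cwt(seg.data[row], grid, cfg.morlet, channel_label=ch)
        imgs[ch] = render_tfr(scal, out_size=cfg.out_size, power=cfg.power)
    if cfg.input_mode != "cdml":
        if cfg.input_mode not in CHANNEL_ORDER:
            raise ValueError(f"input_mode must be 'cdml' or one of {CHANNEL_ORDER}")
        # single-layer ablation: the chosen channel replicated across depth
        imgs = {c: imgs[cfg.input_mode] for c in CHANNEL_ORDER}
    return stack_channels(imgs, order=cfg.channel_order, label=seg.label,
                          subject_id=seg.subject_id, trial_index=seg.trial_index)


def build_dataset(segments: list[TrialSegment],
                  cfg: PipelineConfig | None = None) -> list[CDMLTensor]:
    """Deterministically map trial segments to CDML tensors, labels preserved."""
    cfg = cfg or PipelineConfig()
    return [build_tensor(seg, cfg) for seg in segments]


# ----------------------------------------------------------------------- cache

def save_dataset(path: str | Path, tensors: list[CDMLTensor],
                 cfg: PipelineConfig) -> Path:
    """Cache tensors to NPZ, keyed by the config fingerprint."""
    path = Path(path)
    np.savez_compressed(
        path,
        layers=np.stack([t.layers for t in tensors]) if tensors else
        np.zeros((0, 0, 0, 3), np.float32),
        labels=np.array([t.label for t in tensors]),
        subjects=np.array([t.subject_id for t in tensors]),
        trial_index=np.array([t.trial_index for t in tensors]),
        fingerprint=np.array(cfg.fingerprint()),
    )
    return path


def load_dataset(path: str | Path, cfg: PipelineConfig | None = None
                 ) -> list[CDMLTensor]:
    """Load cached tensors; refuses a cache built under a different config."""
    with np.load(path, allow_pickle=False) as data:
        if cfg is not None and str(data["fingerprint"]) != cfg.fingerprint():
            raise ValueError(
                "tensor cache was built under a different configuration")
        return [CDMLTensor(layers=data["layers"][i],
                           label=str(data["labels"][i]),
                           subject_id=str(data["subjects"][i]),
                           trial_index=int(data["trial_index"][i]))
                for i in range(len(data["labels"]))]
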