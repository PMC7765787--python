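"""Desk-scale experiment profile.

The full-scale defaults (W = 6000 samples, M = 500, N = 300, test stride
300, K = 3) are the package defaults in :class:`~kmargin.types.AugmentationConfig`.
For self-contained experiments on one CPU the package uses a proportionally
scaled profile: 100 Hz records of 30-45 s, 15 s windows (W = 1500) of five 3 s
fragments (N = 300), the same maximum stride threshold and test stride, and a
small trunk.  Class skew, the injected-noise fraction rho, the record count
and K are experiment inputs, not part of the profile.
"""

from __future__ import annotations

from .model import ModelConfig
from .synth import SynthConfig
from .types import AugmentationConfig

__all__ = ["desk_augmentation", "desk_model", "desk_synth"]


def desk_augmentation() -> AugmentationConfig:
    return AugmentationConfig(window=1500, max_stride=500, fragment_len=300, test_stride=300)


def desk_model(n_classes: int = 3, n_features: int = 0, seed: int = 0, epochs: int = 8) -> ModelConfig:
    return ModelConfig(
        n_classes=n_classes,
        n_features=n_features,
        window=1500,
        fragment_len=300,
        n_residual_blocks=2,
        conv_channels=8,
        recurrent_units=12,
        knowledge_hidden=16,
        learning_rate=3e-3,
        batch_size=64,
        epochs=epochs,
        seed=seed,
    )


def desk_synth(n_records: int = 200, rho: float = 0.0, seed: int = 0) -> SynthConfig:
    return SynthConfig(n_records=n_records, noisy_span_fraction=rho, seed=seed)
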