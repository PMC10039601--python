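"""Shared fixtures: deterministic synthetic samples and a tiny trained net."""

from __future__ import annotations

import numpy as np
import pytest

import sellamorph as sm
from sellamorph.pipeline import PipelineConfig, network_input
from sellamorph.landmarks import CornerParams


@pytest.fixture(scope="session")
def sample400() -> sm.SyntheticSample:
    """One reference-scale synthetic sella (400 px canvas)."""
    return sm.make_sample(7, canvas_size=400)


@pytest.fixture(scope="session")
def samples400() -> list[sm.SyntheticSample]:
    """A small batch of reference-scale samples for property tests."""
    rng = np.random.default_rng(1234)
    return [sm.make_sample(int(s), canvas_size=400)
            for s in rng.integers(0, 2**31, size=12)]


@pytest.fixture(scope="session")
def tiny_pipeline_config() -> PipelineConfig:
    """Pipeline settings for 64 px rasters (corner params scaled 400->64)."""
    return PipelineConfig(roi=None, ksize=5, corner=CornerParams().scaled(64 / 400))


@pytest.fixture(scope="session")
def overfit_run(tiny_pipeline_config) -> tuple[sm.UNet, sm.SyntheticSample, sm.TrainHistory]:
    """A 64 px U-net memorizing a single easy pair (shared oracle model).

    Constant learning rate (plateau patience effectively off): with one
    batch per epoch the per-epoch plateau schedule is far too trigger-happy
    to study convergence.
    """
    samp = sm.make_sample(3, canvas_size=64)
    net_in = network_input(samp.image, tiny_pipeline_config)
    imgs, masks = [net_in] * 8, [samp.mask] * 8
    ucfg = sm.UNetConfig(depth=2, base_channels=8, in_size=64)
    tcfg = sm.TrainConfig(learning_rate=1e-3, batch_size=8, epochs=350,
                          seed=0, lr_patience=10_000)
    model, hist = sm.train(imgs, masks, ucfg, tcfg, val_images=imgs, val_masks=masks)
    return model, samp, hist
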