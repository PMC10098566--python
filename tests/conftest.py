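"""Shared fixtures: synthetic recordings written once per session."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from rppgkit import video_io
from rppgkit.synthetic_data import SynthConfig, generate_video, roi_box


@pytest.fixture(scope="session")
def synth_recording_factory(tmp_path_factory):
    """Return a factory writing a synthetic recording to disk (cached).

    The factory yields ``(video_path, gt_path, box)`` for a given
    SynthConfig and frame geometry; identical requests reuse the same
    files.
    """
    root = tmp_path_factory.mktemp("recordings")
    cache: dict = {}

    def make(config: SynthConfig, width: int = 160, height: int = 120,
             roi_fraction: float = 0.5):
        key = (config, width, height, roi_fraction)
        if key not in cache:
            frames, _, gt = generate_video(config, width, height, roi_fraction)
            d = root / f"rec{len(cache)}"
            d.mkdir()
            video_io.write_video(d / "video.tiff", frames, config.fps)
            gt.to_csv(d / "gt.csv")
            cache[key] = (d / "video.tiff", d / "gt.csv",
                          roi_box(width, height, roi_fraction))
        return cache[key]

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
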