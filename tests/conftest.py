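"""Shared fixtures: compiled-kernel warmup and cached transport runs."""

from __future__ import annotations

import numpy as np
import pytest

from turbiflim import SourcePosition, TissueOptics, propagate_batch


@pytest.fixture(scope="session")
def default_optics() -> TissueOptics:
    return TissueOptics()


@pytest.fixture(scope="session")
def depth_runs(default_optics):
    """One 1e5-photon transport run per depth, reused across tests."""
    out = {}
    for i, z in enumerate((0.1, 0.2, 0.3)):
        out[z] = propagate_batch(
            100_000, SourcePosition(0.0, 0.0, z), default_optics, seed=1000 + i
        )
    return out


def escape_stats(res) -> tuple[float, float, int]:
    """(escape fraction, mean exit radius, n escaped) of a transport run."""
    esc = res["outcome"] == 1
    n = int(esc.sum())
    frac = n / res["outcome"].size
    radius = float(np.hypot(res["exit_x"][esc], res["exit_y"][esc]).mean()) if n else np.nan
    return frac, radius, n
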