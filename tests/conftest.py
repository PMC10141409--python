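import numpy as np
import pytest

import ferrotrace as ft


@pytest.fixture(scope="session")
def apo_trace():
    """12 s apo trapping recording (trap step at 2 s), shared across tests."""
    return ft.trapped_experiment(ft.apo_preset(), seed=101, duration=12.0)


@pytest.fixture(scope="session")
def apo_trapped_filtered(apo_trace):
    """1 kHz-filtered trapped span of the apo recording (settling excluded)."""
    filtered = ft.gaussian_lowpass(apo_trace.trace, 1000.0)
    return filtered.crop(2.6, 12.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def segments_from_boundaries(t_start, boundaries, t_end, first_label="on"):
    """Build a SegmentSet from exact switching times (ground truth)."""
    edges = np.concatenate(([t_start], np.asarray(boundaries), [t_end]))
    labels = [first_label if i % 2 == 0 else
              ("off" if first_label == "on" else "on")
              for i in range(len(edges) - 1)]
    segs = [ft.Segment(float(a), float(b), lab)
            for a, b, lab in zip(edges[:-1], edges[1:], labels)]
    return ft.SegmentSet(segs, threshold=0.0, hysteresis=0.0, min_dwell=0.0)
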