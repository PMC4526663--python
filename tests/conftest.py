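"""Shared fixtures: small rendered stacks with ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True)
_hsettings.load_profile("deterministic")

from arcfish import SimConfig, classify_stack, render_stack, simulate_labels
from arcfish.simulate import truth_label

Z_SCALE = 8.0 / 6.0  # anisotropy factor used to match centroids in 3D


def single_cell_truth(z=20.0, y=32.0, x=32.0, e1=False, e2=False, r=8.0) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": [0], "is_neuron": [True], "e1": [e1], "e2": [e2],
        "z": [z], "y": [y], "x": [x], "r": [r],
    })


def single_cell_config(**kw) -> SimConfig:
    defaults = dict(n_cells=1, glia_fraction=0.0, noise_sd=0.0, seed=1,
                    stack_shape=(40, 64, 64))
    defaults.update(kw)
    return SimConfig(**defaults)


def match_records_to_truth(records, truth):
    """Pair each truth neuron with its nearest segmented record.

    Returns (truth_label, predicted_label) pairs; undetected neurons pair
    with "missed".
    """
    neurons = truth[truth["is_neuron"]]
    used: set[int] = set()
    pairs = []
    for rec in records:
        d = np.sqrt(((neurons["z"] - rec.centroid[0]) * Z_SCALE) ** 2
                    + (neurons["y"] - rec.centroid[1]) ** 2
                    + (neurons["x"] - rec.centroid[2]) ** 2)
        i = d.idxmin()
        if d[i] < 8 and i not in used:
            used.add(i)
            pairs.append((truth_label(neurons["e1"][i], neurons["e2"][i]), rec.label))
    for i in neurons.index:
        if i not in used:
            pairs.append((truth_label(neurons["e1"][i], neurons["e2"][i]), "missed"))
    return pairs


def per_class_f1(pairs):
    out = {}
    for cls in ("negative", "nuclear", "cytoplasmic", "double"):
        tp = sum(1 for t, p in pairs if t == cls and p == cls)
        fp = sum(1 for t, p in pairs if t != cls and p == cls)
        fn = sum(1 for t, p in pairs if t == cls and p != cls)
        out[cls] = 2 * tp / max(1, 2 * tp + fp + fn)
    return out


@pytest.fixture(scope="session")
def small_stack_with_truth():
    """One noiseless 20-nucleus stack, classified, with its truth table."""
    cfg = SimConfig(n_cells=20, p1=0.33, p2=0.33, kappa=0.5, glia_fraction=0.2,
                    noise_sd=0.0, seed=42, stack_shape=(40, 192, 192))
    truth = simulate_labels(cfg)
    stack = render_stack(truth, cfg)
    records = classify_stack(stack, apply_dissector=False)
    return cfg, truth, stack, records

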