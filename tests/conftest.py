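"""Shared fixtures: small synthetic fields that keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

from compartquant import SimulationConfig, generate_field


def small_sim_config(**overrides) -> SimulationConfig:
    """A compact field (8 cells, 288×288) with the default intensity model."""
    kwargs = dict(n_cells=8, field_size=(288, 288), seed=11)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_field(small_config):
    """(FieldImage, GroundTruth) for a compact control field."""
    return generate_field(small_config, "control")


@pytest.fixture(scope="session")
def small_recovery_field(small_config):
    return generate_field(small_config, "recovery_1h")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def overlap_matched_dice(pred_labels: np.ndarray, truth_labels: np.ndarray
                         ) -> list[float]:
    """Per-predicted-object Dice against the best-overlapping truth object."""
    out = []
    for pid in np.unique(pred_labels):
        if pid == 0:
            continue
        pm = pred_labels == pid
        ov = np.bincount(truth_labels[pm], minlength=truth_labels.max() + 1)
        if ov[1:].max() == 0:
            out.append(0.0)
            continue
        tm = truth_labels == (ov[1:].argmax() + 1)
        out.append(2 * np.logical_and(pm, tm).sum() / (pm.sum() + tm.sum()))
    return out
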