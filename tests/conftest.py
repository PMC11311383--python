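"""Shared fixtures: small, fast synthetic presets and feature helpers."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from domainmatch import DomainPreset, FeatureMatrix, generate_domain


@pytest.fixture(scope="session")
def tiny_preset() -> DomainPreset:
    """Single-egg 96x96 preset: fast to render, fine for feature/MMD tests."""
    return DomainPreset(name="tiny", eggs_per_image=(1, 1), washed=True,
                        motion_blur_sigma=0.0, background_level=60,
                        image_size=(96, 96))


@pytest.fixture(scope="session")
def small_multi_preset() -> DomainPreset:
    """2-3 eggs per 192x192 frame; exercises multi-egg placement cheaply."""
    return DomainPreset(name="multi", eggs_per_image=(2, 3), washed=True,
                        motion_blur_sigma=0.8, background_level=80,
                        image_size=(192, 192))


@pytest.fixture(scope="session")
def tiny_domain(tiny_preset):
    return generate_domain(tiny_preset, n_images=6, seed=7)


def feature_matrix(values, domain_id="x", config_hash="h") -> FeatureMatrix:
    """Build a FeatureMatrix directly from a 2-D array for kernel tests."""
    return FeatureMatrix(domain_id=domain_id,
                         values=np.asarray(values, dtype=float),
                         config_hash=config_hash)
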