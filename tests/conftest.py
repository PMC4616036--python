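"""Shared fixtures: stimulus definitions, tone builders, small populations."""

from __future__ import annotations

import numpy as np
import pytest

from crocvoice import (
    PopulationConfig,
    Waveform,
    default_allometry_model,
    design_contour,
    generate_dataset,
)

SR = 44100

#: printed design constraints of the three experimental stimuli:
#: (f_start, f_mean, f_end), all 160 ms
STIMULUS_SPECS = {
    "SYNTsmall": (630.0, 638.0, 350.0),
    "SYNTlarge": (300.0, 384.0, 200.0),
    "NOFM": (500.0, 500.0, 500.0),
}


def make_tone(freq: float, duration: float = 0.16, sr: int = SR,
              amplitude: float = 0.7) -> Waveform:
    t = np.arange(int(round(duration * sr))) / sr
    return Waveform(amplitude * np.sin(2 * np.pi * freq * t), sr, label=f"tone{freq:.0f}")


@pytest.fixture(scope="session")
def stimuli():
    """The three synthetic stimuli as (name -> (spec, contour))."""
    out = {}
    for name, (fs, fm, fe) in STIMULUS_SPECS.items():
        out[name] = design_contour(fs, fm, fe, 0.16, 0.25)
    return out


@pytest.fixture(scope="session")
def small_population():
    """A small two-species population with audio, for pipeline tests."""
    config = PopulationConfig(
        species_counts={"american_alligator": 4, "nile_crocodile": 4},
        calls_mean=4.0,
        calls_sd=1.0,
    )
    return config, generate_dataset(config, seed=1234)


@pytest.fixture(scope="session")
def feature_population():
    """A mid-sized five-species population without audio (analytic features)."""
    config = PopulationConfig(
        species_counts={
            "american_alligator": 20,
            "nile_crocodile": 16,
            "spectacled_caiman": 4,
            "morelets_crocodile": 4,
            "orinoco_crocodile": 5,
        },
        calls_mean=8.0,
        calls_sd=3.0,
    )
    return config, generate_dataset(config, seed=77, emit_audio=False)


@pytest.fixture
def zero_noise_model():
    return default_allometry_model(
        individual_sd=0.0, call_sd=0.0,
        centroid_individual_sd=0.0, centroid_call_sd=0.0, shape_jitter=0.0,
    )
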