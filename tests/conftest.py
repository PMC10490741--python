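"""Shared fixtures: a small synthetic study sized for fast tests.

The reduced study keeps the paradigm timing of the full design (7.5 s
trials at 250 Hz, imagery window 2.5-5 s) but uses 8 channels and 20
trials per class, a coarse scattering bank (Q1=2) on a 4-channel subset,
and a small hyperparameter grid, so an end-to-end run takes seconds
rather than minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from mibci.evaluation import TrainConfig
from mibci.model import PipelineConfig
from mibci.preprocess import TrialSet
from mibci.scattering import ScatteringConfig
from mibci.simulate import ClassSignature, ParadigmConfig, generate_session, to_trial_set

SMALL_MONTAGE = ("FC1", "FCz", "FC2", "C3", "Cz", "C4", "CP1", "CP2")

#: per-class ERD channels and coupled pairs used by the planted scenarios
ERD_CHANNELS = {"LH": ("C4",), "RH": ("C3",), "F": ("Cz",), "T": ("FCz",)}
COUPLED_PAIRS = {
    "LH": ("C4", "CP2"),
    "RH": ("C3", "CP1"),
    "F": ("Cz", "FCz"),
    "T": ("FC1", "FC2"),
}


def small_paradigm(**overrides) -> ParadigmConfig:
    defaults = dict(
        n_channels=len(SMALL_MONTAGE),
        montage=SMALL_MONTAGE,
        trials_per_class=20,
        artifact_rate=0.0,
    )
    defaults.update(overrides)
    return ParadigmConfig(**defaults)


def coupling_signatures(strength: float = 1.0, lag: float = np.pi / 2):
    """Class information planted only in inter-channel phase coupling."""
    return {
        cls: ClassSignature(coupling_pairs=((a, b, lag, strength),))
        for cls, (a, b) in COUPLED_PAIRS.items()
    }


def erd_signatures(depth: float = 0.6):
    """Class information planted only in channel-local beta-band amplitude."""
    return {
        cls: ClassSignature(erd_channels=chs, erd_band=(18.0, 22.0), erd_depth=depth)
        for cls, chs in ERD_CHANNELS.items()
    }


def both_signatures():
    """ERD and coupling plants together."""
    return {
        cls: ClassSignature(
            erd_channels=ERD_CHANNELS[cls],
            erd_band=(18.0, 22.0),
            erd_depth=0.6,
            coupling_pairs=((*COUPLED_PAIRS[cls], np.pi / 2, 1.0),),
        )
        for cls in ERD_CHANNELS
    }


def null_signatures():
    """Identical signatures: no class information at all."""
    return {cls: ClassSignature() for cls in ERD_CHANNELS}


def fast_pipeline_config() -> PipelineConfig:
    return PipelineConfig(
        tif_subset=("C3", "Cz", "C4", "FCz"),
        scattering=ScatteringConfig(wavelets_per_octave=(2, 1)),
        training=TrainConfig(
            c_grid=(1.0, 8.0),
            gamma_grid=(2.0**-5, 2.0**-3),
            s_grid=(30,),
            n_folds=5,
        ),
    )


def session_pair(signatures, seed: int, cfg: ParadigmConfig | None = None):
    cfg = cfg or small_paradigm()
    s1 = to_trial_set(generate_session(cfg, signatures, seed=seed, session_id="S1"))
    s2 = to_trial_set(generate_session(cfg, signatures, seed=seed + 1000, session_id="S2"))
    return s1, s2


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_session() -> TrialSet:
    """One default-signature session of the reduced study."""
    return to_trial_set(
        generate_session(small_paradigm(trials_per_class=6), seed=5, session_id="S1")
    )
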