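import dataclasses

import numpy as np
import pytest

import clsm
from clsm.cohort import BehaviorScores, SubjectRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_parcellation():
    # 3 dorsal-left + 4 ventral per hemisphere = 11 ROIs
    return clsm.make_parcellation(3, 4)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = clsm.CohortConfig(
        n_subjects=20,
        n_dorsal_left=3,
        n_ventral_per_hemi=4,
        n_timepoints=80,
        lesion_behavior_coef=0.01,
    )
    return clsm.generate_cohort(cfg, seed=7)


def behavior_from_latent(latent_200: float, latent_20: float = 15.0) -> BehaviorScores:
    """Map latent scores to subtests so composites equal the latents / 20."""
    frac = float(np.clip(latent_200 / 200.0, 0.0, 1.0))
    frac20 = float(np.clip(latent_20 / 20.0, 0.0, 1.0))
    return BehaviorScores(
        yes_no=round(frac * 60),
        word_recognition=round(frac * 60),
        sequential_commands=round(frac * 80),
        info_content=round(frac20 * 10),
        fluency=round(frac20 * 10),
    )


def with_behavior(subject: SubjectRecord, latent_200: float) -> SubjectRecord:
    """Copy a subject with its comprehension score replaced."""
    return dataclasses.replace(subject, behavior=behavior_from_latent(latent_200))
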