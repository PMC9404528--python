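"""Shared fixtures: tiny hand-built atlases and a small simulated one."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from miratlas.atlas_io import (
    CountMatrix,
    MiRNAAnnotation,
    NormalizedMatrix,
    RunMetadata,
)
from miratlas.simulate import AtlasSimConfig, simulate_atlas


@pytest.fixture
def tiny_counts() -> CountMatrix:
    df = pd.DataFrame(
        [[5, 10], [15, 30], [80, 160]],
        index=["m1", "m2", "m3"],
        columns=["r1", "r2"],
    )
    return CountMatrix(df)


@pytest.fixture
def tiny_meta() -> list[RunMetadata]:
    return [
        RunMetadata("r1", "s1", "studyA", "neuron", "brain"),
        RunMetadata("r2", "s2", "studyB", "tcell", "immune"),
    ]


@pytest.fixture
def tiny_annotation() -> list[MiRNAAnnotation]:
    return [
        MiRNAAnnotation("m1", "Mir-1_5p", "5p", "guide", "Bilateria", "fam1"),
        MiRNAAnnotation("m2", "Mir-1_3p", "3p", "star", "Bilateria", "fam1"),
        MiRNAAnnotation("m3", None, "5p", None, "other", "fam3"),
    ]


@pytest.fixture(scope="session")
def small_atlas():
    """A modest simulated atlas shared by read-only tests."""
    cfg = AtlasSimConfig(
        n_mirnas=120,
        n_cell_types=6,
        n_classes=3,
        n_studies=6,
        samples_per_study=6,
        nb_dispersion=0.2,
        batch_log_sd=0.3,
        planted_category_counts={"cell_specific": 12, "ubiquitous": 6},
        seed=11,
    )
    return simulate_atlas(cfg)


def as_normalized(df: pd.DataFrame, unit: str = "adjusted") -> NormalizedMatrix:
    prov = [] if unit == "raw" else ["test"]
    return NormalizedMatrix(df, unit, prov)
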