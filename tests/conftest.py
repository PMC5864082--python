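"""Shared fixtures: small catalogs, sheets and synthetic runs, all generated
programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from barfit.catalog import BarcodeCatalog, SampleRow, SampleSheet, StrainRecord
from barfit.sim import SimConfig, make_catalog, make_sample_sheet


def _tag(rng: np.random.Generator, length: int = 20) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture()
def catalog6() -> BarcodeCatalog:
    """Six strains with deterministic random 20-mer TAGs."""
    r = np.random.default_rng(42)
    classes = ["SUT", "CUT", "tRNA", "snoRNA", "SUT", "other"]
    records = [
        StrainRecord(
            strain_id=f"S{i:04d}", ncrna_name=f"{cls}{100 + i}", ncrna_class=cls,
            uptag=_tag(r), downtag=_tag(r))
        for i, cls in enumerate(classes)
    ]
    return BarcodeCatalog(records=records)


@pytest.fixture()
def sheet2() -> SampleSheet:
    return SampleSheet(rows=[
        SampleRow("Clim30_P_r1", "AAAAAA", "Clim30", "P", 1),
        SampleRow("Clim30_B_r1", "AAAAAT", "Clim30", "B", 1),
    ])


@pytest.fixture()
def sim_cfg() -> SimConfig:
    return SimConfig(n_strains=40, depth=500, error_rate=0.0, seed=0)


@pytest.fixture()
def sim_catalog(sim_cfg) -> BarcodeCatalog:
    return make_catalog(sim_cfg.n_strains, seed=sim_cfg.seed)


@pytest.fixture()
def sim_sheet(sim_cfg):
    return make_sample_sheet(("Clim30",), n_bio_reps=sim_cfg.n_bio_reps)
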