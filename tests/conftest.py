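"""Shared fixtures: simulated datasets at the study's default conditions.

The session-scoped datasets are generated once in memory; the small
on-disk dataset exercises every reader/writer and the pipeline driver.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dremap

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim() -> dremap.SimulatedDataset:
    """Default study conditions: depth 30, 50-bp jitter, 5% dropouts and
    decoys, 30% activation at fourfold, 40% motif planting."""
    return dremap.simulate(dremap.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noise_free_sim() -> dremap.SimulatedDataset:
    """Same design with every corruption channel off."""
    return dremap.simulate(dremap.SimulationConfig(seed=0).noise_free())


@pytest.fixture(scope="session")
def small_disk_dataset(tmp_path_factory) -> tuple:
    """A scaled-down dataset written to disk, plus its pipeline config."""
    outdir = tmp_path_factory.mktemp("dataset")
    ds = dremap.simulate(dremap.SimulationConfig(seed=0).small(), outdir=outdir)
    cfg_path = outdir / "pipeline.cfg"
    cfg_path.write_text(dremap.report.dataset_config_text(outdir))
    return ds, outdir, cfg_path


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_genes(spec: list[tuple[str, int, int, str]],
               ids: list[str] | None = None) -> list[dremap.GeneModel]:
    """Quick gene models from (scaffold, start, end, strand) tuples."""
    out = []
    for i, (scaf, start, end, strand) in enumerate(spec):
        gid = ids[i] if ids else f"g{i:03d}"
        out.append(dremap.GeneModel(
            gid, dremap.GenomicInterval(scaf, start, end, strand),
            [dremap.GenomicInterval(scaf, start, end, strand)]))
    return out


def make_peak(scaf: str, start: int, end: int, name: str = "p",
              signal: float = 1.0, summit: int | None = None) -> dremap.Peak:
    return dremap.Peak(dremap.GenomicInterval(scaf, start, end), name, signal, summit)
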