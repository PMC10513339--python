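"""Shared fixtures: small catalogs and a full-depth simulated WT pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import settings

import pirnakit as pk

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_catalog() -> pk.ReferenceCatalog:
    return pk.make_reference_catalog(5, 3, 12, 2, (500, 1000), seed=7)


@dataclass
class PipelineRun:
    """One simulated library pushed through trim -> align -> normalize."""

    catalog: pk.ReferenceCatalog
    params: pk.SmallRnaSimParams
    reads: list
    truth: pk.SimTruth
    library: pk.ProcessedLibrary
    alignments: list
    unmapped: int


def run_pipeline(catalog: pk.ReferenceCatalog, params: pk.SmallRnaSimParams,
                 align_seed: int = 0) -> PipelineRun:
    reads, truth = pk.simulate_small_rna_library(catalog, params)
    library = pk.process_library(reads)
    alignments, unmapped = pk.align_reads(library, catalog,
                                          max_mismatches=1, seed=align_seed)
    return PipelineRun(catalog, params, reads, truth, library, alignments,
                       unmapped)


@pytest.fixture(scope="session")
def study_catalog() -> pk.ReferenceCatalog:
    """Catalog sized like the simulated study conditions."""
    return pk.make_reference_catalog(25, 20, 12, 3, (500, 1000), seed=7)


@pytest.fixture(scope="session")
def wt_run_100k(study_catalog) -> PipelineRun:
    """Deep wild-type library at the study conditions (ping-pong 0.7,
    1U 0.9, 10A 0.8, 20% background)."""
    params = pk.SmallRnaSimParams(depth=100_000, pingpong_fraction=0.7,
                                  bias_1U=0.9, bias_10A=0.8,
                                  background_fraction=0.2, seed=1)
    return run_pipeline(study_catalog, params)
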