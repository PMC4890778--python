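"""Shared fixtures: one small synthetic study, generated once per session."""

from __future__ import annotations

import pytest

from mircold import pipeline, synthdata


SMALL = dict(seed=7, depth=4000, n_conserved=8, n_novel=5, n_contigs=12)


@pytest.fixture(scope="session")
def small_params() -> synthdata.SynthParams:
    return synthdata.SynthParams(**SMALL)


@pytest.fixture(scope="session")
def small_refs(small_params):
    """(References, GroundTruth) for the small study."""
    return synthdata.build_references(small_params)


@pytest.fixture(scope="session")
def small_demo(tmp_path_factory, small_params):
    """(RunReport, GroundTruth, PipelineConfig) for a small end-to-end run."""
    outdir = tmp_path_factory.mktemp("demo")
    return pipeline.demo(seed=small_params.seed, outdir=outdir, params=small_params)
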