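"""Shared fixtures: registry, panel, prebuilt search indexes, and the
session-scoped end-to-end scenario runs used by several test modules."""

from __future__ import annotations

import numpy as np
import pytest

from arpmap import chemdb, pipeline, synth
from arpmap.panel import protein_panel


@pytest.fixture(scope="session")
def registry():
    return chemdb.builtin_registry()


@pytest.fixture(scope="session")
def registry_by_id(registry):
    return {m.id: m for m in registry}


@pytest.fixture(scope="session")
def panel():
    return protein_panel()


@pytest.fixture(scope="session")
def default_indexes(panel, registry):
    return pipeline.build_indexes(panel, registry, pipeline.PipelineParams())


def run_scenario(config, seed, indexes):
    """Generate, render in memory, and run the full pipeline."""
    manifest = synth.generate_truth(config, seed)
    by_run = {
        rid: synth.render_run(manifest, rid, np.random.default_rng((seed, k)))
        for k, rid in enumerate(manifest.runs)
    }
    result = pipeline.run_pipeline(
        by_run, manifest.runs, manifest.proteins, indexes=indexes
    )
    return manifest, by_run, result


@pytest.fixture(scope="session")
def noiseless_e2e(default_indexes):
    """Noiseless 50-peptide scenario: the planted-truth recovery surface."""
    return run_scenario(synth.scenario("baseline"), 1, default_indexes)


@pytest.fixture(scope="session")
def noisy_e2e(default_indexes):
    """10-ppm jitter + background scenario."""
    return run_scenario(synth.scenario("noisy"), 1, default_indexes)


def planted_arp_ids(manifest):
    return {p.pid for p in manifest.planted if p.is_arp}


def result_pid(psm):
    return psm.peptidoform.sequence + "/" + ",".join(
        f"{pos}:{mid}" for pos, mid in psm.peptidoform.mods
    )
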