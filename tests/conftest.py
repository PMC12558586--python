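"""Shared fixtures: one synthetic study bundle plus a full pipeline run,
generated once per session and reused across test modules."""

from __future__ import annotations

import networkx as nx
import pytest

from regswitch.config import RunConfig
from regswitch.ontology import OntologyGraph, propagate_annotations
from regswitch.pipeline import run
from regswitch.synthetic import FixtureSpec, generate_fixture

STUDY_SEED = 11
PIPELINE_SEED = 7


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Noiseless planted study bundle: (input dir, ground truth)."""
    outdir = tmp_path_factory.mktemp("study")
    gt = generate_fixture(FixtureSpec(seed=STUDY_SEED), outdir)
    return outdir, gt


@pytest.fixture(scope="session")
def pipeline_run(study):
    """Full pipeline run over the study: (config, state, ground truth)."""
    outdir, gt = study
    cfg = RunConfig(outdir=str(outdir / "results"), n_perm=120,
                    seed=PIPELINE_SEED).resolve(outdir)
    state = run("all", cfg)
    return cfg, state, gt


def make_ontology(parents: dict[str, list[str]],
                  annotations: dict[str, list[str]] | None = None) -> OntologyGraph:
    """Build an annotated OntologyGraph directly from a child→parents map."""
    g = nx.DiGraph()
    for child, plist in parents.items():
        g.add_node(child, name=child)
        for p in plist:
            g.add_node(p, name=p)
            g.add_edge(child, p, relation="is_a")
    onto = OntologyGraph(graph=g)
    if annotations:
        propagate_annotations(onto, annotations)
    return onto
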