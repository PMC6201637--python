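"""Shared fixtures: the toy instance and its (session-cached) flux scores."""

import pytest

import regutarget as rt


@pytest.fixture(scope="session")
def toy():
    return rt.make_toy_instance(seed=1)


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("toy_inputs")
    return rt.make_toy_instance(seed=1, outdir=outdir)


@pytest.fixture(scope="session")
def toy_rap(toy):
    ranges = rt.flux_variability(toy.model, growth_fraction=0.5)
    return rt.compute_nrap(toy.model, ranges, growth_fraction=0.5)


@pytest.fixture(scope="session")
def toy_gap(toy, toy_rap):
    return rt.compute_ngap(toy_rap, toy.model.gpr_factor_table())


@pytest.fixture(scope="session")
def toy_scored_interactions(toy):
    scored = rt.compute_nrs(toy.trn, toy.expression)
    return rt.filter_sign_consistency(scored)


def split_tr_edges(interactions):
    """(TR->gene edges, TR->TR edges) given the scored interaction list."""
    trs = {ia.regulator for ia in interactions}
    gene_edges = [ia for ia in interactions if ia.target not in trs]
    tr_edges = [ia for ia in interactions if ia.target in trs]
    return gene_edges, tr_edges
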