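import textwrap

import pytest

from gothemes import (
    FixtureSpec,
    attach_annotations,
    augment,
    fit_null,
    generate,
    parse_obo,
    propagate,
    prune_unannotated,
    read_gaf,
    two_cluster_spec,
    weight_all_edges,
)


def write_obo(path, body: str) -> str:
    """Write an OBO file with a standard header plus the given term stanzas."""
    header = textwrap.dedent(
        """\
        format-version: 1.2
        default-namespace: biological_process

        """
    )
    path.write_text(header + textwrap.dedent(body))
    return str(path)


def write_gaf(path, rows) -> str:
    """Write a minimal 17-column GAF 2.2 file from (gene, term[, evidence])."""
    lines = ["!gaf-version: 2.2"]
    for row in rows:
        gene, term = row[0], row[1]
        evidence = row[2] if len(row) > 2 else "IEA"
        cols = ["SYN", gene, gene, "", term, "REF:1", evidence, "", "P",
                gene, "", "protein", "taxon:9606", "20260101", "SYN", "", ""]
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")
    return str(path)


CHAIN_OBO = """\
    [Term]
    id: T:A
    name: alpha process

    [Term]
    id: T:B
    name: beta process
    is_a: T:A ! alpha process

    [Term]
    id: T:C
    name: gamma process
    is_a: T:B ! beta process
    """

DIAMOND_OBO = """\
    [Term]
    id: T:A
    name: top process

    [Term]
    id: T:B
    name: left process
    is_a: T:A ! top process

    [Term]
    id: T:C
    name: right process
    is_a: T:A ! top process

    [Term]
    id: T:D
    name: bottom process
    is_a: T:B ! left process
    is_a: T:C ! right process
    """


@pytest.fixture
def chain_graph(tmp_path):
    """A <- B <- C chain with one gene on the leaf, propagated."""
    obo = write_obo(tmp_path / "chain.obo", CHAIN_OBO)
    gaf = write_gaf(tmp_path / "chain.gaf", [("g1", "T:C")])
    g = parse_obo(obo)
    attach_annotations(g, read_gaf(gaf))
    return propagate(g)


@pytest.fixture
def diamond_graph(tmp_path):
    """Diamond DAG (D under both B and C) with one gene on D, propagated."""
    obo = write_obo(tmp_path / "diamond.obo", DIAMOND_OBO)
    gaf = write_gaf(tmp_path / "diamond.gaf", [("g1", "T:D")])
    g = parse_obo(obo)
    attach_annotations(g, read_gaf(gaf))
    return propagate(g)


def build_pipeline(spec: FixtureSpec, tmpdir, metric="ic", scheme="augmented",
                   null_sizes=range(5, 51, 5), null_reps=60, null_seed=None):
    """Generate a fixture bundle and run the full pipeline on it."""
    bundle = generate(spec, tmpdir)
    g = parse_obo(bundle.obo)
    attach_annotations(g, read_gaf(bundle.gaf))
    propagate(g)
    g = prune_unannotated(g)
    wg = weight_all_edges(g, metric)
    graph = augment(wg) if scheme == "augmented" else wg
    null = fit_null(graph, sizes=null_sizes, reps=null_reps,
                    seed=spec.seed + 1 if null_seed is None else null_seed)
    return bundle, g, graph, null


@pytest.fixture(scope="session")
def generic_pipeline(tmp_path_factory):
    """Standard depth-5 fixture with IC weights, augmented scheme and a
    fitted null; shared across tests that only read from it."""
    tmpdir = tmp_path_factory.mktemp("generic")
    return build_pipeline(FixtureSpec(seed=5), tmpdir)


@pytest.fixture(scope="session")
def two_cluster_pipeline(tmp_path_factory):
    """The two-planted-cluster demonstration fixture (seed 1), full pipeline."""
    tmpdir = tmp_path_factory.mktemp("twocluster")
    return build_pipeline(two_cluster_spec(1), tmpdir, null_reps=100)
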