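import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycomotif.exceptions import EmptyFilterError, ValidationError
from mycomotif.io import parse_newick
from mycomotif.networks import (
    TripartiteNetwork,
    community_psv,
    fungal_similarity,
    normalized_degree,
    plant_plant_overlap,
    psv,
    restrict_to_shared_fungi,
)

from conftest import make_net, random_net


# ---------- tripartite container ----------

def test_network_rejects_misaligned_columns():
    mh = pd.DataFrame([[1, 0]], index=["M0"], columns=["f0", "f1"])
    auto = pd.DataFrame([[1, 0]], index=["A0"], columns=["f1", "f0"])
    with pytest.raises(ValidationError):
        TripartiteNetwork(mh=mh, auto=auto)


def test_network_rejects_non_binary():
    with pytest.raises(ValidationError):
        make_net([[2, 0]], [[1, 1]])


# ---------- normalised degree ----------

def test_normalized_degree_rows_and_columns(toy_net):
    nd_plants = normalized_degree(toy_net.auto, axis="rows")
    assert nd_plants["A0"] == pytest.approx(3 / 4)
    assert nd_plants["A2"] == pytest.approx(1 / 4)
    nd_fungi = normalized_degree(toy_net.auto, axis="columns")
    assert nd_fungi["f1"] == pytest.approx(2 / 3)


def test_normalized_degree_conservation(toy_net):
    # sum(deg_i) computed either way equals the number of links
    for block in (toy_net.mh, toy_net.auto):
        links = int(block.to_numpy().sum())
        assert normalized_degree(block, "rows").sum() * block.shape[1] == pytest.approx(links)
        assert normalized_degree(block, "columns").sum() * block.shape[0] == pytest.approx(links)


# ---------- psv ----------

def test_psv_star_tree_is_one():
    tree = parse_newick("(A:1,B:1,C:1,D:1);")
    result = psv(["A", "B", "C", "D"], tree)
    assert result.psv == pytest.approx(1.0)


def test_psv_identical_pair_is_zero():
    # two tips with zero-length terminal branches under a shared stem
    tree = parse_newick("((A:0,B:0):1,C:2);")
    assert psv(["A", "B"], tree).psv == pytest.approx(0.0)


def test_psv_undefined_below_two_members():
    tree = parse_newick("(A:1,B:1);")
    result = psv(["A"], tree)
    assert result.psv is None and not result.defined


def _naive_psv(newick: str, members: list[str]) -> float:
    """Independent oracle: correlations from root-to-MRCA path lengths found
    by walking parent chains."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    nodes = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}

    def root_path(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path[::-1]

    def depth_along(path, upto):
        total = 0.0
        for nd in path[1: upto + 1]:
            total += nd.edge.length or 0.0
        return total

    n = len(members)
    corr = np.eye(n)
    paths = {m: root_path(nodes[m]) for m in members}
    depths = {m: depth_along(paths[m], len(paths[m]) - 1) for m in members}
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[members[i]], paths[members[j]]
            shared_nodes = 0
            for a, b in zip(pi, pj):
                if a is b:
                    shared_nodes += 1
                else:
                    break
            shared_len = depth_along(pi, shared_nodes - 1)
            corr[i, j] = corr[j, i] = shared_len / np.sqrt(
                depths[members[i]] * depths[members[j]]
            )
    return float((n * np.trace(corr) - corr.sum()) / (n * (n - 1)))


@pytest.mark.parametrize(
    "newick,members",
    [
        ("((A:1,B:2):1,(C:1.5,(D:0.5,E:0.7):1):2,F:4);", ["A", "C", "D", "E"]),
        ("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);", ["A", "B", "C", "D", "E"]),
        ("((A:3,B:1):0.5,(C:2,D:2):1.5);", ["A", "B", "C", "D"]),
    ],
)
def test_psv_matches_naive_oracle(newick, members):
    expected = _naive_psv(newick, members)
    assert psv(members, parse_newick(newick)).psv == pytest.approx(expected, abs=1e-10)


def test_psv_invariances():
    newick = "(((A:1,B:1):1,C:2):1,(D:2,E:2):1);"
    members = ["A", "B", "D", "E"]
    base = psv(members, parse_newick(newick)).psv
    # uniform branch scaling
    scaled = "(((A:10,B:10):10,C:20):10,(D:20,E:20):10);"
    assert psv(members, parse_newick(scaled)).psv == pytest.approx(base, abs=1e-12)
    # tip relabeling
    relabeled = "(((X:1,Y:1):1,C:2):1,(W:2,V:2):1);"
    assert psv(["X", "Y", "W", "V"], parse_newick(relabeled)).psv == pytest.approx(
        base, abs=1e-12
    )


def test_psv_matches_picante():
    """Cross-check against the reference implementation in R (picante)."""
    newick = "(((A:1,B:1):1,C:2):1,(D:2,E:2):1);"
    script = (
        'suppressMessages(library(picante));'
        f'tree <- ape::read.tree(text="{newick}");'
        'comm <- matrix(c(1,1,1,1,0, 1,1,0,0,1), nrow=2, byrow=TRUE,'
        ' dimnames=list(c("s1","s2"), c("A","B","C","D","E")));'
        'cat(sprintf("%.12f", psv(comm, tree)$PSVs[1]))'
    )
    proc = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
    )
    assert proc.returncode == 0, proc.stderr
    expected = float(proc.stdout.strip())
    ours = psv(["A", "B", "C", "D"], parse_newick(newick)).psv
    assert ours == pytest.approx(expected, abs=1e-8)


def test_community_psv_per_row(toy_net):
    tree = parse_newick("((f0:1,f1:1):1,(f2:1,f3:1):1);")
    results = {r.plant_id: r for r in community_psv(toy_net.auto, tree)}
    assert results["A2"].psv is None  # single fungus
    assert results["A1"].n == 2


# ---------- plant-plant overlap ----------

def test_overlap_edges_and_types(toy_net):
    edges = plant_plant_overlap(toy_net)
    lookup = {
        tuple(sorted((r.plant_1, r.plant_2))): (r.weight, r.pair_type)
        for r in edges.itertuples()
    }
    assert lookup[("A0", "M0")] == (2, "MH-A")
    assert lookup[("M0", "M1")] == (1, "MH-MH")
    assert ("A2", "M0") not in lookup  # disjoint fungal sets


def test_overlap_matches_bruteforce_sets():
    rng = np.random.default_rng(3)
    net = random_net(rng, 3, 5, 7, p=0.5)
    edges = plant_plant_overlap(net)
    stacked = net.stacked()
    sets = {p: set(stacked.columns[stacked.loc[p] > 0]) for p in stacked.index}
    expected = {
        tuple(sorted((p, q))): len(sets[p] & sets[q])
        for i, p in enumerate(stacked.index)
        for q in stacked.index[i + 1 :]
        if sets[p] & sets[q]
    }
    got = {
        tuple(sorted((r.plant_1, r.plant_2))): r.weight for r in edges.itertuples()
    }
    assert got == expected


# ---------- fungal similarity ----------

def test_similarity_formulas_on_known_sets():
    # fungus x: plants {A,B}; fungus y: plants {B,C,D}
    inc = pd.DataFrame(
        {"x": [1, 1, 0, 0], "y": [0, 1, 1, 1]}, index=list("ABCD")
    )
    jac = fungal_similarity(inc, "jaccard").matrix
    ove = fungal_similarity(inc, "overlap").matrix
    assert jac.loc["x", "y"] == pytest.approx(0.25)
    assert ove.loc["x", "y"] == pytest.approx(0.5)


def test_similarity_identical_and_disjoint():
    inc = pd.DataFrame({"x": [1, 1, 0], "y": [1, 1, 0], "z": [0, 0, 1]})
    for measure in ("jaccard", "overlap"):
        sim = fungal_similarity(inc, measure).matrix
        assert sim.loc["x", "y"] == pytest.approx(1.0)
        assert sim.loc["x", "z"] == pytest.approx(0.0)
        assert np.allclose(np.diag(sim), 1.0)


def test_similarity_excludes_zero_degree_fungi():
    inc = pd.DataFrame({"x": [1, 0], "y": [0, 0]})
    sim = fungal_similarity(inc, "jaccard")
    assert list(sim.matrix.index) == ["x"]


@settings(derandomize=True, deadline=None, max_examples=40)
@given(st.integers(0, 2**32 - 1))
def test_overlap_at_least_jaccard(seed):
    rng = np.random.default_rng(seed)
    inc = pd.DataFrame(
        (rng.random((6, 8)) < 0.5).astype(int),
        columns=[f"f{i}" for i in range(8)],
    )
    inc = inc.loc[:, inc.sum(axis=0) > 0]
    if inc.shape[1] < 2:
        return
    jac = fungal_similarity(inc, "jaccard").matrix.to_numpy()
    ove = fungal_similarity(inc, "overlap").matrix.to_numpy()
    assert (ove >= jac - 1e-12).all()
    assert (jac >= -1e-12).all() and (ove <= 1 + 1e-12).all()


# ---------- shared-fungi restriction ----------

def test_restrict_to_shared_fungi_examples(toy_net):
    shared = restrict_to_shared_fungi(toy_net)
    # f3 only in autotrophs, f0 is in both (M0 and A0)
    assert "f3" not in shared.fungi
    assert set(shared.fungi) == {"f0", "f1", "f2"}
    assert "A2" not in shared.auto.index  # left with no fungus


def test_restrict_matches_bruteforce_and_errors_when_empty():
    rng = np.random.default_rng(5)
    net = random_net(rng, 4, 6, 10, p=0.3)
    expected = {
        f
        for f in net.fungi
        if net.mh[f].sum() > 0 and net.auto[f].sum() > 0
    }
    if expected:
        assert set(restrict_to_shared_fungi(net).fungi) == expected
    disjoint = make_net([[1, 0]], [[0, 1]])
    with pytest.raises(EmptyFilterError):
        restrict_to_shared_fungi(disjoint)
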