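import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycomotif.exceptions import NullModelError, ValidationError
from mycomotif.motifs import (
    DiamondMotifResult,
    DiamondMotifTest,
    count_diamond_modules,
    count_diamonds_bruteforce,
    motif_null_test,
    null_probabilities,
    randomize_tripartite,
    sample_null_network,
)

from conftest import make_net, random_net


# ---------- counting ----------

def test_minimal_diamond_counts_one(minimal_diamond):
    assert count_diamond_modules(minimal_diamond) == 1


def test_single_shared_fungus_is_not_a_module():
    # a plant pair sharing one fungus (not a pair of fungi) must not count
    net = make_net([[1, 0]], [[1, 0]])
    assert count_diamond_modules(net) == 0


def test_complete_network_closed_form():
    m, a, f = 3, 4, 6
    net = make_net([[1] * f] * m, [[1] * f] * a)
    assert count_diamond_modules(net) == (f * (f - 1) // 2) * m * a


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    st.integers(1, 6), st.integers(1, 6), st.integers(2, 10),
    st.integers(0, 2**32 - 1),
)
def test_pairsum_equals_bruteforce(n_mh, n_auto, n_fungi, seed):
    rng = np.random.default_rng(seed)
    net = random_net(rng, n_mh, n_auto, n_fungi, p=float(rng.uniform(0.2, 0.8)))
    assert count_diamond_modules(net) == count_diamonds_bruteforce(net)


def test_adding_a_link_never_decreases_count():
    rng = np.random.default_rng(0)
    net = random_net(rng, 3, 4, 6, p=0.4)
    base = count_diamond_modules(net)
    zeros = np.argwhere(net.mh.to_numpy() == 0)
    if len(zeros):
        i, j = zeros[0]
        mh = net.mh.copy()
        mh.iloc[i, j] = 1
        richer = make_net(mh.values.tolist(), net.auto.values.tolist())
        assert count_diamond_modules(richer) >= base


# ---------- null model ----------

def test_null_probabilities_all_ones_and_checkerboard():
    ones = pd.DataFrame(np.ones((3, 4), dtype=int))
    assert np.allclose(null_probabilities(ones).probs, 1.0)
    eye = pd.DataFrame(np.eye(2, dtype=int))
    assert np.allclose(null_probabilities(eye).probs, 0.5)


@settings(derandomize=True, deadline=None, max_examples=40)
@given(st.integers(0, 2**32 - 1))
def test_null_probability_mass_equals_links(seed):
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame((rng.random((5, 8)) < rng.uniform(0.2, 0.9)).astype(int))
    if mat.to_numpy().sum() == 0:
        return
    spec = null_probabilities(mat)
    assert spec.probs.sum() == pytest.approx(mat.to_numpy().sum(), abs=1e-9)
    assert (spec.probs >= 0).all() and (spec.probs <= 1).all()


def test_sample_all_ones_spec_is_deterministic():
    spec = null_probabilities(pd.DataFrame(np.ones((3, 3), dtype=int)))
    draw = sample_null_network(spec, np.random.default_rng(0))
    assert (draw.to_numpy() == 1).all()


def test_sample_cell_means_match_probabilities():
    # dense spec where empties are impossible, so rejection never biases cells
    mat = pd.DataFrame(
        [[1, 1, 0, 1], [1, 0, 1, 1], [0, 1, 1, 1]]
    )
    spec = null_probabilities(mat)
    rng = np.random.default_rng(1)
    total = np.zeros(spec.probs.shape)
    n = 10_000
    links = []
    for _ in range(n):
        draw = sample_null_network(spec, rng, forbid_empty="none").to_numpy()
        total += draw
        links.append(draw.sum())
    freq = total / n
    se = np.sqrt(spec.probs * (1 - spec.probs) / n)
    assert (np.abs(freq - spec.probs) <= 3 * np.maximum(se, 1e-4)).all()
    # conservation: mean links ~ empirical link count
    se_links = np.sqrt((spec.probs * (1 - spec.probs)).sum() / n)
    assert abs(np.mean(links) - mat.to_numpy().sum()) < 3 * se_links


def test_sample_rejects_on_pathological_spec():
    from mycomotif.motifs import NullModelSpec

    spec = NullModelSpec(
        probs=np.full((3, 3), 1e-6),
        row_degrees=np.zeros(3, dtype=int),
        col_degrees=np.zeros(3, dtype=int),
        row_ids=("a", "b", "c"),
        col_ids=("x", "y", "z"),
    )
    with pytest.raises(NullModelError):
        sample_null_network(spec, np.random.default_rng(0), max_retries=50)


def test_randomize_preserves_alignment_and_block_independence(toy_net):
    rng = np.random.default_rng(2)
    rand = randomize_tripartite(toy_net, rng)
    assert list(rand.mh.columns) == list(toy_net.mh.columns)
    assert list(rand.auto.columns) == list(toy_net.auto.columns)
    # the autotroph spec is computed from the empirical block, not the draw
    spec_a = null_probabilities(toy_net.auto)
    assert spec_a.probs.sum() == pytest.approx(toy_net.auto.to_numpy().sum())


def test_randomized_degrees_match_null_expectation():
    """Row degrees of randomised blocks are centred on the null spec's row
    sums (the additive null shrinks individual degrees toward the block
    mean; only the TOTAL link count is conserved exactly in expectation)."""
    rng = np.random.default_rng(3)
    net = random_net(rng, 4, 8, 12, p=0.5)
    reps = 2000
    deg = np.zeros(4)
    links = []
    for _ in range(reps):
        draw = randomize_tripartite(net, rng).mh
        deg += draw.sum(axis=1).to_numpy()
        links.append(draw.to_numpy().sum())
    spec = null_probabilities(net.mh)
    se = np.sqrt((spec.probs * (1 - spec.probs)).sum(axis=1) / reps)
    assert (np.abs(deg / reps - spec.probs.sum(axis=1)) <= 4 * se).all()
    se_links = np.sqrt((spec.probs * (1 - spec.probs)).sum() / reps)
    assert abs(np.mean(links) - net.mh.to_numpy().sum()) <= 4 * se_links


# ---------- the test object ----------

def test_result_z_p_and_interval_semantics():
    res = DiamondMotifResult(observed=10, null_counts=(8, 10, 12, 10), scope="all")
    assert res.null_mean == pytest.approx(10.0)
    assert res.z == pytest.approx(0.0)
    assert res.ci_low <= res.ci_high
    assert 0 < res.p_empirical <= 1
    flat = DiamondMotifResult(observed=5, null_counts=(3, 3, 3), scope="all")
    assert flat.z is None  # constant null: undefined z, p still reported
    assert flat.p_empirical == pytest.approx(1 / 4)
    assert flat.overrepresented


def test_fit_is_deterministic_under_seed(toy_net):
    r1 = motif_null_test(toy_net, "all", n_null=50, rng=123)
    r2 = motif_null_test(toy_net, "all", n_null=50, rng=123)
    assert r1 == r2


def test_shared_scope_restricts_before_null_construction(toy_net):
    model = DiamondMotifTest(toy_net, scope="shared")
    assert set(model.net.fungi) == {"f0", "f1", "f2"}
    # null probabilities recomputed on the restricted blocks
    assert model.specs[1].probs.shape[1] == 3
    # observed modules are identical across scopes: every diamond fungus is shared
    assert model.observed == DiamondMotifTest(toy_net, scope="all").observed


def test_refit_null_flag_is_conservative_on_null_data():
    """Networks drawn from a fitted null, re-tested with a refitted null,
    should rarely be flagged overrepresented."""
    rng = np.random.default_rng(4)
    template = random_net(rng, 5, 10, 20, p=0.35)
    flags = 0
    for _ in range(40):
        synth = randomize_tripartite(template, rng)
        flags += motif_null_test(synth, "all", n_null=100, rng=rng).overrepresented
    assert flags / 40 <= 0.15


def test_fit_rejects_bad_arguments(toy_net):
    with pytest.raises(ValidationError):
        DiamondMotifTest(toy_net, scope="everything")
    with pytest.raises(ValidationError):
        DiamondMotifTest(toy_net).fit(n_null=1)
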