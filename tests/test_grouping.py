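"""The three grouping algorithms and representative selection."""

import pytest

from umidedup.encoding import encode
from umidedup.errors import InvalidQueryError, InvalidStateError
from umidedup.grouping import (
    adjacency,
    cluster,
    directional,
    directional_threshold,
    run_grouping,
    select_representative,
)
from umidedup.index import BACKENDS, build_index
from umidedup.index.core import NaiveIndex, UMIFreqTable
from umidedup.simulate import simulate_dataset

from conftest import canonical, make_table


def _run(algo, table, k=1, backend="naive", epsilon=0.5):
    return run_grouping(algo, table, build_index(backend, table, k), k, epsilon)


def test_cluster_bridges_across_the_gap(bridging_table):
    # d(AAAA, AATT) = 2 > k, but AAAT is within 1 of both
    result = _run("cluster", bridging_table)
    assert result.n_groups == 1
    assert result.groups[0].representative.seq == "AAAA"
    assert result.groups[0].total_frequency == 18


def test_adjacency_claims_only_direct_neighbors(bridging_table):
    result = _run("adjacency", bridging_table)
    members = [tuple(sorted(u.seq for u in g.members)) for g in result.groups]
    assert sorted(members) == [("AAAA", "AAAT"), ("AATT",)]


def test_directional_recurses_down_the_frequency_chain():
    table = make_table({"AAAA": 10, "AAAT": 5, "AATT": 2})
    result = _run("directional", table)
    # 5 <= 0.5*(10+1) admits AAAT; from AAAT, 2 <= 0.5*(5+1) admits AATT
    assert result.n_groups == 1


def test_directional_inequality_boundary():
    # 6 > 0.5*(10+1) = 5.5: AAAT stays its own group
    result = _run("directional", make_table({"AAAA": 10, "AAAT": 6}))
    assert result.n_groups == 2
    # exactly at the boundary the neighbor is admitted (<=)
    result = _run("directional", make_table({"AAAA": 9, "AAAT": 5}))
    assert result.n_groups == 1


def test_directional_threshold_matches_umi_tools_rule():
    # eps=0.5 encodes 2 f(v) - 1 <= f(u)
    for fu in range(1, 30):
        for fv in range(1, 30):
            assert (fv <= directional_threshold(fu, 0.5)) == (2 * fv - 1 <= fu)


def test_directional_epsilon_validated(bridging_table):
    idx = NaiveIndex(bridging_table, 1)
    with pytest.raises(InvalidQueryError):
        directional(bridging_table, idx, 1, epsilon=1.5)


def test_empty_table_gives_empty_result():
    table = UMIFreqTable({})
    assert _run("cluster", table).n_groups == 0


def test_k_at_least_m_collapses_everything():
    table = make_table({"AAAA": 3, "TTTT": 2, "CGCG": 1})
    assert _run("cluster", table, k=4).n_groups == 1


def test_all_distant_umis_stay_singletons():
    table = make_table({"AAAA": 3, "TTTT": 2, "CGCG": 1})
    result = _run("adjacency", table, k=1)
    assert result.n_groups == 3


def test_select_representative():
    table = make_table({"AAAA": 10, "AAAT": 5})
    assert select_representative(table.keys(), table).seq == "AAAA"
    tied = make_table({"AAAT": 5, "AAAA": 5})
    assert select_representative(tied.keys(), tied).seq == "AAAA"  # lexicographic
    single = make_table({"CCCC": 1})
    assert select_representative(single.keys(), single).seq == "CCCC"
    with pytest.raises(InvalidQueryError):
        select_representative([], table)


def test_consumed_index_rejected(bridging_table):
    idx = NaiveIndex(bridging_table, 1)
    idx.remove_near(encode("AAAA"), 1)
    with pytest.raises(InvalidStateError):
        cluster(bridging_table, idx, 1)


@pytest.mark.parametrize("algo", ["cluster", "adjacency", "directional"])
def test_partition_property_on_simulated_data(algo):
    ds = simulate_dataset(40, 8, 1, seed=11)
    result = _run(algo, ds.table)
    members = [g.members for g in result.groups]
    assert sum(len(m) for m in members) == len(ds.table)
    assert set().union(*members) == set(ds.table.keys())
    for g in result.groups:
        assert g.representative in g.members


def test_cluster_never_more_groups_than_adjacency():
    for seed in range(5):
        ds = simulate_dataset(30, 8, 1, seed=seed)
        assert _run("cluster", ds.table).n_groups <= _run("adjacency", ds.table).n_groups


@pytest.mark.parametrize("algo", ["cluster", "adjacency", "directional"])
def test_output_invariant_to_backend(algo):
    ds = simulate_dataset(25, 10, 1, seed=5)
    reference = canonical(_run(algo, ds.table, backend="naive"))
    for backend in sorted(BACKENDS):
        assert canonical(_run(algo, ds.table, backend=backend)) == reference


def test_grouping_is_deterministic():
    ds1 = simulate_dataset(30, 8, 1, seed=2)
    ds2 = simulate_dataset(30, 8, 1, seed=2)
    for algo in ("cluster", "adjacency", "directional"):
        assert canonical(_run(algo, ds1.table)) == canonical(_run(algo, ds2.table))


def test_directional_recovers_center_count():
    ds = simulate_dataset(100, 10, 1, seed=42)
    result = _run("directional", ds.table, backend="ngrambk")
    assert abs(result.n_groups - 100) <= 2
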