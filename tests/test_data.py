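"""Trial-data types, readers, connectivity and network summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eventnma import (
    EvidenceNetwork,
    RateArm,
    RiskArm,
    Study,
    Treatment,
    read_network,
    simulate_network,
    summarize_network,
    validate_connectivity,
    write_network,
)
from eventnma.data import WEEKS_PER_YEAR, network_to_tables
from eventnma.errors import CodingError, DataError, SchemaError
from eventnma.simulate import GeneratorConfig


def _risk_study(sid, pairs, followup=1.0):
    return Study(
        sid,
        risk_arms=tuple(RiskArm(sid, t, r, n, followup) for t, r, n in pairs),
    )


class TestInvariants:
    def test_more_events_than_patients_rejected(self):
        with pytest.raises(DataError):
            RiskArm("S1", 1, events=5, n=3, followup=1.0)

    def test_nonpositive_exposure_rejected(self):
        with pytest.raises(DataError):
            RateArm("S1", 1, events=5, exposure=0.0)

    def test_single_arm_study_rejected(self):
        with pytest.raises(DataError):
            Study("S1", risk_arms=(RiskArm("S1", 1, 1, 10, 1.0),))

    def test_mismatched_followup_within_study_rejected(self):
        with pytest.raises(DataError):
            Study(
                "S1",
                risk_arms=(
                    RiskArm("S1", 1, 1, 10, 1.0),
                    RiskArm("S1", 2, 1, 10, 2.0),
                ),
            )

    def test_both_formats_must_cover_same_treatments(self):
        with pytest.raises(DataError):
            Study(
                "S1",
                risk_arms=(
                    RiskArm("S1", 1, 1, 10, 1.0),
                    RiskArm("S1", 2, 1, 10, 1.0),
                ),
                rate_arms=(
                    RateArm("S1", 1, 2, 10.0),
                    RateArm("S1", 3, 2, 10.0),
                ),
            )

    def test_noncontiguous_treatment_codes_rejected(self):
        with pytest.raises(CodingError):
            EvidenceNetwork({1: Treatment(1, "a"), 3: Treatment(3, "c")}, [])


class TestReaders:
    def test_two_study_chain_builds_three_node_network(self, tmp_path):
        pd.DataFrame(
            {
                "study_id": ["AB", "AB", "BC", "BC"],
                "treatment_code": [1, 2, 2, 3],
                "r": [5, 4, 3, 2],
                "n": [50, 50, 40, 40],
                "followup": [1.0, 1.0, 0.5, 0.5],
                "followup_unit": ["years"] * 4,
            }
        ).to_csv(tmp_path / "risk.csv", index=False)
        net = read_network(tmp_path / "risk.csv", format="risk")
        graph = net.comparison_graph("risk")
        assert sorted(graph.nodes) == [1, 2, 3]
        assert sorted(graph.edges) == [(1, 2), (2, 3)]

    def test_invalid_row_reported_by_position(self, tmp_path):
        pd.DataFrame(
            {
                "study_id": ["S1", "S1"],
                "treatment_code": [1, 2],
                "r": [5, 5],
                "n": [50, 3],
                "followup": [1.0, 1.0],
                "followup_unit": ["years"] * 2,
            }
        ).to_csv(tmp_path / "risk.csv", index=False)
        with pytest.raises(DataError, match="row 1"):
            read_network(tmp_path / "risk.csv", format="risk")

    def test_missing_column_is_schema_error(self, tmp_path):
        pd.DataFrame({"study_id": ["S1"], "treatment_code": [1]}).to_csv(
            tmp_path / "risk.csv", index=False
        )
        with pytest.raises(SchemaError, match="missing columns"):
            read_network(tmp_path / "risk.csv", format="risk")

    def test_unknown_treatment_code_is_coding_error(self, tmp_path):
        pd.DataFrame({"code": [1, 2], "label": ["a", "b"]}).to_csv(
            tmp_path / "treatments.csv", index=False
        )
        pd.DataFrame(
            {
                "study_id": ["S1", "S1"],
                "treatment_code": [1, 9],
                "r": [5, 5],
                "n": [50, 50],
                "followup": [1.0, 1.0],
                "followup_unit": ["years"] * 2,
            }
        ).to_csv(tmp_path / "risk.csv", index=False)
        with pytest.raises(CodingError, match="9"):
            read_network(tmp_path, format="risk")

    def test_followup_units_converted_to_years(self, tmp_path):
        pd.DataFrame(
            {
                "study_id": ["S1", "S1"],
                "treatment_code": [1, 2],
                "r": [5, 5],
                "n": [50, 50],
                "followup": [26.09, 26.09],
                "followup_unit": ["weeks", "weeks"],
            }
        ).to_csv(tmp_path / "risk.csv", index=False)
        net = read_network(tmp_path / "risk.csv", format="risk")
        assert net.studies[0].followup == pytest.approx(26.09 / WEEKS_PER_YEAR)

    def test_round_trip_is_identity(self, tmp_path, paper_like_sim):
        write_network(paper_like_sim.network, tmp_path)
        reread = read_network(tmp_path, format="mixed")
        orig = network_to_tables(paper_like_sim.network)
        back = network_to_tables(reread)
        for key in ("risk", "rate", "treatments"):
            sort_by = list(orig[key].columns[:2])
            pd.testing.assert_frame_equal(
                orig[key].sort_values(sort_by).reset_index(drop=True),
                back[key].sort_values(sort_by).reset_index(drop=True),
            )
        # a second write -> read cycle is a fixed point, file for file
        (tmp_path / "again").mkdir()
        write_network(reread, tmp_path / "again")
        third = read_network(tmp_path / "again", format="mixed")
        for key, df in network_to_tables(reread).items():
            pd.testing.assert_frame_equal(df, network_to_tables(third)[key])


class TestConnectivity:
    def test_chain_is_one_component(self):
        net = EvidenceNetwork(
            {k: Treatment(k, str(k)) for k in (1, 2, 3)},
            [
                _risk_study("AB", [(1, 2, 50), (2, 3, 50)]),
                _risk_study("BC", [(2, 2, 50), (3, 3, 50)]),
            ],
        )
        assert validate_connectivity(net, "risk") == [{1, 2, 3}]

    def test_disjoint_pairs_are_two_components(self):
        net = EvidenceNetwork(
            {k: Treatment(k, str(k)) for k in (1, 2, 3, 4)},
            [
                _risk_study("AB", [(1, 2, 50), (2, 3, 50)]),
                _risk_study("CD", [(3, 2, 50), (4, 3, 50)]),
            ],
        )
        assert validate_connectivity(net, "risk") == [{1, 2}, {3, 4}]

    def test_paper_like_network_fully_connected_in_every_subset(self, paper_like_sim):
        for subset in ("risk", "rate", "mixed"):
            components = validate_connectivity(paper_like_sim.network, subset)
            assert components[0] == set(range(1, 9))

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_agrees_with_bfs_oracle_on_random_graphs(self, data):
        n_nodes = data.draw(st.integers(2, 10))
        possible = [(a, b) for a in range(1, n_nodes + 1) for b in range(a + 1, n_nodes + 1)]
        edges = data.draw(
            st.lists(st.sampled_from(possible), min_size=1, max_size=12, unique=True)
        )
        studies = [
            _risk_study(f"S{i}", [(a, 2, 50), (b, 3, 50)])
            for i, (a, b) in enumerate(edges)
        ]
        seen = {c for s in studies for c in s.treatments}
        codes = sorted(seen)
        relabel = {c: i + 1 for i, c in enumerate(codes)}
        studies = [
            _risk_study(
                s.study_id,
                [(relabel[a.treatment_code], a.events, a.n) for a in s.risk_arms],
            )
            for s in studies
        ]
        net = EvidenceNetwork(
            {relabel[c]: Treatment(relabel[c], str(c)) for c in codes}, studies
        )

        # independent breadth-first-search oracle
        adj = {relabel[c]: set() for c in codes}
        for a, b in edges:
            adj[relabel[a]].add(relabel[b])
            adj[relabel[b]].add(relabel[a])
        unvisited = set(adj)
        oracle = []
        while unvisited:
            frontier = [min(unvisited)]
            comp = set()
            while frontier:
                node = frontier.pop()
                if node in comp:
                    continue
                comp.add(node)
                frontier.extend(adj[node] - comp)
            oracle.append(comp)
            unvisited -= comp
        oracle.sort(key=lambda c: (-len(c), min(c)))
        assert validate_connectivity(net, "risk") == oracle


class TestSummaries:
    def test_single_study_totals(self):
        net = EvidenceNetwork(
            {1: Treatment(1, "a"), 2: Treatment(2, "b")},
            [_risk_study("S1", [(1, 5, 100), (2, 7, 100)])],
        )
        nodes, edges = summarize_network(net, "risk")
        assert nodes.loc[1, "n_randomised"] == 100
        assert nodes.loc[2, "n_randomised"] == 100
        assert edges.loc[0, "n_trials"] == 1

    def test_duplicated_study_doubles_counts(self):
        studies = [
            _risk_study("S1", [(1, 5, 100), (2, 7, 100)]),
            _risk_study("S2", [(1, 5, 100), (2, 7, 100)]),
        ]
        net = EvidenceNetwork({1: Treatment(1, "a"), 2: Treatment(2, "b")}, studies)
        nodes, edges = summarize_network(net, "risk")
        assert nodes.loc[1, "n_randomised"] == 200
        assert edges.loc[0, "n_trials"] == 2

    def test_synthetic_totals_match_generator_allocation(self, paper_like_sim):
        nodes, _ = summarize_network(paper_like_sim.network, "risk")
        expected = {c: 0 for c in range(1, 9)}
        for study in paper_like_sim.network.studies:
            for arm in study.risk_arms:
                expected[arm.treatment_code] += arm.n
        for code, total in expected.items():
            assert nodes.loc[code, "n_randomised"] == total
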