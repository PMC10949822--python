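import numpy as np
import pytest

from cldmerge import (CLD, AdjacencyMatrix, CausalLink, PolarityConflictError,
                      ValidationError, canonical_key, read_cld, write_cld)
from cldmerge.io import read_clds


class TestCausalLink:
    def test_polarity_must_be_signed_unit(self):
        with pytest.raises(ValidationError):
            CausalLink("a", "b", 0)
        with pytest.raises(ValidationError):
            CausalLink("a", "b", 2)

    def test_labels_whitespace_normalised(self):
        link = CausalLink("  healthy   eating ", "x", 1)
        assert link.source == "healthy eating"
        assert link.key == ("healthy eating", canonical_key("x"))


class TestCLD:
    def test_variable_identity_case_insensitive(self):
        cld = CLD("c1", variables=["Mental Health", "mental  health"])
        assert len(cld) == 1
        assert cld.variables == ("Mental Health",)  # first spelling wins

    def test_self_loop_rejected_by_default(self):
        cld = CLD("c1")
        with pytest.raises(ValidationError, match="self-loop"):
            cld.add_link("a", "a", 1)
        permissive = CLD("c1", allow_self_loops=True)
        permissive.add_link("a", "a", 1)
        assert permissive.polarity_of("a", "a") == 1

    def test_duplicate_link_same_polarity_deduplicated(self, caplog):
        cld = CLD("c1")
        cld.add_link("a", "b", 1)
        with caplog.at_level("WARNING"):
            cld.add_link("a", "b", 1)
        assert len(cld.links) == 1
        assert "duplicate link" in caplog.text

    def test_duplicate_link_opposing_polarity_is_conflict(self):
        cld = CLD("c1", links=[("a", "b", 1)])
        with pytest.raises(PolarityConflictError):
            cld.add_link("A", "B", -1)

    def test_isolated_variables_allowed(self):
        cld = CLD("c1", variables=["lonely"], links=[("a", "b", 1)])
        assert "lonely" in cld and len(cld) == 3


class TestAdjacency:
    @pytest.mark.parametrize("links,index,expected", [
        ([("a", "b", 1)], ("a", "b"), [[0, 1], [0, 0]]),
        ([("a", "b", -1)], ("a", "b"), [[0, -1], [0, 0]]),
        ([], ("a", "b", "c"), np.zeros((3, 3))),
    ])
    def test_single_links_and_empty(self, links, index, expected):
        cld = CLD("c1", variables=index, links=links)
        assert np.array_equal(cld.to_adjacency(index).cells, np.array(expected))

    def test_index_must_cover_all_variables(self):
        cld = CLD("c1", links=[("a", "b", 1)])
        with pytest.raises(ValidationError, match="missing"):
            cld.to_adjacency(("a",))

    def test_roundtrip_reconstructs_exactly(self):
        rng = np.random.default_rng(42)
        labels = tuple(f"v{i}" for i in range(8))
        cld = CLD("c1", variables=labels)
        for _ in range(15):
            i, j = rng.choice(8, size=2, replace=False)
            if cld.polarity_of(labels[i], labels[j]) is None:
                cld.add_link(labels[i], labels[j], int(rng.choice([-1, 1])))
        adj = cld.to_adjacency()
        back = adj.to_cld("c1")
        assert back == cld
        assert adj.n_links == len(cld.links)

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValidationError):
            AdjacencyMatrix(index=("a", "b"), cells=[[0, 2], [0, 0]])
        with pytest.raises(ValidationError):
            AdjacencyMatrix(index=("a", "b"), cells=[[1, 0], [0, 0]])


class TestReadWrite:
    def test_edge_list_roundtrip(self, tmp_path):
        cld = CLD("c1", links=[("a", "b", 1), ("b", "c", -1)])
        path = write_cld(cld, tmp_path / "c1.csv")
        assert read_cld(path) == cld

    def test_json_roundtrip_keeps_isolated_variables(self, tmp_path):
        cld = CLD("c1", variables=["isolated"], links=[("a", "b", 1)])
        path = write_cld(cld, tmp_path / "c1.json")
        back = read_cld(path)
        assert back == cld and "isolated" in back

    def test_edge_list_single_row(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("cld_id,source,target,polarity\nc1,a,b,+1\n")
        cld = read_cld(path)
        assert len(cld) == 2 and cld.polarity_of("a", "b") == 1

    def test_polarity_tokens(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("cld_id,source,target,polarity\n"
                        "c1,a,b,+\nc1,b,c,-\nc1,c,d,1\nc1,d,e,-1\n")
        cld = read_cld(path)
        assert [l.polarity for l in cld.links] == [1, -1, 1, -1]

    def test_bad_polarity_names_line(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("cld_id,source,target,polarity\nc1,a,b,+1\nc1,b,c,0\n")
        with pytest.raises(ValidationError, match=":3"):
            read_cld(path)

    def test_self_loop_row_rejected(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("cld_id,source,target,polarity\nc1,a,a,+1\n")
        with pytest.raises(ValidationError, match="self-loop"):
            read_cld(path)

    def test_intra_file_conflict_lists_pair(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("cld_id,source,target,polarity\nc1,a,b,+1\nc1,a,b,-1\n")
        with pytest.raises(PolarityConflictError) as err:
            read_cld(path)
        assert ("a", "b") in err.value.pairs

    def test_adjacency_csv_roundtrips_bit_exactly(self, tmp_path):
        path = tmp_path / "adj.csv"
        path.write_text(",a,b,c\na,0,1,-1\nb,0,0,1\nc,0,0,0\n")
        cld = read_cld(path)
        adj = cld.to_adjacency(("a", "b", "c"))
        assert np.array_equal(adj.cells, [[0, 1, -1], [0, 0, 1], [0, 0, 0]])

    def test_multi_diagram_file(self, tmp_path):
        path = tmp_path / "many.csv"
        path.write_text("cld_id,source,target,polarity\n"
                        "c1,a,b,+1\nc2,a,b,+1\nc2,b,c,-1\n")
        clds = read_clds(path)
        assert [c.cld_id for c in clds] == ["c1", "c2"]
        with pytest.raises(ValidationError, match="expected one diagram"):
            read_cld(path)
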