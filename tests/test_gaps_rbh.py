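"""Gap detection (dead ends, blocked reactions) and alignment-hit filtering."""

import pytest

from snfba import (HitRecord, Metabolite, Model, RbhCriteria, Reaction,
                   ReactionKind, filter_homologs, filter_rbh,
                   find_blocked_reactions, find_dead_end_metabolites,
                   generate_hit_tables, generate_tiny_model, read_hit_table,
                   write_hit_table, flux_variability)
from oracles import naive_homolog_scan


def linear_model():
    m = Model(id="lin")
    for mid, comp in [("a[e]", "e"), ("a[c]", "c"), ("b[c]", "c")]:
        m.add_metabolite(Metabolite(id=mid, compartment=comp))
    m.add_reaction(Reaction(id="EX_a_e", stoichiometry={"a[e]": -1},
                            lower_bound=-5, upper_bound=5,
                            kind=ReactionKind.EXCHANGE))
    m.add_reaction(Reaction(id="T", stoichiometry={"a[e]": -1, "a[c]": 1},
                            upper_bound=10))
    m.add_reaction(Reaction(id="C", stoichiometry={"a[c]": -1, "b[c]": 1},
                            upper_bound=10))
    m.add_reaction(Reaction(id="SNK", stoichiometry={"b[c]": -1},
                            upper_bound=10))
    return m


class TestDeadEnds:
    def test_complete_chain_has_no_dead_ends(self):
        assert find_dead_end_metabolites(linear_model()) \
            .dead_end_metabolites == []

    def test_consumed_only_metabolite_flagged_no_production(self):
        m = linear_model()
        m.add_metabolite(Metabolite(id="x[c]", compartment="c"))
        m.add_reaction(Reaction(id="USE", stoichiometry={"x[c]": -1},
                                upper_bound=10))
        dead = find_dead_end_metabolites(m).dead_end_metabolites
        assert [(d.metabolite_id, d.kind) for d in dead] == \
            [("x[c]", "no_production")]

    def test_produced_only_metabolite_flagged_no_consumption(self):
        m = linear_model()
        m.add_metabolite(Metabolite(id="x[c]", compartment="c"))
        m.add_reaction(Reaction(id="MAKE", stoichiometry={"x[c]": 1},
                                upper_bound=10))
        dead = find_dead_end_metabolites(m).dead_end_metabolites
        assert [(d.metabolite_id, d.kind) for d in dead] == \
            [("x[c]", "no_consumption")]

    def test_bounds_decide_producibility_not_sign_alone(self):
        m = linear_model()
        # reversible in name only: lb = 0 means b[c] -> a[c] cannot run
        m.reaction("C").upper_bound = 0.0
        dead = {d.metabolite_id: d.kind
                for d in find_dead_end_metabolites(m).dead_end_metabolites}
        # blocking the chain strands b[c] (no producer left) and leaves
        # a[c] with no consumer
        assert dead == {"b[c]": "no_production", "a[c]": "no_consumption"}

    def test_removing_cbs_analogue_strands_cystathionine(self, toy_model):
        assert find_dead_end_metabolites(toy_model).dead_end_metabolites == []
        rxn = toy_model.reaction("CBS")
        rxn.lower_bound = rxn.upper_bound = 0.0
        dead = {d.metabolite_id: d.kind
                for d in find_dead_end_metabolites(toy_model)
                .dead_end_metabolites}
        assert dead.get("cyst[c]") == "no_consumption"
        assert dead.get("cys[c]") == "no_production"


class TestBlockedReactions:
    def test_chain_model_nothing_blocked(self):
        assert find_blocked_reactions(linear_model()) == []

    def test_downstream_of_dead_end_blocked(self):
        m = linear_model()
        m.add_metabolite(Metabolite(id="x[c]", compartment="c"))
        m.add_metabolite(Metabolite(id="y[c]", compartment="c"))
        # x[c] has no producer, so both consumers are forced to zero
        m.add_reaction(Reaction(id="USE1", stoichiometry={"x[c]": -1,
                                                          "y[c]": 1},
                                upper_bound=10))
        m.add_reaction(Reaction(id="USE2", stoichiometry={"y[c]": -1},
                                upper_bound=10))
        assert find_blocked_reactions(m) == ["USE1", "USE2"]

    @pytest.mark.parametrize("seed", range(8))
    def test_agreement_with_exhaustive_fva(self, seed):
        model = generate_tiny_model(seed)
        blocked = set(find_blocked_reactions(model))
        ranges = flux_variability(model, objective_fraction=0.0)
        oracle = {fr.reaction_id for fr in ranges
                  if max(abs(fr.min_flux), abs(fr.max_flux)) <= 1e-9}
        assert blocked == oracle

    def test_locality_disconnected_reaction_changes_nothing(self):
        m = linear_model()
        m.reaction("C").upper_bound = 0.0  # block the tail of the chain
        before = find_blocked_reactions(m)
        m.add_metabolite(Metabolite(id="z[c]", compartment="c"))
        m.add_reaction(Reaction(id="LOOP", stoichiometry={"z[c]": 1},
                                upper_bound=0.0))
        after = find_blocked_reactions(m)
        assert set(before) <= set(after)
        assert set(after) - set(before) == {"LOOP"}


def hit(q, s, e=1e-10, ident=45.0, alen=80, qlen=100, bits=200.0):
    return HitRecord(query=q, subject=s, e_value=e, percent_identity=ident,
                     alignment_length=alen, query_length=qlen, bitscore=bits)


class TestRbhFilter:
    def test_symmetric_passing_pair_kept(self):
        assert filter_rbh([hit("A", "B")], [hit("B", "A")]) == [("A", "B")]

    def test_evalue_at_1e5_rejected(self):
        fwd, rev = [hit("A", "B", e=1e-5)], [hit("B", "A")]
        assert filter_rbh(fwd, rev) == []

    def test_identity_exactly_30_rejected_strict(self):
        fwd, rev = [hit("A", "B", ident=30.0)], [hit("B", "A")]
        assert filter_rbh(fwd, rev) == []

    def test_coverage_exactly_60_rejected_strict(self):
        fwd, rev = [hit("A", "B", alen=60, qlen=100)], [hit("B", "A")]
        assert filter_rbh(fwd, rev) == []

    def test_broken_reciprocity_rejected(self):
        fwd = [hit("A", "B")]
        rev = [hit("B", "A", e=1e-8), hit("B", "C", e=1e-20)]
        assert filter_rbh(fwd, rev) == []

    def test_best_hit_tie_break_by_bitscore_then_subject(self):
        fwd = [hit("A", "B", e=1e-10, bits=100.0),
               hit("A", "C", e=1e-10, bits=300.0)]
        rev = [hit("C", "A")]
        assert filter_rbh(fwd, rev) == [("A", "C")]

    def test_output_symmetric_under_table_swap(self):
        fwd, rev, planted = generate_hit_tables(4, 12, seed=7)
        ab = set(filter_rbh(fwd, rev))
        ba = set(filter_rbh(rev, fwd))
        assert ba == {(s, q) for q, s in ab}

    def test_tightening_criteria_never_enlarges(self):
        fwd, rev, _ = generate_hit_tables(6, 18, seed=3)
        loose = set(filter_rbh(fwd, rev, RbhCriteria()))
        for tighter in (RbhCriteria(max_e=1e-30),
                        RbhCriteria(min_identity_pct=60.0),
                        RbhCriteria(min_coverage_pct=90.0)):
            assert set(filter_rbh(fwd, rev, tighter)) <= loose

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_pairs_recovered_exactly(self, seed):
        fwd, rev, planted = generate_hit_tables(5, 20, seed=seed)
        assert set(filter_rbh(fwd, rev)) == planted

    def test_empty_planting_gives_empty_result(self):
        fwd, rev, planted = generate_hit_tables(0, 10, seed=1)
        assert planted == frozenset()
        assert filter_rbh(fwd, rev) == []


class TestHomologFilter:
    def test_one_passing_hit_keeps_query_once(self):
        hits = [hit("A", "B"), hit("A", "C", e=1.0)]
        assert filter_homologs(hits) == ["A"]

    def test_all_failing_evalues_empty(self):
        hits = [hit("A", "B", e=1e-6), hit("C", "D", e=0.5)]
        assert filter_homologs(hits) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_naive_scan(self, seed):
        fwd, rev, _ = generate_hit_tables(8, 24, seed=seed)
        hits = fwd + rev
        assert filter_homologs(hits) == naive_homolog_scan(hits, 1e-6, 30.0)


class TestHitTableIO:
    def test_round_trip(self, tmp_path):
        fwd, _, _ = generate_hit_tables(3, 5, seed=11)
        path = tmp_path / "hits.tsv"
        write_hit_table(fwd, str(path))
        back = read_hit_table(str(path))
        assert [(h.query, h.subject) for h in back] == \
            [(h.query, h.subject) for h in fwd]
        assert all(a.query_length == b.query_length
                   for a, b in zip(back, fwd))

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\ts1\t45.0\t80\t0\t0\t1\t80\t1\t80\t1e-10\t200\t"
                        "100\nq2\ts2\tnot_a_number\n")
        with pytest.raises(ValueError, match=r"bad\.tsv:2"):
            read_hit_table(str(path))
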