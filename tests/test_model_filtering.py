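import random

import pytest

from tecurate.config import PipelineConfig
from tecurate.model_filtering import (
    CascadeInputs,
    StageReport,
    cluster_models,
    copy_number_filter,
    exon_overlap_filter,
    run_cascade,
    tandem_filter,
    trna_filter,
)
from tecurate.types import AlignmentHit, ConsensusModel, DomainEvidence, TandemRecord

from conftest import cascade_inputs

CFG = PipelineConfig()


def mk_model(mid, length=1000):
    return ConsensusModel(mid, "ACGT" * (length // 4) + "A" * (length % 4))


def mk_hit(q, s, identity=0.95, aln_len=900, q_span=None, evalue=1e-50):
    q_span = q_span or aln_len
    return AlignmentHit(q, s, identity, aln_len, 0, q_span, 0, aln_len, "+", evalue, 100.0)


class TestClusterModels:
    def test_no_hits_all_singletons(self):
        models = [mk_model(f"m{i}") for i in range(5)]
        clusters, discarded = cluster_models(models, [])
        assert len(clusters) == 5
        assert discarded == set()

    def test_direct_rule_evaluation(self):
        a = mk_model("A", 1000)
        b = mk_model("B", 950)
        hit = mk_hit("A", "B", identity=0.95, aln_len=900)
        # 900/950 > 0.90 and 0.95 > 0.90 -> one cluster, longest kept
        clusters, discarded = cluster_models([a, b], [hit])
        assert len(clusters) == 1
        assert clusters[0].representative_id == "A"
        assert discarded == {"B"}

    def test_coverage_below_threshold_not_linked(self):
        a, b = mk_model("A", 1000), mk_model("B", 1000)
        hit = mk_hit("A", "B", identity=0.95, aln_len=850)  # 0.85 < 0.90
        clusters, discarded = cluster_models([a, b], [hit])
        assert len(clusters) == 2 and not discarded

    def test_transitive_closure_chain(self):
        a, b, c = mk_model("A", 1000), mk_model("B", 990), mk_model("C", 980)
        hits = [mk_hit("A", "B"), mk_hit("B", "C", aln_len=950)]
        clusters, discarded = cluster_models([a, b, c], hits)
        assert len(clusters) == 1
        assert clusters[0].member_ids == {"A", "B", "C"}
        assert clusters[0].representative_id == "A"

    def test_matches_connected_components_oracle(self):
        # brute-force transitive closure via adjacency-matrix powers
        rng = random.Random(5)
        for _ in range(20):
            n = rng.randint(3, 10)
            models = [mk_model(f"m{i}", 500 + i) for i in range(n)]
            edges = set()
            for _ in range(rng.randint(0, n * 2)):
                i, j = rng.randrange(n), rng.randrange(n)
                if i != j:
                    edges.add((min(i, j), max(i, j)))
            hits = [mk_hit(f"m{i}", f"m{j}", aln_len=499) for i, j in edges]
            clusters, _ = cluster_models(models, hits)

            # oracle: boolean closure
            adj = [[i == j for j in range(n)] for i in range(n)]
            for i, j in edges:
                adj[i][j] = adj[j][i] = True
            for k in range(n):
                for i in range(n):
                    for j in range(n):
                        adj[i][j] = adj[i][j] or (adj[i][k] and adj[k][j])
            oracle = {frozenset(f"m{j}" for j in range(n) if adj[i][j]) for i in range(n)}
            got = {frozenset(c.member_ids) for c in clusters}
            assert got == oracle

    def test_unknown_model_id_error(self):
        with pytest.raises(ValueError, match="unknown model id"):
            cluster_models([mk_model("A")], [mk_hit("A", "ghost")])

    def test_order_invariance(self):
        models = [mk_model(mid, ln) for mid, ln in
                  [("A", 1000), ("B", 990), ("C", 980), ("D", 970)]]
        hits = [mk_hit("A", "B"), mk_hit("C", "D", aln_len=950)]
        c1, d1 = cluster_models(models, hits)
        c2, d2 = cluster_models(models[::-1], hits[::-1])
        assert {c.representative_id for c in c1} == {c.representative_id for c in c2}
        assert d1 == d2


class TestCopyNumberFilter:
    def mk_genome_hits(self, counts_per_genome, q_span=900):
        return {
            f"g{k}": [mk_hit("M", f"g{k}_c0", q_span=q_span) for _ in range(n)]
            for k, n in enumerate(counts_per_genome)
        }

    def test_two_everywhere_discarded(self):
        model = mk_model("M", 1000)
        keep, reason = copy_number_filter(model, self.mk_genome_hits([2, 2, 2]))
        assert not keep and reason == "low_copy_or_partial"

    def test_three_in_one_genome_kept(self):
        model = mk_model("M", 1000)
        keep, _ = copy_number_filter(model, self.mk_genome_hits([3, 0, 0]))
        assert keep

    def test_partial_hits_never_count(self):
        model = mk_model("M", 1000)
        hits = self.mk_genome_hits([10], q_span=300)  # 30% of the model
        keep, reason = copy_number_filter(model, hits)
        assert not keep and reason == "low_copy_or_partial"

    def test_full_length_boundary_inclusive(self):
        model = mk_model("M", 1000)
        keep, _ = copy_number_filter(model, self.mk_genome_hits([3], q_span=800))
        assert keep  # exactly 80% counts as full length


class TestExonOverlapFilter:
    def test_union_oracle(self):
        model = mk_model("M", 1000)
        hits = [
            AlignmentHit("M", "e1", 0.9, 200, 100, 300, 0, 200),
            AlignmentHit("M", "e2", 0.9, 300, 200, 500, 0, 300),
        ]
        # position-set cardinality oracle
        union = len({p for h in hits for p in range(h.q_start, h.q_end)})
        assert union == 400
        keep, fraction = exon_overlap_filter(model, hits)
        assert fraction == pytest.approx(0.400)
        assert keep  # 0.400 not > 0.40

    def test_401_discards(self):
        model = mk_model("M", 1000)
        hits = [AlignmentHit("M", "e1", 0.9, 401, 0, 401, 0, 401)]
        keep, fraction = exon_overlap_filter(model, hits)
        assert not keep and fraction == pytest.approx(0.401)

    def test_hypothetical_and_te_products_excluded(self):
        model = mk_model("M", 1000)
        hits = [
            AlignmentHit("M", "e1", 0.9, 500, 0, 500, 0, 500),
            AlignmentHit("M", "e2", 0.9, 500, 500, 1000, 0, 500),
        ]
        products = {"e1": "hypothetical protein", "e2": "retrotransposon gag protein"}
        keep, fraction = exon_overlap_filter(model, hits, products=products)
        assert keep and fraction == 0.0


class TestTandemFilter:
    def test_full_length_tandem_discarded(self):
        model = ConsensusModel("M", "AT" * 100)
        keep, fraction = tandem_filter(model, records=None)
        assert not keep and fraction == 1.0

    def test_no_records_kept(self):
        model = mk_model("M", 1000)
        keep, fraction = tandem_filter(model, records=[])
        assert keep and fraction == 0.0

    def test_union_oracle_45_percent(self):
        model = mk_model("M", 1000)
        records = [
            TandemRecord("M", 0, 250, 10, 25.0),
            TandemRecord("M", 200, 450, 10, 25.0),
        ]
        keep, fraction = tandem_filter(model, records)
        assert fraction == pytest.approx(0.45)
        assert not keep

    def test_exactly_40_percent_kept(self):
        model = mk_model("M", 1000)
        records = [TandemRecord("M", 0, 400, 10, 40.0)]
        keep, fraction = tandem_filter(model, records)
        assert keep and fraction == pytest.approx(0.40)


class TestTrnaFilter:
    def mk_row(self, pseudo):
        return DomainEvidence("M", "trna", "tRNA-Ala", "tRNA-Ala (AGC)", 0, 75, pseudo=pseudo)

    def test_intact_discards(self):
        keep, reason = trna_filter(mk_model("M"), [self.mk_row(False)])
        assert not keep and reason == "trna_gene"

    def test_pseudo_only_flags_sine(self):
        keep, flag = trna_filter(mk_model("M"), [self.mk_row(True)])
        assert keep and flag == "SINE_candidate"

    def test_no_rows_keeps_unflagged(self):
        keep, flag = trna_filter(mk_model("M"), [])
        assert keep and flag == ""

    def test_mixed_intact_wins(self):
        keep, reason = trna_filter(mk_model("M"), [self.mk_row(True), self.mk_row(False)])
        assert not keep and reason == "trna_gene"


class TestStageReport:
    def test_flow_invariant_enforced(self):
        report = StageReport()
        report.add("clustering", 10, 2)
        with pytest.raises(ValueError):
            report.add("copy_number", 9, 1)  # previous n_out was 8

    def test_discard_bound(self):
        report = StageReport()
        with pytest.raises(ValueError):
            report.add("clustering", 3, 4)


class TestRunCascade:
    def test_empty_model_list(self):
        survivors, report, flags = run_cascade([], CascadeInputs())
        assert survivors == []
        assert report.counts == [0, 0, 0, 0, 0, 0]

    def test_synthetic_flow_matches_ground_truth(self, default_dataset):
        import copy

        ds = copy.deepcopy(default_dataset)
        survivors, report, flags = run_cascade(ds.models, cascade_inputs(ds))
        assert report.counts == [10, 8, 7, 5, 3, 2]
        assert {m.model_id for m in survivors} == ds.truth.expected_survivors()
        # every discarded model carries exactly one (stage, reason)
        for m in ds.models:
            if m.status == "discarded":
                assert m.discard_stage and m.discard_reason

    def test_idempotent_on_survivors(self, default_dataset):
        import copy

        ds = copy.deepcopy(default_dataset)
        inputs = cascade_inputs(ds)
        survivors, _, _ = run_cascade(ds.models, inputs)
        again, report2, _ = run_cascade(survivors, inputs)
        assert {m.model_id for m in again} == {m.model_id for m in survivors}
        assert all(r.n_discarded == 0 for r in report2.rows)

    def test_flow_conservation(self, default_dataset):
        import copy

        ds = copy.deepcopy(default_dataset)
        survivors, report, _ = run_cascade(ds.models, cascade_inputs(ds))
        total_discarded = sum(r.n_discarded for r in report.rows)
        assert total_discarded + len(survivors) == len(ds.models)

    def test_rerun_gives_identical_verdicts(self, default_dataset):
        import copy

        ds1 = copy.deepcopy(default_dataset)
        ds2 = copy.deepcopy(default_dataset)
        run_cascade(ds1.models, cascade_inputs(ds1))
        run_cascade(ds2.models, cascade_inputs(ds2))
        v1 = [(m.model_id, m.status, m.discard_stage, m.discard_reason) for m in ds1.models]
        v2 = [(m.model_id, m.status, m.discard_stage, m.discard_reason) for m in ds2.models]
        assert v1 == v2
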