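import pytest

from spinqc.io_formats import BlastHit
from spinqc.orthology import (
    OrthologyCall,
    PathwayComponent,
    ReferenceDB,
    best_hits,
    ohr,
    ohr_summary,
    ortholog_counts,
    pathway_presence,
    prediction_gain,
    rbh_classify,
    species_distribution,
    unique_hit_stats,
)


def hit(q, s, bitscore=200.0, evalue=1e-50, sstart=1, send=100):
    return BlastHit(q, s, 90.0, send - sstart + 1, 0, 0, 1, 300, sstart, send,
                    evalue, bitscore)


class TestBestHits:
    def test_highest_bitscore_wins(self):
        best = best_hits([hit("t1", "g1", 150), hit("t1", "g2", 200)])
        assert best["t1"].sseqid == "g2"

    def test_tie_breaks_to_lexicographically_smallest_subject(self):
        best = best_hits([hit("t1", "gB", 200), hit("t1", "gA", 200)])
        assert best["t1"].sseqid == "gA"

    def test_evalue_cutoff_excludes_query(self):
        best = best_hits([hit("t1", "g1", evalue=1e-4)], evalue_cutoff=1e-10)
        assert "t1" not in best

    def test_lower_evalue_breaks_bitscore_tie(self):
        best = best_hits([hit("t1", "gB", 200, 1e-60), hit("t1", "gA", 200, 1e-50)])
        assert best["t1"].sseqid == "gB"


class TestRbhClassify:
    def test_mutual_best_hit_is_ortholog(self):
        calls = rbh_classify({"t1": hit("t1", "g1")}, {"g1": hit("g1", "t1")})
        assert calls[0].status == "ortholog"

    def test_reciprocity_failure_is_paralog(self):
        calls = rbh_classify(
            {"t1": hit("t1", "g1"), "t2": hit("t2", "g1")},
            {"g1": hit("g1", "t1")},
        )
        by_id = {c.transcript_id: c.status for c in calls}
        assert by_id == {"t1": "ortholog", "t2": "paralog"}

    def test_gene_missing_from_reverse_map_is_paralog(self):
        calls = rbh_classify({"t3": hit("t3", "g2")}, {})
        assert calls[0].status == "paralog"

    def test_transcripts_without_forward_hit_are_none(self):
        calls = rbh_classify({}, {}, transcript_ids=["t9"])
        assert calls[0].status == "none" and calls[0].reference_gene is None

    def test_status_none_forbids_reference_gene(self):
        with pytest.raises(ValueError):
            OrthologyCall(transcript_id="t", status="none", reference_gene="g")

    def test_recovers_planted_map_with_decoys(self, small_dataset):
        ds = small_dataset
        fwd_best = best_hits(ds.fwd, 1e-5)
        rev_best = best_hits(ds.rev, 1e-5)
        calls = rbh_classify(fwd_best, rev_best)
        recovered = {
            c.transcript_id: c.reference_gene
            for c in calls
            if c.status == "ortholog"
        }
        assert recovered == ds.gt.orthology_map
        paralogs = {c.transcript_id for c in calls if c.status == "paralog"}
        assert paralogs == set(ds.gt.paralogs)

    def test_each_gene_partners_at_most_one_ortholog(self, small_dataset):
        ds = small_dataset
        calls = rbh_classify(best_hits(ds.fwd, 1e-5), best_hits(ds.rev, 1e-5))
        genes = [c.reference_gene for c in calls if c.status == "ortholog"]
        assert len(genes) == len(set(genes))


class TestOrthologCounts:
    def test_single_mutual_pair(self):
        calls = rbh_classify({"t1": hit("t1", "g1")}, {"g1": hit("g1", "t1")})
        counts = ortholog_counts(calls)
        assert (counts.genes_with_calls, counts.genes_with_orthologs) == (1, 1)

    def test_extra_paralog_counted_at_call_level_only(self):
        calls = rbh_classify(
            {"t1": hit("t1", "g1"), "t2": hit("t2", "g1")},
            {"g1": hit("g1", "t1")},
        )
        counts = ortholog_counts(calls)
        assert (counts.genes_with_calls, counts.genes_with_orthologs) == (1, 1)
        assert (counts.calls_total, counts.calls_ortholog) == (2, 1)

    def test_no_hits(self):
        counts = ortholog_counts([])
        assert counts.genes_with_calls == 0 and counts.calls_total == 0


class TestUniqueHitStats:
    def test_distribution(self):
        best = {"t1": hit("t1", "p1"), "t2": hit("t2", "p1"), "t3": hit("t3", "p2")}
        stats = unique_hit_stats(best)
        assert stats.n_unique_subjects == 2
        assert stats.mean_queries_per_subject == 1.5
        assert (stats.max_queries_per_subject, stats.min_queries_per_subject) == (2, 1)

    def test_empty_reports_zero(self):
        assert unique_hit_stats({}).n_unique_subjects == 0

    def test_all_distinct(self):
        best = {f"t{i}": hit(f"t{i}", f"p{i}") for i in range(4)}
        assert unique_hit_stats(best).mean_queries_per_subject == 1.0


class TestOhr:
    DB = ReferenceDB(lengths={"g1": 100, "g2": 1}, taxa={"g1": "A", "g2": "B"})

    def test_half_span(self):
        assert ohr(hit("t", "g1", sstart=26, send=75), self.DB) == 0.5

    def test_full_span_is_one(self):
        assert ohr(hit("t", "g1", sstart=1, send=100), self.DB) == 1.0

    def test_single_residue_on_unit_protein(self):
        assert ohr(hit("t", "g2", sstart=1, send=1), self.DB) == 1.0

    def test_missing_subject_names_accession(self):
        with pytest.raises(KeyError, match="gX"):
            ohr(hit("t", "gX"), self.DB)

    def test_invariant_to_query_coords_and_monotone_in_span(self):
        narrow = ohr(hit("t", "g1", sstart=10, send=39), self.DB)
        wide = ohr(hit("t", "g1", sstart=10, send=79), self.DB)
        assert wide > narrow
        moved = BlastHit("t", "g1", 90.0, 30, 0, 0, 500, 800, 10, 39, 1e-50, 200)
        assert ohr(moved, self.DB) == narrow

    def test_planted_values_recovered_from_simulated_tables(self, small_dataset):
        ds = small_dataset
        fwd_best = best_hits(ds.fwd, 1e-5)
        for tid, planted in ds.gt.ohr_map.items():
            assert ohr(fwd_best[tid], ds.db) == pytest.approx(planted)


class TestOhrSummary:
    def test_proportions_use_geq(self):
        summary = ohr_summary([0.5, 0.8, 1.0, 0.2])
        assert summary.frac_ge_50 == 0.75
        assert summary.frac_ge_80 == 0.5

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            ohr_summary([])

    def test_all_full_length(self):
        summary = ohr_summary([1.0, 1.0])
        assert summary.frac_ge_50 == summary.frac_ge_80 == 1.0
        assert summary.histogram[-1] == (0.9, 1.0, 2)

    def test_histogram_counts_sum_to_n(self):
        values = [0.05, 0.15, 0.55, 0.95, 1.0, 0.85]
        summary = ohr_summary(values)
        assert sum(c for *_, c in summary.histogram) == len(values)


class TestSpeciesDistribution:
    DB = ReferenceDB(
        lengths={"g1": 10, "g2": 10, "g3": 10},
        taxa={"g1": "A", "g2": "A", "g3": "B"},
    )

    def test_proportions(self):
        best = {"t1": hit("t1", "g1"), "t2": hit("t2", "g2"), "t3": hit("t3", "g3")}
        dist = species_distribution(best, self.DB)
        assert dist == {"A": pytest.approx(2 / 3), "B": pytest.approx(1 / 3)}
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_unlabeled_subject_is_error(self):
        db = ReferenceDB(lengths={"g1": 10})
        with pytest.raises(KeyError):
            species_distribution({"t1": hit("t1", "g1")}, db)


class TestPathwayPresence:
    def test_overall_percentages_on_pathway_shaped_table(self):
        # six pathways shaped 25/21, 47/23, 75/45, 16/14, 27/14, 18/14
        # with 4+2+12+4+0+0 previously-known among the present components
        shape = [
            ("notch", 25, 21, 4),
            ("tgfb", 47, 23, 2),
            ("wnt", 75, 45, 12),
            ("hedgehog", 16, 14, 4),
            ("jakstat", 27, 14, 0),
            ("mapk", 18, 14, 0),
        ]
        table = {}
        present = set()
        gene = 0
        for name, n, n_present, n_known in shape:
            comps = []
            for i in range(n):
                gid = f"g{gene}"
                gene += 1
                comps.append(PathwayComponent(f"{name}_{i}", gid, i < n_known))
                if i < n_present:
                    present.add(gid)
            table[name] = comps
        df = pathway_presence(table, present)
        overall = df[df.pathway == "overall"].iloc[0]
        assert overall.n_components == 208
        assert overall.n_present == 131
        assert overall.pct_present == 62.98
        assert overall.n_previously_known == 22
        assert overall.pct_previously_known_of_present == 16.79

    def test_fully_present_pathway(self):
        table = {"p": [PathwayComponent("c1", "g1"), PathwayComponent("c2", "g2")]}
        df = pathway_presence(table, {"g1", "g2"})
        assert df[df.pathway == "p"].pct_present.iloc[0] == 100.00


class TestPredictionGain:
    def test_increase_mode_worked_examples(self):
        assert prediction_gain(8917, 6255, "increase") == 42.56
        assert prediction_gain(6396, 5554, "increase") == 15.16

    def test_ratio_mode_worked_example(self):
        assert prediction_gain(6396, 76, "ratio") == 8416

    def test_no_change_is_zero(self):
        assert prediction_gain(123, 123, "increase") == 0.00

    def test_zero_baseline_is_error(self):
        with pytest.raises(ValueError):
            prediction_gain(10, 0, "increase")
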