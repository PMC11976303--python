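"""Synthetic backbone generation and the corruption-recall benchmark."""

import random

import pytest

from conftest import oracle_distance
from phytonym import (
    build_index,
    generate_taxonomy,
    parse_name,
    perturb_name,
    run_match_benchmark,
    run_parse_benchmark,
)
from phytonym.benchmark import CorruptionSpec, GeneratorParams, build_test_sets


class TestGenerator:
    def test_counts(self):
        taxonomy = generate_taxonomy(seed=42, n_genera=10, species_per_genus=5)
        by_rank = {}
        for r in taxonomy.records:
            if not r.isVernacular:
                by_rank[r.taxonRank] = by_rank.get(r.taxonRank, 0) + 1
        assert by_rank["genus"] == 10
        assert by_rank["species"] >= 50  # cross-dataset duplicates add a few
        assert len(taxonomy.binomials()) >= 50

    def test_deterministic(self, tmp_path):
        a = generate_taxonomy(seed=42, n_genera=5, species_per_genus=4)
        b = generate_taxonomy(seed=42, n_genera=5, species_per_genus=4)
        assert a.records == b.records
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_tsv(pa)
        b.to_tsv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_seed_changes_output(self):
        a = generate_taxonomy(seed=1, n_genera=5, species_per_genus=4)
        b = generate_taxonomy(seed=2, n_genera=5, species_per_genus=4)
        assert a.records != b.records

    def test_no_synonyms_when_fraction_zero(self):
        taxonomy = generate_taxonomy(
            seed=3, n_genera=8, species_per_genus=6,
            synonym_fraction=0.0, vernacular_fraction=0.0,
        )
        assert all(not r.acceptedNameUsageID for r in taxonomy.records)

    def test_synonym_links_resolve(self, taxonomy):
        by_key = {
            (r.datasetID, r.taxonID): r
            for r in taxonomy.records
            if not r.isVernacular
        }
        for r in taxonomy.records:
            if r.acceptedNameUsageID:
                target = by_key[(r.datasetID, r.acceptedNameUsageID)]
                assert target.taxonomicStatus == "accepted"

    def test_all_names_parse(self, taxonomy):
        for r in taxonomy.records:
            assert parse_name(r.scientificName).parseRemark == "parsed", (
                r.scientificName
            )

    def test_provenance_keys_unique(self, taxonomy):
        keys = [
            (r.datasetID, r.taxonID) for r in taxonomy.records if not r.isVernacular
        ]
        assert len(keys) == len(set(keys))

    def test_empty_taxonomy(self):
        assert generate_taxonomy(seed=0, n_genera=0).records == []

    def test_tsv_round_trips_through_ingest(self, tmp_path):
        from phytonym import read_taxon_table, rows_to_records

        taxonomy = generate_taxonomy(seed=9, n_genera=4, species_per_genus=3)
        path = tmp_path / "backbone.tsv"
        taxonomy.to_tsv(path)
        rows, skipped = read_taxon_table(path, "SYNTH")
        assert skipped == 0
        records = rows_to_records(rows)
        assert [r.scientificName for r in records] == [
            r.scientificName for r in taxonomy.records
        ]
        assert [r.isVernacular for r in records] == [
            r.isVernacular for r in taxonomy.records
        ]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(synonym_fraction=1.5)


class TestPerturbation:
    def test_zero_edits_is_identity(self):
        assert perturb_name("Acer palmatum", CorruptionSpec(0, seed=1)).text == (
            "Acer palmatum"
        )

    def test_substitution_distance_exact(self):
        """Substitution corruption at k edits per word puts every word at
        Levenshtein distance exactly k (word length permitting), verified
        against an independent alignment oracle over many seeded draws."""
        rng = random.Random(13)
        words_pool = ["Acer", "palmatum", "sinensis", "×freemanii", "Poa", "annua",
                      "var.", "longissimifolia", "Be"]
        for trial in range(2500):
            k = rng.choice((1, 2))
            name = " ".join(rng.choice(words_pool) for _ in range(rng.randint(1, 3)))
            out = perturb_name(name, CorruptionSpec(k, seed=trial))
            src_words = name.split(" ")
            dst_words = out.text.split(" ")
            assert len(src_words) == len(dst_words)  # spaces untouched
            expected_shortfall = 0
            for s, d in zip(src_words, dst_words):
                n_letters = sum(c.isalpha() for c in s)
                applied = min(k, n_letters)
                expected_shortfall += k - applied
                assert oracle_distance(s, d) == applied, (s, d, k)
            assert out.shortfall == expected_shortfall

    def test_single_letter_word_shortfall(self):
        out = perturb_name("A", CorruptionSpec(2, seed=5))
        assert out.shortfall == 1
        assert oracle_distance("A", out.text) == 1

    def test_mixed_edits_bounded(self):
        rng = random.Random(99)
        for trial in range(300):
            k = rng.choice((1, 2))
            out = perturb_name(
                "Acer palmatum", CorruptionSpec(k, "mixed", seed=trial)
            )
            for s, d in zip("Acer palmatum".split(), out.text.split()):
                assert oracle_distance(s, d) <= k

    def test_corrupted_differs(self):
        for seed in range(50):
            out = perturb_name("Acer palmatum", CorruptionSpec(1, seed=seed))
            assert out.text != "Acer palmatum"

    def test_deterministic(self):
        spec = CorruptionSpec(2, seed=123)
        assert perturb_name("Acer palmatum", spec) == perturb_name(
            "Acer palmatum", spec
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            perturb_name("", CorruptionSpec(1, seed=0))


class TestBenchmarks:
    def test_correct_names_fully_recalled(self, taxonomy, backbone_index):
        names = taxonomy.binomials()[:150]
        report = run_match_benchmark({"correct": names}, backbone_index)
        (cat,) = report.categories
        assert cat.recalled == cat.total == len(names)
        assert cat.matched == len(names)

    def test_far_names_not_recalled(self, backbone_index):
        junk = [f"Qqqqxx{i} wwyyzz{i}qq" for i in range(20)]
        report = run_match_benchmark({"junk": junk}, backbone_index)
        assert report.categories[0].recalled == 0

    def test_one_char_per_word_recalled(self, taxonomy, backbone_index):
        sets = build_test_sets(taxonomy.binomials(), 100, seed=3)
        report = run_match_benchmark({"oneChar": sets["oneChar"]}, backbone_index)
        (cat,) = report.categories
        assert cat.recalled == cat.total
        assert cat.recorrected >= cat.total - cat.matched

    def test_report_frame_shape(self, taxonomy, backbone_index):
        sets = build_test_sets(taxonomy.binomials(), 30, seed=4)
        frame = run_match_benchmark(sets, backbone_index).to_frame()
        assert list(frame["category"]) == ["correct", "oneChar", "twoChar"]
        assert (frame["recalled"] <= frame["total"]).all()

    def test_parse_benchmark_counts(self, taxonomy):
        names = taxonomy.full_names()[:200]
        report = run_parse_benchmark(names)
        assert report.resolved == report.total == 200
        assert report.failures == []

    def test_parse_benchmark_hybrid_names(self):
        report = run_parse_benchmark(["×Sorbopyrus auricularis",
                                      "Sorbopyrus _x auricularis",
                                      "Acer ×freemanii"])
        assert report.resolved == 3 and report.failures == []

    def test_parse_benchmark_empty(self):
        report = run_parse_benchmark([])
        assert report.total == 0 and report.counts == {}

    def test_skip_authorship_leaves_citation(self):
        names = ["Acer palmatum Thunb."]
        sets = build_test_sets(names, 1, seed=0, skip_authorship=True)
        corrupted = sets["oneChar"][0]
        assert corrupted.endswith(" Thunb.")
        assert corrupted != names[0]
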