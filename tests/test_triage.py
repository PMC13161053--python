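"""Decision-tree categories, material lookup and dereplication."""

import itertools

import pytest
from hypothesis import given, strategies as st

from magtriage.io_formats import MagRecord, ReferenceHit
from magtriage.novelty import NoveltyCall
from magtriage.quality_gate import QualityVerdict
from magtriage.taxonomy_lca import LcaResult
from magtriage.triage import (
    MaterialRecord,
    dereplicate,
    material_category,
    triage_mag,
)


def registry(**statuses):
    out = {}
    for ref, status in statuses.items():
        kwargs = {"collection_ids": ["CC:1"]} if status == "public_collection_strain" else {}
        out[ref] = MaterialRecord(reference_id=ref, status=status, **kwargs)
    return out


def novelty(mag_id="m", ani=None, aai=None):
    ani_hit = (
        ReferenceHit(query_id=mag_id, reference_id="ref", metric="ANI", value=ani)
        if ani is not None
        else None
    )
    aai_hit = (
        ReferenceHit(query_id=mag_id, reference_id="ref", metric="AAI", value=aai)
        if aai is not None
        else None
    )
    status = "no_hit" if ani is None else ("known_species" if ani >= 95 else "novel_species")
    return NoveltyCall(
        mag_id=mag_id, best_ani_hit=ani_hit, best_aai_hit=aai_hit,
        species_status=status, genus_status="unresolved",
    )


PASSED = QualityVerdict(mag_id="m", passed=True)
FAILED = QualityVerdict(mag_id="m", passed=False, reasons=["completeness"])
CONGRUENT = LcaResult(lca_rank="family", lca_name="F", congruent=True, contributing_lineages=3)
INCONGRUENT = LcaResult(lca_rank="class", lca_name="C", congruent=False, contributing_lineages=3)


class TestMaterialCategory:
    def test_status_to_index_mapping(self):
        reg = registry(
            a="type_strain", b="public_collection_strain", c="cultivated_undeposited", d="in_silico"
        )
        assert material_category("a", reg, gtdb_hit_available=True) == 1
        assert material_category("b", reg, gtdb_hit_available=True) == 2
        assert material_category("c", reg, gtdb_hit_available=True) == 3
        assert material_category("d", reg, gtdb_hit_available=True) == 4
        assert material_category("d", reg, gtdb_hit_available=False) == 5

    def test_unknown_reference_defaults_to_in_silico_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert material_category("mystery", {}, gtdb_hit_available=False) == 5
        assert any("mystery" in rec.message for rec in caplog.records)

    def test_public_collection_requires_collection_ids(self):
        with pytest.raises(ValueError, match="collection id"):
            MaterialRecord(reference_id="x", status="public_collection_strain")


class TestTriageMag:
    def test_cultivated_undeposited_match_gets_description_plus_deposit(self):
        result = triage_mag(novelty(ani=99.6772), 3, None, PASSED)
        assert result.category == "A3"
        assert "deposit" in result.action.lower()

    def test_novel_species_with_gtdb_reference_is_b4(self):
        result = triage_mag(novelty(ani=94.3411), 4, None, PASSED)
        assert result.category == "B4"

    def test_type_strain_match_means_no_registration(self):
        result = triage_mag(novelty(ani=99.9), 1, None, PASSED)
        assert result.category == "A1"
        assert "No SeqCode registration" in result.action

    def test_quality_failure_short_circuits(self):
        result = triage_mag(novelty(ani=99.9), 1, None, FAILED)
        assert result.category == "FAIL_QUALITY"

    @pytest.mark.parametrize("ani,side", [(99.0, "A"), (80.0, "B")])
    def test_ncbi_only_requires_congruence(self, ani, side):
        assert triage_mag(novelty(ani=ani), 5, CONGRUENT, PASSED).category == f"{side}5"
        assert triage_mag(novelty(ani=ani), 5, INCONGRUENT, PASSED).category == "REJECT_INCONGRUENT"
        assert triage_mag(novelty(ani=ani), 5, None, PASSED).category == "REJECT_INCONGRUENT"

    def test_known_species_without_hit_is_inconsistent(self):
        broken = NoveltyCall(
            mag_id="m", best_ani_hit=None, best_aai_hit=None,
            species_status="known_species", genus_status="unresolved",
        )
        with pytest.raises(ValueError, match="without a best ANI hit"):
            triage_mag(broken, 3, None, PASSED)

    def test_every_input_combination_receives_exactly_one_category(self):
        for ani, index, lca, verdict in itertools.product(
            (99.0, 80.0, None), range(1, 6), (CONGRUENT, INCONGRUENT, None), (PASSED, FAILED)
        ):
            result = triage_mag(novelty(ani=ani), index, lca, verdict)
            assert result.category in (
                {f"A{i}" for i in range(1, 6)}
                | {f"B{i}" for i in range(1, 6)}
                | {"REJECT_INCONGRUENT", "FAIL_QUALITY"}
            )


def mag(mag_id, completeness, contamination, n50=None, size=None):
    return MagRecord(
        mag_id=mag_id, completeness=completeness, contamination=contamination,
        n50=n50, genome_size=size,
    )


class TestDereplicate:
    def test_representative_maximises_quality_score(self):
        records = {
            "a": mag("a", 98, 1),   # score 93
            "b": mag("b", 97, 0.5),  # score 94.5 -> representative
            "c": mag("c", 96, 2),   # score 86
        }
        pairwise = {(x, y): 99.0 for x in records for y in records if x != y}
        (cluster,) = dereplicate(["a", "b", "c"], pairwise, records)
        assert cluster.representative == "b"
        assert cluster.representative_score == pytest.approx(94.5)

    def test_below_threshold_pairs_stay_singletons(self):
        records = {"a": mag("a", 98, 1), "b": mag("b", 97, 1)}
        clusters = dereplicate(["a", "b"], {("a", "b"): 90.0, ("b", "a"): 90.0}, records)
        assert [c.members for c in clusters] == [["a"], ["b"]]
        assert all(c.representative == c.members[0] for c in clusters)

    def test_single_linkage_chains_transitively(self):
        records = {m: mag(m, 98, 1) for m in "abc"}
        pairwise = {("a", "b"): 96.0, ("b", "a"): 96.0, ("b", "c"): 96.0, ("c", "b"): 96.0,
                    ("a", "c"): 94.0, ("c", "a"): 94.0}
        (cluster,) = dereplicate(["a", "b", "c"], pairwise, records)
        assert cluster.members == ["a", "b", "c"]

    def test_missing_record_is_an_error(self):
        with pytest.raises(ValueError, match="ghost"):
            dereplicate(["ghost"], {}, {})

    def test_tie_breaks_use_n50_then_size_then_id(self):
        records = {
            "b": mag("b", 98, 1, n50=50_000, size=6_000_000),
            "a": mag("a", 98, 1, n50=40_000, size=7_000_000),
        }
        pairwise = {("a", "b"): 99.0, ("b", "a"): 99.0}
        (cluster,) = dereplicate(["a", "b"], pairwise, records)
        assert cluster.representative == "b"  # larger N50 wins despite larger size of a

    @given(st.data())
    def test_matches_brute_force_union_find(self, data):
        n = data.draw(st.integers(min_value=1, max_value=12))
        members = [f"m{i}" for i in range(n)]
        records = {
            m: mag(m, data.draw(st.floats(min_value=90, max_value=100)),
                   data.draw(st.floats(min_value=0, max_value=5)))
            for m in members
        }
        pairwise = {}
        for i in range(n):
            for j in range(i + 1, n):
                value = data.draw(st.floats(min_value=80, max_value=100))
                pairwise[(members[i], members[j])] = value
                pairwise[(members[j], members[i])] = value

        # oracle: naive union-find over >= 95 edges
        parent = {m: m for m in members}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for (a, b), value in pairwise.items():
            if value >= 95.0:
                parent[find(a)] = find(b)
        oracle = {}
        for m in members:
            oracle.setdefault(find(m), set()).add(m)
        expected = sorted(sorted(c) for c in oracle.values())

        clusters = dereplicate(members, pairwise, records)
        assert sorted(c.members for c in clusters) == expected
        for cluster in clusters:
            best = max(
                cluster.members,
                key=lambda m: (records[m].completeness - 5 * records[m].contamination, m),
            )
            score = records[best].completeness - 5 * records[best].contamination
            assert cluster.representative_score == pytest.approx(
                records[cluster.representative].completeness
                - 5 * records[cluster.representative].contamination
            )
            assert cluster.representative_score == pytest.approx(score, abs=1e-9)
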