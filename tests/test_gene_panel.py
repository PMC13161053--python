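"""HMMER tblout parsing and panel presence/absence profiling."""

import pytest
from hypothesis import given, strategies as st

from magtriage.gene_panel import (
    TbloutRecord,
    load_panel,
    parse_tblout,
    profile_genes,
)
from magtriage.io_formats import GenePanelEntry, ParseError


def tbl_line(target="prot1", query="apcA", evalue="1.2e-30", score="250.3"):
    return f"{target} - {query} - {evalue} {score} 0.1 1e-30 249.0 0.1 1.0 1 1 0 1 1 1 1 ok"


class TestParseTblout:
    def test_valid_line_keeps_model_and_scores(self, tmp_path):
        path = tmp_path / "x.tbl"
        path.write_text("# comment\n" + tbl_line() + "\n")
        (rec,) = parse_tblout(path)
        assert rec.query_protein == "apcA"
        assert rec.full_seq_evalue == pytest.approx(1.2e-30)
        assert rec.full_seq_score == pytest.approx(250.3)

    def test_comment_only_file_is_empty(self, tmp_path):
        path = tmp_path / "x.tbl"
        path.write_text("# one\n# two\n")
        assert parse_tblout(path) == []

    def test_non_numeric_evalue_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "x.tbl"
        path.write_text(tbl_line() + "\n" + tbl_line(evalue="oops") + "\n")
        with pytest.raises(ParseError, match=":2:"):
            parse_tblout(path)

    def test_truncated_line_rejected(self, tmp_path):
        path = tmp_path / "x.tbl"
        path.write_text("too few fields here\n")
        with pytest.raises(ParseError, match="truncated"):
            parse_tblout(path)


PANEL = [
    GenePanelEntry(gene_symbol="apcA", category="phycobilisome", model_id="apcA"),
    GenePanelEntry(gene_symbol="cydA", category="electron_transport_respiration", model_id="cydA"),
    GenePanelEntry(gene_symbol="cydB", category="electron_transport_respiration", model_id="cydB"),
    GenePanelEntry(gene_symbol="cydX", category="electron_transport_respiration", model_id="cydX"),
    GenePanelEntry(gene_symbol="psaG", category="photosystem", model_id="psaG", eukaryote_specific=True),
]


def hits_for(models, evalue=1e-30):
    return [TbloutRecord(f"p_{m}", m, evalue, 200.0) for m in models]


class TestProfileGenes:
    def test_saturated_panel(self):
        profile = profile_genes(hits_for([e.gene_symbol for e in PANEL]), PANEL, mag_id="m")
        assert profile.present_count == profile.panel_size == len(PANEL)
        assert profile.missing_expected == []

    def test_no_hits_gives_zero_everywhere(self):
        profile = profile_genes([], PANEL)
        assert profile.present_count == 0
        assert profile.category_counts["electron_transport_respiration"] == (0, 3)
        assert profile.missing_expected == ["psaG"]

    def test_cytochrome_bd_absence_detected(self):
        present = [e.gene_symbol for e in PANEL if not e.gene_symbol.startswith("cyd")]
        profile = profile_genes(hits_for(present), PANEL)
        assert profile.present_count == len(PANEL) - 3
        missing = {g for g, p in profile.presence.items() if not p}
        assert missing == {"cydA", "cydB", "cydX"}

    def test_hits_above_cutoff_do_not_count(self):
        profile = profile_genes(hits_for(["apcA"], evalue=1e-3), PANEL, max_evalue=1e-5)
        assert not profile.presence["apcA"]

    def test_bitscore_mode(self):
        profile = profile_genes(hits_for(["apcA"], evalue=1.0), PANEL, min_bitscore=100.0)
        assert profile.presence["apcA"]

    def test_duplicate_hits_are_idempotent(self):
        once = profile_genes(hits_for(["apcA"]), PANEL)
        thrice = profile_genes(hits_for(["apcA", "apcA", "apcA"]), PANEL)
        assert once.presence == thrice.presence

    def test_hits_outside_panel_ignored(self):
        profile = profile_genes(hits_for(["notAPanelGene"]), PANEL)
        assert profile.present_count == 0

    @given(
        evalues=st.lists(
            st.floats(min_value=1e-60, max_value=1.0, allow_nan=False), min_size=1, max_size=20
        ),
        cutoff_a=st.floats(min_value=1e-40, max_value=1e-2),
        cutoff_b=st.floats(min_value=1e-40, max_value=1e-2),
    )
    def test_tightening_cutoff_never_adds_genes(self, evalues, cutoff_a, cutoff_b):
        lo, hi = sorted([cutoff_a, cutoff_b])
        panel = [
            GenePanelEntry(gene_symbol=f"g{i}", category="photosystem", model_id=f"g{i}")
            for i in range(len(evalues))
        ]
        hits = [TbloutRecord(f"p{i}", f"g{i}", e, 100.0) for i, e in enumerate(evalues)]
        tight = profile_genes(hits, panel, max_evalue=lo)
        loose = profile_genes(hits, panel, max_evalue=hi)
        assert tight.present_count <= loose.present_count
        # and the count matches an independent re-scan of the raw hits
        assert loose.present_count == sum(e <= hi for e in evalues)


class TestDefaultPanel:
    def test_default_panel_has_115_unique_genes(self):
        panel = load_panel()
        assert len(panel) == 115
        assert len({e.gene_symbol for e in panel}) == 115

    def test_eukaryote_specific_subunits_flagged(self):
        panel = load_panel()
        euk = {e.gene_symbol for e in panel if e.eukaryote_specific}
        assert euk == {"psaG", "psaH", "psaN", "psaO", "psbQ", "psbR", "psbW"}

    def test_category_totals_sum_to_panel_size(self):
        panel = load_panel()
        profile = profile_genes([], panel)
        assert sum(total for _, total in profile.category_counts.values()) == 115
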