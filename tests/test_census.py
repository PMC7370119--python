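"""Census loading, writing, and validation."""

import pytest

from rnamodcensus import (CensusError, CensusValidationError, load_census,
                          validate_census, write_census)
from rnamodcensus.census import TSV_COLUMNS

from conftest import make_census, make_record


HEADER = "\t".join(TSV_COLUMNS)


def row(short, status="placed", root="A", parent=""):
    cells = {c: "" for c in TSV_COLUMNS}
    cells.update(short_name=short, ascii_alias=short, full_name=f"fn {short}",
                 status=status, root_base=root, parent=parent)
    return "\t".join(cells[c] for c in TSV_COLUMNS)


class TestLoading:
    def test_packaged_census_cardinalities(self, census):
        assert len(census) == 158
        assert len(census.by_status("placed")) == 134
        assert len(census.by_status("unplaced")) == 3
        assert len(census.by_status("nascent")) == 21

    def test_lookup_by_short_name_and_alias(self, census):
        assert census["m6A"].full_name == "6-methyladenosine"
        assert census["psi"].short_name == "Ψ"
        assert census.find("psi-m").short_name == "Ψm"
        assert census.find("no-such-mark") is None

    def test_unresolvable_parent_is_an_error(self):
        text = "\n".join([HEADER, row("mX"), row("mY", parent="zzz")])
        with pytest.raises(CensusError, match="unresolvable parent"):
            load_census(text.encode(), format="tsv")

    def test_duplicate_short_name_names_both_rows(self):
        text = "\n".join([HEADER, row("m5C", root="C"), row("m5C", root="C")])
        with pytest.raises(CensusError, match=r"rows 1 and 2"):
            load_census(text.encode(), format="tsv")

    def test_unknown_column_is_an_error(self):
        text = HEADER + "\tbogus\n" + row("mX") + "\tv\n"
        with pytest.raises(CensusError, match="unknown TSV column"):
            load_census(text.encode(), format="tsv")

    def test_malformed_enum_reports_row_and_column(self):
        bad = row("mX").replace("placed", "misplaced")
        with pytest.raises(CensusError, match=r"row 2.*status"):
            load_census(("\n".join([HEADER, bad])).encode(), format="tsv")

    def test_json_schema_rejects_unknown_keys(self):
        doc = (b'{"version":"1","source_note":"x","records":'
               b'[{"short_name":"mX","ascii_alias":"mX","full_name":"f",'
               b'"status":"placed","root_base":"A","bogus":1}]}')
        with pytest.raises(CensusError, match="schema violation"):
            load_census(doc, format="json")


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_packaged_round_trip(self, census, fmt):
        reloaded = load_census(write_census(census, fmt), format=fmt)
        assert reloaded.records == census.records
        if fmt == "json":
            assert reloaded == census  # version/source_note survive JSON

    def test_dialect_equivalence(self, census):
        via_tsv = load_census(write_census(census, "tsv"), format="tsv")
        via_json = load_census(write_census(census, "json"), format="json")
        assert via_tsv.records == via_json.records

    def test_write_is_byte_stable(self, census):
        assert write_census(census, "tsv") == write_census(census, "tsv")
        assert write_census(census, "json") == write_census(census, "json")

    def test_write_refuses_invalid_census(self):
        bad = make_census([make_record("n1", status="nascent", parent="n1")])
        with pytest.raises(CensusValidationError) as exc:
            write_census(bad, "tsv")
        assert not exc.value.report.ok


class TestValidation:
    def test_packaged_census_is_valid(self, census):
        assert validate_census(census).ok

    def test_status_partition(self, census):
        total = sum(len(census.by_status(s))
                    for s in ("placed", "unplaced", "nascent"))
        assert total == len(census)

    def test_nascent_with_parent_flagged(self, census):
        bad = make_census(list(census.records)
                          + [make_record("capX", status="nascent", parent="m7G")])
        rules = {v[0] for v in validate_census(bad).violations}
        assert "nascent-has-parent" in rules

    def test_duplicate_short_name_flagged(self):
        recs = [make_record("m5C", root="C"), make_record("m5C", root="C")]
        rules = {v[0] for v in validate_census(make_census(recs)).violations}
        assert "duplicate-short-name" in rules

    def test_parent_cycle_flagged_once(self):
        recs = [make_record("x1", root="A", parent="y1"),
                make_record("y1", root="A", parent="x1")]
        report = validate_census(make_census(recs))
        cycles = [v for v in report.violations if v[0] == "parent-cycle"]
        assert len(cycles) == 1

    def test_parent_root_mismatch_flagged(self):
        recs = [make_record("mXu", root="U"),
                make_record("mXc", root="C", parent="mXu")]
        rules = {v[0] for v in validate_census(make_census(recs)).violations}
        assert "parent-root-mismatch" in rules

    def test_placed_needs_root_base(self):
        rules = {v[0] for v in
                 validate_census(make_census([make_record("mX")])).violations}
        assert "placed-missing-root" in rules

    def test_trna_positions_require_trna_class(self):
        rec = make_record("mX", root="A", trna_positions=("34",))
        rules = {v[0] for v in validate_census(make_census([rec])).violations}
        assert "trna-position-without-class" in rules


class TestCurationDetails:
    def test_unplaced_are_exactly_the_inset_marks(self, census):
        assert {r.short_name for r in census.by_status("unplaced")} == \
            {"ac6A", "cm5s2U", "cnm5U"}

    def test_doubly_glossed_legend_names_deduplicated(self, census):
        # the tree legend glosses these twice; one record each
        for name in ("m2,2Gm", "m2,7Gm"):
            assert sum(r.short_name == name for r in census.records) == 1

    def test_m3U_follows_tree_legend_not_text_gloss(self, census):
        assert census["m3U"].full_name == "3-methyluridine"

    def test_reversibility_only_where_stated(self, census):
        assert {r.short_name for r in census.records if r.reversible == "yes"} \
            == {"m1A", "m6A", "Am", "m6Am"}
        assert census["Q"].reversible == "no"
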