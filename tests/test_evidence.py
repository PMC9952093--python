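"""Evidence-table loading, bacterium normalization, shares and means."""

import pytest

from conftest import write_csv
from litmine.evidence import (
    category_share,
    load_activity_table,
    mean_activity,
    normalize_bacterium,
    packaged_table_path,
    summarize,
    write_activity_table,
)

HEADER = ["species", "part", "solvent", "bacterium", "value", "reference"]


def make_table(tmp_path, rows, name="table.csv"):
    return write_csv(tmp_path / name, HEADER, rows)


@pytest.fixture()
def toy_records(tmp_path):
    path = make_table(
        tmp_path,
        [
            ["Cistus alpha", "Leaves", "Ethanol", "S. aureus", "2", "r1"],
            ["Cistus alpha", "Leaves", "Ethanol", "S. aureus ATCC 1", "4", "r1"],
            ["Cistus beta", "Flowers", "Water", "E. coli", "1.5", "r2"],
            ["Cistus beta", "Fruits", "Water", "S. aureus", "0.5 #", "r2"],
        ],
    )
    return load_activity_table(path)


def test_load_parses_rows(toy_records):
    assert len(toy_records) == 4
    rec = toy_records[0]
    assert rec.bacterium == "Staphylococcus aureus"
    assert (rec.value, rec.unit, rec.measure) == (2.0, "mg_per_mL", "MIC")
    assert toy_records[3].measure == "MIC50"


def test_load_percent_range_flagged(tmp_path, caplog):
    path = make_table(
        tmp_path,
        [["Cistus x", "Aerial parts", "Hydroalcoholic", "Borrelia burgdorferi", "0.25-0.5%", "r1"]],
    )
    with caplog.at_level("WARNING"):
        records = load_activity_table(path)
    assert records[0].unit == "percent"
    assert records[0].value == pytest.approx(0.375)  # range midpoint
    assert "percent" in caplog.text


def test_load_rejects_malformed_value_with_row_number(tmp_path):
    path = make_table(
        tmp_path,
        [
            ["Cistus a", "Leaves", "Water", "E. coli", "1.0", "r1"],
            ["Cistus a", "Leaves", "Water", "E. coli", "abc", "r1"],
        ],
    )
    with pytest.raises(ValueError, match="row 3"):
        load_activity_table(path)


def test_load_requires_columns(tmp_path):
    path = write_csv(tmp_path / "bad.csv", ["species", "value"], [["x", "1"]])
    with pytest.raises(KeyError, match="missing columns"):
        load_activity_table(path)


@pytest.mark.parametrize(
    ("raw", "expected"),
    [
        ("S. aureus ATCC 29213", "Staphylococcus aureus"),
        ("Methicillin-resistant S. aureus", "Staphylococcus aureus"),
        ("Staphylococcus aureus", "Staphylococcus aureus"),
        ("E. coli ATCC 25922", "Escherichia coli"),
        ("E. faecalis", "Enterococcus faecalis"),
        ("Porphyromonas gingivalis W381", "Porphyromonas gingivalis"),
        ("Prevotella intermedia MSP 34", "Prevotella intermedia"),
    ],
)
def test_normalize_bacterium(raw, expected):
    assert normalize_bacterium(raw) == expected


def test_normalize_keeps_qualifier_on_request():
    assert (
        normalize_bacterium("Methicillin-resistant S. aureus", keep_qualifiers=True)
        == "Methicillin-resistant Staphylococcus aureus"
    )


def test_normalize_unmappable_kept_with_warning(caplog):
    with caplog.at_level("WARNING"):
        assert normalize_bacterium("X. unknownii") == "X. unknownii"
    assert "cannot expand" in caplog.text


def test_category_share_counts_rows(toy_records):
    shares = category_share(toy_records, "part").set_index("category")
    assert shares.loc["Leaves", "share_pct"] == 50
    assert shares.loc["Flowers", "share_pct"] == 25
    assert shares.loc["Fruits", "share_pct"] == 25


def test_category_share_single_record(toy_records):
    shares = category_share(toy_records[:1], "solvent")
    assert shares.loc[0, "share_exact"] == 100.0


def test_category_share_empty():
    with pytest.raises(ValueError):
        category_share([], "part")


def test_category_share_exact_sums_to_100(toy_records):
    for field in ("species", "part", "solvent", "bacterium"):
        assert category_share(toy_records, field)["share_exact"].sum() == pytest.approx(100.0)


def test_mean_activity_simple(toy_records):
    mean, n = mean_activity(toy_records, "Staphylococcus aureus", "MIC_only")
    assert (mean, n) == (3.0, 2)  # 2 and 4; the MIC50 row is out of scope
    mean, n = mean_activity(toy_records, "S. aureus", "MIC_and_MIC50")
    assert (mean, n) == (pytest.approx(6.5 / 3), 3)


def test_mean_activity_excludes_percent_rows(tmp_path):
    path = make_table(
        tmp_path,
        [
            ["C a", "Leaves", "Water", "E. coli", "2", "r"],
            ["C a", "Leaves", "Water", "E. coli", "4", "r"],
            ["C a", "Leaves", "Water", "E. coli", "0.5%", "r"],
        ],
    )
    records = load_activity_table(path)
    mean, n = mean_activity(records, "E. coli")
    assert (mean, n) == (3.0, 2)


def test_mean_activity_no_match(toy_records):
    assert mean_activity(toy_records, "Bacillus cereus") == (None, 0)


def test_mean_activity_invariances(toy_records):
    forward = mean_activity(toy_records, "S. aureus")
    backward = mean_activity(list(reversed(toy_records)), "S. aureus")
    assert forward == backward


def test_mean_activity_pools_strains(tmp_path):
    split = load_activity_table(
        make_table(
            tmp_path,
            [
                ["C a", "Leaves", "Water", "S. aureus ATCC 1", "2", "r"],
                ["C a", "Leaves", "Water", "S. aureus ATCC 2", "6", "r"],
            ],
            name="split.csv",
        )
    )
    pooled = load_activity_table(
        make_table(
            tmp_path,
            [
                ["C a", "Leaves", "Water", "Staphylococcus aureus", "2", "r"],
                ["C a", "Leaves", "Water", "Staphylococcus aureus", "6", "r"],
            ],
            name="pooled.csv",
        )
    )
    assert mean_activity(split, "S. aureus") == mean_activity(pooled, "S. aureus") == (4.0, 2)


def test_packaged_table_round_trips_byte_identically(tmp_path):
    source = packaged_table_path()
    records = load_activity_table(source)
    assert len(records) == 172
    out = tmp_path / "rewritten.csv"
    write_activity_table(records, out)
    assert out.read_bytes() == source.read_bytes()


def test_summarize_shape(toy_records):
    summary = summarize(toy_records)
    assert summary.n_records == 4
    assert set(summary.shares) == {"species", "part", "solvent", "bacterium"}
    means = summary.means.set_index("bacterium")
    assert means.loc["Staphylococcus aureus", "n"] == 2


def test_summarize_empty():
    with pytest.raises(ValueError):
        summarize([])
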