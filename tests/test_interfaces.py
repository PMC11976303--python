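"""Batch I/O, CLI subcommands, the JSON service, and config loading."""

import json
import threading
import urllib.request

import pytest
from click.testing import CliRunner

from phytonym import BatchLimitError, SchemaError, ToolkitConfig, generate_taxonomy
from phytonym.cli import main
from phytonym.config import load_config
from phytonym.io import (
    read_name_csv,
    read_name_workbook,
)
from phytonym.service import ServiceContext, dispatch, make_server


class TestReadNameCsv:
    def test_template_shaped(self, tmp_path):
        p = tmp_path / "names.csv"
        p.write_text("scientificName\nAcer palmatum\nQuercus robur\nPoa annua\n")
        assert read_name_csv(p) == ["Acer palmatum", "Quercus robur", "Poa annua"]

    def test_blank_rows_skipped_and_counted(self, tmp_path, caplog):
        p = tmp_path / "names.csv"
        p.write_text("scientificName\nAcer palmatum\n\nQuercus robur\n")
        with caplog.at_level("INFO", logger="phytonym.io"):
            names = read_name_csv(p)
        assert names == ["Acer palmatum", "Quercus robur"]
        assert "skipped 1" in caplog.text

    def test_headerless_rejected(self, tmp_path):
        p = tmp_path / "names.csv"
        p.write_text("Acer palmatum\nQuercus robur\n")
        with pytest.raises(SchemaError, match="scientificName"):
            read_name_csv(p)

    def test_case_insensitive_header(self, tmp_path):
        p = tmp_path / "names.csv"
        p.write_text("ScientificName\nAcer\n")
        assert read_name_csv(p) == ["Acer"]

    def test_limit_enforced(self, tmp_path):
        p = tmp_path / "names.csv"
        p.write_text("scientificName\n" + "\n".join(f"Name {i}" for i in range(5)))
        with pytest.raises(BatchLimitError):
            read_name_csv(p, limit=4)


def test_read_name_workbook_autodetects_column(tmp_path, caplog):
    # a synthetic stand-in for a published test workbook
    import openpyxl

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.append(["No", "TestName"])
    ws.append([1, "Acer palmatum"])
    ws.append([2, "Quercus robur"])
    path = tmp_path / "tests.xlsx"
    wb.save(path)
    with caplog.at_level("INFO", logger="phytonym.io"):
        names = read_name_workbook(path)
    assert names == ["Acer palmatum", "Quercus robur"]
    assert "TestName" in caplog.text  # the chosen column is logged


def test_config_file_round_trip(tmp_path):
    p = tmp_path / "phytonym.conf"
    p.write_text("batch_limit = 50\nfuzzy_mode = whole_string\n# comment\n")
    config = load_config(p)
    assert config.batch_limit == 50 and config.fuzzy_mode == "whole_string"


def test_config_unknown_key_rejected(tmp_path):
    p = tmp_path / "phytonym.conf"
    p.write_text("no_such_key = 1\n")
    with pytest.raises(ValueError, match="no_such_key"):
        load_config(p)


def test_default_config_registry_has_source_datasets():
    registry = ToolkitConfig().dataset_registry
    for code in ("COL", "GBIF", "WFO", "POWO", "LCVP", "COLChina"):
        assert code in registry


@pytest.fixture(scope="module")
def ingested_db(tmp_path_factory):
    """A store + TSV backbone built once for the CLI tests."""
    root = tmp_path_factory.mktemp("cli")
    taxonomy = generate_taxonomy(seed=21, n_genera=6, species_per_genus=5)
    tsv = root / "backbone.tsv"
    taxonomy.to_tsv(tsv)
    db = root / "records.sqlite"
    runner = CliRunner()
    result = runner.invoke(main, ["--db", str(db), "ingest", str(tsv),
                                  "--dataset", "SYNTH"])
    assert result.exit_code == 0, result.output
    return db, taxonomy


class TestCli:
    def test_ingest_reports_count(self, ingested_db):
        db, taxonomy = ingested_db
        runner = CliRunner()
        result = runner.invoke(main, ["--db", str(db), "index"])
        assert result.exit_code == 0, result.output
        assert f"records: {len(taxonomy.records)}" in result.output

    def test_normalize_stdin(self):
        result = CliRunner().invoke(main, ["normalize"], input="Acer   palmatum\n")
        assert result.exit_code == 0
        assert result.output.strip() == "Acer palmatum"

    def test_parse_stdin_csv_output(self):
        result = CliRunner().invoke(main, ["parse"], input="Acer palmatum Thunb.\n")
        assert result.exit_code == 0
        assert "parseRemark" in result.output.splitlines()[0]
        assert "Thunb." in result.output

    def test_match_roundtrip(self, ingested_db, tmp_path):
        db, taxonomy = ingested_db
        query = taxonomy.binomials()[0]
        names_csv = tmp_path / "q.csv"
        names_csv.write_text(f"scientificName\n{query}\n{query[:-1]}x\n")
        out_csv = tmp_path / "report.csv"
        result = CliRunner().invoke(
            main, ["--db", str(db), "match", str(names_csv), "--out", str(out_csv)]
        )
        assert result.exit_code == 0, result.output
        lines = out_csv.read_text().splitlines()
        assert lines[0].startswith("query,status,matchedName")
        assert lines[1].split(",")[1] == "Match"
        assert lines[2].split(",")[1] in ("Match", "Recorrect")

    def test_find_text(self, ingested_db, tmp_path):
        db, taxonomy = ingested_db
        name = taxonomy.binomials()[3]
        doc = tmp_path / "doc.txt"
        doc.write_text(f"We observed {name} growing wild.")
        html = tmp_path / "doc.html"
        result = CliRunner().invoke(
            main, ["--db", str(db), "find", str(doc), "--html", str(html)]
        )
        assert result.exit_code == 0, result.output
        assert name in result.output
        assert '<mark class="taxon">' in html.read_text()

    def test_retrieve_json(self, ingested_db):
        db, taxonomy = ingested_db
        genus = taxonomy.binomials()[0].split(" ")[0]
        result = CliRunner().invoke(main, ["--db", str(db), "retrieve", genus])
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert payload["totalHits"] >= 1
        assert set(payload["facets"]) == {
            "taxonRank", "taxonomicStatus", "namePublishedInYear", "datasetID",
        }

    def test_benchmark_command(self, tmp_path):
        result = CliRunner().invoke(
            main,
            ["benchmark", "--seed", "5", "--n-per-category", "20",
             "--out-dir", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "match_benchmark.csv").exists()
        assert (tmp_path / "parse_benchmark.csv").exists()


@pytest.fixture(scope="module")
def ctx():
    taxonomy = generate_taxonomy(seed=8, n_genera=5, species_per_genus=4)
    from phytonym import build_index

    return ServiceContext(build_index(taxonomy.records))


class TestService:
    def test_parse_route(self, ctx):
        status, body = dispatch("/Api/Parse", {"name": "Acer palmatum Thunb."}, ctx)
        assert status == 200 and body["status"] == "ok"
        assert body["result"]["genusOrAbove"] == "Acer"
        assert body["result"]["scientificNameAuthorship"] == "Thunb."

    def test_match_route_limit(self, ctx):
        status, body = dispatch("/Api/Match", {"names": ["x"] * 1001}, ctx)
        assert status == 400 and body["code"] == "batch_limit"
        assert "1000" in body["message"]

    def test_detail_not_found(self, ctx):
        status, body = dispatch("/Api/Detail", {"recordID": 10**6}, ctx)
        assert status == 404 and body["code"] == "not_found"

    def test_malformed_payload(self, ctx):
        status, body = dispatch("/Api/Parse", {"nom": "Acer"}, ctx)
        assert status == 400 and body["code"] == "bad_request"

    def test_unknown_route(self, ctx):
        status, body = dispatch("/Api/Frobnicate", {}, ctx)
        assert status == 404 and body["code"] == "unknown_route"

    def test_service_cli_parity_for_match(self, ctx):
        """The service and the batch matcher expose identical result fields."""
        name = ctx.index.records[1].scientificName
        _, body = dispatch("/Api/Match", {"names": [name]}, ctx)
        from phytonym import match_batch

        (direct,) = match_batch([name], ctx.index)
        via_api = body["result"]["results"][0]
        assert via_api["status"] == direct.status
        assert via_api["stageUsed"] == direct.stage_used
        assert (
            via_api["candidates"][0]["scientificName"]
            == direct.best.record.scientificName
        )

    def test_live_http_round_trip(self, ctx):
        server = make_server(ctx, "127.0.0.1", 0)
        port = server.server_address[1]
        thread = threading.Thread(target=server.serve_forever, daemon=True)
        thread.start()
        try:
            req = urllib.request.Request(
                f"http://127.0.0.1:{port}/Api/Search",
                data=json.dumps(
                    {"text": f"Saw {ctx.index.records[1].scientificName} today"}
                ).encode(),
                headers={"Content-Type": "application/json"},
            )
            with urllib.request.urlopen(req, timeout=10) as resp:
                body = json.loads(resp.read())
            assert body["status"] == "ok"
            assert len(body["result"]["matches"]) == 1
        finally:
            server.shutdown()
            server.server_close()
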