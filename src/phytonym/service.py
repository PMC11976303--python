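"""JSON service layer: five routes mirroring the toolkit's operations.

``dispatch`` is a pure function from (route, payload) to a status code
and a JSON-serializable body, so the service logic is testable without a
socket; ``make_server`` wraps it in a stdlib threading HTTP server
exposing ``/Api/Retrieval``, ``/Api/Match``, ``/Api/Search``,
``/Api/Parse`` and ``/Api/Detail`` as POST endpoints.  Responses reuse
Darwin Core term names verbatim; errors carry machine-readable codes and
never leak stack traces.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from . import __version__
from .config import DEFAULT_CONFIG, ToolkitConfig
from .errors import BatchLimitError, RecordNotFoundError
from .finder import find_names
from .matcher import MatchResult, match_batch
from .nameindex import NameIndex
from .parser import parse_name
from .retrieval import DetailResult, ResultPage, RetrievalQuery, detail, retrieve

log = logging.getLogger(__name__)

ROUTES = ("retrieval", "match", "search", "parse", "detail")


@dataclass
class ServiceContext:
    index: NameIndex
    config: ToolkitConfig = field(default_factory=lambda: DEFAULT_CONFIG)


class PayloadError(ValueError):
    pass


def _require(payload: dict, key: str, types) -> object:
    if key not in payload:
        raise PayloadError(f"missing field: {key}")
    value = payload[key]
    if not isinstance(value, types):
        raise PayloadError(f"field {key} has the wrong type")
    return value


def _match_result_json(res: MatchResult) -> dict:
    return {
        "query": res.query,
        "status": res.status,
        "stageUsed": res.stage_used,
        "candidates": [
            {
                **c.record.as_dict(),
                "totalDistance": c.total_distance,
                "similarity": round(c.similarity, 6),
            }
            for c in res.candidates
        ],
    }


def _page_json(page: ResultPage) -> dict:
    return {
        "totalHits": page.totalHits,
        "page": page.page,
        "pageSize": page.pageSize,
        "hits": [r.as_dict() for r in page.hits],
        "facets": page.facets,
    }


def _detail_json(d: DetailResult) -> dict:
    return {
        **d.record.as_dict(),
        "acceptedName": d.acceptedName,
        "acceptedRecord": d.acceptedRecord.as_dict() if d.acceptedRecord else None,
        "higherClassificationResolved": d.lineage,
        "warning": d.warning,
    }


def dispatch(route: str, payload: dict, ctx: ServiceContext) -> tuple[int, dict]:
    """Execute one API request; returns (HTTP status, response body)."""
    route = route.strip("/").casefold().removeprefix("api/")
    try:
        if not isinstance(payload, dict):
            raise PayloadError("payload must be a JSON object")
        if route == "parse":
            name = _require(payload, "name", str)
            result = parse_name(name).as_dict()
        elif route == "match":
            if "names" in payload:
                names = _require(payload, "names", list)
                if not all(isinstance(n, str) for n in names):
                    raise PayloadError("names must be a list of strings")
            else:
                names = [_require(payload, "name", str)]
            datasets = payload.get("datasets")
            if datasets is not None and not (
                isinstance(datasets, list) and all(isinstance(d, str) for d in datasets)
            ):
                raise PayloadError("datasets must be a list of strings")
            results = match_batch(names, ctx.index, datasets, ctx.config)
            result = {"results": [_match_result_json(r) for r in results]}
        elif route == "search":
            text = _require(payload, "text", str)
            matches = find_names(text, ctx.index, ctx.config.finder_min_tokens)
            result = {"matches": [m.as_dict() for m in matches]}
        elif route == "retrieval":
            query = RetrievalQuery(
                queryText=str(payload.get("query", "")),
                yearFilter=_year_filter(payload.get("year")),
                rankFilter=_str_set(payload, "rank"),
                statusFilter=_str_set(payload, "status"),
                datasetFilter=_str_set(payload, "datasets"),
                includeVernacular=bool(payload.get("includeVernacular", False)),
                page=int(payload.get("page", 1)),
                pageSize=int(payload.get("pageSize", 0)),
            )
            result = _page_json(retrieve(query, ctx.index, ctx.config))
        elif route == "detail":
            record_id = _require(payload, "recordID", int)
            result = _detail_json(detail(record_id, ctx.index))
        else:
            return 404, _error("unknown_route", f"unknown route: {route!r}")
        return 200, {"status": "ok", "version": __version__, "result": result}
    except BatchLimitError as exc:
        return 400, _error("batch_limit", str(exc))
    except RecordNotFoundError as exc:
        return 404, _error("not_found", str(exc))
    except (PayloadError, ValueError) as exc:
        return 400, _error("bad_request", str(exc))
    except Exception:
        log.exception("internal error on route %r", route)
        return 500, _error("internal_error", "internal server error")


def _error(code: str, message: str) -> dict:
    return {"status": "error", "version": __version__, "code": code, "message": message}


def _year_filter(value) -> tuple[int, int] | int | None:
    if value is None:
        return None
    if isinstance(value, int):
        return value
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return int(value[0]), int(value[1])
    raise PayloadError("year must be an integer or a [from, to] pair")


def _str_set(payload: dict, key: str) -> set[str] | None:
    value = payload.get(key)
    if value is None:
        return None
    if isinstance(value, list) and all(isinstance(v, str) for v in value):
        return set(value)
    raise PayloadError(f"{key} must be a list of strings")


def make_server(
    ctx: ServiceContext, host: str = "127.0.0.1", port: int = 8440
) -> ThreadingHTTPServer:
    """Build (but do not start) the HTTP server; call ``serve_forever()``."""

    class Handler(BaseHTTPRequestHandler):
        def do_POST(self) -> None:  # noqa: N802 (stdlib API)
            try:
                length = int(self.headers.get("Content-Length", 0))
                body = self.rfile.read(length) if length else b"{}"
                payload = json.loads(body or b"{}")
            except (ValueError, json.JSONDecodeError):
                status, response = 400, _error("bad_request", "invalid JSON body")
            else:
                status, response = dispatch(self.path, payload, ctx)
            data = json.dumps(response).encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json; charset=utf-8")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def log_message(self, fmt: str, *args) -> None:
            log.info("%s " + fmt, self.client_address[0], *args)

    return ThreadingHTTPServer((host, port), Handler)


def serve(ctx: ServiceContext, host: str = "127.0.0.1", port: int = 8440) -> None:
    """Run the service until interrupted."""
    server = make_server(ctx, host, port)
    log.info("serving on http://%s:%d/Api/<Route>", host, port)
    try:
        server.serve_forever()
    finally:
        server.server_close()
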