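"""Programmatic access point: vocabularies, matching, standardization
as a service, study persistence and string-equality sample retrieval.

The service is an in-process object whose methods mirror the HTTP
endpoints a repository frontend would call; a thin stdlib WSGI
adapter (:func:`create_wsgi_app`) exposes the same surface over HTTP
for integration into existing pipelines.  The service owns one
vocabulary store and its fitted matcher models; vocabulary mutations
are serialized behind a lock and immediately refit the affected
models, and any detected store/model version skew makes the service
refuse queries until retrained.

Stored studies are re-validated on ingest: a matrix that does not
satisfy the standardization guarantee (every non-empty controlled
value is a main term) is rejected, so everything in storage is
queryable by plain string equality.
"""

from __future__ import annotations

import json
import threading
import time
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol
from urllib.parse import parse_qsl

from .categories import REGISTRY, get_category
from .errors import CategoryError, MatrixValidationError, SampleMetaError
from .matcher import TrigramModel, nearest
from .matrix_io import SubmissionMatrix
from .standardizer import (
    ConfirmationRequired,
    ConfirmationSet,
    fit_models,
    standardize,
    verify_guarantee,
)
from .vocabulary import VocabularyStore, normalize_string

__all__ = [
    "StoredStudy",
    "MemoryStorage",
    "FileStorage",
    "MetadataService",
    "create_wsgi_app",
]


@dataclass
class StoredStudy:
    study_id: str
    author: str
    submitted_at: float
    matrix: SubmissionMatrix
    report: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "author": self.author,
            "submitted_at": self.submitted_at,
            "matrix": matrix_to_payload(self.matrix),
            "report": self.report,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StoredStudy":
        return cls(
            study_id=data["study_id"],
            author=data["author"],
            submitted_at=data["submitted_at"],
            matrix=matrix_from_payload(data["matrix"]),
            report=data.get("report", {}),
        )


def matrix_to_payload(matrix: SubmissionMatrix) -> dict:
    return {"categories": matrix.category_names, "rows": matrix.rows}


def matrix_from_payload(payload: dict) -> SubmissionMatrix:
    try:
        categories = [get_category(name) for name in payload["categories"]]
        rows = [list(r) for r in payload["rows"]]
    except KeyError as exc:
        raise MatrixValidationError(f"matrix payload missing {exc}") from None
    matrix = SubmissionMatrix(categories=categories, rows=rows)
    matrix.validate()
    return matrix


class StudyStorage(Protocol):
    """Persistence interface for standardized studies."""

    def save(self, study: StoredStudy) -> None: ...

    def get(self, study_id: str) -> StoredStudy | None: ...

    def all(self) -> Iterable[StoredStudy]: ...


class MemoryStorage:
    def __init__(self) -> None:
        self._studies: dict[str, StoredStudy] = {}

    def save(self, study: StoredStudy) -> None:
        self._studies[study.study_id] = study

    def get(self, study_id: str) -> StoredStudy | None:
        return self._studies.get(study_id)

    def all(self) -> list[StoredStudy]:
        return [self._studies[k] for k in sorted(self._studies)]


class FileStorage:
    """One JSON file per study under a directory."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, study_id: str) -> Path:
        return self.directory / f"{study_id}.json"

    def save(self, study: StoredStudy) -> None:
        with open(self._path(study.study_id), "w", encoding="utf-8") as fh:
            json.dump(study.to_dict(), fh)
            fh.write("\n")

    def get(self, study_id: str) -> StoredStudy | None:
        path = self._path(study_id)
        if not path.exists():
            return None
        with open(path, encoding="utf-8") as fh:
            return StoredStudy.from_dict(json.load(fh))

    def all(self) -> list[StoredStudy]:
        studies = []
        for path in sorted(self.directory.glob("*.json")):
            with open(path, encoding="utf-8") as fh:
                studies.append(StoredStudy.from_dict(json.load(fh)))
        return studies


class MetadataService:
    """Vocabulary queries, standardization and sample retrieval."""

    def __init__(
        self,
        store: VocabularyStore,
        storage: StudyStorage | None = None,
        models: dict[str, TrigramModel] | None = None,
    ):
        self.store = store
        self.storage: StudyStorage = storage if storage is not None else MemoryStorage()
        self.models = models if models is not None else fit_models(store)
        self._lock = threading.Lock()
        self._check_versions()

    def _check_versions(self) -> None:
        from .standardizer import _check_model_versions

        _check_model_versions(self.store, self.models)

    # -- vocabulary endpoints ----------------------------------------

    def list_categories(self) -> list[dict]:
        out = []
        for name, spec in REGISTRY.items():
            entry = {
                "name": name,
                "grouping": spec.grouping.value,
                "value_class": spec.value_class.value,
            }
            if name in self.store:
                entry["term_count"] = len(self.store[name].main_terms)
            out.append(entry)
        return out

    def get_terms(
        self,
        category: str,
        prefix: str | None = None,
        offset: int = 0,
        limit: int = 50,
    ) -> dict:
        vocab = self.store[category]
        terms = sorted(vocab.main_terms)
        if prefix:
            p = normalize_string(prefix)
            terms = [t for t in terms if t.startswith(p)]
        return {
            "category": category,
            "total": len(terms),
            "offset": offset,
            "limit": limit,
            "terms": terms[offset : offset + limit],
        }

    def match(self, category: str, strings: list[str], k: int = 5) -> list[dict]:
        self._check_versions()
        model = self.models.get(category)
        if model is None:
            raise CategoryError(f"no model for category {category!r}")
        results = []
        for s in strings:
            result = nearest(model, s, k)
            results.append(
                {
                    "query": s,
                    "decision": result.decision,
                    "candidates": [
                        {
                            "term": c.term,
                            "surface": c.surface,
                            "similarity": c.similarity,
                        }
                        for c in result.candidates
                    ],
                }
            )
        return results

    # -- standardization ---------------------------------------------

    def standardize(
        self, matrix_payload: dict, confirmations_payload: dict | None = None
    ) -> tuple[int, dict]:
        """Standardize a matrix; commit new terms on success.

        Returns ``(200, result payload)`` on success or ``(409,
        pending payload)`` when confirmations are still needed.
        """
        matrix = matrix_from_payload(matrix_payload)
        confirmations = (
            ConfirmationSet.from_dict(confirmations_payload)
            if confirmations_payload
            else None
        )
        with self._lock:
            self._check_versions()
            try:
                result = standardize(matrix, self.store, self.models, confirmations)
            except ConfirmationRequired as exc:
                return 409, {
                    "needs_confirmation": [p.to_dict() for p in exc.pending]
                }
            self.store = result.store
            self.models = result.models
        return 200, {
            "matrix": matrix_to_payload(result.matrix),
            "report": result.report.to_dict(),
        }

    def add_main_term(self, category: str, term: str) -> bool:
        """Add a vocabulary term and refit its model (serialized)."""
        with self._lock:
            changed = self.store.add_main_term(category, term)
            if changed:
                from .matcher import fit

                self.models[category] = fit(self.store[category])
            return changed

    # -- studies ------------------------------------------------------

    def submit_study(
        self, author: str, matrix_payload: dict, report: dict | None = None
    ) -> str:
        matrix = matrix_from_payload(matrix_payload)
        violations = verify_guarantee(matrix, self.store)
        if violations:
            listed = ", ".join(
                f"(row {r + 1}, {c}, {v!r})" for r, c, v in violations[:5]
            )
            raise MatrixValidationError(
                f"matrix violates the standardization guarantee: {listed}"
            )
        study = StoredStudy(
            study_id=uuid.uuid4().hex,
            author=author,
            submitted_at=time.time(),
            matrix=matrix,
            report=report or {},
        )
        self.storage.save(study)
        return study.study_id

    def list_studies(self) -> list[dict]:
        return [
            {
                "study_id": s.study_id,
                "author": s.author,
                "submitted_at": s.submitted_at,
                "n_samples": len(s.matrix.rows),
            }
            for s in self.storage.all()
        ]

    def query_samples(
        self, filters: list[tuple[str, str]]
    ) -> list[tuple[str, int]]:
        """Samples matching every (category, value) filter by string equality.

        A sample matches a filter when the cell's ``";"``-delimited
        value set contains the normalized value; filters are
        conjunctive.  An empty filter list matches every sample.
        """
        for category, _ in filters:
            get_category(category)
        wanted = [(c, normalize_string(v)) for c, v in filters]
        hits: list[tuple[str, int]] = []
        for study in self.storage.all():
            names = study.matrix.category_names
            for i, row in enumerate(study.matrix.rows):
                ok = True
                for category, value in wanted:
                    if category not in names:
                        ok = False
                        break
                    cell = row[names.index(category)]
                    if value not in {p.strip() for p in cell.split(";")}:
                        ok = False
                        break
                if ok:
                    hits.append((study.study_id, i))
        return hits


# -- WSGI adapter ----------------------------------------------------


def create_wsgi_app(service: MetadataService):
    """A minimal WSGI wrapper over the service (stdlib only).

    Routes: ``GET /categories``, ``GET /vocabularies/<cat>/terms``,
    ``POST /match``, ``POST /standardize``, ``POST /studies``,
    ``GET /studies``, ``GET /samples``.  Bodies and responses are
    JSON; ``GET /samples`` takes category=value query parameters.
    """

    def respond(start_response, status: int, payload) -> list[bytes]:
        body = json.dumps(payload).encode()
        reasons = {200: "OK", 400: "Bad Request", 404: "Not Found", 409: "Conflict"}
        start_response(
            f"{status} {reasons.get(status, 'Error')}",
            [("Content-Type", "application/json"), ("Content-Length", str(len(body)))],
        )
        return [body]

    def read_json(environ) -> dict:
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        raw = environ["wsgi.input"].read(length) if length else b"{}"
        return json.loads(raw.decode() or "{}")

    def app(environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/").rstrip("/") or "/"
        query = dict(parse_qsl(environ.get("QUERY_STRING", "")))
        try:
            if method == "GET" and path == "/categories":
                return respond(start_response, 200, service.list_categories())
            if method == "GET" and path.startswith("/vocabularies/") and path.endswith(
                "/terms"
            ):
                category = path[len("/vocabularies/") : -len("/terms")]
                return respond(
                    start_response,
                    200,
                    service.get_terms(
                        category,
                        prefix=query.get("prefix"),
                        offset=int(query.get("offset", 0)),
                        limit=int(query.get("limit", 50)),
                    ),
                )
            if method == "POST" and path == "/match":
                body = read_json(environ)
                return respond(
                    start_response,
                    200,
                    service.match(body["category"], body["strings"], int(body.get("k", 5))),
                )
            if method == "POST" and path == "/standardize":
                body = read_json(environ)
                status, payload = service.standardize(
                    body["matrix"], body.get("confirmations")
                )
                return respond(start_response, status, payload)
            if method == "POST" and path == "/studies":
                body = read_json(environ)
                study_id = service.submit_study(
                    body.get("author", ""), body["matrix"], body.get("report")
                )
                return respond(start_response, 200, {"study_id": study_id})
            if method == "GET" and path == "/studies":
                return respond(start_response, 200, service.list_studies())
            if method == "GET" and path == "/samples":
                filters = [(k, v) for k, v in query.items()]
                hits = service.query_samples(filters)
                return respond(
                    start_response,
                    200,
                    [{"study_id": s, "row": r} for s, r in hits],
                )
        except (SampleMetaError, KeyError, ValueError) as exc:
            return respond(start_response, 400, {"error": str(exc)})
        return respond(start_response, 404, {"error": f"no route {method} {path}"})

    return app
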