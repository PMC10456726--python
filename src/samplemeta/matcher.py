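"""Character-trigram tf-idf matching of freetext against vocabularies.

Every vocabulary *surface* (main term or synonym) is embedded in a
vector space whose dimensions are the character trigrams occurring in
at least one surface — sliding length-3 windows over the full string,
spaces included, no boundary padding, so ``mus musculus`` yields
``mus``, ``us ``, ``s m``, `` mu``, ``usc`` (and ``mus`` again: grams
carry multiplicity).  Weights are tf-idf: raw gram count times a
smoothed inverse document frequency ``ln((1+D)/(1+df)) + 1`` over the
D surfaces, followed by L2 normalization.  A query is coerced into the
fitted space (unknown grams are dropped) and ranked against all
surfaces by cosine similarity; the winning surface's main term is the
match.  Synonyms are first-class rows, so ``mouse`` matches its own
vector at 1.0 and then maps onto ``mus musculus``.

Exact main-term or synonym hits short-circuit the vector search at
similarity 1.0.  A query sharing no gram with the vocabulary has the
zero vector and is unmatched.  Decisions are threshold-based: cosine
at or above ``accept_threshold`` is applied automatically, at or above
``propose_threshold`` it becomes a proposal needing confirmation, and
below that the query is unmatched.

``fit`` is backed by scikit-learn's ``TfidfVectorizer`` (the standard
implementation of exactly this weighting); :func:`brute_force_nearest`
is a deliberately independent pure-Python re-derivation used as a
cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import log, sqrt
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .vocabulary import Vocabulary, normalize_string

__all__ = [
    "DEFAULT_ACCEPT_THRESHOLD",
    "DEFAULT_PROPOSE_THRESHOLD",
    "extract_ngrams",
    "TrigramModel",
    "Candidate",
    "MatchResult",
    "fit",
    "vectorize",
    "nearest",
    "BruteForceMatcher",
    "brute_force_nearest",
    "SubstringHit",
    "substring_match",
    "save_model",
    "load_model",
]

DEFAULT_ACCEPT_THRESHOLD = 0.80
DEFAULT_PROPOSE_THRESHOLD = 0.20

#: Similarities are quantized at this resolution before ranking so the
#: indexed and brute-force paths break ties identically despite
#: last-bit float differences.
_RANK_QUANTUM = 1e-12


def extract_ngrams(s: str, n: int = 3) -> list[str]:
    """All length-``n`` sliding windows over ``s``, with multiplicity.

    Internal spaces participate in grams; there is no boundary
    padding.  A non-empty string shorter than ``n`` contributes itself
    as a single gram (units like ``"g"`` must stay representable); the
    empty string yields no grams.
    """
    if not s:
        return []
    if len(s) < n:
        return [s]
    return [s[i : i + n] for i in range(len(s) - n + 1)]


@dataclass(frozen=True)
class ModelRow:
    surface: str
    maps_to: str
    category: str


@dataclass(frozen=True)
class Candidate:
    """One ranked match candidate."""

    term: str
    surface: str
    similarity: float


@dataclass(frozen=True)
class MatchResult:
    query: str
    candidates: tuple[Candidate, ...]
    decision: Literal["auto", "proposed", "unmatched"]

    @property
    def best(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None


@dataclass
class TrigramModel:
    """The fitted trigram tf-idf space over a set of vocabulary surfaces."""

    n: int
    component_index: dict[str, int]
    idf: np.ndarray
    matrix: sp.csr_matrix  # L2-normalized surface vectors, one row per surface
    rows: list[ModelRow]
    vocab_versions: dict[str, int]
    _exact: dict[str, ModelRow] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._exact:
            # first surface wins on (unlikely) cross-category collisions;
            # rows are already in deterministic order
            for row in self.rows:
                self._exact.setdefault(row.surface, row)

    @property
    def n_components(self) -> int:
        return len(self.component_index)


def _surfaces_in_order(vocabularies: Sequence[Vocabulary]) -> list[ModelRow]:
    rows: list[ModelRow] = []
    for vocab in vocabularies:
        for surface, main in vocab.surfaces():
            rows.append(ModelRow(surface=surface, maps_to=main, category=vocab.category.name))
    return rows


def fit(vocabularies: Vocabulary | Iterable[Vocabulary], n: int = 3) -> TrigramModel:
    """Fit the trigram tf-idf space on every surface of the vocabularies.

    Dimensions are the union of the surfaces' grams; each surface row
    is tf-idf weighted and unit-normalized.  Raises ``ValueError``
    when there is no surface to fit on.
    """
    if isinstance(vocabularies, Vocabulary):
        vocabularies = [vocabularies]
    vocabularies = list(vocabularies)
    rows = _surfaces_in_order(vocabularies)
    if not rows:
        raise ValueError("cannot fit a trigram model on zero surfaces")
    vectorizer = TfidfVectorizer(
        analyzer=lambda s: extract_ngrams(s, n),
        lowercase=False,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    matrix = vectorizer.fit_transform([row.surface for row in rows]).tocsr()
    component_index = {gram: int(i) for gram, i in vectorizer.vocabulary_.items()}
    return TrigramModel(
        n=n,
        component_index=component_index,
        idf=np.asarray(vectorizer.idf_, dtype=float),
        matrix=matrix,
        rows=rows,
        vocab_versions={v.category.name: v.version for v in vocabularies},
    )


def vectorize(model: TrigramModel, s: str) -> np.ndarray:
    """Coerce a string into the fitted space as a dense unit vector.

    Grams absent from the fitted component index are dropped; when no
    gram is known the zero vector is returned.
    """
    vec = np.zeros(model.n_components)
    for gram in extract_ngrams(normalize_string(s), model.n):
        idx = model.component_index.get(gram)
        if idx is not None:
            vec[idx] += model.idf[idx]
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def _rank_key(similarity: float, surface: str) -> tuple[float, int, str]:
    return (-round(similarity / _RANK_QUANTUM) * _RANK_QUANTUM, len(surface), surface)


def _decide(
    best: float | None, accept_threshold: float, propose_threshold: float
) -> Literal["auto", "proposed", "unmatched"]:
    if best is None:
        return "unmatched"
    if best >= accept_threshold:
        return "auto"
    if best >= propose_threshold:
        return "proposed"
    return "unmatched"


def nearest(
    model: TrigramModel,
    s: str,
    k: int = 5,
    *,
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD,
    propose_threshold: float = DEFAULT_PROPOSE_THRESHOLD,
) -> MatchResult:
    """Top-``k`` vocabulary surfaces by cosine similarity to ``s``.

    An exact surface hit (main term or synonym) short-circuits to an
    automatic decision at similarity 1.0.  Ties are broken by shorter
    surface, then lexicographic surface order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = normalize_string(s)
    exact = model._exact.get(q)
    if exact is not None:
        return MatchResult(
            query=s,
            candidates=(Candidate(exact.maps_to, exact.surface, 1.0),),
            decision="auto",
        )
    qvec = vectorize(model, q)
    if not qvec.any():
        return MatchResult(query=s, candidates=(), decision="unmatched")
    sims = model.matrix @ qvec
    order = sorted(
        range(len(model.rows)),
        key=lambda i: _rank_key(float(sims[i]), model.rows[i].surface),
    )
    candidates = tuple(
        Candidate(model.rows[i].maps_to, model.rows[i].surface, float(sims[i]))
        for i in order[:k]
    )
    decision = _decide(
        candidates[0].similarity if candidates else None,
        accept_threshold,
        propose_threshold,
    )
    return MatchResult(query=s, candidates=candidates, decision=decision)


class BruteForceMatcher:
    """Independent oracle: per-pair tf-idf cosine without the indexed model.

    Re-derives document frequencies, idf weights and surface vectors
    with plain dictionaries and ``math`` — no scikit-learn, no shared
    code with :func:`fit`/:func:`vectorize` beyond the gram extractor
    and the published weighting formula.
    """

    def __init__(self, vocabularies: Vocabulary | Iterable[Vocabulary], n: int = 3):
        if isinstance(vocabularies, Vocabulary):
            vocabularies = [vocabularies]
        self.n = n
        self.rows = _surfaces_in_order(list(vocabularies))
        if not self.rows:
            raise ValueError("cannot match against zero surfaces")
        counts_per_surface: list[dict[str, int]] = []
        df: dict[str, int] = {}
        for row in self.rows:
            counts: dict[str, int] = {}
            for gram in extract_ngrams(row.surface, n):
                counts[gram] = counts.get(gram, 0) + 1
            counts_per_surface.append(counts)
            for gram in counts:
                df[gram] = df.get(gram, 0) + 1
        n_docs = len(self.rows)
        self.idf = {
            gram: log((1 + n_docs) / (1 + d)) + 1.0 for gram, d in df.items()
        }
        self.vectors: list[dict[str, float]] = []
        for counts in counts_per_surface:
            weighted = {g: c * self.idf[g] for g, c in counts.items()}
            norm = sqrt(sum(w * w for w in weighted.values()))
            self.vectors.append(
                {g: w / norm for g, w in weighted.items()} if norm > 0 else {}
            )
        self._exact: dict[str, ModelRow] = {}
        for row in self.rows:
            self._exact.setdefault(row.surface, row)

    def query_vector(self, s: str) -> dict[str, float]:
        weighted: dict[str, float] = {}
        for gram in extract_ngrams(normalize_string(s), self.n):
            if gram in self.idf:
                weighted[gram] = weighted.get(gram, 0.0) + self.idf[gram]
        norm = sqrt(sum(w * w for w in weighted.values()))
        return {g: w / norm for g, w in weighted.items()} if norm > 0 else {}

    def nearest(
        self,
        s: str,
        k: int = 5,
        *,
        accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD,
        propose_threshold: float = DEFAULT_PROPOSE_THRESHOLD,
    ) -> MatchResult:
        q = normalize_string(s)
        exact = self._exact.get(q)
        if exact is not None:
            return MatchResult(
                query=s,
                candidates=(Candidate(exact.maps_to, exact.surface, 1.0),),
                decision="auto",
            )
        qvec = self.query_vector(q)
        if not qvec:
            return MatchResult(query=s, candidates=(), decision="unmatched")
        sims = [
            sum(w * vec.get(g, 0.0) for g, w in qvec.items()) for vec in self.vectors
        ]
        order = sorted(
            range(len(self.rows)),
            key=lambda i: _rank_key(sims[i], self.rows[i].surface),
        )
        candidates = tuple(
            Candidate(self.rows[i].maps_to, self.rows[i].surface, sims[i])
            for i in order[:k]
        )
        decision = _decide(
            candidates[0].similarity, accept_threshold, propose_threshold
        )
        return MatchResult(query=s, candidates=candidates, decision=decision)


def brute_force_nearest(
    vocabularies: Vocabulary | Iterable[Vocabulary],
    s: str,
    k: int = 5,
    **thresholds,
) -> MatchResult:
    """One-shot wrapper around :class:`BruteForceMatcher`."""
    return BruteForceMatcher(vocabularies).nearest(s, k, **thresholds)


@dataclass(frozen=True)
class SubstringHit:
    term: str
    surface: str
    direction: Literal["query_in_surface", "surface_in_query"]
    score: float  # |shorter| / |longer|


def substring_match(
    vocabularies: Vocabulary | Iterable[Vocabulary], s: str
) -> list[SubstringHit]:
    """Surfaces containing the query, or contained in it.

    The second-pass rescue for abbreviations and truncations: a hit is
    any surface (main or synonym) such that the normalized query is a
    substring of the surface or vice versa.  Hits are ranked by length
    ratio ``|shorter|/|longer|`` descending, then shorter surface,
    then lexicographic surface.
    """
    q = normalize_string(s)
    if not q:
        raise ValueError("substring_match requires a non-empty query")
    if isinstance(vocabularies, Vocabulary):
        vocabularies = [vocabularies]
    hits: list[SubstringHit] = []
    seen: set[str] = set()
    for vocab in vocabularies:
        for surface, main in vocab.surfaces():
            if surface in seen:
                continue
            seen.add(surface)
            if q in surface:
                direction = "query_in_surface"
            elif surface in q:
                direction = "surface_in_query"
            else:
                continue
            score = min(len(q), len(surface)) / max(len(q), len(surface))
            hits.append(SubstringHit(main, surface, direction, score))
    hits.sort(key=lambda h: (-h.score, len(h.surface), h.surface))
    return hits


# -- serialization ---------------------------------------------------


def save_model(model: TrigramModel, path: str | Path) -> None:
    """Serialize a model to a single JSON file.

    The header records the gram length and the vocabulary versions the
    model was fitted on; the payload holds the component index, idf
    weights, rows, and the surface matrix in coordinate form.
    """
    coo = model.matrix.tocoo()
    payload = {
        "format": "samplemeta-trigram-model",
        "format_version": 1,
        "n": model.n,
        "vocab_versions": model.vocab_versions,
        "component_index": model.component_index,
        "idf": model.idf.tolist(),
        "rows": [
            {"surface": r.surface, "maps_to": r.maps_to, "category": r.category}
            for r in model.rows
        ],
        "matrix": {
            "shape": list(model.matrix.shape),
            "row": coo.row.tolist(),
            "col": coo.col.tolist(),
            "data": coo.data.tolist(),
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_model(path: str | Path) -> TrigramModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "samplemeta-trigram-model":
        raise ValueError(f"{path} is not a trigram model file")
    m = payload["matrix"]
    matrix = sp.coo_matrix(
        (m["data"], (m["row"], m["col"])), shape=tuple(m["shape"])
    ).tocsr()
    return TrigramModel(
        n=payload["n"],
        component_index={g: int(i) for g, i in payload["component_index"].items()},
        idf=np.asarray(payload["idf"], dtype=float),
        matrix=matrix,
        rows=[ModelRow(**r) for r in payload["rows"]],
        vocab_versions={c: int(v) for c, v in payload["vocab_versions"].items()},
    )
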