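"""Classification of query reformulations between consecutive searches.

A keyword change between two consecutive searches is coded as *no change*,
*syntactic only*, *semantic only*, or *syntactic and semantic*.  Syntactic
reformulations alter surface form only and come in five sub-kinds:

==================  ==========================================================
capitalization      "IVF" → "ivf"
word_order          "asthma diagnosis" → "diagnosis asthma"
conjunction         remove/add/replace/reorder AND, OR, NOT
spacing             split/group/merge words with punctuation,
                    "heart-attack" → "heart attack", quoting a phrase
typographic         stems, plurals, spelling variants: "apple" → "apples",
                    "behavior" → "behaviour"
==================  ==========================================================

Semantic reformulations add, remove, or replace content keywords.

The coder works on a normalization cascade with a fixed order — strip and
record grouping punctuation → tokenize → remove conjunctions → case-fold →
collapse typographic variants to a base form — so each sub-kind is the
change visible at exactly its own layer.  Queries are compared per keyword
category (disease/drug/symptom/other) and flags are OR'd across categories.

Two surfaces are exposed:

* The five ``detect_*`` predicates implement the strict single-edit
  definitions (e.g. a capitalization change requires the two queries to be
  position-wise equal ignoring case).  They answer "is this pair exactly
  this kind of edit?".
* :func:`classify_query_reformulation` decomposes *combined* edits: it
  pairs words across the two queries (equal base form first, then
  typographic-variant pairing among the remainder), reads capitalization
  and typographic flips off the pairs, word order off the pair sequence,
  and codes unpairable words as semantic change.  On single edits the two
  surfaces agree.

The typographic-variant relation (equal after suffix-stripping stemming,
or small edit distance with a shared prefix) is a declared, configurable
stand-in for whatever rule the original manual coding used; thresholds
live in :class:`CoderConfig`.
"""

from __future__ import annotations

import re
from collections import Counter, deque
from dataclasses import dataclass, field
from enum import Enum

from .log_model import KEYWORD_CATEGORIES

__all__ = [
    "CoderConfig",
    "DEFAULT_CONFIG",
    "SyntacticSubtype",
    "ReformulationType",
    "QueryCode",
    "Token",
    "CodingError",
    "tokenize",
    "detect_capitalization_change",
    "detect_word_order_change",
    "detect_conjunction_change",
    "detect_spacing_change",
    "detect_typographic_change",
    "detect_semantic_change",
    "classify_query_reformulation",
    "is_typographic_variant",
    "light_stem",
]


class CodingError(ValueError):
    """Raised for malformed coder input (e.g. missing keyword category)."""


@dataclass(frozen=True)
class CoderConfig:
    """Tunable parameters of the reformulation coder.

    conjunctions
        Operator vocabulary, matched case-insensitively as standalone words.
    spacing_punctuation
        Characters treated as word-spacing/grouping punctuation.
    variant_max_edits, variant_prefix, variant_min_length
        Two tokens with unequal stems still count as typographic variants
        (spelling variants such as behaviour/behavior) when both are at
        least ``variant_min_length`` characters, share their first
        ``variant_prefix`` characters, and are within ``variant_max_edits``
        Levenshtein edits.
    stemmer
        Whether suffix-stripping stemming participates in the variant
        relation and in base-form normalization.
    """

    conjunctions: frozenset[str] = frozenset({"and", "or", "not"})
    spacing_punctuation: str = "-,;/‘’“”'"
    variant_max_edits: int = 2
    variant_prefix: int = 3
    variant_min_length: int = 4
    stemmer: bool = True


DEFAULT_CONFIG = CoderConfig()


class SyntacticSubtype(str, Enum):
    CAPITALIZATION = "capitalization"
    WORD_ORDER = "word_order"
    CONJUNCTION = "conjunction"
    SPACING = "spacing"
    TYPOGRAPHIC = "typographic"


class ReformulationType(str, Enum):
    NONE = "none"
    SYNTACTIC_ONLY = "syntactic_only"
    SEMANTIC_ONLY = "semantic_only"
    SYNTACTIC_AND_SEMANTIC = "syntactic_and_semantic"


@dataclass(frozen=True)
class QueryCode:
    """Overall reformulation code plus the set of fired syntactic sub-kinds."""

    value: ReformulationType
    subtypes: frozenset[SyntacticSubtype] = frozenset()

    def __post_init__(self) -> None:
        syntactic = self.value in (
            ReformulationType.SYNTACTIC_ONLY,
            ReformulationType.SYNTACTIC_AND_SEMANTIC,
        )
        if syntactic != bool(self.subtypes):
            raise ValueError(
                f"subtypes {set(self.subtypes)} inconsistent with value {self.value}"
            )


@dataclass(frozen=True)
class Token:
    """A query token; ``group`` is a within-query grouping id for tokens
    produced by splitting on grouping punctuation or by quoted phrases."""

    text: str
    group: int | None = None


# ---------------------------------------------------------------------------
# stemming and the variant relation


def light_stem(word: str) -> str:
    """Light suffix-stripping stemmer covering plurals, -ing and -ed forms.

    Intentionally conservative: it only needs to identify inflectional
    variants of the same word (apples→apple, running→run, studies→study),
    not to produce linguistically correct lemmas.
    """
    w = word
    if w.endswith("ies") and len(w) > 4:
        w = w[:-3] + "y"
    elif w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s") and len(w) > 3:
        w = w[:-1]
    if w.endswith("ing") and len(w) > 5:
        w = w[:-3]
        if len(w) >= 3 and w[-1] == w[-2] and w[-1] not in "ls":
            w = w[:-1]
    elif w.endswith("ed") and len(w) > 4:
        w = w[:-2]
        if len(w) >= 3 and w[-1] == w[-2] and w[-1] not in "ls":
            w = w[:-1]
    return w


def _levenshtein_within(a: str, b: str, limit: int) -> bool:
    """True iff edit distance between ``a`` and ``b`` is ≤ ``limit``."""
    if abs(len(a) - len(b)) > limit:
        return False
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        best = i
        for j, cb in enumerate(b, start=1):
            cost = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            cur.append(cost)
            best = min(best, cost)
        if best > limit:
            return False
        prev = cur
    return prev[-1] <= limit


def is_typographic_variant(w1: str, w2: str, config: CoderConfig = DEFAULT_CONFIG) -> bool:
    """Variant relation on case-folded words (stems/plurals/spellings).

    Holds iff the words differ but share a stem, or are long enough, share
    a prefix and are within the configured edit distance.  Identical words
    are *not* variants.
    """
    a, b = w1.casefold(), w2.casefold()
    if a == b:
        return False
    if config.stemmer and light_stem(a) == light_stem(b):
        return True
    if (
        len(a) >= config.variant_min_length
        and len(b) >= config.variant_min_length
        and a[: config.variant_prefix] == b[: config.variant_prefix]
        and _levenshtein_within(a, b, config.variant_max_edits)
    ):
        return True
    return False


# ---------------------------------------------------------------------------
# tokenization and per-query views


def tokenize(text: str, config: CoderConfig = DEFAULT_CONFIG) -> list[Token]:
    """Split a query into tokens.

    Separators are whitespace plus the configured spacing punctuation.
    A chunk that splits on internal punctuation ("heart-attack") yields
    multiple tokens sharing a group id; a double-quoted phrase yields a
    single token (quotes stripped) carrying a group id.
    """
    punct_class = "[" + re.escape(config.spacing_punctuation) + "]"
    tokens: list[Token] = []
    group = 0
    parts = re.split(r'"([^"]*)"', text)
    for i, part in enumerate(parts):
        if i % 2 == 1:  # inside double quotes
            inner = " ".join(part.split())
            if inner:
                tokens.append(Token(inner, group))
                group += 1
            continue
        for chunk in part.split():
            pieces = [p for p in re.split(punct_class, chunk) if p]
            if not pieces:
                continue
            if len(pieces) == 1:
                tokens.append(Token(pieces[0]))
            else:
                for p in pieces:
                    tokens.append(Token(p, group))
                group += 1
    return tokens


@dataclass
class _QueryView:
    """Layered representation of one query per the normalization cascade."""

    conjunctions: list[str]  # case-folded operator words, in order
    words: list[str]  # content words, case preserved, in order
    folded: list[str] = field(default_factory=list)  # case-folded content words
    keys: list[str] = field(default_factory=list)  # stemmed base forms
    groups: list[int | None] = field(default_factory=list)  # normalized group ids

    @property
    def stream(self) -> str:
        """Concatenated case-folded character stream of the content words."""
        return "".join(self.folded)

    @property
    def structure(self) -> tuple:
        """Word-boundary/grouping signature, case-insensitive."""
        return tuple(zip(self.folded, self.groups))


def _view(text: str, config: CoderConfig) -> _QueryView:
    conj: list[str] = []
    words: list[str] = []
    raw_groups: list[int | None] = []
    for tok in tokenize(text, config):
        for w in tok.text.split():
            cf = w.casefold()
            if cf in config.conjunctions:
                conj.append(cf)
            else:
                words.append(w)
                raw_groups.append(tok.group)
    # renumber groups in order of first appearance so ids compare structurally
    remap: dict[int, int] = {}
    groups: list[int | None] = []
    for g in raw_groups:
        if g is None:
            groups.append(None)
        else:
            if g not in remap:
                remap[g] = len(remap)
            groups.append(remap[g])
    folded = [w.casefold() for w in words]
    keys = [light_stem(f) if config.stemmer else f for f in folded]
    return _QueryView(conjunctions=conj, words=words, folded=folded, keys=keys, groups=groups)


# ---------------------------------------------------------------------------
# strict single-edit detectors


def detect_capitalization_change(q1: str, q2: str, config: CoderConfig = DEFAULT_CONFIG) -> bool:
    """Content word sequences differ case-sensitively but are position-wise
    equal case-insensitively (conjunctions removed first)."""
    v1, v2 = _view(q1, config), _view(q2, config)
    return v1.words != v2.words and v1.folded == v2.folded


def detect_word_order_change(q1: str, q2: str, config: CoderConfig = DEFAULT_CONFIG) -> bool:
    """Same case-folded content-word multiset, different order."""
    v1, v2 = _view(q1, config), _view(q2, config)
    return v1.folded != v2.folded and Counter(v1.folded) == Counter(v2.folded)


def detect_conjunction_change(q1: str, q2: str, config: CoderConfig = DEFAULT_CONFIG) -> bool:
    """The ordered sequences of conjunction words differ."""
    v1, v2 = _view(q1, config), _view(q2, config)
    return v1.conjunctions != v2.conjunctions


def detect_spacing_change(q1: str, q2: str, config: CoderConfig = DEFAULT_CONFIG) -> bool:
    """Identical case-folded character stream, different word-boundary or
    grouping structure (splits, merges, hyphens, quoted phrases)."""
    v1, v2 = _view(q1, config), _view(q2, config)
    return v1.stream == v2.stream and v1.structure != v2.structure


def detect_typographic_change(q1: str, q2: str, config: CoderConfig = DEFAULT_CONFIG) -> bool:
    """At least one position-aligned pair is a typographic variant and no
    pair differs beyond variant status."""
    v1, v2 = _view(q1, config), _view(q2, config)
    if len(v1.folded) != len(v2.folded):
        return False
    any_variant = False
    for a, b in zip(v1.folded, v2.folded):
        if a == b:
            continue
        if is_typographic_variant(a, b, config):
            any_variant = True
        else:
            return False
    return any_variant


def detect_semantic_change(q1: str, q2: str, config: CoderConfig = DEFAULT_CONFIG) -> bool:
    """Multisets of fully normalized base forms differ (typographic
    variants collapsed across the two queries before comparing)."""
    v1, v2 = _view(q1, config), _view(q2, config)
    _, left1, left2 = _pair_words(v1, v2, config)
    return bool(left1 or left2)


# ---------------------------------------------------------------------------
# combined-edit analysis (classifier)


def _pair_words(
    v1: _QueryView, v2: _QueryView, config: CoderConfig
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Match content words across the two queries.

    First by equal stemmed base form (in order of occurrence, respecting
    multiplicity), then by the typographic-variant relation among the
    remainder.  Returns (pairs, unmatched-in-q1, unmatched-in-q2); any
    unmatched word is a semantic addition/removal.
    """
    by_key: dict[str, deque[int]] = {}
    for j, k in enumerate(v2.keys):
        by_key.setdefault(k, deque()).append(j)
    pairs: list[tuple[int, int]] = []
    left1: list[int] = []
    for i, k in enumerate(v1.keys):
        q = by_key.get(k)
        if q:
            pairs.append((i, q.popleft()))
        else:
            left1.append(i)
    matched2 = {j for _, j in pairs}
    left2 = [j for j in range(len(v2.words)) if j not in matched2]
    still1: list[int] = []
    for i in left1:
        j_match = next(
            (j for j in left2 if is_typographic_variant(v1.folded[i], v2.folded[j], config)),
            None,
        )
        if j_match is None:
            still1.append(i)
        else:
            pairs.append((i, j_match))
            left2.remove(j_match)
    return pairs, still1, left2


def _analyze_field(q1: str, q2: str, config: CoderConfig) -> tuple[set[SyntacticSubtype], bool]:
    """Decompose the change in one keyword-category field into syntactic
    subtypes and a semantic flag."""
    if q1 == q2:
        return set(), False
    v1, v2 = _view(q1, config), _view(q2, config)
    subtypes: set[SyntacticSubtype] = set()

    if v1.conjunctions != v2.conjunctions:
        subtypes.add(SyntacticSubtype.CONJUNCTION)

    pairs, left1, left2 = _pair_words(v1, v2, config)
    semantic = bool(left1 or left2)

    for i, j in pairs:
        if v1.folded[i] == v2.folded[j]:
            if v1.words[i] != v2.words[j]:
                subtypes.add(SyntacticSubtype.CAPITALIZATION)
        else:  # paired only via the variant relation
            subtypes.add(SyntacticSubtype.TYPOGRAPHIC)

    # word order: the shared (paired) words appear in a different relative order
    order1 = [pid for pid, (i, _) in sorted(enumerate(pairs), key=lambda x: x[1][0])]
    order2 = [pid for pid, (_, j) in sorted(enumerate(pairs), key=lambda x: x[1][1])]
    if order1 != order2:
        subtypes.add(SyntacticSubtype.WORD_ORDER)

    if v1.stream == v2.stream and v1.structure != v2.structure:
        subtypes.add(SyntacticSubtype.SPACING)

    return subtypes, semantic


def classify_query_reformulation(
    prev: dict[str, str], curr: dict[str, str], config: CoderConfig = DEFAULT_CONFIG
) -> QueryCode:
    """Code the keyword change between two consecutive searches.

    Each of the four keyword-category fields is compared with its
    same-category counterpart and flags are OR'd across categories, so a
    keyword moved between categories codes as remove + add (semantic).
    Raises :class:`CodingError` if either map lacks a category key.
    """
    for name, m in (("prev", prev), ("curr", curr)):
        missing = set(KEYWORD_CATEGORIES) - set(m)
        if missing:
            raise CodingError(f"{name} keywords missing categories {sorted(missing)}")
    subtypes: set[SyntacticSubtype] = set()
    semantic = False
    for cat in KEYWORD_CATEGORIES:
        s, sem = _analyze_field(prev[cat], curr[cat], config)
        subtypes |= s
        semantic |= sem
    if subtypes and semantic:
        value = ReformulationType.SYNTACTIC_AND_SEMANTIC
    elif subtypes:
        value = ReformulationType.SYNTACTIC_ONLY
    elif semantic:
        value = ReformulationType.SEMANTIC_ONLY
    else:
        value = ReformulationType.NONE
    return QueryCode(value=value, subtypes=frozenset(subtypes))
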