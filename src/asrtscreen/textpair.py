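"""Transcript normalization, word error rate, and directed text-pair features.

Story-recall assessments compare a participant's retelling against the story
source text.  Each story yields three texts (source, immediate recall,
delayed recall) and hence six directed comparison pairs; a fixed-length
feature vector is computed for every directed pair and the six vectors are
averaged into one vector per story.

The feature extractor here is a deterministic surrogate for a learned
text-pair ("edit") encoder: it measures lexical overlap, ordering, length
and disfluency structure between the two texts.  Any object implementing
:class:`PairEncoder` can be swapped in behind the same interface.
"""

from __future__ import annotations

import unicodedata
import warnings
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np

__all__ = [
    "TokenSequence",
    "PairVector",
    "StoryVector",
    "PairEncoder",
    "SurrogateEncoder",
    "FEATURE_NAMES",
    "DEFAULT_FILLER_LEXICON",
    "normalize_transcript",
    "word_error_rate",
    "corpus_wer",
    "mean_wer",
    "pair_features",
    "story_vector",
]

#: Filled pauses dropped during normalization when ``remove_fillers`` is set.
DEFAULT_FILLER_LEXICON = frozenset(
    {"um", "uh", "er", "erm", "uhm", "uhhuh", "mm", "mmm", "hmm", "mhm", "ah", "eh", "hm"}
)

# Dash-like characters treated as token separators (never partial-word marks).
_SEPARATOR_DASHES = "–—―−"

# Small closed-class lexicon; "content words" are everything outside it.
_STOPWORDS = frozenset(
    """a an the and or but if then than that this these those there here
    is are was were be been being am i you he she it we they his her its
    their my your our me him them us of to in on at by for with from as
    into onto about over under after before up down out off so not no yes
    do does did done have has had having will would can could shall should
    may might must what which who whom whose when where why how all any
    some each very just also too own same s t don now d ll m o re ve y""".split()
)


@dataclass(frozen=True)
class TokenSequence:
    """Normalized transcript: lowercase, punctuation-free word tokens.

    ``filler_mask`` flags filled pauses / partial words that were *kept*
    (only possible when normalization ran with ``remove_fillers=False``).
    """

    tokens: tuple[str, ...]
    filler_mask: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not self.filler_mask:
            object.__setattr__(self, "filler_mask", tuple(False for _ in self.tokens))
        if len(self.filler_mask) != len(self.tokens):
            raise ValueError("filler_mask length must match tokens length")

    def __len__(self) -> int:
        return len(self.tokens)

    def filler_rate(self) -> float:
        return float(np.mean(self.filler_mask)) if self.tokens else 0.0


def _is_partial_word(raw: str) -> bool:
    # Manual transcription convention: interrupted words end in an ASCII hyphen.
    return len(raw) > 1 and raw.endswith("-") and not raw.endswith("--")


def _clean_token(raw: str) -> str:
    return "".join(
        ch for ch in raw if not unicodedata.category(ch).startswith("P")
    )


def normalize_transcript(
    text: str,
    remove_fillers: bool = True,
    filler_lexicon: Iterable[str] = DEFAULT_FILLER_LEXICON,
) -> TokenSequence:
    """Lowercase, strip punctuation, tokenize on whitespace.

    Em/en-dashes and internal hyphens split tokens; a trailing ASCII hyphen
    marks a partial word.  With ``remove_fillers`` set, filled pauses
    (``filler_lexicon``) and partial words are dropped; otherwise they are
    retained and flagged in the filler mask.
    """
    lexicon = frozenset(filler_lexicon)
    lowered = text.lower()
    for dash in _SEPARATOR_DASHES:
        lowered = lowered.replace(dash, " ")

    tokens: list[str] = []
    mask: list[bool] = []
    for raw in lowered.split():
        partial = _is_partial_word(raw)
        # Internal hyphens act as separators; the final fragment of a
        # partial word inherits the partial flag.
        fragments = [f for f in raw.split("-") if f]
        for i, fragment in enumerate(fragments):
            cleaned = _clean_token(fragment)
            if not cleaned:
                continue
            is_filler = cleaned in lexicon or (partial and i == len(fragments) - 1)
            if is_filler and remove_fillers:
                continue
            tokens.append(cleaned)
            mask.append(is_filler)
    return TokenSequence(tokens=tuple(tokens), filler_mask=tuple(mask))


def _as_tokens(seq: "TokenSequence | Sequence[str]") -> tuple[str, ...]:
    if isinstance(seq, TokenSequence):
        return seq.tokens
    return tuple(seq)


def _levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Token-level minimum edit distance (substitutions/insertions/deletions)."""
    n, m = len(a), len(b)
    if n == 0:
        return m
    if m == 0:
        return n
    b_arr = np.array(b, dtype=object)
    prev = np.arange(m + 1)
    for i in range(1, n + 1):
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = i
        sub_cost = prev[:-1] + (b_arr != a[i - 1])
        for j in range(1, m + 1):
            cur[j] = min(sub_cost[j - 1], prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev[m])


def word_error_rate(
    reference: "TokenSequence | Sequence[str]",
    hypothesis: "TokenSequence | Sequence[str]",
) -> float:
    """Edit-distance errors per reference word.

    Raises ``ValueError`` on an empty reference (the rate is undefined).
    """
    ref = _as_tokens(reference)
    hyp = _as_tokens(hypothesis)
    if not ref:
        raise ValueError("word_error_rate requires a non-empty reference")
    return _levenshtein(ref, hyp) / len(ref)


def corpus_wer(
    pairs: Iterable[tuple["TokenSequence | Sequence[str]", "TokenSequence | Sequence[str]"]],
) -> float:
    """Corpus-level WER: total errors over total reference words."""
    errors = 0
    ref_words = 0
    for reference, hypothesis in pairs:
        ref = _as_tokens(reference)
        hyp = _as_tokens(hypothesis)
        if not ref:
            raise ValueError("corpus_wer requires non-empty references")
        errors += _levenshtein(ref, hyp)
        ref_words += len(ref)
    if ref_words == 0:
        raise ValueError("corpus_wer requires at least one pair")
    return errors / ref_words


def mean_wer(
    pairs: Iterable[tuple["TokenSequence | Sequence[str]", "TokenSequence | Sequence[str]"]],
) -> float:
    """Average WER across recordings (unweighted mean of per-pair rates)."""
    rates = [word_error_rate(r, h) for r, h in pairs]
    if not rates:
        raise ValueError("mean_wer requires at least one pair")
    return float(np.mean(rates))


# ---------------------------------------------------------------------------
# Directed pair features

FEATURE_NAMES: tuple[str, ...] = (
    "unigram_precision",
    "unigram_recall",
    "bigram_precision",
    "bigram_recall",
    "lcs_ratio",
    "length_ratio",
    "content_precision",
    "content_recall",
    "ordering_concordance",
    "unigram_jaccard",
    "bigram_jaccard",
    "filler_rate_a",
    "filler_rate_b",
    "repetition_rate_a",
    "repetition_rate_b",
    "edit_similarity",
)


@dataclass(frozen=True)
class PairVector:
    """Feature vector for one directed text pair (direction ``a -> b``)."""

    direction: tuple[str, str]
    features: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if len(self.features) != len(self.feature_names):
            raise ValueError("feature vector length must match schema length")


@dataclass(frozen=True)
class StoryVector:
    """Mean of the six directed pair vectors for one story triplet."""

    participant_id: str
    story_id: int
    vector: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES


def _counts(tokens: Sequence[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for t in tokens:
        out[t] = out.get(t, 0) + 1
    return out


def _clipped_overlap(a: Sequence[str], b: Sequence[str]) -> int:
    ca, cb = _counts(a), _counts(b)
    return sum(min(n, cb.get(t, 0)) for t, n in ca.items())


def _bigrams(tokens: Sequence[str]) -> list[tuple[str, str]]:
    return list(zip(tokens, tokens[1:]))


def _precision(a: Sequence, b: Sequence) -> float:
    # Clipped-count precision: fraction of a's items matched in b.
    return _clipped_overlap(a, b) / len(a) if a else 0.0


def _jaccard(a: Sequence, b: Sequence) -> float:
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    if not a or not b:
        return 0
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for x in a:
        cur = np.zeros(len(b) + 1, dtype=np.int64)
        for j, y in enumerate(b, start=1):
            cur[j] = prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1])
        prev = cur
    return int(prev[-1])


def _ordering_concordance(a: Sequence[str], b: Sequence[str]) -> float:
    """Concordance of first-occurrence order among shared distinct tokens."""
    first_a: dict[str, int] = {}
    for i, t in enumerate(a):
        first_a.setdefault(t, i)
    first_b: dict[str, int] = {}
    for i, t in enumerate(b):
        first_b.setdefault(t, i)
    shared = sorted(set(first_a) & set(first_b), key=first_a.get)
    if len(shared) < 2:
        return 1.0
    pos_b = [first_b[t] for t in shared]
    concordant = 0
    total = 0
    for i in range(len(pos_b)):
        for j in range(i + 1, len(pos_b)):
            total += 1
            if pos_b[i] < pos_b[j]:
                concordant += 1
    return concordant / total


def _repetition_rate(tokens: Sequence[str]) -> float:
    if not tokens:
        return 0.0
    return 1.0 - len(set(tokens)) / len(tokens)


class PairEncoder(Protocol):
    """Interface for text-pair encoders: a directed pair in, a vector out."""

    feature_names: tuple[str, ...]

    def encode(self, a: TokenSequence, b: TokenSequence) -> np.ndarray: ...


class SurrogateEncoder:
    """Deterministic lexical-overlap encoder over directed token-sequence pairs.

    Produces the 16 named features in :data:`FEATURE_NAMES`.  All overlap,
    precision/recall and similarity features lie in [0, 1].
    """

    feature_names = FEATURE_NAMES

    def encode(self, a: TokenSequence, b: TokenSequence) -> np.ndarray:
        ta, tb = a.tokens, b.tokens
        if not ta and not tb:
            warnings.warn("both sequences empty; returning all-zero pair vector")
            return np.zeros(len(self.feature_names))
        ba, bb = _bigrams(ta), _bigrams(tb)
        ca = [t for t in ta if t not in _STOPWORDS]
        cb = [t for t in tb if t not in _STOPWORDS]
        max_len = max(len(ta), len(tb))
        values = np.array(
            [
                _precision(ta, tb),
                _precision(tb, ta),
                _precision(ba, bb),
                _precision(bb, ba),
                _lcs_length(ta, tb) / max_len,
                min(len(ta), len(tb)) / max_len,
                _precision(ca, cb),
                _precision(cb, ca),
                _ordering_concordance(ta, tb),
                _jaccard(ta, tb),
                _jaccard(ba, bb),
                a.filler_rate(),
                b.filler_rate(),
                _repetition_rate(ta),
                _repetition_rate(tb),
                1.0 - _levenshtein(ta, tb) / max_len,
            ]
        )
        return values


_DEFAULT_ENCODER = SurrogateEncoder()


def pair_features(
    a: TokenSequence,
    b: TokenSequence,
    direction: tuple[str, str] = ("a", "b"),
    encoder: PairEncoder | None = None,
) -> PairVector:
    """Feature vector for the directed pair ``a -> b``."""
    enc = encoder if encoder is not None else _DEFAULT_ENCODER
    return PairVector(
        direction=direction,
        features=enc.encode(a, b),
        feature_names=tuple(enc.feature_names),
    )


#: The six non-redundant directed combinations of (source, immediate, delayed).
PAIR_DIRECTIONS: tuple[tuple[str, str], ...] = (
    ("source", "immediate"),
    ("immediate", "source"),
    ("source", "delayed"),
    ("delayed", "source"),
    ("immediate", "delayed"),
    ("delayed", "immediate"),
)


def story_vector(
    record,
    remove_fillers: bool = True,
    encoder: PairEncoder | None = None,
) -> StoryVector:
    """Average the six directed pair vectors of one story triplet.

    ``record`` needs ``participant_id``, ``story_id``, ``source_text``,
    ``immediate_recall`` and ``delayed_recall`` attributes.
    """
    texts = {
        "source": record.source_text,
        "immediate": record.immediate_recall,
        "delayed": record.delayed_recall,
    }
    for slot, text in texts.items():
        if text is None or not str(text).strip():
            raise ValueError(
                f"record {record.participant_id}/story {record.story_id}: "
                f"missing {slot} text"
            )
    seqs = {k: normalize_transcript(v, remove_fillers=remove_fillers) for k, v in texts.items()}
    enc = encoder if encoder is not None else _DEFAULT_ENCODER
    vectors = [
        pair_features(seqs[a], seqs[b], direction=(a, b), encoder=enc).features
        for a, b in PAIR_DIRECTIONS
    ]
    return StoryVector(
        participant_id=record.participant_id,
        story_id=record.story_id,
        vector=np.mean(vectors, axis=0),
        feature_names=tuple(enc.feature_names),
    )
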