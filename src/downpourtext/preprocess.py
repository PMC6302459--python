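"""Tokenization, vocabulary construction, document encoding and data splits.

The processing pipeline mirrors standard word-CNN practice for clinical
free text: documents are split on whitespace and non-alphanumeric symbols
with alphabetic characters lowercased; decimal numbers collapse to a single
FLOAT token and integers of three or more digits to a LARGEINT token (short
integers such as a tumor grade "2" are kept literal); tokens whose document
frequency falls below a threshold (default 5) map to a shared RARE token;
encoded documents are truncated/right-padded to a fixed length (default
1500) with PAD index 0, which embeds as the all-zero vector.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from downpourtext.corpus import LabeledCorpus

__all__ = [
    "PAD_TOKEN", "RARE_TOKEN", "FLOAT_TOKEN", "LARGEINT_TOKEN",
    "PAD_INDEX", "RARE_INDEX", "FLOAT_INDEX", "LARGEINT_INDEX",
    "tokenize", "Vocabulary", "build_vocabulary",
    "EncodedDocument", "encode", "filter_classes",
    "SplitPlan", "make_splits",
]

PAD_TOKEN = "<pad>"
RARE_TOKEN = "<rare>"
FLOAT_TOKEN = "<float>"
LARGEINT_TOKEN = "<largeint>"

PAD_INDEX = 0
RARE_INDEX = 1
FLOAT_INDEX = 2
LARGEINT_INDEX = 3

_SPECIAL_INDICES = {
    PAD_TOKEN: PAD_INDEX,
    RARE_TOKEN: RARE_INDEX,
    FLOAT_TOKEN: FLOAT_INDEX,
    LARGEINT_TOKEN: LARGEINT_INDEX,
}

# Alternation order matters: special-token literals pass through unchanged
# (making tokenize idempotent on its own rendered output), decimals are
# matched before their digit runs would be split apart.
_TOKEN_RE = re.compile(r"<rare>|<float>|<largeint>|\d+\.\d+|[a-z0-9]+")
_DECIMAL_RE = re.compile(r"\d+\.\d+")
_LARGEINT_RE = re.compile(r"\d{3,}")


def tokenize(text: str) -> list[str]:
    """Split lowercased text on whitespace/punctuation and substitute numerics.

    >>> tokenize("Tumor measures 2.5 cm.")
    ['tumor', 'measures', '<float>', 'cm']
    """
    out: list[str] = []
    for tok in _TOKEN_RE.findall(text.lower()):
        if _DECIMAL_RE.fullmatch(tok):
            out.append(FLOAT_TOKEN)
        elif _LARGEINT_RE.fullmatch(tok):
            out.append(LARGEINT_TOKEN)
        else:
            out.append(tok)
    return out


@dataclass
class Vocabulary:
    """Token-to-index map with PAD/RARE/FLOAT/LARGEINT special tokens.

    Indices are contiguous ``0..size-1``; PAD is always index 0 and is the
    only index whose embedding is frozen at zero.  Every non-special entry
    had document frequency >= ``min_doc_freq`` in the corpus it was built
    from; unknown tokens resolve to RARE at encode time.
    """

    token_to_index: dict[str, int]
    min_doc_freq: int = 5

    def __post_init__(self) -> None:
        for tok, idx in _SPECIAL_INDICES.items():
            if self.token_to_index.get(tok) != idx:
                raise ValueError(f"special token {tok!r} must have index {idx}")
        indices = sorted(self.token_to_index.values())
        if indices != list(range(len(indices))):
            raise ValueError("vocabulary indices must be contiguous from 0")

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    def index_of(self, token: str) -> int:
        return self.token_to_index.get(token, RARE_INDEX)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# min_doc_freq={self.min_doc_freq}\n")
            for tok, idx in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{idx}\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        mapping: dict[str, int] = {}
        min_df = 5
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    if "min_doc_freq=" in line:
                        min_df = int(line.split("min_doc_freq=")[1])
                    continue
                if not line:
                    continue
                tok, idx = line.split("\t")
                mapping[tok] = int(idx)
        return cls(token_to_index=mapping, min_doc_freq=min_df)


def build_vocabulary(corpus: LabeledCorpus, min_doc_freq: int = 5) -> Vocabulary:
    """Assign indices to every token appearing in >= ``min_doc_freq`` documents.

    All other tokens map to RARE.  Retained tokens are ordered by descending
    document frequency then lexicographically, so construction is
    deterministic.  An empty corpus yields the special tokens only.
    """
    doc_freq: dict[str, int] = {}
    for text, _ in corpus.records:
        for tok in set(tokenize(text)):
            if tok in _SPECIAL_INDICES:
                continue
            doc_freq[tok] = doc_freq.get(tok, 0) + 1
    kept = sorted(
        (tok for tok, df in doc_freq.items() if df >= min_doc_freq),
        key=lambda tok: (-doc_freq[tok], tok),
    )
    mapping = dict(_SPECIAL_INDICES)
    for offset, tok in enumerate(kept):
        mapping[tok] = len(_SPECIAL_INDICES) + offset
    return Vocabulary(token_to_index=mapping, min_doc_freq=min_doc_freq)


@dataclass
class EncodedDocument:
    """A fixed-length index sequence plus its true (pre-padding) length."""

    indices: np.ndarray
    true_length: int
    label_index: int = -1

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if not 0 <= self.true_length <= self.indices.shape[0]:
            raise ValueError("true_length out of range")


def encode(
    tokens: list[str],
    vocab: Vocabulary,
    max_len: int = 1500,
    label_index: int = -1,
) -> EncodedDocument:
    """Map tokens to indices, truncating to ``max_len`` and right-padding with PAD."""
    kept = tokens[:max_len]
    indices = np.full(max_len, PAD_INDEX, dtype=np.int64)
    for i, tok in enumerate(kept):
        indices[i] = vocab.index_of(tok)
    return EncodedDocument(indices=indices, true_length=len(kept), label_index=label_index)


def filter_classes(corpus: LabeledCorpus, min_cases: int = 10) -> LabeledCorpus:
    """Drop classes (and their records) with fewer than ``min_cases`` records."""
    counts = corpus.class_counts()
    kept_classes = [label for label in corpus.class_set if counts[label] >= min_cases]
    if not kept_classes:
        raise ValueError(f"no class has >= {min_cases} records")
    kept = set(kept_classes)
    records = [(text, label) for text, label in corpus.records if label in kept]
    return LabeledCorpus(records=records, class_set=kept_classes)


@dataclass
class SplitPlan:
    """Class-stratified fold assignments with per-test-fold validation masks.

    ``fold_of[i]`` is record *i*'s fold in ``0..k-1``; per-class fold counts
    differ by at most one.  For a chosen test fold, a stratified
    ``validation_fraction`` of the remaining (training) records is flagged as
    the validation set, disjoint from the test fold and deterministic in
    (seed, test_fold).
    """

    fold_of: np.ndarray
    k: int
    labels: list[str]
    validation_fraction: float = 0.25
    seed: int = 0
    class_set: list[str] = field(default_factory=list)

    def test_indices(self, test_fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == test_fold)

    def train_val_indices(self, test_fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) index arrays for the given held-out fold."""
        if not 0 <= test_fold < self.k:
            raise ValueError(f"test_fold must be in 0..{self.k - 1}")
        rng = np.random.default_rng([self.seed, 104729, test_fold])
        pool = np.flatnonzero(self.fold_of != test_fold)
        val: list[int] = []
        for label in self.class_set:
            cls = pool[[self.labels[i] == label for i in pool]]
            cls = rng.permutation(cls)
            n_val = round(self.validation_fraction * len(cls))
            val.extend(cls[:n_val].tolist())
        val_set = set(val)
        train = np.array([i for i in pool if i not in val_set], dtype=np.int64)
        return train, np.array(sorted(val), dtype=np.int64)


def make_splits(
    corpus: LabeledCorpus,
    k: int = 10,
    validation_fraction: float = 0.25,
    seed: int = 0,
) -> SplitPlan:
    """Stratified k-fold assignment: seeded per-class shuffle then round-robin.

    Remainder records fall on the lowest-index folds, the deterministic
    tie-break.  Raises if any class has fewer than ``k`` records.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = corpus.class_counts()
    for label in corpus.class_set:
        if counts[label] < k:
            raise ValueError(
                f"class {label!r} has {counts[label]} records, fewer than k={k}"
            )
    rng = np.random.default_rng([seed, 15485863])
    labels = corpus.labels()
    fold_of = np.empty(len(corpus), dtype=np.int64)
    for label in corpus.class_set:
        members = np.flatnonzero([lab == label for lab in labels])
        members = rng.permutation(members)
        for j, idx in enumerate(members):
            fold_of[idx] = j % k
    return SplitPlan(
        fold_of=fold_of,
        k=k,
        labels=labels,
        validation_fraction=validation_fraction,
        seed=seed,
        class_set=list(corpus.class_set),
    )
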