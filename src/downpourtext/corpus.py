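"""Synthetic labeled corpora with registry-like class imbalance, plus disk I/O.

Real cancer-registry pathology reports are access-restricted, so this module
generates stand-in corpora that reproduce the *statistical* structure such a
dataset exhibits: a long-tailed per-class case-count profile, documents of
variable token length (almost all under 1500 tokens), class-informative
keywords mixed with shared background vocabulary, numeric literals (decimals
and large integers) and singleton rare tokens.  No attempt is made at
clinically plausible prose; only token-level statistics matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorpusConfig",
    "LabeledCorpus",
    "default_class_profile",
    "registry_site_codes",
    "scale_profile",
    "demo_corpus_config",
    "generate_corpus",
    "read_corpus",
    "write_corpus",
    "CorpusFormatError",
]

# Per-class case counts of the 64 ICD-O-3 primary-site codes retained after
# the >=10-case filter (breast C50 is the largest class with 4415 reports,
# adrenal gland C74 the smallest with 10).  Total: 22,976 annotated reports.
_REGISTRY_PROFILE: list[tuple[str, int]] = [
    ("C00", 16), ("C01", 53), ("C02", 108), ("C04", 39),
    ("C05", 31), ("C06", 48), ("C07", 66), ("C08", 16),
    ("C09", 71), ("C10", 27), ("C11", 43), ("C12", 11),
    ("C13", 14), ("C14", 24), ("C15", 199), ("C16", 427),
    ("C17", 156), ("C18", 1951), ("C19", 118), ("C20", 646),
    ("C21", 75), ("C22", 268), ("C23", 27), ("C24", 26),
    ("C25", 151), ("C26", 32), ("C30", 47), ("C31", 15),
    ("C32", 240), ("C34", 1570), ("C38", 106), ("C40", 14),
    ("C41", 88), ("C42", 1800), ("C44", 1151), ("C48", 84),
    ("C49", 261), ("C50", 4415), ("C51", 97), ("C52", 39),
    ("C53", 314), ("C54", 882), ("C55", 174), ("C56", 448),
    ("C57", 83), ("C60", 18), ("C61", 2313), ("C62", 60),
    ("C64", 458), ("C65", 20), ("C66", 32), ("C67", 947),
    ("C68", 30), ("C69", 18), ("C70", 17), ("C71", 296),
    ("C72", 36), ("C73", 305), ("C74", 10), ("C75", 22),
    ("C76", 196), ("C77", 741), ("C80", 962), ("C90", 24),
]


def default_class_profile() -> list[int]:
    """The 64 per-class case counts of the registry corpus (sums to 22,976)."""
    return [count for _, count in _REGISTRY_PROFILE]


def registry_site_codes() -> list[str]:
    """ICD-O-3 topography codes matching :func:`default_class_profile` order."""
    return [code for code, _ in _REGISTRY_PROFILE]


def scale_profile(profile: list[int], factor: float, min_cases: int = 1) -> list[int]:
    """Scale a case-count profile by ``factor``, keeping every class non-empty."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return [max(min_cases, round(c * factor)) for c in profile]


class CorpusFormatError(ValueError):
    """A corpus file line that cannot be parsed into a (text, label) record."""


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of the synthetic corpus generator.

    Each document is a stream of tokens drawn independently from a four-way
    mixture: a keyword informative of the document's class
    (``keyword_signal_rate``), a numeric literal — decimal or >=3-digit
    integer — (``numeric_token_rate``), a fresh never-repeated rare token
    (``rare_token_rate``), else a background token shared by all classes with
    Zipf-like frequencies.  Document lengths are negative-binomial with the
    given mean and dispersion (variance = mean + dispersion * mean**2).
    """

    n_classes: int
    class_profile: list[int]
    vocab_size_informative: int = 20
    background_vocab_size: int = 500
    mean_doc_length: float = 600.0
    doc_length_dispersion: float = 0.2
    keyword_signal_rate: float = 0.3
    numeric_token_rate: float = 0.05
    rare_token_rate: float = 0.02
    keyword_overlap: float = 0.0
    seed: int = 0
    class_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be positive")
        if len(self.class_profile) != self.n_classes:
            raise ValueError("class_profile length must equal n_classes")
        if any(c < 1 for c in self.class_profile):
            raise ValueError("every class_profile entry must be >= 1")
        for name in ("vocab_size_informative", "background_vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.mean_doc_length <= 0 or self.doc_length_dispersion <= 0:
            raise ValueError("mean_doc_length and doc_length_dispersion must be positive")
        rates = (self.keyword_signal_rate, self.numeric_token_rate, self.rare_token_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("token mixture rates must lie in [0, 1]")
        if sum(rates) > 1.0:
            raise ValueError("per-token mixture rates must sum to <= 1")
        if not 0.0 <= self.keyword_overlap <= 1.0:
            raise ValueError("keyword_overlap must lie in [0, 1]")
        if self.class_labels is not None and len(self.class_labels) != self.n_classes:
            raise ValueError("class_labels length must equal n_classes")


@dataclass
class LabeledCorpus:
    """An ordered list of (document text, class label) records."""

    records: list[tuple[str, str]]
    class_set: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_set:
            seen: dict[str, None] = {}
            for _, label in self.records:
                seen.setdefault(label, None)
            self.class_set = list(seen)
        known = set(self.class_set)
        for _, label in self.records:
            if label not in known:
                raise ValueError(f"record label {label!r} not in class_set")

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in self.class_set}
        for _, label in self.records:
            counts[label] += 1
        return counts

    def texts(self) -> list[str]:
        return [text for text, _ in self.records]

    def labels(self) -> list[str]:
        return [label for _, label in self.records]


def demo_corpus_config(seed: int = 0, **overrides) -> CorpusConfig:
    """A desk-scale learnable corpus: the 8 largest registry classes scaled
    to roughly 50-400 cases each, short documents, default signal rates."""
    top8 = sorted(default_class_profile(), reverse=True)[:8]
    profile = scale_profile(top8, 400 / max(top8))
    defaults = dict(
        n_classes=8,
        class_profile=profile,
        mean_doc_length=60.0,
        seed=seed,
    )
    defaults.update(overrides)
    return CorpusConfig(**defaults)


def _doc_length(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # negative binomial with variance mean + dispersion * mean**2
    r = 1.0 / dispersion
    p = r / (r + mean)
    return max(1, int(rng.negative_binomial(r, p)))


def generate_corpus(config: CorpusConfig) -> LabeledCorpus:
    """Generate a synthetic labeled corpus; byte-identical for a fixed config.

    Class ``c``'s keyword set is disjoint from every other class's unless
    ``keyword_overlap > 0``, in which case the leading
    ``floor(overlap * vocab_size_informative)`` keywords are borrowed from the
    cyclically next class, emulating confusable site pairs.
    """
    rng = np.random.default_rng(config.seed)
    labels = (
        list(config.class_labels)
        if config.class_labels is not None
        else [f"class{c:02d}" for c in range(config.n_classes)]
    )

    n_kw = config.vocab_size_informative
    own_keywords = [
        [f"kw{c:02d}w{j}" for j in range(n_kw)] for c in range(config.n_classes)
    ]
    n_shared = int(config.keyword_overlap * n_kw)
    keywords = []
    for c in range(config.n_classes):
        donor = (c + 1) % config.n_classes
        keywords.append(own_keywords[donor][:n_shared] + own_keywords[c][n_shared:])

    background = [f"bg{j}" for j in range(config.background_vocab_size)]
    bg_probs = 1.0 / np.arange(1, config.background_vocab_size + 1)
    bg_probs /= bg_probs.sum()

    p_kw = config.keyword_signal_rate
    p_num = config.numeric_token_rate
    p_rare = config.rare_token_rate
    rare_counter = 0
    records: list[tuple[str, str]] = []
    for c in range(config.n_classes):
        kws = keywords[c]
        for _ in range(config.class_profile[c]):
            length = _doc_length(rng, config.mean_doc_length, config.doc_length_dispersion)
            u = rng.random(length)
            tokens: list[str] = []
            for ui in u:
                if ui < p_kw:
                    tokens.append(kws[rng.integers(n_kw)])
                elif ui < p_kw + p_num:
                    if rng.random() < 0.5:
                        tokens.append(f"{rng.uniform(0.0, 100.0):.1f}")
                    else:
                        tokens.append(str(rng.integers(100, 100000)))
                elif ui < p_kw + p_num + p_rare:
                    tokens.append(f"rare{rare_counter}x")
                    rare_counter += 1
                else:
                    tokens.append(background[rng.choice(config.background_vocab_size, p=bg_probs)])
            records.append((" ".join(tokens), labels[c]))
    return LabeledCorpus(records=records, class_set=labels)


def write_corpus(corpus: LabeledCorpus, path) -> None:
    """Write one JSON record per line with deterministic key order (label, text)."""
    with open(path, "w", encoding="utf-8") as fh:
        for text, label in corpus.records:
            fh.write(json.dumps({"label": label, "text": text}) + "\n")


def read_corpus(path) -> LabeledCorpus:
    """Read a line-delimited JSON corpus; raises naming the offending line."""
    records: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            if not isinstance(obj, dict) or "text" not in obj or "label" not in obj:
                raise CorpusFormatError(f"line {lineno}: record must have 'text' and 'label' keys")
            records.append((str(obj["text"]), str(obj["label"])))
    return LabeledCorpus(records=records)
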