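"""Clinical-variable-to-text serialization and text-embedding providers.

Tabular clinical variables become a natural-language paragraph through one
sentence template per variable, emitted in a fixed canonical order (the
schema order). Units accompany numeric values; a MISSING variable simply
produces no sentence. The paragraph optionally ends with follow-up/outcome
sentences, controlled by the phase:

* ``include``  — append the follow-up length and the true outcome sentence
  (contrastive pretraining);
* ``exclude``  — append neither (finetuning: the classifier must not see
  the label in its input);
* ``override_positive`` / ``override_negative`` — append the templated
  outcome sentence for the queried class in place of the true label
  (zero-shot classification).

A text-embedding provider maps a paragraph to a fixed-length vector. The
shipped provider is a deterministic hashed bag-of-tokens: no learned
weights, stable across processes, sensitive to every token. Numeric tokens
additionally emit a coarse decade-binned token so nearby magnitudes share
mass — a tokenizer choice that lets small cohorts generalize over numbers.
Any callable with the same ``embed``/``dim`` surface (e.g. a real sentence
encoder) can be plugged in instead.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Protocol

import numpy as np
import yaml

from .cohort import MISSING, NUMERIC_VARIABLES, SCHEMA_VARIABLES

logger = logging.getLogger("cplp")

__all__ = [
    "TemplateRegistry",
    "DEFAULT_REGISTRY",
    "OutcomeMode",
    "to_paragraph",
    "TextEmbedder",
    "HashedTextEmbedder",
    "embed_paragraph",
]

OutcomeMode = str  # {"include", "exclude", "override_positive", "override_negative"}
_OUTCOME_MODES = ("include", "exclude", "override_positive", "override_negative")

# value rewriting for flag variables so templates keep one placeholder
_FLAG_PHRASE = {"yes": "has", "no": "does not have"}

_DEFAULT_TEMPLATES: dict[str, str] = {
    "age": "The patient is {age} years old.",
    "sex": "The patient is {sex}.",
    "race": "The patient's race is {race}.",
    "bmi": "The patient's BMI is {bmi} kg/m2.",
    "smoking_quit_years": "The patient quit smoking {smoking_quit_years} years ago.",
    "smoking_duration_years": "The patient smoked for {smoking_duration_years} years.",
    "pack_years": "The patient smoked {pack_years} pack years.",
    "copd": "The patient {copd} chronic obstructive pulmonary disease.",
    "emphysema": "The patient {emphysema} emphysema.",
    "personal_cancer_history": "The patient {personal_cancer_history} a personal history of cancer.",
    "family_lung_cancer_history": "The patient {family_lung_cancer_history} a family history of lung cancer.",
    "smoking_status": "The patient is a {smoking_status} smoker.",
}

_FOLLOWUP_TEMPLATE = "The patient was followed for {followup_days} days without lung cancer."
_OUTCOME_POSITIVE = "The patient developed lung cancer after 2 years."
_OUTCOME_NEGATIVE = "The patient did not develop lung cancer after 2 years."


@dataclass
class TemplateRegistry:
    """One sentence template per schema variable plus outcome templates.

    Serializable to/from YAML so wording can be localized without code
    changes.
    """

    templates: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_TEMPLATES))
    order: tuple[str, ...] = SCHEMA_VARIABLES
    followup_template: str = _FOLLOWUP_TEMPLATE
    outcome_positive: str = _OUTCOME_POSITIVE
    outcome_negative: str = _OUTCOME_NEGATIVE

    def __post_init__(self):
        missing = set(self.order) - set(self.templates)
        if missing:
            raise ValueError(f"variables without a template: {sorted(missing)}")
        for name, tpl in self.templates.items():
            if len(re.findall(r"\{[a-z_]+\}", tpl)) != 1:
                raise ValueError(
                    f"template for {name!r} must contain exactly one placeholder")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "templates": self.templates,
            "order": list(self.order),
            "followup_template": self.followup_template,
            "outcome_positive": self.outcome_positive,
            "outcome_negative": self.outcome_negative,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TemplateRegistry":
        payload = yaml.safe_load(Path(path).read_text())
        payload["order"] = tuple(payload["order"])
        return cls(**payload)


DEFAULT_REGISTRY = TemplateRegistry()


def _format_value(name: str, value: Any) -> str:
    if name in NUMERIC_VARIABLES:
        value = float(value)
        # integers as-is, reals to one decimal
        return str(int(value)) if value == int(value) else f"{value:.1f}"
    value = str(value)
    return _FLAG_PHRASE.get(value, value) if name in _FLAG_PHRASE_VARS else value


_FLAG_PHRASE_VARS = ("copd", "emphysema", "personal_cancer_history",
                     "family_lung_cancer_history")


def to_paragraph(variables: dict[str, Any], outcome_mode: OutcomeMode,
                 label: int | None = None, followup_days: int | None = None,
                 registry: TemplateRegistry = DEFAULT_REGISTRY) -> str:
    """Serialize one patient's variables to a paragraph.

    MISSING variables are left out entirely; sentences follow the canonical
    schema order. See the module docstring for the outcome modes.
    """
    unknown = set(variables) - set(registry.order)
    if unknown:
        raise KeyError(f"unknown clinical variables: {sorted(unknown)}")
    if outcome_mode not in _OUTCOME_MODES:
        raise ValueError(f"unknown outcome_mode {outcome_mode!r}")

    sentences = []
    for name in registry.order:
        value = variables.get(name, MISSING)
        if value is MISSING:
            continue
        sentences.append(registry.templates[name].format(
            **{name: _format_value(name, value)}))

    if outcome_mode == "include":
        if label is None or followup_days is None:
            raise ValueError("outcome_mode='include' needs label and followup_days")
        sentences.append(registry.followup_template.format(
            followup_days=int(followup_days)))
        sentences.append(registry.outcome_positive if label
                         else registry.outcome_negative)
    elif outcome_mode == "override_positive":
        sentences.append(registry.outcome_positive)
    elif outcome_mode == "override_negative":
        sentences.append(registry.outcome_negative)

    return " ".join(sentences)


class TextEmbedder(Protocol):
    """A frozen text representation model: paragraph -> fixed-length vector,
    deterministic for a fixed input."""

    dim: int

    def embed(self, paragraph: str) -> np.ndarray: ...


_TOKEN_RE = re.compile(r"[a-z]+|\d+(?:\.\d+)?")


class HashedTextEmbedder:
    """Deterministic hashed bag-of-tokens text embedder.

    Each token is hashed (md5, salt-free, so stable across processes) to a
    bucket and a sign; the paragraph embedding is the signed token-count
    vector. Numeric tokens also emit a coarse token binned to the nearest
    ten, giving the downstream MLP a smooth handle on magnitudes.
    """

    def __init__(self, dim: int = 256):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim

    @staticmethod
    def _tokens(paragraph: str) -> list[str]:
        toks = _TOKEN_RE.findall(paragraph.lower())
        out = []
        for t in toks:
            out.append(t)
            if t[0].isdigit():
                out.append(f"~{round(float(t) / 10) * 10}")
        return out

    def _bucket(self, token: str) -> tuple[int, float]:
        h = int.from_bytes(hashlib.md5(token.encode()).digest()[:8], "little")
        return h % self.dim, 1.0 if (h >> 32) & 1 else -1.0

    def embed(self, paragraph: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float32)
        for tok in self._tokens(paragraph):
            idx, sign = self._bucket(tok)
            vec[idx] += sign
        return vec


def embed_paragraph(provider: TextEmbedder, paragraph: str) -> np.ndarray:
    """Embed one paragraph; an empty paragraph yields the zero vector."""
    if not paragraph.strip():
        logger.warning("embedding an empty paragraph -> zero vector")
        return np.zeros(provider.dim, dtype=np.float32)
    return np.asarray(provider.embed(paragraph), dtype=np.float32)
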