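"""Configurable lexicons backing the rule-based detectors.

Defaults mirror the checklist's own guidance: the discouraged jargon words,
the second tier of terms whose everyday meaning differs from their meaning in
medicine, the five recommended subtitles, common bibliographic database names,
statistical-notation pattern classes and quality-of-evidence phrases.

A lexicon file is plain text with ``[section]`` headers and one term per
line; ``#`` starts a comment.  Sections not present keep their defaults.
"""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, ConfigDict, field_validator

from .errors import ValidationError

__all__ = ["Lexicons", "RECOMMENDED_HEADINGS", "load_lexicons"]

#: The five recommended subtitles of a structured PLS, in recommended order.
RECOMMENDED_HEADINGS = (
    "Review Question",
    "Background",
    "Study Characteristics",
    "Key Results",
    "Quality of Evidence",
)

_DEFAULT_JARGON = ("outcome", "literature", "case series", "efficacy", "effect size")
_DEFAULT_AMBIGUOUS = ("local", "blinding", "control", "practice")
# Proper names are matched case-sensitively (``central`` is an ordinary word,
# CENTRAL is a trials register).
_DEFAULT_DATABASES = (
    "MEDLINE",
    "EMBASE",
    "CENTRAL",
    "CINAHL",
    "PsycINFO",
    "PubMed",
    "LILACS",
    "Cochrane Central Register of Controlled Trials",
)
# Statistical-notation pattern classes: label -> regex. Word forms are matched
# case-insensitively via inline groups; bare acronyms stay case-sensitive and
# require a nearby digit so prose ("or", "MD" the degree) cannot match.
_DEFAULT_STAT_PATTERNS = {
    "odds-ratio": r"(?:(?i:odds\s+ratio)|(?<!\w)OR(?!\w))[^.;\n]{0,30}?\d",
    "risk-ratio": r"(?:(?i:risk\s+ratio)|(?i:relative\s+risk)|(?<!\w)RR(?!\w))[^.;\n]{0,30}?\d",
    "hazard-ratio": r"(?:(?i:hazard\s+ratio)|(?<!\w)HR(?!\w))[^.;\n]{0,30}?\d",
    "smd": r"(?<!\w)SMD(?!\w)[^.;\n]{0,30}?\d",
    "mean-difference": r"(?:(?i:mean\s+difference)|(?<!\w)MD(?!\w))[^.;\n]{0,30}?\d",
    "confidence-interval": r"(?:(?i:confidence\s+interval)|\b95\s*%\s*CI\b|(?<!\w)CI(?!\w))[^.;\n]{0,30}?\d",
    "p-value": r"(?<!\w)[pP]\s*[<=>]\s*0?\.\d+",
}
_DEFAULT_QUALITY_PHRASES = (
    "quality of the evidence",
    "quality of evidence",
    "quality of the included studies",
    "quality of the studies",
    "certainty of the evidence",
    "certainty of evidence",
    "risk of bias",
)
# Graded-quality adjectives are handled as a pattern in the detector; these
# phrase lexicons are exact (case-insensitive) multiword matches.
_DEFAULT_EXPLANATION_CUES = (
    "this means",
    "in other words",
    "which means",
    "put simply",
    "out of 100",
    "out of 1000",
    "per 100",
    "per 1000",
    "equivalent to",
)


class Lexicons(BaseModel):
    """All term lists used by the detectors, externally configurable."""

    model_config = ConfigDict(frozen=True)

    jargon_terms: tuple[str, ...] = _DEFAULT_JARGON
    ambiguous_terms: tuple[str, ...] = _DEFAULT_AMBIGUOUS
    database_names: tuple[str, ...] = _DEFAULT_DATABASES
    stat_patterns: dict[str, str] = dict(_DEFAULT_STAT_PATTERNS)
    quality_phrases: tuple[str, ...] = _DEFAULT_QUALITY_PHRASES
    explanation_cues: tuple[str, ...] = _DEFAULT_EXPLANATION_CUES
    recommended_headings: tuple[str, ...] = RECOMMENDED_HEADINGS

    @field_validator("recommended_headings")
    @classmethod
    def _exactly_five(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(v) != 5:
            raise ValueError("recommended_headings must contain exactly 5 entries")
        return v


_SECTIONS = {
    "jargon": "jargon_terms",
    "ambiguous": "ambiguous_terms",
    "databases": "database_names",
    "quality": "quality_phrases",
    "explanation_cues": "explanation_cues",
    "headings": "recommended_headings",
}


def load_lexicons(path: str | Path) -> Lexicons:
    """Load lexicon overrides from a plain-text sectioned file."""
    path = Path(path)
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip().lower()
            if name not in _SECTIONS:
                raise ValidationError(f"unknown lexicon section [{name}] in {path}")
            current = name
            sections[current] = []
        elif current is None:
            raise ValidationError(f"term {line!r} outside any [section] in {path}")
        else:
            sections[current].append(line)
    overrides = {_SECTIONS[k]: tuple(v) for k, v in sections.items()}
    return Lexicons(**overrides)
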