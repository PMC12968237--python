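"""Canonical cognitive-distortion taxonomy.

The default taxonomy is the 18 distortion categories from the
cognitive-behavioural-therapy literature, in a fixed canonical order. All
pairwise (153) and triadic (816) enumerations in the rest of the package are
defined relative to this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 18 distortion categories, canonical order.
DEFAULT_LABELS: tuple[str, ...] = (
    "All-or-Nothing Thinking",
    "Overgeneralization",
    "Mental Filter",
    "Disqualifying the Positive",
    "Fortune Telling",
    "Mind Reading",
    "Catastrophizing",
    "Emotional Reasoning",
    "Should Statements",
    "Labeling",
    "Personalization",
    "External Locus of Control",
    "Tunnel Vision",
    "Social Comparison",
    "Rationalization",
    "Rumination",
    "Learned Helplessness",
    "Fairness Fallacy",
)


@dataclass(frozen=True)
class DistortionTaxonomy:
    """An ordered set of unique label names.

    Parameters
    ----------
    labels
        Ordered category names. Must be unique, non-empty strings. Labels are
        matched case-sensitively after stripping surrounding whitespace.
    """

    labels: tuple[str, ...] = field(default=DEFAULT_LABELS)

    def __post_init__(self) -> None:
        cleaned = tuple(str(lab).strip() for lab in self.labels)
        if any(not lab for lab in cleaned):
            raise ValueError("taxonomy labels must be non-empty strings")
        if len(set(cleaned)) != len(cleaned):
            raise ValueError("taxonomy labels must be unique")
        object.__setattr__(self, "labels", cleaned)

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Index of *label* (stripped, case-sensitive match)."""
        try:
            return self.labels.index(label.strip())
        except ValueError:
            raise KeyError(f"unknown label: {label!r}") from None

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: str) -> bool:
        return label.strip() in self.labels
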