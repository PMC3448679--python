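"""Canonical page-category vocabulary.

Ten thematic categories of cancer-related web pages. Every category
sequence, emission matrix and label ballot in the package is expressed
over this fixed, ordered alphabet; the order is the canonical tie-break
order used wherever probabilities tie.
"""

from __future__ import annotations

CATEGORIES: tuple[str, ...] = (
    "causes",
    "prevention",
    "symptoms",
    "information",
    "treatment",
    "social_media",
    "support",
    "celebrity",
    "pets",
    "other",
)

N_CATEGORIES: int = len(CATEGORIES)

CATEGORY_INDEX: dict[str, int] = {c: i for i, c in enumerate(CATEGORIES)}

#: Token used in query-log files for pages whose category is unknown.
UNKNOWN_CATEGORY: str = "NA"


def encode(tokens) -> list[int]:
    """Map category tokens to integer codes, rejecting unknown tokens."""
    try:
        return [CATEGORY_INDEX[t] for t in tokens]
    except KeyError as exc:  # pragma: no cover - message formatting
        raise ValueError(f"unknown category token: {exc.args[0]!r}") from None


def decode(codes) -> list[str]:
    """Inverse of :func:`encode`."""
    return [CATEGORIES[int(c)] for c in codes]
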