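"""Text normalization shared by the descriptor engine and the vocabulary loader.

Product long names and ingredient lists arrive in mixed case, with diacritics
(Greek tonos, Latin accents) and label punctuation. Matching happens on a
normalized form: lowercase, accent-folded, punctuation collapsed to spaces.
``%`` and ``&`` survive normalization because they are load-bearing on labels
("0% fat", "ham & cheese").
"""

from __future__ import annotations

import re
import unicodedata

_PUNCT_RE = re.compile(r"[^\w%&]+", re.UNICODE)


def fold_accents(text: str) -> str:
    """Strip combining marks after NFKD decomposition (e.g. 'ά' -> 'α')."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def normalize_text(text: str) -> str:
    """Normalize free label text for pattern matching.

    Lowercases, folds accents and replaces every run of characters other than
    word characters, ``%`` and ``&`` with a single space.
    """
    text = fold_accents(text).lower()
    return _PUNCT_RE.sub(" ", text).strip()


def normalize_pattern(pattern: str) -> str:
    """Normalize a regex pattern to target normalized text.

    Only case and accents are folded; regex syntax (punctuation, escapes,
    anchors) is left intact, so authors write patterns in lowercase unaccented
    form against the output of :func:`normalize_text`.
    """
    return fold_accents(pattern).lower()
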