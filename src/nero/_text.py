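"""Shared tokenization: whitespace + punctuation split with character spans."""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(r"\w+(?:[-'’]\w+)*|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Tokens with 0-based half-open character spans.

    Hyphenated/apostrophed words stay single tokens so entity surfaces like
    ``life-altering`` do not fragment.
    """
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
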