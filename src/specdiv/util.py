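"""Shared helpers: seed derivation and error types."""

from __future__ import annotations

import hashlib


class UndefinedResultError(ValueError):
    """A quantity is mathematically undefined for the given inputs.

    Raised instead of silently coercing to 0, 1 or NaN (e.g. a correlation
    over a zero-variance vector, or a rate over an empty group).
    """


def derive_seed(master: int, *tokens: object) -> int:
    """Derive a child seed from a master seed and a stage/index path.

    Uses SHA-256 of ``"<master>|tok1|tok2|..."`` truncated to 63 bits, so the
    derivation is stable across platforms and reimplementations that follow
    the same convention (structure, not bit-stream, compatibility).
    """
    key = "|".join([str(int(master))] + [str(t) for t in tokens])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") >> 1
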