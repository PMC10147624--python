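"""Deterministic seed fan-out.

One user-facing seed is expanded into independent per-stage (or per-gene,
per-repetition) seeds by hashing the stage name into the stream, so any
stage can be rerun in isolation and results are invariant to the order in
which stages or genes are processed.
"""

from __future__ import annotations

import zlib


def derive_seed(base_seed: int, *tokens) -> int:
    """Stable 31-bit seed derived from a base seed and string-able tokens."""
    key = ":".join([str(base_seed), *map(str, tokens)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF
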