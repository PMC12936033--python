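"""Per-stage seed derivation from a single master seed."""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: blake2b(master_seed, stage) mod 2^31."""
    digest = hashlib.blake2b(
        f"{master_seed}:{stage}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)
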