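"""Small shared helpers."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO

import numpy as np


def openf(path, mode: str = "rt") -> IO:
    """Open ``path`` transparently, gzip-compressed or plain."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def rng_from(seed: int, *stream: int) -> np.random.Generator:
    """Derive an independent generator from a base seed and a stream tag.

    Seeding goes through :class:`numpy.random.SeedSequence` so distinct
    stream tags give statistically independent streams of the same seed.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *stream]))


class FormatError(ValueError):
    """Malformed input file; carries the offending path and line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{self.path}:{lineno}" if lineno is not None else self.path
        super().__init__(f"{where}: {message}")
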