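"""Shared helpers: seeded RNG streams, errors, label normalisation."""
from __future__ import annotations

import re
import zlib

import numpy as np


class CrosstraitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrosstraitError, ValueError):
    """A configuration field violates its constraint; message names the field."""


class FormatError(CrosstraitError, ValueError):
    """An input file does not conform to its declared dialect."""


class DomainError(CrosstraitError, ValueError):
    """Arguments outside the mathematical domain of an operation."""


def rng_stream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream derived from a master seed and a fixed label.

    Each consumer of randomness gets its own label, so adding a new
    generator never perturbs the draws of existing ones.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


_WS = re.compile(r"\s+")


def norm_label(label: str) -> str:
    """Case-fold and collapse whitespace for trait-label comparison."""
    return _WS.sub(" ", label.strip()).casefold()
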