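"""Shared primitives: the fundus image container and seeded RNG streams.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)`` with pixel centers at
  integer positions;
* orientations are unsigned line orientations, i.e. angles in ``[0, pi)``
  measured from the +col axis toward the +row axis;
* curvature is reported in ``px^-1`` (inverse osculating-circle radius).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

VESSEL_CLASSES = ("artery", "vein")
HIERARCHIES = ("main", "branch")
#: the four vessel classes reported in cohort tables
REPORT_CLASSES = ("main_artery", "main_vein", "branch_artery", "branch_vein")
GROUPS = ("nonDR", "V1", "V2", "V3")
#: multiplier applied to curvature (px^-1) in table output
REPORT_SCALE = 1e4


@dataclass
class FundusImage:
    """A 2D intensity grid, vessels dark on a bright background.

    Emulates the green (520 nm) channel of a confocal scanning laser
    ophthalmoscope, which offers the best vessel contrast of the
    available channels.
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("FundusImage requires a 2D pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("FundusImage pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _stable_key_hash(key: object) -> int:
    digest = hashlib.sha256(repr(key).encode("utf8")).digest()
    return int.from_bytes(digest[:4], "little")


def spawn_rng(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic child RNG keyed by ``(seed, *keys)``.

    All randomness in the package flows through this helper so that a
    single global seed reproduces every stage, including partial reruns.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_stable_key_hash(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class RunContext:
    """Carries the global seed through pipeline stages."""

    seed: int = 0
    substream_cache: dict = field(default_factory=dict)

    def rng(self, *keys: object) -> np.random.Generator:
        return spawn_rng(self.seed, *keys)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
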