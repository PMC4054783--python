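"""Hexamer motif catalogues and their set algebra.

Exonic splice enhancers (ESEs) are short exonic motifs, conventionally
represented as 6-mers over {A,C,G,T}, that promote recognition of nearby
splice sites.  The published catalogues (RESCUE-ESE, PESE, ESR, the
experimental Ke screens) are plain lists of hexamers; everything downstream
-- concordance statistics, density profiling, selection tests -- operates on
such lists.  This module provides the :class:`HexamerSet` container, the
octamer-to-hexamer derivation used by the PESE catalogue, k-of-n
intersection sets, and descriptive statistics (base composition, per-position
information content).

Motifs are stored strand-naively: ESEs act on the sense strand of the
pre-mRNA, so no reverse complementation happens anywhere in the package.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DNA_BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(DNA_BASES)

#: number of distinct hexamers over {A,C,G,T}
HEXAMER_UNIVERSE = 4 ** 6


def _validate_motif(motif: str, length: int) -> str:
    m = motif.strip().upper()
    if len(m) != length:
        raise ValueError(f"motif {motif!r} has length {len(m)}, expected {length}")
    bad = set(m) - _BASE_SET
    if bad:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters {sorted(bad)}")
    return m


@dataclass(frozen=True)
class HexamerSet:
    """A named catalogue of unique 6-mers over {A,C,G,T}.

    Motifs are canonicalised to uppercase.  Duplicate motifs in the input
    are collapsed with a logged warning rather than rejected, since several
    published supplements contain repeated lines.
    """

    name: str
    motifs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for m in self.motifs:
            _validate_motif(m, 6)

    @classmethod
    def from_iterable(cls, name: str, motifs: Iterable[str]) -> "HexamerSet":
        cleaned = [_validate_motif(m, 6) for m in motifs]
        counts = Counter(cleaned)
        dups = [m for m, c in counts.items() if c > 1]
        if dups:
            logger.warning(
                "catalogue %s: %d duplicated motifs collapsed (e.g. %s)",
                name, len(dups), dups[0],
            )
        return cls(name, frozenset(cleaned))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "HexamerSet":
        """Read a plain-text motif list: one motif per line, ``#`` comments."""
        path = Path(path)
        motifs = []
        for line in path.read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                motifs.append(line)
        return cls.from_iterable(name or path.stem, motifs)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{m}\n" for m in sorted(self.motifs)))

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, motif: str) -> bool:
        return motif in self.motifs

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.motifs))

    def rename(self, name: str) -> "HexamerSet":
        return HexamerSet(name, self.motifs)


@dataclass(frozen=True)
class OctamerList:
    """An ordered list of 8-mers, duplicates allowed.

    This mirrors the raw PESE supplement, which reports octamers; the
    published hexamer catalogue is derived from it (see
    :func:`hexamers_from_octamers`).
    """

    octamers: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "octamers", tuple(_validate_motif(o, 8) for o in self.octamers)
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "OctamerList":
        lines = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                lines.append(line)
        return cls(tuple(lines))

    def __len__(self) -> int:
        return len(self.octamers)


def hexamers_from_octamers(
    octamers: OctamerList | Iterable[str],
    min_occurrences: int = 7,
    name: str = "octamer-derived",
) -> HexamerSet:
    """Derive a hexamer catalogue from an octamer list.

    Each octamer contributes its three constituent hexamers (offsets 0, 1
    and 2); occurrences are tallied over the whole list, counting every
    offset separately, and hexamers seen at least ``min_occurrences`` times
    are retained.  With the default threshold of 7 this is the rule that
    produced the 238-hexamer PESE catalogue from its 2,069 octamers.
    """
    if not isinstance(octamers, OctamerList):
        octamers = OctamerList(tuple(octamers))
    counts: Counter = Counter()
    for octamer in octamers.octamers:
        for i in range(3):
            counts[octamer[i:i + 6]] += 1
    kept = [h for h, c in counts.items() if c >= min_occurrences]
    return HexamerSet.from_iterable(name, kept)


def intersect_at_least(sets: list, k: int) -> HexamerSet:
    """Motifs present in at least ``k`` of the given catalogues.

    ``k = len(sets)`` is the full intersection; ``k = 1`` the union.  The
    consensus catalogues built this way from the four published screens are
    the INT2 / INT3 style sets.
    """
    if not sets:
        raise ValueError("need at least one input catalogue")
    if not 1 <= k <= len(sets):
        raise ValueError(f"k={k} out of range for {len(sets)} catalogues")
    counts: Counter = Counter()
    for s in sets:
        counts.update(s.motifs)
    members = [m for m, c in counts.items() if c >= k]
    name = f"INT{k}(" + ",".join(s.name for s in sets) + ")"
    return HexamerSet.from_iterable(name, members)


def union_size(n1: int, n2: int, n_common: int) -> int:
    """Inclusion-exclusion size of the union of two motif sets.

    E.g. 103 donor-end and 198 acceptor-end motifs with 63 in common give
    the 238 hexamers of the RESCUE-ESE catalogue.
    """
    if n1 < 0 or n2 < 0 or n_common < 0:
        raise ValueError("counts must be non-negative")
    if n_common > min(n1, n2):
        raise ValueError(
            f"n_common={n_common} exceeds a set size (n1={n1}, n2={n2})"
        )
    return n1 + n2 - n_common


def composition(hexamers: HexamerSet) -> dict:
    """Base fractions of a catalogue, over all ``6 * |set|`` base slots.

    Returns A, C, G, T fractions plus the purine fraction AG = A + G and
    GC = G + C.
    """
    if len(hexamers) == 0:
        raise ValueError("composition of an empty catalogue is undefined")
    counts = Counter()
    for motif in hexamers:
        counts.update(motif)
    total = 6 * len(hexamers)
    frac = {b: counts.get(b, 0) / total for b in DNA_BASES}
    frac["AG"] = frac["A"] + frac["G"]
    frac["GC"] = frac["G"] + frac["C"]
    return frac


def composition_chisquare(hexamers: HexamerSet, background: dict) -> tuple:
    """Chi-square test of a catalogue's base counts against a background.

    ``background`` maps each base to an expected fraction (summing to 1).
    Returns ``(statistic, p_value)``.  Descriptive convenience only; no
    particular null is implied beyond the supplied composition.
    """
    from scipy import stats

    counts = Counter()
    for motif in hexamers:
        counts.update(motif)
    obs = np.array([counts.get(b, 0) for b in DNA_BASES], dtype=float)
    exp_frac = np.array([background[b] for b in DNA_BASES], dtype=float)
    if not math.isclose(exp_frac.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background fractions must sum to 1")
    exp = exp_frac * obs.sum()
    stat, p = stats.chisquare(obs, exp)
    return float(stat), float(p)


def positional_information(hexamers: HexamerSet) -> np.ndarray:
    """Information content (bits) at each of the six motif positions.

    For position i with base fractions f_b the information is
    ``2 + sum_b f_b log2 f_b``; 2 bits for a fixed base, 0 for a uniform
    position.  Returned as an array of six values in [0, 2].
    """
    if len(hexamers) == 0:
        raise ValueError("information content of an empty catalogue is undefined")
    motifs = sorted(hexamers.motifs)
    info = np.empty(6)
    n = len(motifs)
    for i in range(6):
        counts = Counter(m[i] for m in motifs)
        h = -sum((c / n) * math.log2(c / n) for c in counts.values())
        info[i] = 2.0 - h
    # clip tiny negative rounding noise
    return np.clip(info, 0.0, 2.0)


def all_hexamers() -> list:
    """The full universe of 4,096 hexamers, lexicographically sorted."""
    from itertools import product

    return ["".join(p) for p in product(DNA_BASES, repeat=6)]
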