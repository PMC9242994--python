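"""Per-transcript hexamer-set frequencies, class comparisons and profiles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import kstwobign

from .screen import HEXAMER_K, N_HEXAMERS, all_hexamers

WINDOW = HEXAMER_K


@dataclass
class HexamerSet:
    """A named subset of the 4096-hexamer space."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        space = set(all_hexamers())
        bad = self.members - space
        if bad:
            raise ValueError(f"not hexamers: {sorted(bad)[:5]}")

    @classmethod
    def full_space(cls) -> "HexamerSet":
        return cls("all", frozenset(all_hexamers()))


@dataclass
class FrequencyDistribution:
    """Per-transcript average frequencies of a hexamer set."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.values.size)


def transcript_set_frequency(
    seq: str,
    hset: HexamerSet | frozenset[str] | set[str],
    mode: str = "per_window",
) -> float:
    """Fraction of overlapping hexamer windows whose hexamer is in the set.

    Windows advance by 1 nt; windows containing N are excluded from both
    numerator and denominator.  ``mode='per_hexamer_mean'`` divides the
    per-window value by the set size (mean of per-hexamer frequencies).
    """
    members = hset.members if isinstance(hset, HexamerSet) else frozenset(hset)
    if len(seq) < WINDOW:
        raise ValueError(f"sequence shorter than {WINDOW} nt")
    hits = 0
    valid = 0
    for i in range(len(seq) - WINDOW + 1):
        window = seq[i : i + WINDOW]
        if "N" in window:
            continue
        valid += 1
        if window in members:
            hits += 1
    if valid == 0:
        raise ValueError("no N-free windows in sequence")
    freq = hits / valid
    if mode == "per_hexamer_mean":
        return freq / len(members)
    if mode != "per_window":
        raise ValueError(f"unknown mode: {mode!r}")
    return freq


def set_frequency_distribution(
    records: Mapping[str, str],
    hset: HexamerSet | frozenset[str] | set[str],
    label: str = "",
    mode: str = "per_window",
) -> FrequencyDistribution:
    values = [transcript_set_frequency(seq, hset, mode=mode) for seq in records.values()]
    return FrequencyDistribution(np.asarray(values), label=label)


def compare_sets_ks(
    a: FrequencyDistribution | Sequence[float],
    b: FrequencyDistribution | Sequence[float],
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov D and asymptotic p.

    D is the supremum ECDF difference; the p-value is the asymptotic
    Kolmogorov distribution evaluated at sqrt(n*m/(n+m)) * D.
    """
    xa = np.sort(np.asarray(a.values if isinstance(a, FrequencyDistribution) else a, dtype=float))
    xb = np.sort(np.asarray(b.values if isinstance(b, FrequencyDistribution) else b, dtype=float))
    n, m = xa.size, xb.size
    if n < 2 or m < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([xa, xb])
    cdf_a = np.searchsorted(xa, pooled, side="right") / n
    cdf_b = np.searchsorted(xb, pooled, side="right") / m
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = np.sqrt(n * m / (n + m))
    p = float(np.clip(kstwobign.sf(en * d), 0.0, 1.0))
    return d, p


def positional_profile(
    regions: Sequence[str],
    hset: HexamerSet | frozenset[str] | set[str],
) -> np.ndarray:
    """Sliding-window set frequency across a stack of equal-length regions.

    Entry ``w`` of the returned vector (length L-5) is the fraction of
    sequences whose window starting at ``w`` is a member of the set,
    counted over windows that contain no N.
    """
    members = hset.members if isinstance(hset, HexamerSet) else frozenset(hset)
    if not regions:
        raise ValueError("no regions supplied")
    length = len(regions[0])
    if any(len(r) != length for r in regions):
        raise ValueError("all regions must have the same length")
    if length < WINDOW:
        raise ValueError(f"regions shorter than {WINDOW} nt")
    n_windows = length - WINDOW + 1
    hits = np.zeros(n_windows)
    contributing = np.zeros(n_windows)
    for seq in regions:
        for w in range(n_windows):
            window = seq[w : w + WINDOW]
            if "N" in window:
                continue
            contributing[w] += 1
            if window in members:
                hits[w] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(contributing > 0, hits / np.maximum(contributing, 1), np.nan)
    return profile


def anchored_regions(
    sequences: Mapping[str, str], anchors: Mapping[str, int], flank: int = 300
) -> list[str]:
    """Cut ``anchor - flank .. anchor + flank`` regions; out-of-bounds dropped."""
    regions = []
    for sid, seq in sequences.items():
        if sid not in anchors:
            continue
        a = anchors[sid]
        if a - flank < 0 or a + flank > len(seq):
            continue
        regions.append(seq[a - flank : a + flank])
    return regions


def split_heptamer(heptamer: str) -> tuple[str, str]:
    """A 7-mer yields its two overlapping hexamers."""
    if len(heptamer) != 7:
        raise ValueError(f"not a heptamer: {heptamer!r}")
    return heptamer[:6], heptamer[1:]


def heptamer_split_lookup(
    heptamers_by_class: Mapping[str, Sequence[str]],
    z_by_hexamer: Mapping[str, float],
) -> dict[str, np.ndarray]:
    """Z scores of the two hexamers of every heptamer, grouped by class.

    ``z_by_hexamer`` must cover the whole hexamer space (e.g. built from
    the screen score table).
    """
    if len(z_by_hexamer) < N_HEXAMERS:
        raise ValueError("score table must cover all 4096 hexamers")
    out: dict[str, np.ndarray] = {}
    for cls, heptamers in heptamers_by_class.items():
        zs: list[float] = []
        for hep in heptamers:
            left, right = split_heptamer(hep)
            zs.append(float(z_by_hexamer[left]))
            zs.append(float(z_by_hexamer[right]))
        out[cls] = np.asarray(zs)
    return out
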