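"""Insert recovery from sorted-fraction reads and hexamer enrichment statistics.

The screen inserts a random decamer into a circular reporter between two
fixed vector flanks.  Reads are recovered only on an exact flank match,
each decamer is extended into a 14-mer with two vector nucleotides on
each side, and the 9 overlapping hexamers of every 14-mer are counted
per fraction.  Enrichment of a hexamer between two fractions is scored
with a pooled two-proportion z statistic; hexamers with z above / below
the configured thresholds are classified enriched / depleted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

BASES = "ACGT"
HEXAMER_K = 6
N_HEXAMERS = 4 ** HEXAMER_K
INSERT_LEN = 10
UPSTREAM_MATCH_LEN = 24
DOWNSTREAM_MATCH_LEN = 30

DEFAULT_Z_HI = 7.0
DEFAULT_Z_LO = -7.0

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i

_HEXAMER_WEIGHTS = (4 ** np.arange(HEXAMER_K - 1, -1, -1)).astype(np.int64)


def all_hexamers() -> list[str]:
    """All 4096 hexamers in lexicographic order (index == base-4 code)."""
    return ["".join(p) for p in itertools.product(BASES, repeat=HEXAMER_K)]


_HEXAMERS = all_hexamers()


def hexamer_code(hexamer: str) -> int:
    """Base-4 integer code of a hexamer (A=0, C=1, G=2, T=3)."""
    if len(hexamer) != HEXAMER_K:
        raise ValueError(f"not a hexamer: {hexamer!r}")
    code = 0
    for ch in hexamer:
        idx = _BASE_CODE[ord(ch)]
        if idx == 255:
            raise ValueError(f"invalid base in hexamer: {hexamer!r}")
        code = code * 4 + int(idx)
    return code


@dataclass(frozen=True)
class VectorContext:
    """Fixed reporter sequence around the random insert.

    ``extension_left``/``extension_right`` are the two vector nucleotides
    appended to each side of the insert before hexamer counting; they are
    derived from the flanks and therefore always consistent with them.
    """

    upstream_flank: str
    downstream_flank: str

    def __post_init__(self) -> None:
        if len(self.upstream_flank) < UPSTREAM_MATCH_LEN:
            raise ValueError(
                f"upstream flank must be >= {UPSTREAM_MATCH_LEN} nt, "
                f"got {len(self.upstream_flank)}"
            )
        if len(self.downstream_flank) < DOWNSTREAM_MATCH_LEN:
            raise ValueError(
                f"downstream flank must be >= {DOWNSTREAM_MATCH_LEN} nt, "
                f"got {len(self.downstream_flank)}"
            )
        for flank in (self.upstream_flank, self.downstream_flank):
            if set(flank) - set(BASES):
                raise ValueError(f"flank contains non-ACGT characters: {flank!r}")

    @property
    def extension_left(self) -> str:
        return self.upstream_flank[-2:]

    @property
    def extension_right(self) -> str:
        return self.downstream_flank[:2]


# Default context: the cloning primer places the insert directly after an
# ...AGTAA reporter stop and before an ATC spacer + ATG start.  The exact
# post-cloning construct is configurable; these defaults only pin the two
# extension dinucleotides (AA upstream, AT downstream).
DEFAULT_VECTOR = VectorContext(
    upstream_flank="CACTCTCGGCATGGACGAGTTGTAA",
    downstream_flank="ATCATGGTGAGCAAGGGCGAGGAGCTGTTC",
)


@dataclass
class InsertSet:
    """Multiset of recovered 10-nt inserts for one sorted fraction."""

    fraction_label: str
    inserts: list[str]
    n_reads_total: int
    n_reads_matched: int

    def __post_init__(self) -> None:
        if self.n_reads_matched > self.n_reads_total:
            raise ValueError("n_reads_matched exceeds n_reads_total")
        if self.n_reads_matched != len(self.inserts):
            raise ValueError("n_reads_matched must equal the number of inserts")


def extract_inserts(
    reads: Iterable[str],
    ctx: VectorContext = DEFAULT_VECTOR,
    fraction_label: str = "",
    insert_len: int = INSERT_LEN,
) -> InsertSet:
    """Recover inserts that sit between exact matches of both vector flanks.

    Only the last 24 nt of the upstream flank and the first 30 nt of the
    downstream flank are compared, both must match exactly on the read's
    forward orientation, and inserts containing any non-ACGT character
    are dropped (such reads count as unmatched).
    """
    up = ctx.upstream_flank[-UPSTREAM_MATCH_LEN:]
    down = ctx.downstream_flank[:DOWNSTREAM_MATCH_LEN]
    valid = set(BASES)
    inserts: list[str] = []
    n_total = 0
    for read in reads:
        n_total += 1
        pos = read.find(up)
        while pos >= 0:
            start = pos + UPSTREAM_MATCH_LEN
            candidate = read[start : start + insert_len]
            tail = read[start + insert_len : start + insert_len + DOWNSTREAM_MATCH_LEN]
            if len(candidate) == insert_len and tail == down:
                if set(candidate) <= valid:
                    inserts.append(candidate)
                break
            pos = read.find(up, pos + 1)
    return InsertSet(
        fraction_label=fraction_label,
        inserts=inserts,
        n_reads_total=n_total,
        n_reads_matched=len(inserts),
    )


@dataclass
class HexamerCountTable:
    """Counts over the full 4096-hexamer space.

    ``counts[i]`` is the count of the hexamer with base-4 code ``i``;
    ``total`` is the sum of all counts (9 windows per counted insert).
    """

    counts: np.ndarray
    total: int
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_HEXAMERS,):
            raise ValueError("counts must cover the 4096-hexamer space")
        if int(self.counts.sum()) != self.total:
            raise ValueError("total must equal the sum of counts")

    def count(self, hexamer: str) -> int:
        return int(self.counts[hexamer_code(hexamer)])

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros(N_HEXAMERS)
        return self.counts / self.total

    def as_mapping(self) -> dict[str, int]:
        return {h: int(c) for h, c in zip(_HEXAMERS, self.counts)}


def _encode_14mers(fourteen_mers: Sequence[str]) -> np.ndarray:
    flat = np.frombuffer("".join(fourteen_mers).encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[flat].reshape(len(fourteen_mers), INSERT_LEN + 4)


def count_hexamers(
    insert_set: InsertSet | Sequence[str],
    ctx: VectorContext = DEFAULT_VECTOR,
    weights: Sequence[int] | None = None,
) -> HexamerCountTable:
    """Count the 9 overlapping hexamers of every vector-extended 14-mer.

    Inserts that are not 10 nt of pure ACGT are rejected (logged and
    reported in ``n_rejected``).  ``weights`` optionally gives a
    per-insert multiplicity (for pre-aggregated ``(insert, count)`` input).
    """
    inserts = insert_set.inserts if isinstance(insert_set, InsertSet) else list(insert_set)
    if weights is not None and len(weights) != len(inserts):
        raise ValueError("weights must align with inserts")
    valid = set(BASES)
    kept: list[str] = []
    kept_w: list[int] = []
    n_rejected = 0
    for i, ins in enumerate(inserts):
        if len(ins) == INSERT_LEN and set(ins) <= valid:
            kept.append(ctx.extension_left + ins + ctx.extension_right)
            kept_w.append(1 if weights is None else int(weights[i]))
        else:
            n_rejected += 1
    if n_rejected:
        log.warning("count_hexamers: rejected %d malformed inserts", n_rejected)
    if not kept:
        return HexamerCountTable(np.zeros(N_HEXAMERS, dtype=np.int64), 0, n_rejected)
    codes = _encode_14mers(kept).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, HEXAMER_K, axis=1)
    hexcodes = windows @ _HEXAMER_WEIGHTS  # (n, 9)
    w = np.repeat(np.asarray(kept_w, dtype=np.int64), hexcodes.shape[1])
    counts = np.bincount(hexcodes.ravel(), weights=w, minlength=N_HEXAMERS).astype(np.int64)
    return HexamerCountTable(counts, int(counts.sum()), n_rejected)


@dataclass(frozen=True)
class EnrichmentScore:
    hexamer: str
    z: float
    class_label: str  # enriched | depleted | neutral


def _pooled_z(
    c1: np.ndarray, n1: int, c2: np.ndarray, n2: int
) -> np.ndarray:
    p1 = c1 / n1
    p2 = c2 / n2
    pooled = (c1 + c2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
        z = (p1 - p2) / se
    return np.where(se > 0, z, 0.0)


def score_enrichment(
    green: HexamerCountTable,
    dark: HexamerCountTable,
    z_hi: float = DEFAULT_Z_HI,
    z_lo: float = DEFAULT_Z_LO,
) -> list[EnrichmentScore]:
    """Pooled two-proportion z for every hexamer, green vs dark.

    A hexamer absent from both tables scores 0 by convention (no
    pseudocounts).  Classification: enriched iff z > z_hi, depleted iff
    z < z_lo, neutral otherwise.
    """
    if green.total <= 0 or dark.total <= 0:
        raise ValueError("both count tables must have positive totals")
    z = _pooled_z(green.counts, green.total, dark.counts, dark.total)
    labels = np.where(z > z_hi, "enriched", np.where(z < z_lo, "depleted", "neutral"))
    return [
        EnrichmentScore(h, float(zi), str(li))
        for h, zi, li in zip(_HEXAMERS, z, labels)
    ]


def score_table(
    green: HexamerCountTable,
    dark: HexamerCountTable,
    z_hi: float = DEFAULT_Z_HI,
    z_lo: float = DEFAULT_Z_LO,
) -> pd.DataFrame:
    """Tabular form of :func:`score_enrichment` (one row per hexamer)."""
    scores = score_enrichment(green, dark, z_hi=z_hi, z_lo=z_lo)
    return pd.DataFrame(
        {
            "hexamer": _HEXAMERS,
            "count_green": green.counts,
            "count_dark": dark.counts,
            "freq_green": green.frequencies(),
            "freq_dark": dark.frequencies(),
            "z": [s.z for s in scores],
            "class": [s.class_label for s in scores],
        }
    )


def classified(scores: Iterable[EnrichmentScore], label: str) -> list[str]:
    return [s.hexamer for s in scores if s.class_label == label]


@dataclass
class CompositionStats:
    base_freq: dict[str, float]
    dinuc_freq: dict[str, float]
    odds_ratio: dict[str, float]  # NaN when a base frequency in the denominator is 0


def composition_stats(insert_set: InsertSet | Sequence[str]) -> CompositionStats:
    """Base frequencies and dinucleotide odds ratios of an insert library.

    Base frequencies are computed over all insert positions; dinucleotide
    probabilities over the 9 overlapping dinucleotide windows of each
    insert.  odds(XY) = P(XY) / (P(X) * P(Y)).
    """
    inserts = insert_set.inserts if isinstance(insert_set, InsertSet) else list(insert_set)
    if not inserts:
        raise ValueError("composition_stats requires a non-empty insert set")
    base_counts = {b: 0 for b in BASES}
    dinuc_counts = {a + b: 0 for a in BASES for b in BASES}
    n_bases = 0
    n_dinucs = 0
    for ins in inserts:
        for ch in ins:
            base_counts[ch] += 1
            n_bases += 1
        for i in range(len(ins) - 1):
            dinuc_counts[ins[i : i + 2]] += 1
            n_dinucs += 1
    base_freq = {b: c / n_bases for b, c in base_counts.items()}
    dinuc_freq = {d: c / n_dinucs for d, c in dinuc_counts.items()}
    odds: dict[str, float] = {}
    for d, p in dinuc_freq.items():
        denom = base_freq[d[0]] * base_freq[d[1]]
        odds[d] = p / denom if denom > 0 else float("nan")
    return CompositionStats(base_freq, dinuc_freq, odds)


# ---------------------------------------------------------------------------
# motif clustering


@dataclass
class MotifCluster:
    members: list[str]
    consensus_matrix: pd.DataFrame  # rows A/C/G/T, one column per aligned position
    label: str


def _offset_distance(a: str, b: str, max_shift: int = 2) -> int:
    """Minimal mismatches of b against a over ungapped offsets -2..+2.

    Positions left unaligned by a shift count as mismatches, so shifting
    is never free.
    """
    best = len(a)
    for off in range(-max_shift, max_shift + 1):
        overlap = 0
        mismatches = 0
        for i in range(len(a)):
            j = i - off
            if 0 <= j < len(b):
                overlap += 1
                if a[i] != b[j]:
                    mismatches += 1
        best = min(best, mismatches + (len(a) - overlap))
    return best


def _best_offset(ref: str, s: str, max_shift: int = 2) -> int:
    best_off = 0
    best_key = (-1, 0, 0)
    for off in range(-max_shift, max_shift + 1):
        matches = 0
        for i in range(len(ref)):
            j = i - off
            if 0 <= j < len(s) and ref[i] == s[j]:
                matches += 1
        key = (matches, -abs(off), -off)
        if key > best_key:
            best_key = key
            best_off = off
    return best_off


def _consensus(members: list[str], max_shift: int = 2) -> tuple[pd.DataFrame, str]:
    ref = min(members)
    placed = [(_best_offset(ref, m, max_shift), m) for m in members]
    lo = min(off for off, _ in placed)
    hi = max(off + len(m) for off, m in placed)
    width = hi - lo
    counts = np.zeros((4, width))
    for off, m in placed:
        for j, ch in enumerate(m):
            counts[_BASE_CODE[ord(ch)], off - lo + j] += 1
    colsum = counts.sum(axis=0)
    keep = colsum > 0
    freq = counts[:, keep] / colsum[keep]
    matrix = pd.DataFrame(freq, index=list(BASES), columns=range(int(keep.sum())))
    label = "".join(BASES[i] for i in freq.argmax(axis=0))
    return matrix, label


def cluster_hexamers(
    hexamers: Sequence[str], n_clusters: int, max_shift: int = 2
) -> list[MotifCluster]:
    """Deterministic average-linkage clustering on best-offset mismatch distance.

    Input order does not matter: members are sorted lexicographically
    before the distance matrix is built, which fixes all tie-breaks.
    """
    members = sorted(hexamers)
    if not members:
        raise ValueError("need at least one hexamer")
    if not 1 <= n_clusters <= len(members):
        raise ValueError(
            f"n_clusters must be in [1, {len(members)}], got {n_clusters}"
        )
    for h in members:
        hexamer_code(h)  # validates
    if len(members) == 1:
        matrix, label = _consensus(members, max_shift)
        return [MotifCluster(members, matrix, label)]
    m = len(members)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = _offset_distance(members[i], members[j], max_shift)
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = cut_tree(Z, n_clusters=n_clusters).ravel()
    clusters: list[MotifCluster] = []
    for k in sorted(set(labels)):
        group = [members[i] for i in np.flatnonzero(labels == k)]
        matrix, label = _consensus(group, max_shift)
        clusters.append(MotifCluster(group, matrix, label))
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def write_pfms(clusters: Iterable[MotifCluster], path) -> None:
    """Write consensus matrices as JASPAR-style position frequency text."""
    with open(path, "w") as fh:
        for i, cluster in enumerate(clusters, 1):
            fh.write(f">cluster{i} {cluster.label}\n")
            for base in BASES:
                row = " ".join(
                    f"{v:.6f}" for v in cluster.consensus_matrix.loc[base].to_numpy()
                )
                fh.write(f"{base} [ {row} ]\n")
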