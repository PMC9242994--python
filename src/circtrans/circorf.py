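"""ORF prediction on circular sequences, including rolling-circle ORFs.

A circle of length L is scanned via its 4x concatemer.  Every NTG start
codon whose offset is < L opens a reading; if a stop codon appears
within 3L nt past the start the reading is a finite cORF, otherwise the
frame path is stop-free forever (frames repeat with period 3L) and the
start defines a rolling-circle ORF (rcORF).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

START_CODONS = frozenset({"ATG", "CTG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_MIN_AA = 20
DEFAULT_MIN_OVERLAP_AA = 7
DEFAULT_MAX_MISMATCH = 2

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = dict(unambiguous_dna_by_id[1].forward_table)
    for stop in STOP_CODONS:
        table[stop] = "*"
    return table


def translate(seq: str) -> str:
    """Translate a DNA string codon by codon; stops become ``*``."""
    if not _CODON_TABLE:
        _CODON_TABLE.update(_build_codon_table())
    return "".join(
        _CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3)
    )


@dataclass
class CircRNA:
    """A mature circle; position 0 immediately follows the back-splice junction."""

    id: str
    seq: str
    host_id: str | None = None
    host_map: list[tuple[int, tuple[int, int]]] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.id}: empty circle")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CircOrf:
    """An ORF on a circle.  ``length_aa`` is ``math.inf`` for an rcORF."""

    start_offset: int
    start_codon: str
    type: str  # "cORF" | "rcORF"
    length_aa: float
    stop_offset: int | None
    crosses_junction: bool
    peptide: str


def _validate_circle(seq: str) -> None:
    if set(seq) - set("ACGT"):
        raise ValueError("circle contains non-ACGT characters")


def find_circorfs(
    circ: CircRNA | str,
    min_aa: int = DEFAULT_MIN_AA,
    starts: frozenset[str] | set[str] = START_CODONS,
) -> list[CircOrf]:
    """All qualifying ORFs opened by NTG starts on the sense strand.

    Starts are enumerated in the first concatemer copy only (offset < L).
    A finite reading is emitted only when its peptide is >= ``min_aa``;
    a stop-free reading over 3L nt past the start is an rcORF whose
    stored peptide is the translation of exactly L codons.
    """
    seq = circ.seq if isinstance(circ, CircRNA) else circ
    _validate_circle(seq)
    L = len(seq)
    if L < 3:
        return []
    concat = seq * 4
    orfs: list[CircOrf] = []
    for i in range(L):
        codon = concat[i : i + 3]
        if codon not in starts:
            continue
        # exactly L codons = 3L nt past the start
        peptide = translate(concat[i : i + 3 * L])
        stop_idx = peptide.find("*")
        if stop_idx == -1:
            orfs.append(
                CircOrf(
                    start_offset=i,
                    start_codon=codon,
                    type="rcORF",
                    length_aa=math.inf,
                    stop_offset=None,
                    crosses_junction=True,
                    peptide=peptide,
                )
            )
        elif stop_idx >= min_aa:
            orfs.append(
                CircOrf(
                    start_offset=i,
                    start_codon=codon,
                    type="cORF",
                    length_aa=float(stop_idx),
                    stop_offset=(i + 3 * stop_idx) % L,
                    crosses_junction=(i + 3 * stop_idx + 3) > L,
                    peptide=peptide[:stop_idx],
                )
            )
    return orfs


# ---------------------------------------------------------------------------
# survey


SURVEY_CATEGORIES = (
    "overlapped_cORF",
    "overlapped_rcORF",
    "homologous_cORF",
    "homologous_rcORF",
    "non_homologous",
    "no_orf",
)


@dataclass
class OrfSurvey:
    categories: dict[str, str]  # circ id -> category
    fractions: dict[str, float]
    counts: dict[str, int]


def longest_common_run(a: str, b: str) -> int:
    """Length of the longest common substring (consecutive identical run)."""
    if not a or not b:
        return 0
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    best = 0
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    for ca in a.encode("ascii"):
        cur = np.zeros(len(b) + 1, dtype=np.int32)
        match = bb == ca
        cur[1:][match] = prev[:-1][match] + 1
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def ungapped_homology(
    peptide: str, proteins: Iterable[str], max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> bool:
    """Best ungapped alignment with <= max_mismatch substitutions over the
    shorter sequence, tested against every protein."""
    for prot in proteins:
        short, long_ = (peptide, prot) if len(peptide) <= len(prot) else (prot, peptide)
        if not short:
            continue
        ls = len(short)
        for off in range(len(long_) - ls + 1):
            mism = 0
            for x, y in zip(short, long_[off : off + ls]):
                if x != y:
                    mism += 1
                    if mism > max_mismatch:
                        break
            if mism <= max_mismatch:
                return True
    return False


def _pick_representative(orfs: Sequence[CircOrf]) -> CircOrf:
    # rcORF outranks any cORF, then length, then leftmost start
    return max(orfs, key=lambda o: (o.type == "rcORF", o.length_aa, -o.start_offset))


def survey_orfs(
    circs: Sequence[CircRNA],
    host_proteins: Mapping[str, str],
    known_proteins: Sequence[str],
    min_aa: int = DEFAULT_MIN_AA,
    min_overlap_aa: int = DEFAULT_MIN_OVERLAP_AA,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    homology_fn: Callable[[str, Sequence[str], int], bool] | None = None,
) -> OrfSurvey:
    """Classify every circle into one mutually exclusive survey category.

    Priority: overlapped (>= min_overlap_aa consecutive residues shared
    with the host protein) > homologous (<= max_mismatch substitutions
    against any known protein) > non_homologous > no_orf.  The cORF/rcORF
    sub-label comes from the qualifying ORF (rcORF preferred, then
    longest).
    """
    if homology_fn is None:
        homology_fn = ungapped_homology
    categories: dict[str, str] = {}
    for circ in circs:
        orfs = find_circorfs(circ, min_aa=min_aa)
        if not orfs:
            categories[circ.id] = "no_orf"
            continue
        host = host_proteins.get(circ.host_id) if circ.host_id else None
        if circ.host_id and host is None:
            log.warning("survey_orfs: no host protein for %s; overlap test skipped", circ.id)
        overlapped = (
            [o for o in orfs if longest_common_run(o.peptide, host) >= min_overlap_aa]
            if host
            else []
        )
        if overlapped:
            rep = _pick_representative(overlapped)
            categories[circ.id] = f"overlapped_{rep.type}"
            continue
        homologous = [
            o for o in orfs if homology_fn(o.peptide, known_proteins, max_mismatch)
        ]
        if homologous:
            rep = _pick_representative(homologous)
            categories[circ.id] = f"homologous_{rep.type}"
            continue
        categories[circ.id] = "non_homologous"
    counts = Counter(categories.values())
    n = max(len(categories), 1)
    fractions = {cat: counts.get(cat, 0) / n for cat in SURVEY_CATEGORIES}
    return OrfSurvey(
        categories=categories,
        fractions=fractions,
        counts={cat: counts.get(cat, 0) for cat in SURVEY_CATEGORIES},
    )


def make_controls(
    circs: Sequence[CircRNA], seed: int
) -> tuple[list[CircRNA], list[CircRNA]]:
    """Reversed (plain character reversal) and seeded per-sequence shuffles."""
    rng = np.random.default_rng(seed)
    reversed_set = [
        CircRNA(id=f"{c.id}_rev", seq=c.seq[::-1], host_id=c.host_id) for c in circs
    ]
    shuffled_set = []
    for c in circs:
        chars = np.array(list(c.seq))
        shuffled = "".join(chars[rng.permutation(len(chars))])
        shuffled_set.append(CircRNA(id=f"{c.id}_shuf", seq=shuffled, host_id=c.host_id))
    return reversed_set, shuffled_set


# ---------------------------------------------------------------------------
# first-exon statistics


@dataclass
class TranscriptAnnotation:
    """Host transcript exon structure with a CDS span (plus-strand coords)."""

    exons: list[tuple[int, int]]  # half-open genomic spans, 5'->3'
    cds: tuple[int, int]


@dataclass
class FirstExonStats:
    histogram: dict[int, int]  # first-exon ordinal -> circRNA count
    region_fractions: dict[str, float]
    n_unmapped: int


def _region_category(span: tuple[int, int], ann: TranscriptAnnotation) -> str:
    start, end = span
    cds_start, cds_end = ann.cds
    tx_start = min(s for s, _ in ann.exons)
    tx_end = max(e for _, e in ann.exons)
    in_utr5 = start < cds_start and tx_start < cds_start
    in_cds = start < cds_end and end > cds_start
    in_utr3 = end > cds_end and tx_end > cds_end
    if in_cds and not in_utr5 and not in_utr3:
        return "CDS"
    if in_cds and in_utr5 and not in_utr3:
        return "5UTR-CDS"
    if in_cds and in_utr3 and not in_utr5:
        return "CDS-3UTR"
    return "other"


def first_exon_stats(
    circs: Sequence[CircRNA], annotation: Mapping[str, TranscriptAnnotation]
) -> FirstExonStats:
    """Ordinal of each circle's first exon in its host, plus region classes.

    Exon ordinals in ``host_map`` are 1-based.  Circles without a host
    map or whose host is not annotated count as unmapped.
    """
    histogram: Counter[int] = Counter()
    region_counts: Counter[str] = Counter()
    n_unmapped = 0
    n_mapped = 0
    for circ in circs:
        ann = annotation.get(circ.host_id) if circ.host_id else None
        if not circ.host_map or ann is None:
            n_unmapped += 1
            log.warning("first_exon_stats: %s unmapped", circ.id)
            continue
        first_idx = min(idx for idx, _ in circ.host_map)
        if not 1 <= first_idx <= len(ann.exons):
            n_unmapped += 1
            log.warning("first_exon_stats: %s exon index out of range", circ.id)
            continue
        n_mapped += 1
        histogram[first_idx] += 1
        span = (
            min(s for _, (s, _) in circ.host_map),
            max(e for _, (_, e) in circ.host_map),
        )
        region_counts[_region_category(span, ann)] += 1
    n = max(n_mapped, 1)
    fractions = {
        cat: region_counts.get(cat, 0) / n
        for cat in ("5UTR-CDS", "CDS", "CDS-3UTR", "other")
    }
    return FirstExonStats(dict(histogram), fractions, n_unmapped)
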