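"""Back-splice-junction peptide database and the sequential PSM filter cascade.

The junction lies between the last and the first base of the mature
circle.  For every reading frame a "junction protein" is translated
through the junction, bounded by stop codons or by one full circle per
side.  Tryptic digestion of these proteins yields candidate junction
peptides; only peptides that span the junction with at least two novel
residues on each side, length >= 8 and <= 3 missed cleavages enter the
search database.  Matches reported against that database are then
passed through the cascade in :func:`filter_psms`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .circorf import CircRNA, translate

log = logging.getLogger(__name__)

DEFAULT_Q_MAX = 0.01
DEFAULT_MIN_PEPTIDE_LEN = 8
DEFAULT_MIN_FLANK = 2
DEFAULT_MAX_MISSED = 3

#: modification name -> residues it may sit on; None means any residue but
#: the position must be the peptide N-terminus.
MOD_WHITELIST: dict[str, frozenset[str] | None] = {
    "Carbamidomethyl": frozenset("C"),
    "Oxidation": frozenset("M"),
    "Acetyl": None,  # protein/peptide N-term
    "Pyro-Glu": frozenset("Q"),  # N-terminal Q only
    "Phospho": frozenset("STY"),
}

_NTERM_ONLY = {"Acetyl", "Pyro-Glu"}


@dataclass
class JunctionProtein:
    circ_id: str
    frame: int
    sequence: str
    junction_pos: int  # index of the first residue whose codon spans/follows the junction


def _translate_through(seq: str, junction: int, frame: int) -> tuple[str, int]:
    """Translate through position ``junction`` of a linear string in ``frame``.

    The codon grid is anchored so that codon starts satisfy
    ``start % 3 == frame``.  Extension runs left and right until a stop
    codon or the end of ``seq``.  Returns the protein and the index of
    the residue whose codon contains ``junction`` (== len(protein) when
    that codon is a stop or falls off the right end).
    """
    j_codon = junction - ((junction - frame) % 3)
    # left boundary
    left = j_codon
    p = j_codon - 3
    while p >= 0:
        if seq[p : p + 3] in ("TAA", "TAG", "TGA"):
            break
        left = p
        p -= 3
    # right boundary (exclusive)
    right = j_codon
    p = j_codon
    while p + 3 <= len(seq):
        if seq[p : p + 3] in ("TAA", "TAG", "TGA"):
            break
        right = p + 3
        p += 3
    protein = translate(seq[left:right]) if right > left else ""
    junction_pos = (j_codon - left) // 3
    return protein, junction_pos


def junction_translations(circ: CircRNA | str, circ_id: str = "") -> list[JunctionProtein]:
    """The three frame translations through the back-splice junction.

    Each side is bounded by the first stop codon or by one full circle,
    whichever comes first, so the result is finite even for stop-free
    (rolling-circle) frames.
    """
    if isinstance(circ, CircRNA):
        seq, cid = circ.seq, circ.id
    else:
        seq, cid = circ, circ_id
    if set(seq) - set("ACGT"):
        raise ValueError("circle contains non-ACGT characters")
    L = len(seq)
    if L < 6:
        raise ValueError("circle must be at least 6 nt for junction translation")
    doubled = seq + seq
    out = []
    for frame in range(3):
        protein, junction_pos = _translate_through(doubled, L, frame)
        out.append(JunctionProtein(cid, frame, protein, junction_pos))
    return out


# ---------------------------------------------------------------------------
# digestion


@dataclass(frozen=True)
class TrypticPeptide:
    sequence: str
    start: int  # 0-based within the parent protein
    end: int
    missed_cleavages: int


def cleavage_sites(protein: str, suppress_proline: bool = True) -> list[int]:
    """Positions after which trypsin cuts (C-terminal to K/R, not before P)."""
    sites = []
    for i, ch in enumerate(protein[:-1]):
        if ch in "KR" and not (suppress_proline and protein[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def digest_trypsin(
    protein: str,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    suppress_proline: bool = True,
) -> list[TrypticPeptide]:
    """All tryptic peptides with <= max_missed internal cleavage sites.

    A peptide made of k+1 consecutive fully-cleaved fragments carries k
    missed cleavages.  Set ``min_len=1`` to obtain the unfiltered
    digest (the 0-missed peptides then concatenate back to the protein).
    """
    if not protein:
        raise ValueError("cannot digest an empty protein")
    bounds = [0] + cleavage_sites(protein, suppress_proline) + [len(protein)]
    peptides: list[TrypticPeptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for k in range(max_missed + 1):
            if i + k + 1 > n_frag:
                break
            start, end = bounds[i], bounds[i + k + 1]
            if end - start >= min_len:
                peptides.append(TrypticPeptide(protein[start:end], start, end, k))
    return peptides


# ---------------------------------------------------------------------------
# database


@dataclass
class JunctionPeptideRecord:
    sequence: str
    junction_offset: int  # residue index of the junction within the peptide
    left_flank_aa: int
    right_flank_aa: int
    missed_cleavages: int
    sources: list[tuple[str, int]]  # (circ_id, frame)


@dataclass
class JunctionDatabase:
    records: list[JunctionPeptideRecord]

    def __post_init__(self) -> None:
        self.by_sequence = {r.sequence: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def junction_index(self) -> dict[str, int]:
        return {r.sequence: r.junction_offset for r in self.records}


def _spanning_peptides(
    jp: JunctionProtein,
    min_len: int,
    max_missed: int,
    min_flank: int,
) -> list[JunctionPeptideRecord]:
    if not jp.sequence or jp.junction_pos >= len(jp.sequence):
        return []
    out = []
    for pep in digest_trypsin(jp.sequence, max_missed=max_missed, min_len=min_len):
        offset = jp.junction_pos - pep.start
        left = offset
        right = len(pep.sequence) - offset
        if left >= min_flank and right >= min_flank:
            out.append(
                JunctionPeptideRecord(
                    sequence=pep.sequence,
                    junction_offset=offset,
                    left_flank_aa=left,
                    right_flank_aa=right,
                    missed_cleavages=pep.missed_cleavages,
                    sources=[(jp.circ_id, jp.frame)],
                )
            )
    return out


def build_junction_db(
    circs: Sequence[CircRNA],
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> JunctionDatabase:
    """Union over circles and frames of junction-spanning tryptic peptides.

    Records are deduplicated by sequence; provenance of every copy is
    kept in ``sources``.
    """
    merged: dict[str, JunctionPeptideRecord] = {}
    for circ in circs:
        for jp in junction_translations(circ):
            for rec in _spanning_peptides(jp, min_len, max_missed, min_flank):
                if rec.sequence in merged:
                    merged[rec.sequence].sources.extend(rec.sources)
                else:
                    merged[rec.sequence] = rec
    return JunctionDatabase(list(merged.values()))


def write_junction_fasta(db: JunctionDatabase, path) -> None:
    with open(path, "w") as fh:
        for rec in db.records:
            cid, frame = rec.sources[0]
            fh.write(f">circ|{cid}|f{frame}|j{rec.junction_offset}\n{rec.sequence}\n")


def read_junction_fasta(path) -> JunctionDatabase:
    records = []
    header = None
    seq_lines: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        _, cid, frame_s, off_s = header.split("|")
        seq = "".join(seq_lines)
        offset = int(off_s[1:])
        records.append(
            JunctionPeptideRecord(
                sequence=seq,
                junction_offset=offset,
                left_flank_aa=offset,
                right_flank_aa=len(seq) - offset,
                missed_cleavages=len(cleavage_sites(seq)),
                sources=[(cid, int(frame_s[1:]))],
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                _flush()
                header = line[1:]
                seq_lines = []
            elif line:
                seq_lines.append(line)
        _flush()
    return JunctionDatabase(records)


# ---------------------------------------------------------------------------
# PSMs


@dataclass
class PSMRecord:
    spectrum_id: str
    peptide: str
    q_value: float
    modifications: list[tuple[int, str]] | None  # None => malformed string
    sample_id: str
    fragments: list[tuple[str, int]]  # (series 'b'|'y', ordinal)
    mod_error: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"{self.spectrum_id}: q-value outside [0, 1]")
        n = len(self.peptide)
        for series, ordinal in self.fragments:
            if series not in ("b", "y") or not 1 <= ordinal <= n - 1:
                raise ValueError(f"{self.spectrum_id}: bad fragment {series}{ordinal}")


def format_modifications(mods: list[tuple[int, str]]) -> str:
    return ";".join(f"{i}:{name}" for i, name in mods) if mods else "-"


def parse_modifications(text: str) -> list[tuple[int, str]]:
    if text in ("", "-"):
        return []
    mods = []
    for item in text.split(";"):
        pos_s, _, name = item.partition(":")
        if not name:
            raise ValueError(f"malformed modification: {item!r}")
        mods.append((int(pos_s), name))
    return mods


def format_fragments(fragments: list[tuple[str, int]]) -> str:
    return ";".join(f"{s}{o}" for s, o in fragments) if fragments else "-"


def parse_fragments(text: str) -> list[tuple[str, int]]:
    if text in ("", "-"):
        return []
    out = []
    for item in text.split(";"):
        out.append((item[0], int(item[1:])))
    return out


PSM_COLUMNS = ["spectrum_id", "peptide", "q_value", "modifications", "sample_id", "matched_ions"]


def write_psm_tsv(psms: Sequence[PSMRecord], path) -> None:
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "peptide": p.peptide,
            "q_value": p.q_value,
            "modifications": format_modifications(p.modifications or []),
            "sample_id": p.sample_id,
            "matched_ions": format_fragments(p.fragments),
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_psm_tsv(path) -> list[PSMRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    psms = []
    for row in df.itertuples(index=False):
        mods: list[tuple[int, str]] | None
        mod_error = None
        try:
            mods = parse_modifications(row.modifications)
        except ValueError as exc:
            mods, mod_error = None, str(exc)
        psms.append(
            PSMRecord(
                spectrum_id=row.spectrum_id,
                peptide=row.peptide,
                q_value=float(row.q_value),
                modifications=mods,
                sample_id=row.sample_id,
                fragments=parse_fragments(row.matched_ions),
                mod_error=mod_error,
            )
        )
    return psms


# ---------------------------------------------------------------------------
# filter cascade


@dataclass
class FilterReport:
    steps: list[tuple[str, int, int]]  # (name, records in, records out)

    def __post_init__(self) -> None:
        prev_out = None
        for name, n_in, n_out in self.steps:
            if n_out > n_in:
                raise ValueError(f"filter {name} increased record count")
            if prev_out is not None and n_in != prev_out:
                raise ValueError(f"filter {name} input does not chain")
            prev_out = n_out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "records_in", "records_out"])


def _fold_il(seq: str) -> str:
    return seq.replace("I", "L")


def check_modifications(
    peptide: str,
    mods: list[tuple[int, str]] | None,
    whitelist: Mapping[str, frozenset[str] | None] = MOD_WHITELIST,
) -> str | None:
    """None if acceptable, else a rejection reason."""
    if mods is None:
        return "malformed modification string"
    for pos, name in mods:
        if name not in whitelist:
            return f"modification not whitelisted: {name}"
        if not 0 <= pos < len(peptide):
            return f"modification position out of range: {pos}"
        if name in _NTERM_ONLY and pos != 0:
            return f"{name} only allowed at the N-terminus"
        allowed = whitelist[name]
        if allowed is not None and peptide[pos] not in allowed:
            return f"{name} not allowed on {peptide[pos]}"
    return None


def min_mismatch_ungapped(peptide: str, protein: str) -> int:
    """Minimal substitutions over any full-length ungapped placement of
    ``peptide`` inside ``protein`` (I and L are not folded here)."""
    lp = len(peptide)
    if lp == 0 or len(protein) < lp:
        return lp
    best = lp
    for off in range(len(protein) - lp + 1):
        mism = 0
        for x, y in zip(peptide, protein[off : off + lp]):
            if x != y:
                mism += 1
                if mism >= best:
                    break
        if mism < best:
            best = mism
            if best == 0:
                return 0
    return best


def filter_psms(
    psms: Sequence[PSMRecord],
    reference_proteome: Mapping[str, str] | Sequence[str],
    junction_index: Mapping[str, int] | JunctionDatabase,
    q_max: float = DEFAULT_Q_MAX,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    min_flank: int = DEFAULT_MIN_FLANK,
    max_missed: int = DEFAULT_MAX_MISSED,
    max_mismatch: int = 2,
    il_equivalent: bool = True,
    whitelist: Mapping[str, frozenset[str] | None] = MOD_WHITELIST,
) -> tuple[list[PSMRecord], FilterReport]:
    """Sequential PSM filters with per-step bookkeeping.

    Step 0 (thresholds): q < q_max, peptide length >= min_len, junction
    flanks >= min_flank on each side, <= max_missed missed cleavages,
    modifications within the whitelist.  Step 1 removes peptides that
    are exact substrings of the reference proteome; step 2 removes
    peptides within ``max_mismatch`` substitutions of any reference
    window; step 3 keeps only PSMs with at least one matched b/y ion
    whose fragmentation site lies strictly left of the junction and one
    strictly right.  I/L are treated as equivalent in steps 1-2 when
    ``il_equivalent`` is set.
    """
    if isinstance(junction_index, JunctionDatabase):
        junction_index = junction_index.junction_index()
    proteins = (
        list(reference_proteome.values())
        if isinstance(reference_proteome, Mapping)
        else list(reference_proteome)
    )
    fold = _fold_il if il_equivalent else (lambda s: s)
    folded_proteins = [fold(p) for p in proteins]
    reference_blob = "|".join(folded_proteins)

    steps: list[tuple[str, int, int]] = []

    # step 0: thresholds
    current: list[PSMRecord] = []
    n_in = len(psms)
    for p in psms:
        if not p.q_value < q_max:
            continue
        if len(p.peptide) < min_len:
            continue
        j = junction_index.get(p.peptide)
        if j is None:
            continue
        if j < min_flank or len(p.peptide) - j < min_flank:
            continue
        internal_missed = len(cleavage_sites(p.peptide))
        if internal_missed > max_missed:
            continue
        reason = check_modifications(p.peptide, p.modifications, whitelist)
        if reason is not None:
            log.info("filter_psms: %s rejected (%s)", p.spectrum_id, reason)
            continue
        current.append(p)
    steps.append(("thresholds", n_in, len(current)))

    # step 1: exact match to a known protein
    n_in = len(current)
    current = [p for p in current if fold(p.peptide) not in reference_blob]
    steps.append(("known_protein", n_in, len(current)))

    # step 2: homology to a known protein (<= max_mismatch substitutions)
    n_in = len(current)
    survivors = []
    for p in current:
        folded = fold(p.peptide)
        if any(
            min_mismatch_ungapped(folded, prot) <= max_mismatch
            for prot in folded_proteins
        ):
            continue
        survivors.append(p)
    current = survivors
    steps.append(("homology", n_in, len(current)))

    # step 3: fragment ions on both sides of the junction
    n_in = len(current)
    survivors = []
    for p in current:
        j = junction_index[p.peptide]
        n = len(p.peptide)
        sites = [
            ordinal if series == "b" else n - ordinal for series, ordinal in p.fragments
        ]
        if any(s < j for s in sites) and any(s > j for s in sites):
            survivors.append(p)
    current = survivors
    steps.append(("fragment_ions", n_in, len(current)))

    return current, FilterReport(steps)


# ---------------------------------------------------------------------------
# linear splice-junction controls


def linear_control_peptides(
    exon_seqs: Sequence[str],
    circ_first_exon: int,
    circ_last_exon: int,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> list[JunctionPeptideRecord]:
    """Peptides spanning the linear splice junctions adjacent to a circle.

    ``exon_seqs`` is the ordered exon sequence list of the host
    transcript and the circle covers exons ``circ_first_exon`` ..
    ``circ_last_exon`` (1-based, inclusive).  The 5' control junction is
    the boundary into the first circle exon; the 3' control the boundary
    out of the last.  Sides without an adjacent exon are skipped.
    """
    n_exons = len(exon_seqs)
    if not 1 <= circ_first_exon <= circ_last_exon <= n_exons:
        raise ValueError("circle exon range outside the transcript")
    transcript = "".join(exon_seqs)
    cumulative = [0]
    for e in exon_seqs:
        cumulative.append(cumulative[-1] + len(e))
    junctions: list[tuple[str, int]] = []
    if circ_first_exon > 1:
        junctions.append(("5prime", cumulative[circ_first_exon - 1]))
    else:
        log.warning("linear_control_peptides: no upstream exon; 5' side skipped")
    if circ_last_exon < n_exons:
        junctions.append(("3prime", cumulative[circ_last_exon]))
    else:
        log.warning("linear_control_peptides: no downstream exon; 3' side skipped")
    out: list[JunctionPeptideRecord] = []
    for side, pos in junctions:
        for frame in range(3):
            if pos - ((pos - frame) % 3) < 0:
                continue
            protein, junction_pos = _translate_through(transcript, pos, frame)
            jp = JunctionProtein(f"linear_{side}", frame, protein, junction_pos)
            out.extend(_spanning_peptides(jp, min_len, max_missed, min_flank))
    return out


# ---------------------------------------------------------------------------
# summaries


def junction_residue_stats(
    junction_proteins: Iterable[JunctionProtein],
) -> tuple[float, float]:
    """(fraction with K/R immediately left of the junction, fraction with
    any K/R at all), over proteins whose junction is interior."""
    n = 0
    kr_minus1 = 0
    kr_any = 0
    for jp in junction_proteins:
        if jp.junction_pos < 1 or jp.junction_pos >= len(jp.sequence):
            log.warning("junction_residue_stats: %s junction at boundary; skipped", jp.circ_id)
            continue
        n += 1
        if jp.sequence[jp.junction_pos - 1] in "KR":
            kr_minus1 += 1
        if any(ch in "KR" for ch in jp.sequence):
            kr_any += 1
    if n == 0:
        return float("nan"), float("nan")
    return kr_minus1 / n, kr_any / n


def spectra_summaries(
    psms: Sequence[PSMRecord], db: JunctionDatabase
) -> pd.DataFrame:
    """Per-junction spectra and distinct-sample counts for surviving PSMs."""
    rows: dict[str, dict] = {}
    for p in psms:
        rec = db.by_sequence.get(p.peptide)
        if rec is None:
            continue
        cid, frame = rec.sources[0]
        key = f"{cid}|f{frame}"
        entry = rows.setdefault(key, {"junction": key, "spectra": 0, "samples": set()})
        entry["spectra"] += 1
        entry["samples"].add(p.sample_id)
    table = [
        {"junction": e["junction"], "spectra": e["spectra"], "samples": len(e["samples"])}
        for e in rows.values()
    ]
    return pd.DataFrame(table, columns=["junction", "spectra", "samples"]).sort_values(
        "junction", ignore_index=True
    )
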