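"""Ground-truthed synthetic inputs for every pipeline stage.

All generators are pure functions of (config, seed): the same seed
reproduces byte-identical output files.  The screen simulator uses a
two-probability Bernoulli sorter (an insert whose vector-extended
14-mer contains a planted hexamer sorts into the green fractions with
``p_active``, otherwise with ``p_background``), which is the minimal
structure that makes the enrichment z statistic informative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .circorf import CircRNA, STOP_CODONS
from .junction import (
    JunctionDatabase,
    PSMRecord,
    cleavage_sites,
    min_mismatch_ungapped,
    _fold_il,
)
from .screen import BASES, DEFAULT_VECTOR, VectorContext

FRACTIONS = ("negative", "low", "medium", "high")
GREEN_FRACTIONS = ("medium", "high")

# five planted hexamers sharing shift-space (consecutive hexamers of one
# decamer) so near-duplicate shifted variants largely coincide with the
# planted set itself
DEFAULT_PLANTED = ("ATTACA", "TTACAG", "TACAGT", "ACAGTC", "CAGTCA")

_NON_STOP_CODONS = sorted(
    {a + b + c for a in BASES for b in BASES for c in BASES} - set(STOP_CODONS)
)

# a 12-nt tile with stop codons in all three frames and no NTG start
_NO_ORF_TILE = "ATAAATAAATAA"


# ---------------------------------------------------------------------------
# screen


@dataclass
class ScreenSimConfig:
    n_inserts: int = 200_000
    planted_hexamers: tuple[str, ...] = DEFAULT_PLANTED
    p_active: float = 0.8
    p_background: float = 0.02
    reads_per_fraction: int = 8_000
    vector: VectorContext = field(default_factory=lambda: DEFAULT_VECTOR)
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_background < self.p_active <= 1.0:
            raise ValueError("need 0 <= p_background < p_active <= 1")


@dataclass
class ScreenTruth:
    planted_hexamers: tuple[str, ...]
    inserts: list[str]
    active: np.ndarray  # bool per insert


@dataclass
class ScreenSim:
    reads: dict[str, list[str]]  # fraction label -> reads
    truth: ScreenTruth

    def green_reads(self) -> list[str]:
        return [r for f in GREEN_FRACTIONS for r in self.reads[f]]

    def dark_reads(self) -> list[str]:
        return list(self.reads["negative"])


def simulate_screen(cfg: ScreenSimConfig) -> ScreenSim:
    rng = np.random.default_rng(cfg.seed)
    chars = np.array(list(BASES))
    ints = rng.integers(0, 4, size=(cfg.n_inserts, 10))
    inserts = ["".join(row) for row in chars[ints]]
    ext_l, ext_r = cfg.vector.extension_left, cfg.vector.extension_right
    planted = tuple(cfg.planted_hexamers)
    active = np.array(
        [any(p in (ext_l + ins + ext_r) for p in planted) for ins in inserts]
    )
    w_green = np.where(active, cfg.p_active, cfg.p_background)
    w_dark = 1.0 - w_green
    up, down = cfg.vector.upstream_flank, cfg.vector.downstream_flank
    reads: dict[str, list[str]] = {}
    for fraction in FRACTIONS:
        w = w_green if fraction in GREEN_FRACTIONS else w_dark
        idx = rng.choice(cfg.n_inserts, size=cfg.reads_per_fraction, p=w / w.sum())
        fraction_reads = [up + inserts[i] + down for i in idx]
        if cfg.error_rate > 0:
            fraction_reads = _add_noise(fraction_reads, cfg.error_rate, rng)
        reads[fraction] = fraction_reads
    return ScreenSim(reads=reads, truth=ScreenTruth(planted, inserts, active))


def _add_noise(reads: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    out = []
    for read in reads:
        arr = np.array(list(read))
        mask = rng.random(arr.size) < rate
        if mask.any():
            arr[mask] = np.array(list(BASES))[rng.integers(0, 4, int(mask.sum()))]
        out.append("".join(arr))
    return out


def write_fastq(reads: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")


def read_fastq(path) -> list[str]:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                reads.append(line.strip())
    return reads


def write_screen_sim(sim: ScreenSim, outdir) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for fraction, fraction_reads in sim.reads.items():
        p = outdir / f"{fraction}.fastq"
        write_fastq(fraction_reads, p)
        paths[fraction] = str(p)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "planted_hexamers": list(sim.truth.planted_hexamers),
                "n_inserts": len(sim.truth.inserts),
                "n_active": int(sim.truth.active.sum()),
            },
            fh,
            indent=1,
        )
    return paths


# ---------------------------------------------------------------------------
# circRNAs


@dataclass
class CircSimPlan:
    n_corf: int = 10
    n_rcorf: int = 10
    n_noorf: int = 10
    corf_aa: int = 25  # planted peptide length, start codon included
    circle_codons: int = 60  # circle length in codons for ORF-planted circles
    seed: int = 0


@dataclass
class PlantedOrf:
    circ_id: str
    start_offset: int
    type: str  # cORF | rcORF | none
    length_aa: float
    peptide: str


@dataclass
class CircSim:
    circs: list[CircRNA]
    host_proteins: dict[str, str]
    truth: list[PlantedOrf]


def _random_codons(n: int, rng: np.random.Generator) -> str:
    return "".join(
        _NON_STOP_CODONS[i] for i in rng.integers(0, len(_NON_STOP_CODONS), n)
    )


def _translate_codons(s: str) -> str:
    from .circorf import translate

    return translate(s)


def simulate_circrnas(plan: CircSimPlan) -> CircSim:
    """Circles with planted cORFs, stop-free rcORF frames, and ORF-free tiles.

    Planted circles are built on a codon grid and then rotated by a
    random offset; rotation moves the start but preserves the circular
    reading, so the truth records the post-rotation start offset.
    """
    rng = np.random.default_rng(plan.seed)
    if plan.corf_aa + 1 > plan.circle_codons:
        raise ValueError("planted ORF does not fit in the circle")
    circs: list[CircRNA] = []
    hosts: dict[str, str] = {}
    truth: list[PlantedOrf] = []
    L = plan.circle_codons * 3
    for i in range(plan.n_corf):
        cid = f"corf{i}"
        body = _random_codons(plan.corf_aa - 1, rng)
        pad = _random_codons(plan.circle_codons - plan.corf_aa - 1, rng)
        seq = "ATG" + body + "TAA" + pad
        rot = int(rng.integers(0, L))
        seq = seq[rot:] + seq[:rot]
        start = (L - rot) % L
        peptide = "M" + _translate_codons(body)
        host_id = f"host_{cid}"
        hosts[host_id] = (
            _aa_string(10, rng) + peptide + _aa_string(10, rng)
        )
        circs.append(CircRNA(id=cid, seq=seq, host_id=host_id))
        truth.append(PlantedOrf(cid, start, "cORF", float(plan.corf_aa), peptide))
    for i in range(plan.n_rcorf):
        cid = f"rcorf{i}"
        seq = "ATG" + _random_codons(plan.circle_codons - 1, rng)
        rot = int(rng.integers(0, L))
        seq_r = seq[rot:] + seq[:rot]
        start = (L - rot) % L
        peptide = _translate_codons(seq)
        host_id = f"host_{cid}"
        hosts[host_id] = _aa_string(10, rng) + peptide[:15] + _aa_string(10, rng)
        circs.append(CircRNA(id=cid, seq=seq_r, host_id=host_id))
        truth.append(PlantedOrf(cid, start, "rcORF", float("inf"), peptide))
    for i in range(plan.n_noorf):
        cid = f"noorf{i}"
        n_tiles = max(plan.circle_codons * 3 // len(_NO_ORF_TILE), 2)
        seq = _NO_ORF_TILE * n_tiles
        rot = int(rng.integers(0, len(seq)))
        circs.append(CircRNA(id=cid, seq=seq[rot:] + seq[:rot]))
        truth.append(PlantedOrf(cid, -1, "none", 0.0, ""))
    return CircSim(circs=circs, host_proteins=hosts, truth=truth)


_AA_ALPHABET = "ACDEFGHLMNQSTVWY"  # no I (I/L folding), no K/R (cleavage), no P


def _aa_string(n: int, rng: np.random.Generator) -> str:
    return "".join(_AA_ALPHABET[i] for i in rng.integers(0, len(_AA_ALPHABET), n))


def write_circ_sim(sim: CircSim, outdir) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "circs.fa"
    with open(fasta, "w") as fh:
        for c in sim.circs:
            host = f" host={c.host_id}" if c.host_id else ""
            fh.write(f">{c.id}{host}\n{c.seq}\n")
    hosts = outdir / "host_proteins.fa"
    with open(hosts, "w") as fh:
        for hid, prot in sim.host_proteins.items():
            fh.write(f">{hid}\n{prot}\n")
    bed = outdir / "circs.bed"
    with open(bed, "w") as fh:
        pos = 0
        for c in sim.circs:
            fh.write(f"chrS\t{pos}\t{pos + len(c.seq)}\t{c.id}\t0\t+\n")
            pos += len(c.seq) + 100
    with open(outdir / "truth.json", "w") as fh:
        json.dump([asdict(t) for t in sim.truth], fh, indent=1, default=str)
    return {"fasta": str(fasta), "hosts": str(hosts), "bed": str(bed)}


# ---------------------------------------------------------------------------
# PSMs


VIOLATOR_KINDS = (
    "q",  # fails the q-value threshold
    "length",  # peptide shorter than 8
    "flank",  # fewer than 2 residues on one side of the junction
    "missed",  # more than 3 missed cleavages
    "modification",  # modification outside the whitelist
    "ref_exact",  # exact substring of the reference proteome
    "ref_2mm",  # within 2 substitutions of a reference window
    "ions",  # fragment ions on one side of the junction only
)

_EXPECTED_STEP = {
    "q": "thresholds",
    "length": "thresholds",
    "flank": "thresholds",
    "missed": "thresholds",
    "modification": "thresholds",
    "ref_exact": "known_protein",
    "ref_2mm": "homology",
    "ions": "fragment_ions",
}


@dataclass
class PsmSimPlan:
    n_true: int = 10
    violators: tuple[str, ...] = VIOLATOR_KINDS
    samples: tuple[str, ...] = ("tissue1", "tissue2", "cellA")
    max_spectra_per_peptide: int = 3
    seed: int = 0


@dataclass
class PsmSim:
    psms: list[PSMRecord]
    junction_index: dict[str, int]
    truth: dict[str, str]  # spectrum_id -> "retained" | removing filter step


def _both_side_ions(n: int, j: int) -> list[tuple[str, int]]:
    # b ordinal k fragments at site k; y ordinal k at site n-k
    return [("b", j - 1), ("y", n - j - 1)]


def _clean_vs_reference(peptide: str, folded_refs: Sequence[str]) -> bool:
    folded = _fold_il(peptide)
    return all(min_mismatch_ungapped(folded, ref) > 2 for ref in folded_refs)


def simulate_psms(
    db: JunctionDatabase,
    reference_proteome: Mapping[str, str],
    plan: PsmSimPlan,
) -> PsmSim:
    """True junction PSMs plus one planted violator per requested kind.

    Every violator is constructed to fail exactly one cascade step; the
    truth maps each spectrum id to "retained" or to the step expected to
    remove it.  Fabricated peptides receive entries in the returned
    junction index so the cascade can resolve their junction offsets.
    """
    if not db.records:
        raise ValueError("empty junction database")
    rng = np.random.default_rng(plan.seed)
    folded_refs = [_fold_il(p) for p in reference_proteome.values()]
    ref_blob = "|".join(folded_refs)
    index = db.junction_index()
    psms: list[PSMRecord] = []
    truth: dict[str, str] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"spec{counter:04d}"

    def sample_id() -> str:
        return plan.samples[int(rng.integers(0, len(plan.samples)))]

    # true PSMs over randomly chosen database records
    usable = [
        r
        for r in db.records
        if len(cleavage_sites(r.sequence)) <= 3
        and _clean_vs_reference(r.sequence, folded_refs)
    ]
    if not usable:
        raise ValueError("no database record usable as a clean true PSM")
    order = rng.permutation(len(usable))
    for k in range(plan.n_true):
        rec = usable[order[k % len(usable)]]
        n, j = len(rec.sequence), rec.junction_offset
        n_spectra = int(rng.integers(1, plan.max_spectra_per_peptide + 1))
        for _ in range(n_spectra):
            sid = next_id()
            psms.append(
                PSMRecord(
                    spectrum_id=sid,
                    peptide=rec.sequence,
                    q_value=float(rng.uniform(0, 0.009)),
                    modifications=_maybe_oxidation(rec.sequence, rng),
                    sample_id=sample_id(),
                    fragments=_both_side_ions(n, j),
                )
            )
            truth[sid] = "retained"

    def fabricate(length: int, offset: int, max_tries: int = 200) -> str:
        for _ in range(max_tries):
            pep = _aa_string(length, rng)
            if (
                pep not in index
                and _fold_il(pep) not in ref_blob
                and _clean_vs_reference(pep, folded_refs)
            ):
                index[pep] = offset
                return pep
        raise RuntimeError("could not fabricate a clean peptide")

    for kind in plan.violators:
        sid = next_id()
        q = float(rng.uniform(0, 0.009))
        mods: list[tuple[int, str]] = []
        if kind == "q":
            pep = fabricate(10, 5)
            frags = _both_side_ions(10, 5)
            q = 0.05
        elif kind == "length":
            pep = fabricate(7, 3)
            frags = _both_side_ions(7, 3)
        elif kind == "flank":
            pep = fabricate(10, 1)
            frags = [("y", 4)]
        elif kind == "missed":
            core = _aa_string(5, rng)
            pep = "AKAKAKAK" + core[:2]
            if pep in index or not _clean_vs_reference(pep, folded_refs):
                pep = "AKAKAKAK" + _aa_string(2, rng)
            index[pep] = 5
            frags = _both_side_ions(len(pep), 5)
        elif kind == "modification":
            pep = fabricate(10, 5)
            mods = [(2, "TMT")]
            frags = _both_side_ions(10, 5)
        elif kind == "ref_exact":
            pep = _reference_window(reference_proteome, rng, mutate=0)
            index.setdefault(pep, 5)
            frags = _both_side_ions(len(pep), index[pep])
        elif kind == "ref_2mm":
            pep = _reference_window(reference_proteome, rng, mutate=2, ref_blob=ref_blob)
            index.setdefault(pep, 5)
            frags = _both_side_ions(len(pep), index[pep])
        elif kind == "ions":
            pep = fabricate(10, 5)
            frags = [("b", 2), ("b", 4)]  # sites 2 and 4, both < junction at 5
        else:
            raise ValueError(f"unknown violator kind: {kind}")
        psms.append(
            PSMRecord(
                spectrum_id=sid,
                peptide=pep,
                q_value=q,
                modifications=mods,
                sample_id=sample_id(),
                fragments=frags,
            )
        )
        truth[sid] = _EXPECTED_STEP[kind]
    return PsmSim(psms=psms, junction_index=index, truth=truth)


def _maybe_oxidation(
    peptide: str, rng: np.random.Generator
) -> list[tuple[int, str]]:
    if "M" in peptide and rng.random() < 0.5:
        return [(peptide.index("M"), "Oxidation")]
    return []


def _reference_window(
    reference: Mapping[str, str],
    rng: np.random.Generator,
    mutate: int,
    length: int = 10,
    ref_blob: str = "",
    max_tries: int = 500,
) -> str:
    proteins = list(reference.values())
    for _ in range(max_tries):
        prot = proteins[int(rng.integers(0, len(proteins)))]
        if len(prot) < length:
            continue
        start = int(rng.integers(0, len(prot) - length + 1))
        window = list(prot[start : start + length])
        if len(cleavage_sites("".join(window))) > 3:
            continue
        if mutate:
            positions = rng.choice(length, size=mutate, replace=False)
            for pos in positions:
                current = window[pos]
                options = [a for a in _AA_ALPHABET if a != current]
                window[pos] = options[int(rng.integers(0, len(options)))]
        candidate = "".join(window)
        if mutate and _fold_il(candidate) in ref_blob:
            continue  # accidental exact hit elsewhere; retry
        return candidate
    raise RuntimeError("could not draw a reference window")


def simulate_reference_proteome(
    n_proteins: int = 20, length: int = 200, seed: int = 0
) -> dict[str, str]:
    """A toy reference proteome of random tryptic-looking proteins."""
    rng = np.random.default_rng(seed)
    proteins = {}
    for i in range(n_proteins):
        chunks = []
        remaining = length
        while remaining > 0:
            k = int(rng.integers(5, 12))
            chunks.append(_aa_string(min(k, remaining) - 1, rng) + "K")
            remaining -= k
        proteins[f"ref{i}"] = "".join(chunks)[:length]
    return proteins


def write_psm_sim(sim: PsmSim, outdir) -> dict[str, str]:
    from .junction import write_psm_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / "psms.tsv"
    write_psm_tsv(sim.psms, tsv)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(sim.truth, fh, indent=1)
    with open(outdir / "junction_index.json", "w") as fh:
        json.dump(sim.junction_index, fh, indent=1)
    return {"psms": str(tsv)}
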