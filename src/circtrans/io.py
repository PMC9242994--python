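"""Small format helpers shared by the CLI and the pipeline."""

from __future__ import annotations

from typing import Mapping

from Bio import SeqIO


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {first header token: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def read_hexamer_set(path) -> set[str]:
    """One hexamer per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip().upper()
            if line and not line.startswith("#"):
                out.add(line)
    return out
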