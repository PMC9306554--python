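"""Thin FASTA/TSV I/O wrappers shared by the pipeline stages."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to an ordered {id: sequence} dict; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def write_fasta(path: str | Path, seqs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
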