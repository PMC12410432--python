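"""Thin FASTA helpers shared across modules."""

from __future__ import annotations

from Bio import SeqIO

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path) -> dict[str, str]:
    """FASTA records as an id -> uppercase sequence dict (ids must be unique)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
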