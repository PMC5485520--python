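"""Shared sequence helpers: complementing, encoding, FASTA/FASTQ round-trips.

All sequences are handled in the DNA alphabet (U is normalized to T on
input); reverse complements and pairing rules therefore use A-T / C-G,
with G-T standing in for the G·U wobble where folding allows it.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: byte codes used by the numeric encoders below
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_RC)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and convert U to T so RNA references compare against DNA tags."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Report a DNA sequence in the RNA alphabet (T shown as U)."""
    return seq.upper().replace("T", "U")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 vector (A=0, C=1, G=2, T=3, N=4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, _CODE["N"], dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    g = seq.count("G") + seq.count("g") + seq.count("C") + seq.count("c")
    return g / len(seq)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence} with U normalized to T."""
    return {rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records, path) -> None:
    """Write an iterable of (id, sequence) pairs as FASTA."""
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fastq_seqs(path) -> list[str]:
    """Sequences only from a FASTQ file (qualities are not used downstream)."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads, path, prefix: str = "read", quality: int = 40) -> None:
    """Write read sequences as Sanger-encoded FASTQ with uniform quality."""
    records = []
    for i, seq in enumerate(reads):
        rec = SeqRecord(Seq(seq), id=f"{prefix}_{i + 1}", description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
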