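"""Synthetic small-RNA study generator.

Emulates a two-condition (salt vs. control), two-replicate small-RNA
sequencing experiment: a random background genome with planted pre-miRNA
hairpins, negative-binomial read counts with condition-specific fold
changes, contaminating ncRNA fragments, and 3' adapter-bearing reads.
Everything is driven by a single integer seed so downstream stages can be
tested against exact truth.

The planted precursor is a perfect inverted repeat::

    5' [arm5 .. mature ..][loop][.. revcomp(arm5) ..] 3'

with the mature sequence lying entirely on one arm, so the precursor
folds into a stem-loop that satisfies the discovery module's hairpin
criteria by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqtools import revcomp, write_fasta, write_fastq

BASES = np.array(list("ACGT"))

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

NCRNA_CATEGORIES = ("rRNA", "tRNA", "snoRNA", "other_ncRNA")
#: sampling weights for contaminant fragments, roughly rRNA-dominated as
#: in real plant sRNA libraries
NCRNA_WEIGHTS = (0.6, 0.25, 0.1, 0.05)


@dataclass(frozen=True)
class MiRNATruth:
    """One planted miRNA: mature/star sequences and the precursor locus."""

    id: str
    mature_seq: str
    star_seq: str
    precursor_interval: tuple[str, int, int, str]  # chrom, start, end (0-based half-open), strand
    is_conserved: bool = False
    family: str | None = None


@dataclass
class TruthSet:
    """Planted miRNAs plus their simulated abundance model."""

    genome_id: str
    mirnas: list[MiRNATruth]
    fold_changes: dict[str, float]
    base_abundance: dict[str, float]

    def __post_init__(self) -> None:
        if any(fc <= 0 for fc in self.fold_changes.values()):
            raise ValueError("fold changes must be strictly positive")
        ivals = sorted(m.precursor_interval[1:3] for m in self.mirnas)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("precursor intervals must be disjoint")

    @property
    def ids(self) -> list[str]:
        return sorted(self.base_abundance)


@dataclass(frozen=True)
class SimDesign:
    """Shape and noise model of the simulated sequencing experiment."""

    n_replicates: int = 2
    library_depth: int = 100_000
    nb_dispersion: float = 0.1
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = ""
    contaminant_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must lie in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per condition")

    @property
    def libraries(self) -> list[str]:
        """Salt libraries first, then controls (S1, S2, ..., Ck1, Ck2, ...)."""
        salt = [f"S{i + 1}" for i in range(self.n_replicates)]
        ctrl = [f"Ck{i + 1}" for i in range(self.n_replicates)]
        return salt + ctrl

    def condition(self, library: str) -> str:
        return "salt" if library.startswith("S") else "control"


def generate_genome(length: int, gc: float = 0.45, seed: int = 0) -> str:
    """Random background genome with the requested GC content."""
    if length < 1000:
        raise ValueError("genome length must be at least 1000")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _draw_hairpin_shape(
    rng: np.random.Generator,
    stem_len: tuple[int, int],
    loop_len: tuple[int, int],
    mature_len: tuple[int, int],
    min_hairpin_len: int,
) -> tuple[int, int, int]:
    """Sample (stem, loop, mature) with stem >= mature and total >= min length.

    Rejection-sampled so that every planted precursor is long enough to
    pass the default hairpin-length criterion; if the ranges cannot reach
    the minimum, the longest achievable shape is used.
    """
    m = int(rng.integers(mature_len[0], mature_len[1] + 1))
    s_lo = max(stem_len[0], m)
    s_hi = max(stem_len[1], s_lo)
    feasible = 2 * s_hi + loop_len[1] >= min_hairpin_len
    for _ in range(200):
        s = int(rng.integers(s_lo, s_hi + 1))
        loop = int(rng.integers(loop_len[0], loop_len[1] + 1))
        if not feasible or 2 * s + loop >= min_hairpin_len:
            return s, loop, min(m, s)
    return s_hi, loop_len[1], min(m, s_hi)


def plant_hairpins(
    genome: str,
    n: int,
    stem_len: tuple[int, int] = (18, 25),
    loop_len: tuple[int, int] = (4, 15),
    mature_len: tuple[int, int] = (20, 22),
    seed: int = 0,
    genome_id: str = "chr1",
    n_conserved: int = 0,
    min_hairpin_len: int = 62,
    min_separation: int = 700,
) -> tuple[str, TruthSet]:
    """Insert ``n`` disjoint stem-loop precursors into ``genome``.

    Precursors are placed at least ``min_separation`` bp apart (so their
    read clusters never merge under the 200 bp locus rule) and on either
    strand with probability 1/2. Returns the modified genome and the truth
    set; fold changes are initialized to 1 and base abundances drawn
    log-normally (callers assign condition effects afterwards).
    """
    if n < 1:
        raise ValueError("must plant at least one hairpin")
    rng = np.random.default_rng(seed)
    max_prec = 2 * max(stem_len[1], mature_len[1]) + loop_len[1]
    margin = 250  # keep the ±200 nt flank extraction unclipped
    n_slots = (len(genome) - 2 * margin - max_prec) // min_separation + 1
    if len(genome) < 2 * margin + max_prec or n_slots < n:
        raise ValueError(
            f"genome of {len(genome)} bases cannot hold {n} disjoint precursors"
        )
    slots = np.sort(rng.choice(n_slots, size=n, replace=False))

    out = list(genome.upper())
    mirnas: list[MiRNATruth] = []
    abundance: dict[str, float] = {}
    folds: dict[str, float] = {}
    for i, slot in enumerate(slots):
        s, loop, m = _draw_hairpin_shape(rng, stem_len, loop_len, mature_len, min_hairpin_len)
        arm5 = _random_seq(rng, s)
        loop_seq = _random_seq(rng, loop)
        precursor = arm5 + loop_seq + revcomp(arm5)
        on_5p = bool(rng.random() < 0.5)
        off = int(rng.integers(0, s - m + 1))
        if on_5p:
            mature = arm5[off : off + m]
            star = revcomp(mature)
        else:
            arm3 = revcomp(arm5)
            mature = arm3[off : off + m]
            star = revcomp(mature)
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = precursor if strand == "+" else revcomp(precursor)
        start = margin + int(slot) * min_separation + int(rng.integers(0, 100))
        end = start + len(precursor)
        out[start:end] = list(inserted)
        conserved = i < n_conserved
        name = f"planted-{i + 1}"
        mirnas.append(
            MiRNATruth(
                id=name,
                mature_seq=mature,
                star_seq=star,
                precursor_interval=(genome_id, start, end, strand),
                is_conserved=conserved,
                family=f"miR{160 + i}" if conserved else None,
            )
        )
        abundance[name] = float(np.exp(rng.normal(0.0, 1.0)))
        folds[name] = 1.0
    truth = TruthSet(genome_id=genome_id, mirnas=mirnas, fold_changes=folds, base_abundance=abundance)
    return "".join(out), truth


def assign_fold_changes(
    truth: TruthSet, n_up: int, n_down: int, fold: float = 8.0, seed: int = 0
) -> TruthSet:
    """Mark the first ``n_up`` miRNAs as salt-induced (x fold) and the next
    ``n_down`` as repressed (x 1/fold); order randomized by ``seed``."""
    rng = np.random.default_rng(seed)
    ids = list(truth.base_abundance)
    rng.shuffle(ids)
    folds = dict(truth.fold_changes)
    for name in ids[:n_up]:
        folds[name] = float(fold)
    for name in ids[n_up : n_up + n_down]:
        folds[name] = 1.0 / float(fold)
    return dataclasses.replace(truth, fold_changes=folds)


def make_count_truth(
    n: int, seed: int = 0, fold: float = 1.0, n_affected: int = 0, prefix: str = "mir"
) -> TruthSet:
    """Abundance-only truth set (no genome) for count-model simulations."""
    rng = np.random.default_rng(seed)
    ids = [f"{prefix}-{i + 1}" for i in range(n)]
    abundance = {name: float(np.exp(rng.normal(0.0, 1.0))) for name in ids}
    folds = {name: (float(fold) if i < n_affected else 1.0) for i, name in enumerate(ids)}
    return TruthSet(genome_id="none", mirnas=[], fold_changes=folds, base_abundance=abundance)


def simulate_counts(truth: TruthSet, design: SimDesign) -> pd.DataFrame:
    """miRNA x library matrix of negative-binomial counts.

    Per-library expected counts are proportional to base abundance times
    the fold change in salt libraries, scaled so each column's expectation
    equals the miRNA share of the library depth. ``nb_dispersion`` is the
    NB dispersion phi (variance = mu + phi mu^2); 0 degenerates to Poisson.
    """
    rng = np.random.default_rng(design.seed)
    ids = truth.ids
    base = np.array([truth.base_abundance[i] for i in ids], dtype=float)
    fold = np.array([truth.fold_changes.get(i, 1.0) for i in ids], dtype=float)
    if np.any(fold <= 0):
        raise ValueError("fold changes must be strictly positive")
    mirna_reads = design.library_depth * (1.0 - design.contaminant_fraction)
    cols = {}
    for lib in design.libraries:
        w = base * fold if design.condition(lib) == "salt" else base
        mu = mirna_reads * w / w.sum()
        if design.nb_dispersion > 0:
            k = 1.0 / design.nb_dispersion
            p = k / (k + mu)
            cols[lib] = rng.negative_binomial(k, p)
        else:
            cols[lib] = rng.poisson(mu)
    return pd.DataFrame(cols, index=ids, dtype=int)


def make_ncrna_references(seed: int = 0, n_per_class: int = 3, length: int = 400) -> dict[str, dict[str, str]]:
    """Synthetic ncRNA reference sets, one FASTA-shaped dict per category."""
    rng = np.random.default_rng(seed)
    refs: dict[str, dict[str, str]] = {}
    for cat in NCRNA_CATEGORIES:
        refs[cat] = {
            f"{cat}_{j + 1}": _random_seq(rng, length) for j in range(n_per_class)
        }
    return refs


def synthesize_reads(
    counts: pd.DataFrame,
    truth: TruthSet,
    design: SimDesign,
    ncrna_refs: dict[str, dict[str, str]] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, list[str]]:
    """Expand the count matrix into per-library reads (optionally FASTQ files).

    Each miRNA read is its mature sequence plus the 3' adapter when one is
    configured. Contaminants are random 18–28 nt fragments of the ncRNA
    references, added so they make up ``contaminant_fraction`` of each
    library. Read order is shuffled deterministically.
    """
    if not truth.mirnas and not counts.index.size:
        raise ValueError("empty truth set: nothing to synthesize")
    mature = {m.id: m.mature_seq for m in truth.mirnas}
    missing = [i for i in counts.index if i not in mature]
    if missing:
        raise ValueError(f"counts refer to miRNAs absent from the truth set: {missing[:3]}")
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(design.seed + 1)
    reads_by_lib: dict[str, list[str]] = {}
    for lib in counts.columns:
        reads: list[str] = []
        for mid, c in counts[lib].items():
            reads.extend([mature[mid]] * int(c))
        n_mirna = len(reads)
        cf = design.contaminant_fraction
        if cf > 0 and ncrna_refs:
            n_contam = int(round(n_mirna * cf / (1.0 - cf)))
            cats = rng.choice(len(NCRNA_CATEGORIES), size=n_contam, p=np.array(NCRNA_WEIGHTS))
            for ci in cats:
                refs = ncrna_refs[NCRNA_CATEGORIES[int(ci)]]
                ref = list(refs.values())[int(rng.integers(0, len(refs)))]
                flen = int(rng.integers(18, 29))
                pos = int(rng.integers(0, len(ref) - flen + 1))
                reads.append(ref[pos : pos + flen])
        if design.adapter3:
            reads = [r + design.adapter3 for r in reads]
        order = rng.permutation(len(reads))
        reads_by_lib[lib] = [reads[i] for i in order]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for lib, reads in reads_by_lib.items():
            write_fastq(reads, out_dir / f"{lib}.fastq", prefix=lib)
    return reads_by_lib


def write_truth(truth: TruthSet, out_dir: str | Path) -> None:
    """Export the truth set as TSV plus GFF3 (1-based inclusive coordinates)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in truth.mirnas:
        chrom, start, end, strand = m.precursor_interval
        rows.append(
            {
                "id": m.id,
                "mature_seq": m.mature_seq,
                "star_seq": m.star_seq,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "is_conserved": m.is_conserved,
                "family": m.family or "",
                "base_abundance": truth.base_abundance.get(m.id, float("nan")),
                "fold_change": truth.fold_changes.get(m.id, 1.0),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    with open(out_dir / "truth.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for m in truth.mirnas:
            chrom, start, end, strand = m.precursor_interval
            fh.write(
                f"{chrom}\temmir_sim\tmiRNA_primary_transcript\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f"ID={m.id};mature={m.mature_seq}\n"
            )


def write_mature_reference(truth: TruthSet, path: str | Path, species: str = "tae") -> int:
    """miRBase-style mature FASTA for the conserved subset (RNA alphabet)."""
    records = []
    for m in truth.mirnas:
        if m.is_conserved and m.family:
            records.append((f"{species}-{m.family}", m.mature_seq.replace("T", "U")))
    write_fasta(records, path)
    return len(records)
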