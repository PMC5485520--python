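"""miRNA discovery: conserved assignment and novel hairpin prediction.

The novel-prediction chain mirrors the classic plant small-RNA recipe:

1. candidate tag hits within 200 bp cluster into loci;
2. each locus is extracted with ±200 nt genomic flanks;
3. an einverted-style local alignment of the window against its own
   reverse complement finds inverted repeats (match 3, mismatch −3,
   linear gap 6, score threshold 40, span ≤ 240);
4. each repeat, extended by 10 nt per side, is folded by maximum
   weighted nested base pairing (GC=3, AU=2, GU=1 — a deterministic,
   exhaustively verifiable stand-in for a thermodynamic folder);
5. the candidate mature placement is judged against MirCheck-style
   stem-loop criteria.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_map import AlignmentHit
from .preprocess import UniqueTag
from .seqtools import normalize_rna, revcomp

NEG = np.int64(-(10**9))

# Watson-Crick complement codes under the A=0,C=1,G=2,T=3 encoding
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}

#: folding pair weights (DNA alphabet; T plays U): GC=3, AU=2, GU=1
PAIR_WEIGHT = {
    (1, 2): 3, (2, 1): 3,
    (0, 3): 2, (3, 0): 2,
    (2, 3): 1, (3, 2): 1,
}

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(b, 4) for b in seq.upper()], dtype=np.int64)


# ---------------------------------------------------------------------------
# conserved matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureRef:
    """One known mature miRNA (reference set entry), T-normalized."""

    id: str
    family: str
    sequence: str


@dataclass(frozen=True)
class ConservedMatch:
    ref_id: str
    family: str
    n_mismatches: int
    tie: bool = False


def parse_family(ref_id: str) -> str:
    """miRBase-style id -> family name (``tae-miR166a-5p`` -> ``miR166``)."""
    import re

    m = re.search(r"(miR)[-]?(\d+)", ref_id, flags=re.IGNORECASE)
    return f"miR{m.group(2)}" if m else ref_id


def load_mature_references(fasta: dict[str, str]) -> list[MatureRef]:
    return [
        MatureRef(id=name, family=parse_family(name), sequence=normalize_rna(seq))
        for name, seq in fasta.items()
    ]


def _overlap_mismatches(tag: str, ref: str) -> int | None:
    """Minimum substitutions over an ungapped end-to-end comparison.

    Sequences must be within ±1 nt in length; the 1-nt overhang of the
    longer sequence is allowed at either end and its bases are uncounted.
    """
    if len(tag) == len(ref):
        return sum(a != b for a, b in zip(tag, ref))
    longer, shorter = (tag, ref) if len(tag) > len(ref) else (ref, tag)
    if len(longer) - len(shorter) != 1:
        return None
    return min(
        sum(a != b for a, b in zip(longer[off : off + len(shorter)], shorter))
        for off in (0, 1)
    )


def match_conserved(
    tag: UniqueTag | str,
    references: list[MatureRef],
    max_mismatches: int = 2,
) -> ConservedMatch | None:
    """Assign a tag to the known mature with the fewest mismatches (<= 2).

    Ties at the minimal mismatch count are broken by reference order and
    recorded on the returned match.
    """
    seq = (tag if isinstance(tag, str) else tag.sequence).upper()
    best: tuple[int, int] | None = None  # (mismatches, ref index)
    tie = False
    for i, ref in enumerate(references):
        mm = _overlap_mismatches(seq, ref.sequence)
        if mm is None or mm > max_mismatches:
            continue
        if best is None or mm < best[0]:
            best, tie = (mm, i), False
        elif mm == best[0] and references[best[1]].family != ref.family:
            tie = True
    if best is None:
        return None
    ref = references[best[1]]
    return ConservedMatch(ref_id=ref.id, family=ref.family, n_mismatches=best[0], tie=tie)


# ---------------------------------------------------------------------------
# locus clustering and precursor extraction
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    """A cluster of tag hits on one chromosome and strand."""

    chrom: str
    start: int
    end: int
    strand: str
    members: list[AlignmentHit] = field(default_factory=list)


def cluster_loci(hits: list[AlignmentHit], max_gap: int = 200) -> list[Locus]:
    """Single-linkage chaining of hits with start-to-start distance < max_gap.

    Hits on different chromosomes or strands never join. The input need
    not be sorted; output loci are ordered by (chrom, strand, start).
    """
    loci: list[Locus] = []
    for (chrom, strand) in sorted({(h.chrom, h.strand) for h in hits}):
        group = sorted(
            (h for h in hits if h.chrom == chrom and h.strand == strand),
            key=lambda h: (h.start, h.end, h.tag_id),
        )
        current: Locus | None = None
        prev_start = None
        for h in group:
            if current is not None and h.start - prev_start < max_gap:
                current.members.append(h)
                current.end = max(current.end, h.end)
            else:
                current = Locus(chrom=chrom, start=h.start, end=h.end, strand=strand, members=[h])
                loci.append(current)
            prev_start = h.start
    loci.sort(key=lambda l: (l.chrom, l.strand, l.start))
    return loci


@dataclass
class Precursor:
    """Extracted candidate sequence around a locus, strand-oriented 5'→3'."""

    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    clipped: bool = False

    def window_offset(self, hit: AlignmentHit) -> int:
        """Offset of a member hit inside the oriented window sequence."""
        if self.strand == "+":
            return hit.start - self.start
        return self.end - hit.end


def extract_precursor(locus: Locus, genome: dict[str, str] | str, flank: int = 200) -> Precursor:
    """Locus plus ±flank genomic context; minus-strand loci are reverse
    complemented so the returned sequence reads 5'→3' on the locus strand."""
    if isinstance(genome, str):
        genome = {"chr1": genome}
    chrom_seq = genome[locus.chrom]
    start = locus.start - flank
    end = locus.end + flank
    clipped = start < 0 or end > len(chrom_seq)
    start = max(0, start)
    end = min(len(chrom_seq), end)
    seq = chrom_seq[start:end].upper()
    if locus.strand == "-":
        seq = revcomp(seq)
    return Precursor(sequence=seq, chrom=locus.chrom, start=start, end=end,
                     strand=locus.strand, clipped=clipped)


# ---------------------------------------------------------------------------
# inverted-repeat dynamic programming (einverted-style)
# ---------------------------------------------------------------------------

@dataclass
class InvertedRepeat:
    """A self-complementary arm pair within one sequence.

    ``alignment`` lists columns outermost-first as (left_pos, right_pos,
    label) with label in {match, mismatch, gap}; gap columns consume one
    side only. The score identity 3·matches − 3·mismatches − 6·gaps holds
    by construction.
    """

    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    loop: tuple[int, int]
    score: int
    alignment: list[tuple[int | None, int | None, str]]

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_arm[0], self.right_arm[1])


def _ir_matrices(code: np.ndarray, match: int, mismatch: int, gap_penalty: int, min_loop: int):
    """Fill the pair DP.

    D[i,j]: best stem alignment whose outermost column pairs i with j.
    G[i,j]: best stem alignment lying entirely within [i, j] (the inner-
    extension relaxation: D, or a gap consuming i or j). Terminal gap
    columns never pay, so restricting outer/inner columns to substitutions
    loses no score. The innermost pair must leave >= min_loop unpaired
    bases between the arms.
    """
    n = len(code)
    D = np.full((n + 1, n + 1), NEG, dtype=np.int64)
    G = np.full((n + 1, n + 1), NEG, dtype=np.int64)
    comp = np.array([_COMP.get(int(c), -9) for c in code], dtype=np.int64)
    for i in range(n - 2, -1, -1):
        j = np.arange(i + 1, n)
        delta = np.where(code[j] == comp[i], match, mismatch).astype(np.int64)
        inner = G[i + 1, j - 1]
        base = np.where(j - i - 1 >= min_loop, 0, NEG)
        best_inner = np.maximum(base, inner)
        D[i, i + 1 : n] = np.where(best_inner <= NEG // 2, NEG, delta + best_inner)
        # G row: max(D[i,j], G[i+1,j]-gap, G[i,j-1]-gap) via a decayed scan
        A = np.maximum(D[i, : n], G[i + 1, : n] - gap_penalty)
        B = A + gap_penalty * np.arange(n)
        run = np.maximum.accumulate(B) - gap_penalty * np.arange(n)
        G[i, :n] = np.maximum(A, run)
        G[i, : i + 1] = NEG
    return D, G


def _traceback(code, D, G, i, j, match, mismatch, gap_penalty, min_loop):
    comp_i = lambda a: _COMP.get(int(code[a]), -9)
    cols: list[tuple[int | None, int | None, str]] = []
    a, b = i, j
    state = "D"
    while True:
        if state == "D":
            label = "match" if int(code[b]) == comp_i(a) else "mismatch"
            cols.append((a, b, label))
            base = 0 if (b - a - 1) >= min_loop else NEG
            inner = G[a + 1, b - 1] if b - 1 >= a + 1 else NEG
            if base >= inner:  # prefer closing the stem on ties
                left_end, right_start = a + 1, b
                break
            state = "G"
            a, b = a + 1, b - 1
        else:
            v = G[a, b]
            if v == D[a, b]:
                state = "D"
            elif v == G[a + 1, b] - gap_penalty:
                cols.append((a, None, "gap"))
                a += 1
            else:
                cols.append((None, b, "gap"))
                b -= 1
    left_positions = [c[0] for c in cols if c[0] is not None]
    right_positions = [c[1] for c in cols if c[1] is not None]
    return cols, (i, max(left_positions) + 1), (min(right_positions), j + 1)


def find_inverted_repeats(
    sequence: str,
    threshold: int = 40,
    match: int = 3,
    mismatch: int = -3,
    gap_penalty: int = 6,
    max_repeat: int = 240,
    min_loop: int = 3,
) -> list[InvertedRepeat]:
    """Inverted repeats scoring >= threshold, pruned to score-maximal ones.

    Local alignment of the sequence against its own downstream reverse
    complement (arms never overlap); linear gap cost. Overlapping reported
    repeats are pruned greedily by (score desc, leftmost start, shortest
    span), so each stem is reported once at its best outer pair.
    """
    code = _encode(sequence)
    n = len(code)
    if n < 2 * 1 + min_loop + 1:
        return []
    D, G = _ir_matrices(code, match, mismatch, gap_penalty, min_loop)
    ii, jj = np.nonzero(D[:n, :n] >= threshold)
    cand = [(int(D[i, j]), int(i), int(j)) for i, j in zip(ii, jj) if j - i + 1 <= max_repeat]
    cand.sort(key=lambda t: (-t[0], t[1], t[2] - t[1]))
    chosen: list[InvertedRepeat] = []
    for score, i, j in cand:
        if any(not (j < ir.span[0] or i > ir.span[1] - 1) for ir in chosen):
            continue
        cols, left, right = _traceback(code, D, G, i, j, match, mismatch, gap_penalty, min_loop)
        chosen.append(
            InvertedRepeat(
                left_arm=left,
                right_arm=right,
                loop=(left[1], right[0]),
                score=score,
                alignment=cols,
            )
        )
    chosen.sort(key=lambda ir: ir.span)
    return chosen


def best_inverted_repeat_score(sequence: str, **kwargs) -> int | None:
    """Best alignment score regardless of threshold (None if no pair exists)."""
    code = _encode(sequence)
    if len(code) < 3:
        return None
    D, _ = _ir_matrices(
        code,
        kwargs.get("match", 3),
        kwargs.get("mismatch", -3),
        kwargs.get("gap_penalty", 6),
        kwargs.get("min_loop", 3),
    )
    best = int(D[: len(code), : len(code)].max())
    return None if best <= int(NEG) // 2 else best


def extend_repeat(ir: InvertedRepeat, seq_len: int, pad: int = 10) -> tuple[int, int]:
    """Pad the repeat span by up to ``pad`` nt per side, clipped to bounds."""
    return (max(0, ir.span[0] - pad), min(seq_len, ir.span[1] + pad))


# ---------------------------------------------------------------------------
# folding: maximum weighted nested base pairing
# ---------------------------------------------------------------------------

@dataclass
class HairpinStructure:
    """Nested pairing of a sequence: dot-bracket plus partner table.

    ``mfe_proxy`` is the negated total pair weight — a deterministic
    ordering proxy, not a thermodynamic free energy.
    """

    sequence: str
    pairing: str
    partner: np.ndarray
    n_pairs: int
    mfe_proxy: float


def _pair_weight(a: int, b: int) -> int:
    return PAIR_WEIGHT.get((a, b), 0)


def fold_hairpin(sequence: str, min_loop: int = 3) -> HairpinStructure:
    """Maximum weighted nested pairing (Nussinov-style) of a sequence.

    Pairs are Watson-Crick or G·U, weighted GC=3, AU=2, GU=1; positions
    closer than ``min_loop`` cannot pair; bifurcations are allowed, so the
    result is the best nested structure, not necessarily a single stem.
    Traceback tie-breaking is deterministic (leave-left, then pair, then
    leftmost bifurcation).
    """
    code = _encode(sequence)
    n = len(code)
    W = np.zeros((n + 1, n + 1), dtype=np.int64)
    wmat = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            wmat[i, j] = _pair_weight(int(code[i]), int(code[j]))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = max(W[i + 1, j], W[i, j - 1])
            if j - i - 1 >= min_loop and wmat[i, j] > 0:
                best = max(best, W[i + 1, j - 1] + wmat[i, j])
            if span >= 2:
                k = np.arange(i, j)
                best = max(best, int(np.max(W[i, k] + W[k + 1, j])))
            W[i, j] = best
    partner = np.full(n, -1, dtype=np.int64)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        w = W[i, j]
        if w == W[i + 1, j]:
            stack.append((i + 1, j))
        elif w == W[i, j - 1]:
            stack.append((i, j - 1))
        elif j - i - 1 >= min_loop and wmat[i, j] > 0 and w == W[i + 1, j - 1] + wmat[i, j]:
            partner[i], partner[j] = j, i
            stack.append((i + 1, j - 1))
        else:
            for k in range(i, j):
                if w == W[i, k] + W[k + 1, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    dots = np.full(n, ".", dtype="<U1")
    dots[(partner >= 0) & (np.arange(n) < partner)] = "("
    dots[(partner >= 0) & (np.arange(n) > partner)] = ")"
    n_pairs = int((partner >= 0).sum()) // 2
    return HairpinStructure(
        sequence=sequence.upper(),
        pairing="".join(dots),
        partner=partner,
        n_pairs=n_pairs,
        mfe_proxy=-float(W[0, n - 1] if n else 0),
    )


# ---------------------------------------------------------------------------
# hairpin evaluation (MirCheck-style criteria)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinCriteria:
    """Stem-loop acceptance rules for a candidate mature placement."""

    mature_min_len: int = 18
    mature_max_len: int = 25
    max_unpaired: int = 4          # unpaired mature positions
    max_unpaired_run: int = 2      # consecutive unpaired mature positions
    max_bulges: int = 1            # asymmetric bulges > bulge_size allowed
    bulge_size: int = 2
    min_hairpin_len: int = 60


@dataclass
class HairpinEvaluation:
    passed: bool
    reasons: list[str]


def evaluate_hairpin(
    mature: tuple[int, int],
    structure: HairpinStructure,
    criteria: HairpinCriteria = HairpinCriteria(),
) -> HairpinEvaluation:
    """Judge a mature interval against the folded structure.

    Fails are reported with all violated criteria; a mature interval
    outside the structure is an error (the placement is nonsensical, not
    merely a failed candidate).
    """
    n = len(structure.sequence)
    start, end = mature
    if not (0 <= start < end <= n):
        raise ValueError(f"mature interval {mature} outside structure of length {n}")
    reasons: list[str] = []
    mlen = end - start
    if not (criteria.mature_min_len <= mlen <= criteria.mature_max_len):
        reasons.append("mature_length")
    part = structure.partner[start:end]
    inside = (part >= start) & (part < end)
    if bool(inside.any()):
        reasons.append("mature_spans_loop")
    unpaired = part < 0
    if int(unpaired.sum()) > criteria.max_unpaired:
        reasons.append("mature_unpaired_total")
    run = best = 0
    for u in unpaired:
        run = run + 1 if u else 0
        best = max(best, run)
    if best > criteria.max_unpaired_run:
        reasons.append("mature_unpaired_run")
    paired_idx = [start + k for k in range(mlen) if part[k] >= 0 and not inside[k]]
    n_bulges = 0
    for k1, k2 in zip(paired_idx, paired_idx[1:]):
        p1 = int(structure.partner[k1])
        p2 = int(structure.partner[k2])
        if p2 > p1:  # partners not monotone: the duplex is broken here
            n_bulges += 1
            continue
        asym = abs((k2 - k1 - 1) - (p1 - p2 - 1))
        if asym > criteria.bulge_size:
            n_bulges += 1
    if n_bulges > criteria.max_bulges:
        reasons.append("duplex_bulges")
    if n < criteria.min_hairpin_len:
        reasons.append("hairpin_length")
    return HairpinEvaluation(passed=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# novel miRNA calling
# ---------------------------------------------------------------------------

@dataclass
class MiRNARecord:
    """A called miRNA (conserved family or novel) with its evidence."""

    id: str
    mature_seq: str
    star_seq: str | None
    precursors: list[tuple[str, int, int, str]]
    kind: str  # "conserved" | "novel"
    family: str | None
    counts: dict[str, int]
    structure: str | None = None


def _star_from_structure(structure: HairpinStructure, mature: tuple[int, int]) -> str | None:
    part = structure.partner[mature[0] : mature[1]]
    partners = part[part >= 0]
    if partners.size == 0:
        return None
    lo, hi = int(partners.min()), int(partners.max()) + 1
    return structure.sequence[lo:hi]


def call_novel(
    loci: list[Locus],
    tags_by_id: dict[str, UniqueTag],
    genome: dict[str, str] | str,
    flank: int = 200,
    ir_params: dict | None = None,
    pad: int = 10,
    criteria: HairpinCriteria = HairpinCriteria(),
    fold_min_loop: int = 3,
) -> list[MiRNARecord]:
    """Predict novel miRNAs from candidate loci.

    For every locus the extracted window is scanned for inverted repeats;
    member tags inside each extended repeat are tried most-abundant-first
    as the mature, and the first placement passing the hairpin criteria
    yields a call. Identical matures from different loci collapse into one
    record with several precursor intervals; ids are assigned after
    sorting records by their first precursor position.
    """
    ir_params = ir_params or {}
    by_mature: dict[str, MiRNARecord] = {}
    for locus in loci:
        prec = extract_precursor(locus, genome, flank=flank)
        repeats = find_inverted_repeats(prec.sequence, **ir_params)
        called = False
        for ir in repeats:
            if called:
                break
            ext0, ext1 = extend_repeat(ir, len(prec.sequence), pad=pad)
            structure = fold_hairpin(prec.sequence[ext0:ext1], min_loop=fold_min_loop)
            members = []
            for hit in locus.members:
                off = prec.window_offset(hit)
                tag = tags_by_id.get(hit.tag_id)
                if tag is None:
                    continue
                mstart = off - ext0
                if 0 <= mstart and mstart + len(tag.sequence) <= ext1 - ext0:
                    members.append((tag, mstart))
            members.sort(key=lambda tm: (-tm[0].total_count, tm[0].sequence))
            for tag, mstart in members:
                ev = evaluate_hairpin((mstart, mstart + len(tag.sequence)), structure, criteria)
                if not ev.passed:
                    continue
                if locus.strand == "+":
                    g0 = prec.start + ext0
                    g1 = prec.start + ext1
                else:
                    g0 = prec.end - ext1
                    g1 = prec.end - ext0
                interval = (locus.chrom, g0, g1, locus.strand)
                rec = by_mature.get(tag.sequence)
                if rec is None:
                    by_mature[tag.sequence] = MiRNARecord(
                        id="",
                        mature_seq=tag.sequence,
                        star_seq=_star_from_structure(structure, (mstart, mstart + len(tag.sequence))),
                        precursors=[interval],
                        kind="novel",
                        family=None,
                        counts=dict(tag.counts),
                        structure=structure.pairing,
                    )
                elif interval not in rec.precursors:
                    rec.precursors.append(interval)
                called = True
                break
    records = sorted(by_mature.values(), key=lambda r: (r.precursors[0], r.mature_seq))
    for i, rec in enumerate(records):
        rec.id = f"novel-{i + 1}"
    return records


def call_conserved(
    tags: list[UniqueTag],
    references: list[MatureRef],
    max_mismatches: int = 2,
) -> list[MiRNARecord]:
    """Group tags by their best reference match into conserved records.

    Counts of all tags assigned to the same reference (sequence variants
    of one miRNA) are summed; the most abundant tag provides the mature
    sequence.
    """
    assigned: dict[str, list[UniqueTag]] = {}
    for tag in tags:
        m = match_conserved(tag, references, max_mismatches=max_mismatches)
        if m is not None:
            assigned.setdefault(m.ref_id, []).append(tag)
    records = []
    for ref_id in sorted(assigned):
        group = sorted(assigned[ref_id], key=lambda t: (-t.total_count, t.sequence))
        counts: dict[str, int] = {}
        for tag in group:
            for lib, c in tag.counts.items():
                counts[lib] = counts.get(lib, 0) + c
        family = next(r.family for r in references if r.id == ref_id)
        records.append(
            MiRNARecord(
                id=ref_id,
                mature_seq=group[0].sequence,
                star_seq=None,
                precursors=[],
                kind="conserved",
                family=family,
                counts=counts,
            )
        )
    return records
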