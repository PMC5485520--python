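"""Exact-match genome mapping with a k-mer index, plus tag classification.

Reproduces a Bowtie-style "report all perfect hits on both strands" step
at desk scale, the ncRNA-reference triage of collapsed tags, and the
repeat / low-expression classification of the surviving tags.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .preprocess import UniqueTag
from .seqtools import revcomp

#: classification priority: the first matching rule wins
CATEGORY_ORDER = (
    "rRNA",
    "tRNA",
    "snoRNA",
    "other_ncRNA",
    "high_repeat",
    "low_expression",
    "candidate",
)

HIGH_REPEAT_HITS = 20  # "> 20" genomic hits marks a repeat-derived tag


@dataclass(frozen=True)
class AlignmentHit:
    """One genomic occurrence of a tag (0-based half-open interval)."""

    tag_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int = 0


@dataclass
class TagHits:
    tag_id: str
    hits: list[AlignmentHit]
    truncated: bool = False


class KmerIndex:
    """Exact k-mer location index over one or more chromosomes."""

    def __init__(self, genome: dict[str, str] | str, k: int = 12):
        if k < 4:
            raise ValueError("word size k must be at least 4")
        if isinstance(genome, str):
            genome = {"chr1": genome}
        self.k = k
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((chrom, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer.upper(), [])


def _hamming_le(a: str, b: str, limit: int) -> int | None:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return None
    return mm


def map_tag(
    tag: UniqueTag | str,
    index: KmerIndex,
    max_mismatches: int = 0,
    max_hits: int = 100,
) -> TagHits:
    """All genomic occurrences of a tag on both strands.

    Seed-and-verify: every k-gram of the tag (step k) is looked up, so all
    hits with <= max_mismatches are found as long as the tag holds more
    than ``max_mismatches`` non-overlapping k-grams (pigeonhole). The hit
    list is truncated at ``max_hits`` with an explicit flag.
    """
    if isinstance(tag, str):
        tag = UniqueTag(tag_id=tag, sequence=tag, counts={})
    seq = tag.sequence.upper()
    k = index.k
    if len(seq) < k:
        raise ValueError(f"tag shorter than index word size ({len(seq)} < {k})")
    if len(seq) // k <= max_mismatches:
        raise ValueError("tag too short to guarantee hits at this mismatch level")
    found: dict[tuple[str, int, str], int] = {}
    for strand in "+-":
        query = seq if strand == "+" else revcomp(seq)
        starts = list(range(0, len(query) - k + 1, k))
        cand: set[tuple[str, int]] = set()
        for s in starts:
            for chrom, pos in index.lookup(query[s : s + k]):
                cand.add((chrom, pos - s))
        for chrom, pos in cand:
            ref = index.genome[chrom]
            if pos < 0 or pos + len(query) > len(ref):
                continue
            mm = _hamming_le(query, ref[pos : pos + len(query)], max_mismatches)
            if mm is not None:
                found[(chrom, pos, strand)] = mm
    hits = [
        AlignmentHit(tag.tag_id, chrom, pos, pos + len(seq), strand, mm)
        for (chrom, pos, strand), mm in found.items()
    ]
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    truncated = len(hits) > max_hits
    return TagHits(tag_id=tag.tag_id, hits=hits[:max_hits], truncated=truncated)


def map_tags(
    tags: list[UniqueTag], index: KmerIndex, max_mismatches: int = 0, max_hits: int = 100
) -> dict[str, TagHits]:
    return {t.tag_id: map_tag(t, index, max_mismatches, max_hits) for t in tags}


def annotate_ncrna(
    tags: list[UniqueTag],
    references: dict[str, dict[str, str]],
) -> dict[str, str]:
    """Assign ncRNA categories by exact substring match against references.

    ``references`` maps category -> {ref_id: sequence}. A tag matching a
    reference on either strand takes that category; categories are tried
    in priority order (rRNA first) so overlaps resolve deterministically.
    Only the first matching category is assigned; annotated tags are meant
    to be removed from the candidate pool by the caller.
    """
    classes: dict[str, str] = {}
    ordered = [c for c in CATEGORY_ORDER if c in references]
    for tag in tags:
        seq = tag.sequence.upper()
        rc = revcomp(seq)
        for cat in ordered:
            refs = references[cat]
            if any(seq in ref or rc in ref for ref in map(str.upper, refs.values())):
                classes[tag.tag_id] = cat
                break
    return classes


def classify_residual(
    tags: list[UniqueTag],
    hits_by_tag: dict[str, TagHits],
) -> dict[str, str]:
    """Classify mapped, non-ncRNA tags: high_repeat, low_expression or candidate."""
    classes: dict[str, str] = {}
    for tag in tags:
        th = hits_by_tag.get(tag.tag_id)
        if th is None or not th.hits:
            continue
        n_hits = len(th.hits) if not th.truncated else HIGH_REPEAT_HITS + 1
        if n_hits > HIGH_REPEAT_HITS:
            classes[tag.tag_id] = "high_repeat"
        elif tag.total_count == 1:
            classes[tag.tag_id] = "low_expression"
        else:
            classes[tag.tag_id] = "candidate"
    return classes


def hits_to_bed(hits_by_tag: dict[str, TagHits], path) -> None:
    """Export all hits as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for th in hits_by_tag.values():
            for h in th.hits:
                fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.tag_id}\t{h.mismatches}\t{h.strand}\n")
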