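"""miRNA target-site scanning under a strict complementarity rule.

A transcript site is a hit when its sense-strand slice equals the
reverse complement of the mature miRNA up to at most ``max_mm``
substitutions (no indels), with the bases opposite miRNA positions 10
and 11 (1-based from the miRNA 5' end) matching perfectly — the
cleavage-site constraint. G·U wobble counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqtools import encode, revcomp

MAX_MISMATCHES = 3
PROTECTED_POSITIONS = (10, 11)


@dataclass(frozen=True)
class TargetHit:
    """A complementary site; mismatch positions are miRNA coordinates
    (1-based from the 5' end), never 10 or 11."""

    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based offset on the transcript
    mismatch_positions: tuple[int, ...]
    n_mismatches: int


def find_targets(
    mature: str,
    transcripts: dict[str, str],
    max_mm: int = MAX_MISMATCHES,
    protected: tuple[int, ...] = PROTECTED_POSITIONS,
    mirna_id: str = "",
) -> list[TargetHit]:
    """All qualifying sites of one mature miRNA over a transcript set.

    The transcript base opposite miRNA position p sits at site_start +
    (L − p); overlapping sites are all reported.
    """
    mature = mature.upper()
    L = len(mature)
    if not (18 <= L <= 26):
        raise ValueError("mature must be 18-26 nt")
    if "N" in mature:
        raise ValueError("mature containing N rejected")
    pattern = encode(revcomp(mature))
    # window offset w pairs miRNA position L - w
    protected_cols = np.array([L - p for p in protected], dtype=int)
    hits: list[TargetHit] = []
    for tid, tseq in transcripts.items():
        tcode = encode(tseq.upper())
        if len(tcode) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(tcode, L)
        mm = windows != pattern
        ok = (mm.sum(axis=1) <= max_mm) & ~mm[:, protected_cols].any(axis=1)
        for s in np.nonzero(ok)[0]:
            wpos = np.nonzero(mm[s])[0]
            positions = tuple(sorted(int(L - w) for w in wpos))
            hits.append(
                TargetHit(
                    mirna_id=mirna_id,
                    transcript_id=tid,
                    site_start=int(s),
                    mismatch_positions=positions,
                    n_mismatches=len(positions),
                )
            )
    return hits


def scan_all(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    max_mm: int = MAX_MISMATCHES,
    protected: tuple[int, ...] = PROTECTED_POSITIONS,
) -> list[TargetHit]:
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        hits.extend(
            find_targets(mirnas[mid], transcripts, max_mm=max_mm, protected=protected, mirna_id=mid)
        )
    return hits


def target_summary(hits: list[TargetHit], mirna_ids: list[str]) -> pd.DataFrame:
    """Per-miRNA site and transcript-level target counts (deduplicated)."""
    rows = []
    for mid in mirna_ids:
        mine = [h for h in hits if h.mirna_id == mid]
        rows.append(
            {
                "mirna_id": mid,
                "n_sites": len(mine),
                "n_targets": len({h.transcript_id for h in mine}),
            }
        )
    return pd.DataFrame(rows).set_index("mirna_id")


def hits_table(hits: list[TargetHit], path=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "mirna_id": [h.mirna_id for h in hits],
            "transcript_id": [h.transcript_id for h in hits],
            "site_start": [h.site_start for h in hits],
            "n_mismatches": [h.n_mismatches for h in hits],
            "mismatch_positions": [
                ",".join(map(str, h.mismatch_positions)) for h in hits
            ],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
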