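"""Summary tables and composition statistics.

Percent cells follow the conventions of the printed sequencing-summary
tables: half-up rounding to two decimals, with denominators fixed per
row (high-quality % of raw total; matched % of high-quality; unique % of
high-quality; unique-matched % of unique; category rows % of the
category totals).
"""

from __future__ import annotations

from collections import Counter
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genome_map import CATEGORY_ORDER
from .preprocess import UniqueTag

TABLE2_ROWS = (
    ("rRNA", "rRNA"),
    ("tRNA", "tRNA"),
    ("snoRNA", "snoRNA"),
    ("other_ncRNA", "Other"),
    ("high_repeat", "High repeats (matched genome times >20)"),
    ("low_expression", "Low expression (sequence times = 1)"),
    ("candidate", "Total Potential miRNA"),
)


def percent(count: int, denominator: int) -> float:
    """100·count/denominator, rounded half-up to two decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = Decimal(count) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def table1(condition_counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Sequencing-summary table: counts plus percent per condition.

    ``condition_counts`` maps condition -> {total, high_quality, matched,
    unique, unique_matched}. Denominators: high-quality over raw total,
    matched and unique over high-quality, unique-matched over unique.
    """
    rows = [
        ("Total reads", "total", "total"),
        ("High quality (size >= 18 nt)", "high_quality", "total"),
        ("Total of perfectly matched", "matched", "high_quality"),
        ("Unique reads", "unique", "high_quality"),
        ("Unique reads matched", "unique_matched", "unique"),
    ]
    data = {}
    for cond, c in condition_counts.items():
        col_counts, col_pct = [], []
        for _, key, denom in rows:
            col_counts.append(c[key])
            col_pct.append(percent(c[key], c[denom]) if c[denom] > 0 else float("nan"))
        data[f"{cond}_reads"] = col_counts
        data[f"{cond}_pct"] = col_pct
    return pd.DataFrame(data, index=[r[0] for r in rows])


def table2(category_counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Category-distribution table over (unique, total) read counts.

    Percentages are taken over the summed unique / total counts, so the
    category rows partition 100% up to rounding.
    """
    uniq_total = sum(u for u, _ in category_counts.values())
    read_total = sum(t for _, t in category_counts.values())
    rows = [("Total reads", uniq_total, read_total)]
    for key, label in TABLE2_ROWS:
        u, t = category_counts.get(key, (0, 0))
        rows.append((label, u, t))
    df = pd.DataFrame(rows, columns=["Class", "unique_reads", "total_reads"]).set_index("Class")
    df["unique_pct"] = [
        percent(u, uniq_total) if uniq_total else float("nan") for u in df["unique_reads"]
    ]
    df["total_pct"] = [
        percent(t, read_total) if read_total else float("nan") for t in df["total_reads"]
    ]
    return df[["unique_reads", "unique_pct", "total_reads", "total_pct"]]


def composition_table(
    condition_counts: dict[str, dict[str, int]],
    category_counts: dict[str, tuple[int, int]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both summary tables from pipeline accounting."""
    return table1(condition_counts), table2(category_counts)


def category_counts_from_classes(
    tags: list[UniqueTag], classes: dict[str, str]
) -> dict[str, tuple[int, int]]:
    """Aggregate per-tag classes into (unique, total-read) counts."""
    out: dict[str, list[int]] = {c: [0, 0] for c in CATEGORY_ORDER}
    for tag in tags:
        cat = classes.get(tag.tag_id)
        if cat is None:
            continue
        out[cat][0] += 1
        out[cat][1] += tag.total_count
    return {c: (u, t) for c, (u, t) in out.items()}


def nucleotide_bias(
    sequences: list[str] | list[UniqueTag],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positional base-frequency matrix and first-base-by-length table.

    Frequencies are computed over the distinct sequences (one vote each,
    as in miRNA composition summaries) and reported in the RNA alphabet
    (T shown as U). Each position row sums to 1 over the sequences long
    enough to have that position.
    """
    seqs = [s.sequence if isinstance(s, UniqueTag) else s for s in sequences]
    if not seqs:
        raise ValueError("need at least one sequence")
    seqs = [s.upper() for s in seqs]
    max_len = max(len(s) for s in seqs)
    bases = ["A", "C", "G", "U"]
    freq = np.zeros((max_len, 4))
    for s in seqs:
        for i, b in enumerate(s):
            b = "U" if b == "T" else b
            if b in bases:
                freq[i, bases.index(b)] += 1
    totals = freq.sum(axis=1, keepdims=True)
    freq = np.divide(freq, totals, out=np.zeros_like(freq), where=totals > 0)
    freq_df = pd.DataFrame(freq, columns=bases, index=pd.RangeIndex(1, max_len + 1, name="position"))

    by_len: dict[int, Counter] = {}
    for s in seqs:
        b = "U" if s[0] == "T" else s[0]
        by_len.setdefault(len(s), Counter())[b] += 1
    rows = []
    for length in sorted(by_len):
        counts = by_len[length]
        n = sum(counts.values())
        row = {"length": length, "n": n}
        for b in bases:
            row[b] = counts.get(b, 0) / n
        row["mode"] = max(bases, key=lambda b: (counts.get(b, 0), -bases.index(b)))
        rows.append(row)
    return freq_df, pd.DataFrame(rows).set_index("length")
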