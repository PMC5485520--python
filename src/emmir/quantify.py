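"""TPM normalization and exact two-group differential expression.

The differential test is a desk-scale exact negative-binomial count
test: replicate libraries are scaled to the geometric-mean depth and
pooled per condition, a single common dispersion is estimated across all
miRNAs by the method of moments, and the salt pool is tested against the
control pool conditionally on their sum (the Poisson/binomial limit
applies when the dispersion is zero). Two-sided p-values sum the
probabilities of all outcomes no more likely than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import false_discovery_control

ALPHA = 0.05
PSEUDOCOUNT = 0.5


def tpm(count: float, total_mapped: float) -> float:
    """Transcripts per million: count / total × 10^6."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count / total_mapped * 1e6


def tpm_matrix(counts: pd.DataFrame, totals: pd.Series | None = None) -> pd.DataFrame:
    """Column-wise TPM. With ``totals`` unset, per-library count sums are
    used, making every TPM column sum to 10^6."""
    if totals is None:
        totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    return counts / totals * 1e6


def estimate_common_dispersion(
    counts: pd.DataFrame, conditions: dict[str, str]
) -> float:
    """Common NB dispersion by an equal-weight method-of-moments average.

    Counts are scaled to the geometric-mean library depth; within each
    condition the per-miRNA moment estimate (v − m) / m² is computed from
    the replicate sample mean m and variance v, and all per-miRNA values
    (over conditions, for miRNAs with m > 0.5) are averaged with equal
    weight and floored at zero. Equal weighting keeps a handful of
    high-abundance miRNAs — whose few-replicate variance estimates are
    the noisiest in absolute terms — from dominating the estimate. Needs
    >= 2 replicates in some condition, else returns 0.
    """
    totals = counts.sum(axis=0).astype(float)
    sf = np.exp(np.log(totals).mean()) / totals
    scaled = counts * sf
    vals = []
    for cond in set(conditions.values()):
        libs = [l for l in counts.columns if conditions[l] == cond]
        if len(libs) < 2:
            continue
        sub = scaled[libs]
        m = sub.mean(axis=1).to_numpy()
        v = sub.var(axis=1, ddof=1).to_numpy()
        keep = m > 0.5
        vals.append((v[keep] - m[keep]) / m[keep] ** 2)
    if not vals or not np.concatenate(vals).size:
        return 0.0
    return max(0.0, float(np.concatenate(vals).mean()))


def _conditional_logpmf(T: int, a: float, b: float) -> np.ndarray:
    """log P(Z = z | Z + Z' = T) for independent NB(a, p), NB(b, p)."""
    z = np.arange(T + 1, dtype=float)
    logw = (
        gammaln(z + a) - gammaln(z + 1.0)
        + gammaln(T - z + b) - gammaln(T - z + 1.0)
    )
    logw -= logw.max()
    return logw - np.log(np.exp(logw).sum())


def exact_count_test(
    salt_counts,
    control_counts,
    salt_totals,
    control_totals,
    dispersion: float = 0.0,
) -> float:
    """Two-sided exact test of equal relative abundance between conditions.

    Replicate counts are scaled to the geometric-mean depth of all
    libraries, rounded and pooled per condition; the conditional law of
    the salt pool given the grand total is negative hypergeometric (with
    shape n_reps/dispersion per side) or binomial when dispersion is 0.
    The p-value is the total probability of outcomes no more probable
    than the observed pool, hence 1 for a perfectly balanced split.
    """
    salt_counts = np.atleast_1d(np.asarray(salt_counts, dtype=float))
    control_counts = np.atleast_1d(np.asarray(control_counts, dtype=float))
    salt_totals = np.atleast_1d(np.asarray(salt_totals, dtype=float))
    control_totals = np.atleast_1d(np.asarray(control_totals, dtype=float))
    if (salt_totals <= 0).any() or (control_totals <= 0).any():
        raise ValueError("library totals must be positive")
    all_totals = np.concatenate([salt_totals, control_totals])
    ref = np.exp(np.log(all_totals).mean())
    zs = int(round(float((salt_counts * ref / salt_totals).sum())))
    zc = int(round(float((control_counts * ref / control_totals).sum())))
    T = zs + zc
    if T == 0:
        return 1.0
    ns, nc = len(salt_counts), len(control_counts)
    if dispersion <= 1e-12:
        # Poisson limit: conditional binomial(T, ns / (ns + nc))
        z = np.arange(T + 1, dtype=float)
        logp = (
            gammaln(T + 1.0) - gammaln(z + 1.0) - gammaln(T - z + 1.0)
            + z * np.log(ns / (ns + nc)) + (T - z) * np.log(nc / (ns + nc))
        )
        pmf = np.exp(logp - logp.max())
        pmf /= pmf.sum()
    else:
        k = 1.0 / dispersion
        pmf = np.exp(_conditional_logpmf(T, ns * k, nc * k))
    p = float(pmf[pmf <= pmf[zs] * (1.0 + 1e-9)].sum())
    return min(1.0, p)


@dataclass(frozen=True)
class DEResult:
    """One differential-expression row (the printed-table shape)."""

    mirna_id: str
    ratio: float
    p_value: float
    mark: str  # UP | DOWN | NS


def call_differential(
    counts: pd.DataFrame,
    conditions: dict[str, str],
    alpha: float = ALPHA,
    totals: pd.Series | None = None,
    dispersion: float | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-miRNA salt/control ratio, exact-test p-value and UP/DOWN mark.

    The ratio is the mean salt TPM over the mean control TPM with a raw
    pseudocount added on both sides before normalization; p-values use
    unadjusted counts. A Benjamini-Hochberg column is reported but marks
    threshold the raw p-value, as the printed tables do.
    """
    if counts.empty:
        raise ValueError("need at least one miRNA")
    salt_libs = [l for l in counts.columns if conditions[l] == "salt"]
    ctrl_libs = [l for l in counts.columns if conditions[l] == "control"]
    if totals is None:
        totals = counts.sum(axis=0).astype(float)
    totals = totals.astype(float)
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, conditions)
    tpms = tpm_matrix(counts, totals)
    salt_tpm = tpm_matrix(counts[salt_libs] + pseudocount, totals[salt_libs]).mean(axis=1)
    ctrl_tpm = tpm_matrix(counts[ctrl_libs] + pseudocount, totals[ctrl_libs]).mean(axis=1)
    ratio = salt_tpm / ctrl_tpm
    pvals = np.ones(len(counts))
    st = totals[salt_libs].to_numpy()
    ct = totals[ctrl_libs].to_numpy()
    for i, (_, row) in enumerate(counts.iterrows()):
        sc = row[salt_libs].to_numpy(dtype=float)
        cc = row[ctrl_libs].to_numpy(dtype=float)
        if sc.sum() + cc.sum() == 0:
            pvals[i] = 1.0
            continue
        pvals[i] = exact_count_test(sc, cc, st, ct, dispersion=dispersion)
    mark = np.where(
        (pvals <= alpha) & (ratio > 1), "UP",
        np.where((pvals <= alpha) & (ratio < 1), "DOWN", "NS"),
    )
    out = pd.DataFrame(
        {
            "salt_mean_tpm": tpms[salt_libs].mean(axis=1),
            "control_mean_tpm": tpms[ctrl_libs].mean(axis=1),
            "ratio": ratio,
            "p_value": pvals,
            "fdr": false_discovery_control(pvals),
            "mark": mark,
        },
        index=counts.index,
    )
    out.index.name = "mirna_id"
    return out


def scaled_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scaling (sample sd, ddof=1) for heatmap export; constant
    rows map to all zeros."""
    if values.shape[1] < 2:
        raise ValueError("need at least two columns to scale")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    centered = values.sub(mean, axis=0)
    out = centered.div(sd.where(sd > 0), axis=0)
    return out.fillna(0.0)


def de_table(
    de: pd.DataFrame, sequences: dict[str, str], path=None
) -> pd.DataFrame:
    """Printed-table shape: Name, Sequence, Length, p-Value, Ratio, Mark."""
    rows = pd.DataFrame(
        {
            "Name": de.index,
            "Sequence": [sequences.get(i, "") for i in de.index],
            "Length": [len(sequences.get(i, "")) for i in de.index],
            "p-Value": de["p_value"].to_numpy(),
            "Ratio": de["ratio"].to_numpy(),
            "Mark": de["mark"].to_numpy(),
        }
    )
    if path is not None:
        rows.to_csv(path, sep="\t", index=False)
    return rows
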