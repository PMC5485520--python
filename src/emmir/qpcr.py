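"""Relative qRT-PCR quantification by the Livak 2^-ΔΔCT method.

ΔCT is the target Ct minus the reference-gene Ct within a sample
(replicate-paired); ΔΔCT subtracts the control sample's ΔCT, so the
control's fold change is 1 by construction. Replicate ΔCT sets are
compared between treatment and control with an unpaired two-sample
Student's t-test (pooled variance; Welch available via flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_RANGE = (0.0, 45.0)


@dataclass(frozen=True)
class CtRecord:
    """Ct triplicates for one target in one sample, with its reference."""

    target_id: str
    sample_id: str
    ct_replicates: tuple[float, ...]
    reference_id: str = "18S"
    reference_ct: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for ct in tuple(self.ct_replicates) + tuple(self.reference_ct):
            if not (CT_RANGE[0] < ct < CT_RANGE[1]):
                raise ValueError(f"Ct value {ct} outside plausible range {CT_RANGE}")
        if len(self.ct_replicates) < 2:
            raise ValueError("need at least two Ct replicates")

    @property
    def delta_ct(self) -> np.ndarray:
        """Per-replicate ΔCT, pairing target and reference wells by index."""
        if not self.reference_ct:
            raise ValueError(f"sample {self.sample_id!r} has no reference Ct values")
        t = np.asarray(self.ct_replicates, dtype=float)
        r = np.asarray(self.reference_ct, dtype=float)
        if len(t) == len(r):
            return t - r
        return t - r.mean()


@dataclass(frozen=True)
class RelExpression:
    target_id: str
    sample_id: str
    fold: float
    p_value: float | None = None


def delta_delta_ct(treatment: CtRecord, control: CtRecord) -> RelExpression:
    """Fold change of the treatment sample relative to control: 2^-ΔΔCT
    with ΔCT as replicate-mean target Ct minus reference Ct."""
    ddct = float(treatment.delta_ct.mean() - control.delta_ct.mean())
    return RelExpression(
        target_id=treatment.target_id,
        sample_id=treatment.sample_id,
        fold=float(2.0 ** (-ddct)),
    )


def replicate_ttest(
    treatment_dct, control_dct, equal_var: bool = True
) -> float:
    """Two-sided, two-sample t-test on per-replicate ΔCT values."""
    a = np.asarray(treatment_dct, dtype=float)
    b = np.asarray(control_dct, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def relative_expression(
    ct_table: pd.DataFrame,
    reference_id: str = "18S",
    control_sample: str = "control",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Table-level 2^-ΔΔCT analysis.

    ``ct_table`` columns: target, sample, replicate, ct. Every (target,
    sample) pair needs a matching reference record in the same sample;
    each non-control sample is quantified against ``control_sample`` and
    tested on replicate ΔCT values.
    """
    required = {"target", "sample", "replicate", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    records: dict[tuple[str, str], CtRecord] = {}
    for (target, sample), grp in ct_table.groupby(["target", "sample"]):
        if target == reference_id:
            continue
        ref = ct_table[(ct_table["target"] == reference_id) & (ct_table["sample"] == sample)]
        if ref.empty:
            raise ValueError(f"no reference ({reference_id}) Ct values for sample {sample!r}")
        records[(target, sample)] = CtRecord(
            target_id=target,
            sample_id=sample,
            ct_replicates=tuple(grp.sort_values("replicate")["ct"]),
            reference_id=reference_id,
            reference_ct=tuple(ref.sort_values("replicate")["ct"]),
        )
    rows = []
    for (target, sample), rec in sorted(records.items()):
        ctrl = records.get((target, control_sample))
        if ctrl is None:
            raise ValueError(f"no control sample {control_sample!r} for target {target!r}")
        rel = delta_delta_ct(rec, ctrl)
        p = None
        if sample != control_sample:
            p = replicate_ttest(rec.delta_ct, ctrl.delta_ct, equal_var=equal_var)
        rows.append(
            {
                "target": target,
                "sample": sample,
                "fold": rel.fold,
                "p_value": p if p is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
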