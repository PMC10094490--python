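"""Relative qPCR quantification by the 2^-ddCt method.

Each sample's target Ct is normalized to a reference gene
(dCt = Ct_target - Ct_reference), then to the mean dCt of a control group
(ddCt), giving a relative quantity RQ = 2^-ddCt per sample. Group
differences are tested with a Welch two-sided t-test, by default on the dCt
scale (approximately normal), while fold changes are reported as RQ.
Technical replicates are averaged per (sample, gene) before dCt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class QPCRError(ValueError):
    pass


@dataclass
class RelativeExpression:
    """Per-sample RQ values plus per-group summaries for one target gene."""

    target: str
    reference: str
    control_group: str
    per_sample: pd.DataFrame  # sample, group, delta_ct, ddct, rq
    group_summary: pd.DataFrame  # group, n, mean_rq, sem_rq, mean_delta_ct
    t_statistic: float = np.nan
    p_value: float = np.nan


def _mean_ct(table: pd.DataFrame, gene: str) -> pd.Series:
    """Average technical-replicate Ct per sample for one gene."""
    sub = table[table["gene"] == gene]
    return sub.groupby("sample")["ct"].mean()


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    control_group: str,
    test_scale: str = "delta_ct",
) -> RelativeExpression:
    """2^-ddCt relative quantification of `target` against `reference`.

    ``ddCt_i = dCt_i - mean(dCt over control-group samples)``;
    ``RQ_i = 2^-ddCt_i``. The two-group Welch t-test runs on dCt values by
    default (``test_scale="rq"`` switches to RQ) and is reported only when
    both groups have >= 2 samples.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(table.columns):
        raise QPCRError(f"Ct table needs columns {sorted(required)}")
    if (table["ct"] <= 0).any():
        raise QPCRError("Ct values must be positive")
    groups = table.drop_duplicates("sample").set_index("sample")["group"]
    ct_target = _mean_ct(table, target)
    ct_ref = _mean_ct(table, reference)
    if ct_target.empty:
        raise QPCRError(f"target gene {target!r} not in table")
    missing_ref = sorted(set(ct_target.index) - set(ct_ref.index))
    if missing_ref:
        raise QPCRError(
            f"reference gene {reference!r} missing for sample(s) {missing_ref}"
        )
    delta = (ct_target - ct_ref.reindex(ct_target.index)).rename("delta_ct")
    sample_groups = groups.reindex(delta.index)
    control = delta[sample_groups == control_group]
    if control.empty:
        raise QPCRError(f"control group {control_group!r} has no samples")
    ddct = delta - control.mean()
    rq = np.exp2(-ddct)
    per_sample = pd.DataFrame(
        {
            "sample": delta.index,
            "group": sample_groups.to_numpy(),
            "delta_ct": delta.to_numpy(),
            "ddct": ddct.to_numpy(),
            "rq": rq.to_numpy(),
        }
    ).reset_index(drop=True)
    summary = (
        per_sample.groupby("group", sort=False)
        .agg(
            n=("rq", "size"),
            mean_rq=("rq", "mean"),
            sem_rq=("rq", "sem"),
            mean_delta_ct=("delta_ct", "mean"),
        )
        .reset_index()
    )
    result = RelativeExpression(
        target=target,
        reference=reference,
        control_group=control_group,
        per_sample=per_sample,
        group_summary=summary,
    )
    labels = [g for g in per_sample["group"].unique()]
    if len(labels) == 2:
        col = "delta_ct" if test_scale == "delta_ct" else "rq"
        a = per_sample.loc[per_sample["group"] == labels[0], col]
        b = per_sample.loc[per_sample["group"] == labels[1], col]
        if len(a) >= 2 and len(b) >= 2:
            t, p = group_ttest(a, b)
            result.t_statistic, result.p_value = t, p
    return result


def group_ttest(values_a, values_b) -> tuple[float, float]:
    """Welch two-sided t-test between two groups of measurements."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise QPCRError("each group needs >= 2 values for a t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def analyze_targets(
    table: pd.DataFrame,
    targets: list[str],
    reference: str,
    control_group: str,
    test_scale: str = "delta_ct",
) -> pd.DataFrame:
    """Run delta_delta_ct for several targets; one summary row per target/group."""
    rows = []
    for gene in targets:
        res = delta_delta_ct(table, gene, reference, control_group, test_scale)
        for r in res.group_summary.itertuples(index=False):
            rows.append(
                {
                    "gene": gene,
                    "group": r.group,
                    "n": r.n,
                    "mean_rq": r.mean_rq,
                    "sem_rq": r.sem_rq,
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
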