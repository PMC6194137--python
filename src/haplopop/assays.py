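"""Expression-assay statistics: qPCR delta-CT fold changes and reporter ANOVA.

Technical replicates are collapsed to their mean before any inference; the
biological replicate is the unit of analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

log = logging.getLogger(__name__)


@dataclass
class QpcrResult:
    per_sample: pd.DataFrame  # sample, group, delta_ct, fold_change
    t_statistic: float
    df: float
    p_value: float
    baseline_group: str


def qpcr_fold_change(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    baseline_group: str = "solitary",
    equal_var: bool = True,
) -> QpcrResult:
    """Delta-CT normalization, fold change vs the baseline group, and a t-test.

    ``table`` is long format with columns (sample, group, gene, ct); the
    replicate CTs of each sample/gene are averaged first.  Per sample,
    delta_ct = mean CT(target) - mean CT(reference) and
    fold = 2^-(delta_ct - mean baseline delta_ct).  The two-sided
    two-sample t-test (pooled variance by default, Welch with
    ``equal_var=False``) compares delta_ct between the two groups.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required <= set(table.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    means = (
        table.groupby(["sample", "group", "gene"], sort=True)["ct"].mean().unstack("gene")
    )
    for gene in (target_gene, reference_gene):
        if gene not in means.columns:
            raise ValueError(f"gene {gene!r} absent from table")
    per_sample = means.reset_index()
    per_sample["delta_ct"] = per_sample[target_gene] - per_sample[reference_gene]
    groups = per_sample["group"].unique()
    if baseline_group not in groups:
        raise ValueError(f"baseline group {baseline_group!r} not present")
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    base_mean = per_sample.loc[per_sample["group"] == baseline_group, "delta_ct"].mean()
    per_sample["fold_change"] = 2.0 ** -(per_sample["delta_ct"] - base_mean)
    other = [g for g in groups if g != baseline_group][0]
    a = per_sample.loc[per_sample["group"] == other, "delta_ct"].to_numpy()
    b = per_sample.loc[per_sample["group"] == baseline_group, "delta_ct"].to_numpy()
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else np.nan
    return QpcrResult(
        per_sample=per_sample[["sample", "group", "delta_ct", "fold_change"]],
        t_statistic=float(t),
        df=float(df),
        p_value=float(p),
        baseline_group=baseline_group,
    )


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame  # group1, group2, mean_diff, p_adj, lower, upper, reject


def anova_tukey(groups: dict[str, np.ndarray] | pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA plus all-pairs Tukey HSD.

    ``groups`` is either a mapping label -> replicate values or a frame
    with columns (group, value).  Groups with a single replicate are
    excluded from the Tukey table with a warning (they still enter the
    ANOVA).  Unbalanced designs use the Tukey-Kramer form.
    """
    if isinstance(groups, pd.DataFrame):
        data = {g: sub["value"].to_numpy(float) for g, sub in groups.groupby("group")}
    else:
        data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        warnings.simplefilter("ignore")  # ConstantInputWarning on degenerate data
        f, p = sps.f_oneway(*data.values())
    if not np.isfinite(f):  # all values identical across groups
        f, p = 0.0, 1.0
    n_total = sum(len(v) for v in data.values())
    df_b = len(data) - 1
    df_w = n_total - len(data)

    multi = {g: v for g, v in data.items() if len(v) >= 2}
    dropped = set(data) - set(multi)
    if dropped:
        log.warning("groups with 1 replicate excluded from Tukey HSD: %s", sorted(dropped))
    if len(multi) >= 2:
        values = np.concatenate(list(multi.values()))
        labels = np.concatenate([[g] * len(v) for g, v in multi.items()])
        if np.ptp(values) == 0:
            pairs = [
                (a, b)
                for i, a in enumerate(sorted(multi))
                for b in sorted(multi)[i + 1 :]
            ]
            tukey = pd.DataFrame(
                {
                    "group1": [a for a, _ in pairs],
                    "group2": [b for _, b in pairs],
                    "mean_diff": 0.0,
                    "p_adj": 1.0,
                    "lower": 0.0,
                    "upper": 0.0,
                    "reject": False,
                }
            )
        else:
            res = pairwise_tukeyhsd(values, labels, alpha=alpha)
            tukey = pd.DataFrame(
                res.summary().data[1:],
                columns=["group1", "group2", "mean_diff", "p_adj", "lower", "upper", "reject"],
            )
            tukey["p_adj"] = res.pvalues
            tukey["mean_diff"] = res.meandiffs
    else:
        tukey = pd.DataFrame(
            columns=["group1", "group2", "mean_diff", "p_adj", "lower", "upper", "reject"]
        )
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=float(p),
        tukey=tukey,
    )
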