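"""Age-matched bootstrap subsampling.

The deconfounding procedure: repeatedly draw k samples per disease
stage without replacement, keep only draws in which the stages show no
age difference (ANOVA p > alpha), and summarize the outcome test (for
example Faith's PD across stages) over the retained draws.  Body
weight, body-condition score and sex balance are tracked but do not
gate retention; retention is on age alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def anova_p(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA p with the degenerate rule: zero total variance -> p = 1."""
    if np.ptp(values) == 0:
        return 1.0
    groups = [values[codes == g] for g in range(n_groups)]
    import warnings

    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # zero within-group variance, non-zero between
        return 0.0
    return float(p)


def chi_square_independence(table) -> float:
    """Pearson chi-square p (no continuity correction) for an r x c count
    table; any zero expected cell yields p = 1 by convention."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    total = t.sum()
    if total == 0:
        return 1.0
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if (expected == 0).any():
        return 1.0
    statistic = ((t - expected) ** 2 / expected).sum()
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(statistic, df))


@dataclass
class BootstrapAgeResult:
    """Per-iteration p values and the retained-subcohort summary.

    ``iterations`` columns: p_age, p_bw, p_bcs, p_sex, retained,
    p_outcome (NaN when not retained), sampled_ids.
    ``summary``: n_retained, prop_outcome_significant, median_p_outcome,
    iqr_low/iqr_high (NaN when nothing is retained).
    """

    iterations: pd.DataFrame
    summary: dict


def matched_bootstrap(outcome: pd.Series, metadata: pd.DataFrame, B: int = 1000,
                      k: int = 12, alpha_match: float = 0.05, alpha_out: float = 0.05,
                      seed: int = 0) -> BootstrapAgeResult:
    """Run the age-matched bootstrap.

    Parameters
    ----------
    outcome : pandas.Series
        Per-sample outcome (e.g. Faith's PD), defined for every sample.
    metadata : pandas.DataFrame
        Columns stage, age, body_weight, bcs, sex.
    B, k : int
        Number of iterations and per-group subsample size.
    alpha_match, alpha_out : float
        Retention threshold on the age ANOVA p, and the significance
        threshold applied to the outcome ANOVA p in the summary.
    """
    stages = sorted(metadata["stage"].unique())
    n_groups = len(stages)
    # sample over sorted ids so results depend on ids, not row order
    ids_by_group = {s: np.array(sorted(metadata.index[metadata["stage"] == s])) for s in stages}
    for s, ids in ids_by_group.items():
        if len(ids) < k:
            raise ValueError(f"group {s!r} has {len(ids)} samples, fewer than k={k}")
    outcome = outcome.reindex(metadata.index)
    if outcome.isna().any():
        missing = list(outcome.index[outcome.isna()])[:10]
        raise ValueError(f"outcome undefined for sample(s): {missing}")

    meta = metadata.copy()
    sex_code = (meta["sex"] == "M").astype(int)
    rng = np.random.default_rng(seed)
    codes_template = np.repeat(np.arange(n_groups), k)
    rows = []
    for it in range(B):
        chosen = np.concatenate([rng.choice(ids_by_group[s], size=k, replace=False)
                                 for s in stages])
        sub = meta.loc[chosen]
        p_age = anova_p(sub["age"].to_numpy(dtype=float), codes_template, n_groups)
        p_bw = anova_p(sub["body_weight"].to_numpy(dtype=float), codes_template, n_groups)
        p_bcs = anova_p(sub["bcs"].to_numpy(dtype=float), codes_template, n_groups)
        sex_table = np.zeros((2, n_groups))
        sc = sex_code.loc[chosen].to_numpy()
        for g in range(n_groups):
            block = sc[codes_template == g]
            sex_table[0, g] = (block == 0).sum()
            sex_table[1, g] = (block == 1).sum()
        p_sex = chi_square_independence(sex_table)
        retained = p_age > alpha_match
        p_outcome = (
            anova_p(outcome.loc[chosen].to_numpy(dtype=float), codes_template, n_groups)
            if retained else np.nan
        )
        rows.append({"iteration": it, "p_age": p_age, "p_bw": p_bw, "p_bcs": p_bcs,
                     "p_sex": p_sex, "retained": retained, "p_outcome": p_outcome,
                     "sampled_ids": ";".join(chosen)})
    iterations = pd.DataFrame(rows)
    retained_p = iterations.loc[iterations["retained"], "p_outcome"]
    n_retained = int(iterations["retained"].sum())
    if n_retained:
        summary = {
            "n_iterations": B,
            "n_retained": n_retained,
            "prop_outcome_significant": float((retained_p < alpha_out).mean()),
            "median_p_outcome": float(retained_p.median()),
            "iqr_low": float(retained_p.quantile(0.25)),
            "iqr_high": float(retained_p.quantile(0.75)),
        }
    else:
        summary = {
            "n_iterations": B,
            "n_retained": 0,
            "prop_outcome_significant": float("nan"),
            "median_p_outcome": float("nan"),
            "iqr_low": float("nan"),
            "iqr_high": float("nan"),
        }
    return BootstrapAgeResult(iterations, summary)


def unmatched_significant_fraction(result: BootstrapAgeResult, outcome: pd.Series,
                                   metadata: pd.DataFrame, alpha_out: float = 0.05) -> float:
    """Fraction of ALL iterations with a significant outcome test,
    ignoring the age-retention rule (the comparison the matching is
    meant to improve on)."""
    stages = sorted(metadata["stage"].unique())
    n_groups = len(stages)
    fracs = []
    for ids in result.iterations["sampled_ids"]:
        chosen = ids.split(";")
        k = len(chosen) // n_groups
        codes = np.repeat(np.arange(n_groups), k)
        p = anova_p(outcome.loc[chosen].to_numpy(dtype=float), codes, n_groups)
        fracs.append(p < alpha_out)
    return float(np.mean(fracs))
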