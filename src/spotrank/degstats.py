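"""Per-gene hypothesis tests, FCS/SNS scoring and dual-contrast hit calling.

The two ranking scores weight an effect size by the evidence for it:

    FCS = log2(µ_T / µ_C) · (−log10 P)          (fold change score)
    SNS = (µ_T − µ_C) / (σ_T + σ_C) · (−log10 P)  (signal-to-noise score)

where µ and σ are the group mean and standard deviation of a gene's
expression in the treated (T) and control (C) groups and P is the
two-sided p-value of an unpaired t-test between them.  Both scores are
invariant under a positive rescaling of all measurements and share the
sign of the mean difference.

A gene is a hit when its p-value clears ``alpha`` in BOTH
treated-vs-vehicle and treated-vs-agonist-alone contrasts (and, when a
``top_k`` is set, when it sits in the top k of both |FCS| and |SNS|
rankings).  General-purpose two-group tests used elsewhere in the
pipeline (summary-statistic t-tests, permutation test, KS test,
Holm-Šidák adjustment) live here too.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GroupSummary, SpotMatrix, TestResult

logger = logging.getLogger(__name__)

#: p-values are clipped into [P_FLOOR, 1] before taking −log10.
P_FLOOR = 1e-300

#: Total relabelings at or below which the permutation test enumerates
#: exhaustively instead of sampling.
EXHAUSTIVE_CAP = 20_000


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

def ttest_two_sample(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "student_pooled",
) -> TestResult:
    """Two-sided unpaired t-test on raw values.

    ``student_pooled`` pools variances (df = n_a + n_b − 2);
    ``welch`` uses the Satterthwaite approximation.  Two groups with
    zero variance and equal means give t = 0, p = 1 rather than an
    error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n ≥ 2, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")

    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            df = float(a.size + b.size - 2)
            return TestResult(0.0, 1.0, f"ttest_{variant}", df, a.size, b.size)
        # infinite t; report a hard zero p with the pooled df
        return TestResult(
            math.inf if a.mean() > b.mean() else -math.inf,
            0.0,
            f"ttest_{variant}",
            float(a.size + b.size - 2),
            a.size,
            b.size,
        )

    res = stats.ttest_ind(a, b, equal_var=(variant == "student_pooled"))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"ttest_{variant}",
        df=float(res.df),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def ttest_from_summary(
    summary_a: GroupSummary,
    summary_b: GroupSummary,
    variant: str = "student_pooled",
) -> TestResult:
    """Two-sided unpaired t-test from (mean, SD-or-SEM, n) summaries.

    Identical to :func:`ttest_two_sample` evaluated on any data with
    these summaries; this is how in-text "mean ± SEM (n)" values are
    re-tested.
    """
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    for s in (summary_a, summary_b):
        if s.sd <= 0:
            raise ValueError(f"group {s.label!r}: dispersion must be > 0")
    res = stats.ttest_ind_from_stats(
        summary_a.mean,
        summary_a.sd,
        summary_a.n,
        summary_b.mean,
        summary_b.sd,
        summary_b.n,
        equal_var=(variant == "student_pooled"),
    )
    if variant == "student_pooled":
        df = float(summary_a.n + summary_b.n - 2)
    else:
        va, vb = summary_a.sd**2 / summary_a.n, summary_b.sd**2 / summary_b.n
        df = (va + vb) ** 2 / (
            va**2 / (summary_a.n - 1) + vb**2 / (summary_b.n - 1)
        )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"ttest_{variant}",
        df=df,
        n_a=summary_a.n,
        n_b=summary_b.n,
    )


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: Union[int, str] = "exhaustive",
    seed: Optional[int] = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> TestResult:
    """Permutation test on the absolute difference of group means.

    When the number of relabelings C(n_a+n_b, n_a) is at most
    ``exhaustive_cap`` (always when ``n_perm="exhaustive"`` requests
    it and the cap allows), every relabeling is enumerated and p is the
    exact fraction — including the observed labeling — whose statistic
    is at least the observed one.  Otherwise ``n_perm`` Monte-Carlo
    draws are used with the (k+1)/(n_perm+1) correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a, n_total = a.size, a.size + b.size
    total = math.comb(n_total, n_a)

    exhaustive = total <= exhaustive_cap
    if n_perm == "exhaustive" and not exhaustive:
        warnings.warn(
            f"{total} relabelings exceed the exhaustive cap {exhaustive_cap}; "
            "falling back to 10000 Monte-Carlo permutations",
            stacklevel=2,
        )
        n_perm = 10_000

    if exhaustive:
        total_sum = pooled.sum()
        count = 0
        for idx in combinations(range(n_total), n_a):
            mean_a = pooled[list(idx)].mean()
            mean_b = (total_sum - pooled[list(idx)].sum()) / (n_total - n_a)
            if abs(mean_a - mean_b) >= observed - 1e-12:
                count += 1
        return TestResult(
            statistic=float(observed),
            p_value=count / total,
            method="permutation_exhaustive",
            df=None,
            n_a=int(n_a),
            n_b=int(b.size),
        )

    n_perm = int(n_perm)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small for Monte-Carlo", stacklevel=2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= observed - 1e-12:
            count += 1
    return TestResult(
        statistic=float(observed),
        p_value=(count + 1) / (n_perm + 1),
        method="permutation_montecarlo",
        df=None,
        n_a=int(n_a),
        n_b=int(b.size),
    )


def ks_two_sample(
    values_a: Sequence[float],
    values_b: Sequence[float],
    mode: str = "asymptotic",
) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test (D = sup |ECDF_a − ECDF_b|)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("asymptotic", "exact"):
        raise ValueError(f"mode must be 'asymptotic' or 'exact', got {mode!r}")
    res = stats.ks_2samp(a, b, method="exact" if mode == "exact" else "asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"ks_{mode}",
        df=None,
        n_a=int(a.size),
        n_b=int(b.size),
    )


# ---------------------------------------------------------------------------
# FCS / SNS
# ---------------------------------------------------------------------------

def _neg_log10(p: float) -> float:
    if p == 0:
        raise ValueError(
            "p = 0 is outside the score domain; clip p to a floor (e.g. 1e-300) first"
        )
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    return -math.log10(max(p, P_FLOOR))


def compute_fcs(
    summary_treated: GroupSummary,
    summary_control: GroupSummary,
    p: float,
    pseudocount: float = 0.0,
) -> Optional[float]:
    """Fold change score: log2(µ_T/µ_C) · (−log10 p).

    Returns ``None`` (undefined) when either group mean is ≤ 0 and no
    pseudocount is configured, since the log ratio does not exist.
    """
    nlp = _neg_log10(p)
    mu_t = summary_treated.mean + pseudocount
    mu_c = summary_control.mean + pseudocount
    if mu_t <= 0 or mu_c <= 0:
        return None
    return math.log2(mu_t / mu_c) * nlp


def compute_sns(
    summary_treated: GroupSummary,
    summary_control: GroupSummary,
    p: float,
) -> float:
    """Signal-to-noise score: (µ_T − µ_C)/(σ_T + σ_C) · (−log10 p)."""
    nlp = _neg_log10(p)
    denom = summary_treated.sd + summary_control.sd
    if denom <= 0:
        raise ValueError("σ_T + σ_C must be > 0")
    return (summary_treated.mean - summary_control.mean) / denom * nlp


# ---------------------------------------------------------------------------
# gene scoring and hit calling
# ---------------------------------------------------------------------------

@dataclass
class GeneScoreTable:
    """Per-gene scores for one treated-vs-control contrast.

    ``table`` columns: gene, mean_treated, mean_control, sd_treated,
    sd_control, n_treated, n_control, p_value, fcs, sns, fcs_defined,
    fcs_rank, sns_rank.  Ranks are dense on the absolute score,
    descending (rank 1 = strongest); genes with undefined FCS carry no
    FCS rank.
    """

    table: pd.DataFrame
    contrast: str
    treated: str
    control: str

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene"])


def _dense_rank_desc(values: pd.Series) -> pd.Series:
    return values.rank(method="dense", ascending=False)


def score_genes(
    matrix: SpotMatrix,
    treated_group: str,
    control_group: str,
    test_variant: str = "student_pooled",
    region_mask: Optional[np.ndarray] = None,
    fcs_pseudocount: float = 0.0,
) -> GeneScoreTable:
    """Score every gene for one contrast over the selected spots.

    For each gene: group summaries (mean, SD, n over spots), a
    two-sided t-test p-value, FCS and SNS, and dense ranks by |FCS| and
    |SNS|.  Deterministic given the input.
    """
    mask = (
        np.ones(matrix.n_spots, dtype=bool)
        if region_mask is None
        else np.asarray(region_mask, dtype=bool)
    )
    groups = matrix.spot_meta["group"].to_numpy()
    treated_idx = mask & (groups == treated_group)
    control_idx = mask & (groups == control_group)
    for label, idx in ((treated_group, treated_idx), (control_group, control_idx)):
        if idx.sum() < 2:
            raise ValueError(
                f"group {label!r} has {int(idx.sum())} spots in the mask; need ≥ 2"
            )

    t_vals = matrix.counts[treated_idx].astype(float)
    c_vals = matrix.counts[control_idx].astype(float)
    n_t, n_c = t_vals.shape[0], c_vals.shape[0]

    mean_t, mean_c = t_vals.mean(axis=0), c_vals.mean(axis=0)
    sd_t, sd_c = t_vals.std(axis=0, ddof=1), c_vals.std(axis=0, ddof=1)

    res = stats.ttest_ind(
        t_vals, c_vals, axis=0, equal_var=(test_variant == "student_pooled")
    )
    p = np.asarray(res.pvalue, dtype=float)
    # constant gene in both groups with equal means: define t = 0, p = 1
    degenerate = (sd_t == 0) & (sd_c == 0)
    p[degenerate & (mean_t == mean_c)] = 1.0
    p[degenerate & (mean_t != mean_c)] = 0.0
    p = np.clip(p, P_FLOOR, 1.0)

    nlp = -np.log10(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (mean_t + fcs_pseudocount) / (mean_c + fcs_pseudocount)
        fcs = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)) * nlp, np.nan)
    fcs_defined = ((mean_t + fcs_pseudocount) > 0) & ((mean_c + fcs_pseudocount) > 0)
    fcs = np.where(fcs_defined, fcs, np.nan)
    denom = sd_t + sd_c
    sns = np.where(denom > 0, (mean_t - mean_c) / np.where(denom > 0, denom, 1.0) * nlp, 0.0)

    n_undef = int((~fcs_defined).sum())
    if n_undef:
        logger.warning(
            "%d genes have undefined FCS (a group mean ≤ 0, no pseudocount)", n_undef
        )

    table = pd.DataFrame(
        {
            "gene": matrix.gene_meta["symbol"].to_numpy(),
            "mean_treated": mean_t,
            "mean_control": mean_c,
            "sd_treated": sd_t,
            "sd_control": sd_c,
            "n_treated": n_t,
            "n_control": n_c,
            "p_value": p,
            "fcs": fcs,
            "sns": sns,
            "fcs_defined": fcs_defined,
        }
    )
    table["fcs_rank"] = _dense_rank_desc(table["fcs"].abs())
    table["sns_rank"] = _dense_rank_desc(table["sns"].abs())
    return GeneScoreTable(
        table=table,
        contrast=f"{treated_group}_vs_{control_group}",
        treated=treated_group,
        control=control_group,
    )


@dataclass
class HitList:
    """Genes significant in both contrasts, ranked by score strength."""

    genes: list[str]
    alpha: float
    top_k: Union[int, str]
    contrasts: tuple[str, str]
    table: pd.DataFrame


def call_hits(
    table_vs_veh: GeneScoreTable,
    table_vs_cno_alone: GeneScoreTable,
    alpha: float = 0.05,
    top_k: Union[int, str] = "all",
) -> HitList:
    """Dual-contrast hit calling.

    A gene is a hit iff p < alpha in BOTH contrasts and — when
    ``top_k`` is an integer — it appears in the top k of both the |FCS|
    and |SNS| rankings of the treated-vs-vehicle table ("appeared in
    both scoring metrics").  Hits are ordered by |SNS|, then |FCS|,
    then symbol.
    """
    t1, t2 = table_vs_veh.table, table_vs_cno_alone.table
    if set(t1["gene"]) != set(t2["gene"]):
        raise ValueError("the two contrasts do not share the same gene universe")
    merged = t1.merge(
        t2[["gene", "p_value"]].rename(columns={"p_value": "p_value_cno_alone"}),
        on="gene",
        validate="one_to_one",
    )
    sig = (merged["p_value"] < alpha) & (merged["p_value_cno_alone"] < alpha)
    if top_k != "all":
        k = int(top_k)
        sig &= (merged["fcs_rank"] <= k) & (merged["sns_rank"] <= k)
    hits = merged[sig].copy()
    hits["_abs_sns"] = hits["sns"].abs()
    hits["_abs_fcs"] = hits["fcs"].abs()
    hits = hits.sort_values(
        ["_abs_sns", "_abs_fcs", "gene"], ascending=[False, False, True]
    ).drop(columns=["_abs_sns", "_abs_fcs"])
    return HitList(
        genes=hits["gene"].tolist(),
        alpha=alpha,
        top_k=top_k,
        contrasts=(table_vs_veh.contrast, table_vs_cno_alone.contrast),
        table=hits.reset_index(drop=True),
    )


def holm_sidak_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Šidák multiple-comparison adjustment.

    Sort ascending; adj_i = max_{j≤i} (1 − (1 − p_j)^(m − j + 1)),
    clipped at 1; returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, adjusted, _, _ = multipletests(p, method="holm-sidak")
    return adjusted
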