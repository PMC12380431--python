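"""Cross-species directional-congruence analysis.

Mouse differentially expressed genes are matched by symbol
(case-insensitively) to a human DEG table; the signs of their
expression changes are cross-tabulated in a 2×2 table (mouse up/down ×
human up/down) and the association is tested with a Pearson chi-square.
A goodness-of-fit mode testing concordant-vs-discordant counts against
50:50 is available as an alternative reading of the same question.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TestResult
from .degstats import GeneScoreTable

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceTable:
    """2×2 cross-tabulation of mouse vs human change direction.

    ``counts[i, j]``: rows are mouse direction (0 = up, 1 = down),
    columns human direction.  ``n_mouse_degs`` counts every mouse DEG,
    matched or not; ``n_found`` is the table total.
    """

    counts: np.ndarray
    n_mouse_degs: int
    n_found: int
    concordant_fraction: float
    per_gene: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValueError(f"counts must be 2×2, got {self.counts.shape}")
        if self.counts.sum() != self.n_found:
            raise ValueError("2×2 cells must sum to n_found")
        if self.n_found > self.n_mouse_degs:
            raise ValueError("n_found cannot exceed n_mouse_degs")


def _directions_from_mouse(mouse_degs) -> pd.DataFrame:
    """Normalize the mouse input to (symbol, direction) with ±1 directions."""
    if isinstance(mouse_degs, GeneScoreTable):
        df = mouse_degs.table
        direction = np.sign(df["mean_treated"] - df["mean_control"]).astype(int)
        out = pd.DataFrame({"symbol": df["gene"], "direction": direction})
    else:
        df = pd.DataFrame(mouse_degs)
        sym_col = "symbol" if "symbol" in df.columns else "gene"
        if "direction" in df.columns:
            direction = np.sign(df["direction"]).astype(int)
        elif "fcs" in df.columns:
            direction = np.sign(df["fcs"]).fillna(0).astype(int)
        elif "logFC" in df.columns:
            direction = np.sign(df["logFC"]).astype(int)
        elif "true_fold" in df.columns:
            direction = np.where(df["true_fold"] > 1.0, 1, -1)
        else:
            raise ValueError(
                "mouse table needs a direction, fcs, logFC or true_fold column"
            )
        out = pd.DataFrame({"symbol": df[sym_col], "direction": direction})
    zero = out["direction"] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} mouse genes with zero direction excluded",
            stacklevel=3,
        )
        out = out[~zero]
    return out.reset_index(drop=True)


def _directions_from_human(human_degs, fdr_max: Optional[float]) -> pd.DataFrame:
    df = pd.DataFrame(human_degs)
    sym_col = "symbol" if "symbol" in df.columns else "gene"
    if fdr_max is not None and "adj_p" in df.columns:
        df = df[df["adj_p"] < fdr_max]
    if "direction" in df.columns:
        direction = np.sign(df["direction"]).astype(int)
    elif "logFC" in df.columns:
        direction = np.sign(df["logFC"]).astype(int)
    else:
        raise ValueError("human table needs a direction or logFC column")
    out = pd.DataFrame({"symbol": df[sym_col], "direction": direction})
    zero = out["direction"] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} human genes with zero direction excluded",
            stacklevel=3,
        )
        out = out[~zero]
    return out.reset_index(drop=True)


def build_concordance_table(
    mouse_degs,
    human_degs,
    human_fdr_max: Optional[float] = None,
) -> ConcordanceTable:
    """Cross-tabulate mouse vs human change directions by gene symbol.

    Mouse genes absent from the human table count toward
    ``n_mouse_degs`` but not the 2×2 table.  Matching folds case, the
    mouse/human orthology convention for symbols.
    """
    mouse = _directions_from_mouse(mouse_degs)
    if mouse.empty:
        raise ValueError("mouse DEG table is empty")
    human = _directions_from_human(human_degs, human_fdr_max)
    human_map = {
        str(s).casefold(): int(d)
        for s, d in zip(human["symbol"], human["direction"])
    }

    counts = np.zeros((2, 2), dtype=int)
    rows = []
    for sym, m_dir in zip(mouse["symbol"], mouse["direction"]):
        h_dir = human_map.get(str(sym).casefold())
        found = h_dir is not None
        if found:
            i = 0 if m_dir > 0 else 1
            j = 0 if h_dir > 0 else 1
            counts[i, j] += 1
        rows.append(
            {
                "symbol": sym,
                "mouse_direction": int(m_dir),
                "human_direction": h_dir if found else np.nan,
                "found": found,
                "concordant": (h_dir == m_dir) if found else np.nan,
            }
        )
    n_found = int(counts.sum())
    if n_found == 0:
        raise ValueError("no mouse DEGs matched the human table")
    concordant = int(counts[0, 0] + counts[1, 1])
    return ConcordanceTable(
        counts=counts,
        n_mouse_degs=len(mouse),
        n_found=n_found,
        concordant_fraction=concordant / n_found,
        per_gene=pd.DataFrame(rows),
    )


def chi_square_2x2(
    table: Union[np.ndarray, ConcordanceTable],
    correction: bool = False,
) -> TestResult:
    """Pearson chi-square test of independence on a 2×2 table.

    Closed form χ² = n(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)), df = 1;
    ``correction`` applies Yates' continuity adjustment.  A zero row or
    column margin gives χ² = 0, p = 1 with a warning.
    """
    if isinstance(table, ConcordanceTable):
        table = table.counts
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"table must be 2×2, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    n = t.sum()
    if n < 1:
        raise ValueError("table total must be ≥ 1")
    a, b = t[0]
    c, d = t[1]
    margins = np.array([a + b, c + d, a + c, b + d])
    if np.any(margins == 0):
        warnings.warn("zero margin in 2×2 table; chi-square undefined, reporting "
                      "statistic 0, p 1", stacklevel=2)
        return TestResult(0.0, 1.0, "chi2_2x2", df=1.0, n_a=int(n))
    det = a * d - b * c
    if correction:
        det = max(abs(det) - n / 2.0, 0.0)
    chi2 = n * det**2 / margins.prod()
    p = float(stats.chi2.sf(chi2, df=1))
    method = "chi2_2x2_yates" if correction else "chi2_2x2"
    return TestResult(float(chi2), p, method, df=1.0, n_a=int(n))


def chi_square_goodness_of_fit(concordant: int, discordant: int) -> TestResult:
    """Concordant-vs-discordant counts tested against a 50:50 split."""
    if concordant < 0 or discordant < 0:
        raise ValueError("counts must be nonnegative")
    n = concordant + discordant
    if n < 1:
        raise ValueError("need at least one matched gene")
    chi2, p = stats.chisquare([concordant, discordant])
    return TestResult(float(chi2), float(p), "chi2_gof_50_50", df=1.0, n_a=n)


def congruence_report(
    mouse_degs,
    human_degs,
    alpha: float = 0.05,
    mode: str = "independence",
    correction: bool = False,
    human_fdr_max: Optional[float] = None,
) -> dict:
    """Full congruence analysis: table, chi-square, per-gene listing.

    ``mode="independence"`` (default) tests the 2×2 sign table;
    ``mode="goodness_of_fit"`` tests concordant vs discordant counts
    against 50:50.
    """
    if mode not in ("independence", "goodness_of_fit"):
        raise ValueError(f"mode must be 'independence' or 'goodness_of_fit', got {mode!r}")
    table = build_concordance_table(mouse_degs, human_degs, human_fdr_max)
    if mode == "independence":
        test = chi_square_2x2(table, correction=correction)
    else:
        concordant = int(table.counts[0, 0] + table.counts[1, 1])
        test = chi_square_goodness_of_fit(concordant, table.n_found - concordant)
    return {
        "n_mouse_degs": table.n_mouse_degs,
        "n_found": table.n_found,
        "table": table.counts.tolist(),
        "concordant_fraction": table.concordant_fraction,
        "chi_square": test.statistic,
        "p_value": test.p_value,
        "mode": mode,
        "significant": bool(test.p_value < alpha),
        "alpha": alpha,
        "per_gene": table.per_gene,
    }
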