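"""Group-level paired comparisons of the connection metrics.

Five comparison families mirror the result-table structure of the analysis:

1. Ratio, standard vs deviant, within each state;
2. S_all and L_all, awake vs anesthesia, within each condition;
3. L_all and S_all, standard vs deviant, within each state;
4. per-area L_k, standard vs deviant, within each state;
5. per-area L_k, awake vs anesthesia, within each condition.

All tests are classical two-sided paired t-tests at alpha = 0.05 with no
multiple-testing correction by default (matching the original design of 14
uncorrected per-area tests); Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import AREA_CODES
from .config import ANESTHESIA, AWAKE, DEVIANT, STANDARD, ConfigError

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class GroupComparisonResult:
    label: str
    mean_x: float
    std_x: float
    mean_y: float
    std_y: float
    t: float
    df: int
    p: float
    significant: bool

    def as_row(self) -> dict:
        return {"comparison": self.label, "mean_x": self.mean_x,
                "std_x": self.std_x, "mean_y": self.mean_y,
                "std_y": self.std_y, "t": self.t, "df": self.df,
                "p": self.p, "significant": self.significant}


def paired_ttest(x, y, label: str = "",
                 alpha: float = ALPHA) -> GroupComparisonResult:
    """Two-sided paired t-test on per-subject values (aligned by position).

    Zero variance of the differences leaves t undefined and raises; unequal
    lengths (missing subjects) raise rather than silently dropping.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigError(f"paired samples differ in length: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 2:
        raise ConfigError("paired t-test needs at least 2 subjects")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ConfigError("non-finite values in paired samples")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ConfigError("zero variance of paired differences: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparisonResult(label, float(x.mean()), float(x.std(ddof=1)),
                                 float(y.mean()), float(y.std(ddof=1)),
                                 float(t), df, float(p), bool(p < alpha))


_CELLS = [(STANDARD, AWAKE), (DEVIANT, AWAKE),
          (STANDARD, ANESTHESIA), (DEVIANT, ANESTHESIA)]


def _check_balanced(metrics: pd.DataFrame) -> list:
    subjects = sorted(metrics["subject"].unique())
    missing = []
    for s in subjects:
        for cond, state in _CELLS:
            sel = metrics[(metrics.subject == s) & (metrics.condition == cond)
                          & (metrics.state == state)]
            if len(sel) != 1:
                missing.append((s, cond, state))
    if missing:
        raise ConfigError(f"unbalanced design; missing/duplicate cells: "
                          f"{missing[:8]}")
    return subjects


def _cell(metrics: pd.DataFrame, subjects, cond: str, state: str,
          col: str) -> np.ndarray:
    sel = metrics[(metrics.condition == cond) & (metrics.state == state)]
    sel = sel.set_index("subject").loc[subjects]
    return sel[col].to_numpy(dtype=float)


def build_comparison_tables(metrics: pd.DataFrame, alpha: float = ALPHA,
                            bh_correction: bool = False) -> dict[str, pd.DataFrame]:
    """Build the five comparison tables from per-subject metrics.

    ``metrics`` is long-format with one row per subject x condition x state
    and columns subject, condition, state, ratio, l_all, s_all and
    L_<area> for each of the 14 areas. Every subject must appear in all
    four condition-state cells.
    """
    subjects = _check_balanced(metrics)
    area_cols = [f"L_{a}" for a in AREA_CODES if f"L_{a}" in metrics.columns]

    def test(col, cond_x, state_x, cond_y, state_y, label):
        x = _cell(metrics, subjects, cond_x, state_x, col)
        y = _cell(metrics, subjects, cond_y, state_y, col)
        try:
            return paired_ttest(x, y, label, alpha)
        except ConfigError as err:
            if "zero variance" not in str(err):
                raise
            # a comparison between literally identical cells (possible in
            # fully deterministic simulations) is reported as undecidable,
            # not as an error that aborts the other tables
            logger.warning("%s: %s; reporting NaN", label, err)
            return GroupComparisonResult(label, float(x.mean()),
                                         float(x.std(ddof=1)),
                                         float(y.mean()),
                                         float(y.std(ddof=1)),
                                         float("nan"), len(x) - 1,
                                         float("nan"), False)

    tables: dict[str, pd.DataFrame] = {}

    rows = [test("ratio", STANDARD, st, DEVIANT, st,
                 f"{st}: Ratio standard vs deviant")
            for st in (AWAKE, ANESTHESIA)]
    tables["ratio_by_condition"] = pd.DataFrame(r.as_row() for r in rows)

    rows = [test(col, cond, AWAKE, cond, ANESTHESIA,
                 f"{cond} {col}: awake vs anesthesia")
            for col in ("s_all", "l_all") for cond in (STANDARD, DEVIANT)]
    tables["global_by_state"] = pd.DataFrame(r.as_row() for r in rows)

    rows = [test(col, STANDARD, st, DEVIANT, st,
                 f"{st} {col}: standard vs deviant")
            for st in (AWAKE, ANESTHESIA) for col in ("l_all", "s_all")]
    tables["global_by_condition"] = pd.DataFrame(r.as_row() for r in rows)

    rows = [test(col, STANDARD, st, DEVIANT, st,
                 f"{st} {col}: standard vs deviant")
            for st in (AWAKE, ANESTHESIA) for col in area_cols]
    tables["area_long_by_condition"] = pd.DataFrame(r.as_row() for r in rows)

    rows = [test(col, cond, AWAKE, cond, ANESTHESIA,
                 f"{cond} {col}: awake vs anesthesia")
            for cond in (STANDARD, DEVIANT) for col in area_cols]
    tables["area_long_by_state"] = pd.DataFrame(r.as_row() for r in rows)

    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        logger.info("applying Benjamini-Hochberg correction per table")
        for name, tab in tables.items():
            rej, p_adj, _, _ = multipletests(tab["p"], alpha=alpha,
                                             method="fdr_bh")
            tab["p_adjusted"] = p_adj
            tab["significant"] = rej
    return tables
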