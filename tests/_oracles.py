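"""Independent oracles used by the test suite.

These deliberately take different computational routes than the package:
statsmodels OLS ANOVA for mean squares, pingouin for the ICC family,
direct summation for agreement.  They exist only to cross-check the
implementation and must stay independent of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def anova_mean_squares_oracle(x: np.ndarray) -> dict:
    """Two-way and one-way mean squares via statsmodels OLS ANOVA."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n, k = x.shape
    df = pd.DataFrame({
        "y": x.ravel(),
        "subject": np.repeat(np.arange(n), k).astype(str),
        "session": np.tile(np.arange(k), n).astype(str),
    })
    two_way = sm.stats.anova_lm(ols("y ~ C(subject) + C(session)", df).fit(), typ=2)
    one_way = sm.stats.anova_lm(ols("y ~ C(subject)", df).fit(), typ=2)
    ms = lambda tab, row: tab.loc[row, "sum_sq"] / tab.loc[row, "df"]
    return {
        "MSR": ms(two_way, "C(subject)"),
        "MSC": ms(two_way, "C(session)"),
        "MSE": ms(two_way, "Residual"),
        "MSW": ms(one_way, "Residual"),
    }


def icc_oracle(x: np.ndarray) -> dict:
    """ICC(1), ICC(A,1), ICC(C,1) estimates via pingouin."""
    import pingouin as pg

    n, k = x.shape
    df = pd.DataFrame({
        "y": x.ravel(),
        "subject": np.repeat(np.arange(n), k),
        "session": np.tile(np.arange(k), n),
    })
    tab = pg.intraclass_corr(
        df, targets="subject", raters="session", ratings="y"
    ).set_index("Type")
    return {
        "oneway": float(tab.loc["ICC(1,1)", "ICC"]),
        "agreement": float(tab.loc["ICC(A,1)", "ICC"]),
        "consistency": float(tab.loc["ICC(C,1)", "ICC"]),
    }
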