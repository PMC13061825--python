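"""Model/Results front end.

`CfaModel` is constructed from data (or a covariance matrix) and a
`CfaModelSpec`; `fit()` returns a `CfaResults` object carrying the
estimates, fit statistics and the robust test battery.  Nested
comparisons are driven by `NestedModelComparison` over two results
sharing the same data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gof import TestResult, run_all_tests, t_ml, t_rls
from .model import CfaModelSpec, FittedModel, fit_ntml, sample_cov
from .nested import compare_nested, nested_pvalues, sb_2001_trace


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [r.label for r in results],
            "procedure": [r.procedure for r in results],
            "base": [r.base for r in results],
            "gamma_variant": [r.gamma_variant for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "flags": [r.flags for r in results],
        }
    )


class CfaModel:
    """A confirmatory factor model bound to data.

    Parameters
    ----------
    data : array-like or list of array-like
        One n x p matrix per group (a single matrix for G = 1).
    spec : CfaModelSpec
    """

    def __init__(self, data, spec: CfaModelSpec):
        if isinstance(data, (np.ndarray, pd.DataFrame)):
            data = [data]
        self.data = [np.asarray(X, dtype=float) for X in data]
        if len(self.data) != spec.n_groups:
            raise ValueError("number of data groups != spec groups")
        self.spec = spec

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: CfaModelSpec,
                       group_col: str | None = None, columns=None):
        if group_col is None:
            X = df[columns] if columns is not None else df
            return cls([X.to_numpy(dtype=float)], spec)
        groups = sorted(df[group_col].unique())
        cols = columns if columns is not None else [c for c in df.columns
                                                    if c != group_col]
        data = [df.loc[df[group_col] == g, cols].to_numpy(dtype=float)
                for g in groups]
        return cls(data, spec)

    def fit(self, start=None, **kwargs) -> "CfaResults":
        S_list = [sample_cov(X) for X in self.data]
        N_list = [X.shape[0] for X in self.data]
        fitted = fit_ntml(S_list, N_list, self.spec, start=start, **kwargs)
        return CfaResults(self, fitted)


class CfaResults:
    """NTML solution with fit statistics and the robust test battery."""

    def __init__(self, model: CfaModel, fitted: FittedModel):
        self.model = model
        self.fitted = fitted

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fitted.theta, index=self.fitted.spec.param_names)

    @property
    def df(self) -> int:
        return self.fitted.df

    @property
    def converged(self) -> bool:
        return self.fitted.converged

    @property
    def t_ml(self) -> float:
        return t_ml(self.fitted)

    @property
    def t_rls(self) -> float:
        return t_rls(self.fitted)

    def gof_tests(self, methods=None,
                  gamma_variants=("biased", "unbiased")) -> pd.DataFrame:
        res = run_all_tests(self.fitted, self.model.data, methods=methods,
                            gamma_variants=gamma_variants)
        return results_to_frame(res)

    def summary(self) -> str:
        f = self.fitted
        lines = [
            "Confirmatory factor model (NTML)",
            "=" * 40,
            f"groups:            {f.spec.n_groups}",
            f"observed vars:     {f.spec.n_vars}",
            f"free parameters:   {f.spec.q}",
            f"degrees of freedom:{f.df:>6d}",
            f"total N:           {f.n_total}",
            f"converged:         {f.converged} ({f.n_iter} iterations)",
            f"F_min:             {f.F_min:.6f}",
            f"T_ML:              {self.t_ml:.3f}",
            f"T_RLS:             {self.t_rls:.3f}",
        ]
        return "\n".join(lines)


class NestedModelComparison:
    """Robust difference testing of a constrained model M0 against M1."""

    def __init__(self, results0: CfaResults, results1: CfaResults,
                 ud_method: str = "2000"):
        if results0.model.data is not results1.model.data:
            shapes0 = [X.shape for X in results0.model.data]
            shapes1 = [X.shape for X in results1.model.data]
            if shapes0 != shapes1:
                raise ValueError("the two results must share the same data")
        self.results0 = results0
        self.results1 = results1
        self.ud_method = ud_method

    def pvalues(self, methods=("ALL", "pEBA2", "pEBA4", "pEBA6", "pEBAdf",
                               "pOLS2", "SB", "SS", "SF"),
                gamma_variants=("biased", "unbiased"),
                include_sb_2001: bool = False) -> pd.DataFrame:
        out = []
        X = self.results1.model.data
        for variant in gamma_variants:
            cmp = compare_nested(self.results0.fitted, self.results1.fitted,
                                 X, ud_method=self.ud_method,
                                 gamma_variant=variant)
            out.extend(nested_pvalues(cmp, methods=methods))
            if include_sb_2001:
                cmp01 = (cmp if self.ud_method == "2001" else
                         compare_nested(self.results0.fitted,
                                        self.results1.fitted, X,
                                        ud_method="2001",
                                        gamma_variant=variant))
                out.append(sb_2001_trace(cmp01))
        return results_to_frame(out)

    def summary(self) -> str:
        from .nested import t_diff
        f0, f1 = self.results0.fitted, self.results1.fitted
        return "\n".join([
            "Nested model comparison",
            "=" * 40,
            f"df0, df1:   {f0.df}, {f1.df}",
            f"T_D (ML):   {t_diff(f0, f1, 'T_ML'):.3f}",
            f"T_D (RLS):  {t_diff(f0, f1, 'T_RLS'):.3f}",
            f"U_D method: {self.ud_method}",
        ])
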