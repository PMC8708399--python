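"""Fixed-effects factor analysis of virulence scores.

The scores are modelled by ordinary least squares on the categorical
factors phage, bacterium and MOI plus all two-way interactions, with a
normally distributed error term.  Effects are judged by F-tests on
sequential (Type I) sums of squares, main effects entered before
interactions; for the (near-)balanced designs of a plate study the term
order is immaterial.  MOI is always treated as a 3-level categorical
factor, never as a covariate.

The model follows the ``Model.fit() -> Results`` idiom: build a
:class:`GrowthFactorModel` from a scores table, call :meth:`~GrowthFactorModel.fit`
and read the :class:`AnovaTable` it returns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaTable", "GrowthFactorModel", "TERM_ORDER"]

TERM_ORDER = (
    "phage",
    "bacterium",
    "moi",
    "phage:bacterium",
    "phage:moi",
    "bacterium:moi",
)

_FACTOR_COLS = {"phage": "phage_id", "bacterium": "bacterium_id", "moi": "moi"}


@dataclass(frozen=True)
class AnovaTable:
    """Sequential-SS ANOVA results: one row per term plus the residual."""

    terms: tuple[str, ...]
    df: tuple[int, ...]
    ss: tuple[float, ...]
    f: tuple[float, ...]
    p: tuple[float, ...]
    df_resid: int
    ss_resid: float
    n_obs: int
    response: str = "score"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"term": self.terms, "df": self.df, "sum_sq": self.ss,
             "F": self.f, "p_value": self.p}
        )
        resid = pd.DataFrame(
            {"term": ["residual"], "df": [self.df_resid],
             "sum_sq": [self.ss_resid], "F": [np.nan], "p_value": [np.nan]}
        )
        return pd.concat([df, resid], ignore_index=True)

    def summary(self) -> str:
        lines = [f"Fixed-effects ANOVA ({self.response}, n={self.n_obs}, Type I SS)",
                 f"{'term':<18}{'df':>6}{'sum_sq':>14}{'F':>10}{'p':>12}"]
        for t, d, s, f_, p_ in zip(self.terms, self.df, self.ss, self.f, self.p):
            p_str = f"{p_:.3g}" if p_ >= 1e-4 else "<0.0001"
            lines.append(f"{t:<18}{d:>6}{s:>14.3f}{f_:>10.1f}{p_str:>12}")
        lines.append(f"{'residual':<18}{self.df_resid:>6}{self.ss_resid:>14.3f}")
        return "\n".join(lines)


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment coding: indicator columns for levels 1..n_levels-1."""
    out = np.zeros((codes.size, n_levels - 1))
    for lvl in range(1, n_levels):
        out[codes == lvl, lvl - 1] = 1.0
    return out


class GrowthFactorModel:
    """OLS of a score on phage + bacterium + MOI and two-way interactions."""

    def __init__(self, response: np.ndarray, phage, bacterium, moi,
                 response_name: str = "score"):
        y = np.asarray(response, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response must be finite")
        factors = {}
        for name, vals in (("phage", phage), ("bacterium", bacterium), ("moi", moi)):
            codes, levels = pd.factorize(pd.Series(vals).astype(str), sort=True)
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} needs >= 2 observed levels")
            factors[name] = (np.asarray(codes), len(levels))
        self.endog = y
        self.response_name = response_name
        self._factors = factors
        self._build_design()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       response: str = "virulence_score") -> "GrowthFactorModel":
        """Build from a scores table with phage_id / bacterium_id / moi columns."""
        return cls(
            df[response].to_numpy(),
            df["phage_id"], df["bacterium_id"], df["moi"],
            response_name=response,
        )

    def _build_design(self):
        n = self.endog.size
        mains = {name: _dummies(codes, k) for name, (codes, k) in self._factors.items()}
        blocks = [np.ones((n, 1))]
        self.term_slices: dict[str, slice] = {}
        pos = 1
        for term in TERM_ORDER:
            if ":" in term:
                a, b = term.split(":")
                # column-wise products of the two main-effect codings
                block = (mains[a][:, :, None] * mains[b][:, None, :]).reshape(n, -1)
            else:
                block = mains[term]
            blocks.append(block)
            self.term_slices[term] = slice(pos, pos + block.shape[1])
            pos += block.shape[1]
        self.exog = np.hstack(blocks)
        if self.exog.shape[1] >= n:
            raise ValueError(
                "design is saturated or over-parameterised "
                f"({self.exog.shape[1]} columns, {n} observations)"
            )
        q, r = np.linalg.qr(self.exog)
        diag = np.abs(np.diag(r))
        bad = diag < 1e-8 * diag.max()
        if bad.any():
            aliased = sorted(
                {t for t, sl in self.term_slices.items()
                 if bad[sl.start:sl.stop].any()}
            )
            raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
        self._q = q

    def fit(self) -> AnovaTable:
        return self._anova(self.endog)

    def fit_many(self, responses: np.ndarray) -> np.ndarray:
        """p-values for many response vectors on the same design.

        ``responses`` is (n_draws, n_obs); returns (n_draws, n_terms) of
        F-test p-values in :data:`TERM_ORDER`.  Used for null-calibration
        simulations, where refitting the design each draw would dominate.
        """
        Y = np.asarray(responses, dtype=float)
        C = Y @ self._q                          # (draws, p) projections
        tot = np.einsum("ij,ij->i", Y, Y)
        expl = np.einsum("ij,ij->i", C, C)
        ss_res = tot - expl
        n = Y.shape[1]
        df_res = n - self.exog.shape[1]
        out = np.empty((Y.shape[0], len(TERM_ORDER)))
        for j, term in enumerate(TERM_ORDER):
            sl = self.term_slices[term]
            ss = np.einsum("ij,ij->i", C[:, sl], C[:, sl])
            df = sl.stop - sl.start
            f = (ss / df) / (ss_res / df_res)
            out[:, j] = stats.f.sf(f, df, df_res)
        return out

    def _anova(self, y: np.ndarray) -> AnovaTable:
        c = self._q.T @ y
        ss_res = float(y @ y - c @ c)
        n = y.size
        df_res = n - self.exog.shape[1]
        terms, dfs, sss, fs, ps = [], [], [], [], []
        for term in TERM_ORDER:
            sl = self.term_slices[term]
            ss = float(c[sl] @ c[sl])
            df = sl.stop - sl.start
            f = (ss / df) / (ss_res / df_res)
            terms.append(term)
            dfs.append(df)
            sss.append(ss)
            fs.append(f)
            ps.append(float(stats.f.sf(f, df, df_res)))
        return AnovaTable(
            terms=tuple(terms), df=tuple(dfs), ss=tuple(sss), f=tuple(fs),
            p=tuple(ps), df_resid=df_res, ss_resid=ss_res, n_obs=n,
            response=self.response_name,
        )
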