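"""Population-level statistics for the mismatch decomposition.

Station-level inference uses distribution-free tests (Friedman across the
three matched conditions with Fisher's-LSD pairwise comparisons on rank
sums, Wilcoxon signed-rank, rank-sum), linear models for the
prediction-error index (hierarchy × nucleus; sound level × deviant
direction), Benjamini-Hochberg FDR control, and power-based minimum sample
sizes for a one-sample t-test on the index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols, rlm
from statsmodels.robust.norms import TukeyBiweight
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestPower

__all__ = [
    "FriedmanResult",
    "ModelFit",
    "SampleSizeResult",
    "friedman_conditions",
    "fit_hierarchy_model",
    "fit_spl_model",
    "bh_fdr",
    "min_sample_size",
    "signed_rank_test",
    "rank_sum_test",
    "correlate",
]

_PAIRS = (("DEV", "STD"), ("CTR", "STD"), ("DEV", "CTR"))


@dataclass
class FriedmanResult:
    """Friedman omnibus plus Fisher's-LSD pairwise p-values on rank sums."""

    statistic: float
    p_value: float
    n: int
    pairwise_p: dict[tuple[str, str], float]
    pairwise_z: dict[tuple[str, str], float]
    median_diff: dict[tuple[str, str], float]


def friedman_conditions(
    dev: np.ndarray, std: np.ndarray, ctr: np.ndarray
) -> FriedmanResult:
    """Within-station comparison of the three matched conditions.

    Each neuron/tone point is a block; conditions are ranked within blocks.
    The post hoc comparisons follow Fisher's least-significant-difference
    logic on the rank sums, with standard error sqrt(n·k·(k+1)/6) and no
    further multiplicity correction.
    """
    dev, std, ctr = (np.asarray(x, dtype=float) for x in (dev, std, ctr))
    if not dev.shape == std.shape == ctr.shape or dev.ndim != 1:
        raise ValueError("conditions must be matched 1-D samples")
    n = dev.size
    if n < 2:
        raise ValueError("need at least two matched points")
    stat, p = sps.friedmanchisquare(dev, std, ctr)
    mat = np.column_stack([dev, std, ctr])
    ranks = sps.rankdata(mat, axis=1)
    sums = dict(zip(("DEV", "STD", "CTR"), ranks.sum(axis=0)))
    k = 3
    se = math.sqrt(n * k * (k + 1) / 6.0)
    vals = {"DEV": dev, "STD": std, "CTR": ctr}
    zd, pd_, md = {}, {}, {}
    for a, b in _PAIRS:
        z = (sums[a] - sums[b]) / se
        zd[(a, b)] = z
        pd_[(a, b)] = 2.0 * sps.norm.sf(abs(z))
        md[(a, b)] = float(np.median(vals[a] - vals[b]))
    return FriedmanResult(
        statistic=float(stat), p_value=float(p), n=n,
        pairwise_p=pd_, pairwise_z=zd, median_diff=md,
    )


@dataclass
class ModelFit:
    """Linear-model coefficients with standard errors and an ANOVA table."""

    params: pd.Series
    bse: pd.Series
    anova: pd.DataFrame | None
    robust: bool
    model: object = field(repr=False, default=None)

    def predict_sum(self, terms: list[str]) -> float:
        """Sum of the named coefficients (a fitted cell mean for dummy
        coding)."""
        return float(sum(self.params[t] for t in terms))


_HIER_RENAME = {
    "Intercept": "const",
    'C(hierarchy, Treatment("L"))[T.NL]': "NL",
    'C(nucleus, Treatment("IC"))[T.MGB]': "MGB",
    'C(nucleus, Treatment("IC"))[T.AC]': "AC",
    'C(hierarchy, Treatment("L"))[T.NL]:C(nucleus, Treatment("IC"))[T.MGB]': "NL:MGB",
    'C(hierarchy, Treatment("L"))[T.NL]:C(nucleus, Treatment("IC"))[T.AC]': "NL:AC",
    'C(hierarchy, Treatment("L"))': "hierarchy",
    'C(nucleus, Treatment("IC"))': "nucleus",
    'C(hierarchy, Treatment("L")):C(nucleus, Treatment("IC"))': "hierarchy:nucleus",
}

_SPL_RENAME = {
    "Intercept": "const",
    'C(direction, Treatment("descending"))[T.ascending]': "ascending",
    "spl_bels": "SPL",
    'C(direction, Treatment("descending"))[T.ascending]:spl_bels': "ascending:SPL",
    'C(direction, Treatment("descending"))': "direction",
    'C(direction, Treatment("descending")):spl_bels': "direction:SPL",
}


def _fit(df: pd.DataFrame, formula: str, rename: dict, robust: bool) -> ModelFit:
    if robust:
        res = rlm(formula, data=df, M=TukeyBiweight()).fit()
        anova = None
    else:
        res = ols(formula, data=df).fit()
        anova = anova_lm(res, typ=2)
        anova.index = [rename.get(i, i) for i in anova.index]
    params = res.params.rename(rename)
    bse = res.bse.rename(rename)
    return ModelFit(params=params, bse=bse, anova=anova, robust=robust, model=res)


def fit_hierarchy_model(points: pd.DataFrame, robust: bool = False) -> ModelFit:
    """iPE ~ hierarchy × nucleus, dummy-coded with L and IC as reference.

    ``points`` needs columns ``ipe``, ``hierarchy`` (L/NL), ``nucleus``
    (IC/MGB/AC).  The reported terms are const, NL, MGB, AC, NL:MGB, NL:AC;
    the ANOVA (type-II sums of squares) gives F and p for hierarchy,
    nucleus, and their interaction.
    """
    _require(points, {"ipe", "hierarchy", "nucleus"})
    cells = points.groupby(["hierarchy", "nucleus"], observed=True).size()
    if len(cells) < 6:
        import warnings

        warnings.warn("empty hierarchy×nucleus cell: design is rank deficient")
    formula = 'ipe ~ C(hierarchy, Treatment("L")) * C(nucleus, Treatment("IC"))'
    return _fit(points, formula, _HIER_RENAME, robust)


def fit_spl_model(points: pd.DataFrame, robust: bool = False) -> ModelFit:
    """iPE ~ direction × SPL (SPL in Bels; descending is the reference).

    ``points`` needs columns ``ipe``, ``direction``
    (ascending/descending), ``spl_bels`` (dB SPL / 10).
    """
    _require(points, {"ipe", "direction", "spl_bels"})
    if points["spl_bels"].nunique() < 2:
        import warnings

        warnings.warn("single SPL level: SPL slope is rank deficient")
    formula = 'ipe ~ C(direction, Treatment("descending")) * spl_bels'
    return _fit(points, formula, _SPL_RENAME, robust)


def bh_fdr(p_values, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure at FDR level ``q``.

    Returns (reject flags, adjusted p-values); flags are monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class SampleSizeResult:
    """Minimum n for 0.8 power on the prediction-error index."""

    n: int
    effect_size: float
    degenerate: bool = False


def min_sample_size(
    values,
    power: float = 0.8,
    alpha: float = 0.05,
    effect_floor: float = 0.05,
) -> SampleSizeResult:
    """Smallest n giving the target power for a two-sided one-sample t-test.

    The assumed effect is max(effect_floor, |mean|) against zero at the
    sample SD, mirroring the usual power planning for the index.  Zero
    variance is flagged degenerate (any n ≥ 2 suffices).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    sd = float(np.std(x, ddof=1))
    effect = max(effect_floor, abs(float(np.mean(x))))
    if sd == 0.0:
        return SampleSizeResult(n=2, effect_size=math.inf, degenerate=True)
    d = effect / sd

    def _power(n: int) -> float:
        crit = sps.t.ppf(1 - alpha / 2, n - 1)
        nc = d * math.sqrt(n)
        return float(sps.nct.sf(crit, n - 1, nc) + sps.nct.cdf(-crit, n - 1, nc))

    # the t-test needs n >= 2; huge effects already reach the target there
    if _power(2) >= power:
        return SampleSizeResult(n=2, effect_size=d)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n = TTestPower().solve_power(
            effect_size=d, alpha=alpha, power=power, alternative="two-sided"
        )
    n = float(np.atleast_1d(n)[0])
    if not math.isfinite(n):  # solver failure: direct scan on the power curve
        k = 2
        while _power(k) < power and k < 10_000_000:
            k = max(k + 1, int(k * 1.5))
        while k > 2 and _power(k - 1) >= power:
            k -= 1
        n = k
    return SampleSizeResult(n=max(2, int(math.ceil(n))), effect_size=d)


def signed_rank_test(x, y=None) -> tuple[float, float]:
    """Wilcoxon signed-rank test (paired, or one sample against zero)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if np.all(d == 0):
        return 0.0, 1.0
    stat, p = sps.wilcoxon(d)
    return float(stat), float(p)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when both samples are small and tie-free, normal approximation
    with tie correction otherwise.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(stat), float(p)


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Rank (or Pearson) correlation with its p-value."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must pair up")
    if x.size < 3:
        raise ValueError("need at least three pairs")
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(rho), float(p)


def _require(df: pd.DataFrame, cols: set[str]) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
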