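"""Spearman correlation stage: all parameter pairs, significance counting
across electrodes, and the ROI amplitude-vs-slope table.

The statistic is fixed to Spearman (the parameter marginals are generally
non-normal); a normality check is still run and logged.  Counting is
deliberately simple: per parameter pair and ISI condition, how many of the
electrodes show p < 0.1 (combined) and how many p < 0.05 (strict).  No
multiple-comparison correction is applied — the counts themselves are the
robustness heuristic — and the family size is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .extraction import PARAMETER_NAMES

logger = logging.getLogger(__name__)

#: Parameters entering the correlations as absolute values.
ABS_PARAMETERS = frozenset({"amplitude", "ampavg", "upslope", "downslope"})

DEFAULT_ALPHA_STRICT = 0.05
DEFAULT_ALPHA_COMBINED = 0.1
MIN_SUBJECTS = 5


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n_used: int
    ok: bool
    reason: str | None = None

    @classmethod
    def missing(cls, n_used: int, reason: str) -> "SpearmanResult":
        return cls(math.nan, math.nan, n_used, False, reason)


def normality_check(values: Sequence[float]) -> NormalityResult:
    """Lilliefors-corrected KS test against a normal with estimated moments.

    Degenerate (constant) input is flagged with an undefined p-value rather
    than raising.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError(f"need >= 5 finite values, got {x.size}")
    if np.ptp(x) == 0:
        return NormalityResult(math.nan, math.nan, int(x.size), degenerate=True)
    stat, p = lilliefors(x, dist="norm")
    return NormalityResult(float(stat), float(p), int(x.size))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    *,
    min_n: int = MIN_SUBJECTS,
    method: str = "t",
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> SpearmanResult:
    """Spearman rank correlation with pairwise-complete handling.

    rho is the Pearson correlation of average-ranked values; the two-tailed
    p-value comes from the t-approximation with ``n - 2`` degrees of freedom
    (``method="t"``) or from a permutation distribution of rho
    (``method="permutation"``; exhaustive for n <= 8, Monte-Carlo above).

    Pairs with a non-finite member are dropped; fewer than ``min_n``
    remaining pairs, or zero rank variance in either variable, yields a
    missing (flagged) result instead of an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < min_n:
        return SpearmanResult.missing(n, f"n_used={n} < {min_n}")

    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return SpearmanResult.missing(n, "zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "t":
        p = _t_pvalue(rho, n)
    elif method == "permutation":
        p = _permutation_pvalue(rx, ry, rho, n_resamples, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpearmanResult(rho, p, n, True)


def _t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _permutation_pvalue(
    rx: np.ndarray, ry: np.ndarray, rho: float, n_resamples: int, seed: int | None
) -> float:
    n = rx.size
    sx = (rx - rx.mean()) / rx.std()
    sy = (ry - ry.mean()) / ry.std()

    def corr(perm_y: np.ndarray) -> float:
        return float(np.mean(sx * perm_y))

    target = abs(rho) - 1e-12
    if n <= 8:  # exhaustive
        count = sum(abs(corr(sy[list(p)])) >= target for p in permutations(range(n)))
        total = math.factorial(n)
        return count / total
    rng = np.random.default_rng(seed)
    count = sum(
        abs(corr(sy[rng.permutation(n)])) >= target for _ in range(n_resamples)
    )
    return (count + 1) / (n_resamples + 1)


def parameter_pairs(
    parameters: Sequence[str] = PARAMETER_NAMES,
) -> list[tuple[str, str]]:
    """All unordered parameter pairs, in canonical listing order."""
    return list(combinations(parameters, 2))


def _prepared_values(params: pd.DataFrame, name: str) -> pd.Series:
    values = params[name].astype(float)
    if name in ABS_PARAMETERS:
        values = values.abs()
    return values


def all_pairs_correlations(
    params: pd.DataFrame,
    *,
    parameters: Sequence[str] = PARAMETER_NAMES,
    channel_col: str = "channel",
    min_n: int = MIN_SUBJECTS,
) -> pd.DataFrame:
    """Spearman rho/p for every parameter pair × ISI × channel.

    ``params`` is the extraction table (one row per subject × ISI ×
    channel).  Rows with ``valid == False`` are dropped first; within each
    cell, pairs with missing values are dropped pairwise.  Magnitude
    parameters are converted to absolute values here and nowhere else.

    Returns a long DataFrame: param_a, param_b, isi_s, channel, rho, p,
    n_used, ok, reason.
    """
    pairs = parameter_pairs(parameters)
    data = params[params["valid"]].copy() if "valid" in params else params.copy()
    for name in parameters:
        data[name] = _prepared_values(data, name)

    n_cells = data.groupby(["isi_s", channel_col], sort=True).ngroups
    logger.info(
        "correlation family: %d pairs x %d ISI-channel cells = %d tests "
        "(no multiplicity correction applied)",
        len(pairs), n_cells, len(pairs) * n_cells,
    )

    rows = []
    for (isi, channel), grp in params.groupby(["isi_s", channel_col], sort=True):
        sub = data.loc[grp.index.intersection(data.index)]
        for a, b in pairs:
            if len(sub) == 0:
                res = SpearmanResult.missing(0, "no valid subjects")
            else:
                res = spearman(sub[a].to_numpy(), sub[b].to_numpy(), min_n=min_n)
            rows.append(
                {
                    "param_a": a,
                    "param_b": b,
                    "isi_s": float(isi),
                    "channel": channel,
                    "rho": res.rho,
                    "p": res.p,
                    "n_used": res.n_used,
                    "ok": res.ok,
                    "reason": res.reason,
                }
            )
    return pd.DataFrame(rows)


def count_table(
    results: pd.DataFrame,
    *,
    alpha_strict: float = DEFAULT_ALPHA_STRICT,
    alpha_combined: float = DEFAULT_ALPHA_COMBINED,
) -> pd.DataFrame:
    """Electrode counts of (marginally) significant correlations.

    Per parameter pair × ISI: ``count_combined`` = number of channels with
    p < ``alpha_combined``; ``count_strict`` = number with p <
    ``alpha_strict``.  Counting ignores the correlation sign, but positive/
    negative tallies of the counted channels are carried along.
    """
    if not alpha_strict < alpha_combined:
        raise ValueError("alpha_strict must be below alpha_combined")
    rows = []
    for (a, b, isi), grp in results.groupby(["param_a", "param_b", "isi_s"], sort=True):
        p = grp["p"].to_numpy()
        hit = p < alpha_combined  # NaN compares False
        rows.append(
            {
                "param_a": a,
                "param_b": b,
                "isi_s": float(isi),
                "count_combined": int(hit.sum()),
                "count_strict": int((p < alpha_strict).sum()),
                "n_channels": int(len(grp)),
                "n_positive": int((hit & (grp["rho"].to_numpy() > 0)).sum()),
                "n_negative": int((hit & (grp["rho"].to_numpy() < 0)).sum()),
            }
        )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def roi_analysis(
    roi_params: pd.DataFrame,
    *,
    pairs: Sequence[tuple[str, str]] = (
        ("amplitude", "upslope"),
        ("amplitude", "downslope"),
    ),
    min_n: int = MIN_SUBJECTS,
) -> pd.DataFrame:
    """Amplitude-vs-slope Spearman correlations on ROI-averaged parameters.

    ``roi_params`` is an extraction table whose ``channel`` column holds
    region names.  Returns region × ISI × pair rows with rho, p, n_used and
    ``stars`` ('*' p < 0.05, '**' p < 0.01).
    """
    results = all_pairs_correlations(
        roi_params,
        parameters=sorted({name for pair in pairs for name in pair},
                          key=PARAMETER_NAMES.index),
        min_n=min_n,
    )
    wanted = {tuple(sorted(p, key=PARAMETER_NAMES.index)) for p in pairs}
    mask = results.apply(
        lambda r: (r["param_a"], r["param_b"]) in wanted, axis=1
    )
    out = results[mask].rename(columns={"channel": "region"}).copy()
    out["stars"] = out["p"].map(significance_stars)
    return out.reset_index(drop=True)
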