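"""Heterosis and reciprocal-cross analysis of predicted group means.

Percent heterosis for a crossbred group is the percentage by which its
predicted mean exceeds the parental mean (the average of the two pure-line
predicted means):

    H% = 100 * (crossbred mean - parental mean) / parental mean

and the reciprocal-cross difference is the gap between the two reciprocal
crossbreds on the same scale:

    RC% = 100 * (WY mean - YW mean) / parental mean.

The module also provides the equivalent Dickerson-style reparameterization
(line effects, average heterosis, reciprocal effect - an exact linear
bijection with the four group means), Benjamini-Hochberg FDR control for
the contrast families, a Box-Cox transform with profile-likelihood lambda
selection, weekly egg-production rates from cumulative counts, and the
heterosis-versus-heritability regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "percent_heterosis",
    "reciprocal_difference",
    "weekly_rate",
    "boxcox_transform",
    "bh_fdr",
    "dickerson_reparameterization",
    "dickerson_to_means",
    "heterosis_table",
    "heterosis_vs_heritability",
    "plot_heterosis_by_age",
]


def _parental_mean(ww: float, yy: float) -> float:
    return 0.5 * (ww + yy)


def percent_heterosis(ww: float, yy: float, cross: float) -> float:
    """H% of one crossbred group relative to the parental mean."""
    pm = _parental_mean(ww, yy)
    if pm == 0:
        return np.nan
    return 100.0 * (cross - pm) / pm


def reciprocal_difference(ww: float, yy: float, wy: float, yw: float) -> float:
    """Reciprocal-cross difference (WY - YW) as a % of the parental mean."""
    pm = _parental_mean(ww, yy)
    if pm == 0:
        return np.nan
    return 100.0 * (wy - yw) / pm


def weekly_rate(en_early: float, en_late: float, weeks_apart: float) -> float:
    """Eggs per week between two cumulative egg numbers."""
    if weeks_apart <= 0:
        raise ValueError("weeks_apart must be positive")
    return (en_late - en_early) / weeks_apart


# ---------------------------------------------------------------------- #
def boxcox_transform(
    values: np.ndarray, lmbda: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Box-Cox power transform ``(y^l - 1)/l`` (natural log at l = 0).

    When ``lmbda`` is None, the value maximising the profile
    log-likelihood on the grid [-2, 2] with step 0.01 is used.  Values must
    be positive; if any are <= 0 a shift making the minimum 1 is applied
    first and returned so the transform can be undone.
    Returns (transformed values, lambda, shift).
    """
    y = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    shift = 0.0
    if y.min() <= 0:
        shift = 1.0 - y.min()
        y = y + shift
    if lmbda is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
        llf = np.array([stats.boxcox_llf(l, y) for l in grid])
        lmbda = float(grid[np.argmax(llf)])
    if abs(lmbda) < 1e-12:
        out = np.log(y)
    else:
        out = (y**lmbda - 1.0) / lmbda
    return out, float(lmbda), shift


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one test family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------- #
def dickerson_reparameterization(
    ww: float, yy: float, wy: float, yw: float
) -> dict:
    """Group means -> (line effects, average heterosis, reciprocal effect).

    Average heterosis is the crossbred mean minus the parental mean (the
    direct heterosis of the Dickerson crossbreeding model); the reciprocal
    effect is WY - YW.  The map is linear and invertible:
    :func:`dickerson_to_means` reconstructs the four means exactly.
    """
    return {
        "line_W": ww,
        "line_Y": yy,
        "avg_heterosis": 0.5 * (wy + yw) - 0.5 * (ww + yy),
        "reciprocal_effect": wy - yw,
    }


def dickerson_to_means(params: dict) -> dict:
    """Inverse of :func:`dickerson_reparameterization`."""
    ww, yy = params["line_W"], params["line_Y"]
    base = 0.5 * (ww + yy) + params["avg_heterosis"]
    return {
        "WW": ww,
        "YY": yy,
        "WY": base + 0.5 * params["reciprocal_effect"],
        "YW": base - 0.5 * params["reciprocal_effect"],
    }


# ---------------------------------------------------------------------- #
def heterosis_table(
    group_means: pd.DataFrame,
    p_values: pd.DataFrame | None = None,
    alpha_tiers: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Heterosis summary for a table of predicted group means.

    ``group_means`` is indexed by trait with columns WW, YY, WY, YW.
    ``p_values`` (optional, same index) holds raw p-values in columns
    ``p_WY``, ``p_YW``, ``p_recip``; each column is treated as one FDR
    family (one per crossbred group, one for the reciprocal contrasts) and
    significance markers '*' (FDR <= 0.05) / '**' (FDR <= 0.01) are added.
    """
    req = {"WW", "YY", "WY", "YW"}
    if not req.issubset(group_means.columns):
        raise ValueError(f"group_means needs columns {sorted(req)}")
    out = group_means.copy()
    out["parental_mean"] = 0.5 * (out["WW"] + out["YY"])
    out["H_pct_WY"] = [
        percent_heterosis(r.WW, r.YY, r.WY) for r in out.itertuples()
    ]
    out["H_pct_YW"] = [
        percent_heterosis(r.WW, r.YY, r.YW) for r in out.itertuples()
    ]
    out["recip_pct"] = [
        reciprocal_difference(r.WW, r.YY, r.WY, r.YW) for r in out.itertuples()
    ]
    if p_values is not None:
        for col, tag in (("p_WY", "WY"), ("p_YW", "YW"), ("p_recip", "recip")):
            if col not in p_values.columns:
                continue
            padj = pd.Series(
                bh_fdr(p_values[col].to_numpy()), index=p_values.index
            ).reindex(out.index)
            out[f"fdr_{tag}"] = padj
            out[f"sig_{tag}"] = [
                "**" if q <= alpha_tiers[1] else "*" if q <= alpha_tiers[0] else ""
                for q in padj.fillna(1.0)
            ]
    return out


# ---------------------------------------------------------------------- #
def heterosis_vs_heritability(
    h2: pd.Series,
    heterosis_pct: pd.Series,
    family: pd.Series | None = None,
    signed: bool = True,
) -> pd.DataFrame:
    """Spearman correlation and regression of heterosis on heritability.

    For all traits (and per trait family when ``family`` is given) returns
    the Spearman rank correlation between heritability and (signed, or
    absolute when ``signed=False``) mean heterosis, the least-squares slope
    expressed per 0.1 increase in h2, and the p-values of both.
    """
    h2, het = h2.align(heterosis_pct, join="inner")
    if not signed:
        het = het.abs()
    if len(h2) < 3:
        raise ValueError("need at least 3 traits")

    def one(name, x, y):
        if x.nunique() < 2 or y.nunique() < 2:
            return {
                "family": name, "n": len(x), "spearman_rho": np.nan,
                "spearman_p": np.nan, "slope_per_0.1_h2": np.nan, "slope_p": np.nan,
            }
        rho, rho_p = stats.spearmanr(x, y)
        reg = stats.linregress(x, y)
        return {
            "family": name,
            "n": len(x),
            "spearman_rho": float(rho),
            "spearman_p": float(rho_p),
            "slope_per_0.1_h2": float(reg.slope) * 0.1,
            "slope_p": float(reg.pvalue),
        }

    rows = [one("all", h2, het)]
    if family is not None:
        fam = family.reindex(h2.index)
        for name, idx in h2.groupby(fam).groups.items():
            if len(idx) >= 3:
                rows.append(one(name, h2.loc[idx], het.loc[idx]))
    return pd.DataFrame(rows).set_index("family")


def plot_heterosis_by_age(het_table: pd.DataFrame, trait_prefix: str, ax=None):
    """Plot H% of both crossbreds against age for one trait family.

    Rows of ``het_table`` whose index starts with ``trait_prefix`` followed
    by digits are interpreted as ages in weeks.
    """
    import matplotlib.pyplot as plt

    rows = []
    for name in het_table.index:
        if name.startswith(trait_prefix) and name[len(trait_prefix):].isdigit():
            rows.append((int(name[len(trait_prefix):]), name))
    rows.sort()
    if not rows:
        raise ValueError(f"no rows matching {trait_prefix}<age>")
    ages = [a for a, _ in rows]
    if ax is None:
        _, ax = plt.subplots()
    for col, label in (("H_pct_WY", "WY"), ("H_pct_YW", "YW")):
        ax.plot(ages, [het_table.loc[n, col] for _, n in rows], marker="o", label=label)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("age (weeks)")
    ax.set_ylabel("heterosis (%)")
    ax.set_title(trait_prefix)
    ax.legend()
    return ax
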