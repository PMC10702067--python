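"""Pedigree animal models for crossbred laying-hen data.

Model classes follow the statsmodels pattern: a model object is built from a
long-format trait table plus a :class:`~crosslay.pedigree.Pedigree`, and
``fit()`` returns a results object carrying variance components, their
asymptotic standard errors, heritability/repeatability, predicted genetic
group means and Wald contrasts.

Three models are provided:

``AnimalModel``
    Univariate model: overall mean + genetic group + rack as fixed effects,
    an additive animal effect with covariance ``A * sigma_a^2``, an optional
    permanent environmental effect for repeated records, and a residual
    variance per genetic group (heterogeneous) or a single one.

``GroupMultivariateAnimalModel``
    The group-specific variant: each trait is treated as three pseudo-traits
    (one for each pure line, one for the crossbreds) with all between-group
    covariances fixed at zero; reports per-group components plus weighted
    averages.

``BivariateAnimalModel``
    Two traits with 2 x 2 additive (optionally permanent environmental and
    residual) covariance blocks; reports genetic, permanent environmental,
    residual and phenotypic correlations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .pedigree import Pedigree
from .reml import (
    DiagonalResidual,
    PairedResidual,
    RandomTerm,
    REMLProblem,
    _pack,
    _unpack,
)

__all__ = [
    "AnimalModel",
    "AnimalModelResults",
    "GroupMultivariateAnimalModel",
    "GroupMultivariateResults",
    "BivariateAnimalModel",
    "BivariateResults",
    "GROUPS",
]

#: canonical genetic group order: pure W line, pure Y line, and the two
#: reciprocal crosses (first letter = sire line)
GROUPS = ["WW", "YY", "WY", "YW"]


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------- #
class _FixedDesign:
    """Mean + genetic group + rack design with an explicit constraint.

    ``coding='reference'`` drops the first level of each factor;
    ``coding='sum'`` uses sum-to-zero contrasts.  Predicted group means are
    estimable functions and do not depend on the choice (asserted in the
    test-suite).
    """

    def __init__(self, groups: pd.Series, racks: pd.Series | None, coding="reference"):
        self.coding = coding
        self.group_levels = [g for g in GROUPS if g in set(groups)] or sorted(
            set(groups)
        )
        extra = sorted(set(groups) - set(self.group_levels))
        self.group_levels += extra
        self.rack_levels = sorted(set(racks)) if racks is not None else []
        cols = [np.ones(len(groups))]
        names = ["mu"]
        cols_g, names_g = self._encode_factor(
            groups, self.group_levels, "group"
        )
        cols += cols_g
        names += names_g
        if racks is not None and len(self.rack_levels) > 1:
            cols_r, names_r = self._encode_factor(racks, self.rack_levels, "rack")
            cols += cols_r
            names += names_r
        self.X = np.column_stack(cols)
        self.names = names
        self.rank = np.linalg.matrix_rank(self.X)
        if self.rank < self.X.shape[1]:
            raise ValueError(
                "fixed-effect design is rank deficient (genetic group and "
                "rack are confounded); merge or drop rack levels"
            )

    def _encode_factor(self, values, levels, label):
        cols, names = [], []
        if self.coding == "reference":
            for lev in levels[1:]:
                cols.append((values == lev).astype(float).to_numpy())
                names.append(f"{label}[{lev}]")
        elif self.coding == "sum":
            last = levels[-1]
            for lev in levels[:-1]:
                col = (values == lev).astype(float).to_numpy()
                col = col - (values == last).astype(float).to_numpy()
                cols.append(col)
                names.append(f"{label}[S.{lev}]")
        else:
            raise ValueError(f"unknown coding {self.coding!r}")
        return cols, names

    def _factor_row(self, level, levels, label):
        """Encoding of one factor level, matching the column layout."""
        row = []
        if self.coding == "reference":
            row = [1.0 if lev == level else 0.0 for lev in levels[1:]]
        else:
            if level == levels[-1]:
                row = [-1.0] * (len(levels) - 1)
            else:
                row = [1.0 if lev == level else 0.0 for lev in levels[:-1]]
        return np.array(row)

    def group_mean_row(self, group) -> np.ndarray:
        """X-row for 'group g with rack effects averaged over all levels'."""
        parts = [np.array([1.0]), self._factor_row(group, self.group_levels, "group")]
        if self.rack_levels and len(self.rack_levels) > 1:
            rack_rows = np.vstack(
                [self._factor_row(r, self.rack_levels, "rack") for r in self.rack_levels]
            )
            parts.append(rack_rows.mean(axis=0))
        return np.concatenate(parts)


def _prepare(data: pd.DataFrame, trait=None):
    df = data.copy()
    if trait is not None:
        df = df[df["trait"] == trait]
        if df.empty:
            raise ValueError(f"no records for trait {trait!r}")
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    return df


def _delta_se(fun, theta, theta_cov):
    """Delta-method standard error of ``fun(theta)``."""
    if not np.all(np.isfinite(theta_cov)):
        return np.nan
    g = np.zeros_like(theta)
    h0 = fun(theta)
    for k in range(theta.size):
        eps = 1e-6 * max(abs(theta[k]), 1e-6)
        tp = theta.copy()
        tp[k] += eps
        g[k] = (fun(tp) - h0) / eps
    var = float(g @ theta_cov @ g)
    return float(np.sqrt(var)) if var >= 0 else np.nan


# ---------------------------------------------------------------------- #
class AnimalModel:
    """Univariate pedigree animal model, optionally with repeated records.

    Parameters
    ----------
    data : DataFrame
        Long-format records with columns ``animal`` (or ``hen``), ``group``,
        ``rack``, ``value`` and optionally ``trait`` (filtered when the
        ``trait`` argument is given).
    pedigree : Pedigree
    trait : str, optional
        Restrict ``data`` to this trait.
    permanent_env : bool, optional
        Include a permanent environmental effect.  Defaults to True when
        any animal has more than one record.  If requested but no animal
        has repeated records the effect is unidentifiable: it is dropped
        with a warning and reported as 0.
    residual_by_group : bool
        One residual variance per genetic group (default) or a single one.
    coding : str
        Fixed-effect constraint, ``'reference'`` or ``'sum'``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        pedigree: Pedigree,
        trait: str | None = None,
        permanent_env: bool | None = None,
        residual_by_group: bool = True,
        coding: str = "reference",
    ):
        df = _prepare(data, trait)
        if "animal" not in df.columns and "hen" in df.columns:
            df = df.rename(columns={"hen": "animal"})
        self.data = df
        self.trait = trait
        self.pedigree = pedigree
        self.animals = df["animal"].astype(str)
        self.level_idx = pedigree.position(self.animals)
        counts = self.animals.value_counts()
        has_repeats = bool((counts > 1).any())
        if permanent_env is None:
            permanent_env = has_repeats
        if permanent_env and not has_repeats:
            warnings.warn(
                "permanent environmental variance is unidentifiable without "
                "repeated records; fixing it to 0",
                ConvergenceWarning,
            )
            permanent_env = False
            self.pe_dropped = True
        else:
            self.pe_dropped = False
        self.permanent_env = permanent_env
        self.residual_by_group = residual_by_group

        racks = df["rack"] if "rack" in df.columns else None
        self.design = _FixedDesign(df["group"], racks, coding=coding)
        self.groups = self.design.group_levels

        terms = [
            RandomTerm(
                "animal",
                level_idx=self.level_idx,
                q=len(pedigree),
                kinv=pedigree.a_inverse(),
                logdet_k=pedigree.log_det_a(),
            )
        ]
        if permanent_env:
            uniq = pd.unique(self.animals)
            pe_map = {a: i for i, a in enumerate(uniq)}
            pe_idx = self.animals.map(pe_map).to_numpy()
            terms.append(
                RandomTerm(
                    "pe",
                    level_idx=pe_idx,
                    q=len(uniq),
                    kinv=sparse.eye(len(uniq), format="csr"),
                    identity_k=True,
                )
            )
        if residual_by_group:
            gmap = {g: i for i, g in enumerate(self.groups)}
            gidx = df["group"].map(gmap).to_numpy()
            residual = DiagonalResidual(group_idx=gidx, n_groups=len(self.groups))
        else:
            residual = DiagonalResidual(
                group_idx=np.zeros(len(df), dtype=int), n_groups=1
            )
        self.problem = REMLProblem(df["value"].to_numpy(float), self.design.X, terms, residual)

    @classmethod
    def from_trait_table(cls, trait_table: pd.DataFrame, pedigree: Pedigree, trait: str, **kw):
        return cls(trait_table, pedigree, trait=trait, **kw)

    def fit(self, **kw) -> "AnimalModelResults":
        raw = self.problem.fit(**kw)
        if not raw.converged and not raw.degenerate:
            warnings.warn(
                f"REML did not converge for trait {self.trait!r} "
                f"({raw.n_iter} iterations); estimates flagged DNC",
                ConvergenceWarning,
            )
        return AnimalModelResults(self, raw)


class AnimalModelResults:
    """Variance components, genetic parameters and predictions for one fit."""

    def __init__(self, model: AnimalModel, raw):
        self.model = model
        self.raw = raw
        self.converged = raw.converged
        self.dnc = not raw.converged
        self.n_iter = raw.n_iter
        self.loglik = raw.loglik
        prob = model.problem
        th = raw.theta
        self.sigma_a2 = float(th[prob.slices[0]][0])
        self.sigma_pe2 = float(th[prob.slices[1]][0]) if model.permanent_env else 0.0
        res_var = th[prob.res_slice]
        if model.residual_by_group:
            self.sigma_e_groups = pd.Series(res_var, index=model.groups)
        else:
            self.sigma_e_groups = pd.Series(
                [res_var[0]] * len(model.groups), index=model.groups
            )
        # the overall residual variance is the average across genetic groups
        self.sigma_e2 = float(np.mean(res_var))
        self.sigma_p2 = self.sigma_a2 + self.sigma_pe2 + self.sigma_e2

    # -- genetic parameters -------------------------------------------- #
    def _components_from(self, theta):
        prob = self.model.problem
        sa2 = theta[prob.slices[0]][0]
        spe2 = theta[prob.slices[1]][0] if self.model.permanent_env else 0.0
        se2 = float(np.mean(theta[prob.res_slice]))
        return sa2, spe2, se2

    @property
    def heritability(self) -> float:
        return self.sigma_a2 / self.sigma_p2

    @property
    def repeatability(self) -> float:
        return (self.sigma_a2 + self.sigma_pe2) / self.sigma_p2

    @property
    def heritability_se(self) -> float:
        def f(th):
            a, p, e = self._components_from(th)
            return a / (a + p + e)

        return _delta_se(f, self.raw.theta, self.raw.theta_cov)

    @property
    def repeatability_se(self) -> float:
        def f(th):
            a, p, e = self._components_from(th)
            return (a + p) / (a + p + e)

        return _delta_se(f, self.raw.theta, self.raw.theta_cov)

    @property
    def sigma_a2_se(self) -> float:
        return float(self.raw.theta_se[self.model.problem.slices[0]][0])

    # -- fixed-effect predictions -------------------------------------- #
    def predicted_group_means(self) -> pd.DataFrame:
        """Predicted mean per genetic group: mu + b_g, racks averaged.

        These are estimable functions, invariant to the fixed-effect
        constraint used in the design.
        """
        rows = []
        for g in self.model.groups:
            L = self.model.design.group_mean_row(g)
            mean = float(L @ self.raw.beta)
            se = float(np.sqrt(max(L @ self.raw.beta_cov @ L, 0.0)))
            rows.append({"group": g, "mean": mean, "se": se})
        return pd.DataFrame(rows).set_index("group")

    @property
    def residual_df(self) -> int:
        return self.model.problem.n - self.model.design.rank

    def wald_contrast(self, weights: dict) -> dict:
        """Wald F test of a zero-sum contrast over predicted group means.

        ``weights`` maps group label -> weight; weights must sum to zero
        (otherwise the contrast is not estimable free of mu and rack).
        """
        wsum = sum(weights.values())
        if abs(wsum) > 1e-9:
            raise ValueError(f"contrast weights must sum to 0, got {wsum}")
        L = np.zeros(self.model.design.X.shape[1])
        for g, w in weights.items():
            if g not in self.model.groups:
                raise ValueError(f"unknown group {g!r} in contrast")
            L = L + w * self.model.design.group_mean_row(g)
        est = float(L @ self.raw.beta)
        var = float(L @ self.raw.beta_cov @ L)
        if var <= 0:
            raise ValueError("contrast is not estimable (zero variance)")
        F = est * est / var
        df2 = self.residual_df
        p = float(stats.f.sf(F, 1, df2))
        return {"estimate": est, "se": float(np.sqrt(var)), "F": F,
                "df": (1, df2), "p_value": p}

    # -- reporting ------------------------------------------------------ #
    def summary(self) -> str:
        lines = [
            f"Animal model REML fit: trait={self.model.trait or '(response)'}",
            f"  records: {self.model.problem.n}   animals: "
            f"{self.model.animals.nunique()}   converged: {self.converged}"
            + ("" if self.converged else "  [DNC]"),
            f"  restricted logL: {self.loglik:.4f}   iterations: {self.n_iter}",
            "  variance components:",
            f"    sigma_a2  = {self.sigma_a2:10.4f}  (SE {self.sigma_a2_se:.4f})",
        ]
        if self.model.permanent_env:
            lines.append(f"    sigma_pe2 = {self.sigma_pe2:10.4f}")
        for g, v in self.sigma_e_groups.items():
            lines.append(f"    sigma_e2[{g}] = {v:10.4f}")
        lines += [
            f"    sigma_e2 (group average) = {self.sigma_e2:.4f}",
            f"    sigma_p2  = {self.sigma_p2:10.4f}",
            f"  heritability  h2 = {self.heritability:.3f} (SE {self.heritability_se:.3f})",
        ]
        if self.model.permanent_env:
            lines.append(
                f"  repeatability r  = {self.repeatability:.3f} "
                f"(SE {self.repeatability_se:.3f})"
            )
        lines.append("  predicted group means (racks averaged):")
        for g, row in self.predicted_group_means().iterrows():
            lines.append(f"    {g}: {row['mean']:.3f} (SE {row['se']:.3f})")
        return "\n".join(lines)


# ---------------------------------------------------------------------- #
PSEUDO_GROUPS = {"WW": "WW", "YY": "YY", "WY": "cross", "YW": "cross"}
#: animal-count weights reported for the source study's design
DEFAULT_WEIGHTS = {"WW": 0.22, "YY": 0.25, "cross": 0.53}


class GroupMultivariateAnimalModel:
    """Trait modelled as three pseudo-traits (WW, YY, crossbreds).

    Additive, permanent environmental and residual (co)variances between
    the pseudo-traits are fixed at zero, so each genetic group gets its own
    component set while sharing the pedigree and fixed effects.  Weighted
    averages (weights = group proportions, or the supplied ones) give the
    pooled heritability and repeatability.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        pedigree: Pedigree,
        trait: str | None = None,
        permanent_env: bool | None = None,
        weights: dict | None = None,
        coding: str = "reference",
    ):
        df = _prepare(data, trait)
        if "animal" not in df.columns and "hen" in df.columns:
            df = df.rename(columns={"hen": "animal"})
        self.data = df
        self.trait = trait
        self.pedigree = pedigree
        self.pseudo = df["group"].map(PSEUDO_GROUPS)
        if self.pseudo.isna().any():
            bad = df.loc[self.pseudo.isna(), "group"].unique()
            raise ValueError(f"unknown genetic groups {bad}")
        self.pseudo_levels = ["WW", "YY", "cross"]
        for lev in self.pseudo_levels:
            n_animals = df.loc[self.pseudo == lev, "animal"].nunique()
            if n_animals < 30:
                warnings.warn(
                    f"pseudo-group {lev} has only {n_animals} animals; "
                    "its component estimates will be unstable",
                    ConvergenceWarning,
                )
        self.animals = df["animal"].astype(str)
        anim_idx = pedigree.position(self.animals)
        counts = self.animals.value_counts()
        has_repeats = bool((counts > 1).any())
        if permanent_env is None:
            permanent_env = has_repeats
        self.permanent_env = permanent_env and has_repeats
        racks = df["rack"] if "rack" in df.columns else None
        self.design = _FixedDesign(df["group"], racks, coding=coding)
        self.groups = self.design.group_levels

        ainv = pedigree.a_inverse()
        logdet = pedigree.log_det_a()
        terms = []
        for lev in self.pseudo_levels:
            mask = (self.pseudo == lev).to_numpy()
            terms.append(
                RandomTerm(
                    f"animal_{lev}",
                    level_idx=np.where(mask, anim_idx, -1),
                    q=len(pedigree),
                    kinv=ainv,
                    logdet_k=logdet,
                )
            )
        if self.permanent_env:
            uniq = pd.unique(self.animals)
            pe_map = {a: i for i, a in enumerate(uniq)}
            pe_idx = self.animals.map(pe_map).to_numpy()
            for lev in self.pseudo_levels:
                mask = (self.pseudo == lev).to_numpy()
                terms.append(
                    RandomTerm(
                        f"pe_{lev}",
                        level_idx=np.where(mask, pe_idx, -1),
                        q=len(uniq),
                        kinv=sparse.eye(len(uniq), format="csr"),
                        identity_k=True,
                    )
                )
        pmap = {g: i for i, g in enumerate(self.pseudo_levels)}
        residual = DiagonalResidual(
            group_idx=self.pseudo.map(pmap).to_numpy(), n_groups=3
        )
        self.problem = REMLProblem(
            df["value"].to_numpy(float), self.design.X, terms, residual
        )
        if weights is None:
            props = (
                df.drop_duplicates("animal").groupby(self.pseudo.loc[
                    df.drop_duplicates("animal").index
                ])["animal"].count()
            )
            weights = (props / props.sum()).to_dict()
        self.weights = {lev: float(weights.get(lev, DEFAULT_WEIGHTS[lev]))
                        for lev in self.pseudo_levels}

    def fit(self, **kw) -> "GroupMultivariateResults":
        raw = self.problem.fit(**kw)
        if not raw.converged and not raw.degenerate:
            warnings.warn(
                f"group-multivariate REML did not converge for {self.trait!r}",
                ConvergenceWarning,
            )
        return GroupMultivariateResults(self, raw)


class GroupMultivariateResults:
    def __init__(self, model: GroupMultivariateAnimalModel, raw):
        self.model = model
        self.raw = raw
        self.converged = raw.converged
        self.dnc = not raw.converged
        self.loglik = raw.loglik
        prob = model.problem
        th = raw.theta
        levels = model.pseudo_levels
        rows = {}
        for i, lev in enumerate(levels):
            sa2 = float(th[prob.slices[i]][0])
            spe2 = (
                float(th[prob.slices[len(levels) + i]][0])
                if model.permanent_env
                else 0.0
            )
            se2 = float(th[prob.res_slice][i])
            rows[lev] = {
                "sigma_a2": sa2,
                "sigma_pe2": spe2,
                "sigma_e2": se2,
                "sigma_p2": sa2 + spe2 + se2,
                "h2": sa2 / (sa2 + spe2 + se2),
                "repeatability": (sa2 + spe2) / (sa2 + spe2 + se2),
            }
        self.by_group = pd.DataFrame(rows).T

    def weighted_components(self) -> dict:
        w = pd.Series(self.model.weights)
        w = w / w.sum()
        out = {
            k: float((self.by_group[k] * w).sum())
            for k in ("sigma_a2", "sigma_pe2", "sigma_e2")
        }
        out["sigma_p2"] = out["sigma_a2"] + out["sigma_pe2"] + out["sigma_e2"]
        return out

    @property
    def heritability(self) -> float:
        c = self.weighted_components()
        return c["sigma_a2"] / c["sigma_p2"]

    @property
    def repeatability(self) -> float:
        c = self.weighted_components()
        return (c["sigma_a2"] + c["sigma_pe2"]) / c["sigma_p2"]

    def summary(self) -> str:
        c = self.weighted_components()
        lines = [
            f"Group-specific multivariate animal model: trait={self.model.trait}",
            f"  converged: {self.converged}" + ("" if self.converged else "  [DNC]"),
            self.by_group.round(4).to_string(),
            f"  weights: {self.model.weights}",
            f"  weighted sigma_a2={c['sigma_a2']:.4f} sigma_pe2={c['sigma_pe2']:.4f} "
            f"sigma_e2={c['sigma_e2']:.4f}",
            f"  weighted h2={self.heritability:.3f}  r={self.repeatability:.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------- #
class BivariateAnimalModel:
    """Bivariate animal model for genetic/phenotypic correlations.

    Records of the two traits are stacked; additive effects get a 2 x 2
    covariance block combined with A by a direct product, permanent
    environmental and residual blocks are combined with identities.
    Residual covariance applies to record pairs: the k-th record of a trait
    on an animal is paired with the k-th record of the other trait on the
    same animal; unpaired records contribute to their trait's variance only.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        pedigree: Pedigree,
        traits: tuple[str, str],
        permanent_env: bool | None = None,
        coding: str = "reference",
    ):
        self.traits = tuple(traits)
        frames = []
        for t_ix, tr in enumerate(self.traits):
            sub = _prepare(data, tr).copy()
            if "animal" not in sub.columns and "hen" in sub.columns:
                sub = sub.rename(columns={"hen": "animal"})
            sub["trait_ix"] = t_ix
            frames.append(sub)
        df = pd.concat(frames, ignore_index=True)
        df["animal"] = df["animal"].astype(str)
        df["rep"] = df.groupby(["trait_ix", "animal"]).cumcount()
        self.data = df
        self.pedigree = pedigree
        self.animals = df["animal"]
        anim_idx = pedigree.position(df["animal"])
        trait_idx = df["trait_ix"].to_numpy()
        counts = df.groupby(["trait_ix", "animal"]).size()
        has_repeats = bool((counts > 1).any())
        if permanent_env is None:
            permanent_env = has_repeats
        self.permanent_env = permanent_env and has_repeats

        racks = df["rack"] if "rack" in df.columns else None
        # trait-specific means: interact intercept+group(+rack) with trait
        base = _FixedDesign(df["group"], racks, coding=coding)
        X0 = base.X
        X = np.zeros((len(df), 2 * X0.shape[1]))
        for t_ix in (0, 1):
            m = trait_idx == t_ix
            X[m, t_ix * X0.shape[1]:(t_ix + 1) * X0.shape[1]] = X0[m]
        self.design = base
        self.groups = base.group_levels
        self._xwidth = X0.shape[1]

        terms = [
            RandomTerm(
                "animal",
                level_idx=anim_idx,
                q=len(pedigree),
                kinv=pedigree.a_inverse(),
                logdet_k=pedigree.log_det_a(),
                n_traits=2,
                trait_idx=trait_idx,
            )
        ]
        if self.permanent_env:
            uniq = pd.unique(df["animal"])
            pe_map = {a: i for i, a in enumerate(uniq)}
            pe_idx = df["animal"].map(pe_map).to_numpy()
            terms.append(
                RandomTerm(
                    "pe",
                    level_idx=pe_idx,
                    q=len(uniq),
                    kinv=sparse.eye(len(uniq), format="csr"),
                    n_traits=2,
                    trait_idx=trait_idx,
                    identity_k=True,
                )
            )
        pair_key = df["animal"].str.cat(df["rep"].astype(str), sep="#")
        pair_codes, _ = pd.factorize(pair_key)
        # a pair id is valid only if it occurs for both traits
        tab = pd.crosstab(pair_codes, trait_idx)
        complete = set(tab.index[(tab.get(0, 0) >= 1) & (tab.get(1, 0) >= 1)])
        pair_id = np.where(np.isin(pair_codes, list(complete)), pair_codes, -1)
        residual = PairedResidual(trait_idx=trait_idx, pair_id=pair_id)
        self.problem = REMLProblem(df["value"].to_numpy(float), X, terms, residual)

    def fit(self, **kw) -> "BivariateResults":
        raw = self.problem.fit(**kw)
        if not raw.converged and not raw.degenerate:
            warnings.warn(
                f"bivariate REML did not converge for {self.traits}; flagged DNC",
                ConvergenceWarning,
            )
        return BivariateResults(self, raw)


class BivariateResults:
    """Covariance blocks and derived correlations for a bivariate fit."""

    def __init__(self, model: BivariateAnimalModel, raw):
        self.model = model
        self.raw = raw
        self.converged = raw.converged
        self.dnc = not raw.converged
        self.loglik = raw.loglik
        prob = model.problem
        th = raw.theta
        self.G_a = _unpack(th[prob.slices[0]], 2)
        self.G_pe = (
            _unpack(th[prob.slices[1]], 2) if model.permanent_env else np.zeros((2, 2))
        )
        self.G_e = _unpack(th[prob.res_slice], 2)
        self.G_p = self.G_a + self.G_pe + self.G_e

    @staticmethod
    def _corr(G):
        d = np.sqrt(G[0, 0] * G[1, 1])
        return float(G[0, 1] / d) if d > 0 else np.nan

    @property
    def r_a(self) -> float:
        return self._corr(self.G_a)

    @property
    def r_pe(self) -> float:
        return self._corr(self.G_pe) if self.model.permanent_env else np.nan

    @property
    def r_e(self) -> float:
        return self._corr(self.G_e)

    @property
    def r_p(self) -> float:
        return self._corr(self.G_p)

    def _corr_se(self, sl) -> float:
        def f(th):
            G = _unpack(th[sl], 2)
            d = np.sqrt(G[0, 0] * G[1, 1])
            return G[0, 1] / d if d > 0 else 0.0

        return _delta_se(f, self.raw.theta, self.raw.theta_cov)

    @property
    def r_a_se(self) -> float:
        return self._corr_se(self.model.problem.slices[0])

    @property
    def r_e_se(self) -> float:
        return self._corr_se(self.model.problem.res_slice)

    def heritabilities(self) -> tuple[float, float]:
        return (
            float(self.G_a[0, 0] / self.G_p[0, 0]),
            float(self.G_a[1, 1] / self.G_p[1, 1]),
        )

    def summary(self) -> str:
        t1, t2 = self.model.traits
        h1, h2_ = self.heritabilities()
        status = "converged" if self.converged else "DNC"
        lines = [
            f"Bivariate animal model: {t1} x {t2}  [{status}]",
            f"  r_a = {self.r_a:.3f} (SE {self.r_a_se:.3f})",
        ]
        if self.model.permanent_env:
            lines.append(f"  r_pe = {self.r_pe:.3f}")
        lines += [
            f"  r_e = {self.r_e:.3f} (SE {self.r_e_se:.3f})",
            f"  r_p = {self.r_p:.3f}",
            f"  h2({t1}) = {h1:.3f}   h2({t2}) = {h2_:.3f}",
        ]
        return "\n".join(lines)
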