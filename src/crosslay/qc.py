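"""Data cleaning and descriptive statistics.

Cleaning follows two rules: hens that never laid an egg are removed from
the egg-production traits, and records deviating more than three standard
deviations from the mean of their genetic group (per trait and age) are
dropped in a single pass.  Descriptives are computed across all animals
pooled over groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QCReport", "remove_nonlayers", "remove_outliers_3sd", "descriptives"]

#: traits derived from the laying records; non-layer removal applies here
PRODUCTION_TRAIT_PREFIXES = ("AFE", "OP", "EN", "NC", "ACL", "APL")


def is_production_trait(trait: str) -> bool:
    return any(trait.startswith(p) for p in PRODUCTION_TRAIT_PREFIXES)


@dataclass
class QCReport:
    """Record of what QC removed."""

    nonlayers: pd.DataFrame = field(default_factory=pd.DataFrame)
    outliers: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        out = self.outliers.copy()
        out.to_csv(path, index=False)

    def summary(self) -> str:
        lines = []
        if len(self.nonlayers):
            per_group = self.nonlayers.groupby("group")["hen"].nunique()
            lines.append(
                "non-layers removed: "
                + ", ".join(f"{n} {g}" for g, n in per_group.items())
            )
        else:
            lines.append("non-layers removed: none")
        if len(self.outliers):
            lines.append(
                f"outlier records removed: {int(self.outliers['n_removed'].sum())} "
                f"of {int(self.outliers['n_before'].sum())}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------- #
def remove_nonlayers(
    trait_table: pd.DataFrame, lay_records: pd.DataFrame
) -> tuple[pd.DataFrame, QCReport]:
    """Drop hens with zero lifetime eggs from the egg-production traits.

    ``lay_records`` is the per-egg table (column ``hen``); any hen present
    in the trait table but absent there laid nothing.  Non-production
    traits are left untouched.
    """
    layers = set(lay_records["hen"]) if len(lay_records) else set()
    prod = trait_table["trait"].map(is_production_trait)
    nonlayer_mask = prod & ~trait_table["hen"].isin(layers)
    removed = (
        trait_table.loc[nonlayer_mask, ["hen", "group"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    cleaned = trait_table.loc[~nonlayer_mask].reset_index(drop=True)
    return cleaned, QCReport(nonlayers=removed)


def remove_outliers_3sd(trait_table: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """One-pass 3-SD outlier filter per trait x age x genetic group.

    For each cell the mean and SD are computed on the current records and
    records with |value - mean| > 3 SD are dropped; the filter is applied
    once, not iterated.  Cells with SD = 0 (or fewer than 2 records) remove
    nothing.  Returns the filtered table and a report with per-cell counts
    and outlier percentages.
    """
    df = trait_table.reset_index(drop=True)
    keep = np.ones(len(df), dtype=bool)
    rows = []
    for (trait, age, group), sub in df.dropna(subset=["value"]).groupby(
        ["trait", "age", "group"], sort=True
    ):
        vals = sub["value"].to_numpy(dtype=float)
        n = vals.size
        if n < 2:
            continue
        mean, sd = vals.mean(), vals.std(ddof=1)
        n_removed = 0
        if sd > 0:
            bad = np.abs(vals - mean) > 3.0 * sd
            keep[sub.index[bad]] = False
            n_removed = int(bad.sum())
        rows.append(
            {
                "trait": trait,
                "age": age,
                "group": group,
                "n_before": n,
                "n_removed": n_removed,
                "pct_outliers": 100.0 * n_removed / n,
            }
        )
    report = QCReport(outliers=pd.DataFrame(rows))
    return df.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------- #
def descriptives(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait descriptive statistics across all animals.

    Returns trait, number of animals (NA), number of observations (NO),
    mean, SD and the coefficient of variation CV% = 100 * SD / mean (NaN
    when the mean is zero).
    """
    rows = []
    for trait, sub in trait_table.dropna(subset=["value"]).groupby("trait", sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        cv = 100.0 * sd / mean if mean != 0 else np.nan
        rows.append(
            {
                "trait": trait,
                "n_animals": int(sub["hen"].nunique()),
                "n_observations": int(vals.size),
                "mean": mean,
                "sd": sd,
                "cv_pct": cv,
            }
        )
    return pd.DataFrame(rows)
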