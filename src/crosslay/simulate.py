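"""Synthetic crossbreeding-design generator.

Emulates the data-generating process the animal models in this package
assume: a reciprocal cross between two layer lines (labelled W and Y) in
which the same sires of each line produce both purebred and crossbred
offspring, additive genetic effects flowing through the pedigree, permanent
environmental and group-heterogeneous residual variation, rack (cage
position) effects, programmed heterosis and reciprocal-cross shifts on the
crossbred group means, and clutch-structured daily egg-laying driven by a
two-state (lay/pause) daily Markov chain.

Defaults mirror the reference study design: 30 sires per line, 150 dams per
mating (5 per sire per mating), four genetic groups with 315/271/315/359
hens on test (YY/WW/WY/YW), 24 rack levels, and laying observed through 100
weeks of age.

Random-number streams are split per module and per hen
(``numpy.random.SeedSequence`` spawning), so enlarging one part of the
design does not perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "MatingDesign",
    "TraitGeneticParams",
    "LayingProcessParams",
    "LayRecords",
    "simulate_pedigree",
    "simulate_rack_assignment",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_laying_records",
    "measurements_from_traits",
]

LINES = ("W", "Y")


# ---------------------------------------------------------------------- #
@dataclass
class MatingDesign:
    """Reciprocal-cross mating design.

    ``offspring_per_group`` hens enter the laying test per genetic group;
    group labels are sire-line first (WY = W sire x Y dam).  The same sires
    of a line serve its purebred and its crossbred matings; the dams differ.
    ``base_generations`` discrete ancestral generations are simulated above
    the parents of the test hens so that the relationship matrix carries
    non-trivial structure.
    """

    n_sires_per_line: int = 30
    n_dams_per_sire_cross: int = 5
    lines: tuple[str, str] = LINES
    offspring_per_group: dict = field(
        default_factory=lambda: {"YY": 315, "WW": 271, "WY": 315, "YW": 359}
    )
    base_generations: int = 2
    n_base_females_per_line: int = 60
    n_racks: int = 24

    @property
    def groups(self) -> list[str]:
        a, b = self.lines
        return [a + a, b + b, a + b, b + a]

    @property
    def n_dams_per_line(self) -> int:
        # each line's dams are split between the pure and the cross mating
        return 2 * self.n_sires_per_line * self.n_dams_per_sire_cross

    def validate(self) -> None:
        counts = [
            self.n_sires_per_line,
            self.n_dams_per_sire_cross,
            self.base_generations,
            self.n_base_females_per_line,
            self.n_racks,
            *self.offspring_per_group.values(),
        ]
        if any(c <= 0 for c in counts):
            raise ValueError(f"all design counts must be positive, got {self}")
        for g in self.offspring_per_group:
            if g not in self.groups:
                raise ValueError(f"group {g!r} does not match lines {self.lines}")


@dataclass
class TraitGeneticParams:
    """Genetic architecture of one trait in the simulation.

    ``heterosis_shift`` is added to the parental-mean expectation of each
    crossbred group (trait units), so the programmed percent heterosis is
    analytically known; ``reciprocal_shift`` is the difference between the
    two crossbred means (first cross minus second, i.e. WY - YW) and is
    applied as +/- half around the common crossbred expectation.
    ``sigma_e2`` may be a single variance or a per-group mapping.
    """

    name: str
    line_means: dict
    sigma_a2: float = 0.0
    sigma_pe2: float = 0.0
    sigma_e2: float | dict = 0.0
    heterosis_shift: float | dict = 0.0
    reciprocal_shift: float = 0.0
    rack_sd: float = 0.0
    n_records: int = 1
    age_label: str = "single"

    def validate(self) -> None:
        evals = (
            list(self.sigma_e2.values())
            if isinstance(self.sigma_e2, dict)
            else [self.sigma_e2]
        )
        if self.sigma_a2 < 0 or self.sigma_pe2 < 0 or any(v < 0 for v in evals):
            raise ValueError(f"variances must be >= 0 for trait {self.name}")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")

    def group_mean(self, group: str, lines: tuple[str, str] = LINES) -> float:
        s, d = group[0], group[1]
        if s == d:
            return float(self.line_means[s])
        pmean = 0.5 * (self.line_means[lines[0]] + self.line_means[lines[1]])
        het = (
            self.heterosis_shift.get(group, 0.0)
            if isinstance(self.heterosis_shift, dict)
            else self.heterosis_shift
        )
        cross12 = lines[0] + lines[1]
        sign = 0.5 if group == cross12 else -0.5
        return pmean + het + sign * self.reciprocal_shift

    def residual_sd(self, group: str) -> float:
        v = (
            self.sigma_e2.get(group, 0.0)
            if isinstance(self.sigma_e2, dict)
            else self.sigma_e2
        )
        return float(np.sqrt(v))


@dataclass
class LayingProcessParams:
    """Daily two-state (lay/pause) laying process.

    Transition probabilities vary linearly with age between the start and
    the end of the observation span: ``p_lay_lay`` is P(lay tomorrow | laid
    today), ``p_pause_lay`` is P(lay tomorrow | paused today).  Oviposition
    clock times drift later within a clutch by ``oviposition_lag_h - 24``
    hours per day, on a 0.5-h recording grid inside 07:00-19:00.
    """

    p_lay_lay: tuple[float, float] = (0.88, 0.70)
    p_pause_lay: tuple[float, float] = (0.78, 0.24)
    afe_mean: float | dict = 168.0
    afe_sd: float = 11.0
    oviposition_lag_h: float = 25.3
    first_lay_time_h: float = 8.0
    end_day: int = 700
    nonlayer_fraction: float = 0.025

    def validate(self) -> None:
        for p in (*self.p_lay_lay, *self.p_pause_lay, self.nonlayer_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must lie in [0, 1]")
        if self.oviposition_lag_h <= 0:
            raise ValueError("oviposition lag must be positive")

    def _interp(self, pair, frac):
        return pair[0] + (pair[1] - pair[0]) * frac


@dataclass
class LayRecords:
    """Daily lay events: one row per egg (hen, day-of-age, clock time)."""

    records: pd.DataFrame  # columns hen, day, time_h (NaN outside window)
    hens: pd.DataFrame  # columns hen, group, rack
    window: tuple[int, int]

    def days_by_hen(self) -> dict:
        return {
            h: sub["day"].to_numpy()
            for h, sub in self.records.groupby("hen", sort=False)
        }


# ---------------------------------------------------------------------- #
def simulate_pedigree(design: MatingDesign, seed: int) -> Pedigree:
    """Simulate the reciprocal-cross pedigree.

    Founders (generation 0) have unknown parents; ``base_generations``
    further pure-line generations are bred by random mating; the final
    generation holds the test hens, labelled by genetic group, with each
    line's sires shared between its purebred and crossbred matings.
    """
    design.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    rows = []
    males: dict = {}
    females: dict = {}
    n_gen = design.base_generations
    for line in design.lines:
        for gen in range(n_gen + 1):
            parental = gen == n_gen
            n_m = design.n_sires_per_line
            n_f = design.n_dams_per_line if parental else design.n_base_females_per_line
            prev_m = males.get((line, gen - 1), [])
            prev_f = females.get((line, gen - 1), [])
            ms, fs = [], []
            for i in range(n_m):
                aid = f"{line}G{gen}M{i:03d}"
                sire = rng.choice(prev_m) if prev_m else ""
                dam = rng.choice(prev_f) if prev_f else ""
                rows.append(
                    {"animal": aid, "sire": sire, "dam": dam,
                     "generation": gen, "group": "base"}
                )
                ms.append(aid)
            for i in range(n_f):
                aid = f"{line}G{gen}F{i:03d}"
                sire = rng.choice(prev_m) if prev_m else ""
                dam = rng.choice(prev_f) if prev_f else ""
                rows.append(
                    {"animal": aid, "sire": sire, "dam": dam,
                     "generation": gen, "group": "base"}
                )
                fs.append(aid)
            males[(line, gen)] = ms
            females[(line, gen)] = fs

    half = design.n_sires_per_line * design.n_dams_per_sire_cross
    for group in design.groups:
        n_off = design.offspring_per_group.get(group, 0)
        if n_off == 0:
            continue
        sire_line, dam_line = group[0], group[1]
        sires = males[(sire_line, n_gen)]
        dams_all = females[(dam_line, n_gen)]
        pure = sire_line == dam_line
        dams = dams_all[:half] if pure else dams_all[half:]
        pairs = []
        for i, s in enumerate(sires):
            for j in range(design.n_dams_per_sire_cross):
                pairs.append((s, dams[i * design.n_dams_per_sire_cross + j]))
        for k in range(n_off):
            s, d = pairs[k % len(pairs)]
            rows.append(
                {
                    "animal": f"{group}_{k:04d}",
                    "sire": s,
                    "dam": d,
                    "generation": n_gen + 1,
                    "group": group,
                }
            )
    return Pedigree(pd.DataFrame(rows))


def simulate_rack_assignment(ped: Pedigree, n_racks: int = 24, seed: int = 0) -> pd.Series:
    """Random rack (cage position) level, 1..n_racks, for every test hen."""
    hens = ped.table.loc[ped.table["group"] != "base", "animal"]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    return pd.Series(
        rng.integers(1, n_racks + 1, size=len(hens)), index=hens.to_numpy(), name="rack"
    )


def simulate_breeding_values(
    ped: Pedigree, params: TraitGeneticParams, seed: int
) -> pd.Series:
    """Additive genetic values down the pedigree.

    Founders are N(0, sigma_a2); descendants get the parent average plus a
    Mendelian-sampling deviation with variance
    ``sigma_a2 * (0.5 - 0.25 (F_sire + F_dam))`` (one known parent:
    ``0.75 - 0.25 F``), so the joint covariance is A * sigma_a2.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    sa2 = params.sigma_a2
    n = len(ped)
    F = ped.inbreeding()
    z = rng.normal(size=n)
    bv = np.zeros(n)
    s_idx, d_idx = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, d = s_idx[i], d_idx[i]
        if s < 0 and d < 0:
            bv[i] = z[i] * np.sqrt(sa2)
        elif s >= 0 and d >= 0:
            ms_var = sa2 * (0.5 - 0.25 * (F[s] + F[d]))
            bv[i] = 0.5 * (bv[s] + bv[d]) + z[i] * np.sqrt(ms_var)
        else:
            p = s if s >= 0 else d
            ms_var = sa2 * (0.75 - 0.25 * F[p])
            bv[i] = 0.5 * bv[p] + z[i] * np.sqrt(ms_var)
    return pd.Series(bv, index=ped.ids, name=params.name)


def simulate_phenotypes(
    ped: Pedigree,
    bv: pd.Series,
    params: TraitGeneticParams,
    rack_assignment: pd.Series,
    seed: int,
) -> pd.DataFrame:
    """Phenotypic records for the test hens of the final generation.

    Each record is group mean (with heterosis / reciprocal shifts for
    crossbreds) + rack effect + additive value + permanent environmental
    value (shared across the hen's repeats) + a record-specific residual
    with the group's variance.  Returns a long-format trait table.
    """
    params.validate()
    ss = np.random.SeedSequence([int(seed), 404])
    rng = np.random.default_rng(ss)
    hens = ped.table.loc[ped.table["group"] != "base", ["animal", "group"]]
    missing_bv = set(hens["animal"]) - set(bv.index)
    if missing_bv:
        raise ValueError(f"no breeding value for animals {sorted(missing_bv)[:5]}")
    missing_rack = set(hens["animal"]) - set(rack_assignment.index)
    if missing_rack:
        raise ValueError(
            f"no rack assignment for animal {sorted(missing_rack)[0]!r}"
            + (f" (+{len(missing_rack) - 1} more)" if len(missing_rack) > 1 else "")
        )
    rack_levels = np.sort(pd.unique(rack_assignment))
    rack_eff = pd.Series(
        rng.normal(0.0, params.rack_sd, size=rack_levels.size), index=rack_levels
    )
    rows = []
    lines = tuple(sorted({g[0] for g in hens["group"]}))
    if len(lines) != 2:
        lines = LINES
    # order lines to match group labels (cross12 = lines[0]+lines[1])
    crosses = [g for g in hens["group"].unique() if g[0] != g[1]]
    if crosses:
        lines = (crosses[0][0], crosses[0][1])
    pe_draw = rng.normal(0.0, np.sqrt(params.sigma_pe2), size=len(hens))
    for k, (_, hen) in enumerate(hens.iterrows()):
        a, g = hen["animal"], hen["group"]
        mu = params.group_mean(g, lines)
        base = mu + rack_eff[rack_assignment[a]] + bv[a] + pe_draw[k]
        e_sd = params.residual_sd(g)
        resid = rng.normal(0.0, e_sd, size=params.n_records) if e_sd > 0 else np.zeros(params.n_records)
        for rix in range(params.n_records):
            rows.append(
                {
                    "hen": a,
                    "group": g,
                    "rack": int(rack_assignment[a]),
                    "trait": params.name,
                    "age": params.age_label,
                    "rep": rix,
                    "value": base + resid[rix],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
def simulate_laying_records(
    ped: Pedigree, params: LayingProcessParams, seed: int
) -> LayRecords:
    """Daily laying histories for the test hens.

    Per hen: age at first egg is drawn from the group's normal distribution;
    from that day to ``end_day`` the hen follows the two-state daily chain,
    laying on 'lay' days.  Clock times start near ``first_lay_time_h`` at
    the beginning of a clutch and drift later by ``oviposition_lag_h - 24``
    hours per within-clutch day, snapped to the 0.5-h grid and capped at
    the 07:00-19:00 recording window.  A ``nonlayer_fraction`` of hens lays
    nothing at all.
    """
    params.validate()
    hens = ped.table.loc[ped.table["group"] != "base", ["animal", "group"]]
    root = np.random.SeedSequence([int(seed), 505])
    picker = np.random.default_rng(root)
    nonlayer = picker.random(len(hens)) < params.nonlayer_fraction
    child_seeds = root.spawn(len(hens))
    drift = params.oviposition_lag_h - 24.0
    rows = []
    for k, (_, hen) in enumerate(hens.iterrows()):
        if nonlayer[k]:
            continue
        rng = np.random.default_rng(child_seeds[k])
        afe_mean = (
            params.afe_mean.get(hen["group"], 168.0)
            if isinstance(params.afe_mean, dict)
            else params.afe_mean
        )
        afe = int(round(rng.normal(afe_mean, params.afe_sd)))
        afe = max(afe, 130)
        day = afe
        laying = True
        clutch_day = 0
        t0 = params.first_lay_time_h
        while day <= params.end_day:
            if laying:
                frac = (day - afe) / max(params.end_day - afe, 1)
                t = t0 + clutch_day * drift
                t = min(max(t, 7.0), 19.0)
                t = np.round(t * 2.0) / 2.0
                rows.append({"hen": hen["animal"], "day": day, "time_h": t})
                p_next = params._interp(params.p_lay_lay, frac)
            else:
                frac = (day - afe) / max(params.end_day - afe, 1)
                p_next = params._interp(params.p_pause_lay, frac)
            nxt = rng.random() < p_next
            if nxt and not laying:
                clutch_day = 0
                t0 = params.first_lay_time_h + rng.choice([-0.5, 0.0, 0.5])
            elif nxt:
                clutch_day += 1
            laying = nxt
            day += 1
    rec = pd.DataFrame(rows, columns=["hen", "day", "time_h"])
    hen_tab = hens.rename(columns={"animal": "hen"}).reset_index(drop=True)
    return LayRecords(records=rec, hens=hen_tab, window=(1, params.end_day))


# ---------------------------------------------------------------------- #
def measurements_from_traits(trait_table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Egg-measurement rows consistent with latent trait values.

    Inverts the derived-trait definitions so that downstream derivation
    recovers the simulated latent values exactly: for a latent first-egg
    weight the three first eggs all weigh that value; egg width/length are
    chosen so that 100*width/length equals the latent shape index; shell
    and yolk weights are latent ratio / 100 times the egg weight.
    Expects trait names FEWt, EWt<age>, ESI<age>, ESR<age>, YR<age>.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    by_hen_age: dict = {}
    for _, row in trait_table.iterrows():
        tr = row["trait"]
        if tr.startswith("FEWt"):
            kind, age = "FEWt", "first"
        else:
            for prefix in ("EWt", "ESI", "ESR", "YR"):
                if tr.startswith(prefix) and tr[len(prefix):].isdigit():
                    kind, age = prefix, tr[len(prefix):]
                    break
            else:
                continue
        rep = int(row["rep"]) if "rep" in row.index else 0
        by_hen_age.setdefault((row["hen"], age, rep), {})[kind] = row["value"]
    rows = []
    for (hen, age, _rep), vals in by_hen_age.items():
        if age == "first":
            for _ in range(3):
                rows.append(
                    {"hen": hen, "age_weeks": "first",
                     "egg_weight": vals["FEWt"], "width": np.nan, "length": np.nan,
                     "shell_weight": np.nan, "yolk_weight": np.nan}
                )
            continue
        ew = vals.get("EWt", np.nan)
        length = 57.5 + rng.normal(0, 0.5)
        width = vals["ESI"] * length / 100.0 if "ESI" in vals else np.nan
        shell = vals["ESR"] * ew / 100.0 if "ESR" in vals and np.isfinite(ew) else np.nan
        yolk = vals["YR"] * ew / 100.0 if "YR" in vals and np.isfinite(ew) else np.nan
        rows.append(
            {"hen": hen, "age_weeks": age, "egg_weight": ew, "width": width,
             "length": length, "shell_weight": shell, "yolk_weight": yolk}
        )
    return pd.DataFrame(rows)
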