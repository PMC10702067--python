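"""End-to-end analysis pipeline: simulate -> derive -> qc -> fit -> heterosis.

Stage contracts are comma-separated text files on disk, so every stage can
be re-run and inspected.  Each output carries a header comment with the
configuration hash and master seed; re-running a stage with the same
configuration and seed reproduces its outputs byte for byte.

Two built-in profiles: ``ci`` (a small design and a three-trait panel, for
quick runs) and ``paper`` (the full reciprocal-cross design with a
representative twelve-trait panel).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qcmod
from . import simulate as sim
from .animal_model import (
    AnimalModel,
    BivariateAnimalModel,
    GroupMultivariateAnimalModel,
)
from .heterosis import boxcox_transform, heterosis_table
from .pedigree import Pedigree
from .traits import derive_measurement_traits, derive_production_traits

__all__ = ["PipelineConfig", "Pipeline", "default_config"]

STAGES = ("simulate", "derive", "qc", "fit", "heterosis", "report")

HETEROSIS_CONTRASTS = {
    "WY": {"WY": 1.0, "WW": -0.5, "YY": -0.5},
    "YW": {"YW": 1.0, "WW": -0.5, "YY": -0.5},
    "recip": {"WY": 1.0, "YW": -1.0},
}


# ---------------------------------------------------------------------- #
def _from_mapping(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in {where}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    seed: int = 1
    design: sim.MatingDesign = field(default_factory=sim.MatingDesign)
    laying: sim.LayingProcessParams = field(default_factory=sim.LayingProcessParams)
    traits: list = field(default_factory=list)  # TraitGeneticParams
    fit_traits: list = field(default_factory=list)
    bivariate_pairs: list = field(default_factory=list)  # [trait1, trait2]
    group_multivariate: bool = False
    production_weeks: tuple = (43, 72, 100)
    fdr_alpha: float = 0.05
    boxcox_prefixes: tuple = ("APL",)

    def validate(self) -> None:
        self.design.validate()
        self.laying.validate()
        for t in self.traits:
            t.validate()
        for pair in self.bivariate_pairs:
            if len(pair) != 2:
                raise ValueError(f"bivariate pair {pair!r} must name two traits")

    # -- (de)serialisation --------------------------------------------- #
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = dataclasses.asdict(self.design)
        d["laying"] = dataclasses.asdict(self.laying)
        d["traits"] = [dataclasses.asdict(t) for t in self.traits]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown configuration keys {sorted(unknown)}")
        if "design" in data:
            data["design"] = _from_mapping(sim.MatingDesign, data["design"], "design")
        if "laying" in data:
            lay = dict(data["laying"])
            for key in ("p_lay_lay", "p_pause_lay"):
                if key in lay:
                    lay[key] = tuple(lay[key])
            data["laying"] = _from_mapping(sim.LayingProcessParams, lay, "laying")
        if "traits" in data:
            data["traits"] = [
                _from_mapping(sim.TraitGeneticParams, t, f"traits[{i}]")
                for i, t in enumerate(data["traits"])
            ]
        for key in ("production_weeks", "boxcox_prefixes"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------- #
def default_config(profile: str = "ci", seed: int = 1) -> PipelineConfig:
    """Built-in configurations.

    ``paper``: full reciprocal-cross design (30 sires/line, 1260 test hens)
    with a twelve-trait representative panel whose genetic parameters echo
    typical layer values (high-heritability repeated egg weights,
    low-heritability single-record production traits, moderate quality
    traits, modest positive heterosis for weights).  ``ci``: an eight-fold
    smaller design and a three-trait panel.
    """
    T = sim.TraitGeneticParams
    panel = [
        T("FEWt", {"W": 45.0, "Y": 40.6}, sigma_a2=5.8, sigma_pe2=0.0,
          sigma_e2=14.1, heterosis_shift=1.3, reciprocal_shift=-1.75,
          rack_sd=0.5, n_records=1, age_label="first"),
        T("EWt40", {"W": 59.3, "Y": 50.5}, sigma_a2=9.9, sigma_pe2=3.7,
          sigma_e2=2.4, heterosis_shift=2.0, reciprocal_shift=-1.0,
          rack_sd=0.5, n_records=3, age_label="40"),
        T("EWt72", {"W": 61.2, "Y": 55.9}, sigma_a2=9.9, sigma_pe2=5.5,
          sigma_e2=6.5, heterosis_shift=3.1, reciprocal_shift=-1.6,
          rack_sd=0.5, n_records=3, age_label="72"),
        T("EWt100", {"W": 61.9, "Y": 57.8}, sigma_a2=12.3, sigma_pe2=9.9,
          sigma_e2=7.8, heterosis_shift=4.2, reciprocal_shift=-2.4,
          rack_sd=0.5, n_records=3, age_label="100"),
        T("ESI32", {"W": 75.1, "Y": 78.0}, sigma_a2=2.4, sigma_pe2=0.7,
          sigma_e2=4.3, heterosis_shift=-0.4, reciprocal_shift=-0.2,
          rack_sd=0.3, n_records=3, age_label="32"),
        T("YR32", {"W": 26.6, "Y": 30.6}, sigma_a2=1.2, sigma_pe2=0.9,
          sigma_e2=2.0, heterosis_shift=0.6, reciprocal_shift=-0.1,
          rack_sd=0.3, n_records=3, age_label="32"),
        T("EWt32", {"W": 57.0, "Y": 48.1}, sigma_a2=6.8, sigma_pe2=2.6,
          sigma_e2=4.0, heterosis_shift=1.7, reciprocal_shift=-0.8,
          rack_sd=0.5, n_records=3, age_label="32"),
        T("ESI54", {"W": 73.4, "Y": 74.3}, sigma_a2=1.9, sigma_pe2=2.3,
          sigma_e2=3.8, heterosis_shift=-0.4, reciprocal_shift=0.1,
          rack_sd=0.3, n_records=3, age_label="54"),
        T("YR54", {"W": 28.2, "Y": 32.2}, sigma_a2=1.7, sigma_pe2=1.0,
          sigma_e2=1.0, heterosis_shift=0.5, reciprocal_shift=-0.2,
          rack_sd=0.3, n_records=3, age_label="54"),
        T("EWt54", {"W": 60.6, "Y": 53.9}, sigma_a2=12.6, sigma_pe2=3.1,
          sigma_e2=2.7, heterosis_shift=2.4, reciprocal_shift=-1.7,
          rack_sd=0.5, n_records=3, age_label="54"),
        T("AFEg", {"W": 157.7, "Y": 180.7}, sigma_a2=44.6, sigma_pe2=0.0,
          sigma_e2=36.5, heterosis_shift=-2.8, reciprocal_shift=-1.2,
          rack_sd=1.0, n_records=1, age_label="single"),
        T("EN43g", {"W": 129.0, "Y": 92.1}, sigma_a2=26.0, sigma_pe2=0.0,
          sigma_e2=147.0, heterosis_shift=2.2, reciprocal_shift=1.1,
          rack_sd=1.5, n_records=1, age_label="43"),
    ]
    if profile == "paper":
        cfg = PipelineConfig(
            seed=seed, traits=panel, fit_traits=[t.name for t in panel],
            bivariate_pairs=[
                ["EWt32", "EWt40"], ["EWt40", "EWt72"], ["EWt72", "EWt100"],
                ["EWt54", "YR54"], ["ESI32", "ESI54"],
            ],
            group_multivariate=True,
        )
    elif profile == "ci":
        design = sim.MatingDesign(
            n_sires_per_line=8,
            n_dams_per_sire_cross=3,
            offspring_per_group={"YY": 40, "WW": 36, "WY": 40, "YW": 44},
            base_generations=1,
            n_base_females_per_line=24,
        )
        laying = sim.LayingProcessParams(end_day=310)
        # FEWt + EWt54 + YR54 (egg weight at 54 weeks is needed to turn the
        # latent yolk ratio into a yolk weight measurement)
        traits = [panel[0], panel[9], panel[8]]
        cfg = PipelineConfig(
            seed=seed, design=design, laying=laying, traits=traits,
            fit_traits=[t.name for t in traits], production_weeks=(43,),
            bivariate_pairs=[["EWt54", "YR54"]],
            group_multivariate=True,
        )
    else:
        raise ValueError(f"unknown profile {profile!r}")
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------- #
class Pipeline:
    """Runs the staged analysis inside an output directory."""

    def __init__(self, config: PipelineConfig, outdir):
        self.cfg = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._header = f"# crosslay config={config.digest()} seed={config.seed}\n"

    # -- io helpers ----------------------------------------------------- #
    def _write(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        with open(path, "w") as fh:
            fh.write(self._header)
            df.to_csv(fh, index=False, lineterminator="\n")
        return path

    def _read(self, name: str, stage: str) -> pd.DataFrame:
        path = self.outdir / name
        if not path.exists():
            raise FileNotFoundError(
                f"{path.name} is missing - run the '{stage}' stage first"
            )
        return pd.read_csv(path, comment="#")

    # -- stages --------------------------------------------------------- #
    def run_simulate(self) -> None:
        cfg = self.cfg
        ped = sim.simulate_pedigree(cfg.design, seed=cfg.seed)
        racks = sim.simulate_rack_assignment(ped, cfg.design.n_racks, seed=cfg.seed)
        self._write(ped.table, "pedigree.csv")
        self._write(
            racks.rename_axis("hen").reset_index(), "racks.csv"
        )
        frames = []
        for i, tp in enumerate(cfg.traits):
            bv = sim.simulate_breeding_values(ped, tp, seed=cfg.seed + 1000 + i)
            frames.append(
                sim.simulate_phenotypes(ped, bv, tp, racks, seed=cfg.seed + 2000 + i)
            )
        phen = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["hen", "group", "rack", "trait", "age", "rep", "value"])
        )
        self._write(phen, "phenotypes.csv")
        meas = sim.measurements_from_traits(phen, seed=cfg.seed + 3000)
        self._write(meas, "measurements.csv")
        lay = sim.simulate_laying_records(ped, cfg.laying, seed=cfg.seed + 4000)
        self._write(lay.records, "lay_records.csv")
        hens = lay.hens.merge(
            racks.rename_axis("hen").reset_index(), on="hen", how="left"
        )
        self._write(hens, "hens.csv")

    def run_derive(self) -> None:
        hens = self._read("hens.csv", "simulate")
        meas = self._read("measurements.csv", "simulate")
        rec = self._read("lay_records.csv", "simulate")
        lay = sim.LayRecords(records=rec, hens=hens, window=(1, self.cfg.laying.end_day))
        prod = derive_production_traits(lay, weeks=self.cfg.production_weeks)
        mtraits = (
            derive_measurement_traits(meas, hens)
            if len(meas)
            else pd.DataFrame(columns=prod.columns)
        )
        traits = pd.concat([mtraits, prod], ignore_index=True)
        self._write(traits, "traits.csv")

    def run_qc(self) -> None:
        traits = self._read("traits.csv", "derive")
        rec = self._read("lay_records.csv", "simulate")
        cleaned, rep_nl = qcmod.remove_nonlayers(traits, rec)
        cleaned, rep_out = qcmod.remove_outliers_3sd(cleaned)
        self._write(cleaned, "traits_clean.csv")
        self._write(rep_out.outliers, "qc_outliers.csv")
        self._write(rep_nl.nonlayers, "qc_nonlayers.csv")
        self._write(qcmod.descriptives(cleaned), "descriptives.csv")

    def run_fit(self) -> None:
        traits = self._read("traits_clean.csv", "qc")
        ped = Pedigree.from_csv(self.outdir / "pedigree.csv")
        fit_traits = self.cfg.fit_traits or sorted(traits["trait"].unique())
        fit_rows, mean_rows, p_rows = [], [], []
        for tr in fit_traits:
            sub = traits[traits["trait"] == tr].dropna(subset=["value"])
            if sub.empty or sub["value"].nunique() < 2:
                continue
            res = AnimalModel(sub, ped, trait=tr).fit()
            fit_rows.append(
                {
                    "trait": tr,
                    "converged": res.converged,
                    "status": "ok" if res.converged else "DNC",
                    "loglik": res.loglik,
                    "sigma_a2": res.sigma_a2,
                    "sigma_pe2": res.sigma_pe2,
                    "sigma_e2": res.sigma_e2,
                    "sigma_p2": res.sigma_p2,
                    "h2": res.heritability,
                    "h2_se": res.heritability_se,
                    "repeatability": res.repeatability,
                }
            )
            gm = res.predicted_group_means()
            for g, row in gm.iterrows():
                mean_rows.append(
                    {"trait": tr, "group": g, "mean": row["mean"], "se": row["se"]}
                )
            contrast_res = res
            if any(tr.startswith(p) for p in self.cfg.boxcox_prefixes):
                bc = sub.copy()
                bc["value"], _, _ = boxcox_transform(bc["value"].to_numpy())
                contrast_res = AnimalModel(bc, ped, trait=tr).fit()
            prow = {"trait": tr}
            for tag, weights in HETEROSIS_CONTRASTS.items():
                try:
                    prow[f"p_{tag}"] = contrast_res.wald_contrast(weights)["p_value"]
                except ValueError:
                    prow[f"p_{tag}"] = np.nan
            p_rows.append(prow)
        self._write(pd.DataFrame(fit_rows), "fits.csv")
        self._write(pd.DataFrame(mean_rows), "group_means.csv")
        self._write(pd.DataFrame(p_rows), "contrast_pvalues.csv")
        if self.cfg.group_multivariate:
            self._write(self._fit_group_multivariate(traits, ped, fit_traits),
                        "fits_group_multivariate.csv")
        if self.cfg.bivariate_pairs:
            self._write(self._fit_bivariate_pairs(traits, ped), "correlations.csv")

    def _fit_group_multivariate(self, traits, ped, fit_traits) -> pd.DataFrame:
        rows = []
        for tr in fit_traits:
            sub = traits[traits["trait"] == tr].dropna(subset=["value"])
            if sub.empty or sub["value"].nunique() < 2:
                continue
            res = GroupMultivariateAnimalModel(sub, ped, trait=tr).fit()
            for lev, comp in res.by_group.iterrows():
                rows.append({"trait": tr, "pseudo_group": lev,
                             "status": "ok" if res.converged else "DNC",
                             **comp.to_dict()})
            w = res.weighted_components()
            rows.append({
                "trait": tr, "pseudo_group": "weighted",
                "status": "ok" if res.converged else "DNC",
                **w, "h2": res.heritability, "repeatability": res.repeatability,
            })
        return pd.DataFrame(rows)

    def _fit_bivariate_pairs(self, traits, ped) -> pd.DataFrame:
        rows = []
        for t1, t2 in self.cfg.bivariate_pairs:
            sub = traits[traits["trait"].isin([t1, t2])].dropna(subset=["value"])
            try:
                res = BivariateAnimalModel(sub, ped, traits=(t1, t2)).fit()
            except (ValueError, np.linalg.LinAlgError):
                rows.append({"trait_1": t1, "trait_2": t2, "status": "DNC",
                             "r_a": np.nan, "r_e": np.nan, "r_p": np.nan,
                             "r_a_se": np.nan})
                continue
            rows.append({
                "trait_1": t1, "trait_2": t2,
                "status": "ok" if res.converged else "DNC",
                "r_a": res.r_a, "r_e": res.r_e, "r_p": res.r_p,
                "r_a_se": res.r_a_se,
            })
        return pd.DataFrame(rows)

    @staticmethod
    def correlation_matrix(correlations: pd.DataFrame) -> pd.DataFrame:
        """Square table: genetic correlations above the diagonal,
        phenotypic below; non-converged pairs rendered as ``DNC``."""
        names = sorted(
            set(correlations["trait_1"]) | set(correlations["trait_2"])
        )
        mat = pd.DataFrame("", index=names, columns=names)
        for row in correlations.itertuples():
            a, b = sorted((row.trait_1, row.trait_2))
            if row.status != "ok":
                mat.loc[a, b] = mat.loc[b, a] = "DNC"
            else:
                mat.loc[a, b] = f"{row.r_a:.2f}"  # genetic above diagonal
                mat.loc[b, a] = f"{row.r_p:.2f}"  # phenotypic below
        return mat

    def run_heterosis(self) -> None:
        means = self._read("group_means.csv", "fit")
        pvals = self._read("contrast_pvalues.csv", "fit").set_index("trait")
        wide = means.pivot(index="trait", columns="group", values="mean")
        het = heterosis_table(
            wide, p_values=pvals,
            alpha_tiers=(self.cfg.fdr_alpha, self.cfg.fdr_alpha / 5.0),
        )
        self._write(het.reset_index(), "heterosis.csv")

    def run_report(self) -> None:
        desc = self._read("descriptives.csv", "qc")
        fits = self._read("fits.csv", "fit")
        het = pd.read_csv(self.outdir / "heterosis.csv", comment="#", keep_default_na=False)
        lines = [
            "crosslay pipeline report",
            f"config {self.cfg.digest()}  seed {self.cfg.seed}",
            "",
            "== Descriptive statistics (after QC) ==",
            desc.round(3).to_string(index=False),
            "",
            "== Variance components and genetic parameters ==",
        ]
        if len(fits):
            show = fits.copy()
            for col in ("sigma_a2", "sigma_pe2", "sigma_e2", "sigma_p2",
                        "h2", "h2_se", "repeatability", "loglik"):
                show[col] = show[col].astype(float).round(3)
            lines.append(show.to_string(index=False))
        else:
            lines.append("no model fits")
        corr_path = self.outdir / "correlations.csv"
        if corr_path.exists():
            corr = pd.read_csv(corr_path, comment="#")
            lines += [
                "",
                "== Correlations (genetic above / phenotypic below diagonal) ==",
                self.correlation_matrix(corr).to_string() if len(corr)
                else "no bivariate fits",
            ]
        lines += ["", "== Heterosis and reciprocal-cross differences =="]
        if len(het):
            show = het.copy()
            for col in ("WW", "YY", "WY", "YW", "parental_mean"):
                show[col] = pd.to_numeric(show[col]).round(2)
            for col in ("H_pct_WY", "H_pct_YW", "recip_pct"):
                show[col] = pd.to_numeric(show[col]).round(1)
            keep = [c for c in show.columns if not c.startswith("fdr_")]
            lines.append(show[keep].to_string(index=False))
        else:
            lines.append("no contrasts computed")
        if len(fits) and (~fits["converged"].astype(bool)).any():
            dnc = fits.loc[~fits["converged"].astype(bool), "trait"].tolist()
            lines += ["", f"DNC (did not converge): {', '.join(dnc)}"]
        text = "\n".join(lines) + "\n"
        (self.outdir / "report.txt").write_text(self._header + text)

    # -- orchestration --------------------------------------------------- #
    def run_stage(self, stage: str) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        getattr(self, f"run_{stage}")()

    def run_all(self) -> None:
        self.cfg.to_yaml(self.outdir / "config_resolved.yaml")
        for stage in STAGES:
            self.run_stage(stage)
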