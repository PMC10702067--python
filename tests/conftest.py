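"""Shared fixtures: small pedigrees and simulated datasets."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crosslay.pedigree import Pedigree

# make scripts/acceptance.py importable (single implementation of the
# end-to-end validation computations, shared by the acceptance tests)
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def trio_pedigree() -> Pedigree:
    """Two unrelated founders and their two full-sib offspring."""
    return Pedigree(
        pd.DataFrame(
            {
                "animal": ["s", "d", "o1", "o2"],
                "sire": ["", "", "s", "s"],
                "dam": ["", "", "d", "d"],
            }
        )
    )


@pytest.fixture(scope="session")
def looped_pedigree() -> Pedigree:
    """Six animals with a full-sib mating (inbred offspring)."""
    return Pedigree(
        pd.DataFrame(
            {
                "animal": ["a", "b", "c", "d", "e", "f"],
                "sire": ["", "", "a", "a", "c", "c"],
                "dam": ["", "", "b", "b", "d", "d"],
            }
        )
    )


def random_pedigree(n_founders: int, n_descendants: int, seed: int) -> Pedigree:
    """A random valid pedigree: descendants pick earlier animals as parents."""
    rng = np.random.default_rng(seed)
    rows = [
        {"animal": f"f{i}", "sire": "", "dam": ""} for i in range(n_founders)
    ]
    ids = [r["animal"] for r in rows]
    for k in range(n_descendants):
        s, d = rng.choice(len(ids), size=2, replace=True)
        rows.append(
            {"animal": f"x{k}", "sire": ids[s], "dam": ids[d]}
        )
        ids.append(f"x{k}")
    return Pedigree(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def halfsib_data():
    """Balanced paternal half-sib design + its ANOVA variance components."""
    rng = np.random.default_rng(42)
    n_sires, n_off, sa2, se2 = 40, 12, 4.0, 12.0
    rows = [{"animal": f"s{i}", "sire": "", "dam": ""} for i in range(n_sires)]
    for i in range(n_sires):
        for j in range(n_off):
            rows.append({"animal": f"o{i}_{j}", "sire": f"s{i}", "dam": ""})
    ped = Pedigree(pd.DataFrame(rows))
    offspring = [a for a in ped.ids if a.startswith("o")]
    sire_of = np.array([int(a.split("_")[0][1:]) for a in offspring])
    sire_eff = rng.normal(0, np.sqrt(sa2 / 4), n_sires)
    y = 20 + sire_eff[sire_of] + rng.normal(0, np.sqrt(0.75 * sa2 + se2), len(offspring))
    df = pd.DataFrame({"y": y, "s": sire_of})
    gmean = df.groupby("s")["y"].mean()
    msb = n_off * ((gmean - y.mean()) ** 2).sum() / (n_sires - 1)
    msw = ((df["y"] - gmean[df["s"]].values) ** 2).sum() / (n_sires * (n_off - 1))
    sa2_anova = 4 * (msb - msw) / n_off
    data = pd.DataFrame(
        {
            "animal": offspring,
            "group": "WW",
            "trait": "y",
            "value": y,
        }
    )
    return {"ped": ped, "data": data, "sa2_anova": sa2_anova, "n_off": n_off}


@pytest.fixture(scope="session")
def family_data():
    """Simulated 4-group data with known components, for model unit tests."""
    from crosslay.simulate import (
        MatingDesign,
        TraitGeneticParams,
        simulate_breeding_values,
        simulate_pedigree,
        simulate_phenotypes,
        simulate_rack_assignment,
    )

    design = MatingDesign(
        n_sires_per_line=10,
        n_dams_per_sire_cross=3,
        offspring_per_group={"YY": 90, "WW": 90, "WY": 90, "YW": 90},
        base_generations=1,
        n_base_females_per_line=30,
    )
    ped = simulate_pedigree(design, seed=11)
    racks = simulate_rack_assignment(ped, 8, seed=11)
    params = TraitGeneticParams(
        "T",
        {"W": 55.0, "Y": 50.0},
        sigma_a2=6.0,
        sigma_pe2=3.0,
        sigma_e2=5.0,
        heterosis_shift=1.0,
        rack_sd=0.4,
        n_records=3,
    )
    bv = simulate_breeding_values(ped, params, seed=12)
    phen = simulate_phenotypes(ped, bv, params, racks, seed=13)
    return {"ped": ped, "phen": phen, "params": params, "racks": racks}
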