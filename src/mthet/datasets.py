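"""Packaged fixtures and ready-made simulated datasets.

The CSV fixtures transcribe the published electropherogram-percentage tables
(16S family table; COI adult table; COI brood/tissue table).  The simulated
datasets bundle a family, a multi-tissue individual and a sexed adult panel
generated under one inheritance scenario, already converted to a
:class:`~mthet.peak_calls.CallTable` for the classifier.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from . import peak_calls, trace_sim
from .peak_calls import CallTable, SpecimenMeta, call_trace_set
from .trace_sim import HaplotypeSeq, MixtureState, ScenarioConfig, stream_rng

FIXTURE_FILES = {
    "table2_16s": "table2_16s.csv",
    "table4_coi_adults": "table4_coi_adults.csv",
    "table5_coi_families_tissues": "table5_coi_families_tissues.csv",
}

POSITIONS_16S = (365, 580)
POSITIONS_COI = (240, 264, 303, 375)


def fixture_path(name: str):
    """Filesystem path of a packaged fixture CSV."""
    return resources.files("mthet.fixtures") / FIXTURE_FILES[name]


def load_fixture(name: str, min_minor_fraction: float = peak_calls.DEFAULT_MIN_MINOR_FRACTION) -> CallTable:
    return peak_calls.read_percent_csv(fixture_path(name), min_minor_fraction)


def load_all_fixtures(min_minor_fraction: float = peak_calls.DEFAULT_MIN_MINOR_FRACTION) -> dict[str, CallTable]:
    """Per-locus call tables from the packaged fixtures (COI tables merged)."""
    t2 = load_fixture("table2_16s", min_minor_fraction)
    t4 = load_fixture("table4_coi_adults", min_minor_fraction)
    t5 = load_fixture("table5_coi_families_tissues", min_minor_fraction)
    return {"16S": t2, "COI": peak_calls.merge_tables(t4, t5)}


# ---------------------------------------------------------------------------
# scenario datasets for the classifier
# ---------------------------------------------------------------------------

#: two mitochondrial variants differing at the diagnostic positions, plus the
#: same second variant reused as paternal donor / nuclear pseudogene copy
_SIM_LENGTH = 40
_SIM_POSITIONS = (10, 30)


def default_haplotypes() -> tuple[HaplotypeSeq, HaplotypeSeq]:
    rng = np.random.default_rng(20200319)
    seq = "".join(rng.choice(list("ACGT"), size=_SIM_LENGTH))
    h1 = list(seq)
    h2 = list(seq)
    for pos, base in zip(_SIM_POSITIONS, ("T", "T")):
        h1[pos - 1] = base
    for pos, base in zip(_SIM_POSITIONS, ("C", "A")):
        h2[pos - 1] = base
    return HaplotypeSeq("H1", "".join(h1)), HaplotypeSeq("H2", "".join(h2))


def _drifted_mix(rng: np.random.Generator, minor: float, n: int) -> MixtureState:
    k = rng.binomial(n, minor)
    return MixtureState({"H1": 1.0 - k / n, "H2": k / n})


def simulate_scenario_dataset(
    scenario: str,
    seed: int = 0,
    n_eggs: int = 12,
    n_tissues: int = 6,
    n_adults_per_sex: int = 3,
    leakage_rate: float = 0.2,
    config_kwargs: dict | None = None,
) -> tuple[CallTable, dict]:
    """One labelled dataset (family + tissue panel + sexed adults) per scenario."""
    h1, h2 = default_haplotypes()
    haps = [h1, h2]
    positions = list(_SIM_POSITIONS)
    cfg = ScenarioConfig(
        scenario=scenario,
        leakage_rate=leakage_rate if scenario == "paternal_leakage" else 0.0,
        n_eggs=n_eggs,
        seed=seed,
        **(config_kwargs or {}),
    )
    numt_id = "H2" if scenario in ("numt_homozygous", "numt_heterozygous") else None
    paternal_id = "H2" if scenario in ("paternal_leakage", "dui") else None
    mother_mix = (
        MixtureState({"H1": 0.5, "H2": 0.5})
        if scenario == "mito_duplication"
        else MixtureState({"H1": 1.0})
    )

    fam = trace_sim.simulate_family(
        haps, mother_mix, cfg, paternal_id=paternal_id, numt_id=numt_id, mother_id="SIM-MOTHER"
    )
    table = peak_calls.call_family(fam, positions)

    # multi-tissue individual
    if scenario == "paternal_leakage":
        panel_mix = MixtureState({"H1": 1.0 - cfg.leakage_rate, "H2": cfg.leakage_rate})
    elif scenario == "dui":
        panel_mix = MixtureState(
            {"H1": 1.0 - trace_sim.DUI_MALE_FRACTION, "H2": trace_sim.DUI_MALE_FRACTION}
        )
    elif scenario == "mito_duplication":
        panel_mix = MixtureState({"H1": 0.5, "H2": 0.5})
    else:
        panel_mix = MixtureState({"H1": 1.0})
    tissues = [f"tissue{i + 1}" for i in range(n_tissues)]
    panel = trace_sim.simulate_tissue_panel(
        haps, panel_mix, tissues, cfg, numt_id=numt_id, individual_id="SIM-PANEL"
    )
    panel_sex = "male" if scenario == "dui" else "female"
    table = peak_calls.merge_tables(table, peak_calls.call_tissue_panel(panel, positions, sex=panel_sex))

    # sexed adult cross-section
    rng = stream_rng(seed, "adults", scenario)
    adult_truth = []
    for sex in ("male", "female"):
        for k in range(n_adults_per_sex):
            name = f"SIM-{sex[0].upper()}{k + 1}"
            carries_numt = False
            if scenario == "maternal_strict":
                mix = MixtureState({"H1": 1.0})
            elif scenario == "paternal_leakage":
                mix = _drifted_mix(rng, cfg.leakage_rate, cfg.bottleneck_N)
            elif scenario == "numt_homozygous":
                mix, carries_numt = MixtureState({"H1": 1.0}), True
            elif scenario == "numt_heterozygous":
                mix = MixtureState({"H1": 1.0})
                carries_numt = bool(rng.random() < 0.5)
            elif scenario == "mito_duplication":
                mix = MixtureState({"H1": 0.5, "H2": 0.5})
            else:  # dui
                mix = (
                    _drifted_mix(rng, trace_sim.DUI_MALE_FRACTION, cfg.bottleneck_N)
                    if sex == "male"
                    else MixtureState({"H1": 1.0})
                )
            obs = trace_sim._observed_mix(mix, "H2" if carries_numt else None, cfg.numt_signal_ratio)
            trace = trace_sim.simulate_trace_set(haps, obs, seed=seed, specimen=name)
            table.add(
                SpecimenMeta(specimen=name, role="adult", sex=sex),
                call_trace_set(trace, positions),
            )
            adult_truth.append(
                {"specimen": name, "sex": sex, "carries_numt": carries_numt, "fractions": dict(obs.fractions)}
            )

    truth = {
        "scenario": scenario,
        "family": fam.truth,
        "panel": panel.truth,
        "adults": adult_truth,
        "positions": positions,
    }
    return table, truth


#: hypothesis whose survival the generating scenario implies; maternal_strict
#: instead implies a clean dataset
SCENARIO_HYPOTHESIS = {
    "paternal_leakage": "paternal_leakage",
    "numt_homozygous": "numt_homozygous",
    "numt_heterozygous": "numt_heterozygous",
    "mito_duplication": "mito_duplication",
    "dui": "dui",
}


def scenario_recovered(scenario: str, result) -> bool:
    """True when the classifier keeps the generating scenario on the table."""
    if scenario == "maternal_strict":
        return result.final_call == "no_heteroplasmy_detected"
    hyp = SCENARIO_HYPOTHESIS[scenario]
    return result.verdicts[hyp].status != "rejected"
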