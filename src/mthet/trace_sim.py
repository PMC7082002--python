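"""Synthetic Sanger-trace and pedigree simulator.

Generates per-position four-channel peak heights for specimen amplicons,
mother/egg families under a germline bottleneck, multi-tissue panels and
single-molecule clone sets, each under one of the candidate explanations for
double peaks (strict maternal inheritance, paternal leakage, homozygous or
heterozygous nuclear pseudogene, mitochondrial gene duplication, doubly
uniparental inheritance).  Every draw descends from one integer seed through
named sub-streams, so any piece can be regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, LengthMismatchError

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SCENARIOS = (
    "maternal_strict",
    "paternal_leakage",
    "numt_homozygous",
    "numt_heterozygous",
    "mito_duplication",
    "dui",
)

#: somatic fraction of the male-transmitted genome in males under DUI
DUI_MALE_FRACTION = 0.3


def stream_rng(seed: int, *keys: object) -> np.random.Generator:
    """Generator for a named sub-stream of the global seed.

    Keys are hashed with CRC32 so the stream depends only on the textual
    key path, not on call order.
    """
    spawn_key = tuple(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn_key))


@dataclass(frozen=True)
class HaplotypeSeq:
    """A named, gap-free nucleotide sequence (1-based positions)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"haplotype {self.id!r} has an empty sequence")
        bad = set(self.seq) - set(BASES)
        if bad:
            raise ValueError(f"haplotype {self.id!r} contains non-ACGT symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def base_at(self, position: int) -> str:
        """Base at a 1-based position."""
        return self.seq[position - 1]


@dataclass(frozen=True)
class MixtureState:
    """Haplotype-id -> fraction; fractions sum to 1."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("empty mixture")
        vals = np.asarray(list(self.fractions.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("mixture fractions must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {vals.sum()!r}, not 1")

    def items(self):
        return self.fractions.items()

    def get(self, hap_id: str) -> float:
        return float(self.fractions.get(hap_id, 0.0))


@dataclass
class ScenarioConfig:
    """Knobs for one simulated inheritance scenario.

    All parameters beyond the scenario label are free choices of the
    simulator, not measured quantities.
    """

    scenario: str
    leakage_rate: float = 0.0
    bottleneck_N: int = 200
    tissue_drift_N: int = 200
    numt_signal_ratio: float = 1.0 / 3.0
    n_eggs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if not 0.0 <= self.leakage_rate <= 1.0:
            raise ConfigurationError("leakage_rate must lie in [0, 1]")
        if self.leakage_rate > 0 and self.scenario != "paternal_leakage":
            raise ConfigurationError("leakage_rate > 0 only makes sense under paternal_leakage")
        if self.bottleneck_N < 1 or self.tissue_drift_N < 1:
            raise ConfigurationError("bottleneck_N and tissue_drift_N must be positive")
        if not 0.0 < self.numt_signal_ratio < 1.0:
            raise ConfigurationError("numt_signal_ratio must lie in (0, 1)")
        if self.n_eggs < 0:
            raise ConfigurationError("n_eggs must be nonnegative")


@dataclass
class ReadTrace:
    """One sequencing read: positions x 4 channel heights plus a baseline scale."""

    direction: str  # "forward" | "reverse"
    heights: np.ndarray  # shape (L, 4), order A,C,G,T
    baseline_level: float = 0.0


@dataclass
class TraceSet:
    """Both reads of one specimen amplicon."""

    specimen: str
    reads: dict[str, ReadTrace] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return next(iter(self.reads.values())).heights.shape[0]

    def heights_at(self, position: int) -> dict[str, dict[str, float]]:
        """Per-read channel->height mapping at a 1-based position."""
        out = {}
        for direction, read in self.reads.items():
            row = read.heights[position - 1]
            out[direction] = {b: float(row[BASE_INDEX[b]]) for b in BASES}
        return out


def _check_haplotypes(haplotypes: Sequence[HaplotypeSeq], mix: MixtureState) -> int:
    if not haplotypes:
        raise ValueError("no haplotypes supplied")
    lengths = {len(h) for h in haplotypes}
    if len(lengths) != 1:
        raise LengthMismatchError(f"haplotype lengths differ: {sorted(lengths)}")
    by_id = {h.id for h in haplotypes}
    missing = set(mix.fractions) - by_id
    if missing:
        raise ValueError(f"mixture refers to unknown haplotypes: {sorted(missing)}")
    return lengths.pop()


def expected_signal(haplotypes: Sequence[HaplotypeSeq], mix: MixtureState) -> np.ndarray:
    """Noise-free per-position channel fractions, shape (L, 4); rows sum to 1."""
    length = _check_haplotypes(haplotypes, mix)
    signal = np.zeros((length, 4))
    for hap in haplotypes:
        frac = mix.get(hap.id)
        if frac == 0.0:
            continue
        for i, base in enumerate(hap.seq):
            signal[i, BASE_INDEX[base]] += frac
    return signal


def simulate_trace_set(
    haplotypes: Sequence[HaplotypeSeq],
    mix: MixtureState,
    amplitude_f: float = 1000.0,
    amplitude_r: float = 700.0,
    noise_sd: float = 0.15,
    baseline_sd: float = 0.02,
    seed: int = 0,
    specimen: str = "sim",
) -> TraceSet:
    """Simulate forward and reverse peak heights for one template mixture.

    Each channel height is ``amplitude x mixture-signal x lognormal(0, noise_sd)``
    plus half-normal baseline noise with scale ``baseline_sd x amplitude``.
    Forward and reverse amplitudes are independent, mimicking unequal PCR yield
    between the two reads.
    """
    if amplitude_f <= 0 or amplitude_r <= 0:
        raise ValueError("read amplitudes must be positive")
    if noise_sd < 0 or baseline_sd < 0:
        raise ValueError("noise parameters must be nonnegative")
    signal = expected_signal(haplotypes, mix)
    ts = TraceSet(specimen=specimen)
    for direction, amplitude in (("forward", amplitude_f), ("reverse", amplitude_r)):
        rng = stream_rng(seed, "trace", specimen, direction)
        heights = amplitude * signal
        if noise_sd > 0:
            heights = heights * rng.lognormal(mean=0.0, sigma=noise_sd, size=signal.shape)
        baseline_level = baseline_sd * amplitude
        if baseline_sd > 0:
            heights = heights + np.abs(rng.normal(0.0, baseline_level, size=signal.shape))
        ts.reads[direction] = ReadTrace(direction=direction, heights=heights, baseline_level=baseline_level)
    return ts


# ---------------------------------------------------------------------------
# families, tissues, clones
# ---------------------------------------------------------------------------


@dataclass
class FamilySim:
    """Mother + egg traces with the generating truth attached."""

    mother: TraceSet
    eggs: list[TraceSet]
    truth: dict


@dataclass
class TissuePanelSim:
    """Per-tissue traces for one individual with the generating truth."""

    tissues: dict[str, TraceSet]
    truth: dict


def _bottleneck_mixture(mix_vec: np.ndarray, ids: list[str], n: int, rng: np.random.Generator) -> MixtureState:
    """One multinomial bottleneck pass: counts/N over the haplotype pool."""
    counts = rng.multinomial(n, mix_vec / mix_vec.sum())
    return MixtureState({h: c / n for h, c in zip(ids, counts)})


def _observed_mix(mito: MixtureState, numt_id: str | None, ratio: float) -> MixtureState:
    """Blend a nuclear pseudogene signal into the mitochondrial mixture."""
    if numt_id is None:
        return mito
    obs = {h: f * (1.0 - ratio) for h, f in mito.items()}
    obs[numt_id] = obs.get(numt_id, 0.0) + ratio
    return MixtureState(obs)


def simulate_family(
    haplotypes: Sequence[HaplotypeSeq],
    mother_mix: MixtureState,
    config: ScenarioConfig,
    paternal_id: str | None = None,
    numt_id: str | None = None,
    trace_kwargs: dict | None = None,
    mother_id: str = "MOTHER",
) -> FamilySim:
    """Simulate a mother and her clutch of eggs under one scenario.

    Egg mitochondrial fractions are drawn as ``Multinomial(bottleneck_N, zygote
    fractions) / bottleneck_N`` (binomial marginals per haplotype); the zygote
    fraction is ``(1 - leakage_rate) * maternal + leakage_rate * paternal``
    under paternal leakage and the maternal mixture otherwise.  NUMT scenarios
    add a fixed, drift-free nuclear signal to every carrier's trace; the
    duplication scenario pins every individual at a 1:1 two-variant signal;
    DUI gives male eggs (and only males) a paternal-genome component.
    """
    scenario = config.scenario
    _check_haplotypes(haplotypes, mother_mix)
    hap_ids = [h.id for h in haplotypes]
    if scenario == "paternal_leakage" and paternal_id is None:
        raise ConfigurationError("paternal_leakage requires a paternal haplotype id")
    if scenario in ("numt_homozygous", "numt_heterozygous") and numt_id is None:
        raise ConfigurationError("NUMT scenarios require a numt haplotype id")
    if scenario in ("dui", "mito_duplication") and paternal_id is None and scenario == "dui":
        raise ConfigurationError("dui requires the male-transmitted haplotype id (paternal_id)")
    if paternal_id is not None and paternal_id not in hap_ids:
        raise ValueError(f"unknown paternal haplotype {paternal_id!r}")
    if numt_id is not None and numt_id not in hap_ids:
        raise ValueError(f"unknown numt haplotype {numt_id!r}")

    trace_kwargs = dict(trace_kwargs or {})
    seed = config.seed
    rng = stream_rng(seed, "family", mother_id)

    maternal_vec = np.array([mother_mix.get(h) for h in hap_ids], dtype=float)
    if scenario == "paternal_leakage":
        paternal_vec = np.array([1.0 if h == paternal_id else 0.0 for h in hap_ids])
        zygote_vec = (1.0 - config.leakage_rate) * maternal_vec + config.leakage_rate * paternal_vec
    elif scenario == "dui":
        paternal_vec = np.array([1.0 if h == paternal_id else 0.0 for h in hap_ids])
        zygote_vec = maternal_vec  # female germ line transmits F only
    else:
        paternal_vec = None
        zygote_vec = maternal_vec

    if scenario == "mito_duplication":
        if len(hap_ids) < 2:
            raise ConfigurationError("mito_duplication needs two haplotype variants")
        dup_mix = MixtureState({hap_ids[0]: 0.5, hap_ids[1]: 0.5})

    mother_numt = numt_id if scenario in ("numt_homozygous", "numt_heterozygous") else None
    if scenario == "mito_duplication":
        mother_obs = dup_mix
    else:
        mother_obs = _observed_mix(mother_mix, mother_numt, config.numt_signal_ratio)

    mother_trace = simulate_trace_set(
        haplotypes, mother_obs, seed=seed, specimen=mother_id, **trace_kwargs
    )

    eggs: list[TraceSet] = []
    truth_eggs = []
    for k in range(config.n_eggs):
        egg_id = f"{mother_id}-{k + 1}"
        sex = ""
        carries_numt = False
        if scenario == "mito_duplication":
            egg_mix = dup_mix
        else:
            egg_vec = zygote_vec.copy()
            if scenario == "dui":
                sex = "male" if rng.random() < 0.5 else "female"
                if sex == "male":
                    egg_vec = (1.0 - DUI_MALE_FRACTION) * zygote_vec + DUI_MALE_FRACTION * paternal_vec
            egg_mix = _bottleneck_mixture(egg_vec, hap_ids, config.bottleneck_N, rng)
            if scenario == "numt_homozygous":
                carries_numt = True
            elif scenario == "numt_heterozygous":
                carries_numt = bool(rng.random() < 0.5)
        egg_obs = _observed_mix(egg_mix, numt_id if carries_numt else None, config.numt_signal_ratio)
        eggs.append(simulate_trace_set(haplotypes, egg_obs, seed=seed, specimen=egg_id, **trace_kwargs))
        truth_eggs.append(
            {
                "specimen": egg_id,
                "sex": sex,
                "carries_numt": carries_numt,
                "mito_fractions": dict(egg_mix.fractions),
                "observed_fractions": dict(egg_obs.fractions),
            }
        )

    truth = {
        "scenario": scenario,
        "mother": mother_id,
        "mother_fractions": dict(mother_obs.fractions),
        "zygote_fractions": {h: float(f) for h, f in zip(hap_ids, zygote_vec)},
        "eggs": truth_eggs,
        "config": {
            "leakage_rate": config.leakage_rate,
            "bottleneck_N": config.bottleneck_N,
            "numt_signal_ratio": config.numt_signal_ratio,
            "seed": seed,
        },
    }
    return FamilySim(mother=mother_trace, eggs=eggs, truth=truth)


def simulate_tissue_panel(
    haplotypes: Sequence[HaplotypeSeq],
    individual_mix: MixtureState,
    tissues: Sequence[str],
    config: ScenarioConfig,
    numt_id: str | None = None,
    trace_kwargs: dict | None = None,
    individual_id: str = "IND",
) -> TissuePanelSim:
    """Per-tissue traces: independent binomial drift of the zygote mixture.

    Under NUMT scenarios the nuclear component is identical in every tissue
    (Mendelian signal is cell-universal); only the mitochondrial part drifts.
    The duplication scenario shows the constant 1:1 signal everywhere.
    """
    if not tissues:
        raise ValueError("tissue list must be nonempty")
    _check_haplotypes(haplotypes, individual_mix)
    hap_ids = [h.id for h in haplotypes]
    scenario = config.scenario
    if scenario in ("numt_homozygous", "numt_heterozygous") and numt_id is None:
        raise ConfigurationError("NUMT scenarios require a numt haplotype id")
    trace_kwargs = dict(trace_kwargs or {})
    rng = stream_rng(config.seed, "tissues", individual_id)
    vec = np.array([individual_mix.get(h) for h in hap_ids], dtype=float)

    panels: dict[str, TraceSet] = {}
    truth_tissues = []
    for tissue in tissues:
        if scenario == "mito_duplication":
            tissue_mix = MixtureState({hap_ids[0]: 0.5, hap_ids[1]: 0.5})
        else:
            tissue_mix = _bottleneck_mixture(vec, hap_ids, config.tissue_drift_N, rng)
        obs = _observed_mix(
            tissue_mix,
            numt_id if scenario in ("numt_homozygous", "numt_heterozygous") else None,
            config.numt_signal_ratio,
        )
        name = f"{individual_id}-{tissue}"
        panels[tissue] = simulate_trace_set(haplotypes, obs, seed=config.seed, specimen=name, **trace_kwargs)
        truth_tissues.append({"tissue": tissue, "observed_fractions": dict(obs.fractions)})

    truth = {
        "scenario": scenario,
        "individual": individual_id,
        "zygote_fractions": dict(individual_mix.fractions),
        "tissues": truth_tissues,
        "config": {"tissue_drift_N": config.tissue_drift_N, "seed": config.seed},
    }
    return TissuePanelSim(tissues=panels, truth=truth)


def simulate_clones(pool: Mapping[str, float], n_clones: int, seed: int = 0) -> list[str]:
    """Draw single molecules from a pool of molecule types.

    ``pool`` maps a molecule label (typically a full sequence or a site-state
    tag) to its fraction; fractions are renormalised.  Each clone is one
    molecule, so clones never show double peaks.
    """
    if not pool:
        raise ValueError("empty molecule pool")
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    labels = list(pool)
    weights = np.asarray([pool[k] for k in labels], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("pool fractions must be nonnegative and sum to > 0")
    rng = stream_rng(seed, "clones")
    picks = rng.choice(len(labels), size=n_clones, p=weights / weights.sum())
    return [labels[i] for i in picks]
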