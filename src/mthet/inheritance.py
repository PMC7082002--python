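"""Elimination logic over heteroplasmy call tables.

Each candidate explanation for confirmed double peaks — nuclear pseudogene
(homozygous or heterozygous), mitochondrial gene duplication, doubly
uniparental inheritance, de novo mutation — is screened by deterministic
counterexample rules with a detection-dropout guard; paternal leakage is the
conclusion left standing when every alternative is rejected.  Recombination
is only flagged (it needs pre-existing heteroplasmy and is too rare to be a
primary cause), never evaluated as a sole explanation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .peak_calls import CallTable, clone_combinations

HYPOTHESES = (
    "de_novo",
    "recombination",
    "numt_homozygous",
    "numt_heterozygous",
    "mito_duplication",
    "dui",
    "paternal_leakage",
)

REJECTED = "rejected"
NOT_REJECTED = "not_rejected"
INSUFFICIENT = "insufficient_data"

#: de novo mutation rate per site per generation measured in Daphnia pulex
DEFAULT_MU = 1.63e-7


@dataclass
class DetectionModel:
    """How small a minor fraction the caller can still see."""

    detection_floor: float = 0.05
    dropout_margin: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_floor < 0.5:
            raise ValueError("detection_floor must lie in (0, 0.5)")
        if self.dropout_margin < 0:
            raise ValueError("dropout_margin must be nonnegative")

    @property
    def reliable_fraction(self) -> float:
        return self.detection_floor + self.dropout_margin


@dataclass
class Evidence:
    rule: str
    specimens: list[str] = field(default_factory=list)
    positions: list[int] = field(default_factory=list)
    observed: str = ""
    predicted: str = ""

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "specimens": self.specimens,
            "positions": self.positions,
            "observed": self.observed,
            "predicted": self.predicted,
        }


@dataclass
class HypothesisVerdict:
    hypothesis: str
    status: str
    evidence: list[Evidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.status not in (REJECTED, NOT_REJECTED, INSUFFICIENT):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == REJECTED and not self.evidence:
            raise ValueError("a rejection requires evidence")

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "status": self.status,
            "evidence": [e.to_dict() for e in self.evidence],
        }


# ---------------------------------------------------------------------------
# helpers over a CallTable
# ---------------------------------------------------------------------------


def _mother_het_positions(table: CallTable, mother_id: str) -> list[int]:
    """Positions at which any somatic record of the mother is heteroplasmic."""
    positions: set[int] = set()
    for rec in table.somatic_records(mother_id):
        positions.update(table.het_positions(rec.specimen))
    return sorted(positions)


def _mother_minor_fraction(table: CallTable, mother_id: str, position: int) -> float:
    """Largest minor proportion the mother shows at a position."""
    best = 0.0
    for rec in table.somatic_records(mother_id):
        for c in table.calls_for(rec.specimen):
            if c.position == position and c.heteroplasmic:
                best = max(best, c.proportion_minor)
    return best


def _mothers_with_eggs(table: CallTable) -> list[str]:
    return sorted({m.mother_id for m in table.specimens.values() if m.role == "egg" and m.mother_id})


def _multi_tissue_individuals(table: CallTable) -> list[str]:
    by_ind: dict[str, int] = {}
    for rec in table.somatic_records():
        by_ind[rec.individual] = by_ind.get(rec.individual, 0) + 1
    return sorted(i for i, n in by_ind.items() if n >= 2)


# ---------------------------------------------------------------------------
# evaluators
# ---------------------------------------------------------------------------


def evaluate_numt(
    table: CallTable,
    det: DetectionModel | None = None,
    numt_signal_ratio: float = 1.0 / 3.0,
) -> tuple[HypothesisVerdict, HypothesisVerdict]:
    """Screen the homozygous- and heterozygous-NUMT explanations.

    A homozygous NUMT predicts a constant nuclear signal in every descendant
    of a carrier mother, so a homoplasmic egg of a double-peak mother is a
    counterexample (guarded against detection dropout).  Any NUMT predicts
    the same nuclear signal in every cell, so tissue-discordant double peaks
    within one individual reject both forms.  Three or more single-molecule
    combinations in one tissue with fewer than two combinations among the
    eggs contradicts the maternal-NUMT reading of the clones.
    """
    det = det or DetectionModel()
    homo_ev: list[Evidence] = []
    het_ev: list[Evidence] = []
    mothers = _mothers_with_eggs(table)
    panels = _multi_tissue_individuals(table)
    if not mothers and not panels:
        return (
            HypothesisVerdict("numt_homozygous", INSUFFICIENT),
            HypothesisVerdict("numt_heterozygous", INSUFFICIENT),
        )
    positions = table.positions()
    numt_detectable = numt_signal_ratio > det.reliable_fraction

    # homozygous rule: homoplasmic offspring of a double-peak mother
    if numt_detectable:
        for mother in mothers:
            het_pos = _mother_het_positions(table, mother)
            if not het_pos:
                continue
            hom_eggs = [
                egg.specimen
                for egg in table.eggs_of(mother)
                if not table.is_het(egg.specimen, positions)
            ]
            if hom_eggs:
                homo_ev.append(
                    Evidence(
                        rule="homoplasmic_offspring_of_carrier_mother",
                        specimens=hom_eggs,
                        positions=het_pos,
                        observed=f"{len(hom_eggs)} egg(s) homoplasmic at every diagnostic site",
                        predicted=(
                            f"every egg shows the nuclear signal at fraction "
                            f"~{numt_signal_ratio:.2f} > {det.reliable_fraction:.2f}"
                        ),
                    )
                )

    # tissue discordance rejects either form
    if numt_detectable:
        for ind in panels:
            recs = table.somatic_records(ind)
            for pos in positions:
                het_recs = [r.specimen for r in recs if table.is_het(r.specimen, [pos])]
                hom_recs = [
                    r.specimen
                    for r in recs
                    if any(c.position == pos for c in table.calls_for(r.specimen))
                    and not table.is_het(r.specimen, [pos])
                ]
                if het_recs and hom_recs:
                    ev = Evidence(
                        rule="tissue_discordant_double_peaks",
                        specimens=sorted(het_recs + hom_recs),
                        positions=[pos],
                        observed=f"{ind}: heteroplasmic in {len(het_recs)}, homoplasmic in {len(hom_recs)} tissues",
                        predicted="a Mendelian nuclear signal is present in every cell of the individual",
                    )
                    homo_ev.append(ev)
                    het_ev.append(ev)

    # clone rule: >= 3 molecule combinations in one tissue, < 2 among eggs
    for mother in mothers:
        try:
            combos = clone_combinations(table, mother, positions)
        except KeyError:
            continue
        if len(combos) < 3:
            continue
        egg_combos = set()
        for egg in table.eggs_of(mother):
            by_pos = {c.position: c for c in table.calls_for(egg.specimen)}
            if any(c.heteroplasmic for c in by_pos.values()):
                continue  # ambiguous egg: combination not directly readable
            combo = tuple(by_pos[p].major_base for p in positions if p in by_pos)
            if combo:
                egg_combos.add(combo)
        if len(egg_combos) < 2:
            homo_ev.append(
                Evidence(
                    rule="clone_combinations_not_transmitted",
                    specimens=[mother],
                    positions=positions,
                    observed=f"{len(combos)} clone combinations, {len(egg_combos)} egg combination(s)",
                    predicted="eggs carry two combinations (one mitochondrial, one maternal NUMT)",
                )
            )

    homo = HypothesisVerdict("numt_homozygous", REJECTED if homo_ev else NOT_REJECTED, homo_ev)
    het = HypothesisVerdict("numt_heterozygous", REJECTED if het_ev else NOT_REJECTED, het_ev)
    return homo, het


def evaluate_duplication(table: CallTable, det: DetectionModel | None = None) -> HypothesisVerdict:
    """A duplicated mitochondrial gene travels with every genome copy, so all
    descendants of a double-peak mother must show the double peak too."""
    det = det or DetectionModel()
    evidence: list[Evidence] = []
    informative = False
    for mother in _mothers_with_eggs(table):
        het_pos = _mother_het_positions(table, mother)
        if not het_pos:
            continue
        informative = True
        for pos in het_pos:
            ratio = _mother_minor_fraction(table, mother, pos)
            if ratio <= det.reliable_fraction:
                continue  # could be missed by dropout; do not count against
            hom_eggs = [
                egg.specimen
                for egg in table.eggs_of(mother)
                if any(c.position == pos for c in table.calls_for(egg.specimen))
                and not table.is_het(egg.specimen, [pos])
            ]
            if hom_eggs:
                evidence.append(
                    Evidence(
                        rule="homoplasmic_offspring_of_duplication_mother",
                        specimens=hom_eggs,
                        positions=[pos],
                        observed=f"{len(hom_eggs)} egg(s) homoplasmic at {pos}",
                        predicted=f"all eggs duplicated (mother minor fraction {ratio:.3f})",
                    )
                )
    if not informative:
        return HypothesisVerdict("mito_duplication", INSUFFICIENT)
    return HypothesisVerdict(
        "mito_duplication", REJECTED if evidence else NOT_REJECTED, evidence
    )


def evaluate_dui(table: CallTable) -> HypothesisVerdict:
    """Doubly uniparental inheritance confines the second genome to males, so
    heteroplasmy observed in both sexes rejects it.  A two-sided Fisher exact
    comparison of incidence by sex is attached as evidence only."""
    by_sex: dict[str, dict[str, bool]] = {"male": {}, "female": {}}
    for rec in table.somatic_records():
        if rec.sex not in by_sex:
            continue
        ind = rec.individual
        het = table.is_het(rec.specimen)
        by_sex[rec.sex][ind] = by_sex[rec.sex].get(ind, False) or het
    males, females = by_sex["male"], by_sex["female"]
    if not males or not females:
        return HypothesisVerdict("dui", INSUFFICIENT)
    het_m = sum(males.values())
    het_f = sum(females.values())
    if het_m == 0 and het_f == 0:
        return HypothesisVerdict("dui", INSUFFICIENT)
    contingency = [[het_m, len(males) - het_m], [het_f, len(females) - het_f]]
    _, p_value = stats.fisher_exact(contingency, alternative="two-sided")
    if het_m > 0 and het_f > 0:
        return HypothesisVerdict(
            "dui",
            REJECTED,
            [
                Evidence(
                    rule="heteroplasmy_in_both_sexes",
                    observed=(
                        f"{het_m}/{len(males)} males and {het_f}/{len(females)} females "
                        f"heteroplasmic (Fisher exact p={p_value:.3g})"
                    ),
                    predicted="second genome detectable in males only",
                )
            ],
        )
    return HypothesisVerdict("dui", NOT_REJECTED)


def evaluate_de_novo(
    observed_het: int,
    n_individuals: int,
    n_sites: int,
    mu: float = DEFAULT_MU,
) -> HypothesisVerdict:
    """Compare observed heteroplasmy incidence with the de novo expectation.

    Per-individual probability of at least one new mutation across the
    diagnostic sites is ``1 - (1 - mu)^n_sites``; de novo mutation is rejected
    as the primary cause when the observed count exceeds the 99.9% binomial
    quantile.  The exact binomial tail is attached.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if observed_het < 0 or n_individuals < 1 or observed_het > n_individuals:
        raise ValueError("invalid counts")
    p_ind = 1.0 - (1.0 - mu) ** n_sites
    threshold = int(stats.binom.ppf(0.999, n_individuals, p_ind))
    tail = float(stats.binom.sf(observed_het - 1, n_individuals, p_ind)) if observed_het else 1.0
    if observed_het > threshold:
        return HypothesisVerdict(
            "de_novo",
            REJECTED,
            [
                Evidence(
                    rule="incidence_exceeds_mutation_expectation",
                    observed=f"{observed_het}/{n_individuals} heteroplasmic (binomial tail {tail:.3g})",
                    predicted=(
                        f"<= {threshold} expected at 99.9% with per-individual "
                        f"probability {p_ind:.3g} (mu={mu:g}, {n_sites} sites)"
                    ),
                )
            ],
        )
    return HypothesisVerdict("de_novo", NOT_REJECTED)


# ---------------------------------------------------------------------------
# full classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationResult:
    verdicts: dict[str, HypothesisVerdict]
    final_call: str
    surviving: list[str]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "verdicts": {h: v.to_dict() for h, v in self.verdicts.items()},
            "final_call": self.final_call,
            "surviving": self.surviving,
            "notes": self.notes,
        }


def _merge_verdicts(parts: Sequence[HypothesisVerdict]) -> HypothesisVerdict:
    hypothesis = parts[0].hypothesis
    evidence = [e for p in parts for e in p.evidence]
    statuses = {p.status for p in parts}
    if REJECTED in statuses:
        return HypothesisVerdict(hypothesis, REJECTED, evidence)
    if NOT_REJECTED in statuses:
        return HypothesisVerdict(hypothesis, NOT_REJECTED, evidence)
    return HypothesisVerdict(hypothesis, INSUFFICIENT, evidence)


def classify_dataset(
    tables: CallTable | Mapping[str, CallTable],
    det: DetectionModel | None = None,
    numt_signal_ratio: float = 1.0 / 3.0,
    mu: float = DEFAULT_MU,
) -> ClassificationResult:
    """Run every evaluator over one or more per-locus call tables.

    The final call is paternal-leakage heteroplasmy when heteroplasmy is
    present and every alternative explanation is rejected; with no
    heteroplasmic call at all the dataset is reported clean.
    """
    det = det or DetectionModel()
    if isinstance(tables, CallTable):
        tables = {"locus": tables}
    notes: list[str] = []

    per_locus: dict[str, list[HypothesisVerdict]] = {h: [] for h in HYPOTHESES}
    for locus, table in tables.items():
        homo, het = evaluate_numt(table, det, numt_signal_ratio)
        per_locus["numt_homozygous"].append(homo)
        per_locus["numt_heterozygous"].append(het)
        per_locus["mito_duplication"].append(evaluate_duplication(table, det))
        per_locus["dui"].append(evaluate_dui(table))
        # eggs heteroplasmic under a mother with no detected double peak:
        # attributed to detection dropout in the mother, recorded only
        for mother in _mothers_with_eggs(table):
            if _mother_het_positions(table, mother):
                continue
            for egg in table.eggs_of(mother):
                if table.is_het(egg.specimen):
                    notes.append(
                        f"maternal-undetected: egg {egg.specimen} heteroplasmic at {locus} "
                        f"while mother {mother} shows no double peak"
                    )

    # de novo incidence pooled over loci
    individuals: dict[str, bool] = {}
    n_sites = 0
    any_het = False
    for table in tables.values():
        n_sites += len(table.positions())
        any_het = any_het or any(c.heteroplasmic for c in table.calls)
        for rec in table.somatic_records():
            ind = rec.individual
            individuals[ind] = individuals.get(ind, False) or table.is_het(rec.specimen)
    if individuals and n_sites:
        de_novo = evaluate_de_novo(sum(individuals.values()), len(individuals), n_sites, mu)
    else:
        de_novo = HypothesisVerdict("de_novo", INSUFFICIENT)
    per_locus["de_novo"].append(de_novo)

    # cross-locus duplication consistency (recorded, not decisive)
    if len(tables) > 1:
        het_by_locus = {
            locus: {
                rec.individual
                for rec in table.somatic_records()
                if table.is_het(rec.specimen)
            }
            for locus, table in tables.items()
        }
        loci = list(het_by_locus)
        for i, a in enumerate(loci):
            for b in loci[i + 1 :]:
                only_a = sorted(het_by_locus[a] - het_by_locus[b])
                if only_a:
                    notes.append(
                        f"cross-locus: {len(only_a)} individual(s) double-peaked at {a} but not {b} "
                        "(would require independent duplications)"
                    )

    per_locus["recombination"].append(
        HypothesisVerdict(
            "recombination",
            NOT_REJECTED,
            [
                Evidence(
                    rule="non_primary_flag",
                    observed="recombination requires pre-existing heteroplasmy",
                    predicted="too infrequent to be the sole explanation; never a final call",
                )
            ],
        )
    )
    per_locus["paternal_leakage"].append(
        HypothesisVerdict("paternal_leakage", NOT_REJECTED if any_het else INSUFFICIENT)
    )

    verdicts = {h: _merge_verdicts(v) for h, v in per_locus.items() if v}
    surviving = [
        h
        for h in HYPOTHESES
        if h != "recombination" and verdicts[h].status != REJECTED
    ]
    alternatives = ("de_novo", "numt_homozygous", "numt_heterozygous", "mito_duplication", "dui")
    if not any_het:
        final = "no_heteroplasmy_detected"
    elif all(verdicts[h].status == REJECTED for h in alternatives):
        final = "paternal_leakage"
    else:
        final = "undetermined"
    return ClassificationResult(
        verdicts=verdicts, final_call=final, surviving=surviving, notes=notes
    )
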