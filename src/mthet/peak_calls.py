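"""Per-site nucleotide proportions and heteroplasmy calls.

Converts paired-read peak heights (or transcribed percentage tables) into
site calls: the proportion of each of the two candidate bases is that base's
height divided by the summed height of both candidates, per read, and the
reported proportion is the arithmetic mean over the available reads.  A site
is heteroplasmic when the minor proportion clears a threshold and the second
peak stands clear of the baseline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import InsufficientDataError, NoSignalError, SchemaError
from .trace_sim import BASES, FamilySim, TissuePanelSim, TraceSet

#: smallest minor fraction called heteroplasmic by default; sits just below
#: the smallest reported positive (6.5%).
DEFAULT_MIN_MINOR_FRACTION = 0.05

#: the second peak must exceed this multiple of the baseline level
BASELINE_FACTOR = 3.0

ROLES = ("adult", "egg", "clone", "tissue")


@dataclass
class SiteProportions:
    """Averaged two-base proportions at one site."""

    bases: tuple[str, ...]  # candidate bases, major first
    proportions: dict[str, float]  # base -> averaged proportion
    per_read: dict[str, dict[str, float]]  # direction -> base -> proportion
    single_read: bool = False


@dataclass
class SiteCall:
    """One specimen x position call."""

    specimen: str
    position: int
    major_base: str | None
    minor_base: str | None
    proportion_major: float
    proportion_minor: float
    heteroplasmic: bool
    forward_major: float | None = None
    reverse_major: float | None = None
    confirmed: bool | None = None  # None = not tested against a replicate
    single_read: bool = False

    def __post_init__(self) -> None:
        if self.proportion_major < self.proportion_minor - 1e-12:
            raise ValueError("major proportion below minor proportion")
        total = self.proportion_major + self.proportion_minor
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total!r}, not 1")
        if self.heteroplasmic and self.minor_base is None:
            raise ValueError("heteroplasmic call lacks a minor base")


@dataclass
class SpecimenMeta:
    specimen: str
    role: str
    sex: str = ""
    tissue: str = ""
    mother_id: str = ""
    population: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def individual(self) -> str:
        """Individual the record belongs to.

        Adult and tissue records named ``<individual>-<tissue>`` collapse to
        the individual; eggs and clones are their own record but keep the
        mother link separately.
        """
        if self.role in ("adult", "tissue") and self.tissue:
            suffix = "-" + self.tissue
            if self.specimen.endswith(suffix):
                return self.specimen[: -len(suffix)]
        return self.specimen


@dataclass
class CallTable:
    """Specimen metadata plus site calls — the machine form of the percentage tables."""

    specimens: dict[str, SpecimenMeta] = field(default_factory=dict)
    calls: list[SiteCall] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, meta: SpecimenMeta, calls: Iterable[SiteCall]) -> None:
        self.specimens[meta.specimen] = meta
        self.calls.extend(calls)

    def calls_for(self, specimen: str) -> list[SiteCall]:
        return [c for c in self.calls if c.specimen == specimen]

    def positions(self) -> list[int]:
        return sorted({c.position for c in self.calls})

    def eggs_of(self, mother_id: str) -> list[SpecimenMeta]:
        return [m for m in self.specimens.values() if m.role == "egg" and m.mother_id == mother_id]

    def clones_of(self, mother_id: str) -> list[SpecimenMeta]:
        return [m for m in self.specimens.values() if m.role == "clone" and m.mother_id == mother_id]

    def somatic_records(self, individual: str | None = None) -> list[SpecimenMeta]:
        """Adult/tissue records, optionally restricted to one individual."""
        recs = [m for m in self.specimens.values() if m.role in ("adult", "tissue")]
        if individual is not None:
            recs = [m for m in recs if m.individual == individual]
        return recs

    def is_het(self, specimen: str, positions: Sequence[int] | None = None) -> bool:
        for c in self.calls_for(specimen):
            if positions is not None and c.position not in positions:
                continue
            if c.heteroplasmic:
                return True
        return False

    def het_positions(self, specimen: str) -> list[int]:
        return sorted({c.position for c in self.calls_for(specimen) if c.heteroplasmic})

    def to_rows(self) -> list[dict]:
        rows = []
        for c in self.calls:
            meta = self.specimens[c.specimen]
            rows.append(
                {
                    "specimen": c.specimen,
                    "role": meta.role,
                    "sex": meta.sex,
                    "tissue": meta.tissue,
                    "mother_id": meta.mother_id,
                    "population": meta.population,
                    "position": c.position,
                    "major_base": c.major_base or "",
                    "minor_base": c.minor_base or "",
                    "proportion_major": round(c.proportion_major, 6),
                    "proportion_minor": round(c.proportion_minor, 6),
                    "heteroplasmic": c.heteroplasmic,
                    "confirmed": "" if c.confirmed is None else c.confirmed,
                }
            )
        return rows

    def write_csv(self, path) -> None:
        rows = self.to_rows()
        fieldnames = list(rows[0]) if rows else ["specimen"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(rows)


# ---------------------------------------------------------------------------
# proportions and calls
# ---------------------------------------------------------------------------


def proportion_from_heights(
    forward: Mapping[str, float] | None,
    reverse: Mapping[str, float] | None,
) -> SiteProportions:
    """Average the two-read, two-candidate-base peak proportions.

    The two candidate bases are the two tallest channels (summed over the
    available reads).  Per read, each candidate's proportion is its height
    over the candidates' summed height; the returned proportion is the mean
    over reads.  With a single read the call is flagged ``single_read``.
    """
    reads = {d: h for d, h in (("forward", forward), ("reverse", reverse)) if h is not None}
    if not reads:
        raise ValueError("at least one read must be present")
    combined = {b: sum(float(h.get(b, 0.0)) for h in reads.values()) for b in BASES}
    if any(v < 0 for h in reads.values() for v in h.values()):
        raise ValueError("peak heights must be nonnegative")
    if sum(combined.values()) <= 0:
        raise NoSignalError("all channel heights are zero")
    # two tallest channels overall; deterministic tie-break by base order
    cand = sorted(BASES, key=lambda b: (-combined[b], b))[:2]
    per_read: dict[str, dict[str, float]] = {}
    for direction, h in reads.items():
        pair_total = sum(float(h.get(b, 0.0)) for b in cand)
        if pair_total <= 0:
            per_read[direction] = {b: 0.0 for b in cand}
        else:
            per_read[direction] = {b: float(h.get(b, 0.0)) / pair_total for b in cand}
    usable = [d for d in per_read if sum(per_read[d].values()) > 0]
    if not usable:
        raise NoSignalError("candidate bases have zero height on every read")
    props = {b: sum(per_read[d][b] for d in usable) / len(usable) for b in cand}
    ordered = sorted(cand, key=lambda b: (-props[b], b))
    return SiteProportions(
        bases=tuple(ordered),
        proportions=props,
        per_read=per_read,
        single_read=len(reads) == 1,
    )


def call_site(
    proportions: SiteProportions | Mapping[str, float],
    min_minor_fraction: float = DEFAULT_MIN_MINOR_FRACTION,
    baseline_ok: bool = True,
    specimen: str = "",
    position: int = 0,
) -> SiteCall:
    """Turn averaged proportions into a heteroplasmy call.

    Heteroplasmic iff the minor proportion reaches ``min_minor_fraction`` and
    the baseline criterion holds.  An exact 50/50 tie is heteroplasmic with
    the major base taken first in the fixed order A<C<G<T.
    """
    if not 0.0 < min_minor_fraction < 0.5:
        raise ValueError("min_minor_fraction must lie in (0, 0.5)")
    single_read = False
    per_read: dict[str, dict[str, float]] = {}
    if isinstance(proportions, SiteProportions):
        props = proportions.proportions
        single_read = proportions.single_read
        per_read = proportions.per_read
    else:
        props = {b: float(p) for b, p in proportions.items()}
        if any(p < 0 for p in props.values()):
            raise ValueError("proportions must be nonnegative")
        total = sum(props.values())
        if total <= 0:
            raise NoSignalError("no signal: proportions all zero")
        props = {b: p / total for b, p in props.items()}
    present = sorted((b for b, p in props.items() if p > 0), key=lambda b: (-props[b], b))[:2]
    if len(present) == 1:
        major, minor = present[0], None
        p_major, p_minor = 1.0, 0.0
    else:
        a, b = present
        if abs(props[a] - props[b]) <= 1e-12:  # exact tie: base order decides
            major, minor = sorted((a, b))
        else:
            major, minor = a, b
        pair = props[major] + props[minor]
        p_major, p_minor = props[major] / pair, props[minor] / pair
    het = minor is not None and p_minor >= min_minor_fraction and baseline_ok
    return SiteCall(
        specimen=specimen,
        position=position,
        major_base=major,
        minor_base=minor,
        proportion_major=p_major,
        proportion_minor=p_minor,
        heteroplasmic=het,
        forward_major=per_read.get("forward", {}).get(major),
        reverse_major=per_read.get("reverse", {}).get(major),
        single_read=single_read,
    )


def call_trace_set(
    trace: TraceSet,
    positions: Sequence[int] | None = None,
    min_minor_fraction: float = DEFAULT_MIN_MINOR_FRACTION,
    baseline_factor: float = BASELINE_FACTOR,
) -> list[SiteCall]:
    """Call every (or the given) position of a simulated/observed trace.

    The baseline criterion requires the minor candidate's raw height to exceed
    ``baseline_factor x baseline_level`` on every available read.
    """
    if positions is None:
        positions = range(1, trace.length + 1)
    calls = []
    for pos in positions:
        by_read = trace.heights_at(pos)
        props = proportion_from_heights(by_read.get("forward"), by_read.get("reverse"))
        baseline_ok = True
        if len(props.bases) > 1:
            minor_cand = props.bases[1]
            for direction, heights in by_read.items():
                level = trace.reads[direction].baseline_level
                if level > 0 and heights.get(minor_cand, 0.0) <= baseline_factor * level:
                    baseline_ok = False
        calls.append(
            call_site(props, min_minor_fraction, baseline_ok, specimen=trace.specimen, position=pos)
        )
    return calls


# ---------------------------------------------------------------------------
# replicate confirmation and counting
# ---------------------------------------------------------------------------


def confirm_replicates(rep1: CallTable, rep2: CallTable) -> CallTable:
    """Cross-check two independent replicates of the same specimens.

    A site is confirmed heteroplasmic iff heteroplasmic in both replicates at
    the same position with the same base pair; heteroplasmic in exactly one
    replicate -> ``confirmed=False`` (kept, flagged).  Matching homoplasmic
    calls are confirmed homoplasmic.  Coverage gaps become warning records.
    """
    out = CallTable(specimens=dict(rep1.specimens))
    idx2 = {(c.specimen, c.position): c for c in rep2.calls}
    seen = set()
    for c1 in rep1.calls:
        key = (c1.specimen, c1.position)
        c2 = idx2.get(key)
        if c2 is None:
            out.warnings.append(f"{c1.specimen} position {c1.position} missing from replicate 2")
            out.calls.append(replace(c1, confirmed=None))
            continue
        seen.add(key)
        if c1.heteroplasmic and c2.heteroplasmic:
            same_pair = {c1.major_base, c1.minor_base} == {c2.major_base, c2.minor_base}
            out.calls.append(replace(c1, confirmed=same_pair))
        elif not c1.heteroplasmic and not c2.heteroplasmic:
            out.calls.append(replace(c1, confirmed=True))
        else:
            out.calls.append(replace(c1, confirmed=False))
    for c2 in rep2.calls:
        if (c2.specimen, c2.position) not in seen and c2.specimen not in rep1.specimens:
            out.warnings.append(f"{c2.specimen} present only in replicate 2")
    return out


def count_het_offspring(
    table: CallTable, mother_id: str, positions: Sequence[int] | None = None
) -> tuple[int, int]:
    """(heteroplasmic eggs, total eggs) for one mother.

    An egg counts as heteroplasmic iff at least one listed position is.
    """
    eggs = table.eggs_of(mother_id)
    if not eggs:
        raise KeyError(f"no eggs recorded for mother {mother_id!r}")
    n_het = sum(1 for egg in eggs if table.is_het(egg.specimen, positions))
    return n_het, len(eggs)


def count_het_tissues(
    table: CallTable, individual_id: str, positions: Sequence[int] | None = None
) -> tuple[int, int]:
    """(heteroplasmic tissue records, total tissue records) for one individual."""
    recs = table.somatic_records(individual_id)
    if not recs:
        raise KeyError(f"no somatic records for individual {individual_id!r}")
    n_het = sum(1 for r in recs if table.is_het(r.specimen, positions))
    return n_het, len(recs)


def clone_combinations(
    table: CallTable, mother_id: str, positions: Sequence[int]
) -> dict[tuple[str, ...], int]:
    """Distinct base tuples (with multiplicity) carried by a mother's clones."""
    clones = table.clones_of(mother_id)
    if not clones:
        raise KeyError(f"no clones recorded for mother {mother_id!r}")
    combos: dict[tuple[str, ...], int] = {}
    for clone in clones:
        by_pos = {c.position: c for c in table.calls_for(clone.specimen)}
        combo = tuple(by_pos[p].major_base for p in positions if p in by_pos)
        if len(combo) == len(positions):
            combos[combo] = combos.get(combo, 0) + 1
    return combos


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

PERCENT_COLUMNS = [
    "specimen",
    "role",
    "sex",
    "tissue",
    "mother_id",
    "population",
    "position",
    "base1",
    "base2",
    "pct1",
    "pct2",
]


def read_percent_csv(path, min_minor_fraction: float = DEFAULT_MIN_MINOR_FRACTION) -> CallTable:
    """Load the percent-dialect CSV (transcribed electropherogram tables).

    Percentages are taken as given (no peak heights survive transcription);
    each row's two percentages are renormalised to sum to 1 to absorb printed
    rounding.
    """
    table = CallTable()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(PERCENT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                position = int(row["position"])
                pct1 = float(row["pct1"])
                pct2 = float(row["pct2"])
                base1 = row["base1"].strip().upper()
                base2 = row["base2"].strip().upper()
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"row {i}: unparsable field ({exc})") from exc
            if base1 not in BASES or base2 not in BASES or base1 == base2:
                raise SchemaError(f"row {i}: invalid base pair {base1!r}/{base2!r}")
            if pct1 < 0 or pct2 < 0:
                raise SchemaError(f"row {i}: negative percentage")
            if pct1 + pct2 <= 0:
                raise SchemaError(f"row {i}: zero total percentage")
            if position < 1:
                raise SchemaError(f"row {i}: position must be >= 1")
            meta = SpecimenMeta(
                specimen=row["specimen"].strip(),
                role=row["role"].strip(),
                sex=row["sex"].strip(),
                tissue=row["tissue"].strip(),
                mother_id=row["mother_id"].strip(),
                population=row["population"].strip(),
            )
            call = call_site(
                {base1: pct1, base2: pct2},
                min_minor_fraction=min_minor_fraction,
                specimen=meta.specimen,
                position=position,
            )
            if meta.specimen not in table.specimens:
                table.specimens[meta.specimen] = meta
            table.calls.append(call)
    if not table.calls:
        raise InsufficientDataError("no data rows in percent CSV")
    return table


def call_family(
    fam: FamilySim,
    positions: Sequence[int],
    min_minor_fraction: float = DEFAULT_MIN_MINOR_FRACTION,
    mother_sex: str = "female",
) -> CallTable:
    """CallTable for a simulated family (mother role=adult, eggs role=egg)."""
    table = CallTable()
    mother_id = fam.truth["mother"]
    table.add(
        SpecimenMeta(specimen=mother_id, role="adult", sex=mother_sex),
        call_trace_set(fam.mother, positions, min_minor_fraction),
    )
    for egg_trace, egg_truth in zip(fam.eggs, fam.truth["eggs"]):
        table.add(
            SpecimenMeta(
                specimen=egg_trace.specimen,
                role="egg",
                sex=egg_truth.get("sex", ""),
                mother_id=mother_id,
            ),
            call_trace_set(egg_trace, positions, min_minor_fraction),
        )
    return table


def call_tissue_panel(
    panel: TissuePanelSim,
    positions: Sequence[int],
    min_minor_fraction: float = DEFAULT_MIN_MINOR_FRACTION,
    sex: str = "female",
) -> CallTable:
    """CallTable for a simulated multi-tissue individual (role=tissue rows)."""
    table = CallTable()
    for tissue, trace in panel.tissues.items():
        table.add(
            SpecimenMeta(specimen=trace.specimen, role="tissue", sex=sex, tissue=tissue),
            call_trace_set(trace, positions, min_minor_fraction),
        )
    return table


def merge_tables(*tables: CallTable) -> CallTable:
    out = CallTable()
    for t in tables:
        for meta in t.specimens.values():
            out.specimens.setdefault(meta.specimen, meta)
        out.calls.extend(t.calls)
        out.warnings.extend(t.warnings)
    return out
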