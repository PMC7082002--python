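"""Alignment-column analysis for pre-aligned amplicons.

Variable-site detection, singleton vs parsimony-informative classification,
haplotype enumeration (sequences flagged as carrying double peaks are
excluded whole), clone-combination counting, reading-frame inference and
synonymous / non-synonymous difference counts under the invertebrate
mitochondrial genetic code (NCBI translation table 5).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import InsufficientDataError, LengthMismatchError

INVERTEBRATE_MITO_TABLE = 5


@dataclass
class Alignment:
    """Equal-length sequences with per-sequence ambiguity flags."""

    ids: list[str]
    seqs: list[str]
    ambiguous: list[bool] = field(default_factory=list)
    locus: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if not self.ambiguous:
            self.ambiguous = [False] * len(self.seqs)
        if len(self.ambiguous) != len(self.seqs):
            raise ValueError("ambiguous flags and seqs differ in length")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise LengthMismatchError(f"aligned sequences differ in length: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def unambiguous(self) -> list[tuple[str, str]]:
        return [(i, s) for i, s, amb in zip(self.ids, self.seqs, self.ambiguous) if not amb]

    @classmethod
    def from_fasta(cls, path, locus: str = "", ambiguous_ids: Iterable[str] = ()) -> "Alignment":
        amb = set(ambiguous_ids)
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        if not ids:
            raise ValueError(f"no sequences in {path}")
        return cls(ids=ids, seqs=seqs, ambiguous=[i in amb for i in ids], locus=locus)

    @classmethod
    def from_haplotype_counts(
        cls, haplotypes: Sequence[tuple[str, str]], counts: Sequence[int], locus: str = ""
    ) -> "Alignment":
        """Expand (id, seq) haplotypes into an alignment with given multiplicities."""
        ids, seqs = [], []
        for (hap_id, seq), n in zip(haplotypes, counts):
            for k in range(n):
                ids.append(f"{hap_id}_{k + 1}")
                seqs.append(seq)
        return cls(ids=ids, seqs=seqs, locus=locus)


@dataclass
class HaplotypeRecord:
    seq: str
    members: list[str]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeSummary:
    haplotypes: list[HaplotypeRecord]
    excluded: list[str]  # ambiguous sequence ids left out
    variable_sites: dict[int, str] = field(default_factory=dict)  # position -> class
    stop_codons: int | None = None
    frame: int | None = None
    max_synonymous: int | None = None
    max_non_synonymous: int | None = None

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def counts(self) -> list[int]:
        return sorted((h.count for h in self.haplotypes), reverse=True)


def find_variable_sites(aln: Alignment) -> list[int]:
    """1-based positions with >= 2 distinct bases among unambiguous sequences."""
    seqs = [s for _, s in aln.unambiguous()]
    if len(seqs) < 2:
        raise InsufficientDataError("need >= 2 unambiguous sequences")
    out = []
    for pos in range(aln.length):
        if len({s[pos] for s in seqs}) > 1:
            out.append(pos + 1)
    return out


def classify_sites(aln: Alignment, sites: Sequence[int]) -> dict[int, str]:
    """Classify variable columns: parsimony_informative iff >= 2 bases each in >= 2 sequences."""
    seqs = [s for _, s in aln.unambiguous()]
    result = {}
    for pos in sites:
        tally = Counter(s[pos - 1] for s in seqs)
        if len(tally) < 2:
            raise ValueError(f"site {pos} is not variable")
        informative = sum(1 for n in tally.values() if n >= 2) >= 2
        result[pos] = "parsimony_informative" if informative else "singleton"
    return result


def enumerate_haplotypes(aln: Alignment) -> HaplotypeSummary:
    """Distinct full sequences among unambiguous members, with membership."""
    groups: dict[str, list[str]] = {}
    for seq_id, seq in aln.unambiguous():
        groups.setdefault(seq, []).append(seq_id)
    haplotypes = [HaplotypeRecord(seq=s, members=m) for s, m in groups.items()]
    haplotypes.sort(key=lambda h: (-h.count, h.seq))
    excluded = [i for i, amb in zip(aln.ids, aln.ambiguous) if amb]
    return HaplotypeSummary(haplotypes=haplotypes, excluded=excluded)


def enumerate_combinations(
    clones: Sequence[str], sites: Sequence[int]
) -> dict[tuple[str, ...], int]:
    """Distinct base tuples at the given 1-based sites across clone sequences."""
    if not clones:
        raise ValueError("need at least one clone")
    combos: Counter = Counter(tuple(seq[p - 1] for p in sites) for seq in clones)
    return dict(combos)


def infer_reading_frame(consensus: str, table: int = INVERTEBRATE_MITO_TABLE) -> tuple[int, dict[int, int]]:
    """Frame (0/1/2) minimising stop codons under the given genetic code.

    Ties break toward the smallest frame index.  If every frame contains a
    stop a warning is emitted and the best frame is still returned.
    """
    stops = {}
    for frame in range(3):
        sub = consensus[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        aa = str(Seq(sub).translate(table=table))
        stops[frame] = aa.count("*")
    best = min(range(3), key=lambda f: (stops[f], f))
    if stops[best] > 0:
        warnings.warn(f"all frames contain stop codons (best frame {best}: {stops[best]})")
    return best, stops


def count_syn_nonsyn(a: str, b: str, frame: int = 0, table: int = INVERTEBRATE_MITO_TABLE) -> tuple[int, int]:
    """Per-site synonymous / non-synonymous difference counts between two sequences.

    Codons are compared pairwise in the given frame; every differing site in a
    codon is classified by whether the two whole codons translate identically
    (no mutational-pathway averaging).  Trailing partial codons are ignored.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    a, b = a.upper()[frame:], b.upper()[frame:]
    n_codons = len(a) // 3
    syn = nonsyn = 0
    for k in range(n_codons):
        ca, cb = a[3 * k : 3 * k + 3], b[3 * k : 3 * k + 3]
        ndiff = sum(1 for x, y in zip(ca, cb) if x != y)
        if ndiff == 0:
            continue
        aa_a = str(Seq(ca).translate(table=table))
        aa_b = str(Seq(cb).translate(table=table))
        if aa_a == aa_b:
            syn += ndiff
        else:
            nonsyn += ndiff
    return syn, nonsyn


def consensus_sequence(aln: Alignment) -> str:
    """Column-majority consensus over unambiguous sequences (ties by base order)."""
    seqs = [s for _, s in aln.unambiguous()]
    if not seqs:
        raise InsufficientDataError("no unambiguous sequences")
    out = []
    for pos in range(aln.length):
        tally = Counter(s[pos] for s in seqs)
        out.append(sorted(tally, key=lambda b: (-tally[b], b))[0])
    return "".join(out)


def summarize_alignment(aln: Alignment, coding: bool = False) -> HaplotypeSummary:
    """Full summary: haplotypes, classified variable sites, codon statistics."""
    summary = enumerate_haplotypes(aln)
    sites = find_variable_sites(aln)
    summary.variable_sites = classify_sites(aln, sites)
    if coding:
        cons = consensus_sequence(aln)
        frame, stops = infer_reading_frame(cons)
        summary.frame = frame
        summary.stop_codons = stops[frame]
        max_syn = max_non = 0
        haps = summary.haplotypes
        for i in range(len(haps)):
            for j in range(i + 1, len(haps)):
                s, n = count_syn_nonsyn(haps[i].seq, haps[j].seq, frame)
                max_syn = max(max_syn, s)
                max_non = max(max_non, n)
        summary.max_synonymous = max_syn
        summary.max_non_synonymous = max_non
    return summary
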