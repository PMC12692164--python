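"""Sample-specific contaminant database construction and labeling QC.

Cell cultures grown in serum-containing medium carry abundant non-target
proteins (bovine serum proteins, added enzymes, resin components).  A
medium-only control run identifies these directly; a contaminant protein is
admitted to the database only if at least one of its evidence peptides is
*specific*, i.e. absent from the in-silico tryptic peptide space of the
entire target proteome after folding the mass-indistinguishable residues
I and L together.  The resulting entries are appended to the target search
database and excluded from quantitative conclusions downstream.

Because medium proteins live entirely in the extracellular space, the
fraction of contaminant entries carrying a biotinylation site is itself a
labeling-efficiency QC metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import CANONICAL_AA, ModType, PeptideRecord, Proteome

__all__ = [
    "ContaminantDB",
    "ContaminantEntry",
    "TEERRecord",
    "digest_tryptic",
    "tryptic_peptide_space",
    "build_contaminant_db",
    "labeling_efficiency",
    "LabelingQC",
    "teer",
]


def digest_tryptic(
    sequence: str,
    missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 50,
) -> list[str]:
    """In-silico tryptic digest: cleave after K/R except before P.

    Returns all products with at most ``missed_cleavages`` internal
    cleavage sites whose length lies in [min_len, max_len], in N-to-C
    order (fully cleaved products first for each start).
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - CANONICAL_AA
    if bad:
        raise ValueError(f"invalid residues: {sorted(bad)}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    # cut points: index i means a cut between sequence[i-1] and sequence[i]
    cuts = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(cuts))):
            pep = sequence[cuts[a] : cuts[b]]
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
    return peptides


def _fold_il(seq: str) -> str:
    return seq.replace("I", "L")


def tryptic_peptide_space(
    proteome: Proteome,
    missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 50,
) -> set[str]:
    """All I/L-folded tryptic peptides of a proteome (the search space a
    database search engine would consider)."""
    space: set[str] = set()
    for seq in proteome.sequences.values():
        space.update(
            _fold_il(p)
            for p in digest_tryptic(
                seq.replace("X", "L"), missed_cleavages, min_len, max_len
            )
        )
    return space


@dataclass(frozen=True)
class ContaminantEntry:
    protein_id: str
    species_tag: str
    n_evidence_peptides: int
    n_specific_peptides: int
    has_biotin_site: bool
    has_nterm_biotin: bool


@dataclass
class ContaminantDB:
    entries: list[ContaminantEntry]
    #: control proteins rejected because every evidence peptide also occurs
    #: in the target peptide space
    shared_only: list[str]

    def __post_init__(self) -> None:
        ids = [e.protein_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contaminant entries")
        for e in self.entries:
            if e.n_specific_peptides > e.n_evidence_peptides:
                raise ValueError(f"specific > evidence for {e.protein_id}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def protein_ids(self) -> list[str]:
        return [e.protein_id for e in self.entries]


def build_contaminant_db(
    control_ids: Sequence[str],
    control_peptides: Sequence[PeptideRecord],
    contaminant_proteome: Proteome,
    target_proteome: Proteome,
    missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    min_specific_peptides: int = 1,
) -> ContaminantDB:
    """Build the contaminant database from a medium-only control run.

    A control protein enters the database iff at least
    ``min_specific_peptides`` of its evidence peptides are absent (after
    I/L folding) from the tryptic peptide space of the target proteome.
    """
    missing = [pid for pid in control_ids if pid not in contaminant_proteome.sequences]
    if missing:
        raise ValueError(f"control ids missing from contaminant proteome: {missing[:5]}")
    target_space = tryptic_peptide_space(target_proteome, missed_cleavages, min_len, max_len)
    by_protein: dict[str, list[PeptideRecord]] = {pid: [] for pid in control_ids}
    for rec in control_peptides:
        if rec.protein_id in by_protein:
            by_protein[rec.protein_id].append(rec)
    entries, shared_only = [], []
    for pid in control_ids:
        recs = by_protein[pid]
        n_specific = sum(1 for r in recs if _fold_il(r.sequence) not in target_space)
        if n_specific >= min_specific_peptides and recs:
            entries.append(
                ContaminantEntry(
                    protein_id=pid,
                    species_tag=contaminant_proteome.species_tag,
                    n_evidence_peptides=len(recs),
                    n_specific_peptides=n_specific,
                    has_biotin_site=any(
                        m.mod_type.is_biotin for r in recs for m in r.modifications
                    ),
                    has_nterm_biotin=any(
                        m.mod_type is ModType.BIOTIN_PROTEIN_NTERM
                        for r in recs
                        for m in r.modifications
                    ),
                )
            )
        else:
            shared_only.append(pid)
    return ContaminantDB(entries=entries, shared_only=shared_only)


@dataclass(frozen=True)
class LabelingQC:
    fraction_with_biotin: float
    fraction_with_nterm: float
    n_entries: int


def labeling_efficiency(db: ContaminantDB) -> LabelingQC:
    """Fraction of contaminant entries with any biotin site / an N-terminal one."""
    if len(db) == 0:
        raise ValueError("empty contaminant database")
    n = len(db)
    return LabelingQC(
        fraction_with_biotin=sum(e.has_biotin_site for e in db.entries) / n,
        fraction_with_nterm=sum(e.has_nterm_biotin for e in db.entries) / n,
        n_entries=n,
    )


@dataclass(frozen=True)
class TEERRecord:
    """Transepithelial electrical resistance: (R - R_blank) * area, in ohm*cm^2."""

    resistance_ohm: float
    blank_resistance_ohm: float
    area_cm2: float
    teer_ohm_cm2: float
    blank_exceeds_culture: bool = False


def teer(resistance_ohm: float, blank_resistance_ohm: float, area_cm2: float) -> TEERRecord:
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    value = (resistance_ohm - blank_resistance_ohm) * area_cm2
    return TEERRecord(
        resistance_ohm=resistance_ohm,
        blank_resistance_ohm=blank_resistance_ohm,
        area_cm2=area_cm2,
        teer_ohm_cm2=value,
        blank_exceeds_culture=value < 0,
    )
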