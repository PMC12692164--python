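"""Canonical data types and TSV/FASTA readers and writers.

The quantitative pipeline operates on four kinds of objects: intensity
matrices (peptide- or protein-level label-free quantification values),
the sample design (which sample is the apical and which the basolateral
member of each bioreplicate pair), peptide records carrying biotinylation
modifications, and membrane-topology segment maps.

Conventions
-----------
* Missing intensities are an explicit state (NaN in memory, ``NA`` on
  disk).  A zero in an input table is converted to missing on read: the
  upstream LFQ tooling reports 0 for "not detected", never a true zero
  abundance.
* All residue coordinates are 1-based inclusive (UniProt convention).
* Canonical tables are UTF-8, tab-separated, ``.`` decimal separator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Side",
    "ModType",
    "SegmentLabel",
    "SampleDesign",
    "IntensityMatrix",
    "PeptideRecord",
    "Modification",
    "Segment",
    "TopologyMap",
    "Proteome",
    "MISSING",
    "read_design",
    "read_quant_table",
    "write_quant_table",
    "read_topology",
    "write_topology",
    "read_fasta",
    "write_fasta",
    "read_peptide_records",
    "write_peptide_records",
]

MISSING = "NA"

# 20 canonical residues; X is tolerated in proteome sequences but flagged.
CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


class Side(str, Enum):
    APICAL = "apical"
    BASOLATERAL = "basolateral"


class ModType(str, Enum):
    BIOTIN_LYSINE = "biotin_lysine"
    BIOTIN_PROTEIN_NTERM = "biotin_protein_nterm"
    OTHER = "other"

    @property
    def is_biotin(self) -> bool:
        return self in (ModType.BIOTIN_LYSINE, ModType.BIOTIN_PROTEIN_NTERM)


class SegmentLabel(str, Enum):
    EXTRACELLULAR = "extracellular"
    TRANSMEMBRANE = "transmembrane"
    INTRACELLULAR = "intracellular"
    UNKNOWN = "unknown"


class DesignError(ValueError):
    """Invalid sample design (duplicates or broken apical/basolateral pairing)."""


@dataclass(frozen=True)
class SampleDesign:
    """Sample -> (bioreplicate, side) mapping.

    Every bioreplicate must contribute exactly one apical and one
    basolateral sample; the pair is the unit of both the replicate-average
    normalization and the paired differential test.
    """

    sample_ids: tuple[str, ...]
    bioreplicate_ids: tuple[str, ...]
    sides: tuple[Side, ...]
    batch_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.bioreplicate_ids) != n or len(self.sides) != n:
            raise DesignError("design columns have unequal lengths")
        if self.batch_ids is not None and len(self.batch_ids) != n:
            raise DesignError("batch_id column has wrong length")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise DesignError(f"duplicate sample_id: {', '.join(dupes)}")
        per_rep: dict[str, dict[Side, list[str]]] = {}
        for sid, rep, side in zip(self.sample_ids, self.bioreplicate_ids, self.sides):
            per_rep.setdefault(rep, {Side.APICAL: [], Side.BASOLATERAL: []})[side].append(sid)
        for rep, sides in per_rep.items():
            if len(sides[Side.APICAL]) != 1 or len(sides[Side.BASOLATERAL]) != 1:
                raise DesignError(f"unpaired bioreplicate {rep}")

    @property
    def n_pairs(self) -> int:
        return len(set(self.bioreplicate_ids))

    def pairs(self) -> dict[str, tuple[str, str]]:
        """bioreplicate_id -> (apical sample_id, basolateral sample_id)."""
        out: dict[str, tuple[str, str]] = {}
        for rep in dict.fromkeys(self.bioreplicate_ids):  # stable order
            ap = baso = None
            for sid, r, side in zip(self.sample_ids, self.bioreplicate_ids, self.sides):
                if r == rep:
                    if side is Side.APICAL:
                        ap = sid
                    else:
                        baso = sid
            out[rep] = (ap, baso)  # type: ignore[assignment]
        return out

    def side_of(self, sample_id: str) -> Side:
        return self.sides[self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "bioreplicate_id": self.bioreplicate_ids,
                "side": [s.value for s in self.sides],
            }
        )
        if self.batch_ids is not None:
            df["batch_id"] = self.batch_ids
        return df


@dataclass
class IntensityMatrix:
    """Feature x sample non-negative intensities with explicit missingness.

    Backed by a pandas DataFrame (rows = features, columns = samples,
    ``NaN`` = missing).  ``level`` records whether the features are
    peptides or proteins.
    """

    data: pd.DataFrame
    level: str  # "peptide" | "protein"

    def __post_init__(self) -> None:
        if self.level not in ("peptide", "protein"):
            raise ValueError(f"unknown matrix level {self.level!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("negative intensity")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy(), self.level)

    def log2(self) -> pd.DataFrame:
        """log2 of present values (missing stays missing; zeros cannot occur)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.data)


@dataclass(frozen=True)
class Modification:
    """A residue modification located by 1-based offset in the protein."""

    residue_offset_in_protein: int
    mod_type: ModType


@dataclass(frozen=True)
class PeptideRecord:
    peptide_id: str
    sequence: str
    protein_id: str
    start_in_protein: int  # 1-based
    modifications: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValueError(f"non-canonical residues in peptide {self.peptide_id}: {sorted(bad)}")
        if self.start_in_protein < 1:
            raise ValueError("start_in_protein must be 1-based positive")
        lo, hi = self.start_in_protein, self.start_in_protein + len(self.sequence) - 1
        for mod in self.modifications:
            off = mod.residue_offset_in_protein
            if not (lo <= off <= hi):
                raise ValueError(
                    f"modification offset {off} outside peptide span [{lo}, {hi}] "
                    f"({self.peptide_id})"
                )
            if mod.mod_type is ModType.BIOTIN_PROTEIN_NTERM and off != lo:
                raise ValueError("n-terminal biotin offset must equal the peptide start")

    @property
    def end_in_protein(self) -> int:
        return self.start_in_protein + len(self.sequence) - 1

    def validate_against(self, proteome: "Proteome") -> None:
        seq = proteome.sequences.get(self.protein_id)
        if seq is None:
            raise ValueError(f"protein {self.protein_id} not in proteome")
        sub = seq[self.start_in_protein - 1 : self.end_in_protein]
        if sub != self.sequence:
            raise ValueError(
                f"peptide {self.peptide_id} does not match protein substring at "
                f"{self.start_in_protein}"
            )


@dataclass(frozen=True)
class Segment:
    start: int  # 1-based inclusive
    end: int
    label: SegmentLabel


class TopologyError(ValueError):
    pass


@dataclass
class TopologyMap:
    """protein_id -> sorted, non-overlapping topology segments."""

    segments: dict[str, list[Segment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, segs in self.segments.items():
            segs.sort(key=lambda s: s.start)
            prev_end = 0
            for seg in segs:
                if seg.start < 1 or seg.end < seg.start:
                    raise TopologyError(f"invalid segment ({seg.start}, {seg.end}) for {pid}")
                if seg.start <= prev_end:
                    raise TopologyError(f"overlapping segments for {pid} at {seg.start}")
                prev_end = seg.end

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.segments

    def label_at(self, protein_id: str, residue: int) -> SegmentLabel | None:
        """Segment label covering ``residue`` or None when unmapped."""
        for seg in self.segments.get(protein_id, ()):
            if seg.start <= residue <= seg.end:
                return seg.label
        return None

    def is_tm(self, protein_id: str) -> bool:
        return any(
            s.label is SegmentLabel.TRANSMEMBRANE for s in self.segments.get(protein_id, ())
        )

    def extracellular_positions(self, protein_id: str) -> list[tuple[int, int]]:
        return [
            (s.start, s.end)
            for s in self.segments.get(protein_id, ())
            if s.label is SegmentLabel.EXTRACELLULAR
        ]


@dataclass
class Proteome:
    """protein_id -> amino-acid sequence."""

    sequences: dict[str, str]
    species_tag: str = ""
    flagged_ids: tuple[str, ...] = ()  # sequences containing X

    def __post_init__(self) -> None:
        flagged = []
        for pid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {pid}")
            bad = set(seq) - CANONICAL_AA - {"X"}
            if bad:
                raise ValueError(f"non-canonical residues in {pid}: {sorted(bad)}")
            if "X" in seq:
                flagged.append(pid)
        self.flagged_ids = tuple(flagged)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, pid: str) -> str:
        return self.sequences[pid]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design TSV (sample_id, bioreplicate_id, side[, batch_id])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "bioreplicate_id", "side"}
    if not required.issubset(df.columns):
        raise DesignError(f"design table must have columns {sorted(required)}")
    sides = []
    for raw in df["side"]:
        s = str(raw).strip().lower()
        try:
            sides.append(Side(s))
        except ValueError:
            raise DesignError(f"unknown side value {raw!r}") from None
    batch = tuple(df["batch_id"]) if "batch_id" in df.columns else None
    return SampleDesign(
        sample_ids=tuple(df["sample_id"]),
        bioreplicate_ids=tuple(df["bioreplicate_id"]),
        sides=tuple(sides),
        batch_ids=batch,
    )


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def _finish_matrix(df: pd.DataFrame, level: str, feature_col: str) -> IntensityMatrix:
    if df[feature_col].duplicated().any():
        dupes = df.loc[df[feature_col].duplicated(), feature_col].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")
    df = df.set_index(feature_col)
    values = df.apply(pd.to_numeric, errors="coerce")
    # cells that were non-numeric text (not the NA marker) are an input error
    bad = values.isna() & df.notna() & (df.astype(str) != MISSING)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"non-numeric cell at feature {df.index[r]!r}, column {df.columns[c]!r}")
    if (values < 0).to_numpy().any():
        raise ValueError("negative intensity")
    n_zero = int((values == 0).to_numpy().sum())
    values = values.mask(values == 0)  # LFQ zero == not detected
    mat = IntensityMatrix(values, level=level)
    mat.n_zero_converted = n_zero  # type: ignore[attr-defined]
    return mat


def read_quant_table(
    path: str | Path,
    dialect: str = "canonical",
    level: str = "protein",
    intensity_suffix: str = " Intensity",
    feature_column: str | None = None,
) -> IntensityMatrix:
    """Read a quantification table into an :class:`IntensityMatrix`.

    ``canonical``: first column is the feature id, every other column a
    sample; ``NA`` marks missing.  ``fragpipe_protein``/``fragpipe_peptide``:
    combined-table style, intensity columns selected by ``intensity_suffix``
    and renamed to the bare sample name.  Zeros become missing in all
    dialects.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    if dialect == "canonical":
        feature_col = feature_column or df.columns[0]
        return _finish_matrix(df, level, feature_col)
    if dialect in ("fragpipe_protein", "fragpipe_peptide"):
        level = "protein" if dialect == "fragpipe_protein" else "peptide"
        default_feature = "Protein ID" if level == "protein" else "Peptide Sequence"
        feature_col = feature_column or default_feature
        if feature_col not in df.columns:
            raise ValueError(f"feature column {feature_col!r} not found")
        intensity_cols = [c for c in df.columns if c.endswith(intensity_suffix)]
        if not intensity_cols:
            raise ValueError(f"no intensity columns matched suffix {intensity_suffix!r}")
        sub = df[[feature_col] + intensity_cols].rename(
            columns={c: c[: -len(intensity_suffix)] for c in intensity_cols}
        )
        return _finish_matrix(sub, level, feature_col)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_quant_table(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write the canonical dialect; missing cells become ``NA``."""
    out = matrix.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep=MISSING)


def read_topology(path: str | Path) -> TopologyMap:
    """Read a topology TSV (protein_id, start, end, label); empty file -> empty map."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return TopologyMap({})
    if df.empty:
        return TopologyMap({})
    segs: dict[str, list[Segment]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based incl. header
        try:
            label = SegmentLabel(str(row.label).strip().lower())
        except ValueError:
            raise TopologyError(f"unknown label {row.label!r} at row {i}") from None
        start, end = int(row.start), int(row.end)
        if end < start:
            raise TopologyError(f"end < start at row {i}")
        segs.setdefault(str(row.protein_id), []).append(Segment(start, end, label))
    return TopologyMap(segs)


def write_topology(topology: TopologyMap, path: str | Path) -> None:
    rows = [
        (pid, s.start, s.end, s.label.value)
        for pid, segs in topology.segments.items()
        for s in segs
    ]
    pd.DataFrame(rows, columns=["protein_id", "start", "end", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path: str | Path, species_tag: str = "") -> Proteome:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return Proteome(seqs, species_tag=species_tag)


def write_fasta(proteome: Proteome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description=proteome.species_tag)
        for pid, seq in proteome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


_MOD_RE = re.compile(r"^(\d+):([a-z_]+)$")


def write_peptide_records(records: Sequence[PeptideRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        mods = ";".join(
            f"{m.residue_offset_in_protein}:{m.mod_type.value}" for m in r.modifications
        )
        rows.append((r.peptide_id, r.sequence, r.protein_id, r.start_in_protein, mods))
    pd.DataFrame(
        rows,
        columns=["peptide_id", "sequence", "protein_id", "start_in_protein", "modifications"],
    ).to_csv(path, sep="\t", index=False)


def read_peptide_records(path: str | Path) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        mods = []
        if row.modifications:
            for token in row.modifications.split(";"):
                m = _MOD_RE.match(token)
                if not m:
                    raise ValueError(f"bad modification token {token!r}")
                mods.append(Modification(int(m.group(1)), ModType(m.group(2))))
        out.append(
            PeptideRecord(
                peptide_id=row.peptide_id,
                sequence=row.sequence,
                protein_id=row.protein_id,
                start_in_protein=int(row.start_in_protein),
                modifications=tuple(mods),
            )
        )
    return out
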