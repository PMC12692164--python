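"""Biotin Topology Check: classify biotinylation sites against membrane topology.

The membrane-impermeable labeling reagent can only reach the extracellular
face of an intact monolayer, so every genuine surface-labeling event must
fall inside an annotated extracellular segment.  Each biotinylated residue
is classified against the protein's topology segments: a site in an
extracellular segment is "OK", a site in a transmembrane or intracellular
segment is flagged (it most likely comes from a damaged cell), and a site
on a protein without topology — or outside all annotated segments — is
"unmapped".  Sites in segments annotated "unknown" are also treated as
unmapped rather than flagged, which is the conservative reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import ModType, PeptideRecord, SegmentLabel, TopologyMap

__all__ = [
    "SiteCall",
    "TopologySummary",
    "GlobalTopologyRates",
    "map_biotin_sites",
    "topology_summary",
    "CALL_OK",
    "CALL_FLAGGED",
    "CALL_UNMAPPED",
]

CALL_OK = "OK_extracellular"
CALL_FLAGGED = "flagged"
CALL_UNMAPPED = "unmapped"


@dataclass(frozen=True)
class SiteCall:
    protein_id: str
    residue: int  # 1-based
    mod_type: ModType
    segment_label: SegmentLabel | None
    call: str


def map_biotin_sites(
    records: Sequence[PeptideRecord], topology: TopologyMap
) -> list[SiteCall]:
    """One SiteCall per biotin modification, in input order."""
    calls: list[SiteCall] = []
    for rec in records:
        for mod in rec.modifications:
            if not mod.mod_type.is_biotin:
                continue
            residue = mod.residue_offset_in_protein
            label = topology.label_at(rec.protein_id, residue)
            if label is None or label is SegmentLabel.UNKNOWN:
                call = CALL_UNMAPPED
            elif label is SegmentLabel.EXTRACELLULAR:
                call = CALL_OK
            else:
                call = CALL_FLAGGED
            calls.append(
                SiteCall(
                    protein_id=rec.protein_id,
                    residue=residue,
                    mod_type=mod.mod_type,
                    segment_label=label,
                    call=call,
                )
            )
    return calls


@dataclass(frozen=True)
class TopologySummary:
    protein_id: str
    n_sites: int
    n_extracellular: int
    n_unmapped: int
    any_extracellular: bool
    all_extracellular: bool
    is_tm: bool


@dataclass
class GlobalTopologyRates:
    site_extracellular_rate: float
    protein_any_rate: float
    protein_all_rate: float
    n_sites: int
    n_proteins: int
    n_tm_proteins: int
    n_tm_any_extracellular: int
    n_tm_all_extracellular: int


def topology_summary(
    calls: Sequence[SiteCall], topology: TopologyMap
) -> tuple[list[TopologySummary], GlobalTopologyRates]:
    """Per-protein site counts plus the global extracellular rates.

    ``all_extracellular`` requires every site of the protein to be OK
    (unknown-segment and unmapped sites count as not extracellular but are
    reported separately via ``n_unmapped``).
    """
    per: dict[str, list[SiteCall]] = {}
    for c in calls:
        per.setdefault(c.protein_id, []).append(c)
    summaries = []
    for pid in sorted(per):
        sites = per[pid]
        n_extra = sum(1 for c in sites if c.call == CALL_OK)
        summaries.append(
            TopologySummary(
                protein_id=pid,
                n_sites=len(sites),
                n_extracellular=n_extra,
                n_unmapped=sum(1 for c in sites if c.call == CALL_UNMAPPED),
                any_extracellular=n_extra > 0,
                all_extracellular=n_extra == len(sites),
                is_tm=topology.is_tm(pid),
            )
        )
    n_sites = len(calls)
    n_ok = sum(1 for c in calls if c.call == CALL_OK)
    n_prot = len(summaries)
    tm = [s for s in summaries if s.is_tm]
    rates = GlobalTopologyRates(
        site_extracellular_rate=n_ok / n_sites if n_sites else float("nan"),
        protein_any_rate=(
            sum(s.any_extracellular for s in summaries) / n_prot if n_prot else float("nan")
        ),
        protein_all_rate=(
            sum(s.all_extracellular for s in summaries) / n_prot if n_prot else float("nan")
        ),
        n_sites=n_sites,
        n_proteins=n_prot,
        n_tm_proteins=len(tm),
        n_tm_any_extracellular=sum(s.any_extracellular for s in tm),
        n_tm_all_extracellular=sum(s.all_extracellular for s in tm),
    )
    return summaries, rates


def calls_to_frame(calls: Sequence[SiteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in calls],
            "residue": [c.residue for c in calls],
            "mod_type": [c.mod_type.value for c in calls],
            "segment_label": [c.segment_label.value if c.segment_label else "none" for c in calls],
            "call": [c.call for c in calls],
        }
    )


def summaries_to_frame(summaries: Sequence[TopologySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
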