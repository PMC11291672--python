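"""Marker panel: ancestry-informative SNPs and the introgression-island map.

The panel describes a KASP genotyping design for the *Ciona robusta* /
*C. intestinalis* contact zone: one mitochondrial SNP, eleven SNPs on
chromosome 5 (ten inside the introgression island plus one background SNP
"SB" outside it), and eleven unlinked nuclear SNPs pooled in a single
multiplex reaction that estimates a genome-wide hybrid index.

Island markers carry a region label (``core``, ``left_shoulder``,
``right_shoulder``, ``island_other``) that drives every downstream
partition: the 45 island SNP pairs split into core–shoulder, within-left,
within-right and cross-shoulder classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

__all__ = [
    "Region",
    "PairClass",
    "SnpMarker",
    "Panel",
    "read_panel",
    "write_panel",
    "default_panel",
]


class Region(str, Enum):
    """Where a marker sits relative to the introgression island."""

    CORE = "core"
    LEFT_SHOULDER = "left_shoulder"
    RIGHT_SHOULDER = "right_shoulder"
    ISLAND_OTHER = "island_other"
    BACKGROUND = "background"
    MITOCHONDRIAL = "mitochondrial"
    MULTIPLEX_MEMBER = "multiplex_member"


#: regions counted as inside the introgression island
ISLAND_REGIONS = frozenset(
    {Region.CORE, Region.LEFT_SHOULDER, Region.RIGHT_SHOULDER, Region.ISLAND_OTHER}
)

#: regions counted as shoulders (hitchhiking footprint)
SHOULDER_REGIONS = frozenset({Region.LEFT_SHOULDER, Region.RIGHT_SHOULDER})


class PairClass(str, Enum):
    """Classification of an island SNP pair by the regions of its members."""

    CORE_SHOULDER = "core_shoulder"
    LEFT_SHOULDER = "left_shoulder"
    RIGHT_SHOULDER = "right_shoulder"
    CROSS_SHOULDER = "cross_shoulder"


_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class SnpMarker:
    """A single ancestry-informative SNP assay."""

    marker_id: str
    chromosome: str
    position_bp: int
    allele_robusta: str
    allele_intestinalis: str
    region: Region

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"{self.marker_id}: negative position_bp")
        for allele in (self.allele_robusta, self.allele_intestinalis):
            if allele.upper() not in _IUPAC:
                raise ValueError(f"{self.marker_id}: non-IUPAC allele {allele!r}")
        if self.allele_robusta.upper() == self.allele_intestinalis.upper():
            raise ValueError(
                f"{self.marker_id}: diagnostic alleles must differ "
                f"({self.allele_robusta})"
            )


@dataclass
class Panel:
    """An ordered marker collection with the island pair partition.

    Exactly one marker must be labelled ``core``.  Island markers are kept
    sorted by physical position; the multiplex members are listed
    separately because they are read out as a single pooled assay.
    """

    markers: list[SnpMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.marker_id for m in self.markers]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate marker_id(s): {sorted(dupes)}")
        cores = [m for m in self.markers if m.region is Region.CORE]
        if len(cores) != 1:
            raise ValueError(
                f"panel must contain exactly one core marker, found {len(cores)}"
            )
        pos_seen: set[tuple[str, int]] = set()
        for m in self.markers:
            key = (m.chromosome, m.position_bp)
            if key in pos_seen:
                raise ValueError(f"duplicate position on {m.chromosome}: {m.position_bp}")
            pos_seen.add(key)

    # -- lookups -------------------------------------------------------

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, marker_id: str) -> SnpMarker:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    def __contains__(self, marker_id: str) -> bool:
        return any(m.marker_id == marker_id for m in self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def core_marker_id(self) -> str:
        return next(m.marker_id for m in self.markers if m.region is Region.CORE)

    @property
    def mito_marker_id(self) -> str | None:
        for m in self.markers:
            if m.region is Region.MITOCHONDRIAL:
                return m.marker_id
        return None

    @property
    def multiplex_marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers if m.region is Region.MULTIPLEX_MEMBER]

    @property
    def island_markers(self) -> list[SnpMarker]:
        """Island markers sorted by position (the chromosome-5 map)."""
        island = [m for m in self.markers if m.region in ISLAND_REGIONS]
        return sorted(island, key=lambda m: m.position_bp)

    @property
    def island_marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.island_markers]

    @property
    def shoulder_marker_ids(self) -> list[str]:
        return [
            m.marker_id for m in self.island_markers if m.region in SHOULDER_REGIONS
        ]

    @property
    def simplex_assay_ids(self) -> list[str]:
        """Assays read out one-by-one: everything except multiplex members."""
        return [
            m.marker_id for m in self.markers if m.region is not Region.MULTIPLEX_MEMBER
        ]

    # -- pair partition ------------------------------------------------

    def pair_class(self, id_a: str, id_b: str) -> PairClass:
        ra, rb = self[id_a].region, self[id_b].region
        regions = {ra, rb}
        if Region.CORE in regions:
            other = (regions - {Region.CORE}) or {Region.CORE}
            if next(iter(other)) in SHOULDER_REGIONS:
                return PairClass.CORE_SHOULDER
            return PairClass.CROSS_SHOULDER
        if regions == {Region.LEFT_SHOULDER}:
            return PairClass.LEFT_SHOULDER
        if regions == {Region.RIGHT_SHOULDER}:
            return PairClass.RIGHT_SHOULDER
        return PairClass.CROSS_SHOULDER

    def island_pairs(self) -> list[tuple[str, str, PairClass]]:
        """All C(n,2) island pairs in map order with their class labels."""
        ids = self.island_marker_ids
        return [
            (a, b, self.pair_class(a, b)) for a, b in itertools.combinations(ids, 2)
        ]


_PANEL_COLUMNS = [
    "marker_id",
    "chromosome",
    "position_bp",
    "allele_robusta",
    "allele_intestinalis",
    "region",
]


def read_panel(path: str | Path) -> Panel:
    """Read a panel definition TSV (one row per marker).

    The file must have a header naming the ``SnpMarker`` fields.  Duplicate
    marker ids and a core-marker count other than one are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file missing column(s): {missing}")
    markers = [
        SnpMarker(
            marker_id=row.marker_id,
            chromosome=row.chromosome,
            position_bp=int(row.position_bp),
            allele_robusta=row.allele_robusta,
            allele_intestinalis=row.allele_intestinalis,
            region=Region(row.region),
        )
        for row in df.itertuples()
    ]
    return Panel(markers)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel to TSV in the same layout ``read_panel`` expects."""
    rows = [
        {
            "marker_id": m.marker_id,
            "chromosome": m.chromosome,
            "position_bp": m.position_bp,
            "allele_robusta": m.allele_robusta,
            "allele_intestinalis": m.allele_intestinalis,
            "region": m.region.value,
        }
        for m in panel
    ]
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def default_panel() -> Panel:
    """The built-in 23-marker routine-genotyping panel.

    Ten island SNPs on chromosome 5 (four left-shoulder, the core SNP 15
    next to the candidate CYP450 tandem repeat, five right-shoulder), the
    background SNP "SB" outside the island, one mitochondrial SNP, and
    eleven multiplex members spread over the remaining nuclear chromosomes.
    Positions honour the documented anchors (core at 877,292 bp; SNP15–16
    ~22 kb apart; SNP12–13 ~35 kb; SNP20–21 ~74 kb) with the island
    spanning ~700 kb–1.3 Mb; the rest are interpolated.
    """
    L, R = Region.LEFT_SHOULDER, Region.RIGHT_SHOULDER
    island = [
        ("SNP11", 700_000, L),
        ("SNP12", 760_000, L),
        ("SNP13", 795_000, L),
        ("SNP14", 838_000, L),
        ("SNP15", 877_292, Region.CORE),
        ("SNP16", 899_292, R),
        ("SNP18", 1_010_000, R),
        ("SNP19", 1_120_000, R),
        ("SNP20", 1_226_000, R),
        ("SNP21", 1_300_000, R),
    ]
    markers = [
        SnpMarker(mid, "chr5", pos, "G", "A", region) for mid, pos, region in island
    ]
    markers.append(SnpMarker("SB", "chr5", 2_500_000, "C", "T", Region.BACKGROUND))
    markers.append(SnpMarker("SNPmt", "MT", 5_000, "G", "A", Region.MITOCHONDRIAL))
    # one multiplex member on each nuclear chromosome except 5, 8 and 10
    for i, chrom in enumerate([1, 2, 3, 4, 6, 7, 9, 11, 12, 13, 14], start=1):
        markers.append(
            SnpMarker(
                f"MPX{i:02d}", f"chr{chrom}", 1_000_000 + i, "G", "A",
                Region.MULTIPLEX_MEMBER,
            )
        )
    return Panel(markers)
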