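"""Neighbor windows, cross-species conserved synteny, paralogon detection.

A *region* is a whole chromosome restricted to the convex hull of its
member genes; gene order within a region is deliberately ignored (the
evidence type is family co-occurrence, not collinearity).  Paralogon
assembly is greedy: starting from seed regions, repeatedly add the
chromosome sharing the most gene families with the current set, subject to
a minimum-sharing threshold and a region cap (4 by default, the expectation
after two rounds of whole-genome duplication).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from wgdkit.io_formats.tables import GeneRecord, GeneTable


@dataclass
class SyntenyConfig:
    window_radius: int = 10_000_000
    min_family_members: int = 2
    include_family_sizes: Tuple[int, int] = (3, 4)
    min_shared_families_per_region_pair: int = 2
    max_regions: int = 4

    def __post_init__(self):
        if self.window_radius <= 0:
            raise ValueError("window_radius must be positive")
        if self.min_family_members < 1 or self.min_shared_families_per_region_pair < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass
class NeighborWindow:
    focal: GeneRecord
    chromosome: str
    start: int
    end: int
    members: List[GeneRecord]

    def family_ids(self) -> Set[str]:
        return {g.family_id for g in self.members}


@dataclass
class Region:
    chromosome: str
    start: int
    end: int
    genes: List[GeneRecord] = field(default_factory=list)


@dataclass
class ParalogonReport:
    regions: List[Region]
    family_membership: Dict[str, Dict[str, int]]  # family -> chromosome -> count
    multiplicity_histogram: Dict[int, int]        # regions-per-family -> n families

    def families(self) -> List[str]:
        return sorted(self.family_membership)


def extract_window(
    table: GeneTable, focal_gene_id: str, config: SyntenyConfig
) -> NeighborWindow:
    """Genes overlapping ``[focal.start - R, focal.end + R)`` on the focal chromosome."""
    focal = table.get(focal_gene_id)
    start = max(0, focal.start - config.window_radius)
    end = focal.end + config.window_radius
    members = [
        g
        for g in table.on_chromosome(focal.chromosome)
        if g.overlaps(start, end)
    ]
    return NeighborWindow(
        focal=focal, chromosome=focal.chromosome, start=start, end=end, members=members
    )


def select_candidate_families(
    windows: Sequence[NeighborWindow], genome: GeneTable, config: SyntenyConfig
) -> Dict[str, bool]:
    """Families seen in a window with enough genome-wide copies.

    Returns family -> extended-search flag; flagged families have a
    genome-wide size inside ``config.include_family_sizes`` (the ones whose
    additional members were pulled in by the extended search).
    """
    sizes = {fam: len(recs) for fam, recs in genome.families().items()}
    lo, hi = config.include_family_sizes
    out: Dict[str, bool] = {}
    for window in windows:
        for fam in window.family_ids():
            if sizes.get(fam, 0) >= config.min_family_members:
                out[fam] = lo <= sizes[fam] <= hi
    return out


def _region_from_chromosome(
    genome: GeneTable, chromosome: str, families: Set[str]
) -> Region:
    genes = [g for g in genome.on_chromosome(chromosome) if g.family_id in families]
    if genes:
        start = min(g.start for g in genes)
        end = max(g.end for g in genes)
    else:
        start = end = 0
    return Region(chromosome=chromosome, start=start, end=end, genes=genes)


def detect_paralogon(
    genome: GeneTable,
    seed_regions: Sequence[str],
    families: Set[str],
    config: Optional[SyntenyConfig] = None,
) -> ParalogonReport:
    """Greedy paralogon assembly from seed chromosomes.

    Candidate chromosomes are added while they share at least
    ``min_shared_families_per_region_pair`` families with the current set
    and the region count stays within ``max_regions``.  Ties break on
    higher shared count, then larger member count, then chromosome name.
    """
    config = config or SyntenyConfig()
    if not seed_regions:
        raise ValueError("detect_paralogon needs at least one seed region")
    regions = [_region_from_chromosome(genome, c, families) for c in seed_regions]
    chosen = {r.chromosome for r in regions}

    def families_of(region: Region) -> Set[str]:
        return {g.family_id for g in region.genes}

    current_families: Set[str] = set()
    for r in regions:
        current_families |= families_of(r)

    candidates = sorted(c for c in genome.chromosomes() if c not in chosen)
    while len(regions) < config.max_regions:
        best = None
        # candidates are pre-sorted, so strict > keeps the lexicographically
        # first chromosome on ties
        for chrom in candidates:
            region = _region_from_chromosome(genome, chrom, families)
            shared = len(families_of(region) & current_families)
            if shared < config.min_shared_families_per_region_pair:
                continue
            key = (shared, len(region.genes))
            if best is None or key > best[0]:
                best = (key, region)
        if best is None:
            break
        region = best[1]
        regions.append(region)
        chosen.add(region.chromosome)
        candidates.remove(region.chromosome)
        current_families |= families_of(region)

    membership: Dict[str, Dict[str, int]] = {}
    for region in regions:
        for gene in region.genes:
            membership.setdefault(gene.family_id, {}).setdefault(region.chromosome, 0)
            membership[gene.family_id][region.chromosome] += 1
    histogram: Dict[int, int] = {}
    for fam, per_chrom in membership.items():
        k = len(per_chrom)
        histogram[k] = histogram.get(k, 0) + 1
    return ParalogonReport(
        regions=regions,
        family_membership=membership,
        multiplicity_histogram=histogram,
    )


def genes_retained(report: ParalogonReport) -> int:
    """Total member genes across regions and families in the report."""
    return sum(
        count
        for per_chrom in report.family_membership.values()
        for count in per_chrom.values()
    )


@dataclass
class SpeciesSynteny:
    species: str
    focal_status: str                     # present | duplicated | missing | pseudogene | unplaceable
    neighbor_status: Dict[str, str]       # family -> present | duplicated | missing
    flank_contiguous: Optional[bool]      # None when not applicable


@dataclass
class SyntenyComparison:
    focal_family: str
    rows: List[SpeciesSynteny]


def _status_from_count(n: int) -> str:
    if n == 0:
        return "missing"
    if n == 1:
        return "present"
    return "duplicated"


def compare_synteny(
    tables: Dict[str, GeneTable],
    family_orthology: Dict[str, str],
    focal_family: str,
    config: Optional[SyntenyConfig] = None,
    expected_flanks: Optional[Tuple[str, str]] = None,
) -> SyntenyComparison:
    """Per-species focal/neighbor status table.

    ``family_orthology`` maps gene families to themselves or to a merged
    family label (curated orthology is an input, not computed here).  When
    the focal gene is missing and ``expected_flanks`` is given, the
    flank-contiguity flag reports whether the two flanking families are
    adjacent (no other mapped-family gene between them on one chromosome).
    """
    config = config or SyntenyConfig()
    neighbor_families = sorted(
        {fam for fam in family_orthology.values() if fam != focal_family}
    )
    rows: List[SpeciesSynteny] = []
    for species in sorted(tables):
        table = tables[species]
        mapped = [
            g for g in table if family_orthology.get(g.family_id) is not None
        ]
        if not mapped:
            rows.append(
                SpeciesSynteny(species, "unplaceable", {}, None)
            )
            continue
        by_family: Dict[str, List[GeneRecord]] = {}
        for g in mapped:
            by_family.setdefault(family_orthology[g.family_id], []).append(g)
        focal_genes = by_family.get(focal_family, [])
        if focal_genes and all(g.status == "pseudogene" for g in focal_genes):
            focal_status = "pseudogene"
        else:
            focal_status = _status_from_count(
                sum(1 for g in focal_genes if g.status == "coding")
            )
        neighbor_status = {
            fam: _status_from_count(len(by_family.get(fam, [])))
            for fam in neighbor_families
        }
        contiguous: Optional[bool] = None
        if focal_status == "missing" and expected_flanks is not None:
            contiguous = _flanks_adjacent(
                table, family_orthology, expected_flanks
            )
        rows.append(
            SpeciesSynteny(species, focal_status, neighbor_status, contiguous)
        )
    return SyntenyComparison(focal_family=focal_family, rows=rows)


def _flanks_adjacent(
    table: GeneTable,
    family_orthology: Dict[str, str],
    flanks: Tuple[str, str],
) -> bool:
    """True when some gene of each flank family sit next to each other,
    counting only genes whose family is in the orthology map."""
    left, right = flanks
    for chrom in table.chromosomes():
        mapped = [
            g
            for g in table.on_chromosome(chrom)
            if family_orthology.get(g.family_id) is not None
        ]
        fams = [family_orthology[g.family_id] for g in mapped]
        for a, b in zip(fams, fams[1:]):
            if {a, b} == {left, right}:
                return True
    return False
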