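"""Genome evolution simulator with WGDs, tandem duplications, losses,
pseudogenizations and rearrangements, plus a full truth log.

The simulator walks the species tree preorder carrying a genome (an
ordered list of genes per chromosome).  A WGD on a tagged branch copies
every chromosome; each *new* gene copy is retained independently with
``wgd_retention_prob`` (originals always survive, so family presence can
only be erased by explicit loss events).  Event counts per branch are
Poisson with the configured rates; positions are uniform.  Identical
config + seed gives byte-identical outputs.

True gene trees are built during simulation: every duplication creates a
binary split, every speciation fans a lineage out to the child branches,
and dead or unary nodes are pruned afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from wgdkit.io_formats.matrix import PresenceMatrix, State
from wgdkit.io_formats.tables import GeneRecord, GeneTable
from wgdkit.io_formats.trees import Tree, parse_newick
from wgdkit.synteny_paralogon import ParalogonReport, Region


@dataclass
class SimulationConfig:
    species_tree: Tree
    n_families: int = 10
    ancestral_chromosomes: int = 1
    genes_per_chromosome: int = 10
    gene_span: int = 10_000
    intergenic_gap: int = 90_000
    wgd_retention_prob: float = 1.0
    local_dup_rate: float = 0.0
    loss_rate: float = 0.0
    pseudogenization_prob: float = 0.0
    rearrangement_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("wgd_retention_prob", "pseudogenization_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in (
            "n_families", "ancestral_chromosomes", "genes_per_chromosome",
            "gene_span", "intergenic_gap",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("local_dup_rate", "loss_rate", "rearrangement_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class _HistNode:
    """Node of the in-simulation gene history forest."""

    __slots__ = ("children", "label", "kind", "branch", "tag")

    def __init__(self, kind: str = "lineage", branch: Optional[str] = None,
                 tag: Optional[str] = None):
        self.children: List[_HistNode] = []
        self.label: Optional[str] = None
        self.kind = kind          # lineage | duplication | leaf | dead
        self.branch = branch
        self.tag = tag


class _SimGene:
    __slots__ = ("gene_id", "family", "status", "hist")

    def __init__(self, gene_id: str, family: str, status: str, hist: _HistNode):
        self.gene_id = gene_id
        self.family = family
        self.status = status
        self.hist = hist


@dataclass
class RealizedEvent:
    branch: str
    kind: str                     # wgd | local_duplication | loss | pseudogenization | rearrangement
    family: Optional[str] = None
    gene_id: Optional[str] = None
    parent_gene_id: Optional[str] = None
    tag: Optional[str] = None
    detail: Optional[str] = None


@dataclass
class ObservableDuplication:
    """A realized duplication with surviving descendants on both sides.

    ``mrca_species`` is the species-tree MRCA of the species carrying the
    surviving descendants — derived by walking the truth pedigree, which is
    exactly what LCA reconciliation of the true gene tree must recover.
    """

    family: str
    branch: str
    kind: str
    tag: Optional[str]
    mrca_species: str


@dataclass
class TruthLog:
    events: List[RealizedEvent]
    pedigree: Dict[str, Optional[str]]           # gene_id -> parent gene_id
    family_of: Dict[str, str]                    # gene_id -> family
    ancestral_chromosome_of: Dict[str, str]      # ancestral gene -> chromosome
    chromosome_origin: Dict[str, str]            # chromosome -> ancestral chromosome
    observable_duplications: Dict[str, List[ObservableDuplication]] = field(
        default_factory=dict
    )

    def root_ancestor(self, gene_id: str) -> str:
        while self.pedigree.get(gene_id) is not None:
            gene_id = self.pedigree[gene_id]  # type: ignore[assignment]
        return gene_id

    def to_dict(self) -> dict:
        return {
            "events": [vars(e) for e in self.events],
            "pedigree": dict(self.pedigree),
            "family_of": dict(self.family_of),
            "ancestral_chromosome_of": dict(self.ancestral_chromosome_of),
            "chromosome_origin": dict(self.chromosome_origin),
        }


@dataclass
class SimulationResult:
    gene_tables: Dict[str, GeneTable]            # leaf species -> table
    gene_trees: Dict[str, Tree]                  # family -> true tree
    presence_matrix: PresenceMatrix
    truth_log: TruthLog


_Genome = Dict[str, List[_SimGene]]  # chromosome -> ordered genes


def simulate(config: SimulationConfig) -> SimulationResult:
    rng = np.random.default_rng(config.seed)
    tree = config.species_tree
    counter = {"gene": 0, "wgd": 0}
    log = TruthLog(events=[], pedigree={}, family_of={},
                   ancestral_chromosome_of={}, chromosome_origin={})

    # ancestral genome: families assigned cyclically across positions
    genome: _Genome = {}
    roots: Dict[str, List[_HistNode]] = {}
    pos = 0
    for c in range(config.ancestral_chromosomes):
        chrom = f"chr{c + 1}"
        log.chromosome_origin[chrom] = chrom
        genes: List[_SimGene] = []
        for i in range(config.genes_per_chromosome):
            fam = f"fam{(pos % config.n_families) + 1}" if config.n_families else "fam0"
            gid = f"g{counter['gene']}"
            counter["gene"] += 1
            hist = _HistNode()
            gene = _SimGene(gid, fam, "coding", hist)
            genes.append(gene)
            roots.setdefault(fam, []).append(hist)
            log.pedigree[gid] = None
            log.family_of[gid] = fam
            log.ancestral_chromosome_of[gid] = chrom
            pos += 1
        genome[chrom] = genes

    def new_gene(parent: _SimGene, suffix: str, hist: _HistNode) -> _SimGene:
        gid = f"{parent.gene_id}_{suffix}{counter['gene']}"
        counter["gene"] += 1
        gene = _SimGene(gid, parent.family, parent.status, hist)
        log.pedigree[gid] = parent.gene_id
        log.family_of[gid] = parent.family
        return gene

    def apply_wgd(gen: _Genome, branch: str, tag: str) -> None:
        counter["wgd"] += 1
        k = counter["wgd"]
        for chrom in list(gen):
            new_chrom = f"{chrom}_w{k}"
            log.chromosome_origin[new_chrom] = log.chromosome_origin[chrom]
            new_genes: List[_SimGene] = []
            for gene in gen[chrom]:
                if rng.random() < config.wgd_retention_prob:
                    dup = gene.hist
                    dup.kind = "duplication"
                    dup.branch = branch
                    dup.tag = tag
                    keep = _HistNode()
                    copy_h = _HistNode()
                    dup.children = [keep, copy_h]
                    gene.hist = keep
                    copy_gene = new_gene(gene, "w", copy_h)
                    new_genes.append(copy_gene)
                    log.events.append(RealizedEvent(
                        branch=branch, kind="wgd", family=gene.family,
                        gene_id=copy_gene.gene_id, parent_gene_id=gene.gene_id,
                        tag=tag,
                    ))
            gen[new_chrom] = new_genes

    def all_genes(gen: _Genome) -> List[Tuple[str, int, _SimGene]]:
        return [
            (chrom, i, gene)
            for chrom in sorted(gen)
            for i, gene in enumerate(gen[chrom])
        ]

    def apply_local_duplication(gen: _Genome, branch: str) -> None:
        pool = all_genes(gen)
        if not pool:
            return
        chrom, i, gene = pool[rng.integers(len(pool))]
        dup = gene.hist
        dup.kind = "duplication"
        dup.branch = branch
        dup.tag = None
        keep = _HistNode()
        copy_h = _HistNode()
        dup.children = [keep, copy_h]
        gene.hist = keep
        copy_gene = new_gene(gene, "d", copy_h)
        gen[chrom].insert(i + 1, copy_gene)  # tandem: adjacent to parent
        log.events.append(RealizedEvent(
            branch=branch, kind="local_duplication", family=gene.family,
            gene_id=copy_gene.gene_id, parent_gene_id=gene.gene_id,
        ))

    def apply_loss(gen: _Genome, branch: str) -> None:
        pool = [(c, i, g) for c, i, g in all_genes(gen) if g.status == "coding"]
        if not pool:
            return
        chrom, i, gene = pool[rng.integers(len(pool))]
        if rng.random() < config.pseudogenization_prob:
            gene.status = "pseudogene"
            log.events.append(RealizedEvent(
                branch=branch, kind="pseudogenization", family=gene.family,
                gene_id=gene.gene_id,
            ))
        else:
            gene.hist.kind = "dead"
            gen[chrom].pop(i)
            log.events.append(RealizedEvent(
                branch=branch, kind="loss", family=gene.family,
                gene_id=gene.gene_id,
            ))

    def apply_rearrangement(gen: _Genome, branch: str) -> None:
        chroms = sorted(c for c in gen if gen[c])
        if not chroms:
            return
        chrom = chroms[rng.integers(len(chroms))]
        genes = gen[chrom]
        n = len(genes)
        a = int(rng.integers(n))
        b = int(rng.integers(a, n)) + 1
        block = genes[a:b]
        if rng.random() < 0.5:
            gen[chrom] = genes[:a] + block[::-1] + genes[b:]
            detail = f"inversion {chrom}[{a}:{b}]"
        else:
            rest = genes[:a] + genes[b:]
            gen[chrom] = rest
            target = chroms[rng.integers(len(chroms))]
            tgenes = gen[target]
            at = int(rng.integers(len(tgenes) + 1)) if tgenes else 0
            gen[target] = tgenes[:at] + block + tgenes[at:]
            detail = f"translocation {chrom}[{a}:{b}]->{target}@{at}"
        log.events.append(RealizedEvent(
            branch=branch, kind="rearrangement", detail=detail,
        ))

    def apply_branch(gen: _Genome, branch: str) -> None:
        tag = tree.wgd_tags.get(branch)
        if tag is not None:
            apply_wgd(gen, branch, tag)
        for _ in range(rng.poisson(config.local_dup_rate)):
            apply_local_duplication(gen, branch)
        for _ in range(rng.poisson(config.loss_rate)):
            apply_loss(gen, branch)
        for _ in range(rng.poisson(config.rearrangement_rate)):
            apply_rearrangement(gen, branch)

    gene_tables: Dict[str, GeneTable] = {}

    def emit_table(species: str, gen: _Genome) -> None:
        table = GeneTable(species)
        for chrom in sorted(gen):
            for i, gene in enumerate(gen[chrom]):
                start = i * (config.gene_span + config.intergenic_gap)
                table.add(GeneRecord(
                    gene_id=gene.gene_id,
                    species=species,
                    family_id=gene.family,
                    chromosome=chrom,
                    start=start,
                    end=start + max(config.gene_span, 1),
                    strand="+",
                    status=gene.status,
                ))
                gene.hist.kind = "leaf"
                gene.hist.label = f"{species}|{gene.gene_id}"
        gene_tables[species] = table

    def branch_genome(gen: _Genome) -> _Genome:
        """Clone for one child branch, fanning each lineage node out."""
        out: _Genome = {}
        for chrom, genes in gen.items():
            new_genes = []
            for gene in genes:
                cont = _HistNode()
                gene.hist.children.append(cont)
                clone = _SimGene(gene.gene_id, gene.family, gene.status, cont)
                new_genes.append(clone)
            out[chrom] = new_genes
        return out

    def recurse(node, gen: _Genome) -> None:
        apply_branch(gen, node.label)
        if node.is_leaf:
            emit_table(node.label, gen)
        else:
            for child in node.children:
                recurse(child, branch_genome(gen))

    recurse(tree.root, genome)

    gene_trees = _build_gene_trees(roots)
    matrix = _presence_from_tables(gene_tables, tree)
    log.observable_duplications = _observable_duplications(roots, tree, log)
    return SimulationResult(
        gene_tables=gene_tables,
        gene_trees=gene_trees,
        presence_matrix=matrix,
        truth_log=log,
    )


def _prune(node: _HistNode) -> Optional[_HistNode]:
    """Drop dead subtrees and suppress unary pass-through nodes."""
    if node.kind == "leaf":
        return node
    kept = [c for c in (_prune(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    return node


def _newick_of(node: _HistNode) -> str:
    if node.kind == "leaf":
        return node.label  # type: ignore[return-value]
    inner = ",".join(_newick_of(c) for c in node.children)
    return f"({inner})"


def _build_gene_trees(roots: Dict[str, List[_HistNode]]) -> Dict[str, Tree]:
    trees: Dict[str, Tree] = {}
    for fam in sorted(roots):
        survivors = [p for p in (_prune(r) for r in roots[fam]) if p is not None]
        if not survivors:
            continue
        if len(survivors) == 1:
            text = _newick_of(survivors[0]) + ";"
        else:  # family seeded by several ancestral genes: forest under a root
            text = "(" + ",".join(_newick_of(s) for s in survivors) + ");"
        trees[fam] = parse_newick(text)
    return trees


def _presence_from_tables(
    gene_tables: Dict[str, GeneTable], tree: Tree
) -> PresenceMatrix:
    species = tree.leaf_labels()
    matrix = PresenceMatrix(species)
    families: Set[str] = set()
    for table in gene_tables.values():
        families |= set(table.families())
    for fam in sorted(families):
        states = {}
        for sp in species:
            recs = gene_tables[sp].families().get(fam, [])
            if any(r.status == "coding" for r in recs):
                states[sp] = State.PRESENT
            elif recs:
                states[sp] = State.PSEUDOGENE
            else:
                states[sp] = State.ABSENT
        matrix.set_row(fam, states)
    return matrix


def _leaf_species_below(node: _HistNode, out: Set[str]) -> None:
    if node.kind == "leaf":
        out.add(node.label.split("|", 1)[0])  # type: ignore[union-attr]
    for c in node.children:
        _leaf_species_below(c, out)


def _observable_duplications(
    roots: Dict[str, List[_HistNode]], tree: Tree, log: TruthLog
) -> Dict[str, List[ObservableDuplication]]:
    """Pedigree-walk derivation of the duplications reconciliation can see."""
    out: Dict[str, List[ObservableDuplication]] = {}

    def walk(node: _HistNode, fam: str) -> Set[str]:
        below: Set[str] = set()
        if node.kind == "leaf":
            below.add(node.label.split("|", 1)[0])  # type: ignore[union-attr]
        sides = []
        for c in node.children:
            s = walk(c, fam)
            sides.append(s)
            below |= s
        if node.kind == "duplication":
            live = [s for s in sides if s]
            # identifiable iff one copy's surviving species span the same
            # MRCA as the union: two copies surviving in disjoint clades
            # below the duplication are indistinguishable from a speciation
            if len(live) >= 2:
                mrca = tree.mrca(sorted(below)).label
                side_mrcas = {tree.mrca(sorted(s)).label for s in live}
                if mrca in side_mrcas:
                    out.setdefault(fam, []).append(ObservableDuplication(
                        family=fam,
                        branch=node.branch or "",
                        kind="wgd" if node.tag else "local_duplication",
                        tag=node.tag,
                        mrca_species=mrca,
                    ))
        return below

    for fam in sorted(roots):
        for root in roots[fam]:
            walk(root, fam)
    return out


def truth_paralogon(
    result: SimulationResult,
    leaf_species: str,
    ancestral_chromosome: str = "chr1",
) -> ParalogonReport:
    """Ground-truth paralogon: the regions of one leaf genome descended from
    a single ancestral chromosome, with true family multiplicities."""
    if leaf_species not in result.gene_tables:
        raise KeyError(f"species {leaf_species!r} was not simulated")
    table = result.gene_tables[leaf_species]
    origin = result.truth_log.chromosome_origin
    regions: List[Region] = []
    membership: Dict[str, Dict[str, int]] = {}
    for chrom in table.chromosomes():
        if origin.get(chrom) != ancestral_chromosome:
            continue
        genes = table.on_chromosome(chrom)
        if not genes:
            continue
        regions.append(Region(
            chromosome=chrom,
            start=min(g.start for g in genes),
            end=max(g.end for g in genes),
            genes=genes,
        ))
        for g in genes:
            membership.setdefault(g.family_id, {}).setdefault(chrom, 0)
            membership[g.family_id][chrom] += 1
    histogram: Dict[int, int] = {}
    for fam, per_chrom in membership.items():
        k = len(per_chrom)
        histogram[k] = histogram.get(k, 0) + 1
    return ParalogonReport(
        regions=regions,
        family_membership=membership,
        multiplicity_histogram=histogram,
    )
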