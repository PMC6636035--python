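"""Synthetic multi-species gene catalogs with planted GC structure.

The generator emulates, at desk scale, the compositional structure of
vertebrate exomes:

* a reference genome of ``n_genes`` ranked genes split over chromosomes,
  with a regionally autocorrelated GC *target* curve — a baseline plus
  Gaussian bumps (the analogue of GC-rich isochores), clipped to [25, 75]%;
* coding sequences whose amino-acid usage is coupled to the local GC
  target: the probability of drawing a GARP residue rises with the target
  and the FYMINK probability falls symmetrically, with strength κ ∈ [0,1],
  while synonymous codons favor G/C third positions with probability
  gc_target/100;
* evolution of the ancestral genome down a species tree: per-site
  substitutions at each branch's rate, with GC-biased gene conversion
  (gBGC) emulated in chosen rank intervals per branch — inside an interval
  of bias β the substitution rate is scaled by (1+β) and replacement bases
  favor G/C with weight (1+β), so biased regions both gain GC and diverge
  faster, as gBGC hotspots do over deep time;
* gene-order rearrangements: contiguous blocks of genes move to new
  positions along a branch (coordinates change, sequences do not),
  emulating synteny breaks.

All randomness flows from a single seed; equal seeds give byte-identical
outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import yaml
from Bio.Data import CodonTable

from .catalog import GeneRecord, SpeciesTable

# base encoding used throughout: 0=A, 1=C, 2=G, 3=T
BASES = "ACGT"
_GC_BASES = np.array([1, 2])  # C, G

P_GROUP_BASELINE = 0.25  # P(GARP) = P(FYMINK) = 1/4 at a 50% GC target

_GARP = "GARP"
_FYMINK = "FYMINK"
_MIXED = "LSCHQTVDEW"


def _build_code():
    table = CodonTable.unambiguous_dna_by_name["Standard"]
    aa_of = np.empty(64, dtype="<U1")
    stops = np.zeros(64, dtype=bool)
    for i0, b0 in enumerate(BASES):
        for i1, b1 in enumerate(BASES):
            for i2, b2 in enumerate(BASES):
                idx = 16 * i0 + 4 * i1 + i2
                codon = b0 + b1 + b2
                if codon in table.stop_codons:
                    aa_of[idx] = "*"
                    stops[idx] = True
                else:
                    aa_of[idx] = table.forward_table[codon]
    codons_of: dict[str, dict[str, np.ndarray]] = {}
    for aa in set(aa_of) - {"*"}:
        idxs = np.nonzero(aa_of == aa)[0]
        third = idxs % 4
        gc3 = idxs[np.isin(third, _GC_BASES)]
        at3 = idxs[~np.isin(third, _GC_BASES)]
        codons_of[aa] = {"gc3": gc3, "at3": at3}
    return aa_of, stops, codons_of


AA_OF_CODON, STOP_CODONS, CODONS_OF_AA = _build_code()


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``tree`` is a Newick string whose branch lengths are expected
    substitutions per site; internal nodes may be labeled so that
    ``gbgc`` (node label → list of ``[start_rank, end_rank, bias]``)
    and the clade map can address them. Ranks are 1-based inclusive.
    """

    n_genes: int = 1000
    n_chromosomes: int = 2
    n_codons: int = 150
    gc_baseline: float = 50.0
    peaks: list = field(default_factory=list)  # (center_rank, width_ranks, amplitude_pct)
    coupling: float = 1.0
    tree: str | None = None
    clades: dict = field(default_factory=dict)  # leaf -> clade label
    gbgc: dict = field(default_factory=dict)  # node label -> [(start, end, bias)]
    rearrangement_rate: float = 0.0  # expected block moves per branch
    max_block: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling κ must lie in [0, 1]")
        if self.rearrangement_rate < 0:
            raise ValueError("rearrangement_rate must be ≥ 0")
        for c, wdt, amp in self.peaks:
            if not 1 <= c <= self.n_genes:
                raise ValueError(f"peak center {c} outside [1, {self.n_genes}]")
            if wdt <= 0:
                raise ValueError("peak width must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "peaks" in raw:
            raw["peaks"] = [tuple(p) for p in raw["peaks"]]
        if "gbgc" in raw:
            raw["gbgc"] = {k: [tuple(v) for v in vs] for k, vs in raw["gbgc"].items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """What the simulator planted, for recovery tests."""

    gc_target: np.ndarray  # per ancestral rank, %
    peaks: list
    tree: str | None
    gbgc: dict
    rearrangements: dict = field(default_factory=dict)  # branch label -> moves

    def to_json(self) -> str:
        return json.dumps(
            {
                "gc_target": [round(float(x), 6) for x in self.gc_target],
                "peaks": [list(p) for p in self.peaks],
                "tree": self.tree,
                "gbgc": {k: [list(v) for v in vs] for k, vs in self.gbgc.items()},
                "rearrangements": {
                    k: [list(m) for m in v] for k, v in self.rearrangements.items()
                },
            },
            indent=1,
        )


@dataclass
class Genome:
    """A genome state: gene order plus per-gene codon arrays."""

    order: list[str]  # gene symbols, current order
    codons: dict[str, np.ndarray]  # symbol -> (n_codons, 3) base indices
    ancestral_rank: dict[str, int]  # symbol -> rank in the ancestral order


def gc_target_curve(config: SimulationConfig) -> np.ndarray:
    """Baseline + Gaussian bumps, clipped to [25, 75]%."""
    ranks = np.arange(1, config.n_genes + 1, dtype=float)
    target = np.full(config.n_genes, float(config.gc_baseline))
    for center, width, amplitude in config.peaks:
        target += amplitude * np.exp(-0.5 * ((ranks - center) / width) ** 2)
    return np.clip(target, 25.0, 75.0)


def group_probabilities(gc_target: float, kappa: float) -> tuple[float, float, float]:
    """(P_GARP, P_FYMINK, P_MIXED) at one GC target; clipped to [0, 1]."""
    shift = kappa * (gc_target - 50.0) / 100.0
    pg = min(max(P_GROUP_BASELINE + shift, 0.0), 1.0)
    pf = min(max(P_GROUP_BASELINE - shift, 0.0), 1.0)
    pm = max(1.0 - pg - pf, 0.0)
    total = pg + pf + pm
    return pg / total, pf / total, pm / total


def simulate_cds(
    gc_target: float, n_codons: int, kappa: float, rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    """One coding sequence under the GC-coupled sampling law.

    Residue groups are drawn with P(GARP) = 0.25 + κ·(gc−50)/100 and the
    mirror for FYMINK; residues are uniform within group; the synonymous
    codon ends in G/C with probability gc_target/100 (when the amino acid
    offers both). Returns the (n_codons, 3) base-index array and the
    translated protein.
    """
    pg, pf, pm = group_probabilities(gc_target, kappa)
    groups = rng.choice(3, size=n_codons, p=[pg, pf, pm])
    residues = np.empty(n_codons, dtype="<U1")
    for gi, pool in enumerate((_GARP, _FYMINK, _MIXED)):
        mask = groups == gi
        n = int(mask.sum())
        if n:
            residues[mask] = np.array(list(pool))[rng.integers(0, len(pool), size=n)]
    want_gc3 = rng.random(n_codons) < gc_target / 100.0
    codon_idx = np.empty(n_codons, dtype=np.int64)
    for aa, sets in CODONS_OF_AA.items():
        mask = residues == aa
        n = int(mask.sum())
        if not n:
            continue
        gc3, at3 = sets["gc3"], sets["at3"]
        pick_gc = want_gc3[mask]
        if len(gc3) == 0:
            pick_gc = np.zeros(n, dtype=bool)
        if len(at3) == 0:
            pick_gc = np.ones(n, dtype=bool)
        chosen = np.empty(n, dtype=np.int64)
        n_gc = int(pick_gc.sum())
        if n_gc:
            chosen[pick_gc] = gc3[rng.integers(0, len(gc3), size=n_gc)]
        if n - n_gc:
            chosen[~pick_gc] = at3[rng.integers(0, len(at3), size=n - n_gc)]
        codon_idx[mask] = chosen
    codons = np.stack([codon_idx // 16, (codon_idx // 4) % 4, codon_idx % 4], axis=1)
    return codons.astype(np.int8), "".join(AA_OF_CODON[codon_idx])


def translate(codons: np.ndarray) -> str:
    idx = 16 * codons[:, 0].astype(int) + 4 * codons[:, 1].astype(int) + codons[:, 2].astype(int)
    return "".join(AA_OF_CODON[idx])


def to_dna(codons: np.ndarray) -> str:
    return "".join(BASES[b] for b in codons.ravel())


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Genome, GroundTruth]:
    """The ancestral genome: ranked genes with GC-coupled coding sequence."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    target = gc_target_curve(config)
    width = len(str(config.n_genes))
    symbols = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    codons = {}
    for sym, gc in zip(symbols, target):
        arr, _ = simulate_cds(float(gc), config.n_codons, config.coupling, rng)
        codons[sym] = arr
    truth = GroundTruth(
        gc_target=target, peaks=list(config.peaks), tree=config.tree, gbgc=dict(config.gbgc)
    )
    genome = Genome(
        order=list(symbols),
        codons=codons,
        ancestral_rank={s: i + 1 for i, s in enumerate(symbols)},
    )
    return genome, truth


def _site_bias(genome: Genome, intervals) -> np.ndarray:
    """Per-gene gBGC bias from rank intervals on the *ancestral* order."""
    bias = np.zeros(len(genome.order))
    rank = np.array([genome.ancestral_rank[s] for s in genome.order])
    for start, end, beta in intervals:
        bias[(rank >= start) & (rank <= end)] += beta
    return bias


def evolve_branch(
    genome: Genome,
    branch_length: float,
    intervals,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[Genome, list]:
    """One branch: biased per-site substitution + block rearrangements.

    Substitution: each site mutates with probability 1 − exp(−b·(1+β));
    the replacement base is drawn from the other three with G/C weighted
    (1+β), where β is the gene's summed gBGC bias on this branch.
    Substitutions that would create a stop codon are rejected (the codon
    reverts). Rearrangement: Poisson(rate) contiguous blocks move to
    uniformly random new positions in the gene order.
    """
    order = list(genome.order)
    n_genes = len(order)
    gene_bias = _site_bias(genome, intervals)

    stack = np.stack([genome.codons[s] for s in order])  # (genes, codons, 3)
    original = stack.copy()
    beta = gene_bias[:, None, None]
    p = 1.0 - np.exp(-branch_length * (1.0 + beta))
    mutate = rng.random(stack.shape) < p

    flat = stack.reshape(-1)
    mut_idx = np.nonzero(mutate.reshape(-1))[0]
    if mut_idx.size:
        beta_flat = np.broadcast_to(beta, stack.shape).reshape(-1)[mut_idx]
        cur = flat[mut_idx]
        w = np.ones((mut_idx.size, 4))
        w[:, 1] = w[:, 2] = 1.0 + beta_flat
        w[np.arange(mut_idx.size), cur] = 0.0
        cum = np.cumsum(w, axis=1)
        u = rng.random(mut_idx.size) * cum[:, -1]
        flat[mut_idx] = (u[:, None] >= cum).sum(axis=1)
        stack = flat.reshape(stack.shape)
        # reject substitutions that create stop codons
        idx = 16 * stack[..., 0].astype(int) + 4 * stack[..., 1].astype(int) + stack[..., 2].astype(int)
        bad = STOP_CODONS[idx]
        stack[bad] = original[bad]

    codons = {s: stack[i] for i, s in enumerate(order)}

    moves = []
    if config.rearrangement_rate > 0:
        for _ in range(rng.poisson(config.rearrangement_rate)):
            length = int(rng.integers(1, config.max_block + 1))
            length = min(length, n_genes - 1)
            i = int(rng.integers(0, n_genes - length + 1))
            block = order[i : i + length]
            rest = order[:i] + order[i + length :]
            j = int(rng.integers(0, len(rest) + 1))
            order = rest[:j] + block + rest[j:]
            moves.append((i, length, j))

    return Genome(order=order, codons=codons, ancestral_rank=genome.ancestral_rank), moves


@dataclass
class SpeciesData:
    """One simulated leaf: catalog plus sequence maps."""

    table: SpeciesTable
    transcripts: dict[str, str]
    proteins: dict[str, str]

    def proteins_by_symbol(self) -> dict[str, str]:
        return {
            r.gene_symbol: self.proteins[r.protein_accession]
            for r in self.table.records
            if r.protein_accession in self.proteins
        }

    def metric_input(self):
        return self.table, self.transcripts, self.proteins


def _node_label(node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def _emit_species(
    genome: Genome, species: str, species_idx: int, clade: str, config: SimulationConfig
) -> SpeciesData:
    gene_len = 3 * config.n_codons
    spacing = gene_len + 1000
    n = len(genome.order)
    per_chrom = math.ceil(n / config.n_chromosomes)
    records, transcripts, proteins = [], {}, {}
    for pos, sym in enumerate(genome.order):
        chrom = f"chr{pos // per_chrom + 1}"
        offset = pos % per_chrom
        start = offset * spacing + 1
        gi = genome.ancestral_rank[sym]
        tx = f"NM_{species_idx:02d}{gi:06d}"
        pr = f"NP_{species_idx:02d}{gi:06d}"
        records.append(
            GeneRecord(
                gene_symbol=sym,
                chromosome=chrom,
                start=start,
                end=start + gene_len - 1,
                strand="+",
                transcript_accession=tx,
                transcript_length=gene_len,
                protein_accession=pr,
                species=species,
                clade=clade,
            )
        )
        arr = genome.codons[sym]
        transcripts[tx] = to_dna(arr)
        proteins[pr] = translate(arr)
    table = SpeciesTable(species=species, clade=clade, records=records)
    return SpeciesData(table=table, transcripts=transcripts, proteins=proteins)


def evolve_species(
    ancestor: Genome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
) -> dict[str, SpeciesData]:
    """Evolve the ancestor down the config's tree; emit one catalog per leaf.

    Branches are processed in a deterministic preorder; each branch applies
    its own gBGC intervals (``config.gbgc`` keyed by the child node's
    label) on top of the neutral substitution process.
    """
    if config.tree is None:
        raise ValueError("evolve_species: config.tree is required")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("species tree needs at least 2 leaves")

    result: dict[str, SpeciesData] = {}
    state: dict[int, Genome] = {id(tree.seed_node): ancestor}
    species_counter = {"i": 0}

    def visit(node):
        genome = state[id(node)]
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            label = _node_label(child)
            intervals = config.gbgc.get(label, [])
            child_genome, moves = evolve_branch(genome, b, intervals, config, rng)
            if truth is not None and moves:
                truth.rearrangements[label] = moves
            state[id(child)] = child_genome
            if child.is_leaf():
                species_counter["i"] += 1
                clade = config.clades.get(label, "mammal")
                result[label] = _emit_species(
                    child_genome, label, species_counter["i"], clade, config
                )
            else:
                visit(child)

    visit(tree.seed_node)
    return result


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[dict[str, SpeciesData], GroundTruth]:
    """Ancestor + tree evolution in one call (the CLI entry point)."""
    rng = np.random.default_rng(config.seed)
    ancestor, truth = simulate_reference(config, rng)
    species = evolve_species(ancestor, config, rng, truth)
    return species, truth
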