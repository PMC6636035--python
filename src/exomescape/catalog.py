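"""Per-species gene catalogs, representative transcripts and ortholog matching.

A gene catalog is a tab-separated table with one row per gene, carrying the
gene symbol, chromosomal coordinates, the representative RefSeq transcript
accession and a vertebrate clade label.  Catalogs from many species are
matched to a reference species by gene symbol (optionally through an alias
map for unresolved ``LOC``-style symbols) and reduced to a common vertebrate
gene set by a clade-presence rule: keep a gene if at least ``min_count``
species of a basal clade group (fish, amphibia, non-avian reptiles by
default) possess it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

CLADES = ("fish", "amphibia", "non_avian_reptile", "bird", "mammal")

#: clade group used for the common-gene-set rule: basal (non-mammal,
#: non-bird) vertebrate lineages.
BASAL_CLADES = frozenset({"fish", "amphibia", "non_avian_reptile"})

#: RefSeq accession prefixes of protein-coding mRNAs (curated + predicted).
CODING_PREFIXES = ("NM_", "XM_")

_REQUIRED_COLUMNS = (
    "gene_symbol",
    "chromosome",
    "start",
    "end",
    "strand",
    "transcript_accession",
)
_OPTIONAL_COLUMNS = ("transcript_length", "protein_accession", "species", "clade")


class GeneTableFormatError(ValueError):
    """Raised when a gene table does not conform to the expected TSV layout."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identity, coordinates and its representative transcript."""

    gene_symbol: str
    chromosome: str
    start: int
    end: int
    strand: str
    transcript_accession: str
    transcript_length: int | None = None
    protein_accession: str | None = None
    species: str = ""
    clade: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_symbol}: start {self.start} > end {self.end}"
            )
        if self.transcript_length is not None and self.transcript_length <= 0:
            raise ValueError(
                f"gene {self.gene_symbol}: transcript_length must be positive"
            )
        if self.clade and self.clade not in CLADES:
            raise ValueError(
                f"gene {self.gene_symbol}: unknown clade {self.clade!r}; "
                f"expected one of {CLADES}"
            )


@dataclass
class SpeciesTable:
    """A finalized per-species catalog: at most one record per gene symbol."""

    species: str
    clade: str
    records: list[GeneRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def symbols(self) -> list[str]:
        return [r.gene_symbol for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        cols = _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS
        rows = [{c: getattr(r, c) for c in cols} for r in self.records]
        return pd.DataFrame(rows, columns=list(cols))


def read_gene_table(path, species: str, clade: str) -> SpeciesTable:
    """Read a tab-separated gene table into a :class:`SpeciesTable`.

    Rows with missing mandatory fields or violated invariants are rejected
    with their (1-based, data) row number.
    """
    if clade not in CLADES:
        raise ValueError(f"unknown clade label {clade!r}; expected one of {CLADES}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise GeneTableFormatError(f"{path}: missing required column(s) {missing}")
    records: list[GeneRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        for c in _REQUIRED_COLUMNS:
            if pd.isna(d[c]) or str(d[c]) == "":
                raise GeneTableFormatError(
                    f"{path}: row {i}: missing mandatory field {c!r}"
                )
        tl = d.get("transcript_length")
        try:
            records.append(
                GeneRecord(
                    gene_symbol=str(d["gene_symbol"]),
                    chromosome=str(d["chromosome"]),
                    start=int(d["start"]),
                    end=int(d["end"]),
                    strand=str(d["strand"]),
                    transcript_accession=str(d["transcript_accession"]),
                    transcript_length=None if pd.isna(tl) or tl is None else int(tl),
                    protein_accession=(
                        None if pd.isna(d.get("protein_accession")) else str(d["protein_accession"])
                    ),
                    species=species,
                    clade=clade,
                )
            )
        except ValueError as exc:
            raise GeneTableFormatError(f"{path}: row {i}: {exc}") from exc
    return SpeciesTable(species=species, clade=clade, records=records)


def write_gene_table(table: SpeciesTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def filter_protein_coding(records: list[GeneRecord]) -> list[GeneRecord]:
    """Keep records whose transcript accession has an mRNA prefix (NM_/XM_).

    Non-coding RefSeq classes (NR_, XR_) and accession-less rows are dropped.
    """
    return [
        r
        for r in records
        if r.transcript_accession
        and r.transcript_accession.startswith(CODING_PREFIXES)
    ]


def select_representative(records_one_gene: list[GeneRecord]) -> GeneRecord:
    """Pick the record with the longest transcript for one gene.

    Ties break on the lexicographically smallest transcript accession so the
    choice is reproducible.
    """
    if not records_one_gene:
        raise ValueError("select_representative: empty record list")
    symbols = {r.gene_symbol for r in records_one_gene}
    if len(symbols) > 1:
        raise ValueError(f"select_representative: mixed gene symbols {sorted(symbols)}")
    for r in records_one_gene:
        if r.transcript_length is None:
            raise ValueError(
                f"select_representative: {r.transcript_accession} lacks transcript_length"
            )
    return min(
        records_one_gene,
        key=lambda r: (-r.transcript_length, r.transcript_accession),
    )


def finalize_table(table: SpeciesTable) -> SpeciesTable:
    """Protein-coding filter + longest-transcript representative per symbol."""
    coding = filter_protein_coding(table.records)
    by_symbol: dict[str, list[GeneRecord]] = {}
    for r in coding:
        by_symbol.setdefault(r.gene_symbol, []).append(r)
    reps = [select_representative(v) for v in by_symbol.values()]
    reps.sort(key=lambda r: (r.chromosome, r.start, r.gene_symbol))
    return replace(table, records=reps)


@dataclass
class OrthologMatrix:
    """Gene × species presence matrix on a reference gene order."""

    reference_order: list[str]
    presence: pd.DataFrame  # index = reference symbols, columns = species, bool
    species_clades: dict[str, str]
    unmatched: dict[str, list[str]] = field(default_factory=dict)

    def presence_counts(self, clade_group: frozenset[str]) -> pd.Series:
        cols = [s for s, c in self.species_clades.items() if c in clade_group]
        return self.presence[cols].sum(axis=1)


@dataclass(frozen=True)
class CommonGeneSet:
    """Genes passing the clade-presence rule, in reference order."""

    symbols: tuple[str, ...]
    clade_group: frozenset[str]
    min_count: int

    def __len__(self) -> int:
        return len(self.symbols)


def read_alias_map(path) -> dict[str, str]:
    """Two-column TSV (species_symbol, reference_symbol) → dict, case-folded."""
    df = pd.read_csv(path, sep="\t", header=None, names=["species_symbol", "reference_symbol"], dtype=str)
    return {
        str(a).upper(): str(b).upper()
        for a, b in zip(df["species_symbol"], df["reference_symbol"])
    }


def match_orthologs(
    tables: list[SpeciesTable],
    reference: SpeciesTable,
    alias_map: dict[str, str] | None = None,
) -> OrthologMatrix:
    """Match species gene symbols to the reference catalog.

    Matching is case-insensitive (symbol conventions differ between human
    and e.g. rodents); ``alias_map`` redirects species-specific symbols
    (typically ``LOC`` identifiers) to reference symbols. Species symbols
    with no reference counterpart are dropped and listed per species in the
    returned matrix's ``unmatched`` report.
    """
    alias = {k.upper(): v.upper() for k, v in (alias_map or {}).items()}
    ref_symbols = [r.gene_symbol for r in reference.records]
    ref_upper = {s.upper(): s for s in ref_symbols}
    for tgt in alias.values():
        if tgt not in ref_upper:
            raise ValueError(f"alias map target {tgt!r} not in reference order")
    species_names = [reference.species] + [t.species for t in tables]
    if len(set(species_names)) != len(species_names):
        raise ValueError("duplicate species names across tables")

    presence = pd.DataFrame(
        False, index=ref_symbols, columns=species_names, dtype=bool
    )
    presence[reference.species] = True
    unmatched: dict[str, list[str]] = {}
    clades = {reference.species: reference.clade}
    for t in tables:
        clades[t.species] = t.clade
        seen: dict[str, str] = {}
        dups: list[str] = []
        misses: list[str] = []
        for r in t.records:
            u = r.gene_symbol.upper()
            u = alias.get(u, u)
            if u in ref_upper:
                if u in seen:
                    dups.append(ref_upper[u])
                seen[u] = r.gene_symbol
                presence.loc[ref_upper[u], t.species] = True
            else:
                misses.append(r.gene_symbol)
        if dups:
            raise ValueError(
                f"species {t.species}: duplicate symbols after aliasing: {sorted(set(dups))}"
            )
        if misses:
            unmatched[t.species] = misses
    return OrthologMatrix(
        reference_order=ref_symbols,
        presence=presence,
        species_clades=clades,
        unmatched=unmatched,
    )


def build_common_set(
    matrix: OrthologMatrix,
    clade_group: frozenset[str] = BASAL_CLADES,
    min_count: int = 2,
) -> CommonGeneSet:
    """Apply the clade-presence rule (default: ≥ 2 basal-clade species)."""
    group = frozenset(clade_group)
    unknown = group - set(CLADES)
    if unknown:
        raise ValueError(f"unknown clade label(s) {sorted(unknown)}")
    n_group = sum(1 for c in matrix.species_clades.values() if c in group)
    if min_count > n_group:
        raise ValueError(
            f"min_count {min_count} exceeds the {n_group} species in clade group"
        )
    counts = matrix.presence_counts(group)
    kept = tuple(s for s in matrix.reference_order if counts[s] >= min_count)
    return CommonGeneSet(symbols=kept, clade_group=group, min_count=min_count)
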