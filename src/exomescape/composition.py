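"""Per-gene base and amino-acid composition.

GC content is computed on the transcript as 100·(G+C)/(A+C+G+T), with
ambiguous IUPAC bases excluded from both numerator and denominator so that
assembly gaps (runs of N) do not dilute the estimate.

Amino-acid usage is summarised in three codon-composition groups:

* GARP  — glycine, alanine, arginine, proline: encoded by GC-rich codons;
* FYMINK — phenylalanine, tyrosine, methionine, isoleucine, asparagine,
  lysine: encoded by AU-rich codons;
* MIXED — the remaining ten residues, whose codons are neither GC- nor
  AU-rich (tryptophan's single codon UGG is intermediate and is kept here).

The three groups partition the 20 standard residues, so their usage
percentages sum to 100 for any protein of standard residues.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

GARP = frozenset("GARP")
FYMINK = frozenset("FYMINK")
MIXED = frozenset("LSCHQTVDEW")
STANDARD_AA = GARP | FYMINK | MIXED

_GROUP_OF = {aa: "GARP" for aa in GARP}
_GROUP_OF.update({aa: "FYMINK" for aa in FYMINK})
_GROUP_OF.update({aa: "MIXED" for aa in MIXED})


def gc_fraction(sequence: str) -> float:
    """Percent GC of a nucleotide sequence, ambiguous bases excluded.

    Returns NaN for an empty sequence or one with no unambiguous bases
    (callers report such genes as missing). Case-insensitive; U is treated
    as T.
    """
    counts = Counter(sequence.upper().replace("U", "T"))
    gc = counts["G"] + counts["C"]
    at = counts["A"] + counts["T"]
    if gc + at == 0:
        return float("nan")
    return 100.0 * gc / (gc + at)


def aa_group(residue: str) -> str:
    """Group label for a one-letter residue code ('unclassified' for B/Z/X/U/*)."""
    return _GROUP_OF.get(residue.upper(), "unclassified")


def aa_usage(protein: str) -> dict:
    """Mole fractions and group percentages for one protein.

    A trailing stop symbol is stripped; non-standard residues (B, Z, X, U,
    *) are excluded from the totals, so fractions are over classified
    residues only.
    """
    seq = protein.upper().rstrip("*")
    if not seq:
        raise ValueError("aa_usage: empty protein sequence")
    counts = Counter(c for c in seq if c in STANDARD_AA)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("aa_usage: no classifiable residues")
    fractions = {aa: counts.get(aa, 0) / total for aa in sorted(STANDARD_AA)}
    garp = 100.0 * sum(fractions[a] for a in GARP)
    fymink = 100.0 * sum(fractions[a] for a in FYMINK)
    mixed = 100.0 * sum(fractions[a] for a in MIXED)
    return {
        "aa_fraction": fractions,
        "garp_percent": garp,
        "fymink_percent": fymink,
        "mixed_percent": mixed,
    }


def per_gene_metrics(
    table,
    transcripts: dict[str, str],
    proteins: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene composition profiles for one species.

    Parameters
    ----------
    table : SpeciesTable
        Finalized catalog; its transcript (and protein) accessions are the
        lookup keys into the FASTA maps.
    transcripts, proteins : dict
        Accession → sequence. Genes whose sequence is absent get NaN in the
        corresponding columns.

    Returns one row per gene: gene_symbol, species, gc_percent,
    garp_percent, fymink_percent, mixed_percent, then the 20 per-residue
    mole fractions (columns ``frac_A`` … ``frac_Y``).
    """
    rows = []
    aa_cols = [f"frac_{a}" for a in sorted(STANDARD_AA)]
    for r in table.records:
        row: dict = {"gene_symbol": r.gene_symbol, "species": table.species}
        seq = transcripts.get(r.transcript_accession)
        row["gc_percent"] = gc_fraction(seq) if seq else float("nan")
        prot = None
        if proteins is not None and r.protein_accession:
            prot = proteins.get(r.protein_accession)
        if prot:
            usage = aa_usage(prot)
            row["garp_percent"] = usage["garp_percent"]
            row["fymink_percent"] = usage["fymink_percent"]
            row["mixed_percent"] = usage["mixed_percent"]
            for a, f in usage["aa_fraction"].items():
                row[f"frac_{a}"] = f
        else:
            row["garp_percent"] = row["fymink_percent"] = row["mixed_percent"] = float("nan")
            for c in aa_cols:
                row[c] = float("nan")
        rows.append(row)
    cols = ["gene_symbol", "species", "gc_percent", "garp_percent",
            "fymink_percent", "mixed_percent"] + aa_cols
    df = pd.DataFrame(rows, columns=cols)
    df[cols[2:]] = df[cols[2:]].astype(np.float64)
    return df
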