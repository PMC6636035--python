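"""Format round-tripping shared by all stages: FASTA, matrices, Newick.

All writers use stable orderings so rerunning a pipeline with the same
inputs produces byte-identical artifacts.
"""

from __future__ import annotations

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """FASTA (wrapped or unwrapped) → id → sequence; duplicate ids raise."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_matrix(path) -> pd.DataFrame:
    """CSV matrix with a header row and an index column."""
    return pd.read_csv(path, index_col=0)


def write_matrix(m: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    m.to_csv(path, float_format=float_format)


def read_newick(path_or_string) -> dendropy.Tree:
    """Parse Newick from a path or a literal string."""
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        return dendropy.Tree.get(data=s, schema="newick")
    with open(s) as fh:
        return dendropy.Tree.get(data=fh.read(), schema="newick")


def write_newick(tree, path) -> None:
    if isinstance(tree, str):
        text = tree if tree.rstrip().endswith(";") else tree + ";"
    else:
        text = tree.as_string(schema="newick").strip()
    with open(path, "w") as fh:
        fh.write(text + "\n")
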