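"""Plain-text readers and writers for every pipeline artifact.

Counts and design travel as TSV, promoters as FASTA, peaks as 6+1-column BED
(name field carries ``TF|gene``), TSS coordinates as TSV, ground truth as
JSON, dendrograms as Newick.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .containers import FACTORS, CountMatrix, SampleDesign, SyntheticTruth


def write_design(design: SampleDesign, path) -> None:
    design.table.reset_index().to_csv(path, sep="\t", index=False)


def read_design(path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", dtype={f: str for f in FACTORS})
    table = table.set_index("sample_id")
    levels = {f: tuple(dict.fromkeys(table[f])) for f in FACTORS}
    return SampleDesign(table, levels)


def write_counts(counts: CountMatrix, path) -> None:
    counts.counts.rename_axis("gene").to_csv(path, sep="\t")


def read_counts(path, design: SampleDesign) -> CountMatrix:
    table = pd.read_csv(path, sep="\t", index_col="gene")
    return CountMatrix(table[design.sample_ids], design)


def write_matrix(matrix: pd.DataFrame, path, index_name: str = "gene") -> None:
    matrix.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix(path, index_name: str = "gene") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_name)


def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq).upper() for rec in parse(str(path), "fasta")}


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """6-column BED, 0-based half-open; name = ``TF|gene``."""
    bed = pd.DataFrame({
        "chrom": peaks["chrom"],
        "start": peaks["start"].astype(int),
        "end": peaks["end"].astype(int),
        "name": peaks["tf"].astype(str) + "|" + peaks["gene"].astype(str),
        "score": peaks.get("score", 0),
        "strand": peaks.get("strand", "+"),
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    tf_gene = bed["name"].str.split("|", n=1, expand=True)
    bed["tf"], bed["gene"] = tf_gene[0], tf_gene[1]
    return bed.drop(columns=["name"])


def write_tss(tss: pd.DataFrame, path) -> None:
    tss.reset_index().to_csv(path, sep="\t", index=False)


def read_tss(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_term_map(terms: Mapping[str, set], path) -> None:
    rows = [(term, gene) for term, genes in terms.items() for gene in sorted(genes)]
    pd.DataFrame(rows, columns=["term", "gene"]).to_csv(path, sep="\t", index=False)


def read_term_map(path) -> dict[str, set]:
    table = pd.read_csv(path, sep="\t")
    return {t: set(sub["gene"]) for t, sub in table.groupby("term")}


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))
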