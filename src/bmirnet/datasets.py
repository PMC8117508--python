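"""Bundled reference tables for the *Astatotilapia latifasciata* B-chromosome
miRNA study system.

Two small curated tables ship with the package: the genomic coordinates of
the B-DE-miRNA-bearing precursor clusters (five contigs, eleven precursors,
with per-mature tissue/sex expression calls and fold changes), and the
coding-integrity percentages of the 42 B-chromosome gene copies present in
the B-miR-net. Both are printed study values usable as worked-example inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .catalog import PreMiRNA
from .network import GeneIntegrityRecord


def _data_path(name: str):
    return resources.files("bmirnet.data") / name


def load_bde_cluster_table() -> pd.DataFrame:
    """Per-mature records of the clustered B-DE-miRNAs.

    Columns: contig, precursor_id, strand, start, end (1-based inclusive
    genomic coordinates), seed_similarity, mature_id, tissue, sex, direction,
    fold_change.
    """
    with resources.as_file(_data_path("bde_mirna_clusters.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def bde_cluster_precursors() -> list[PreMiRNA]:
    """Unique precursors of the cluster table as PreMiRNA objects.

    Coordinates are converted to the internal 0-based half-open convention.
    """
    df = load_bde_cluster_table()
    seen = {}
    for row in df.itertuples(index=False):
        if row.precursor_id not in seen:
            seen[row.precursor_id] = PreMiRNA(
                id=row.precursor_id,
                contig=row.contig,
                start=int(row.start) - 1,
                end=int(row.end),
                strand=row.strand,
            )
    return list(seen.values())


def load_bgene_integrity_table() -> pd.DataFrame:
    """Coding-integrity percentages of the 42 B-genes in the B-miR-net.

    Columns: gene_name, protein_symbol, category ("B-related" for direct
    B-DE-miRNA targets, "other" for interactors), integrity (percent).
    """
    with resources.as_file(_data_path("bgene_integrity.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def bgene_integrity_records() -> list[GeneIntegrityRecord]:
    df = load_bgene_integrity_table()
    return [
        GeneIntegrityRecord(r.gene_name, r.protein_symbol, float(r.integrity))
        for r in df.itertuples(index=False)
    ]
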