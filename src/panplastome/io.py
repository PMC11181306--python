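"""Readers and writers for the plain-text formats the toolkit exchanges."""

from __future__ import annotations

import json

import pandas as pd

from .annotation import GeneModel
from .errors import InputError
from .popgen import DistanceMatrix, HaplotypeSet
from .structure import PlastomeSequence
from .variants import VariantEvent


def read_fasta_sequences(path: str, circular: bool = True) -> list[PlastomeSequence]:
    from Bio import SeqIO

    records = [
        PlastomeSequence(rec.id, str(rec.seq), circular)
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(model: GeneModel, path: str, seqid: str = "genome") -> None:
    """GFF3 with gene parents and typed segment children (1-based inclusive)."""
    lines = ["##gff-version 3",
             f"##sequence-region {seqid} 1 {model.genome_length}"]
    type_by_category = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    for i, feat in enumerate(model.features):
        gid = f"gene{i + 1:03d}"
        span = feat.span
        attrs = f"ID={gid};gene={feat.name}"
        lines.append(
            "\t".join([seqid, "panplastome", "gene", str(span[0] + 1),
                       str(span[1]), ".", feat.strand, ".", attrs])
        )
        seg_type = type_by_category[feat.category]
        for j, (s, e) in enumerate(feat.exons):
            attrs = f"ID={gid}.{seg_type};Parent={gid};gene={feat.name}"
            if feat.trans_spliced:
                attrs += ";exception=trans-splicing"
            lines.append(
                "\t".join([seqid, "panplastome", seg_type, str(s + 1), str(e),
                           ".", feat.strand, ".", attrs])
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_clusters_tsv(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" in cols and "cluster" in cols:
        df.columns = cols
    elif df.shape[1] >= 2:
        df = df.iloc[:, :2]
        df.columns = ["sample_id", "cluster"]
    else:
        raise InputError(f"cluster table {path} needs sample_id and cluster columns")
    return dict(zip(df["sample_id"], df["cluster"]))


def write_clusters_tsv(labels: dict[str, str], path: str) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "cluster": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def write_events_tsv(events: list[VariantEvent], path: str) -> None:
    rows = [
        {
            "ref_start": ev.ref_start,
            "ref_end": ev.ref_end,
            "aln_start": ev.columns[0],
            "aln_end": ev.columns[1],
            "category": ev.category,
            "region": ev.region,
            "context": ev.context,
            "gene": ev.gene,
            "spans_boundary": ev.spans_boundary,
            "alleles": ",".join(ev.alleles),
        }
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_distance_tsv(dm: DistanceMatrix, path: str) -> None:
    pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels).to_csv(path, sep="\t")


def write_haplotypes_tsv(hs: HaplotypeSet, path: str) -> None:
    rows = [
        {"haplotype_id": h.haplotype_id, "sample_id": m}
        for h in hs.haplotypes
        for m in h.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
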