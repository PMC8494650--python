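"""Transcript annotation from GTF exon records.

Builds the per-transcript table the rest of the pipeline keys on: gene id,
transcript length (sum of exon lengths, 1-based inclusive coordinates),
strand, TSS and 3'-end coordinates, and TSS / end-site groups assigned by
exact coordinate match within each gene.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .containers import validate_annotation

_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(attr: str) -> dict[str, str]:
    return dict(_ATTR.findall(attr))


def read_gtf_exons(gtf_path) -> pd.DataFrame:
    """Read exon records from a 9-column GTF into a flat table.

    Raises if a ``transcript`` record's id never appears in any exon record.
    """
    rows = []
    declared: set[str] = set()
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line: {line[:80]!r}")
            if fields[2] == "transcript":
                declared.add(_parse_attributes(fields[8]).get("transcript_id", ""))
                continue
            if fields[2] != "exon":
                continue
            attrs = _parse_attributes(fields[8])
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise ValueError(f"exon record without transcript_id/gene_id: {line[:80]!r}")
            rows.append((
                attrs["transcript_id"],
                attrs["gene_id"],
                fields[0],
                int(fields[3]),
                int(fields[4]),
                fields[6],
            ))
    if not rows:
        raise ValueError(f"no exon records in {gtf_path}")
    df = pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "seqname", "start", "end", "strand"]
    )
    exonless = declared - {""} - set(df["transcript_id"])
    if exonless:
        raise ValueError(f"transcripts with no exons: {sorted(exonless)[:10]}")
    return df


def annotation_from_gtf(gtf_path, t2g_path=None) -> pd.DataFrame:
    """Build a transcript annotation table from a GTF file.

    Length = sum of exon (end - start + 1).  The TSS is the leftmost exon
    start on the + strand and the rightmost exon end on the - strand; the 3'
    end site is the mirror image.  Transcripts of the same gene sharing a
    TSS coordinate share a TSS group; same for end sites.  ``unique3p``
    marks transcripts whose end-site group is a singleton within the gene.

    ``t2g_path`` optionally overrides the GTF's transcript-to-gene mapping
    with a two-column TSV (transcript_id, gene_id).
    """
    exons = read_gtf_exons(gtf_path)
    if t2g_path is not None:
        t2g = pd.read_csv(
            t2g_path, sep="\t", header=None, usecols=[0, 1],
            names=["transcript_id", "gene_id"],
        )
        mapping = t2g.set_index("transcript_id")["gene_id"]
        exons["gene_id"] = exons["transcript_id"].map(mapping).fillna(exons["gene_id"])

    records = []
    for tid, sub in exons.groupby("transcript_id", sort=False):
        strands = sub["strand"].unique()
        if len(strands) > 1:
            raise ValueError(f"transcript {tid!r} has exons on mixed strands")
        strand = strands[0]
        if strand not in "+-":
            raise ValueError(f"transcript {tid!r} has invalid strand {strand!r}")
        length = int((sub["end"] - sub["start"] + 1).sum())
        if strand == "+":
            tss, end = int(sub["start"].min()), int(sub["end"].max())
        else:
            tss, end = int(sub["end"].max()), int(sub["start"].min())
        records.append({
            "transcript_id": tid,
            "gene_id": sub["gene_id"].iloc[0],
            "length": length,
            "strand": strand,
            "tss_coord": tss,
            "end_coord": end,
        })
    ann = pd.DataFrame(records)

    # group by exact coordinate within gene
    tss_key = ann["gene_id"] + "@" + ann["tss_coord"].astype(str) + ann["strand"]
    end_key = ann["gene_id"] + "@" + ann["end_coord"].astype(str) + ann["strand"]
    ann["tss_group"] = _group_ids(ann["gene_id"], tss_key, "ts")
    ann["end_group"] = _group_ids(ann["gene_id"], end_key, "es")
    end_sizes = ann.groupby("end_group")["transcript_id"].transform("count")
    ann["unique3p"] = (end_sizes == 1).to_numpy()
    ann = ann.drop(columns=["end_coord"])
    return validate_annotation(ann)


def _group_ids(genes: pd.Series, keys: pd.Series, tag: str) -> pd.Series:
    """Stable within-gene group labels like ``<gene>:ts1`` from grouping keys."""
    labels = pd.Series(index=keys.index, dtype=object)
    for gene, sub in keys.groupby(genes, sort=False):
        seen: dict[str, int] = {}
        for idx, key in sub.items():
            if key not in seen:
                seen[key] = len(seen) + 1
            labels.loc[idx] = f"{gene}:{tag}{seen[key]}"
    return labels
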