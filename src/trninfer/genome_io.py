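"""Genome and annotation I/O: gene tables, upstream intergenic regions,
ortholog groups and footprinting input assembly.

Coordinates are 1-based inclusive throughout, matching GFF3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its genomic location and rank along its replicon."""

    gene_id: str
    genome_id: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    gene_index: int = -1  # 0-based rank by start coordinate within replicon

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: coordinates must be positive")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")


@dataclass
class OrthologGroup:
    """An orthologous-gene group: mapping genome_id -> member gene ids."""

    group_id: str
    members: dict[str, list[str]] = field(default_factory=dict)

    def n_genomes(self) -> int:
        return sum(1 for v in self.members.values() if v)


@dataclass(frozen=True)
class IntergenicRegion:
    """The strand-aware upstream intergenic region (IGR) of a gene.

    ``sequence`` is reported on the gene's coding-strand orientation, i.e.
    for a minus-strand gene the replicon-coordinate downstream gap is
    reverse-complemented.
    """

    gene_id: str
    genome_id: str
    replicon_id: str
    sequence: str
    upstream_of_strand: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def load_annotations(annotation_source: str | Path | pd.DataFrame, genome_id: str) -> list[GeneRecord]:
    """Load gene annotations from a 5-column TSV gene table or a GFF3 file.

    TSV columns: gene_id, replicon, start, end, strand (header optional,
    detected from the first row).  GFF3 rows of type ``gene`` are used, with
    the ``ID`` attribute as gene id.

    Returns records sorted by (replicon, start) with ``gene_index`` assigned
    per replicon.
    """
    if isinstance(annotation_source, pd.DataFrame):
        df = annotation_source.copy()
        df.columns = ["gene_id", "replicon", "start", "end", "strand"]
    else:
        path = Path(annotation_source)
        if path.suffix.lower() in {".gff", ".gff3"}:
            df = _read_gff3(path)
        else:
            df = _read_gene_tsv(path)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if df.empty:
        return []
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene ids in {genome_id}: {sorted(df.loc[dup, 'gene_id'])}")
    bad = ~df["strand"].isin(_VALID_STRANDS)
    if bad.any():
        raise ValueError(f"unknown strand symbol(s): {sorted(df.loc[bad, 'strand'].unique())}")
    df = df.sort_values(["replicon", "start"], kind="mergesort").reset_index(drop=True)
    records: list[GeneRecord] = []
    for replicon, sub in df.groupby("replicon", sort=False):
        for idx, row in enumerate(sub.itertuples(index=False)):
            records.append(
                GeneRecord(
                    gene_id=str(row.gene_id),
                    genome_id=genome_id,
                    replicon_id=str(replicon),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                    gene_index=idx,
                )
            )
    return records


def _read_gene_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty and df.columns.size == 0:
        return pd.DataFrame(columns=["gene_id", "replicon", "start", "end", "strand"])
    first = [c.lower() for c in df.columns]
    if "gene_id" not in first:
        # headerless table: re-read without header
        df = pd.read_csv(
            path, sep="\t", dtype=str, header=None, comment="#",
            names=["gene_id", "replicon", "start", "end", "strand"],
        )
    else:
        df.columns = first
    return df[["gene_id", "replicon", "start", "end", "strand"]]


def _read_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand))
    return pd.DataFrame(rows, columns=["gene_id", "replicon", "start", "end", "strand"])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a mapping id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_upstream_igrs(
    genes: list[GeneRecord],
    replicon_seqs: dict[str, str],
    min_len: int = 40,
) -> list[IntergenicRegion]:
    """Extract the upstream IGR of every gene whose upstream gap to the
    nearest annotated gene body is strictly greater than ``min_len`` bp.

    The upstream gap of a plus-strand gene runs from the largest annotated
    end coordinate below its start (or the replicon edge) to ``start - 1``;
    for a minus-strand gene the gap is taken downstream in replicon
    coordinates and the sequence reverse-complemented.  An IGR shared by a
    divergently transcribed gene pair is assigned to both genes.  Genes
    flush against the replicon edge yield no IGR.
    """
    igrs: list[IntergenicRegion] = []
    by_replicon: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_replicon.setdefault(g.replicon_id, []).append(g)
    for replicon_id, recs in by_replicon.items():
        seq = replicon_seqs.get(replicon_id)
        if seq is None:
            raise KeyError(f"no sequence for replicon {replicon_id}")
        L = len(seq)
        for g in recs:
            if g.end > L:
                raise ValueError(f"gene {g.gene_id} extends past replicon {replicon_id}")
        starts = [r.start for r in recs]
        ends = [r.end for r in recs]
        for g in recs:
            if g.strand == "+":
                prev_end = max((e for r, e in zip(recs, ends) if r is not g and e < g.start), default=0)
                lo, hi = prev_end + 1, g.start - 1
            else:
                next_start = min(
                    (s for r, s in zip(recs, starts) if r is not g and s > g.end), default=L + 1
                )
                lo, hi = g.end + 1, next_start - 1
            if hi < lo:
                continue
            # reject windows overlapped by a gene body (nested/overlapping genes)
            if any(r.start <= hi and r.end >= lo for r in recs if r is not g):
                continue
            frag = seq[lo - 1 : hi]
            if len(frag) <= min_len:
                continue
            if g.strand == "-":
                frag = revcomp(frag)
            igrs.append(
                IntergenicRegion(
                    gene_id=g.gene_id,
                    genome_id=g.genome_id,
                    replicon_id=replicon_id,
                    sequence=frag,
                    upstream_of_strand=g.strand,
                )
            )
    return igrs


def load_ortholog_groups(path: str | Path) -> list[OrthologGroup]:
    """Read a TSV ortholog-group table with columns group_id, genome_id, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    groups: dict[str, OrthologGroup] = {}
    for row in df.itertuples(index=False):
        grp = groups.setdefault(str(row.group_id), OrthologGroup(str(row.group_id)))
        grp.members.setdefault(str(row.genome_id), []).append(str(row.gene_id))
    return list(groups.values())


def write_ortholog_groups(groups: list[OrthologGroup], path: str | Path) -> None:
    rows = [
        (g.group_id, genome, gene)
        for g in groups
        for genome, genes in sorted(g.members.items())
        for gene in genes
    ]
    pd.DataFrame(rows, columns=["group_id", "genome_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def assemble_footprinting_groups(
    groups: list[OrthologGroup],
    igrs: list[IntergenicRegion],
    target_genome: str,
    min_seqs: int = 4,
) -> list[tuple[str, list[IntergenicRegion]]]:
    """Collect, per ortholog group, the IGRs of all member genes across
    genomes; retain only groups with at least ``min_seqs`` IGRs and at least
    one member from the target genome.  Sequences are deduplicated by
    (genome, gene).
    """
    index: dict[tuple[str, str], IntergenicRegion] = {}
    for igr in igrs:
        index.setdefault((igr.genome_id, igr.gene_id), igr)
    out: list[tuple[str, list[IntergenicRegion]]] = []
    for grp in groups:
        if not grp.members.get(target_genome):
            continue
        seen: set[tuple[str, str]] = set()
        seqs: list[IntergenicRegion] = []
        for genome, gene_ids in sorted(grp.members.items()):
            for gid in gene_ids:
                key = (genome, gid)
                if key in seen:
                    continue
                seen.add(key)
                igr = index.get(key)
                if igr is not None:
                    seqs.append(igr)
        if len(seqs) >= min_seqs:
            out.append((grp.group_id, seqs))
    return out


def tf_presence_matrix(
    tf_ids: list[str],
    groups: list[OrthologGroup],
    genome_ids: list[str],
    target_genome: str,
) -> pd.DataFrame:
    """Binary TF x genome occurrence matrix from ortholog groups.

    Entry is 1 iff the TF's ortholog group has a member in that genome; a TF
    with no group is present only in the target genome.
    """
    gene_to_group: dict[str, OrthologGroup] = {}
    for grp in groups:
        for genes in grp.members.values():
            for gid in genes:
                if gid in tf_ids and gid in gene_to_group and gene_to_group[gid] is not grp:
                    raise ValueError(f"TF {gid} belongs to more than one ortholog group")
                gene_to_group.setdefault(gid, grp)
    mat = pd.DataFrame(0, index=list(tf_ids), columns=list(genome_ids), dtype=int)
    for tf in tf_ids:
        grp = gene_to_group.get(tf)
        if grp is None:
            warnings.warn(f"TF {tf} has no ortholog group; presence restricted to target genome")
        else:
            for genome in genome_ids:
                if grp.members.get(genome):
                    mat.loc[tf, genome] = 1
        mat.loc[tf, target_genome] = 1
    return mat
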