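"""Readers and writers for the standard formats the pipeline consumes.

All coordinates are converted to 0-based half-open internally (BED and
bedGraph are already half-open; GFF3 is 1-based inclusive).  Text inputs may
be gzip-compressed; writers emit UTF-8 with LF endings and deterministic,
sorted records.
"""

from __future__ import annotations

import gzip
from typing import IO, Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .annotate import RegionModel, Transcript
from .conserve import HIT_COLUMNS
from .errors import ParseError
from .genostats import GENOTYPE_COLUMNS
from .motifs import MotifClass
from .scan import SSRLocus


def _open_text(path, mode: str = "rt") -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8" if "t" in mode else None)
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as handle:
        out: dict[str, str] = {}
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in out:
                raise ParseError(f"{path}: duplicate sequence name {record.id!r}")
            out[record.id] = str(record.seq).upper()
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED (catalogue: BED6 + period column)


def write_catalogue_bed(loci: Iterable[SSRLocus], path) -> None:
    with _open_text(path, "wt") as fh:
        for l in sorted(loci, key=SSRLocus.sort_key):
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.motif.canonical}\t"
                     f"{l.repeat_count}\t+\t{l.motif.period}\n")


def read_catalogue_bed(path) -> list[SSRLocus]:
    loci = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end, motif, score = parts[0], int(parts[1]), int(parts[2]), \
                    parts[3], int(parts[4])
                period = int(parts[6]) if len(parts) > 6 else len(parts[3])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad catalogue BED record") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            loci.append(SSRLocus(chrom, start, end, MotifClass(motif, period), score))
    return loci


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                out.append((parts[0], int(parts[1]), int(parts[2])))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad BED record") from exc
    return out


def write_bed_intervals(intervals: Sequence[tuple[str, int, int]], path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, start, end in sorted(intervals):
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(transcripts: Sequence[Transcript], path) -> None:
    """Serialise gene models (gene/mRNA/exon/CDS rows, 1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[Transcript]] = {}
        for tx in transcripts:
            by_gene.setdefault(tx.gene_id, []).append(tx)
        for gene_id in sorted(by_gene):
            txs = by_gene[gene_id]
            chrom = txs[0].chrom
            strand = txs[0].strand
            lo = min(tx.exons[0][0] for tx in txs)
            hi = max(tx.exons[-1][1] for tx in txs)
            fh.write(f"{chrom}\tsim\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\t"
                     f"ID={gene_id}\n")
            for tx in sorted(txs, key=lambda t: t.tid):
                s, e = tx.exons[0][0], tx.exons[-1][1]
                fh.write(f"{chrom}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                         f"ID={tx.tid};Parent={gene_id}\n")
                for i, (xs, xe) in enumerate(tx.exons, 1):
                    fh.write(f"{chrom}\tsim\texon\t{xs + 1}\t{xe}\t.\t{strand}\t.\t"
                             f"ID={tx.tid}.exon{i};Parent={tx.tid}\n")
                for i, (cs, ce) in enumerate(tx.cds, 1):
                    fh.write(f"{chrom}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{strand}\t0\t"
                             f"ID={tx.tid}.cds{i};Parent={tx.tid}\n")


def read_gff3(path, chrom_lengths: Optional[Mapping[str, int]] = None) -> RegionModel:
    """Build a region model from GFF3 (via gffutils; GTF also accepted)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    transcripts = []
    for feature_type in ("mRNA", "transcript"):
        for tx in db.features_of_type(feature_type):
            exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
            parents = [p.id for p in db.parents(tx, featuretype="gene")]
            if not exons:
                raise ParseError(f"{path}: transcript {tx.id} has no exons")
            transcripts.append(Transcript(
                tid=tx.id, gene_id=parents[0] if parents else tx.id,
                chrom=tx.seqid, strand=tx.strand, exons=exons, cds=cds))
    return RegionModel(transcripts, chrom_lengths)


# ---------------------------------------------------------------------------
# VCF (indel extraction)


def read_vcf_indels(path) -> list[tuple[str, int, int]]:
    """Intervals of indel records (REF/ALT length mismatch), half-open on the
    reference footprint of REF."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: truncated VCF record")
            chrom, pos, _id, ref, alts = parts[0], parts[1], parts[2], parts[3], parts[4]
            try:
                start = int(pos) - 1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad POS {pos!r}") from exc
            if any(len(alt) != len(ref) for alt in alts.split(",") if alt != "."):
                out.append((chrom, start, start + len(ref)))
    return out


# ---------------------------------------------------------------------------
# genotype TSV


def read_genotypes(path, offsets: bool = False,
                   loci: Optional[Sequence[SSRLocus]] = None) -> pd.DataFrame:
    """Genotype table with columns sample, locus, allele_a, allele_b, q, reads.

    With ``offsets=True`` the allele columns hold length offsets from the
    reference tract (the convention of read-based STR genotypers) and are
    normalised to absolute bp lengths using the catalogue, which must then
    be supplied.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = set(GENOTYPE_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing genotype columns {sorted(missing)}")
    frame = frame[GENOTYPE_COLUMNS].copy()
    if offsets:
        if loci is None:
            raise ValueError("offsets mode requires the SSR catalogue")
        ref = {l.locus_id: l.ref_len for l in loci}
        unknown = set(frame["locus"]) - set(ref)
        if unknown:
            raise ParseError(f"{path}: loci absent from catalogue: {sorted(unknown)[:5]}")
        base = frame["locus"].map(ref)
        frame["allele_a"] = base + frame["allele_a"]
        frame["allele_b"] = base + frame["allele_b"]
    if (frame["q"] >= 1).any() or (frame["q"] < 0).any():
        raise ParseError(f"{path}: Q scores must lie in [0, 1)")
    if (frame["reads"] < 1).any():
        raise ParseError(f"{path}: read counts must be >= 1")
    a = frame[["allele_a", "allele_b"]].min(axis=1)
    b = frame[["allele_a", "allele_b"]].max(axis=1)
    frame["allele_a"], frame["allele_b"] = a, b
    return frame


def write_genotypes(calls: pd.DataFrame, path) -> None:
    calls = calls.sort_values(["locus", "sample"], kind="stable")
    calls.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# bedGraph / hits / misc tables


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad bedGraph record") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(frame: pd.DataFrame, path) -> None:
    frame = frame.sort_values(["chrom", "start"], kind="stable")
    with _open_text(path, "wt") as fh:
        for row in frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


def read_flank_hits(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing hit columns {sorted(missing)}")
    return frame[HIT_COLUMNS]


def write_flank_hits(hits: pd.DataFrame, path) -> None:
    hits.sort_values(["locus", "species", "side"], kind="stable").to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_breed_map(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = {"sample", "breed"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing breed-map columns {sorted(missing)}")
    return frame


# ---------------------------------------------------------------------------
# distance matrix and Newick


def write_phylip_matrix(matrix: pd.DataFrame, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with _open_text(path, "wt") as fh:
        fh.write(f"{len(matrix)}\n")
        for name in matrix.index:
            values = " ".join(f"{v:.6f}" for v in matrix.loc[name])
            fh.write(f"{name}  {values}\n")


def read_phylip_matrix(path) -> pd.DataFrame:
    with _open_text(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise ParseError(f"{path}:1: expected taxon count") from exc
    names, rows = [], []
    for lineno, line in enumerate(lines[1:n + 1], 2):
        parts = line.split()
        if len(parts) != n + 1:
            raise ParseError(f"{path}:{lineno}: expected {n + 1} fields")
        names.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return pd.DataFrame(rows, index=names, columns=names)


def write_newick(newick: str, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(newick.rstrip("\n") + "\n")


def read_newick(path):
    """Parse a Newick tree (returns a dendropy Tree)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")
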