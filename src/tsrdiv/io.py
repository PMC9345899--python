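"""Readers and writers for the plain-text interchange formats.

- CTSS: tab-separated ``chrom pos0 strand count`` (0-based positions,
  ``#`` comments); counts are integers for raw tracks and floats (6
  significant digits) for normalized tracks.
- Minimal GTF: gene/exon/CDS features with gene_id/transcript_id attributes,
  1-based inclusive coordinates per the GTF convention.
- BED: 0-based half-open; BED6 for TSRs (score = min(1000, round(total))),
  BED3 for features.
- Matrices, design, gene sets: TSV / one id per line.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ValidationError
from .specificity import SampleGroupDesign
from .tsr import (
    Cluster,
    ConsensusTsr,
    ConsensusTsrSet,
    GeneModel,
    GenomicAnnotation,
    TsrSet,
)
from .tss import TssTrack, build_track


# ---------------------------------------------------------------------------
# CTSS
# ---------------------------------------------------------------------------

def write_ctss(track: TssTrack, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample={track.sample_id} kind={track.kind}\n")
        fh.write("# chrom\tpos0\tstrand\tcount\n")
        for (chrom, strand, pos), value in sorted(track.entries.items()):
            if track.kind == "raw":
                fh.write(f"{chrom}\t{pos}\t{strand}\t{int(value)}\n")
            else:
                fh.write(f"{chrom}\t{pos}\t{strand}\t{value:.6g}\n")


def read_ctss(
    path: str | Path, sample_id: str | None = None, one_based: bool = False
) -> TssTrack:
    path = Path(path)
    kind = "raw"
    meta_sample = path.stem
    records = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("# ").split():
                    if token.startswith("sample="):
                        meta_sample = token.split("=", 1)[1]
                    elif token.startswith("kind="):
                        kind = token.split("=", 1)[1]
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValidationError(f"{path}: expected 4 columns, got {len(fields)}")
            chrom, pos_s, strand, value_s = fields
            pos = int(pos_s) - (1 if one_based else 0)
            records.append((chrom, pos, strand, value_s))
    sid = sample_id or meta_sample
    if kind == "raw":
        return build_track(
            [(c, p, s, int(v)) for c, p, s, v in records], sample_id=sid
        )
    entries: dict[tuple[str, str, int], float] = {}
    for chrom, pos, strand, value_s in records:
        value = float(value_s)
        if value <= 0:
            raise ValidationError(f"{path}: non-positive value {value}")
        entries[(chrom, strand, pos)] = entries.get((chrom, strand, pos), 0.0) + value
    return TssTrack(sample_id=sid, entries=entries, kind="normalized")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def write_gtf(annotation: GenomicAnnotation, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start)):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; biotype "{g.biotype}";'
            def row(feature: str, start0: int, end0: int) -> str:
                # GTF is 1-based inclusive
                return "\t".join(
                    [g.chrom, "tsrdiv", feature, str(start0 + 1), str(end0 + 1),
                     ".", g.strand, ".", attrs]
                ) + "\n"
            fh.write(row("gene", g.start, g.end))
            for s, e in g.exons:
                fh.write(row("exon", s, e))
            for s, e in g.cds:
                fh.write(row("CDS", s, e))


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> GenomicAnnotation:
    path = Path(path)
    genes: dict[str, dict] = {}
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValidationError(f"{path}: GTF line with {len(fields)} fields")
            chrom, _, feature, start1, end1, _, strand, _, attr_s = fields
            attrs = _parse_gtf_attrs(attr_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValidationError(f"{path}: feature without gene_id")
            rec = genes.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "start": None, "end": None,
                 "exons": [], "cds": [], "biotype": attrs.get("biotype", "coding")},
            )
            s0, e0 = int(start1) - 1, int(end1) - 1
            if feature == "gene":
                rec["start"], rec["end"] = s0, e0
            elif feature == "exon":
                rec["exons"].append((s0, e0))
            elif feature == "CDS":
                rec["cds"].append((s0, e0))
    models = []
    for gene_id, rec in genes.items():
        if rec["start"] is None:
            coords = rec["exons"] or rec["cds"]
            rec["start"] = min(s for s, _ in coords)
            rec["end"] = max(e for _, e in coords)
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=rec["start"],
                end=rec["end"],
                exons=tuple(sorted(rec["exons"])),
                cds=tuple(sorted(rec["cds"])),
                biotype=rec["biotype"],
            )
        )
    models.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return GenomicAnnotation(genes=models)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_tsr_bed(tsr_set: TsrSet, path: str | Path) -> None:
    """Sample TSRs as BED6 (half-open intervals)."""
    with Path(path).open("w") as fh:
        for idx, c in enumerate(
            sorted(tsr_set.clusters, key=lambda c: (c.chrom, c.start, c.strand)), 1
        ):
            name = f"{tsr_set.sample_id}_tsr_{idx:05d}"
            score = min(1000, round(c.total))
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end + 1}\t{name}\t{score}\t{c.strand}\n"
            )


def write_consensus_bed(consensus: ConsensusTsrSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in sorted(consensus.tsrs, key=lambda t: (t.chrom, t.start, t.strand)):
            total = sum(t.expression.values())
            score = min(1000, round(total))
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.id}\t{score}\t{t.strand}\n")


def read_consensus_bed(path: str | Path) -> ConsensusTsrSet:
    tsrs = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name, _, strand = line.split("\t")[:6]
            tsrs.append(
                ConsensusTsr(id=name, chrom=chrom, strand=strand.strip(),
                             start=int(start), end=int(end))
            )
    return ConsensusTsrSet(tsrs=tsrs)


def read_bed3(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED3 feature intervals grouped by chromosome (half-open, sorted)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    for chrom in out:
        out[chrom].sort()
    return out


def write_bed3(features: dict[str, list[tuple[int, int]]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom in sorted(features):
            for s, e in sorted(features[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# gene sets, design, matrices
# ---------------------------------------------------------------------------

def read_gene_set(path: str | Path) -> set[str]:
    with Path(path).open() as fh:
        return {
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        }


def write_gene_set(ids: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gid in sorted(ids):
            fh.write(gid + "\n")


def read_design(path: str | Path) -> SampleGroupDesign:
    """TSV with columns sample_id, group, individual_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "group", "individual_id"}
    if not required.issubset(df.columns):
        raise ValidationError(f"design file needs columns {sorted(required)}")
    return SampleGroupDesign(
        assignments={
            r.sample_id: (r.group, r.individual_id) for r in df.itertuples()
        }
    )


def write_design(design: SampleGroupDesign, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "group", "individual_id"])
        for sid, (group, ind) in sorted(design.assignments.items()):
            writer.writerow([sid, group, ind])


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "feature_id")


def read_transcript_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("transcript map needs 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_transcript_map(tx_to_gene: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("transcript_id\tgene_id\n")
        for tid, gid in sorted(tx_to_gene.items()):
            fh.write(f"{tid}\t{gid}\n")
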