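"""Density-based TSS clustering into TSRs, consensus merging, and annotation.

The clustering builds the full density hierarchy of a per-position signal:
each cluster is a run of sites that is a maximal-scoring segment of the
per-bp score ``value - d`` (gap bp score ``-d``) for every density ``d`` in
``[min_density, max_density)``.  The hierarchy is computed top-down by
repeatedly splitting a segment at its weakest prefix or suffix (the one with
the lowest signal density), which is the classical paraclu recursion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .tss import TssTrack

CATEGORY_PRIORITY = [
    "promoter",
    "tts",
    "five_utr",
    "three_utr",
    "exon",
    "noncoding",
    "intron",
    "intergenic",
]


@dataclass(frozen=True)
class Cluster:
    """A node of the density hierarchy (inclusive site coordinates)."""

    chrom: str
    strand: str
    start: int
    end: int
    n_sites: int
    total: float
    min_density: float
    max_density: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class TsrSet:
    """Filtered, non-overlapping clusters for one sample."""

    sample_id: str
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class ConsensusTsr:
    """A cross-sample merged TSR; interval is 0-based half-open."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    presence: dict[str, bool] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)
    contributing: list[str] = field(default_factory=list)

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class ConsensusTsrSet:
    tsrs: list[ConsensusTsr] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tsrs)

    def by_id(self) -> dict[str, ConsensusTsr]:
        return {t.id: t for t in self.tsrs}


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # 0-based inclusive
    exons: tuple[tuple[int, int], ...]  # inclusive intervals
    cds: tuple[tuple[int, int], ...]
    biotype: str = "coding"

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class GenomicAnnotation:
    genes: list[GeneModel] = field(default_factory=list)

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


@dataclass(frozen=True)
class TsrAnnotationRecord:
    tsr_id: str
    category: str
    nearest_gene_id: str
    distance_to_tss: int  # signed in gene orientation


TsrAnnotation = dict[str, TsrAnnotationRecord]


# ---------------------------------------------------------------------------
# paraclu-style hierarchy
# ---------------------------------------------------------------------------

def _weakest_break(
    pos: np.ndarray, val: np.ndarray, i: int, j: int
) -> tuple[float, str, int]:
    """Lowest prefix/suffix density of segment [i..j] (i < j).

    Prefix k covers sites i..k with density sum(i..k)/(pos[k+1]-pos[i]);
    suffix k covers sites k..j with density sum(k..j)/(pos[j]-pos[k-1]).
    Ties resolve prefix before suffix, shorter segment first.
    """
    best_d = np.inf
    best_kind = "prefix"
    best_k = i
    run = 0.0
    for k in range(i, j):  # prefixes, shortest first
        run += val[k]
        d = run / (pos[k + 1] - pos[i])
        if d < best_d:
            best_d, best_kind, best_k = d, "prefix", k
    run = 0.0
    for k in range(j, i, -1):  # suffixes, shortest first
        run += val[k]
        d = run / (pos[j] - pos[k - 1])
        if d < best_d:
            best_d, best_kind, best_k = d, "suffix", k
    return float(best_d), best_kind, best_k


def paraclu_hierarchy(
    sites: Sequence[tuple[int, float]], chrom: str = ".", strand: str = "+"
) -> list[Cluster]:
    """Full density hierarchy of one chromosome/strand's sites.

    ``sites`` are strictly increasing ``(pos, value)`` pairs with positive
    values.  Returns every cluster with ``min_density < max_density``,
    ordered by (start, -span).
    """
    if not sites:
        return []
    pos = np.array([p for p, _ in sites], dtype=np.int64)
    val = np.array([v for _, v in sites], dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValidationError("site positions must be strictly increasing")
    if np.any(val <= 0):
        raise ValidationError("site values must be positive")

    clusters: list[Cluster] = []
    stack: list[tuple[int, int, float]] = [(0, len(sites) - 1, 0.0)]
    while stack:
        i, j, d_in = stack.pop()
        if i == j:
            max_d = float(val[i])  # singleton: value over 1 bp
            if d_in < max_d:
                clusters.append(
                    Cluster(chrom, strand, int(pos[i]), int(pos[i]), 1,
                            float(val[i]), d_in, max_d)
                )
            continue
        break_d, kind, k = _weakest_break(pos, val, i, j)
        total = float(val[i : j + 1].sum())
        if d_in < break_d:
            clusters.append(
                Cluster(chrom, strand, int(pos[i]), int(pos[j]), j - i + 1,
                        total, d_in, break_d)
            )
        child_d = max(d_in, break_d)
        if kind == "prefix":
            stack.append((i, k, child_d))
            stack.append((k + 1, j, child_d))
        else:
            stack.append((i, k - 1, child_d))
            stack.append((k, j, child_d))
    clusters.sort(key=lambda c: (c.start, -c.span))
    return clusters


def cluster_track(track: TssTrack) -> dict[tuple[str, str], list[Cluster]]:
    """Run :func:`paraclu_hierarchy` on every chromosome/strand of a track."""
    out = {}
    for chrom, strand in track.chrom_strands():
        out[(chrom, strand)] = paraclu_hierarchy(
            track.sites(chrom, strand), chrom=chrom, strand=strand
        )
    return out


def select_tsrs(
    hierarchy: Iterable[Cluster],
    sample_id: str = "",
    min_signal: float = 2.0,
    max_span: int = 20,
    min_stability: float = 1.0,
) -> TsrSet:
    """Filter the hierarchy to non-overlapping TSRs.

    Candidates must carry ``total >= min_signal`` (normalized units), span at
    most ``max_span`` bp, and a density stability ratio
    ``max_density / min_density >= min_stability``.  Among nested candidates
    only the outermost is kept, so the result is disjoint.
    """
    if min_signal <= 0:
        raise ConfigError("min_signal must be positive")
    if max_span < 1:
        raise ConfigError("max_span must be >= 1")
    candidates = [
        c
        for c in hierarchy
        if c.total >= min_signal
        and c.span <= max_span
        and c.max_density / max(c.min_density, 1e-9) >= min_stability
    ]
    candidates.sort(key=lambda c: (c.chrom, c.strand, c.start, -c.span))
    kept: list[Cluster] = []
    for c in candidates:
        last = kept[-1] if kept else None
        if (
            last is not None
            and last.chrom == c.chrom
            and last.strand == c.strand
            and c.start >= last.start
            and c.end <= last.end
        ):
            continue  # nested inside an already-kept outer candidate
        kept.append(c)
    return TsrSet(sample_id=sample_id, clusters=kept)


def call_sample_tsrs(
    track: TssTrack,
    min_signal: float = 2.0,
    max_span: int = 20,
    min_stability: float = 1.0,
) -> TsrSet:
    """Hierarchy + filtering for a whole (normalized) track."""
    clusters = list(itertools.chain.from_iterable(cluster_track(track).values()))
    return select_tsrs(
        clusters,
        sample_id=track.sample_id,
        min_signal=min_signal,
        max_span=max_span,
        min_stability=min_stability,
    )


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def merge_consensus(tsr_sets: Sequence[TsrSet], merge_gap: int = 20) -> ConsensusTsrSet:
    """Merge per-sample TSRs into strand-specific consensus intervals.

    Member clusters become half-open intervals ``[start, end+1)``; on each
    (chrom, strand) any two intervals whose gap is <= ``merge_gap`` bp are
    merged transitively.  Ids are assigned deterministically by genomic
    order.
    """
    if not tsr_sets:
        raise ValidationError("merge_consensus requires at least one TsrSet")
    by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for ts in tsr_sets:
        for idx, c in enumerate(ts.clusters):
            member_id = f"{ts.sample_id}:{c.chrom}:{c.start}:{c.strand}"
            by_key.setdefault((c.chrom, c.strand), []).append(
                (c.start, c.end + 1, member_id)
            )
    merged: list[tuple[str, str, int, int, list[str]]] = []
    for (chrom, strand), ivs in by_key.items():
        ivs.sort()
        cur_start, cur_end, members = ivs[0][0], ivs[0][1], [ivs[0][2]]
        for s, e, mid in ivs[1:]:
            if s - cur_end <= merge_gap:
                cur_end = max(cur_end, e)
                members.append(mid)
            else:
                merged.append((chrom, strand, cur_start, cur_end, members))
                cur_start, cur_end, members = s, e, [mid]
        merged.append((chrom, strand, cur_start, cur_end, members))
    merged.sort(key=lambda m: (m[0], m[2], m[1]))
    sample_ids = [ts.sample_id for ts in tsr_sets]
    tsrs = [
        ConsensusTsr(
            id=f"tsr_{n:05d}",
            chrom=chrom,
            strand=strand,
            start=start,
            end=end,
            contributing=sorted(members),
        )
        for n, (chrom, strand, start, end, members) in enumerate(merged, start=1)
    ]
    return ConsensusTsrSet(tsrs=tsrs, sample_ids=sample_ids)


def score_presence(
    consensus: ConsensusTsrSet,
    tsr_sets: Sequence[TsrSet],
    tracks: Sequence[TssTrack],
) -> ConsensusTsrSet:
    """Fill per-sample presence and expression on consensus TSRs.

    A sample is *present* iff one of its filtered TSRs overlaps the consensus
    interval by >= 1 bp on the same strand; its *expression* is the summed
    normalized signal inside the interval regardless of presence.
    """
    set_ids = [ts.sample_id for ts in tsr_sets]
    track_ids = [t.sample_id for t in tracks]
    if sorted(set_ids) != sorted(track_ids):
        raise ValidationError("samples of tsr_sets and tracks do not match")
    for t in tracks:
        if t.kind != "normalized":
            raise ValidationError(f"track {t.sample_id} is not normalized")
    tracks_by_id = {t.sample_id: t for t in tracks}
    sets_by_id = {ts.sample_id: ts for ts in tsr_sets}

    # index sample TSRs and track sites per (chrom, strand) for fast lookup
    for tsr in consensus.tsrs:
        tsr.presence = {}
        tsr.expression = {}
    cons_by_key: dict[tuple[str, str], list[ConsensusTsr]] = {}
    for tsr in consensus.tsrs:
        cons_by_key.setdefault((tsr.chrom, tsr.strand), []).append(tsr)
    for key in cons_by_key:
        cons_by_key[key].sort(key=lambda t: t.start)

    for sid in set_ids:
        ts = sets_by_id[sid]
        track = tracks_by_id[sid]
        for key, cons_list in cons_by_key.items():
            chrom, strand = key
            sample_ivs = sorted(
                (c.start, c.end + 1)
                for c in ts.clusters
                if c.chrom == chrom and c.strand == strand
            )
            sites = track.sites(chrom, strand)
            site_pos = np.array([p for p, _ in sites], dtype=np.int64)
            site_val = np.array([v for _, v in sites], dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(site_val)])
            starts = np.array([s for s, _ in sample_ivs], dtype=np.int64)
            ends = np.array([e for _, e in sample_ivs], dtype=np.int64)
            for tsr in cons_list:
                lo = np.searchsorted(site_pos, tsr.start, side="left")
                hi = np.searchsorted(site_pos, tsr.end, side="left")
                tsr.expression[sid] = float(cum[hi] - cum[lo])
                # overlap exists iff some sample interval starts before
                # tsr.end and ends after tsr.start
                k = np.searchsorted(starts, tsr.end, side="left")
                tsr.presence[sid] = bool(np.any(ends[:k] > tsr.start))
    for tsr in consensus.tsrs:
        for sid in set_ids:
            tsr.presence.setdefault(sid, False)
            tsr.expression.setdefault(sid, 0.0)
    consensus.sample_ids = list(set_ids)
    return consensus


def presence_matrix(consensus: ConsensusTsrSet):
    """Presence as a pandas DataFrame (TSR id x sample)."""
    import pandas as pd

    return pd.DataFrame(
        {sid: [t.presence.get(sid, False) for t in consensus.tsrs]
         for sid in consensus.sample_ids},
        index=[t.id for t in consensus.tsrs],
    )


def expression_matrix(consensus: ConsensusTsrSet):
    import pandas as pd

    return pd.DataFrame(
        {sid: [t.expression.get(sid, 0.0) for t in consensus.tsrs]
         for sid in consensus.sample_ids},
        index=[t.id for t in consensus.tsrs],
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _categorize_against_gene(
    mid: int,
    gene: GeneModel,
    promoter_window: tuple[int, int],
    tts_window: tuple[int, int],
) -> list[str]:
    """All categories the midpoint earns from one gene (unprioritized)."""
    cats = []
    # strand-aware windows around TSS and TTS
    if gene.strand == "+":
        prom = (gene.tss + promoter_window[0], gene.tss + promoter_window[1])
        tts = (gene.tts + tts_window[0], gene.tts + tts_window[1])
    else:
        prom = (gene.tss - promoter_window[1], gene.tss - promoter_window[0])
        tts = (gene.tts - tts_window[1], gene.tts - tts_window[0])
    if prom[0] <= mid <= prom[1]:
        cats.append("promoter")
    if tts[0] <= mid <= tts[1]:
        cats.append("tts")
    if gene.start <= mid <= gene.end:
        in_exon = any(s <= mid <= e for s, e in gene.exons)
        if in_exon:
            if gene.biotype != "coding" or not gene.cds:
                cats.append("noncoding")
            else:
                cds_lo = min(s for s, _ in gene.cds)
                cds_hi = max(e for _, e in gene.cds)
                if cds_lo <= mid <= cds_hi:
                    cats.append("exon")
                elif (gene.strand == "+" and mid < cds_lo) or (
                    gene.strand == "-" and mid > cds_hi
                ):
                    cats.append("five_utr")
                else:
                    cats.append("three_utr")
        else:
            cats.append("intron")
    return cats


def annotate_tsrs(
    consensus: ConsensusTsrSet,
    annotation: GenomicAnnotation,
    promoter_window: tuple[int, int] = (-1000, 100),
    tts_window: tuple[int, int] = (-100, 1000),
) -> TsrAnnotation:
    """Assign each consensus TSR a genomic category and nearest gene.

    The category is decided by the interval midpoint with fixed priority
    promoter > tts > five_utr > three_utr > exon > noncoding > intron >
    intergenic, considering genes on either strand.  The nearest gene is the
    one whose annotated TSS is closest to the midpoint; the distance is
    signed in gene orientation (positive downstream).
    """
    if not annotation.genes:
        raise ValidationError("empty annotation")
    genes_by_chrom = annotation.by_chrom()
    all_genes = annotation.genes
    result: TsrAnnotation = {}
    for tsr in consensus.tsrs:
        mid = (tsr.start + tsr.end - 1) // 2  # midpoint of half-open interval
        cats: set[str] = set()
        for gene in genes_by_chrom.get(tsr.chrom, []):
            cats.update(
                _categorize_against_gene(mid, gene, promoter_window, tts_window)
            )
        category = next((c for c in CATEGORY_PRIORITY if c in cats), "intergenic")
        same_chrom = genes_by_chrom.get(tsr.chrom) or all_genes
        nearest = min(same_chrom, key=lambda g: abs(mid - g.tss))
        dist = mid - nearest.tss
        if nearest.strand == "-":
            dist = -dist
        result[tsr.id] = TsrAnnotationRecord(
            tsr_id=tsr.id,
            category=category,
            nearest_gene_id=nearest.gene_id,
            distance_to_tss=int(dist),
        )
    return result


def nearest_feature_distance(
    consensus: ConsensusTsrSet,
    features: dict[str, Sequence[tuple[int, int]]],
) -> dict[str, float]:
    """Edge-to-edge distance from each TSR to the nearest feature interval.

    ``features`` maps chrom -> sorted half-open intervals.  Overlap gives 0;
    chromosomes with no features give ``nan``.
    """
    out: dict[str, float] = {}
    feat_arrays = {}
    for chrom, ivs in features.items():
        ivs = sorted(ivs)
        feat_arrays[chrom] = (
            np.array([s for s, _ in ivs], dtype=np.int64),
            np.array([e for _, e in ivs], dtype=np.int64),
        )
    for tsr in consensus.tsrs:
        if tsr.chrom not in feat_arrays or feat_arrays[tsr.chrom][0].size == 0:
            out[tsr.id] = float("nan")
            continue
        starts, ends = feat_arrays[tsr.chrom]
        gap_right = starts - tsr.end  # feature starts after TSR ends
        gap_left = tsr.start - ends  # feature ends before TSR starts
        gaps = np.maximum(np.maximum(gap_right, gap_left), 0)
        out[tsr.id] = float(gaps.min())
    return out
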