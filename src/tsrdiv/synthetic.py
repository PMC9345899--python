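"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

Everything is derived deterministically from a :class:`SimConfig`: promoter
positions and group assignments, per-sample tag tracks whose per-promoter
totals follow a discrete power law, gene models anchored at canonical
promoters, tissue TPM matrices with planted tissue-restricted and
housekeeping genes, and isoform-usage profiles with known entropy.  A
:class:`TruthTable` records every planted fact for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, PlacementError
from .tsr import GeneModel, GenomicAnnotation
from .tss import TssTrack

GROUPS = ("hi_specific", "lo_specific", "shared")

#: geometric decay of tag offsets around a promoter center (success prob).
TAG_SPREAD_P = 0.5
#: support of the truncated discrete power law for per-promoter weights.
POWERLAW_MAX = 10**6


@dataclass
class SimConfig:
    seed: int = 0
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 2_000_000), ("chr2", 1_500_000)]
    )
    n_promoters: int = 100
    promoter_width_bp: int = 8
    zipf_exponent: float = 1.5
    total_tags_per_sample: int = 50_000
    n_hi_samples: int = 5
    n_lo_samples: int = 5
    frac_hi_specific: float = 0.2
    frac_lo_specific: float = 0.2
    detection_prob: float = 0.6
    noise_tags_per_kb: float = 0.01
    n_genes: int = 100
    n_tissues: int = 22
    n_tra: int = 30
    n_housekeeping: int = 30
    tra_foreground_tpm: float = 100.0
    background_tpm: float = 0.5
    isoforms_per_gene_range: tuple[int, int] = (1, 6)
    dirichlet_alpha: float = 1.0
    tpm_jitter: float = 0.2  # lognormal sigma (~ +/-20%)
    frac_misinitiated: float = 0.0  # extra non-canonical promoters per gene

    def validate(self) -> None:
        if self.zipf_exponent <= 1:
            raise ConfigError("zipf_exponent must be > 1")
        for name in ("n_promoters", "total_tags_per_sample", "n_hi_samples",
                     "n_lo_samples", "n_genes", "n_tissues", "n_tra",
                     "n_housekeeping", "promoter_width_bp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("frac_hi_specific", "frac_lo_specific"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        if not (0 < self.detection_prob <= 1):
            raise ConfigError("detection_prob must be in (0, 1]")
        if self.noise_tags_per_kb < 0:
            raise ConfigError("noise_tags_per_kb must be >= 0")
        if any(length <= 0 for _, length in self.genome):
            raise ConfigError("genome lengths must be positive")
        if self.isoforms_per_gene_range[0] < 1:
            raise ConfigError("isoforms_per_gene_range minimum must be >= 1")
        if self.dirichlet_alpha <= 0:
            raise ConfigError("dirichlet_alpha must be > 0")
        if self.n_tra + self.n_housekeeping > self.n_genes:
            raise ConfigError("n_tra + n_housekeeping exceeds n_genes")


@dataclass
class PromoterRecord:
    promoter_id: str
    chrom: str
    strand: str
    center: int
    group: str  # hi_specific | lo_specific | shared
    gene_id: str
    canonical: bool
    active_in: dict[str, bool] = field(default_factory=dict)


@dataclass
class GeneRecord:
    gene_id: str
    planted_class: str  # tra | housekeeping | other
    planted_tissues: list[str] = field(default_factory=list)
    expected_tau_class: str = ""  # high | low | ""


@dataclass
class IsoformRecord:
    gene_id: str
    transcript_ids: list[str]
    usage: np.ndarray
    entropy_bits: float


@dataclass
class TruthTable:
    promoters: list[PromoterRecord] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    isoforms: list[IsoformRecord] = field(default_factory=list)

    def promoter_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "promoter_id": p.promoter_id,
                    "chrom": p.chrom,
                    "strand": p.strand,
                    "center": p.center,
                    "group": p.group,
                    "gene_id": p.gene_id,
                    "canonical": p.canonical,
                    **{f"active_{s}": int(v) for s, v in sorted(p.active_in.items())},
                }
                for p in self.promoters
            ]
        )

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "planted_class": g.planted_class,
                    "planted_tissues": ",".join(g.planted_tissues),
                    "expected_tau_class": g.expected_tau_class,
                }
                for g in self.genes
            ]
        )

    def isoform_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "transcript_ids": ",".join(r.transcript_ids),
                    "usage": ",".join(f"{u:.10g}" for u in r.usage),
                    "entropy_bits": r.entropy_bits,
                }
                for r in self.isoforms
            ]
        )


# ---------------------------------------------------------------------------
# deterministic layout shared by the generators
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    promoters: list[PromoterRecord]
    genes: list[GeneModel]
    gene_records: list[GeneRecord]
    sample_ids: list[str]
    gene_sets: dict[str, list[str]]


def sample_ids_for(config: SimConfig) -> list[str]:
    return [f"hi_{i+1}" for i in range(config.n_hi_samples)] + [
        f"lo_{i+1}" for i in range(config.n_lo_samples)
    ]


_ZIPF_CDF_CACHE: dict[float, np.ndarray] = {}


def _zipf_cdf_sampler(ccdf_exponent: float, rng: np.random.Generator, size: int) -> np.ndarray:
    """Inverse-CDF sampling of a discrete power law on 1..POWERLAW_MAX.

    ``ccdf_exponent`` is the tail exponent of the *reverse cumulative*
    (P(X >= x) ~ x**-ccdf_exponent), so the pmf decays as x**-(exponent+1).
    This matches the slope :func:`tsrdiv.tss.fit_power_law` recovers.
    """
    cdf = _ZIPF_CDF_CACHE.get(ccdf_exponent)
    if cdf is None:
        ks = np.arange(1, POWERLAW_MAX + 1, dtype=float)
        pmf = ks ** (-(ccdf_exponent + 1.0))
        cdf = np.cumsum(pmf)
        cdf /= cdf[-1]
        _ZIPF_CDF_CACHE[ccdf_exponent] = cdf
    u = rng.random(size)
    return np.searchsorted(cdf, u, side="left") + 1


def powerlaw_track(
    ccdf_exponent: float,
    n_sites: int,
    seed: int = 0,
    sample_id: str = "powerlaw",
    genome_bp: int = 10**7,
) -> TssTrack:
    """A raw track whose reverse-cumulative count distribution is an exact
    power law: the site at rank r carries ``floor((r/n)**(-1/exponent))``
    tags.  Positions are a seeded draw without replacement."""
    r = np.arange(1, n_sites + 1, dtype=float)
    counts = np.maximum(1, np.floor((r / n_sites) ** (-1.0 / ccdf_exponent))).astype(int)
    rng = np.random.default_rng(seed)
    pos = rng.choice(genome_bp, size=n_sites, replace=False)
    entries = {("chr1", "+", int(p)): float(v) for p, v in zip(pos, counts)}
    return TssTrack(sample_id=sample_id, entries=entries, kind="raw")


def build_layout(config: SimConfig) -> _Layout:
    """Place genes and promoters deterministically from the config seed.

    Each gene occupies a block with its canonical promoter at the annotated
    TSS; blocks are separated so promoter centers keep a pairwise distance
    greater than 4 * promoter_width + 40.  Mis-initiated promoters go inside
    gene bodies, downstream of the canonical start.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n_extra = int(round(config.frac_misinitiated * config.n_promoters))
    n_canonical = config.n_promoters - n_extra
    if n_canonical > config.n_genes:
        # more promoters than genes: surplus canonicals become mis-initiated
        n_extra += n_canonical - config.n_genes
        n_canonical = config.n_genes

    min_sep = 4 * config.promoter_width_bp + 41
    gene_len = max(3000, 2 * min_sep + 200)
    block = gene_len + 2 * min_sep

    # lay gene blocks sequentially over chromosomes
    slots: list[tuple[str, int]] = []  # (chrom, block start)
    for chrom, length in config.genome:
        offset = min_sep
        while offset + block < length - min_sep:
            slots.append((chrom, offset))
            offset += block
    if len(slots) < config.n_genes:
        raise PlacementError(
            f"genome holds only {len(slots)} gene blocks, need {config.n_genes}"
        )
    chosen = sorted(rng.choice(len(slots), size=config.n_genes, replace=False))

    genes: list[GeneModel] = []
    promoters: list[PromoterRecord] = []
    strands = rng.choice(["+", "-"], size=config.n_genes)
    for gi, slot_idx in enumerate(chosen):
        chrom, b0 = slots[slot_idx]
        gene_id = f"gene_{gi+1:04d}"
        strand = str(strands[gi])
        gstart = b0 + min_sep
        gend = gstart + gene_len - 1
        n_exons = int(rng.integers(2, 9))
        # split the gene span into alternating exons/introns
        cuts = np.sort(rng.choice(
            np.arange(gstart + 50, gend - 50), size=2 * n_exons - 2, replace=False))
        bounds = np.concatenate([[gstart], cuts, [gend]])
        exons = tuple(
            (int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)
        )
        # CDS: from inside the first exon to inside the last exon
        cds_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
        cds_end = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2
        cds = tuple(
            (max(s, cds_start), min(e, cds_end))
            for s, e in exons
            if e >= cds_start and s <= cds_end
        )
        genes.append(
            GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, start=gstart,
                      end=gend, exons=exons, cds=cds, biotype="coding")
        )

    # canonical promoters at gene TSSs (first n_canonical genes, shuffled)
    canon_genes = rng.permutation(config.n_genes)[:n_canonical]
    for pi, gi in enumerate(sorted(canon_genes)):
        g = genes[gi]
        promoters.append(
            PromoterRecord(
                promoter_id=f"prom_{pi+1:04d}",
                chrom=g.chrom,
                strand=g.strand,
                center=g.tss,
                group="",
                gene_id=g.gene_id,
                canonical=True,
            )
        )
    # mis-initiated promoters inside gene bodies, far from the canonical TSS
    hosts = rng.integers(0, config.n_genes, size=n_extra)
    for k, gi in enumerate(hosts):
        g = genes[int(gi)]
        lo = g.start + min_sep + 100
        hi = g.end - min_sep - 100
        center = int(rng.integers(lo, hi))
        promoters.append(
            PromoterRecord(
                promoter_id=f"prom_{n_canonical + k + 1:04d}",
                chrom=g.chrom,
                strand=g.strand,
                center=center,
                group="",
                gene_id=g.gene_id,
                canonical=False,
            )
        )

    # group assignment over all promoters
    n_hi = int(round(config.frac_hi_specific * config.n_promoters))
    n_lo = int(round(config.frac_lo_specific * config.n_promoters))
    if n_hi + n_lo > config.n_promoters:
        raise ConfigError("frac_hi_specific + frac_lo_specific exceeds 1")
    order = rng.permutation(config.n_promoters)
    for idx in order[:n_hi]:
        promoters[idx].group = "hi_specific"
    for idx in order[n_hi : n_hi + n_lo]:
        promoters[idx].group = "lo_specific"
    for idx in order[n_hi + n_lo :]:
        promoters[idx].group = "shared"

    # gene classes: TRAs preferentially among genes with a hi_specific
    # canonical promoter so gene-set statistics have planted signal
    hi_genes = [p.gene_id for p in promoters if p.canonical and p.group == "hi_specific"]
    other_genes = [g.gene_id for g in genes if g.gene_id not in set(hi_genes)]
    rng.shuffle(other_genes)
    ordered = hi_genes + other_genes
    tra_ids = ordered[: config.n_tra]
    hk_ids = [g for g in ordered if g not in set(tra_ids)][: config.n_housekeeping]
    tra_set = set(tra_ids)
    hk_set = set(hk_ids)
    gene_records = []
    for g in genes:
        if g.gene_id in tra_set:
            cls, tau_cls = "tra", "high"
        elif g.gene_id in hk_set:
            cls, tau_cls = "housekeeping", "low"
        else:
            cls, tau_cls = "other", ""
        gene_records.append(
            GeneRecord(gene_id=g.gene_id, planted_class=cls, expected_tau_class=tau_cls)
        )
    third = max(1, len(tra_ids) // 3)
    gene_sets = {
        "tra": sorted(tra_ids),
        "housekeeping": sorted(hk_ids),
        "aire_like": sorted(tra_ids[:third]),
        "fezf2_like": sorted(tra_ids[third : 2 * third]),
    }
    return _Layout(
        promoters=promoters,
        genes=genes,
        gene_records=gene_records,
        sample_ids=sample_ids_for(config),
        gene_sets=gene_sets,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_tss_dataset(config: SimConfig) -> tuple[list[TssTrack], TruthTable]:
    """Per-sample raw tag tracks plus the planted truth.

    Each sample's promoter tags are allocated multinomially with power-law
    weights over its active promoters, spread around the center with a
    truncated symmetric geometric offset; uniform singleton background tags
    are added at ``noise_tags_per_kb``.
    """
    layout = build_layout(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    sample_ids = layout.sample_ids
    promoters = layout.promoters
    width = config.promoter_width_bp

    # per-sample activity flags
    for p in promoters:
        for sid in sample_ids:
            group = "hi" if sid.startswith("hi") else "lo"
            if p.group == "hi_specific" and group == "lo":
                active = False
            elif p.group == "lo_specific" and group == "hi":
                active = False
            else:
                active = bool(rng.random() < config.detection_prob)
            p.active_in[sid] = active

    genome_bp = sum(length for _, length in config.genome)
    chrom_names = [c for c, _ in config.genome]
    chrom_lengths = np.array([l for _, l in config.genome], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()

    tracks = []
    for sid in sample_ids:
        active = [p for p in promoters if p.active_in[sid]]
        entries: dict[tuple[str, str, int], float] = {}
        if active and config.total_tags_per_sample > 0:
            weights = _zipf_cdf_sampler(config.zipf_exponent, rng, len(active)).astype(float)
            counts = rng.multinomial(
                config.total_tags_per_sample, weights / weights.sum()
            )
            for p, n_tags in zip(active, counts):
                if n_tags == 0:
                    continue
                # truncated symmetric geometric spread around the center
                mags = rng.geometric(TAG_SPREAD_P, size=n_tags) - 1
                mags = np.minimum(mags, width)
                signs = rng.choice([-1, 1], size=n_tags)
                offsets = mags * signs
                positions, offs_counts = np.unique(p.center + offsets, return_counts=True)
                for pos, cnt in zip(positions, offs_counts):
                    key = (p.chrom, p.strand, int(pos))
                    entries[key] = entries.get(key, 0) + int(cnt)
        n_noise = rng.poisson(config.noise_tags_per_kb * genome_bp / 1000.0)
        if n_noise > 0:
            chroms = rng.choice(len(chrom_names), size=n_noise, p=chrom_probs)
            for ci in chroms:
                pos = int(rng.integers(0, int(chrom_lengths[ci])))
                strand = "+" if rng.random() < 0.5 else "-"
                key = (chrom_names[ci], strand, pos)
                entries[key] = entries.get(key, 0) + 1
        tracks.append(TssTrack(sample_id=sid, entries=entries, kind="raw"))

    truth = TruthTable(promoters=promoters, genes=layout.gene_records)
    return tracks, truth


def gen_annotation(config: SimConfig) -> tuple[GenomicAnnotation, dict[str, list[str]]]:
    """Gene models consistent with the promoter layout, plus gene-set lists."""
    layout = build_layout(config)
    return GenomicAnnotation(genes=layout.genes), layout.gene_sets


def gen_expression_matrix(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Gene x tissue TPM matrix with planted TRA and housekeeping genes."""
    config.validate()
    if config.n_tissues < 3:
        raise ConfigError("n_tissues must be >= 3")
    if config.tra_foreground_tpm <= config.background_tpm:
        raise ConfigError("tra_foreground_tpm must exceed background_tpm")
    layout = build_layout(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    tissues = [f"tissue_{i+1:02d}" for i in range(config.n_tissues)]

    def jitter(shape):
        # lognormal, truncated at 2.5 sigma so planted tau classes stay
        # separable (an unbounded tail occasionally pushes a housekeeping
        # gene past the tau threshold)
        if config.tpm_jitter == 0:
            return np.ones(shape)
        z = np.clip(rng.normal(0.0, 1.0, size=shape), -2.5, 2.5)
        return np.exp(config.tpm_jitter * z)

    rows = {}
    gene_records = []
    for rec in layout.gene_records:
        if rec.planted_class == "tra":
            k = int(rng.integers(1, 4))  # 1-3 expressing tissues
            fg_idx = rng.choice(config.n_tissues, size=k, replace=False)
            vals = np.full(config.n_tissues, config.background_tpm) * jitter(
                config.n_tissues
            )
            vals[fg_idx] = config.tra_foreground_tpm * jitter(k)
            planted = sorted(tissues[i] for i in fg_idx)
        elif rec.planted_class == "housekeeping":
            vals = np.full(config.n_tissues, config.tra_foreground_tpm) * jitter(
                config.n_tissues
            )
            planted = list(tissues)
        else:
            base = float(np.exp(rng.normal(np.log(10.0), 1.0)))
            vals = np.full(config.n_tissues, base) * jitter(config.n_tissues)
            planted = []
        rows[rec.gene_id] = vals
        gene_records.append(
            GeneRecord(
                gene_id=rec.gene_id,
                planted_class=rec.planted_class,
                planted_tissues=planted,
                expected_tau_class=rec.expected_tau_class,
            )
        )
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    matrix.index.name = "feature_id"
    return matrix, TruthTable(genes=gene_records)


def gen_isoform_profiles(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, str], TruthTable]:
    """Transcript x tissue TPM matrix with Dirichlet isoform usage.

    Transcript TPM = gene TPM x usage; the truth records each gene's usage
    vector and its exact Shannon entropy in bits.
    """
    gene_matrix, truth = gen_expression_matrix(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    lo, hi = config.isoforms_per_gene_range
    tx_rows = {}
    tx_to_gene = {}
    iso_records = []
    for gene_id in gene_matrix.index:
        k = int(rng.integers(lo, hi + 1))
        usage = np.ones(1) if k == 1 else rng.dirichlet(np.full(k, config.dirichlet_alpha))
        tx_ids = [f"{gene_id}.t{j+1}" for j in range(k)]
        for tid, u in zip(tx_ids, usage):
            tx_rows[tid] = gene_matrix.loc[gene_id].to_numpy() * u
            tx_to_gene[tid] = gene_id
        pos = usage[usage > 0]
        entropy = max(0.0, float(-(pos * np.log2(pos)).sum()))
        iso_records.append(
            IsoformRecord(gene_id=gene_id, transcript_ids=tx_ids,
                          usage=usage, entropy_bits=entropy)
        )
    tx_matrix = pd.DataFrame.from_dict(
        tx_rows, orient="index", columns=gene_matrix.columns
    )
    tx_matrix.index.name = "feature_id"
    truth.isoforms = iso_records
    return tx_matrix, tx_to_gene, truth
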