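"""Population-specific TSR classification and the associated statistics.

Samples come from two populations ("hi" and "lo"), paired by individual.  A
TSR is specific to a population when it is reproducibly present there
(>= ``min_support`` samples) and not detected at all in the other population.
Downstream statistics compare gene-set composition, promoter usage, and
tissue sharing between the two specific TSR sets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, DesignError, ValidationError
from .tsr import TsrAnnotation

LABELS = ("hi_specific", "lo_specific", "shared", "unreplicated")


@dataclass
class SampleGroupDesign:
    """sample_id -> (group, individual_id); individuals pair hi with lo."""

    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, (group, _) in self.assignments.items():
            if group not in ("hi", "lo"):
                raise DesignError(f"sample {sid}: group must be 'hi' or 'lo'")
        for group in ("hi", "lo"):
            inds = [i for _, (g, i) in self.assignments.items() if g == group]
            if len(inds) != len(set(inds)):
                raise DesignError(f"individual contributes >1 sample to group {group}")

    def samples(self, group: str) -> list[str]:
        return sorted(s for s, (g, _) in self.assignments.items() if g == group)

    def pairs(self) -> list[tuple[str, str, str]]:
        """(individual, hi_sample, lo_sample) for fully paired individuals."""
        by_ind: dict[str, dict[str, str]] = {}
        for sid, (g, ind) in self.assignments.items():
            by_ind.setdefault(ind, {})[g] = sid
        return sorted(
            (ind, d["hi"], d["lo"]) for ind, d in by_ind.items() if len(d) == 2
        )


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[int, int, int, int]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    test: str = "fisher_exact_two_sided"


@dataclass
class LooMatrix:
    """Leave-one-out tissue-specificity fractions and row z-scores."""

    fractions: pd.DataFrame  # rows: source tissue u, cols: held-out tissue t
    zscores: pd.DataFrame
    column_means: pd.Series


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_population_specific(
    presence: pd.DataFrame,
    design: SampleGroupDesign,
    min_support: int = 2,
) -> pd.Series:
    """Label each TSR hi_specific / lo_specific / shared / unreplicated.

    hi_specific: present in >= ``min_support`` hi samples and no lo sample;
    lo_specific symmetrically; shared: present in >= 1 sample of each group;
    unreplicated otherwise.
    """
    hi = design.samples("hi")
    lo = design.samples("lo")
    if len(hi) < min_support or len(lo) < min_support:
        raise DesignError(
            f"each group needs >= {min_support} samples (hi={len(hi)}, lo={len(lo)})"
        )
    missing = [s for s in hi + lo if s not in presence.columns]
    if missing:
        raise ValidationError(f"presence matrix lacks samples: {missing}")
    n_hi = presence[hi].sum(axis=1)
    n_lo = presence[lo].sum(axis=1)
    labels = pd.Series("unreplicated", index=presence.index, dtype=object)
    labels[(n_hi >= min_support) & (n_lo == 0)] = "hi_specific"
    labels[(n_lo >= min_support) & (n_hi == 0)] = "lo_specific"
    labels[(n_hi >= 1) & (n_lo >= 1)] = "shared"
    return labels


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired t-test on per-individual values; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    n = x.size
    if n < 2:
        raise ValidationError("paired t-test needs n >= 2")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("zero variance of paired differences")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def fisher_exact_two_sided(table: tuple[int, int, int, int]) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probs <= observed."""
    a, b, c, d = table
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def odds_ratio_ci(
    table: tuple[int, int, int, int], level: float = 0.95
) -> tuple[float, float, float]:
    """OR with a Woolf logit CI; Haldane-Anscombe 0.5 added iff any cell is 0."""
    a, b, c, d = (float(v) for v in table)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return orr, math.exp(math.log(orr) - z * se), math.exp(math.log(orr) + z * se)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with mid-rank ties.

    Exact enumeration of all group assignments when both groups have
    <= ``exact_max_n`` observations; otherwise the normal approximation with
    tie correction and continuity correction.  Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks
    u_x = float(ranks[:m].sum() - m * (m + 1) / 2)
    if m <= exact_max_n and n <= exact_max_n:
        mu = m * n / 2.0
        obs_dev = abs(u_x - mu)
        total = 0
        extreme = 0
        idx = range(m + n)
        for combo in itertools.combinations(idx, m):
            u = float(ranks[list(combo)].sum() - m * (m + 1) / 2)
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                extreme += 1
        return u_x, extreme / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_x, float(res.pvalue)


# ---------------------------------------------------------------------------
# gene-set statistics
# ---------------------------------------------------------------------------

def geneset_fractions(
    labels: pd.Series,
    annotation: TsrAnnotation,
    presence: pd.DataFrame,
    design: SampleGroupDesign,
    gene_set: Iterable[str],
    pooled: bool = False,
) -> tuple[pd.Series, tuple[float, int, float] | None]:
    """Per-sample fraction of group-specific TSRs whose nearest gene is in the set.

    For a sample of group g the denominator is the set of g-specific TSRs
    present in that sample (or all g-specific TSRs when ``pooled``).  Returns
    the per-sample fractions and the paired hi-vs-lo t-test over individuals
    (None if fewer than two complete pairs remain).
    """
    gene_set = set(gene_set)
    unannotated = [i for i in labels.index if i not in annotation]
    if unannotated:
        raise ValidationError(f"TSRs lack nearest-gene annotation: {unannotated[:5]}")
    in_set = pd.Series(
        {i: annotation[i].nearest_gene_id in gene_set for i in labels.index}
    )
    fractions = {}
    for group in ("hi", "lo"):
        specific = labels.index[labels == f"{group}_specific"]
        for sid in design.samples(group):
            denom_idx = (
                specific if pooled else specific[presence.loc[specific, sid]]
            )
            if len(denom_idx) == 0:
                warnings.warn(
                    f"sample {sid}: no {group}-specific TSRs present; fraction missing"
                )
                fractions[sid] = np.nan
            else:
                fractions[sid] = float(in_set[denom_idx].mean())
    fractions = pd.Series(fractions)
    pairs = design.pairs()
    hi_vals, lo_vals = [], []
    for ind, hi_s, lo_s in pairs:
        fh, fl = fractions.get(hi_s, np.nan), fractions.get(lo_s, np.nan)
        if np.isnan(fh) or np.isnan(fl):
            warnings.warn(f"individual {ind} dropped from paired test (missing fraction)")
            continue
        hi_vals.append(fh)
        lo_vals.append(fl)
    test = None
    if len(hi_vals) >= 2:
        test = paired_t_test(lo_vals, hi_vals)
    return fractions, test


def enrichment_odds_ratio(
    labels: pd.Series, membership: pd.Series
) -> EnrichmentResult:
    """hi-specific vs lo-specific 2x2 enrichment of a TSR property.

    Table: a = hi & member, b = hi & non-member, c = lo & member,
    d = lo & non-member.  Fisher two-sided p; Woolf CI.
    """
    hi = labels == "hi_specific"
    lo = labels == "lo_specific"
    if hi.sum() == 0 or lo.sum() == 0:
        raise ValidationError("need >= 1 hi_specific and >= 1 lo_specific TSR")
    member = membership.reindex(labels.index).fillna(False).astype(bool)
    a = int((hi & member).sum())
    b = int((hi & ~member).sum())
    c = int((lo & member).sum())
    d = int((lo & ~member).sum())
    p = fisher_exact_two_sided((a, b, c, d))
    orr, lo_ci, hi_ci = odds_ratio_ci((a, b, c, d))
    return EnrichmentResult(table=(a, b, c, d), odds_ratio=orr,
                            ci_low=lo_ci, ci_high=hi_ci, p=p)


def tsrs_per_gene(
    labels: pd.Series,
    annotation: TsrAnnotation,
    presence: pd.DataFrame,
    design: SampleGroupDesign,
    scope: str = "population",
) -> dict:
    """Mean TSRs per nearest gene in each population, with a Mann-Whitney test.

    scope='population': count population-specific TSRs; scope='all': count
    every TSR present in >= 1 sample of the population.
    """
    if scope not in ("population", "all"):
        raise ValidationError(f"unknown scope {scope!r}")
    counts = {}
    for group in ("hi", "lo"):
        if scope == "population":
            tsr_ids = labels.index[labels == f"{group}_specific"]
        else:
            cols = design.samples(group)
            tsr_ids = presence.index[presence[cols].any(axis=1)]
        genes = pd.Series([annotation[i].nearest_gene_id for i in tsr_ids])
        if genes.empty:
            raise ValidationError(f"no TSRs (and hence no genes) for group {group}")
        counts[group] = genes.value_counts().to_numpy()
    u, p = mann_whitney_u(counts["hi"], counts["lo"])
    return {
        "mean_hi": float(counts["hi"].mean()),
        "mean_lo": float(counts["lo"].mean()),
        "counts_hi": counts["hi"],
        "counts_lo": counts["lo"],
        "u": u,
        "p": p,
    }


def misinitiation_rates(
    annotation: TsrAnnotation,
    labels: pd.Series,
    presence: pd.DataFrame,
    design: SampleGroupDesign,
    gene_set: Iterable[str] | None = None,
    promoter_like: Iterable[str] = ("promoter",),
    level: str = "tsr",
) -> dict:
    """Per-sample fraction of group-specific TSRs initiating outside promoters.

    level='tsr' computes TSR-level fractions, level='gene' the fraction of
    genes with >= 1 non-promoter TSR.  Also reports the pooled hi-vs-lo
    Fisher enrichment of non-promoter initiation.
    """
    promoter_like = set(promoter_like)
    if level not in ("tsr", "gene"):
        raise ValidationError(f"unknown level {level!r}")
    gene_set = set(gene_set) if gene_set is not None else None

    def eligible(tsr_id: str) -> bool:
        return gene_set is None or annotation[tsr_id].nearest_gene_id in gene_set

    def is_mis(tsr_id: str) -> bool:
        return annotation[tsr_id].category not in promoter_like

    rates = {}
    for group in ("hi", "lo"):
        specific = [
            i for i in labels.index if labels[i] == f"{group}_specific" and eligible(i)
        ]
        for sid in design.samples(group):
            present = [i for i in specific if presence.loc[i, sid]]
            if level == "tsr":
                if not present:
                    warnings.warn(f"sample {sid}: empty denominator; rate missing")
                    rates[sid] = np.nan
                else:
                    rates[sid] = float(np.mean([is_mis(i) for i in present]))
            else:
                by_gene: dict[str, bool] = {}
                for i in present:
                    g = annotation[i].nearest_gene_id
                    by_gene[g] = by_gene.get(g, False) or is_mis(i)
                if not by_gene:
                    warnings.warn(f"sample {sid}: empty denominator; rate missing")
                    rates[sid] = np.nan
                else:
                    rates[sid] = float(np.mean(list(by_gene.values())))
    rates = pd.Series(rates)

    pairs = design.pairs()
    hi_vals, lo_vals = [], []
    for _, hi_s, lo_s in pairs:
        if not (np.isnan(rates[hi_s]) or np.isnan(rates[lo_s])):
            hi_vals.append(rates[hi_s])
            lo_vals.append(rates[lo_s])
    test = None
    if len(hi_vals) >= 2:
        try:
            test = paired_t_test(lo_vals, hi_vals)
        except DegenerateVarianceError:
            warnings.warn("paired test degenerate (zero variance); omitted")

    mis = pd.Series({i: is_mis(i) for i in labels.index if eligible(i)})
    pooled_labels = labels[mis.index]
    enr = None
    if (pooled_labels == "hi_specific").any() and (pooled_labels == "lo_specific").any():
        enr = enrichment_odds_ratio(pooled_labels, mis)
    return {"rates": rates, "paired_test": test, "enrichment": enr}


# ---------------------------------------------------------------------------
# leave-one-out
# ---------------------------------------------------------------------------

def leave_one_out_specificity(presence: pd.DataFrame) -> LooMatrix:
    """How often 'tissue-unique' TSRs re-appear in a held-out tissue.

    ``presence`` is a TSR x tissue boolean matrix.  Holding out tissue t, the
    TSRs unique to a single remaining tissue u are collected; F[u, t] is the
    fraction of them that are present in t.  Z is the row-wise z-score of F
    (population SD) across defined held-out tissues.
    """
    tissues = list(presence.columns)
    if len(tissues) < 3:
        raise ValidationError("leave-one-out needs >= 3 tissues")
    P = presence.astype(bool)
    F = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for t in tissues:
        rest = [u for u in tissues if u != t]
        sub = P[rest]
        n_present = sub.sum(axis=1)
        for u in rest:
            unique_u = P.index[(n_present == 1) & sub[u]]
            if len(unique_u) > 0:
                F.loc[u, t] = float(P.loc[unique_u, t].mean())
    Z = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for u in tissues:
        row = F.loc[u].dropna()
        if len(row) >= 2:
            sd = row.to_numpy().std()  # population SD
            if sd > 0:
                Z.loc[u, row.index] = (row - row.mean()) / sd
            # constant rows have no defined z-score; left missing
    col_means = Z.mean(axis=0, skipna=True)
    return LooMatrix(fractions=F, zscores=Z, column_means=col_means)
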