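"""Per-position TSS tracks, power-law normalization, and saturation curves.

A *track* stores, for one sample, the number of transcripts starting at each
(chrom, strand, position).  Raw integer counts are normalized to a common
reference power law so that samples of different depth are comparable: the
empirical reverse-cumulative count distribution is fit on a log-log scale and
each raw value is mapped to the value that would occupy the same rank under
the reference law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, FitError, ValidationError

STRANDS = ("+", "-")

#: Reference power-law slope used when none is specified.
DEFAULT_REF_ALPHA = 1.25
#: Reference total signal ("tags per million").
DEFAULT_REF_TOTAL = 1e6


@dataclass
class TssTrack:
    """Strand-specific per-position 5'-tag signal for one sample.

    ``entries`` maps ``(chrom, strand, pos)`` (0-based position) to a strictly
    positive value: an integer count for ``kind='raw'`` tracks, a float for
    ``kind='normalized'`` tracks.
    """

    sample_id: str
    entries: dict[tuple[str, str, int], float] = field(default_factory=dict)
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "normalized"):
            raise ValidationError(f"unknown track kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def total(self) -> float:
        return float(sum(self.entries.values()))

    def values(self) -> np.ndarray:
        return np.fromiter(self.entries.values(), dtype=float, count=len(self.entries))

    def sites(self, chrom: str, strand: str) -> list[tuple[int, float]]:
        """Sorted ``(pos, value)`` pairs for one chromosome and strand."""
        out = [
            (pos, v)
            for (c, s, pos), v in self.entries.items()
            if c == chrom and s == strand
        ]
        out.sort()
        return out

    def chrom_strands(self) -> list[tuple[str, str]]:
        seen = sorted({(c, s) for (c, s, _) in self.entries})
        return seen


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of the log-log reverse-cumulative count distribution.

    ``R(x) = 10**log10_c * x**(-alpha)`` approximates the number of positions
    with value >= x.  ``ref_alpha``/``ref_total`` define the common reference
    law that :func:`normalize_to_reference` maps on to.
    """

    alpha: float
    log10_c: float
    fit_min: float
    fit_max: float
    n_points: int
    r2: float
    ref_alpha: float = DEFAULT_REF_ALPHA
    ref_total: float = DEFAULT_REF_TOTAL


def build_track(
    records: Iterable[tuple[str, int, str, int]], sample_id: str
) -> TssTrack:
    """Aggregate ``(chrom, pos, strand, count)`` records into a raw track.

    Duplicate keys are summed.  Counts must be positive integers and
    positions non-negative.
    """
    entries: dict[tuple[str, str, int], float] = {}
    for chrom, pos, strand, count in records:
        if strand not in STRANDS:
            raise ValidationError(f"malformed strand {strand!r}")
        if not float(count).is_integer() or count <= 0:
            raise ValidationError(f"count must be a positive integer, got {count!r}")
        if pos < 0:
            raise ValidationError(f"negative position {pos}")
        key = (str(chrom), strand, int(pos))
        entries[key] = entries.get(key, 0) + int(count)
    return TssTrack(sample_id=sample_id, entries=entries, kind="raw")


def fit_power_law(
    track: TssTrack, fit_min: float = 1, fit_max: float = 1000
) -> PowerLawFit:
    """OLS fit of ``log10 R(x)`` on ``log10 x`` over distinct observed values.

    ``R(x)`` is evaluated at each distinct value in ``[fit_min, fit_max]``;
    the regression is unweighted over distinct values.  Works on raw or
    normalized tracks (refitting a normalized track checks that the
    normalization landed on the reference law).
    """
    values = track.values()
    if values.size == 0:
        raise FitError("empty track")
    distinct = np.unique(values)
    in_range = distinct[(distinct >= fit_min) & (distinct <= fit_max)]
    if in_range.size < 2:
        raise FitError(
            f"need >=2 distinct values in [{fit_min}, {fit_max}], got {in_range.size}"
        )
    # reverse cumulative: number of positions with value >= x
    sorted_vals = np.sort(values)
    rev_cum = values.size - np.searchsorted(sorted_vals, in_range, side="left")
    lx = np.log10(in_range)
    ly = np.log10(rev_cum)
    slope, intercept = np.polyfit(lx, ly, 1)
    if slope >= 0:
        raise FitError("reverse-cumulative tail is non-decreasing; cannot fit")
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(
        alpha=float(-slope),
        log10_c=float(intercept),
        fit_min=float(fit_min),
        fit_max=float(fit_max),
        n_points=int(in_range.size),
        r2=float(r2),
    )


def implied_total(fit: PowerLawFit) -> float:
    """Total signal of the continuous power law a fit describes.

    For reverse cumulative ``R(x) = c * x**-alpha`` (alpha > 1) the signal
    beyond value 1 integrates to ``c / (alpha - 1)``; the reference intercept
    ``c' = ref_total * (ref_alpha - 1)`` makes this exactly ``ref_total``, so
    refitting a correctly normalized track recovers the reference total.
    """
    if fit.alpha <= 1:
        raise FitError("implied total undefined for alpha <= 1")
    return 10.0**fit.log10_c / (fit.alpha - 1.0)


def normalize_to_reference(track: TssTrack, fit: PowerLawFit) -> TssTrack:
    """Map raw counts onto the reference power law, rank for rank.

    A raw value ``x`` sits at reverse-cumulative rank ``r = c * x**-alpha``;
    its normalized value ``y`` satisfies ``r = c' * y**-beta`` with
    ``beta = ref_alpha`` and ``c' = ref_total * (beta - 1)`` (the intercept a
    continuous power law of total ``ref_total`` would have), so

        y = (c * x**-alpha / c') ** (-1 / beta)

    The mapping is strictly increasing, so position ranks are preserved.
    """
    if track.kind != "raw":
        raise ValidationError("normalization input must be a raw track")
    beta = fit.ref_alpha
    if beta <= 1:
        raise ConfigError("ref_alpha must be > 1 for a finite reference total")
    c = 10.0**fit.log10_c
    c_ref = fit.ref_total * (beta - 1.0)
    keys = list(track.entries)
    x = np.array([track.entries[k] for k in keys], dtype=float)
    y = (c * x ** (-fit.alpha) / c_ref) ** (-1.0 / beta)
    entries = {k: float(v) for k, v in zip(keys, y)}
    return TssTrack(sample_id=track.sample_id, entries=entries, kind="normalized")


def saturation_curve(
    track: TssTrack, proportions: Sequence[float], seed: int
) -> list[tuple[float, int]]:
    """Distinct-TSS counts in without-replacement subsamples of the tags.

    Every raw count is expanded to that many individual tags; for each
    proportion ``p`` a prefix of a single seeded permutation of all tags is
    retained (``round(p * total)`` tags) and distinct positions counted.
    Using prefixes of one permutation makes the curve monotone in ``p`` for a
    fixed seed.
    """
    if track.kind != "raw":
        raise ValidationError("saturation analysis requires a raw track")
    proportions = list(proportions)
    for p in proportions:
        if not (0 < p <= 1):
            raise ValidationError(f"proportion {p} outside (0, 1]")
    keys = list(track.entries)
    counts = np.array([track.entries[k] for k in keys], dtype=np.int64)
    total = int(counts.sum())
    tags = np.repeat(np.arange(len(keys)), counts)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(tags)
    out = []
    for p in proportions:
        n_keep = int(round(p * total))
        n_distinct = int(np.unique(perm[:n_keep]).size)
        out.append((float(p), n_distinct))
    return out
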