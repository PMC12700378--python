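"""Per-site methylation statistics.

Replicate aggregation of bedMethyl pileups into per-site mean/SD
frequencies, background correction against a whole-genome-amplified (WGA)
control library, the genome-wide "methylation fraction" statistic, the
SD-versus-mean regression, and rank-order tables of per-site frequencies.

A site's methylation frequency is the fraction of valid reads carrying the
modification (n_mod / valid_coverage).  A WGA library, being enzymatically
stripped of methylation, estimates the modified-basecall error floor; its
frequency is subtracted from the native frequency and the result clamped to
[0, 1].
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from statistics import fmean, stdev
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import FormatError, SiteRecord, read_tsv, write_tsv

__all__ = [
    "SiteSummary",
    "SdMeanFit",
    "compute_frequency",
    "aggregate_replicates",
    "wga_correct",
    "genomic_methylation_fraction",
    "fit_sd_mean",
    "rank_order_table",
    "index_summaries",
    "summaries_to_frame",
    "write_site_summaries",
    "read_site_summaries",
]

SiteKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class SiteSummary:
    """Replicate-aggregated (and optionally WGA-corrected) site statistics."""

    contig: str
    position: int
    strand: str
    mod_code: str
    mean_freq: float
    sd_freq: float
    n_replicates: int
    per_replicate_freq: tuple[float, ...]
    wga_freq: float | None = None
    corrected_freq: float | None = None
    wga_missing: bool = False

    @property
    def key(self) -> SiteKey:
        return (self.contig, self.position, self.strand, self.mod_code)


@dataclass(frozen=True)
class SdMeanFit:
    """Linear and quadratic least-squares fits of per-site SD on mean."""

    linear_r2: float
    quad_r2: float
    quad_coeffs: tuple[float, float, float]  # sd ~ a*m**2 + b*m + c
    linear_coeffs: tuple[float, float]
    n_sites: int


def compute_frequency(n_mod: int, valid_coverage: int) -> float:
    """Methylation frequency: modified reads over valid coverage.

    A zero-coverage site has no defined frequency and must be excluded
    upstream; it is never silently reported as 0.
    """
    if valid_coverage == 0:
        raise FormatError("methylation frequency undefined at zero coverage")
    if not 0 <= n_mod <= valid_coverage:
        raise FormatError(f"n_mod {n_mod} outside [0, {valid_coverage}]")
    return n_mod / valid_coverage


def aggregate_replicates(
    per_library_sites: Sequence[Sequence[SiteRecord]],
    min_replicates: int | None = None,
    min_coverage: int = 1,
) -> list[SiteSummary]:
    """Aggregate per-replicate site records into per-site summaries.

    Sites are keyed by (contig, position, strand, mod_code).  A key is
    reported only if it is present (with coverage >= ``min_coverage``) in at
    least ``min_replicates`` libraries; the default requires all libraries.
    The SD is the sample standard deviation (n-1 denominator), zero for a
    single replicate.  Output is sorted in genome order.
    """
    if not per_library_sites:
        raise ValueError("at least one replicate library is required")
    need = len(per_library_sites) if min_replicates is None else min_replicates
    min_coverage = max(min_coverage, 1)
    per_key: dict[SiteKey, dict[int, float]] = defaultdict(dict)
    for rep, records in enumerate(per_library_sites):
        for rec in records:
            if rec.valid_coverage >= min_coverage:
                per_key[rec.key][rep] = rec.n_mod / rec.valid_coverage
    summaries: list[SiteSummary] = []
    for key in sorted(per_key):
        by_rep = per_key[key]
        if len(by_rep) < need:
            continue
        freqs = tuple(by_rep[r] for r in sorted(by_rep))
        mean = fmean(freqs)
        sd = stdev(freqs) if len(freqs) > 1 else 0.0
        contig, position, strand, mod_code = key
        summaries.append(
            SiteSummary(
                contig=contig,
                position=position,
                strand=strand,
                mod_code=mod_code,
                mean_freq=mean,
                sd_freq=sd,
                n_replicates=len(freqs),
                per_replicate_freq=freqs,
            )
        )
    return summaries


def wga_correct(
    summaries: Sequence[SiteSummary],
    wga_sites: Sequence[SiteRecord],
    min_coverage: int = 1,
) -> list[SiteSummary]:
    """Subtract the WGA error-floor frequency from each site's mean.

    corrected = clamp(mean - wga, 0, 1).  Sites absent from the WGA library
    (or below its coverage floor) are corrected with wga = 0 and flagged
    ``wga_missing``.
    """
    min_coverage = max(min_coverage, 1)
    wga_freq: dict[SiteKey, float] = {}
    for rec in wga_sites:
        if rec.valid_coverage >= min_coverage:
            wga_freq[rec.key] = rec.n_mod / rec.valid_coverage
    corrected = []
    for s in summaries:
        missing = s.key not in wga_freq
        wga = 0.0 if missing else wga_freq[s.key]
        value = min(1.0, max(0.0, s.mean_freq - wga))
        corrected.append(
            dataclasses.replace(
                s, wga_freq=wga, corrected_freq=value, wga_missing=missing
            )
        )
    return corrected


def genomic_methylation_fraction(
    sites: Iterable[SiteSummary] | Iterable[float],
    threshold: float = 0.70,
    freq_attr: str = "mean_freq",
) -> float:
    """Proportion of sites whose frequency meets the threshold (inclusive).

    The comparison is >= throughout the package (the source texts mix ">"
    and "over"; one convention is fixed and documented).
    """
    values = [
        getattr(s, freq_attr) if isinstance(s, SiteSummary) else float(s)
        for s in sites
    ]
    if not values:
        raise ValueError("genomic methylation fraction of an empty site set")
    return sum(v >= threshold for v in values) / len(values)


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0  # constant response: any unbiased fit is exact
    return 1.0 - ss_res / ss_tot


def fit_sd_mean(summaries: Sequence[SiteSummary]) -> SdMeanFit:
    """Least-squares linear and quadratic fits of sd_freq on mean_freq.

    Captures the concave SD-vs-mean relationship of replicated binomial
    sampling: variability peaks at intermediate frequencies and shrinks at
    both extremes, so the quadratic fit should dominate the linear one.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 sites to fit the SD-mean relation")
    m = np.array([s.mean_freq for s in summaries], dtype=float)
    sd = np.array([s.sd_freq for s in summaries], dtype=float)
    if np.ptp(m) == 0.0:
        raise ValueError("all mean frequencies identical: degenerate design")
    lin = np.polyfit(m, sd, 1)
    quad = np.polyfit(m, sd, 2)
    linear_r2 = _r_squared(sd, np.polyval(lin, m))
    quad_r2 = _r_squared(sd, np.polyval(quad, m))
    # nested least-squares models: guard the invariant against fp round-off
    quad_r2 = max(quad_r2, linear_r2)
    return SdMeanFit(
        linear_r2=linear_r2,
        quad_r2=quad_r2,
        quad_coeffs=(float(quad[0]), float(quad[1]), float(quad[2])),
        linear_coeffs=(float(lin[0]), float(lin[1])),
        n_sites=len(summaries),
    )


def rank_order_table(summaries: Sequence[SiteSummary]) -> pd.DataFrame:
    """Sites sorted by ascending mean frequency with a high-variance flag.

    Ties are broken in genome order (contig, position, strand).  The flag
    marks sites whose SD exceeds the 99th percentile of all SDs (linear
    interpolation, numpy default).
    """
    if not summaries:
        raise ValueError("rank_order_table of an empty site set")
    ordered = sorted(
        summaries, key=lambda s: (s.mean_freq, s.contig, s.position, s.strand)
    )
    sds = np.array([s.sd_freq for s in summaries], dtype=float)
    cutoff = float(np.percentile(sds, 99))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "contig": [s.contig for s in ordered],
            "position": [s.position for s in ordered],
            "strand": [s.strand for s in ordered],
            "mod_code": [s.mod_code for s in ordered],
            "mean_freq": [s.mean_freq for s in ordered],
            "min_freq": [min(s.per_replicate_freq) for s in ordered],
            "max_freq": [max(s.per_replicate_freq) for s in ordered],
            "sd_freq": [s.sd_freq for s in ordered],
            "high_variance": [s.sd_freq > cutoff for s in ordered],
        }
    )


# ---------------------------------------------------------------------------
# container helpers and summary-table I/O


def index_summaries(summaries: Iterable[SiteSummary]) -> dict[SiteKey, SiteSummary]:
    return {s.key: s for s in summaries}


def summaries_to_frame(summaries: Sequence[SiteSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [s.contig for s in summaries],
            "position": [s.position for s in summaries],
            "strand": [s.strand for s in summaries],
            "mod_code": [s.mod_code for s in summaries],
            "mean_pct": [100.0 * s.mean_freq for s in summaries],
            "sd_pct": [100.0 * s.sd_freq for s in summaries],
            "n_replicates": [s.n_replicates for s in summaries],
            "replicate_pct": [
                ",".join(repr(100.0 * f) for f in s.per_replicate_freq)
                for s in summaries
            ],
            "wga_pct": [
                "" if s.wga_freq is None else repr(100.0 * s.wga_freq)
                for s in summaries
            ],
            "corrected_pct": [
                "" if s.corrected_freq is None else repr(100.0 * s.corrected_freq)
                for s in summaries
            ],
            "wga_missing": [s.wga_missing for s in summaries],
        }
    )


def write_site_summaries(
    summaries: Sequence[SiteSummary],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    write_tsv(summaries_to_frame(summaries), path, metadata)


def read_site_summaries(path: str | Path) -> list[SiteSummary]:
    frame = read_tsv(path)
    out = []
    for row in frame.itertuples(index=False):
        reps = tuple(float(x) / 100.0 for x in str(row.replicate_pct).split(","))
        wga = None if pd.isna(row.wga_pct) or row.wga_pct == "" else float(row.wga_pct) / 100.0
        corr = (
            None
            if pd.isna(row.corrected_pct) or row.corrected_pct == ""
            else float(row.corrected_pct) / 100.0
        )
        out.append(
            SiteSummary(
                contig=str(row.contig),
                position=int(row.position),
                strand=str(row.strand),
                mod_code=str(row.mod_code),
                mean_freq=float(row.mean_pct) / 100.0,
                sd_freq=float(row.sd_pct) / 100.0,
                n_replicates=int(row.n_replicates),
                per_replicate_freq=reps,
                wga_freq=wga,
                corrected_freq=corr,
                wga_missing=bool(row.wga_missing),
            )
        )
    return out
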