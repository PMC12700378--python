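"""Nucleotide context around highly methylated sites.

Base-composition profiles in a window around "anchor" sites (highly
methylated positions), composition as a function of the minimum-frequency
threshold, and co-methylation profiles (mean frequency of neighbouring
adenine sites by signed offset and relative strand).

Offsets are strand-relative: negative offsets lie 5' of the anchor on the
anchor's own strand, so a minus-strand anchor reads the reverse complement
of the plus-strand sequence.  Anchors too close to a contig end are dropped
rather than zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GenomeSequence, MOD_BASE
from .site_stats import SiteSummary

__all__ = [
    "ContextProfile",
    "composition_around",
    "composition_vs_threshold",
    "comethylation_profile",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ContextProfile:
    """Per-offset base proportions around anchor sites.

    ``table`` has one row per offset (-k..k without 0) and one column per
    base; rows sum to 1 over A/C/G/T (genome N characters are excluded).
    """

    table: pd.DataFrame
    anchor_threshold: float
    n_anchors: int
    n_edge_skipped: int


def _genomes_map(
    genome: GenomeSequence | Mapping[str, GenomeSequence]
) -> Mapping[str, GenomeSequence]:
    if isinstance(genome, GenomeSequence):
        return {genome.contig_id: genome}
    return genome


def _select_anchors(
    summaries: Sequence[SiteSummary],
    threshold: float,
    mod_code: str | None,
    strict: bool,
    freq_attr: str,
) -> list[SiteSummary]:
    out = []
    for s in summaries:
        if mod_code is not None and s.mod_code != mod_code:
            continue
        value = getattr(s, freq_attr)
        if (value > threshold) if strict else (value >= threshold):
            out.append(s)
    return out


def composition_around(
    genome: GenomeSequence | Mapping[str, GenomeSequence],
    summaries: Sequence[SiteSummary],
    anchor_threshold: float,
    flank: int = 5,
    mod_code: str | None = "6mA",
    strict: bool = True,
    freq_attr: str = "mean_freq",
) -> ContextProfile:
    """Base proportions at each offset around highly methylated anchors.

    Anchor selection is strictly greater than the threshold by default,
    matching the ">80% for 6mA and >50% for 5mC" convention (unlike the
    inclusive 70% methylation-fraction threshold).
    """
    genomes = _genomes_map(genome)
    anchors = _select_anchors(summaries, anchor_threshold, mod_code, strict, freq_attr)
    if not anchors:
        raise ValueError("no anchor sites above the threshold")
    offsets = [d for d in range(-flank, flank + 1) if d != 0]
    counts = {d: {b: 0 for b in BASES} for d in offsets}
    n_used = 0
    n_edge = 0
    for anchor in anchors:
        seq = genomes[anchor.contig].sequence
        pos = anchor.position
        if pos - flank < 0 or pos + flank >= len(seq):
            n_edge += 1
            continue
        n_used += 1
        for d in offsets:
            if anchor.strand == "+":
                base = seq[pos + d]
            else:
                base = _COMPLEMENT[seq[pos - d]]
            if base in counts[d]:
                counts[d][base] += 1
    if n_used == 0:
        raise ValueError("all anchor sites fall within a flank of a contig end")
    rows = []
    for d in offsets:
        total = sum(counts[d].values())
        rows.append(
            {
                "offset": d,
                **{b: (counts[d][b] / total if total else float("nan")) for b in BASES},
                "n": total,
            }
        )
    return ContextProfile(
        table=pd.DataFrame(rows),
        anchor_threshold=anchor_threshold,
        n_anchors=n_used,
        n_edge_skipped=n_edge,
    )


def composition_vs_threshold(
    genome: GenomeSequence | Mapping[str, GenomeSequence],
    summaries: Sequence[SiteSummary],
    offsets: Sequence[int],
    thresholds: Sequence[float],
    mod_code: str | None = "6mA",
    freq_attr: str = "mean_freq",
) -> pd.DataFrame:
    """Long-form table of base proportion by (threshold, offset, base).

    At each threshold t the anchors are the sites with frequency >= t
    (inclusive, so t = 0 reproduces the all-site background).  Thresholds
    must be ascending; thresholds that leave no usable anchors still emit
    rows, flagged with n = 0.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    if any(d == 0 for d in offsets):
        raise ValueError("offset 0 is the anchor itself")
    genomes = _genomes_map(genome)
    flank = max(abs(int(d)) for d in offsets)
    rows = []
    for t in thresholds:
        anchors = _select_anchors(summaries, t, mod_code, False, freq_attr)
        counts = {d: {b: 0 for b in BASES} for d in offsets}
        n_used = 0
        for anchor in anchors:
            seq = genomes[anchor.contig].sequence
            pos = anchor.position
            if pos - flank < 0 or pos + flank >= len(seq):
                continue
            n_used += 1
            for d in offsets:
                base = seq[pos + d] if anchor.strand == "+" else _COMPLEMENT[seq[pos - d]]
                if base in counts[d]:
                    counts[d][base] += 1
        for d in offsets:
            total = sum(counts[d].values())
            for b in BASES:
                rows.append(
                    {
                        "threshold": t,
                        "offset": d,
                        "base": b,
                        "proportion": counts[d][b] / total if total else float("nan"),
                        "n": total,
                    }
                )
    return pd.DataFrame(rows)


def comethylation_profile(
    summaries: Sequence[SiteSummary],
    anchor_threshold: float = 0.80,
    window: int = 10,
    mod_code: str = "6mA",
    strict: bool = True,
    freq_attr: str = "mean_freq",
) -> pd.DataFrame:
    """Mean neighbour-site frequency by offset and relative strand.

    For each anchor (frequency > ``anchor_threshold``) and each offset in
    -window..window (excluding 0, measured 5'->3' along the anchor's
    strand), the frequencies of same-strand and opposite-strand sites of
    the same modification type at that offset are averaged.  Offsets with
    no such sites are reported as missing (NaN), never as 0.
    """
    anchors = _select_anchors(summaries, anchor_threshold, mod_code, strict, freq_attr)
    if not anchors:
        raise ValueError("no anchor sites above the threshold")
    lookup: dict[tuple[str, str], dict[int, float]] = {}
    for s in summaries:
        if s.mod_code == mod_code:
            lookup.setdefault((s.contig, s.strand), {})[s.position] = getattr(
                s, freq_attr
            )
    offsets = [d for d in range(-window, window + 1) if d != 0]
    values: dict[tuple[int, str], list[float]] = {
        (d, rel): [] for d in offsets for rel in ("same", "opposite")
    }
    for anchor in anchors:
        sign = 1 if anchor.strand == "+" else -1
        other = "-" if anchor.strand == "+" else "+"
        for d in offsets:
            pos = anchor.position + sign * d
            same = lookup.get((anchor.contig, anchor.strand), {}).get(pos)
            if same is not None:
                values[(d, "same")].append(same)
            opp = lookup.get((anchor.contig, other), {}).get(pos)
            if opp is not None:
                values[(d, "opposite")].append(opp)
    rows = []
    for d in offsets:
        row = {"offset": d, "n_anchors": len(anchors)}
        for rel in ("same", "opposite"):
            vals = values[(d, rel)]
            row[f"{rel}_mean"] = float(np.mean(vals)) if vals else float("nan")
            row[f"{rel}_n"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows)
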