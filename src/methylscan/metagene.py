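"""Strand-aware metagene methylation profiles.

Each gene body is normalized into a fixed number of bins (default 10,
boundaries floor(i*L/10)) and the 1 kb flanks are divided into fixed 50 bp
windows, 20 per side.  Regions are oriented along the coding strand:
U1..U20 run 5'->3' toward the gene start (U20 is the window immediately
upstream), B1..B10 span the body 5'->3', and D1..D20 run away from the
gene end.  Site frequencies are averaged per gene first; the profile then
reports the median across genes with a seeded bootstrap 95% CI.

``sense`` collects sites on the coding strand, ``antisense`` the opposite.
Overlapping genes each receive their own copy of shared sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .formats import GeneFeature, GenomeSequence
from .site_stats import SiteSummary

__all__ = [
    "MetageneProfile",
    "region_names",
    "build_profile",
    "upstream_window_test",
    "body_bin_contrast",
]

REL_STRANDS = ("sense", "antisense")


def region_names(flank_windows: int = 20, body_bins: int = 10) -> list[str]:
    return (
        [f"U{i}" for i in range(1, flank_windows + 1)]
        + [f"B{i}" for i in range(1, body_bins + 1)]
        + [f"D{i}" for i in range(1, flank_windows + 1)]
    )


@dataclass(frozen=True)
class MetageneProfile:
    """Median/CI profile plus the per-gene region means behind it."""

    table: pd.DataFrame  # region, rel_strand, median, ci_lo, ci_hi, mean, n_genes, n_sites
    per_gene: pd.DataFrame  # genes x MultiIndex (region, rel_strand); NaN = no sites
    regions: tuple[str, ...]
    n_genes_used: int
    n_genes_excluded: int


def _gene_region_intervals(
    gene: GeneFeature, flank: int, window: int, body_bins: int
) -> list[tuple[str, int, int]]:
    """(region, start, end) intervals in plus-strand coordinates."""
    s, e, length = gene.start, gene.end, gene.length
    n_win = flank // window
    out = []
    body_bounds = [s + (i * length) // body_bins for i in range(body_bins + 1)]
    if gene.strand == "+":
        for i in range(1, n_win + 1):  # U1 farthest, U20 adjacent
            out.append((f"U{i}", s - flank + (i - 1) * window, s - flank + i * window))
        for i in range(1, body_bins + 1):
            out.append((f"B{i}", body_bounds[i - 1], body_bounds[i]))
        for i in range(1, n_win + 1):  # D1 adjacent, D20 farthest
            out.append((f"D{i}", e + (i - 1) * window, e + i * window))
    else:
        for i in range(1, n_win + 1):
            out.append((f"U{i}", e + flank - i * window, e + flank - (i - 1) * window))
        for i in range(1, body_bins + 1):
            # B1 is the 5' end of a minus-strand gene, i.e. nearest e
            out.append((f"B{i}", e - body_bounds[i] + s, e - body_bounds[i - 1] + s))
        for i in range(1, n_win + 1):
            out.append((f"D{i}", s - i * window, s - (i - 1) * window))
    return out


def build_profile(
    genes: Sequence[GeneFeature],
    summaries: Sequence[SiteSummary],
    contig_lengths: Mapping[str, int],
    flank: int = 1000,
    window: int = 50,
    body_bins: int = 10,
    mod_code: str = "6mA",
    n_bootstrap: int = 1000,
    seed: int = 0,
    freq_attr: str = "mean_freq",
) -> MetageneProfile:
    """Metagene profile over gene bodies and flanks.

    Flank windows falling off a contig end are truncated (empty windows
    yield NaN for that gene); genes shorter than ``body_bins`` are excluded
    and counted.  The bootstrap CI resamples genes, seeded for
    reproducibility.
    """
    if flank % window:
        raise ValueError("flank must be a multiple of the window size")
    regions = tuple(region_names(flank // window, body_bins))
    # sorted position/frequency arrays per (contig, absolute strand)
    by_strand: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for s in summaries:
        if s.mod_code == mod_code:
            grouped.setdefault((s.contig, s.strand), []).append(
                (s.position, getattr(s, freq_attr))
            )
    for key, pairs in grouped.items():
        pairs.sort()
        pos = np.array([p for p, _ in pairs], dtype=np.int64)
        freq = np.array([f for _, f in pairs], dtype=float)
        by_strand[key] = (pos, freq)

    usable = [g for g in genes if g.length >= body_bins]
    n_excluded = len(genes) - len(usable)
    columns = pd.MultiIndex.from_tuples(
        itertools.product(regions, REL_STRANDS), names=["region", "rel_strand"]
    )
    data = np.full((len(usable), len(columns)), np.nan)
    site_counts = np.zeros(len(columns), dtype=np.int64)
    col_index = {key: i for i, key in enumerate(columns)}
    for gi, gene in enumerate(usable):
        contig_len = contig_lengths[gene.contig]
        for region, a, b in _gene_region_intervals(gene, flank, window, body_bins):
            a, b = max(a, 0), min(b, contig_len)
            if a >= b:
                continue
            for rel in REL_STRANDS:
                strand = (
                    gene.strand
                    if rel == "sense"
                    else ("-" if gene.strand == "+" else "+")
                )
                arrays = by_strand.get((gene.contig, strand))
                if arrays is None:
                    continue
                pos, freq = arrays
                lo, hi = np.searchsorted(pos, (a, b))
                if hi > lo:
                    ci = col_index[(region, rel)]
                    data[gi, ci] = float(freq[lo:hi].mean())
                    site_counts[ci] += hi - lo

    per_gene = pd.DataFrame(
        data, index=[g.gene_id for g in usable], columns=columns
    )
    rng = np.random.default_rng(seed)
    rows = []
    for ci, (region, rel) in enumerate(columns):
        vals = data[:, ci]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            median = float(np.median(vals))
            mean = float(vals.mean())
            idx = rng.integers(0, vals.size, size=(n_bootstrap, vals.size))
            boot = np.median(vals[idx], axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
        else:
            median = mean = lo = hi = float("nan")
        rows.append(
            {
                "region": region,
                "rel_strand": rel,
                "median": median,
                "ci_lo": float(lo),
                "ci_hi": float(hi),
                "mean": mean,
                "n_genes": int(vals.size),
                "n_sites": int(site_counts[ci]),
            }
        )
    return MetageneProfile(
        table=pd.DataFrame(rows),
        per_gene=per_gene,
        regions=regions,
        n_genes_used=len(usable),
        n_genes_excluded=n_excluded,
    )


def _letter_display(
    names: Sequence[str],
    significant: set[tuple[str, str]],
    order_stat: Mapping[str, float],
) -> dict[str, str]:
    """Compact letter display: letters are maximal cliques of the
    not-significantly-different graph, ordered by their best member."""
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        if (a, b) not in significant and (b, a) not in significant:
            graph.add_edge(a, b)
    cliques = list(nx.find_cliques(graph))
    cliques.sort(key=lambda c: (min(order_stat[m] for m in c), sorted(c)))
    letters: dict[str, list[str]] = {name: [] for name in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        letter = alphabet[i % len(alphabet)] * (i // len(alphabet) + 1)
        for member in clique:
            letters[member].append(letter)
    return {name: "".join(sorted(ls)) for name, ls in letters.items()}


def upstream_window_test(
    per_gene_windows: pd.DataFrame,
    alpha: float = 1e-4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Mann-Whitney tests across upstream windows with letters.

    ``per_gene_windows`` holds one column per window (genes as rows; NaN
    allowed).  P-values are Holm-corrected; windows that differ from one
    another at the corrected ``alpha`` never share a letter.  Returns the
    per-window letter table and the pairwise p-value table; output is
    deterministic given the input order.
    """
    names = list(per_gene_windows.columns)
    if len(names) < 2:
        raise ValueError("need at least two windows")
    pairs = list(itertools.combinations(names, 2))
    pvals = []
    for a, b in pairs:
        x = per_gene_windows[a].dropna().to_numpy()
        y = per_gene_windows[b].dropna().to_numpy()
        if x.size == 0 or y.size == 0 or (np.ptp(np.concatenate([x, y])) == 0):
            pvals.append(1.0)
        else:
            pvals.append(float(mannwhitneyu(x, y, alternative="two-sided").pvalue))
    adjusted = multipletests(pvals, method="holm")[1]
    significant = {
        pair for pair, p in zip(pairs, adjusted) if p < alpha
    }
    medians = {
        name: float(np.nanmedian(per_gene_windows[name].to_numpy()))
        for name in names
    }
    letters = _letter_display(names, significant, medians)
    pair_frame = pd.DataFrame(
        {
            "window_a": [a for a, _ in pairs],
            "window_b": [b for _, b in pairs],
            "p_value": pvals,
            "p_adjusted": adjusted,
        }
    )
    table = pd.DataFrame(
        {
            "window": names,
            "median": [medians[n] for n in names],
            "letters": [letters[n] for n in names],
            "n_significant": [
                sum(n in pair for pair in significant) for n in names
            ],
        }
    )
    return table, pair_frame


def body_bin_contrast(
    per_gene_bins: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin deviation from the across-bin grand mean with MWU p-values.

    ``per_gene_bins`` columns are a MultiIndex (bin, rel_strand).  Each bin
    is compared against the pooled values of the other bins on the same
    strand; p-values are Holm-adjusted over all bins and strands.
    """
    columns = list(per_gene_bins.columns)
    strands = sorted({rel for _, rel in columns})
    rows = []
    pvals = []
    for rel in strands:
        cols = [c for c in columns if c[1] == rel]
        bin_means = {
            c: float(np.nanmean(per_gene_bins[c].to_numpy())) for c in cols
        }
        grand = float(np.mean(list(bin_means.values())))
        for c in cols:
            own = per_gene_bins[c].dropna().to_numpy()
            others = np.concatenate(
                [per_gene_bins[o].dropna().to_numpy() for o in cols if o != c]
            )
            if own.size == 0 or others.size == 0 or np.ptp(
                np.concatenate([own, others])
            ) == 0:
                p = 1.0
            else:
                p = float(mannwhitneyu(own, others, alternative="two-sided").pvalue)
            pvals.append(p)
            rows.append(
                {
                    "bin": c[0],
                    "rel_strand": rel,
                    "mean": bin_means[c],
                    "difference": bin_means[c] - grand,
                    "p_value": p,
                }
            )
    adjusted = multipletests(pvals, method="holm")[1]
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = adjusted
    frame["significant"] = frame["p_adjusted"] < alpha
    return frame
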