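"""IUPAC methylation motifs: scanning, summaries, palindromes, discovery.

A motif is a degenerate IUPAC string together with the index of the
methylated base (the adenine for 6mA, the cytosine for 5mC), always written
5'->3' on the methylated strand.  Scanning reports every occurrence on both
strands, including overlapping ones; a palindromic motif (equal to its own
reverse IUPAC complement) yields a plus and a minus methylated base per
occurrence, which supports full-/hemi-methylation calling.

The module also provides a simplified de-novo motif discovery stage (greedy
generalization over flanking k-mers of highly methylated sites) and an
in-silico methylation-sensitive restriction digest.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GenomeSequence, MOD_BASE, read_tsv
from .site_stats import SiteKey, SiteSummary, genomic_methylation_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC",
    "Motif",
    "MotifSite",
    "PalindromePair",
    "MotifSummary",
    "EnzymeSpec",
    "ENZYMES",
    "MOTIF_CATALOGUE",
    "reverse_complement_iupac",
    "scan_motif",
    "summarize_motif",
    "pair_palindrome_sites",
    "classify_palindrome",
    "palindrome_proportions",
    "assign_sites",
    "capture_stats",
    "in_silico_digest",
    "DigestResult",
    "discover_motifs",
    "DiscoveredMotif",
    "read_motif_config",
]

#: IUPAC degenerate nucleotide codes and their base expansions.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: two-letter ambiguity codes, the only degeneracy (besides N) produced by
#: motif discovery; matches the codes seen in published motif catalogues.
TWO_LETTER_CODES = ("K", "M", "R", "S", "W", "Y")


def reverse_complement_iupac(iupac: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(iupac))


def _iupac_regex(iupac: str) -> re.Pattern[str]:
    # lookahead so overlapping occurrences are all reported; genome N never
    # matches because expansions only contain A/C/G/T
    return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in iupac) + ")")


@dataclass(frozen=True)
class Motif:
    """An IUPAC motif with the 0-based index of its methylated base."""

    iupac: str
    mod_offset: int
    mod_code: str = "6mA"
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.iupac or any(c not in IUPAC for c in self.iupac):
            raise ValueError(f"invalid IUPAC motif {self.iupac!r}")
        if not 0 <= self.mod_offset < len(self.iupac):
            raise ValueError(
                f"mod_offset {self.mod_offset} outside motif {self.iupac!r}"
            )
        base = MOD_BASE[self.mod_code]
        if base not in IUPAC[self.iupac[self.mod_offset]]:
            raise ValueError(
                f"{self.iupac!r} position {self.mod_offset} cannot be {base}"
            )

    @property
    def motif_id(self) -> str:
        return self.name or self.iupac

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement_iupac(self.iupac) == self.iupac

    def canonical(self) -> "Motif":
        """Deterministic representative among (motif, reverse complement).

        The lexicographically smaller string wins, but only when the swapped
        representation still carries the modified base type at the remapped
        offset (always true for palindromes; a motif is otherwise already
        written on its methylated strand).
        """
        rc = reverse_complement_iupac(self.iupac)
        if rc < self.iupac:
            offset = len(self.iupac) - 1 - self.mod_offset
            if MOD_BASE[self.mod_code] in IUPAC[rc[offset]]:
                return Motif(rc, offset, self.mod_code, self.name)
        return self


@dataclass(frozen=True)
class MotifSite:
    """A genomic occurrence of a motif's methylated base."""

    motif_id: str
    contig: str
    match_start: int  # plus-strand coordinate of the leftmost matched base
    strand: str
    mod_position: int  # plus-strand coordinate of the methylated base

    def summary_key(self, mod_code: str) -> SiteKey:
        return (self.contig, self.mod_position, self.strand, mod_code)


@dataclass(frozen=True)
class PalindromePair:
    """Plus/minus methylated bases of one palindromic motif occurrence."""

    motif_id: str
    contig: str
    match_start: int
    plus_site: MotifSite
    minus_site: MotifSite


@dataclass(frozen=True)
class MotifSummary:
    motif_id: str
    n_sites: int
    n_unjoined: int
    mean_freq: float
    genomic_methylation_fraction: float
    threshold: float


def scan_motif(genome: GenomeSequence, motif: Motif) -> list[MotifSite]:
    """All occurrences of a motif on both strands of one contig.

    Plus-strand matches of the IUPAC pattern are reported as strand "+",
    plus-strand matches of its reverse IUPAC complement as strand "-".  The
    methylated-base coordinate follows the strand convention: ``match_start
    + mod_offset`` on the plus strand and ``match_start + (len - 1 -
    mod_offset)`` on the minus strand.  Overlapping matches are all
    reported; N in the genome never matches.
    """
    seq = genome.sequence
    k = len(motif.iupac)
    sites: list[MotifSite] = []
    for start in (m.start() for m in _iupac_regex(motif.iupac).finditer(seq)):
        sites.append(
            MotifSite(
                motif.motif_id, genome.contig_id, start, "+", start + motif.mod_offset
            )
        )
    rc = reverse_complement_iupac(motif.iupac)
    for start in (m.start() for m in _iupac_regex(rc).finditer(seq)):
        sites.append(
            MotifSite(
                motif.motif_id,
                genome.contig_id,
                start,
                "-",
                start + k - 1 - motif.mod_offset,
            )
        )
    sites.sort(key=lambda s: (s.match_start, s.strand))
    return sites


def summarize_motif(
    motif: Motif,
    sites: Sequence[MotifSite],
    summaries: Mapping[SiteKey, SiteSummary],
    threshold: float = 0.70,
    freq_attr: str = "mean_freq",
) -> MotifSummary:
    """Unweighted mean frequency and methylation fraction over motif sites.

    Sites lacking a joined summary (no coverage) are counted but excluded;
    zero joined sites is an error.
    """
    freqs = []
    unjoined = 0
    for site in sites:
        summary = summaries.get(site.summary_key(motif.mod_code))
        if summary is None:
            unjoined += 1
        else:
            freqs.append(getattr(summary, freq_attr))
    if not freqs:
        raise ValueError(f"motif {motif.motif_id}: no sites joined to summaries")
    return MotifSummary(
        motif_id=motif.motif_id,
        n_sites=len(freqs),
        n_unjoined=unjoined,
        mean_freq=float(np.mean(freqs)),
        genomic_methylation_fraction=genomic_methylation_fraction(freqs, threshold),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# palindromes


def pair_palindrome_sites(
    motif: Motif, sites: Sequence[MotifSite]
) -> tuple[list[PalindromePair], list[MotifSite]]:
    """Pair plus/minus methylated bases of each palindromic occurrence.

    Returns (pairs, unpaired).  Every (contig, match_start) should carry
    exactly one site per strand; stragglers (e.g. pre-filtered inputs) are
    returned unpaired.  Calling this on a non-palindromic motif is an error.
    """
    if not motif.is_palindromic:
        raise ValueError(f"motif {motif.iupac!r} is not palindromic")
    grouped: dict[tuple[str, int], dict[str, MotifSite]] = defaultdict(dict)
    unpaired: list[MotifSite] = []
    for site in sites:
        slot = grouped[(site.contig, site.match_start)]
        if site.strand in slot:
            raise ValueError(
                f"duplicate {site.strand} site at {site.contig}:{site.match_start}"
            )
        slot[site.strand] = site
    pairs: list[PalindromePair] = []
    for (contig, start) in sorted(grouped):
        slot = grouped[(contig, start)]
        if "+" in slot and "-" in slot:
            pairs.append(
                PalindromePair(motif.motif_id, contig, start, slot["+"], slot["-"])
            )
        else:
            unpaired.extend(slot.values())
    return pairs, unpaired


def classify_palindrome(
    pair: PalindromePair,
    summaries: Mapping[SiteKey, SiteSummary],
    threshold: float = 0.70,
    mod_code: str = "6mA",
    freq_attr: str = "mean_freq",
) -> str | None:
    """"full" if both strands reach the threshold, "hemi" if exactly one,
    "unmethylated" otherwise; None when either strand lacks a summary."""
    plus = summaries.get(pair.plus_site.summary_key(mod_code))
    minus = summaries.get(pair.minus_site.summary_key(mod_code))
    if plus is None or minus is None:
        return None
    above = (getattr(plus, freq_attr) >= threshold) + (
        getattr(minus, freq_attr) >= threshold
    )
    return {2: "full", 1: "hemi", 0: "unmethylated"}[above]


@dataclass(frozen=True)
class PalindromeCallSummary:
    motif_id: str
    threshold: float
    n_pairs: int
    n_excluded: int
    proportions: dict[str, float]
    replicate_mean: dict[str, float]
    replicate_sd: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        classes = ["full", "hemi", "unmethylated"]
        return pd.DataFrame(
            {
                "motif_id": self.motif_id,
                "call": classes,
                "proportion": [self.proportions[c] for c in classes],
                "replicate_mean": [self.replicate_mean[c] for c in classes],
                "replicate_sd": [self.replicate_sd[c] for c in classes],
                "n_pairs": self.n_pairs,
            }
        )


def palindrome_proportions(
    pairs: Sequence[PalindromePair],
    summaries: Mapping[SiteKey, SiteSummary],
    threshold: float = 0.70,
    mod_code: str = "6mA",
) -> PalindromeCallSummary:
    """Proportions of full/hemi/unmethylated calls with per-replicate SD.

    The pooled proportions use replicate-mean frequencies; in addition the
    calls are recomputed within each replicate and the per-class proportion
    mean and sample SD across replicates reported.
    """
    classes = ("full", "hemi", "unmethylated")
    calls = []
    kept_pairs = []
    n_excluded = 0
    for pair in pairs:
        call = classify_palindrome(pair, summaries, threshold, mod_code)
        if call is None:
            n_excluded += 1
        else:
            calls.append(call)
            kept_pairs.append(pair)
    if not calls:
        raise ValueError("no palindrome pairs with summaries on both strands")
    counts = Counter(calls)
    proportions = {c: counts.get(c, 0) / len(calls) for c in classes}

    n_reps = min(
        min(
            summaries[p.plus_site.summary_key(mod_code)].n_replicates,
            summaries[p.minus_site.summary_key(mod_code)].n_replicates,
        )
        for p in kept_pairs
    )
    per_rep = np.zeros((n_reps, 3))
    for r in range(n_reps):
        rep_counts = Counter()
        for pair in kept_pairs:
            plus = summaries[pair.plus_site.summary_key(mod_code)]
            minus = summaries[pair.minus_site.summary_key(mod_code)]
            above = (plus.per_replicate_freq[r] >= threshold) + (
                minus.per_replicate_freq[r] >= threshold
            )
            rep_counts[classes[2 - above]] += 1
        for i, c in enumerate(classes):
            per_rep[r, i] = rep_counts.get(c, 0) / len(kept_pairs)
    rep_mean = {c: float(per_rep[:, i].mean()) for i, c in enumerate(classes)}
    rep_sd = {
        c: float(per_rep[:, i].std(ddof=1)) if n_reps > 1 else 0.0
        for i, c in enumerate(classes)
    }
    motif_id = pairs[0].motif_id if pairs else ""
    return PalindromeCallSummary(
        motif_id=motif_id,
        threshold=threshold,
        n_pairs=len(calls),
        n_excluded=n_excluded,
        proportions=proportions,
        replicate_mean=rep_mean,
        replicate_sd=rep_sd,
    )


# ---------------------------------------------------------------------------
# site labelling


def assign_sites(
    summaries: Sequence[SiteSummary],
    motifs: Sequence[Motif],
    genome: GenomeSequence | Mapping[str, GenomeSequence],
) -> pd.DataFrame:
    """Label every summarized site with all motifs covering it.

    A site is covered by a motif when it is the methylated base of one of
    the motif's occurrences (same contig, position, strand, mod type); a
    site may carry several labels, or "non-motif" if none apply.
    """
    genomes = (
        {genome.contig_id: genome} if isinstance(genome, GenomeSequence) else genome
    )
    labels: dict[SiteKey, list[str]] = defaultdict(list)
    for motif in motifs:
        for g in genomes.values():
            for site in scan_motif(g, motif):
                labels[site.summary_key(motif.mod_code)].append(motif.motif_id)
    rows = []
    for s in summaries:
        ids = sorted(set(labels.get(s.key, [])))
        rows.append(
            {
                "contig": s.contig,
                "position": s.position,
                "strand": s.strand,
                "mod_code": s.mod_code,
                "mean_freq": s.mean_freq,
                "motifs": ";".join(ids) if ids else "non-motif",
                "is_motif": bool(ids),
            }
        )
    return pd.DataFrame(rows)


def capture_stats(
    assigned: pd.DataFrame, thresholds: Sequence[float] = (0.50, 0.70)
) -> pd.DataFrame:
    """Fraction of sites above each frequency threshold captured by >=1 motif."""
    rows = []
    for t in thresholds:
        high = assigned[assigned["mean_freq"] >= t]
        rows.append(
            {
                "threshold": t,
                "n_high_sites": len(high),
                "n_motif_labeled": int(high["is_motif"].sum()),
                "captured_fraction": (
                    float(high["is_motif"].mean()) if len(high) else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# in-silico methylation-sensitive digest


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme with optional 6mA sensitivity.

    ``blocked_by_6mA`` enzymes cut only when the sensitive adenine is below
    the threshold on both strands; ``requires_6mA`` enzymes cut when either
    strand reaches it; ``insensitive`` enzymes always cut.
    """

    name: str
    recognition: str
    sensitivity: str  # blocked_by_6mA | requires_6mA | insensitive
    sensitive_offset: int = 0

    def __post_init__(self) -> None:
        if self.sensitivity not in ("blocked_by_6mA", "requires_6mA", "insensitive"):
            raise ValueError(f"unknown sensitivity {self.sensitivity!r}")
        if self.sensitivity != "insensitive":
            if "A" not in IUPAC[self.recognition[self.sensitive_offset]]:
                raise ValueError(
                    f"{self.name}: sensitive position is not an adenine"
                )


ENZYMES: dict[str, EnzymeSpec] = {
    "Hpy166II": EnzymeSpec("Hpy166II", "GTNNAC", "insensitive", 4),
    "XhoI": EnzymeSpec("XhoI", "CTCGAG", "blocked_by_6mA", 4),
    "XbaI": EnzymeSpec("XbaI", "TCTAGA", "blocked_by_6mA", 3),
    "DpnI": EnzymeSpec("DpnI", "GATC", "requires_6mA", 1),
    "DpnII": EnzymeSpec("DpnII", "GATC", "blocked_by_6mA", 1),
}


@dataclass(frozen=True)
class DigestResult:
    enzyme: str
    fragments: tuple[int, ...]  # sorted ascending, summing to genome length
    cut_positions: tuple[int, ...]
    n_sites: int

    @property
    def n_cuts(self) -> int:
        return len(self.cut_positions)


def in_silico_digest(
    genome: GenomeSequence,
    summaries: Mapping[SiteKey, SiteSummary],
    enzyme: EnzymeSpec,
    threshold: float = 0.70,
    freq_attr: str = "mean_freq",
) -> DigestResult:
    """Digest a linear genome respecting per-site 6mA methylation state.

    The sensitive adenine of each recognition occurrence is looked up on
    both strands (a site absent from the pileup counts as unmethylated);
    the occurrence is cut or protected according to the enzyme's
    sensitivity.  Fragment lengths always sum to the genome length.
    """
    k = len(enzyme.recognition)
    occurrences = [
        m.start() for m in _iupac_regex(enzyme.recognition).finditer(genome.sequence)
    ]
    cuts = []
    for start in occurrences:
        if enzyme.sensitivity == "insensitive":
            cuts.append(start)
            continue
        plus_pos = start + enzyme.sensitive_offset
        minus_pos = start + k - 1 - enzyme.sensitive_offset
        freqs = []
        for pos, strand in ((plus_pos, "+"), (minus_pos, "-")):
            summary = summaries.get((genome.contig_id, pos, strand, "6mA"))
            freqs.append(0.0 if summary is None else getattr(summary, freq_attr))
        methylated = max(freqs) >= threshold
        if enzyme.sensitivity == "requires_6mA" and methylated:
            cuts.append(start)
        elif enzyme.sensitivity == "blocked_by_6mA" and not methylated:
            cuts.append(start)
    boundaries = sorted(set([0, *cuts, len(genome)]))
    fragments = tuple(
        sorted(b - a for a, b in zip(boundaries, boundaries[1:]) if b > a)
    )
    return DigestResult(
        enzyme=enzyme.name,
        fragments=fragments,
        cut_positions=tuple(sorted(set(cuts))),
        n_sites=len(occurrences),
    )


# ---------------------------------------------------------------------------
# built-in catalogue (the methylated adenine shared with the CTAG/CTNAG core)

MOTIF_CATALOGUE: tuple[Motif, ...] = (
    Motif("CTAG", 2),
    Motif("CTAGY", 2),
    Motif("CTNAG", 3),
    Motif("TTCTNAG", 5),
    Motif("CTAAG", 3),
    Motif("CTNNAG", 4),
    Motif("CYTAGC", 3),
    Motif("GTNNAC", 4),
    Motif("TGNNCA", 5),
)


def read_motif_config(path: str | Path) -> list[Motif]:
    """Read a motif set from TSV (iupac, mod_offset[, mod_code[, name]])."""
    frame = read_tsv(path)
    motifs = []
    for row in frame.itertuples(index=False):
        motifs.append(
            Motif(
                iupac=str(row.iupac),
                mod_offset=int(row.mod_offset),
                mod_code=str(getattr(row, "mod_code", "6mA")),
                name=str(row.name) if getattr(row, "name", None) else None,
            )
        )
    return motifs


# ---------------------------------------------------------------------------
# de-novo discovery


@dataclass(frozen=True)
class DiscoveredMotif:
    motif: Motif
    n_sites: int
    mean_freq: float
    genomic_methylation_fraction: float
    anchor_support: int


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class _KmerIndex:
    """Exact k-mer -> plus-strand position lookup over one contig.

    Backs candidate evaluation during discovery: gathering the occurrence
    positions of a specific k-mer (and of each expansion of a degenerate
    motif) is a pair of binary searches instead of a regex scan, which keeps
    the greedy generalization loop fast.  Windows containing N are excluded,
    matching scan semantics.
    """

    def __init__(self, genome: GenomeSequence, kmin: int, kmax: int) -> None:
        lut = np.full(256, -1, dtype=np.int64)
        for base, code in _BASE_CODE.items():
            lut[ord(base)] = code
        self.base = lut[np.frombuffer(genome.sequence.encode(), dtype=np.uint8)]
        self.length = len(genome.sequence)
        self._tables: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for k in range(kmin, kmax + 1):
            n = self.length - k + 1
            if n <= 0:
                continue
            ids = np.zeros(n, dtype=np.int64)
            ok = np.ones(n, dtype=bool)
            for j in range(k):
                window = self.base[j : j + n]
                ok &= window >= 0
                ids = ids * 4 + np.where(window >= 0, window, 0)
            ids = np.where(ok, ids, -1)
            order = np.argsort(ids, kind="stable")
            self._tables[k] = (ids[order], order.astype(np.int64))

    def positions(self, kmer: str) -> np.ndarray:
        k = len(kmer)
        if k not in self._tables:
            return np.empty(0, dtype=np.int64)
        value = 0
        for c in kmer:
            value = value * 4 + _BASE_CODE[c]
        ids_sorted, order = self._tables[k]
        lo = np.searchsorted(ids_sorted, value, side="left")
        hi = np.searchsorted(ids_sorted, value, side="right")
        return order[lo:hi]


class _Evaluation:
    """Scored site set of one candidate; key set materialized lazily."""

    __slots__ = ("n_sites", "mean_freq", "fraction", "_plus", "_minus", "_keys")

    def __init__(
        self,
        n_sites: int,
        mean_freq: float,
        fraction: float,
        plus: np.ndarray,
        minus: np.ndarray,
    ) -> None:
        self.n_sites = n_sites
        self.mean_freq = mean_freq
        self.fraction = fraction
        self._plus = plus
        self._minus = minus
        self._keys: frozenset[tuple[int, int]] | None = None

    @property
    def site_keys(self) -> frozenset[tuple[int, int]]:
        if self._keys is None:
            self._keys = frozenset(
                [(int(p), 0) for p in self._plus] + [(int(p), 1) for p in self._minus]
            )
        return self._keys


class _CandidateScorer:
    def __init__(
        self,
        genome: GenomeSequence,
        summaries: Sequence[SiteSummary],
        kmin: int,
        kmax: int,
        threshold: float,
        max_expansions: int = 4096,
    ) -> None:
        self.index = _KmerIndex(genome, kmin, kmax)
        self.threshold = threshold
        self.max_expansions = max_expansions
        self.freq = {
            "+": np.full(self.index.length, np.nan),
            "-": np.full(self.index.length, np.nan),
        }
        for s in summaries:
            if s.contig == genome.contig_id:
                self.freq[s.strand][s.position] = s.mean_freq
        self._cache: dict[tuple[str, int], _Evaluation | None] = {}

    def evaluate(self, iupac: str, mod_offset: int) -> _Evaluation | None:
        key = (iupac, mod_offset)
        if key in self._cache:
            return self._cache[key]
        expansion_sets = [IUPAC[c] for c in iupac]
        n_exp = int(np.prod([len(s) for s in expansion_sets]))
        if n_exp > self.max_expansions:
            self._cache[key] = None
            return None
        k = len(iupac)
        plus_chunks, minus_chunks = [], []
        for bases in itertools.product(*expansion_sets):
            kmer = "".join(bases)
            plus_chunks.append(self.index.positions(kmer) + mod_offset)
            rc = reverse_complement_iupac(kmer)
            minus_chunks.append(self.index.positions(rc) + (k - 1 - mod_offset))
        plus = np.concatenate(plus_chunks) if plus_chunks else np.empty(0, np.int64)
        minus = np.concatenate(minus_chunks) if minus_chunks else np.empty(0, np.int64)
        plus_mask = ~np.isnan(self.freq["+"][plus])
        minus_mask = ~np.isnan(self.freq["-"][minus])
        plus, minus = plus[plus_mask], minus[minus_mask]
        values = np.concatenate([self.freq["+"][plus], self.freq["-"][minus]])
        if values.size == 0:
            result = _Evaluation(0, float("nan"), float("nan"), plus, minus)
        else:
            result = _Evaluation(
                n_sites=int(values.size),
                mean_freq=float(values.mean()),
                fraction=float((values >= self.threshold).mean()),
                plus=plus,
                minus=minus,
            )
        self._cache[key] = result
        return result


def _anchor_windows(
    genome: GenomeSequence,
    anchors: Sequence[tuple[int, str]],
    kmin: int,
    kmax: int,
) -> Counter:
    """Count specific (window sequence, mod offset) contexts around anchors.

    Windows are read 5'->3' on the anchor's strand, so a minus-strand anchor
    contributes the reverse complement of the plus-strand slice.
    """
    seq = genome.sequence
    length = len(seq)
    counts: Counter = Counter()
    for pos, strand in anchors:
        for k in range(kmin, kmax + 1):
            for off in range(k):
                if strand == "+":
                    start = pos - off
                    if start < 0 or start + k > length:
                        continue
                    window = seq[start : start + k]
                else:
                    start = pos - (k - 1 - off)
                    if start < 0 or start + k > length:
                        continue
                    window = reverse_complement_iupac(seq[start : start + k])
                if "N" in window:
                    continue
                counts[(window, off)] += 1
    return counts


def _trim_flanking_n(iupac: str, mod_offset: int) -> tuple[str, int]:
    while iupac.startswith("N") and mod_offset > 0:
        iupac, mod_offset = iupac[1:], mod_offset - 1
    while iupac.endswith("N") and mod_offset < len(iupac) - 1:
        iupac = iupac[:-1]
    return iupac, mod_offset


def discover_motifs(
    genome: GenomeSequence,
    summaries: Sequence[SiteSummary],
    mod_code: str = "6mA",
    kmin: int = 4,
    kmax: int = 8,
    min_mean: float = 0.5,
    min_sites: int = 20,
    anchor_threshold: float = 0.70,
    min_anchor_support: int = 2,
    tolerance: float = 0.10,
    threshold: float = 0.70,
    generalize: bool = True,
) -> list[DiscoveredMotif]:
    """Simplified de-novo motif discovery from per-site frequencies.

    Candidate contexts of length ``kmin``..``kmax`` are enumerated around
    anchor sites (mean frequency >= ``anchor_threshold``), scored by the
    mean methylation of their full genomic site set, then greedily
    generalized position by position (N first, then two-letter codes) for
    as long as the expanded site set's mean stays within ``tolerance`` of
    the seed's.  Reported motifs satisfy ``min_mean`` and ``min_sites``,
    are canonicalized and de-duplicated (a motif whose sites are a subset
    of an equally methylated, already accepted motif is dropped), and are
    sorted by genomic methylation fraction.  No anchors means an empty
    list, not an error.
    """
    relevant = [s for s in summaries if s.mod_code == mod_code]
    anchors = [
        (s.position, s.strand)
        for s in relevant
        if s.contig == genome.contig_id and s.mean_freq >= anchor_threshold
    ]
    if not anchors:
        return []
    scorer = _CandidateScorer(genome, relevant, kmin, kmax, threshold)
    counts = _anchor_windows(genome, anchors, kmin, kmax)
    candidates = sorted(
        (
            (support, window, off)
            for (window, off), support in counts.items()
            if support >= min_anchor_support
        ),
        key=lambda item: (-item[0], item[1], item[2]),
    )
    logger.info("discovery: %d anchors, %d candidate contexts", len(anchors), len(candidates))

    accepted: list[tuple[Motif, _Evaluation, int]] = []
    seen: set[tuple[str, int]] = set()
    for support, window, off in candidates:
        seed = scorer.evaluate(window, off)
        if seed is None or seed.n_sites < min_sites or not seed.mean_freq >= min_mean:
            continue
        # skip seeds already explained by an accepted, equally methylated motif
        redundant = any(
            seed.site_keys <= ev.site_keys
            and abs(seed.mean_freq - ev.mean_freq) <= tolerance
            for _, ev, _ in accepted
        )
        if redundant:
            continue
        iupac, offset, reference = window, off, seed.mean_freq
        if generalize:
            changed = True
            passes = 0
            while changed and passes < 3:
                changed = False
                passes += 1
                for i in range(len(iupac)):
                    if i == offset:
                        continue
                    current = iupac[i]
                    trial_codes = ["N"] + [
                        c for c in TWO_LETTER_CODES if set(IUPAC[current]) <= set(IUPAC[c])
                    ]
                    for code in trial_codes:
                        if code == current:
                            continue
                        trial = iupac[:i] + code + iupac[i + 1 :]
                        ev = scorer.evaluate(trial, offset)
                        if ev is not None and abs(ev.mean_freq - reference) <= tolerance:
                            iupac = trial
                            changed = True
                            break
        iupac, offset = _trim_flanking_n(iupac, offset)
        motif = Motif(iupac, offset, mod_code).canonical()
        if (motif.iupac, motif.mod_offset) in seen:
            continue
        final = scorer.evaluate(motif.iupac, motif.mod_offset)
        if final is None or final.n_sites < min_sites or not final.mean_freq >= min_mean:
            continue
        redundant = any(
            final.site_keys <= ev.site_keys
            and abs(final.mean_freq - ev.mean_freq) <= tolerance
            for _, ev, _ in accepted
        )
        if redundant:
            continue
        seen.add((motif.iupac, motif.mod_offset))
        accepted.append((motif, final, support))

    # final redundancy prune between accepted motifs, most general first
    accepted.sort(key=lambda item: (-item[1].n_sites, item[0].iupac))
    kept: list[tuple[Motif, _Evaluation, int]] = []
    for motif, ev, support in accepted:
        if any(
            ev.site_keys <= kept_ev.site_keys
            and ev.site_keys != kept_ev.site_keys
            and abs(ev.mean_freq - kept_ev.mean_freq) <= tolerance
            for _, kept_ev, _ in kept
        ):
            continue
        kept.append((motif, ev, support))

    results = [
        DiscoveredMotif(
            motif=motif,
            n_sites=ev.n_sites,
            mean_freq=ev.mean_freq,
            genomic_methylation_fraction=ev.fraction,
            anchor_support=support,
        )
        for motif, ev, support in kept
    ]
    results.sort(
        key=lambda r: (-r.genomic_methylation_fraction, -r.n_sites, r.motif.iupac)
    )
    return results
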