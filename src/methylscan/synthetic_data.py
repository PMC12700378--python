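"""Synthetic methylomes with known truth.

Generates an AaV-like genome (i.i.d. bases at a chosen GC fraction,
non-overlapping genes on both strands), plants a methylome on it (motif
sites at target probabilities, leaky ambiguous parents, promoter dips,
hypermethylated blocks, PCR-surviving artifact positions, palindrome
full/hemi mixtures) and simulates replicate bedMethyl pileups plus a
whole-genome-amplified (WGA) control that carries only a basecall error
floor.

Default study conditions: 6mA on a 29% GC genome, background per-read
methylation probability 0.03, mean depth 50, three replicates with a small
between-library jitter on the logit of p (SD 0.05), WGA floor 0.02.
Assignment precedence at conflicting positions is artifact > promoter dip >
hypermethylated block > specific motif > leaky parent > background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import (
    GeneFeature,
    GenomeSequence,
    SiteRecord,
    write_bedmethyl,
    write_fasta,
    write_gff3,
    write_tsv,
)
from .motifs import Motif, scan_motif

__all__ = [
    "PlantedMotif",
    "MethylomeSpec",
    "PlantedMethylome",
    "SyntheticDataset",
    "generate_genome",
    "plant_methylome",
    "simulate_bedmethyl",
    "simulate_methylome",
]

_ANNOTATION_POOL = (
    "DNA replication",
    "transcription",
    "virion structure",
    "nucleotide metabolism",
    "unknown function",
)


@dataclass(frozen=True)
class PlantedMotif:
    """A motif planted at per-read methylation probability ``p``.

    ``leak_parent`` optionally plants a lower probability ``leak_p`` on the
    ambiguous parent's occurrences that are NOT occurrences of this
    specific motif (the "leaky methyltransferase" structure).
    ``palindrome_mix`` instead assigns each palindromic occurrence a class
    (full, hemi, unmethylated) with the given proportions: the methylated
    strand(s) receive ``p``, the others the background.  ``correlation``
    couples the two strands' read sampling (1.0 = fully coupled).
    """

    motif: Motif
    p: float
    leak_parent: Motif | None = None
    leak_p: float | None = None
    palindrome_mix: tuple[float, float, float] | None = None
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.palindrome_mix is not None:
            if not self.motif.is_palindromic:
                raise ValueError("palindrome_mix requires a palindromic motif")
            if not math.isclose(sum(self.palindrome_mix), 1.0, abs_tol=1e-9):
                raise ValueError("palindrome_mix proportions must sum to 1")


@dataclass(frozen=True)
class MethylomeSpec:
    """Study conditions for one synthetic methylome."""

    genome_length: int = 200_000
    gc: float = 0.29
    n_genes: int = 0
    gene_length: tuple[int, int] = (600, 1500)
    gene_spacing: int = 20
    motifs: tuple[PlantedMotif, ...] = ()
    p_background: float = 0.03
    promoter_dip: tuple[int, float] | None = None  # (width bp, probability)
    artifacts: tuple[int, float] | None = None  # (n positions, probability)
    block: tuple[int, int, float] | None = None  # (start, end, probability)
    coverage_mean: float = 50.0
    n_replicates: int = 3
    replicate_jitter_sd: float = 0.05
    wga_error: float = 0.02
    mod_code: str = "6mA"
    contig_id: str = "synthetic_1"

    def __post_init__(self) -> None:
        for pm in self.motifs:
            if not self.p_background < pm.p <= 1.0:
                raise ValueError("planted p must exceed the background")
        if not 0 <= self.wga_error < 0.1:
            raise ValueError("WGA error floor must be < 0.1")


@dataclass
class PlantedMethylome:
    """Per-position true probabilities; NaN marks non-candidate bases."""

    genome: GenomeSequence
    genes: list[GeneFeature]
    p_native: dict[str, np.ndarray]  # per strand
    p_wga: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]  # per-site provenance label codes
    label_names: tuple[str, ...]
    artifact_positions: list[tuple[int, str]]
    coupled_pairs: list[tuple[int, int, float]]  # (plus pos, minus pos, corr)
    pair_classes: pd.DataFrame  # palindrome-mix occurrence truth

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for strand in ("+", "-"):
            p = self.p_native[strand]
            idx = np.flatnonzero(~np.isnan(p))
            for pos in idx:
                rows.append(
                    {
                        "contig": self.genome.contig_id,
                        "position": int(pos),
                        "strand": strand,
                        "true_p": float(p[pos]),
                        "label": self.label_names[int(self.labels[strand][pos])],
                    }
                )
        return pd.DataFrame(rows)


def generate_genome(
    spec: MethylomeSpec, seed: int
) -> tuple[GenomeSequence, list[GeneFeature]]:
    """I.i.d. genome at the requested GC with non-overlapping genes.

    Genes are placed by cutting the slack between them with uniform gaps,
    so placement is uniform, deterministic given the seed, and both strands
    are represented.  Packing that cannot fit raises ValueError.
    """
    if spec.genome_length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    gc_half = spec.gc / 2.0
    at_half = (1.0 - spec.gc) / 2.0
    bases = rng.choice(
        np.array(list("ACGT")), size=spec.genome_length, p=[at_half, gc_half, gc_half, at_half]
    )
    genome = GenomeSequence(spec.contig_id, "".join(bases))
    genes: list[GeneFeature] = []
    if spec.n_genes:
        lengths = rng.integers(
            spec.gene_length[0], spec.gene_length[1] + 1, size=spec.n_genes
        )
        slack = spec.genome_length - int(lengths.sum()) - spec.gene_spacing * (
            spec.n_genes + 1
        )
        if slack < 0:
            raise ValueError("cannot pack the requested genes into the genome")
        gaps = np.sort(rng.integers(0, slack + 1, size=spec.n_genes))
        gaps = np.diff(np.concatenate([[0], gaps]))
        strands = rng.choice(np.array(["+", "-"]), size=spec.n_genes)
        if spec.n_genes >= 2 and len(set(strands)) == 1:
            strands[rng.integers(0, spec.n_genes)] = "+" if strands[0] == "-" else "-"
        cursor = spec.gene_spacing
        width = len(str(spec.n_genes))
        for i in range(spec.n_genes):
            cursor += int(gaps[i])
            start = cursor
            end = start + int(lengths[i])
            cursor = end + spec.gene_spacing
            genes.append(
                GeneFeature(
                    contig=spec.contig_id,
                    start=start,
                    end=end,
                    strand=str(strands[i]),
                    gene_id=f"gene_{i + 1:0{width}d}",
                    annotation=str(rng.choice(np.array(_ANNOTATION_POOL))),
                )
            )
    return genome, genes


_LABELS = ("background", "leak", "motif", "block", "dip", "artifact")


def plant_methylome(
    genome: GenomeSequence,
    spec: MethylomeSpec,
    genes: Sequence[GeneFeature] = (),
    seed: int = 0,
) -> PlantedMethylome:
    """Assign a true methylation probability to every candidate base."""
    rng = np.random.default_rng(seed)
    length = len(genome)
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    plus_base, minus_base = (ord("A"), ord("T")) if spec.mod_code == "6mA" else (
        ord("C"),
        ord("G"),
    )
    candidate = {"+": seq == plus_base, "-": seq == minus_base}
    p = {
        s: np.where(candidate[s], spec.p_background, np.nan) for s in ("+", "-")
    }
    labels = {s: np.zeros(length, dtype=np.int8) for s in ("+", "-")}

    def put(pos: int, strand: str, value: float, label: str) -> bool:
        if 0 <= pos < length and candidate[strand][pos]:
            p[strand][pos] = value
            labels[strand][pos] = _LABELS.index(label)
            return True
        return False

    coupled: list[tuple[int, int, float]] = []
    pair_rows = []

    # leaky parents first (specific motifs overwrite their shared sites)
    for pm in spec.motifs:
        if pm.leak_parent is not None:
            if pm.leak_p is None:
                raise ValueError("leak_parent requires leak_p")
            for site in scan_motif(genome, pm.leak_parent):
                put(site.mod_position, site.strand, pm.leak_p, "leak")
    for pm in spec.motifs:
        sites = scan_motif(genome, pm.motif)
        if pm.palindrome_mix is None:
            for site in sites:
                put(site.mod_position, site.strand, pm.p, "motif")
            if pm.correlation > 0 and pm.motif.is_palindromic:
                by_start: dict[int, dict[str, int]] = {}
                for site in sites:
                    by_start.setdefault(site.match_start, {})[site.strand] = (
                        site.mod_position
                    )
                for start in sorted(by_start):
                    slot = by_start[start]
                    if "+" in slot and "-" in slot:
                        coupled.append((slot["+"], slot["-"], pm.correlation))
        else:
            by_start = {}
            for site in sites:
                by_start.setdefault(site.match_start, {})[site.strand] = (
                    site.mod_position
                )
            classes = ("full", "hemi", "unmethylated")
            for start in sorted(by_start):
                slot = by_start[start]
                if len(slot) != 2:
                    continue
                call = str(rng.choice(np.array(classes), p=pm.palindrome_mix))
                if call == "full":
                    targets = ("+", "-")
                elif call == "hemi":
                    targets = (str(rng.choice(np.array(["+", "-"]))),)
                else:
                    targets = ()
                for strand in ("+", "-"):
                    value = pm.p if strand in targets else spec.p_background
                    put(slot[strand], strand, value, "motif")
                if pm.correlation > 0:
                    coupled.append((slot["+"], slot["-"], pm.correlation))
                pair_rows.append(
                    {
                        "motif_id": pm.motif.motif_id,
                        "match_start": start,
                        "true_call": call,
                    }
                )

    if spec.block is not None:
        b0, b1, bp = spec.block
        for strand in ("+", "-"):
            mask = candidate[strand].copy()
            mask[:b0] = False
            mask[b1:] = False
            p[strand][mask] = bp
            labels[strand][mask] = _LABELS.index("block")

    if spec.promoter_dip is not None:
        width, dip_p = spec.promoter_dip
        for gene in genes:
            if gene.strand == "+":
                lo, hi = max(gene.start - width, 0), gene.start
            else:
                lo, hi = gene.end, min(gene.end + width, length)
            strand = gene.strand
            mask = candidate[strand].copy()
            mask[:lo] = False
            mask[hi:] = False
            p[strand][mask] = dip_p
            labels[strand][mask] = _LABELS.index("dip")

    artifact_positions: list[tuple[int, str]] = []
    wga = {
        s: np.where(candidate[s], spec.wga_error, np.nan) for s in ("+", "-")
    }
    if spec.artifacts is not None:
        n_artifacts, ap = spec.artifacts
        pool = [
            (int(pos), strand)
            for strand in ("+", "-")
            for pos in np.flatnonzero(candidate[strand])
        ]
        chosen = rng.choice(len(pool), size=n_artifacts, replace=False)
        for idx in sorted(chosen):
            pos, strand = pool[idx]
            put(pos, strand, ap, "artifact")
            wga[strand][pos] = ap
            artifact_positions.append((pos, strand))

    return PlantedMethylome(
        genome=genome,
        genes=list(genes),
        p_native=p,
        p_wga=wga,
        labels=labels,
        label_names=_LABELS,
        artifact_positions=artifact_positions,
        coupled_pairs=coupled,
        pair_classes=pd.DataFrame(
            pair_rows, columns=["motif_id", "match_start", "true_call"]
        ),
    )


def _logit(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 1e-9, 1 - 1e-9)
    return np.log(x / (1 - x))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_library(
    planted_p: dict[str, np.ndarray],
    contig: str,
    mod_code: str,
    coverage_mean: float,
    jitter_sd: float,
    rng: np.random.Generator,
    coupled_pairs: Sequence[tuple[int, int, float]] = (),
) -> list[SiteRecord]:
    delta = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
    records: list[SiteRecord] = []
    arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for strand in ("+", "-"):
        p = planted_p[strand]
        idx = np.flatnonzero(~np.isnan(p))
        probs = _sigmoid(_logit(p[idx]) + delta) if jitter_sd > 0 else p[idx]
        depth = np.maximum(1, rng.poisson(coverage_mean, size=idx.size))
        n_mod = rng.binomial(depth, probs)
        arrays[strand] = (idx, depth, n_mod)
    if coupled_pairs:
        pos_to_i = {
            strand: {int(pos): i for i, pos in enumerate(arrays[strand][0])}
            for strand in ("+", "-")
        }
        for plus_pos, minus_pos, corr in coupled_pairs:
            if rng.random() >= corr:
                continue
            pi = pos_to_i["+"].get(plus_pos)
            mi = pos_to_i["-"].get(minus_pos)
            if pi is None or mi is None:
                continue
            _, pdepth, pmod = arrays["+"]
            _, mdepth, mmod = arrays["-"]
            mmod[mi] = int(round(pmod[pi] / pdepth[pi] * mdepth[mi]))
    for strand in ("+", "-"):
        idx, depth, n_mod = arrays[strand]
        records.extend(
            SiteRecord(
                contig=contig,
                position=int(pos),
                strand=strand,
                mod_code=mod_code,
                valid_coverage=int(d),
                n_mod=int(m),
                n_canonical=int(d - m),
            )
            for pos, d, m in zip(idx, depth, n_mod)
        )
    records.sort(key=lambda r: (r.position, r.strand))
    return records


def simulate_bedmethyl(
    planted: PlantedMethylome,
    spec: MethylomeSpec,
    seed: int,
) -> tuple[list[list[SiteRecord]], list[SiteRecord]]:
    """Draw replicate pileups and the WGA control from the planted truth.

    Depth is Poisson(coverage_mean) with its zero mass moved to 1 so every
    candidate site appears; modified counts are binomial at the site's true
    probability, shifted per replicate on the logit scale.  The WGA library
    is drawn without jitter at the error floor (artifacts keep their
    elevated probability there too).
    """
    rng = np.random.default_rng(seed)
    contig = planted.genome.contig_id
    replicates = [
        _draw_library(
            planted.p_native,
            contig,
            spec.mod_code,
            spec.coverage_mean,
            spec.replicate_jitter_sd,
            rng,
            planted.coupled_pairs,
        )
        for _ in range(spec.n_replicates)
    ]
    wga = _draw_library(
        planted.p_wga, contig, spec.mod_code, spec.coverage_mean, 0.0, rng
    )
    return replicates, wga


@dataclass
class SyntheticDataset:
    spec: MethylomeSpec
    seed: int
    genome: GenomeSequence
    genes: list[GeneFeature]
    planted: PlantedMethylome
    replicates: list[list[SiteRecord]]
    wga: list[SiteRecord]
    paths: dict[str, Path] = field(default_factory=dict)

    def write(self, outdir: str | Path, truth_table: bool = True) -> dict[str, Path]:
        """Write FASTA, GFF3, replicate + WGA bedMethyl and truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome"] = outdir / "genome.fasta"
        write_fasta([self.genome], paths["genome"])
        if self.genes:
            paths["genes"] = outdir / "genes.gff3"
            write_gff3(
                self.genes, paths["genes"], {self.genome.contig_id: len(self.genome)}
            )
        for i, records in enumerate(self.replicates, start=1):
            key = f"replicate_{i}"
            paths[key] = outdir / f"{key}.bedmethyl.tsv"
            write_bedmethyl(records, paths[key])
        paths["wga"] = outdir / "wga.bedmethyl.tsv"
        write_bedmethyl(self.wga, paths["wga"])
        if truth_table:
            paths["truth"] = outdir / "truth_sites.tsv"
            write_tsv(
                self.planted.truth_frame(), paths["truth"], {"seed": self.seed}
            )
            if len(self.planted.pair_classes):
                paths["pair_truth"] = outdir / "truth_pairs.tsv"
                write_tsv(
                    self.planted.pair_classes, paths["pair_truth"], {"seed": self.seed}
                )
        self.paths = paths
        return paths


def simulate_methylome(
    spec: MethylomeSpec, seed: int, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Generate genome + genes, plant the methylome and draw the pileups.

    The three stages consume independent child seeds spawned from ``seed``,
    so the same seed reproduces the dataset byte for byte.
    """
    child = np.random.SeedSequence(seed).spawn(3)
    genome_seed, plant_seed, draw_seed = (
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in child
    )
    genome, genes = generate_genome(spec, genome_seed)
    planted = plant_methylome(genome, spec, genes, plant_seed)
    replicates, wga = simulate_bedmethyl(planted, spec, draw_seed)
    dataset = SyntheticDataset(
        spec=spec,
        seed=seed,
        genome=genome,
        genes=genes,
        planted=planted,
        replicates=replicates,
        wga=wga,
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset
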