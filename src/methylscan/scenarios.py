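"""Reference validation scenarios exercising every pipeline stage.

Each scenario simulates a methylome under the package's standard study
conditions (29% GC genome, mean depth 50, three replicates, background
per-read probability 0.03), runs the relevant analysis end to end and
returns the measured quantities.  They back both the validation test suite
and the ``scripts/acceptance.py`` runner, so the numbers are always
recomputed from scratch.

Every scenario takes a seed and returns ``{name: (value, n)}`` where ``n``
is the problem size behind the value.
"""

from __future__ import annotations

import itertools
from typing import Callable

import numpy as np

from .enrichment import window_enrichment
from .formats import GenomeSequence, SiteRecord
from .metagene import build_profile, upstream_window_test
from .motifs import (
    MOTIF_CATALOGUE,
    Motif,
    discover_motifs,
    pair_palindrome_sites,
    palindrome_proportions,
    reverse_complement_iupac,
    scan_motif,
    summarize_motif,
)
from .site_stats import aggregate_replicates, fit_sd_mean, index_summaries, wga_correct
from .synthetic_data import MethylomeSpec, PlantedMotif, simulate_methylome

Result = dict[str, tuple[float, int]]

GTNNAC = Motif("GTNNAC", 4)
CTAG = Motif("CTAG", 2)


def _child_seed(seed: int, label: str) -> int:
    import zlib

    value = np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    return int(value.generate_state(1)[0] % (2**31 - 1))


def motif_recovery(seed: int) -> Result:
    """Planted per-motif methylation recovered by the summary pipeline.

    GTNNAC planted at p = 0.75 and CTAG at p = 0.58 on 200 kb; the
    per-motif mean frequency should come back within sampling error and the
    genomic methylation fractions should preserve the planted order.
    """
    spec = MethylomeSpec(
        motifs=(PlantedMotif(GTNNAC, 0.75), PlantedMotif(CTAG, 0.58))
    )
    ds = simulate_methylome(spec, seed)
    summaries = aggregate_replicates(ds.replicates)
    idx = index_summaries(summaries)
    out: Result = {}
    fractions = {}
    total_sites = 0
    for motif, name in ((GTNNAC, "gtnnac"), (CTAG, "ctag")):
        sites = scan_motif(ds.genome, motif)
        summary = summarize_motif(motif, sites, idx)
        out[f"{name}_mean_frequency_pct"] = (
            100.0 * summary.mean_freq,
            summary.n_sites,
        )
        fractions[name] = summary.genomic_methylation_fraction
        total_sites += summary.n_sites
    out["motif_fraction_order_preserved"] = (
        float(fractions["gtnnac"] > fractions["ctag"]),
        total_sites,
    )
    return out


def palindrome_recovery(seed: int) -> Result:
    """Planted 50/30/20 full/hemi/unmethylated GTNNAC mixture recovered."""
    spec = MethylomeSpec(
        motifs=(PlantedMotif(GTNNAC, 0.9, palindrome_mix=(0.5, 0.3, 0.2)),)
    )
    ds = simulate_methylome(spec, seed)
    idx = index_summaries(aggregate_replicates(ds.replicates))
    pairs, _ = pair_palindrome_sites(GTNNAC, scan_motif(ds.genome, GTNNAC))
    calls = palindrome_proportions(pairs, idx, threshold=0.70)
    return {
        "palindrome_full_pct": (100.0 * calls.proportions["full"], calls.n_pairs),
        "palindrome_hemi_pct": (100.0 * calls.proportions["hemi"], calls.n_pairs),
        "palindrome_unmethylated_pct": (
            100.0 * calls.proportions["unmethylated"],
            calls.n_pairs,
        ),
    }


def wga_correction_check(seed: int) -> Result:
    """Artifacts shared with the WGA control vanish; true motif sites survive.

    100 artifact positions at p = 0.30 in both the native and WGA
    libraries, GTNNAC planted at 0.75.  After subtraction the artifact mean
    should sit near zero while motif sites stay near 0.73.
    """
    spec = MethylomeSpec(
        motifs=(PlantedMotif(GTNNAC, 0.75),), artifacts=(100, 0.30)
    )
    ds = simulate_methylome(spec, seed)
    corrected = wga_correct(aggregate_replicates(ds.replicates), ds.wga)
    idx = index_summaries(corrected)
    contig = ds.genome.contig_id
    artifact_values = [
        idx[(contig, pos, strand, spec.mod_code)].corrected_freq
        for pos, strand in ds.planted.artifact_positions
        if (contig, pos, strand, spec.mod_code) in idx
    ]
    sites = scan_motif(ds.genome, GTNNAC)
    motif_summary = summarize_motif(GTNNAC, sites, idx, freq_attr="corrected_freq")
    return {
        "artifact_corrected_mean": (
            float(np.mean(artifact_values)),
            len(artifact_values),
        ),
        "motif_corrected_mean": (motif_summary.mean_freq, motif_summary.n_sites),
    }


# -- brute-force oracle for the scanner ------------------------------------

_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_force_scan(
    sequence: str, motif: Motif
) -> set[tuple[int, str, int]]:
    """Window-by-window motif matching: (match_start, strand, mod_position).

    Independent of the production scanner: checks every window against the
    pattern and against its reverse complement explicitly.
    """
    k = len(motif.iupac)
    rc = reverse_complement_iupac(motif.iupac)
    hits: set[tuple[int, str, int]] = set()
    for start in range(len(sequence) - k + 1):
        window = sequence[start : start + k]
        if all(window[i] in _EXPANSION[motif.iupac[i]] for i in range(k)):
            hits.add((start, "+", start + motif.mod_offset))
        if all(window[i] in _EXPANSION[rc[i]] for i in range(k)):
            hits.add((start, "-", start + k - 1 - motif.mod_offset))
    return hits


def scan_oracle_check(seed: int, n_sequences: int = 100, length: int = 2000) -> Result:
    """Scanner versus brute force on random sequences, all nine motifs.

    Also verifies palindrome pairing: every palindromic occurrence must
    yield exactly one plus and one minus methylated base at its start.
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    comparisons = 0
    for i in range(n_sequences):
        seq = "".join(rng.choice(np.array(list("ACGT")), size=length))
        genome = GenomeSequence(f"random_{i}", seq)
        for motif in MOTIF_CATALOGUE:
            comparisons += 1
            sites = scan_motif(genome, motif)
            got = {(s.match_start, s.strand, s.mod_position) for s in sites}
            if got != brute_force_scan(seq, motif):
                mismatches += 1
                continue
            if motif.is_palindromic:
                pairs, unpaired = pair_palindrome_sites(motif, sites)
                starts = {s.match_start for s in sites}
                if unpaired or len(pairs) != len(starts):
                    mismatches += 1
    return {"scan_oracle_mismatches": (float(mismatches), comparisons)}


def discovery_recovery(seed: int) -> Result:
    """De-novo discovery finds the planted motifs in canonical form.

    GTNNAC at p = 0.80 and CTAG at p = 0.60 on 200 kb; both should be
    reported, with no spurious motif ranked above either of them.
    """
    spec = MethylomeSpec(
        motifs=(PlantedMotif(GTNNAC, 0.80), PlantedMotif(CTAG, 0.60))
    )
    ds = simulate_methylome(spec, seed)
    summaries = aggregate_replicates(ds.replicates)
    results = discover_motifs(ds.genome, summaries)
    found = [(r.motif.iupac, r.motif.mod_offset) for r in results]
    planted = {("GTNNAC", 4), ("CTAG", 2)}
    recovered = planted & set(found)
    last_planted_rank = max(
        (found.index(p) for p in recovered), default=-1
    )
    spurious_above = sum(
        1 for p in found[: last_planted_rank + 1] if p not in planted
    )
    return {
        "discovery_motifs_recovered": (float(len(recovered)), len(results)),
        "discovery_spurious_above_planted": (float(spurious_above), len(results)),
    }


def enrichment_block(seed: int) -> Result:
    """A hypermethylated 10 kb block lights up the sliding-window z track."""
    block = (95_000, 105_000, 0.8)
    spec = MethylomeSpec(block=block)
    ds = simulate_methylome(spec, seed)
    summaries = aggregate_replicates(ds.replicates)
    track = window_enrichment(summaries, len(ds.genome))
    valid = track.dropna(subset=["z"])
    best = valid.loc[valid["z"].idxmax()]
    overlaps = float(
        best["window_start"] < block[1] and best["window_end"] > block[0]
    )
    return {
        "enrichment_max_z": (float(best["z"]), len(valid)),
        "enrichment_max_window_overlaps_block": (overlaps, len(valid)),
        "enrichment_z_mean": (float(valid["z"].mean()), len(valid)),
        "enrichment_z_sd": (float(valid["z"].std(ddof=0)), len(valid)),
    }


def metagene_dip(seed: int, n_genes: int = 200) -> Result:
    """A planted 50 bp promoter dip shows up in the metagene profile.

    The window immediately upstream of the gene start (U20, sense strand)
    must be the minimum of the upstream medians and receive a significance
    letter shared with no other upstream window.
    """
    spec = MethylomeSpec(
        genome_length=400_000,
        n_genes=n_genes,
        p_background=0.08,
        promoter_dip=(50, 0.01),
    )
    ds = simulate_methylome(spec, seed)
    summaries = aggregate_replicates(ds.replicates)
    profile = build_profile(
        ds.genes,
        summaries,
        {ds.genome.contig_id: len(ds.genome)},
        seed=_child_seed(seed, "bootstrap"),
    )
    upstream = [f"U{i}" for i in range(1, 21)]
    medians = (
        profile.table.query("rel_strand == 'sense'")
        .set_index("region")["median"]
        .loc[upstream]
    )
    u20_is_min = float(medians.idxmin() == "U20")
    per_gene = profile.per_gene.loc[:, [(u, "sense") for u in upstream]]
    per_gene.columns = upstream
    letters, _ = upstream_window_test(per_gene, alpha=1e-4)
    letter_map = dict(zip(letters["window"], letters["letters"]))
    u20_letters = set(letter_map["U20"])
    others = set("".join(letter_map[u] for u in upstream if u != "U20"))
    distinct = float(bool(u20_letters) and not (u20_letters & others))
    return {
        "metagene_u20_is_minimum": (u20_is_min, n_genes),
        "metagene_u20_distinct_letter": (distinct, n_genes),
        "metagene_u20_median_pct": (100.0 * float(medians["U20"]), n_genes),
    }


def sd_mean_shape(
    seed: int, n_sites: int = 2000, depth: int = 30, n_replicates: int = 3
) -> Result:
    """Replicated binomial sampling gives a concave SD-vs-mean relation.

    Site probabilities are uniform on (0, 1); the sample SD of replicate
    frequencies peaks near p = 0.5, so the quadratic fit must beat the
    linear one.
    """
    rng = np.random.default_rng(seed)
    probs = rng.uniform(0.0, 1.0, size=n_sites)
    replicates = []
    for _ in range(n_replicates):
        depths = np.maximum(1, rng.poisson(depth, size=n_sites))
        n_mod = rng.binomial(depths, probs)
        replicates.append(
            [
                SiteRecord("sim", pos, "+", "6mA", int(d), int(m), int(d - m))
                for pos, (d, m) in enumerate(zip(depths, n_mod))
            ]
        )
    fit = fit_sd_mean(aggregate_replicates(replicates))
    return {
        "sd_mean_quad_r2": (fit.quad_r2, n_sites),
        "sd_mean_linear_r2": (fit.linear_r2, n_sites),
    }


SCENARIOS: dict[str, Callable[[int], Result]] = {
    "motif_recovery": motif_recovery,
    "palindrome_recovery": palindrome_recovery,
    "wga_correction_check": wga_correction_check,
    "scan_oracle_check": scan_oracle_check,
    "discovery_recovery": discovery_recovery,
    "enrichment_block": enrichment_block,
    "metagene_dip": metagene_dip,
    "sd_mean_shape": sd_mean_shape,
}


def run_all(seed: int) -> Result:
    """Run every scenario with an independent child seed."""
    out: Result = {}
    for name, fn in SCENARIOS.items():
        out.update(fn(_child_seed(seed, name)))
    return out
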