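"""Synthetic regulatory-genomics studies with planted ground truth.

Generates everything the pipeline consumes — a genome FASTA with gene
annotations, promoters carrying a motif planted preferentially in a
designated target set, ChIP-seq-like peak summits concentrated near the
TSSs of bound genes, and two knockout expression studies (replicate
matrices and probe tables) with a designed overlap between their
down-regulated target sets — so every stage can be exercised and its
parameter recovery measured without any external download.

The default configuration is the study condition used throughout the
test-suite and reproduction script: 10,000 genes, 300 targets per
knockout with 60 shared, a planting probability of 0.4 in the first
knockout's target promoters versus 0.05 in the background, knockout
effects of mean 1.5 (log2) with replicate noise 0.4 and 3 replicates
per group, and 759 peaks. Everything is reproducible bit-for-bit from
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .motifs import ALPHABET, MotifMatrix, reverse_complement
from .promoters import TssRecord
from .peaks import Peak

_BASES = np.frombuffer("ACGT".encode(), dtype=np.uint8)


def nfi_like_motif(strength: float = 0.95, spacer_strength: float = 0.45) -> MotifMatrix:
    """A 13-bp palindromic dimer motif (TGGC-N5-GCCA core).

    Mimics the half-site/spacer/half-site architecture typical of NFI
    family dimers; ``strength`` is the probability of the preferred base
    at the half-site positions. Spacer positions carry a weak preference
    (``spacer_strength`` for one base, the rest uniform), as SELEX-derived
    dimer motifs do; fully uniform spacer columns would make the score
    distribution so coarse that no site could reach a p-value below
    4^-(number of informative positions).
    """
    consensus = "TGGCNNNNNGCCA"
    spacer_pref = "ATCAT"  # arbitrary weak preferences, one per spacer column
    rows = []
    si = 0
    for c in consensus:
        if c == "N":
            row = [(1 - spacer_strength) / 3] * 4
            row[ALPHABET.index(spacer_pref[si])] = spacer_strength
            si += 1
        else:
            row = [(1 - strength) / 3] * 4
            row[ALPHABET.index(c)] = strength
        rows.append(row)
    return MotifMatrix(id="PLANTED_NFI", counts=np.array(rows),
                       gene_label="Nfib", source="synthetic")


def decoy_motifs(motif: MotifMatrix, n: int, seed: int) -> list[MotifMatrix]:
    """Column-permuted copies of a motif.

    Permuting positions preserves the information content and base
    composition while destroying the sequence match, which makes these
    the natural decoys for recovery benchmarks.
    """
    rng = np.random.default_rng(seed)
    decoys = []
    for i in range(n):
        perm = rng.permutation(motif.length)
        # reject the identity-like permutation on informative columns
        while np.array_equal(motif.probabilities[perm], motif.probabilities):
            perm = rng.permutation(motif.length)
        decoys.append(
            MotifMatrix(
                id=f"DECOY_{i:03d}",
                counts=motif.counts[perm].copy(),
                source="synthetic",
            )
        )
    return decoys


@dataclass
class SyntheticConfig:
    """Parameters of a full synthetic two-knockout study."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 6_500_000
    n_genes: int = 10_000
    flank: int = 1_000
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)
    plant_prob_activated: float = 0.4
    plant_prob_background: float = 0.05
    n_peaks: int = 759
    peak_jitter_sd: float = 20.0
    n_targets_a: int = 300
    n_targets_b: int = 300
    n_overlap: int = 60
    effect_log2fc_mean: float = 1.5
    effect_log2fc_sd: float = 0.5
    overlap_effect_weight: float = 0.7
    noise_sd: float = 0.4
    n_reps: int = 3
    repressed_fraction: float = 0.0  # fraction of targets planted as up-regulated

    def __post_init__(self) -> None:
        if not (
            self.n_overlap <= min(self.n_targets_a, self.n_targets_b) <= self.n_genes
        ):
            raise ValueError(
                "need n_overlap <= min(n_targets_a, n_targets_b) <= n_genes"
            )
        for p in (self.plant_prob_activated, self.plant_prob_background):
            if not 0 <= p <= 1:
                raise ValueError("plant probabilities must lie in [0, 1]")
        if self.n_reps < 2:
            raise ValueError("need >= 2 replicates per group")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "base_composition" in d:
            d["base_composition"] = tuple(d["base_composition"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic study."""

    targets_a: set[str]
    targets_b: set[str]
    overlap: set[str]
    planted_sites: list  # (chrom, start, strand, gene_id)
    effects_a: dict[str, float]  # gene -> true log2fc in KO A
    effects_b: dict[str, float]

    def to_json(self, path=None) -> str:
        s = json.dumps(
            {
                "targets_a": sorted(self.targets_a),
                "targets_b": sorted(self.targets_b),
                "overlap": sorted(self.overlap),
                "planted_sites": [list(t) for t in self.planted_sites],
                "effects_a": self.effects_a,
                "effects_b": self.effects_b,
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def simulate_genome(config: SyntheticConfig, rng=None):
    """I.i.d.-background genome plus TSS annotation.

    Genes are evenly spaced along the chromosomes with both strands
    represented; transcript lengths are drawn so the shortest-transcript
    TSS rule has something to do on multi-record genes (a random subset
    of genes gets a second, longer transcript at a nearby TSS).
    Returns ``(genome: dict chrom -> np.uint8 array, tss_records)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    comp = np.asarray(config.base_composition, dtype=float)
    comp = comp / comp.sum()
    genome = {
        f"chr{i+1}": rng.choice(_BASES, size=config.chrom_length, p=comp)
        for i in range(config.n_chroms)
    }
    genes_per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    spacing = config.chrom_length // (genes_per_chrom + 1)
    if spacing <= 2 * config.flank:
        raise ValueError(
            "infeasible packing: chromosomes too short for "
            f"{config.n_genes} genes with flank {config.flank}"
        )
    records = []
    g = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci+1}"
        for k in range(genes_per_chrom):
            if g >= config.n_genes:
                break
            tss = (k + 1) * spacing + int(rng.integers(-spacing // 10, spacing // 10 + 1))
            tss = min(max(tss, config.flank + 1), config.chrom_length - config.flank - 2)
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{g:05d}"
            tlen = int(rng.integers(500, 5001))
            records.append(TssRecord(gid, chrom, strand, tss, tlen))
            if rng.random() < 0.1:  # an alternative, longer transcript
                alt_tss = tss + int(rng.integers(-200, 201))
                records.append(
                    TssRecord(gid, chrom, strand, max(alt_tss, config.flank + 1),
                              tlen + int(rng.integers(100, 2001)))
                )
            g += 1
    return genome, records


def _draw_target_sets(config: SyntheticConfig, gene_ids, rng):
    """Target sets for the two knockouts with a designed overlap."""
    gene_ids = np.asarray(gene_ids)
    picked = rng.choice(
        gene_ids,
        size=config.n_targets_a + config.n_targets_b - config.n_overlap,
        replace=False,
    )
    overlap = set(picked[: config.n_overlap])
    a_only = set(picked[config.n_overlap : config.n_targets_a])
    b_only = set(picked[config.n_targets_a :])
    return a_only | overlap, b_only | overlap, overlap


def plant_motif_sites(
    genome: dict,
    tss_by_gene,
    motif: MotifMatrix,
    targets: set[str],
    config: SyntheticConfig,
    rng,
):
    """Plant motif instances into promoter windows, in place.

    Each gene receives a planted site with probability
    ``plant_prob_activated`` if it belongs to ``targets`` (the bound,
    knockout-responsive set) and ``plant_prob_background`` otherwise. A
    site is a fresh draw from the motif's probability matrix, written on
    a random strand at a uniformly chosen offset within the promoter
    window. Coordinates are returned for the truth record.
    """
    L = motif.length
    if L >= config.flank:
        raise ValueError("motif longer than the promoter flank")
    prob = motif.probabilities
    sites = []
    for gid, rec in sorted(tss_by_gene.items()):
        p = (
            config.plant_prob_activated
            if gid in targets
            else config.plant_prob_background
        )
        if rng.random() >= p:
            continue
        lo = max(0, rec.tss - config.flank)
        hi = min(len(genome[rec.chrom]) - L, rec.tss + config.flank - L)
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        word = "".join(ALPHABET[b] for b in
                       (rng.random((L, 1)) > prob.cumsum(axis=1)).sum(axis=1))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            word = reverse_complement(word)
        genome[rec.chrom][start : start + L] = np.frombuffer(
            word.encode(), dtype=np.uint8
        )
        sites.append((rec.chrom, start, strand, gid))
    return sites


def simulate_peaks(sites, config: SyntheticConfig, rng, motif_length: int = 13):
    """Peak summits: one per planted site (Gaussian jitter around the site
    center) plus uniform background peaks up to ``n_peaks``."""
    if config.peak_jitter_sd < 0:
        raise ValueError("peak_jitter_sd must be >= 0")
    if config.n_peaks < len(sites):
        raise ValueError(
            f"n_peaks={config.n_peaks} < {len(sites)} planted sites"
        )
    peaks = []
    for i, (chrom, start, _strand, _gid) in enumerate(sites):
        center = start + motif_length // 2
        summit = center + int(np.rint(rng.normal(0, config.peak_jitter_sd)))
        summit = min(max(summit, 0), config.chrom_length - 1)
        peaks.append(Peak(chrom=chrom, summit=summit, id=f"site_peak_{i:04d}"))
    for i in range(config.n_peaks - len(sites)):
        chrom = f"chr{int(rng.integers(0, config.n_chroms)) + 1}"
        peaks.append(
            Peak(chrom=chrom, summit=int(rng.integers(0, config.chrom_length)),
                 id=f"bg_peak_{i:04d}")
        )
    return peaks


def simulate_ko_expression(
    gene_ids, targets_a, targets_b, overlap, config: SyntheticConfig, rng
):
    """Replicate matrices for the two knockouts with designed effects.

    For each knockout, target genes receive a true log2 fold change of
    -|N(effect_mean, effect_sd)| (down-regulation; set
    ``repressed_fraction`` for a symmetric up-regulated share) and all
    other genes 0. Genes in the designed overlap draw their effect as a
    weighted mix of a shared component and a knockout-specific one
    (weight ``overlap_effect_weight``), which makes the paired fold
    changes of shared targets correlated, as in real co-regulated sets.
    Each gene carries 1-3 probes; replicate values are the true signal
    plus N(0, noise_sd).

    Returns ``(study_a, study_b, effects_a, effects_b)`` where each study
    is a dict with ``matrix`` (probes x samples log2 DataFrame),
    ``groups`` (sample labels) and ``probe_genes`` (Series).
    """
    gene_ids = list(gene_ids)
    w = config.overlap_effect_weight

    def magnitude(n):
        return np.abs(rng.normal(config.effect_log2fc_mean,
                                 config.effect_log2fc_sd, size=n))

    signs = {}
    for gid in sorted(set(targets_a) | set(targets_b)):
        signs[gid] = 1.0 if rng.random() < config.repressed_fraction else -1.0

    shared_mag = {gid: m for gid, m in zip(sorted(overlap), magnitude(len(overlap)))}
    effects_a, effects_b = {}, {}
    for gid in gene_ids:
        ea = eb = 0.0
        if gid in targets_a:
            own = magnitude(1)[0]
            ea = signs[gid] * (
                w * shared_mag[gid] + (1 - w) * own if gid in overlap else own
            )
        if gid in targets_b:
            own = magnitude(1)[0]
            eb = signs[gid] * (
                w * shared_mag[gid] + (1 - w) * own if gid in overlap else own
            )
        effects_a[gid] = float(ea)
        effects_b[gid] = float(eb)

    def build_study(effects, label):
        probes, pgenes, rows = [], [], []
        for gid in gene_ids:
            for pi in range(int(rng.integers(1, 4))):
                probes.append(f"{gid}_p{pi}")
                pgenes.append(gid)
                baseline = rng.normal(8.0, 1.5)
                wt = baseline + rng.normal(0, config.noise_sd, config.n_reps)
                ko = (
                    baseline
                    + effects[gid]
                    + rng.normal(0, config.noise_sd, config.n_reps)
                )
                rows.append(np.concatenate([ko, wt]))
        cols = [f"KO_{label}_{i+1}" for i in range(config.n_reps)] + [
            f"WT_{label}_{i+1}" for i in range(config.n_reps)
        ]
        matrix = pd.DataFrame(np.array(rows), index=pd.Index(probes, name="probe_id"),
                              columns=cols)
        groups = ["KO"] * config.n_reps + ["WT"] * config.n_reps
        return {
            "matrix": matrix,
            "groups": groups,
            "probe_genes": pd.Series(pgenes, index=matrix.index),
        }

    return (
        build_study(effects_a, "A"),
        build_study(effects_b, "B"),
        effects_a,
        effects_b,
    )


@dataclass
class SyntheticStudy:
    """All artifacts of one simulated study, in memory."""

    config: SyntheticConfig
    genome: dict
    tss_records: list
    motif: MotifMatrix
    truth: SyntheticTruth
    peaks: list
    study_a: dict
    study_b: dict

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.genome.items()}

    def tss_by_gene(self) -> dict:
        from .promoters import select_tss

        return select_tss(self.tss_records)

    def promoter_set(self):
        """Promoters extracted directly from the in-memory genome.

        Uses the same window convention as
        :func:`motifassoc.promoters.extract_promoters` (checked against it
        in the tests), without the FASTA round trip.
        """
        from .promoters import PromoterSet

        flank = self.config.flank
        seqs = {}
        for gid, rec in sorted(self.tss_by_gene().items()):
            arr = self.genome[rec.chrom]
            if rec.strand == "+":
                start, end = rec.tss - flank, rec.tss + flank
            else:
                start, end = rec.tss - flank + 1, rec.tss + flank + 1
            start, end = max(0, start), min(len(arr), end)
            seq = arr[start:end].tobytes().decode("ascii")
            if rec.strand == "-":
                seq = reverse_complement(seq)
            seqs[gid] = seq
        return PromoterSet(sequences=seqs, flank=flank, provenance="synthetic")

    def peak_windows(self, width: int = 100) -> list[str]:
        """100-bp (by default) sequences centered on each peak summit."""
        half = width // 2
        out = []
        for p in self.peaks:
            arr = self.genome[p.chrom]
            start = max(0, p.summit - half)
            out.append(arr[start : start + width].tobytes().decode("ascii"))
        return out

    def genome_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.genome.items():
                fh.write(f">{chrom}\n")
                raw = arr.tobytes().decode("ascii")
                for i in range(0, len(raw), 80):
                    fh.write(raw[i : i + 80] + "\n")


def simulate_study(
    config: SyntheticConfig | None = None, motif: MotifMatrix | None = None
) -> SyntheticStudy:
    """Run the full generator: genome, planted promoters, peaks, expression."""
    if config is None:
        config = SyntheticConfig()
    if motif is None:
        motif = nfi_like_motif()
    rng = np.random.default_rng(config.seed)
    genome, tss_records = simulate_genome(config, rng)
    from .promoters import select_tss

    tss_by_gene = select_tss(tss_records)
    gene_ids = sorted(tss_by_gene)
    targets_a, targets_b, overlap = _draw_target_sets(config, gene_ids, rng)
    sites = plant_motif_sites(genome, tss_by_gene, motif, targets_a, config, rng)
    peaks = simulate_peaks(sites, config, rng, motif_length=motif.length)
    study_a, study_b, eff_a, eff_b = simulate_ko_expression(
        gene_ids, targets_a, targets_b, overlap, config, rng
    )
    truth = SyntheticTruth(
        targets_a=targets_a,
        targets_b=targets_b,
        overlap=overlap,
        planted_sites=sites,
        effects_a=eff_a,
        effects_b=eff_b,
    )
    return SyntheticStudy(
        config=config,
        genome=genome,
        tss_records=tss_records,
        motif=motif,
        truth=truth,
        peaks=peaks,
        study_a=study_a,
        study_b=study_b,
    )
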