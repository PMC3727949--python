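"""Seeded synthetic datasets with the statistical structure the analyses assume.

The generator emulates the inputs of a constraint-versus-diversity study:
genes with a known conservation gradient, a per-base constraint track,
sparse conserved non-coding elements, and multi-population genotypes whose
expected minor-allele frequency is depressed near constrained sequence
with exponentially decaying amplitude,

    m(d, g, pop) = mu_eff(pop) * (1 - A(g) exp(-d / lambda)),

where ``A(g) = a_max * g / g_max`` and ``mu_eff`` mixes a common and a rare
baseline according to the population's SFS-shape parameter theta (the
large-Ne analogue: more rare variants, lower mean MAF). Realized allele
frequencies add Beta noise around m; genotypes are drawn binomially (HWE).

Coding polymorphism uses a separate, Ne-graded site-frequency model: the
probability that a site segregates scales with theta while the conditional
frequency scales inversely, keeping the expected derived-allele mass
constant — so higher-diversity populations carry more heterozygous and
fewer homozygous-derived alleles at constrained sites.

Everything is deterministic given (config, seed): identical inputs produce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import (
    Consequence,
    GeneRecord,
    GerpTrack,
    PopulationPanel,
    write_gene_annotations,
    write_gerp_track,
)
from .profiles import WindowProfile
from .sites import CONS_CODE, SiteTable

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationConfig:
    """One simulated population: sample size, baseline MAF, SFS shape.

    ``theta`` in [0, 1] is the diversity grade (rare-variant enrichment, the
    effective-population-size analogue); ``ne`` optionally labels the
    population with an Ne value carried into the panel.
    """

    name: str
    n_individuals: int = 20
    mu0: float = 0.08
    theta: float = 0.5
    ne: float | None = None

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not 0 < self.mu0 < 0.5:
            raise ValueError("mu0 must be in (0, 0.5)")
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must be in [0, 1]")


@dataclass(frozen=True)
class SpikeConfig:
    """Inject private singleton load into one sample: ``n_sites`` new
    nonsynonymous het singletons with GERP drawn from the base coding score
    distribution shifted by ``delta``."""

    sample: str
    delta: float = 1.5
    n_sites: int = 200


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # genome geometry
    n_chromosomes: int = 22
    chromosome_length: int = 120_000_000
    n_genes: int = 100
    gene_length: int = 6_000
    n_exons: int = 3
    exon_length: int = 1_000
    gene_spacing: int = 2_200_000  # edge-to-edge inter-gene gap (and margins)
    # conservation gradient
    conservation_min: float = 0.3
    conservation_max: float = 6.0
    coding_gerp_jitter: float = 0.3
    # gene-scale depression of expected MAF
    a_max: float = 0.5
    lam: float = 100_000.0
    # non-coding conserved elements and near-zero background strips
    elements_per_gap: int = 1
    element_length: int = 20
    element_score_min: float = 2.0
    element_score_max: float = 6.0
    element_a_max: float = 0.5
    element_lam: float = 1_000.0
    element_flank_snp_density: float = 3e-3
    element_flank_span: int = 10_000
    element_focal_snps: int = 2
    strips_per_gap: int = 2
    strip_length: int = 1_000
    strip_score_sd: float = 0.3
    strip_zero_fraction: float = 0.25
    strip_focal_snps: int = 2
    noncoding_margin: int = 210_000  # features stay this far from genes
    # site-frequency model
    flank_snp_density: float = 1.8e-4
    mu_rare: float = 0.01
    maf_concentration: float = 80.0
    coding_snp_density: float = 0.02
    coding_seg_base: float = 0.7
    coding_freq_mean: float = 0.08
    coding_h_min: float = 0.3
    coding_alpha: float = 0.3  # Beta shape a; a < 1 gives a rare-skewed SFS
    nonsyn_fraction: float = 0.7
    ancestral_flip_fraction: float = 0.05
    missing_rate: float = 0.02
    populations: tuple[PopulationConfig, ...] = (
        PopulationConfig("POP1"),
        PopulationConfig("POP2"),
        PopulationConfig("POP3"),
    )
    spikes: tuple[SpikeConfig, ...] = ()

    def __post_init__(self):
        for name, value in (
            ("chromosome_length", self.chromosome_length),
            ("gene_length", self.gene_length),
            ("exon_length", self.exon_length),
            ("gene_spacing", self.gene_spacing),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.a_max <= 1:
            raise ValueError("a_max must be in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.n_exons * self.exon_length > self.gene_length:
            raise ValueError("exons do not fit in gene_length")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")

    # -- derived model quantities ------------------------------------------

    def amplitude(self, g) -> np.ndarray:
        """Gene-scale depression amplitude A(g), clipped to [0, 1]."""
        return np.clip(self.a_max * np.asarray(g, dtype=float) / self.conservation_max, 0.0, 1.0)

    def element_amplitude(self, score) -> np.ndarray:
        return np.clip(
            self.element_a_max * np.asarray(score, dtype=float) / self.conservation_max,
            0.0,
            1.0,
        )

    def mu_eff(self, pop: PopulationConfig) -> float:
        """Effective baseline mean MAF: theta-weighted common/rare mixture."""
        return (1 - pop.theta) * pop.mu0 + pop.theta * self.mu_rare

    def diversity_scale(self, pop: PopulationConfig) -> float:
        """h(theta) scaling coding segregation probability (and 1/frequency)."""
        return self.coding_h_min + (1 - self.coding_h_min) * pop.theta

    def seg_prob(self, pop: PopulationConfig) -> float:
        return min(1.0, self.coding_seg_base * self.diversity_scale(pop))

    def seg_freq_mean(self, pop: PopulationConfig) -> float:
        return min(0.45, self.coding_freq_mean / self.diversity_scale(pop))

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["populations"] = [dataclasses.asdict(p) for p in self.populations]
        d["spikes"] = [dataclasses.asdict(s) for s in self.spikes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["populations"] = tuple(
            PopulationConfig(**p) for p in d.get("populations", [])
        ) or cls.__dataclass_fields__["populations"].default
        d["spikes"] = tuple(SpikeConfig(**s) for s in d.get("spikes", []))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Reference structures
# ---------------------------------------------------------------------------


@dataclass
class Reference:
    """Genes, constraint features, and coding candidate sites (no genotypes)."""

    genes: list[GeneRecord]
    gene_g: np.ndarray  # injected conservation per gene (gene order)
    exon_scores: list[np.ndarray]  # per gene, per exon
    # non-coding features: parallel arrays
    feat_chrom: np.ndarray
    feat_start: np.ndarray
    feat_end: np.ndarray
    feat_score: np.ndarray
    feat_kind: np.ndarray  # "element" | "strip"
    # coding polymorphic candidates
    cod_chrom: np.ndarray
    cod_pos: np.ndarray
    cod_gene: np.ndarray  # gene index
    cod_score: np.ndarray
    cod_nonsyn: np.ndarray  # bool
    gaps: list[tuple[str, int, int, int, int]]  # chrom, start, end, left gene, right gene

    def build_track(self, extra_sites: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None) -> GerpTrack:
        """Assemble the bedGraph track: exon intervals carved at per-site
        scores, plus elements and background strips.

        ``extra_sites`` is an optional (chrom, pos, score) triple of
        additional 1-bp coding intervals (spiked sites).
        """
        # per-chromosome sorted carve positions for fast exon splitting
        carve_chrom = list(self.cod_chrom)
        carve_pos = list(self.cod_pos.tolist())
        carve_score = list(self.cod_score.tolist())
        if extra_sites is not None:
            carve_chrom += list(extra_sites[0])
            carve_pos += [int(p) for p in extra_sites[1]]
            carve_score += [float(s) for s in extra_sites[2]]
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        carve_chrom_arr = np.array(carve_chrom, dtype=object)
        carve_pos_arr = np.array(carve_pos, dtype=np.int64)
        carve_score_arr = np.array(carve_score, dtype=float)
        for c in np.unique(carve_chrom_arr.astype(str)) if len(carve_pos) else []:
            rows = np.flatnonzero(carve_chrom_arr.astype(str) == c)
            order = np.argsort(carve_pos_arr[rows])
            by_chrom[c] = (carve_pos_arr[rows][order], carve_score_arr[rows][order])
        intervals: list[tuple[str, int, int, float]] = []
        for gene, scores in zip(self.genes, self.exon_scores):
            cpos, cscore = by_chrom.get(gene.chrom, (np.zeros(0, dtype=np.int64), np.zeros(0)))
            for (s, e), score in zip(gene.coding_intervals, scores):
                lo = np.searchsorted(cpos, s, side="left")
                hi = np.searchsorted(cpos, e, side="left")
                cur = s
                for p, ps in zip(cpos[lo:hi], cscore[lo:hi]):
                    p = int(p)
                    if p > cur:
                        intervals.append((gene.chrom, cur, p, float(score)))
                    intervals.append((gene.chrom, p, p + 1, float(ps)))
                    cur = p + 1
                if cur < e:
                    intervals.append((gene.chrom, cur, e, float(score)))
        for chrom, s, e, score in zip(
            self.feat_chrom, self.feat_start, self.feat_end, self.feat_score
        ):
            intervals.append((str(chrom), int(s), int(e), float(score)))
        return GerpTrack.from_intervals(intervals)


def generate_reference(cfg: SimulationConfig, rng: np.random.Generator) -> Reference:
    """Lay out genes, exon scores, non-coding features, and coding sites."""
    spacing, glen = cfg.gene_spacing, cfg.gene_length
    per_chrom = (cfg.chromosome_length - spacing) // (glen + spacing)
    capacity = per_chrom * cfg.n_chromosomes
    if cfg.n_genes > capacity:
        raise ValueError(
            f"cannot place {cfg.n_genes} genes with {spacing} bp spacing on "
            f"{cfg.n_chromosomes} x {cfg.chromosome_length} bp chromosomes "
            f"(capacity {capacity}); increase chromosome_length or n_chromosomes"
        )

    g_values = np.linspace(cfg.conservation_min, cfg.conservation_max, cfg.n_genes)
    g_values = rng.permutation(g_values)

    # exon layout within a gene: first exon at span start, last flush with
    # span end, the rest evenly spread
    if cfg.n_exons == 1:
        exon_offsets = [0]
    else:
        step = (glen - cfg.exon_length) / (cfg.n_exons - 1)
        exon_offsets = [round(k * step) for k in range(cfg.n_exons)]

    genes: list[GeneRecord] = []
    exon_scores: list[np.ndarray] = []
    gaps: list[tuple[str, int, int, int, int]] = []
    placed = 0
    for c in range(cfg.n_chromosomes):
        if placed >= cfg.n_genes:
            break
        chrom = str(c + 1)
        start = spacing
        prev_end, prev_idx = 0, -1
        while placed < cfg.n_genes and start + glen + spacing <= cfg.chromosome_length:
            span = (start, start + glen)
            exons = tuple(
                (start + o, start + o + cfg.exon_length) for o in exon_offsets
            )
            gene = GeneRecord(f"G{placed:05d}", chrom, span[0], span[1], exons)
            g = float(g_values[placed])
            scores = g + cfg.coding_gerp_jitter * rng.standard_normal(cfg.n_exons)
            genes.append(gene)
            exon_scores.append(scores)
            gaps.append((chrom, prev_end, start, prev_idx, placed))
            prev_end, prev_idx = span[1], placed
            placed += 1
            start += glen + spacing
        gaps.append((chrom, prev_end, min(prev_end + spacing, cfg.chromosome_length), prev_idx, -1))

    # non-coding features inside gaps, away from genes
    f_chrom, f_start, f_end, f_score, f_kind = [], [], [], [], []
    margin = cfg.noncoding_margin
    n_feat = cfg.elements_per_gap + cfg.strips_per_gap
    for chrom, gs, ge, left, right in gaps:
        lo = gs + (margin if left >= 0 else 0)
        hi = ge - (margin if right >= 0 else 0)
        if hi - lo < n_feat * 4 * cfg.strip_length or n_feat == 0:
            continue
        slot = (hi - lo) // n_feat
        kinds = ["element"] * cfg.elements_per_gap + ["strip"] * cfg.strips_per_gap
        for k, kind in enumerate(kinds):
            length = cfg.element_length if kind == "element" else cfg.strip_length
            s_lo, s_hi = lo + k * slot, lo + (k + 1) * slot - length
            pos = int(rng.integers(s_lo, max(s_lo + 1, s_hi)))
            if kind == "element":
                score = float(rng.uniform(cfg.element_score_min, cfg.element_score_max))
            else:
                score = (
                    0.0
                    if rng.random() < cfg.strip_zero_fraction
                    else float(rng.normal(0.0, cfg.strip_score_sd))
                )
            f_chrom.append(chrom)
            f_start.append(pos)
            f_end.append(pos + length)
            f_score.append(score)
            f_kind.append(kind)

    # coding polymorphic candidate sites
    c_chrom, c_pos, c_gene, c_score, c_nonsyn = [], [], [], [], []
    for gi, (gene, scores) in enumerate(zip(genes, exon_scores)):
        for (s, e), base_score in zip(gene.coding_intervals, scores):
            n = rng.binomial(e - s, cfg.coding_snp_density)
            if n == 0:
                continue
            pos = np.sort(rng.choice(e - s, size=n, replace=False)) + s
            c_chrom.extend([gene.chrom] * n)
            c_pos.extend(pos.tolist())
            c_gene.extend([gi] * n)
            c_score.extend(
                (base_score + cfg.coding_gerp_jitter * rng.standard_normal(n)).tolist()
            )
            c_nonsyn.extend((rng.random(n) < cfg.nonsyn_fraction).tolist())

    return Reference(
        genes=genes,
        gene_g=g_values[: len(genes)],
        exon_scores=exon_scores,
        feat_chrom=np.array(f_chrom, dtype=object),
        feat_start=np.array(f_start, dtype=np.int64),
        feat_end=np.array(f_end, dtype=np.int64),
        feat_score=np.array(f_score),
        feat_kind=np.array(f_kind, dtype=object),
        cod_chrom=np.array(c_chrom, dtype=object),
        cod_pos=np.array(c_pos, dtype=np.int64),
        cod_gene=np.array(c_gene, dtype=np.int64),
        cod_score=np.array(c_score),
        cod_nonsyn=np.array(c_nonsyn, dtype=bool),
        gaps=gaps,
    )


# ---------------------------------------------------------------------------
# Site frequencies
# ---------------------------------------------------------------------------


@dataclass
class SiteFrequencies:
    """Per-site metadata and per-population allele frequencies.

    ``freq`` holds the alt-allele frequency per (site, population);
    ``expected_maf`` the model mean used to draw it (coding sites record
    the unconditional expectation pi * nu).
    """

    chrom: np.ndarray
    pos: np.ndarray
    kind: np.ndarray  # flank | element | strip | coding
    gerp: np.ndarray
    nonsyn: np.ndarray
    gene_dist: np.ndarray
    gene_g: np.ndarray
    freq: np.ndarray  # (n_sites, n_pops)
    expected_maf: np.ndarray  # (n_sites, n_pops)


def _noncoding_positions(
    cfg: SimulationConfig, ref: Reference, rng: np.random.Generator
) -> tuple[list, list, list]:
    """Draw flank/background SNP positions plus focal SNPs inside features."""
    chroms, positions, kinds = [], [], []
    for chrom, gs, ge, _, _ in ref.gaps:
        length = ge - gs
        if length <= 2:
            continue
        n = rng.poisson(cfg.flank_snp_density * length)
        if n:
            pos = np.sort(rng.integers(gs, ge, size=n))
            chroms.extend([chrom] * n)
            positions.extend(pos.tolist())
            kinds.extend(["flank"] * n)
    for chrom, fs, fe, kind in zip(
        ref.feat_chrom, ref.feat_start, ref.feat_end, ref.feat_kind
    ):
        # extra local density around each feature (meta-profile support)
        span = cfg.element_flank_span
        n = rng.poisson(cfg.element_flank_snp_density * 2 * span)
        if n:
            pos = rng.integers(fs - span, fe + span, size=n)
            chroms.extend([chrom] * n)
            positions.extend(pos.tolist())
            kinds.extend(["flank"] * n)
        n_focal = cfg.element_focal_snps if kind == "element" else cfg.strip_focal_snps
        n_focal = min(n_focal, fe - fs)
        if n_focal:
            pos = rng.choice(fe - fs, size=n_focal, replace=False) + fs
            chroms.extend([chrom] * n_focal)
            positions.extend(pos.tolist())
            kinds.extend([kind] * n_focal)
    return chroms, positions, kinds


def _nearest_gene(
    cfg: SimulationConfig, ref: Reference, chrom: np.ndarray, pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distance to the nearest gene edge (0 = adjacent base) and its g."""
    dist = np.full(len(pos), np.inf)
    g = np.zeros(len(pos))
    by_chrom: dict[str, list[int]] = {}
    for gi, gene in enumerate(ref.genes):
        by_chrom.setdefault(gene.chrom, []).append(gi)
    for c, idxs in by_chrom.items():
        sel = np.flatnonzero(chrom == c)
        if sel.size == 0:
            continue
        starts = np.array([ref.genes[i].span_start for i in idxs])
        ends = np.array([ref.genes[i].span_end for i in idxs])
        gvals = ref.gene_g[np.array(idxs)]
        p = pos[sel]
        i = np.searchsorted(starts, p, side="right") - 1
        d_left = np.where(i >= 0, p - ends[np.clip(i, 0, None)], np.inf)
        d_left = np.where(d_left < 0, 0, d_left)  # inside the gene
        j = np.clip(i + 1, None, len(starts) - 1)
        d_right = np.where(i + 1 < len(starts), starts[j] - p - 1, np.inf)
        use_right = d_right < d_left
        dist[sel] = np.where(use_right, d_right, d_left)
        left_g = gvals[np.clip(i, 0, None)]
        right_g = gvals[j]
        g[sel] = np.where(use_right, right_g, np.where(i >= 0, left_g, right_g))
    return dist, g


def _nearest_feature(
    ref: Reference, chrom: np.ndarray, pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distance to the nearest conserved element (not strips) and its score."""
    dist = np.full(len(pos), np.inf)
    score = np.zeros(len(pos))
    is_el = ref.feat_kind == "element"
    for c in np.unique(ref.feat_chrom[is_el]):
        sel = np.flatnonzero(chrom == c)
        rows = np.flatnonzero(is_el & (ref.feat_chrom == c))
        if sel.size == 0 or rows.size == 0:
            continue
        starts = ref.feat_start[rows]
        ends = ref.feat_end[rows]
        scores = ref.feat_score[rows]
        order = np.argsort(starts)
        starts, ends, scores = starts[order], ends[order], scores[order]
        p = pos[sel]
        i = np.searchsorted(starts, p, side="right") - 1
        d_left = np.where(i >= 0, np.maximum(p - ends[np.clip(i, 0, None)] + 1, 0), np.inf)
        j = np.clip(i + 1, None, len(starts) - 1)
        d_right = np.where(i + 1 < len(starts), starts[j] - p, np.inf)
        use_right = d_right < d_left
        dist[sel] = np.where(use_right, d_right, d_left)
        s_left = scores[np.clip(i, 0, None)]
        score[sel] = np.where(use_right, scores[j], np.where(i >= 0, s_left, scores[j]))
    return dist, score


def simulate_site_frequencies(
    cfg: SimulationConfig, ref: Reference, rng: np.random.Generator
) -> SiteFrequencies:
    """Realize per-population allele frequencies for every site."""
    nc_chrom, nc_pos, nc_kind = _noncoding_positions(cfg, ref, rng)
    chrom = np.concatenate(
        [np.array(nc_chrom, dtype=object), ref.cod_chrom]
    )
    pos = np.concatenate([np.array(nc_pos, dtype=np.int64), ref.cod_pos])
    kind = np.concatenate(
        [np.array(nc_kind, dtype=object), np.full(len(ref.cod_pos), "coding", dtype=object)]
    )
    # de-duplicate colliding positions (keep first occurrence)
    key = np.array([f"{c}:{p}" for c, p in zip(chrom, pos)])
    _, first = np.unique(key, return_index=True)
    keep = np.sort(first)
    chrom, pos, kind = chrom[keep], pos[keep], kind[keep]

    is_coding = kind == "coding"
    n = len(pos)
    n_pops = len(cfg.populations)

    gene_dist, gene_g = _nearest_gene(cfg, ref, chrom, pos)
    gene_dist[is_coding] = 0.0
    el_dist, el_score = _nearest_feature(ref, chrom, pos)

    # depression factor shared by all populations
    dep = 1.0 - cfg.amplitude(gene_g) * np.exp(
        -np.minimum(gene_dist, 1e12) / cfg.lam
    )
    finite_el = np.isfinite(el_dist)
    el_factor = np.ones(n)
    el_factor[finite_el] = 1.0 - cfg.element_amplitude(el_score[finite_el]) * np.exp(
        -el_dist[finite_el] / cfg.element_lam
    )
    dep = dep * el_factor

    freq = np.zeros((n, n_pops))
    expected = np.zeros((n, n_pops))
    nc = ~is_coding
    c = cfg.maf_concentration
    for k, pop in enumerate(cfg.populations):
        # non-coding: theta-mixture of common and rare baselines, Beta noise
        rare = rng.random(n) < pop.theta
        base = np.where(rare, cfg.mu_rare, pop.mu0)
        m = np.clip(base * dep, 1e-4, 0.499)
        draws = rng.beta(m * c, (1 - m) * c)
        folded = np.minimum(draws, 1 - draws)
        freq[nc, k] = folded[nc]
        expected[nc, k] = (cfg.mu_eff(pop) * dep)[nc]
        # coding: Ne-graded segregation probability and frequency; the
        # conditional frequency distribution is a rare-skewed Beta (shape
        # coding_alpha < 1) with mean nu, an SFS-like spectrum
        pi = cfg.seg_prob(pop)
        nu = cfg.seg_freq_mean(pop)
        a0 = cfg.coding_alpha
        seg = rng.random(n) < pi
        cf = rng.beta(a0, a0 * (1 - nu) / nu, size=n)
        coding_freq = np.where(seg, cf, 0.0)
        freq[is_coding, k] = coding_freq[is_coding]
        expected[is_coding, k] = pi * nu

    # per-site GERP is assigned later from the track; coding candidates
    # already carry their realized score
    gerp = np.full(n, np.nan)
    nonsyn = np.zeros(n, dtype=bool)
    cod_lookup = {
        (c_, int(p_)): (s_, ns_)
        for c_, p_, s_, ns_ in zip(
            ref.cod_chrom, ref.cod_pos, ref.cod_score, ref.cod_nonsyn
        )
    }
    for i in np.flatnonzero(is_coding):
        s_, ns_ = cod_lookup[(chrom[i], int(pos[i]))]
        gerp[i] = s_
        nonsyn[i] = ns_

    return SiteFrequencies(
        chrom=chrom,
        pos=pos,
        kind=kind,
        gerp=gerp,
        nonsyn=nonsyn,
        gene_dist=gene_dist,
        gene_g=gene_g,
        freq=freq,
        expected_maf=expected,
    )


def simulate_genotypes(
    freqs: SiteFrequencies,
    panel: PopulationPanel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial (HWE) genotypes per individual from population frequencies."""
    n = len(freqs.pos)
    geno = np.zeros((n, len(panel.samples)), dtype=np.int8)
    col = 0
    for k, pop in enumerate(cfg.populations):
        nk = panel.n_samples(pop.name)
        p = freqs.freq[:, k][:, None]
        block = rng.binomial(2, np.broadcast_to(p, (n, nk))).astype(np.int8)
        if cfg.missing_rate > 0:
            miss = rng.random((n, nk)) < cfg.missing_rate
            block[miss] = -1
        geno[:, col : col + nk] = block
        col += nk
    return geno


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    cfg: SimulationConfig
    panel: PopulationPanel
    genes: list[GeneRecord]
    track: GerpTrack
    table: SiteTable
    truth: dict
    # per-site arrays aligned with ``table`` rows
    kind: np.ndarray
    expected_maf: np.ndarray
    gene_dist: np.ndarray
    gene_g: np.ndarray


def _make_panel(cfg: SimulationConfig) -> PopulationPanel:
    mapping: dict[str, str] = {}
    ne: dict[str, float] = {}
    for pop in cfg.populations:
        for i in range(pop.n_individuals):
            mapping[f"{pop.name}_{i:03d}"] = pop.name
        if pop.ne is not None:
            ne[pop.name] = pop.ne
    return PopulationPanel.from_mapping(mapping, ne)


def simulate_dataset(cfg: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Generate a full dataset (reference + frequencies + genotypes + truth)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    panel = _make_panel(cfg)
    ref = generate_reference(cfg, rng)
    freqs = simulate_site_frequencies(cfg, ref, rng)
    geno = simulate_genotypes(freqs, panel, cfg, rng)

    n = len(freqs.pos)
    ref_base = _BASES[rng.integers(0, 4, size=n)]
    alt_shift = rng.integers(1, 4, size=n)
    base_idx = np.array([np.flatnonzero(_BASES == b)[0] for b in ref_base])
    alt_base = _BASES[(base_idx + alt_shift) % 4]
    flip = rng.random(n) < cfg.ancestral_flip_fraction
    ancestral = np.where(flip, alt_base, ref_base)

    cons = np.full(n, CONS_CODE[Consequence.NONCODING], dtype=np.int8)
    is_coding = freqs.kind == "coding"
    cons[is_coding & freqs.nonsyn] = CONS_CODE[Consequence.NONSYNONYMOUS]
    cons[is_coding & ~freqs.nonsyn] = CONS_CODE[Consequence.SYNONYMOUS]

    # spiked private singleton load
    spike_arrays = None
    spike_truth = []
    if cfg.spikes:
        used = set(zip(freqs.chrom, freqs.pos.tolist()))
        s_chrom, s_pos, s_score, s_rows = [], [], [], []
        for spike in cfg.spikes:
            if spike.sample not in panel.sample_to_pop:
                raise ValueError(f"spike sample {spike.sample!r} not in panel")
            col_idx = list(panel.samples).index(spike.sample)
            placed_pos = []
            attempts = 0
            while len(placed_pos) < spike.n_sites:
                attempts += 1
                if attempts > 50 * spike.n_sites:
                    raise ValueError(
                        "could not place spike sites: not enough unused coding bases"
                    )
                gi = int(rng.integers(0, len(ref.genes)))
                gene = ref.genes[gi]
                ex = int(rng.integers(0, len(gene.coding_intervals)))
                s, e = gene.coding_intervals[ex]
                p = int(rng.integers(s, e))
                if (gene.chrom, p) in used:
                    continue
                used.add((gene.chrom, p))
                score = float(
                    ref.gene_g[gi]
                    + cfg.coding_gerp_jitter * rng.standard_normal()
                    + spike.delta
                )
                s_chrom.append(gene.chrom)
                s_pos.append(p)
                s_score.append(score)
                s_rows.append(col_idx)
                placed_pos.append(p)
            spike_truth.append(
                dict(sample=spike.sample, delta=spike.delta, n_sites=spike.n_sites)
            )
        ns = len(s_pos)
        spike_geno = np.zeros((ns, len(panel.samples)), dtype=np.int8)
        for r, col_idx in enumerate(s_rows):
            spike_geno[r, col_idx] = 1
        spike_arrays = dict(
            chrom=np.array(s_chrom, dtype=object),
            pos=np.array(s_pos, dtype=np.int64),
            score=np.array(s_score),
            geno=spike_geno,
        )
        sref = _BASES[rng.integers(0, 4, size=ns)]
        salt = _BASES[
            (np.array([np.flatnonzero(_BASES == b)[0] for b in sref]) + rng.integers(1, 4, size=ns)) % 4
        ]
        # merge into the site arrays
        chrom_all = np.concatenate([freqs.chrom, spike_arrays["chrom"]])
        pos_all = np.concatenate([freqs.pos, spike_arrays["pos"]])
        geno = np.vstack([geno, spike_geno])
        ref_base = np.concatenate([ref_base, sref])
        alt_base = np.concatenate([alt_base, salt])
        ancestral = np.concatenate([ancestral, sref])
        cons = np.concatenate(
            [cons, np.full(ns, CONS_CODE[Consequence.NONSYNONYMOUS], dtype=np.int8)]
        )
        gerp_all = np.concatenate([freqs.gerp, spike_arrays["score"]])
        kind_all = np.concatenate([freqs.kind, np.full(ns, "spike", dtype=object)])
        expected_all = np.vstack([freqs.expected_maf, np.zeros((ns, len(cfg.populations)))])
        gene_dist_all = np.concatenate([freqs.gene_dist, np.zeros(ns)])
        gene_g_all = np.concatenate([freqs.gene_g, np.zeros(ns)])
    else:
        chrom_all, pos_all = freqs.chrom, freqs.pos
        gerp_all, kind_all = freqs.gerp, freqs.kind
        expected_all = freqs.expected_maf
        gene_dist_all, gene_g_all = freqs.gene_dist, freqs.gene_g

    track = ref.build_track(
        None
        if spike_arrays is None
        else (spike_arrays["chrom"], spike_arrays["pos"], spike_arrays["score"])
    )
    # non-coding site GERP comes from the track (absent off coverage)
    nc_rows = np.flatnonzero(~np.isfinite(gerp_all))
    for c in np.unique(chrom_all[nc_rows].astype(str)):
        rows = nc_rows[chrom_all[nc_rows].astype(str) == c]
        gerp_all[rows] = track.query_many(c, pos_all[rows])

    # sort everything once by (chrom, pos) so aligned arrays match the table
    _, codes = np.unique(chrom_all.astype(str), return_inverse=True)
    order = np.lexsort((pos_all, codes))
    table = SiteTable(
        chrom_all[order],
        pos_all[order],
        ref_base[order],
        alt_base[order],
        geno[order],
        gerp_all[order],
        cons[order],
        ancestral[order].astype(object),
        panel,
    )

    truth = dict(
        seed=int(cfg.seed if seed is None else seed),
        model=dict(
            a_max=cfg.a_max,
            lam=cfg.lam,
            element_a_max=cfg.element_a_max,
            element_lam=cfg.element_lam,
            mu_rare=cfg.mu_rare,
            conservation_max=cfg.conservation_max,
        ),
        genes={g.gene_id: float(gv) for g, gv in zip(ref.genes, ref.gene_g)},
        populations={
            p.name: dict(
                mu0=p.mu0,
                theta=p.theta,
                mu_eff=cfg.mu_eff(p),
                seg_prob=cfg.seg_prob(p),
                seg_freq_mean=cfg.seg_freq_mean(p),
                n_individuals=p.n_individuals,
            )
            for p in cfg.populations
        },
        spiked=spike_truth,
        n_sites=int(table.n_sites),
    )

    return SimulatedDataset(
        cfg=cfg,
        panel=panel,
        genes=ref.genes,
        track=track,
        table=table,
        truth=truth,
        kind=kind_all[order],
        expected_maf=expected_all[order],
        gene_dist=gene_dist_all[order],
        gene_g=gene_g_all[order],
    )


def spike_load_shift(
    cfg: SimulationConfig, sample: str, delta: float, n_sites: int, seed: int
) -> SimulatedDataset:
    """Convenience wrapper: regenerate the dataset with one spiked sample."""
    spiked_cfg = dataclasses.replace(
        cfg, spikes=cfg.spikes + (SpikeConfig(sample, delta, n_sites),)
    )
    return simulate_dataset(spiked_cfg, seed=seed)


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

#: evenly spaced diversity grades for Ne-graded population sets
THETA_GRADES = (0.1, 0.4, 0.7, 1.0)


def profile_gradient_config(n_genes: int = 500) -> SimulationConfig:
    """Constraint-gradient recovery conditions: many genes across the full
    conservation range, sparse genome-wide flank SNPs, three exchangeable
    populations (pooled-MAF profiles)."""
    return SimulationConfig(
        n_genes=n_genes,
        flank_snp_density=1.8e-4,
        coding_snp_density=0.005,
    )


def ne_gradient_config(n_genes: int = 100) -> SimulationConfig:
    """Per-population depth comparison conditions: four diversity-graded
    populations of 30, denser flank SNPs so each population's windowed MAF
    is well determined."""
    pops = tuple(
        PopulationConfig(f"P{i}", n_individuals=30, theta=th)
        for i, th in enumerate(THETA_GRADES)
    )
    return SimulationConfig(
        n_genes=n_genes,
        flank_snp_density=2e-3,
        coding_snp_density=0.005,
        elements_per_gap=0,
        strips_per_gap=0,
        populations=pops,
    )


def load_comparison_config(
    n_pops: int = 3, n_individuals: int = 20, spikes: tuple[SpikeConfig, ...] = ()
) -> SimulationConfig:
    """Individual load-comparison conditions: exchangeable populations,
    coding sites only, sized to give tens of nonsynonymous singletons per
    individual (as in real exomes)."""
    pops = tuple(
        PopulationConfig(f"Q{i}", n_individuals=n_individuals, theta=0.5)
        for i in range(n_pops)
    )
    return SimulationConfig(
        n_genes=120,
        coding_snp_density=0.075,
        flank_snp_density=0.0,
        elements_per_gap=0,
        strips_per_gap=0,
        populations=pops,
        spikes=spikes,
    )


def theta_graded_load_config() -> SimulationConfig:
    """Population load-summary conditions: four diversity-graded populations
    over a coding-site-rich genome (het / hom-derived contrasts)."""
    pops = tuple(
        PopulationConfig(f"P{i}", n_individuals=20, theta=th)
        for i, th in enumerate(THETA_GRADES)
    )
    return SimulationConfig(
        n_genes=100,
        coding_snp_density=0.04,
        flank_snp_density=0.0,
        elements_per_gap=0,
        strips_per_gap=0,
        populations=pops,
    )


# ---------------------------------------------------------------------------
# Analytic expectations (noise-free oracles)
# ---------------------------------------------------------------------------


def window_decay_mean(a: float, b: float, lam: float) -> float:
    """Average of exp(-d/lam) over distances d in [a, b]."""
    if b <= a:
        raise ValueError("need b > a")
    return lam * (math.exp(-a / lam) - math.exp(-b / lam)) / (b - a)


def expected_window_profile(
    mu: float,
    amplitude: float,
    lam: float,
    window_size: int = 10_000,
    n_windows_per_side: int = 100,
) -> WindowProfile:
    """Noise-free meta-profile: each window holds the model's mean MAF."""
    w, n = window_size, n_windows_per_side
    means = np.array(
        [
            mu * (1 - amplitude * window_decay_mean(j * w, (j + 1) * w, lam))
            for j in range(n)
        ]
    )
    ones = np.ones(n, dtype=np.int64)
    return WindowProfile(
        anchor_kind="gene",
        window_size=w,
        n_windows_per_side=n,
        population=None,
        sum_up=means.copy(),
        count_up=ones.copy(),
        sum_down=means.copy(),
        count_down=ones.copy(),
        n_anchors=1,
    )


def analytic_depth(
    mu: float,
    amplitude: float,
    lam: float,
    window_size: int = 10_000,
    n_windows_per_side: int = 100,
    distal_range: tuple[int, int] = (500_000, 1_000_000),
    central_halfwidth: int = 50_000,
) -> float:
    """Closed-form depth of depression for the noise-free profile."""
    w, n = window_size, n_windows_per_side
    lo, hi = distal_range
    distal_j = [j for j in range(n) if j * w >= lo and (j + 1) * w <= hi]
    central_j = [j for j in range(n) if (j + 1) * w <= central_halfwidth]
    if not distal_j or not central_j:
        raise ValueError("window layout leaves distal or central region empty")
    distal_mean = float(
        np.mean(
            [
                mu * (1 - amplitude * window_decay_mean(j * w, (j + 1) * w, lam))
                for j in distal_j
            ]
        )
    )
    central_min = min(
        mu * (1 - amplitude * window_decay_mean(j * w, (j + 1) * w, lam))
        for j in central_j
    )
    return distal_mean - central_min


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

_CONS_LABEL = {
    CONS_CODE[Consequence.NONSYNONYMOUS]: "missense",
    CONS_CODE[Consequence.SYNONYMOUS]: "coding-synonymous",
    CONS_CODE[Consequence.NONCODING]: "intergenic",
}

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(table: SiteTable, path) -> None:
    """Write the genotype table as an uncompressed VCF v4.2 (GT only)."""
    chroms = list(dict.fromkeys(table.chrom.astype(str)))
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bgscan-simulate\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(table.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in table.geno[i])
            fh.write(
                f"{table.chrom[i]}\t{table.pos0[i] + 1}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write VCF, BED, bedGraph, panel/consequence/ancestral TSVs, truth
    JSON, and a manifest of sha256 checksums. Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "sites.vcf",
        "genes": outdir / "genes.bed",
        "gerp": outdir / "gerp.bedgraph",
        "panel": outdir / "panel.tsv",
        "consequences": outdir / "consequences.tsv",
        "ancestral": outdir / "ancestral.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(ds.table, paths["vcf"])
    write_gene_annotations(ds.genes, paths["genes"])
    write_gerp_track(ds.track, paths["gerp"])
    with open(paths["panel"], "wt") as fh:
        for pop, samples in ds.panel.populations.items():
            ne = ds.panel.ne.get(pop)
            for s in samples:
                fh.write(f"{s}\t{pop}" + (f"\t{ne:g}" if ne is not None else "") + "\n")
    with open(paths["consequences"], "wt") as fh:
        for i in range(ds.table.n_sites):
            label = _CONS_LABEL.get(int(ds.table.cons[i]), "unknown")
            fh.write(f"{ds.table.chrom[i]}\t{ds.table.pos0[i] + 1}\t{label}\n")
    with open(paths["ancestral"], "wt") as fh:
        for i in range(ds.table.n_sites):
            fh.write(f"{ds.table.chrom[i]}\t{ds.table.pos0[i] + 1}\t{ds.table.ancestral[i]}\n")
    with open(paths["truth"], "wt") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest = {}
    for name, p in paths.items():
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest[name] = {"path": p.name, "sha256": digest}
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
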