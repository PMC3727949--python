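"""Constraint-stratified MAF meta-profiles and the depth-of-depression statistic.

A meta-profile stacks, over a set of anchors (gene coding spans or focal
SNPs), the folded MAF of segregating sites in non-overlapping fixed-width
windows on each flank. Offsets are measured outward from the anchor
boundaries: upstream windows leftward from the span start, downstream
windows rightward from the span end; sites inside the focal anchor's own
span never contribute to its flanks, and a site contributes once to every
anchor whose flank span contains it.

The depth of depression summarizes one profile as (mean MAF across distal
windows, both flanks) minus (minimum window MAF in the central region) —
positive when diversity dips toward the anchor, as expected under
background selection around constrained sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import Consequence, GeneRecord, GerpTrack, VariantSite, logger
from .sites import CONS_CODE, SiteTable

_CODING_CONS = (
    Consequence.NONSYNONYMOUS,
    Consequence.SYNONYMOUS,
    Consequence.OTHER_CODING,
)
_CODING_CODES = np.array([CONS_CODE[c] for c in _CODING_CONS])


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    """Site filters used in the robustness analyses.

    ``exclude_gerp_exact_zero`` applies only to analyses that compare
    per-site GERP with MAF (a score of exactly 0 means too few aligned
    species, i.e. no information); it never applies to gene-average GERP.
    """

    exclude_singletons: bool = False
    exclude_annotated_functional: bool = False
    exclude_gerp_gt: float | None = None
    exclude_hwe_p_lt: float | None = None
    exclude_gerp_exact_zero: bool = False

    def __post_init__(self):
        if self.exclude_gerp_gt is not None and not math.isfinite(self.exclude_gerp_gt):
            raise ValueError("exclude_gerp_gt must be finite")
        if self.exclude_hwe_p_lt is not None and not 0 < self.exclude_hwe_p_lt < 1:
            raise ValueError("exclude_hwe_p_lt must be in (0, 1)")


def passes_neutral_filter(site: VariantSite, cfg: FilterConfig) -> bool:
    """Putative-neutrality filter for one site (annotation + GERP threshold).

    A site fails when it is at an annotated functional coding position (and
    that exclusion is on) or when its GERP score exceeds the configured
    threshold; a site with no GERP score passes the threshold test.
    """
    if cfg.exclude_annotated_functional and site.consequence in _CODING_CONS:
        return False
    if (
        cfg.exclude_gerp_gt is not None
        and site.gerp is not None
        and site.gerp > cfg.exclude_gerp_gt
    ):
        return False
    return True


def filter_mask(
    table: SiteTable, cfg: FilterConfig, population: str | None = None
) -> np.ndarray:
    """Vectorized filter over a table; scope-aware singleton exclusion."""
    keep = np.ones(table.n_sites, dtype=bool)
    if cfg.exclude_annotated_functional:
        keep &= ~np.isin(table.cons, _CODING_CODES)
    if cfg.exclude_gerp_gt is not None:
        with np.errstate(invalid="ignore"):
            keep &= ~(table.gerp > cfg.exclude_gerp_gt)
    if cfg.exclude_gerp_exact_zero:
        keep &= table.gerp != 0.0
    if cfg.exclude_singletons:
        keep &= ~table.singleton(population)
    if cfg.exclude_hwe_p_lt is not None:
        hom_ref, het, hom_alt = table.genotype_counts()
        idx = np.flatnonzero(keep)
        for i in idx:
            p = hwe_exact_test(int(hom_ref[i]), int(het[i]), int(hom_alt[i]))
            if p < cfg.exclude_hwe_p_lt:
                keep[i] = False
    return keep


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test for one biallelic site.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts that are no more probable than the observed one.
    Monomorphic sites return 1 by convention. Weights are exact integers
    (multinomial coefficient times 2^het), so the p-value is accurate to
    float rounding of a single division.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0
    weights: dict[int, int] = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        rare_hom = (n_minor - het) // 2
        common_hom = n - het - rare_hom
        if common_hom < 0:
            continue
        weights[het] = (
            math.comb(n, het)
            * math.comb(n - het, rare_hom)
            * (1 << het)
        )
    total = sum(weights.values())
    observed = weights[n_het]
    tail = sum(w for w in weights.values() if w <= observed)
    return min(1.0, tail / total)


# ---------------------------------------------------------------------------
# Gene-level constraint
# ---------------------------------------------------------------------------


def gene_average_gerp(gene: GeneRecord, track: GerpTrack) -> float | None:
    """Mean GERP over all coding bases of a gene that have a track score.

    Every scored coding base enters the average regardless of polymorphism
    status (zeros included); bases absent from the track are excluded from
    numerator and denominator. Returns None (with a warning) when no coding
    base is scored.
    """
    total, covered = 0.0, 0
    for s, e in gene.coding_intervals:
        part_sum, part_n = track.overlap_sum(gene.chrom, s, e)
        total += part_sum
        covered += part_n
    if covered == 0:
        logger.warning(
            "gene %s has no coding base covered by the GERP track; "
            "average undefined", gene.gene_id,
        )
        return None
    excluded = gene.n_coding_bases - covered
    if excluded:
        logger.debug(
            "gene %s: %d coding base(s) without GERP score excluded",
            gene.gene_id, excluded,
        )
    return total / covered


def annotate_gene_average_gerp(
    genes: Sequence[GeneRecord], track: GerpTrack
) -> list[GeneRecord]:
    """Set ``avg_gerp`` on each gene in place; returns the genes."""
    for gene in genes:
        gene.avg_gerp = gene_average_gerp(gene, track)
    return list(genes)


def assign_quantile_bins(values: Mapping[str, float], n_bins: int) -> dict[str, int]:
    """Rank-based bins of near-equal size (sizes differ by <= 1).

    Bin 0 holds the smallest values. Ties are broken by stable (value, key)
    order so the assignment is deterministic; when every value is equal the
    split is by key order alone (warned).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    items = [(v, k) for k, v in values.items() if v is not None and np.isfinite(v)]
    if len(items) < n_bins:
        raise ValueError(f"need >= {n_bins} values, got {len(items)}")
    items.sort()
    if items[0][0] == items[-1][0]:
        logger.warning("all values equal; quantile bins assigned by identifier order")
    n = len(items)
    base, extra = divmod(n, n_bins)
    out: dict[str, int] = {}
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        for _, key in items[start : start + size]:
            out[key] = b
        start += size
    return out


# ---------------------------------------------------------------------------
# Window profiles
# ---------------------------------------------------------------------------


@dataclass
class WindowProfile:
    """Stacked mean-MAF meta-profile around a set of anchors.

    Window ``j`` on the upstream flank covers signed offsets
    ``[-(j+1)w, -jw)`` from the span start; window ``j`` downstream covers
    ``[jw, (j+1)w)`` from the span end. ``mean_*`` entries are NaN where no
    site contributed.
    """

    anchor_kind: str
    window_size: int
    n_windows_per_side: int
    population: str | None
    sum_up: np.ndarray
    count_up: np.ndarray
    sum_down: np.ndarray
    count_down: np.ndarray
    n_anchors: int = 0

    @property
    def mean_up(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.sum_up / self.count_up

    @property
    def mean_down(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.sum_down / self.count_down

    @property
    def total_contributions(self) -> int:
        return int(self.count_up.sum() + self.count_down.sum())

    def rows(self) -> list[dict]:
        """Per-window records ordered from most-upstream to most-downstream."""
        w, n = self.window_size, self.n_windows_per_side
        out = []
        mu, md = self.mean_up, self.mean_down
        for j in range(n - 1, -1, -1):
            out.append(
                dict(
                    side="upstream",
                    offset_start=-(j + 1) * w,
                    offset_end=-j * w,
                    mean_maf=float(mu[j]),
                    snp_count=int(self.count_up[j]),
                )
            )
        for j in range(n):
            out.append(
                dict(
                    side="downstream",
                    offset_start=j * w,
                    offset_end=(j + 1) * w,
                    mean_maf=float(md[j]),
                    snp_count=int(self.count_down[j]),
                )
            )
        return out


def _anchor_spans(anchors) -> list[tuple[str, int, int]]:
    spans = []
    for a in anchors:
        if isinstance(a, GeneRecord):
            spans.append((a.chrom, a.span_start, a.span_end))
        else:
            chrom, pos0 = a[0], int(a[1])
            spans.append((chrom, pos0, pos0 + 1))  # focal SNP as zero-length anchor
    return spans


def build_window_profile(
    table: SiteTable,
    anchors: Sequence,
    window_size: int,
    n_windows_per_side: int,
    population: str | None = None,
    cfg: FilterConfig | None = None,
    anchor_kind: str | None = None,
) -> WindowProfile:
    """Stacked mean-MAF profile of segregating, filter-passing sites.

    ``anchors`` are GeneRecords or (chrom, pos0) focal SNPs. MAF is scoped
    to ``population`` when given, else global. Raises when no site
    contributes to any window.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors supplied")
    if anchor_kind is None:
        anchor_kind = "gene" if isinstance(anchors[0], GeneRecord) else "snp"
    w, n = int(window_size), int(n_windows_per_side)
    if w <= 0 or n <= 0:
        raise ValueError("window_size and n_windows_per_side must be positive")

    maf = table.maf(population)
    keep = table.segregating(population) & ~np.isnan(maf)
    if cfg is not None:
        keep &= filter_mask(table, cfg, population)

    sum_up = np.zeros(n)
    count_up = np.zeros(n, dtype=np.int64)
    sum_down = np.zeros(n)
    count_down = np.zeros(n, dtype=np.int64)

    chrom_slices = table.chrom_index()
    for chrom, s, e in _anchor_spans(anchors):
        sl = chrom_slices.get(chrom)
        if sl is None:
            continue
        pos = table.pos0[sl]
        ok = keep[sl]
        vals = maf[sl]
        # upstream flank [s - n*w, s)
        lo = np.searchsorted(pos, s - n * w, side="left")
        hi = np.searchsorted(pos, s, side="left")
        if hi > lo:
            sel = np.arange(lo, hi)[ok[lo:hi]]
            offs = s - 1 - pos[sel]  # 0 for the base immediately upstream
            bins = offs // w
            np.add.at(sum_up, bins, vals[sel])
            np.add.at(count_up, bins, 1)
        # downstream flank [e, e + n*w)
        lo = np.searchsorted(pos, e, side="left")
        hi = np.searchsorted(pos, e + n * w, side="left")
        if hi > lo:
            sel = np.arange(lo, hi)[ok[lo:hi]]
            offs = pos[sel] - e
            bins = offs // w
            np.add.at(sum_down, bins, vals[sel])
            np.add.at(count_down, bins, 1)

    profile = WindowProfile(
        anchor_kind=anchor_kind,
        window_size=w,
        n_windows_per_side=n,
        population=population,
        sum_up=sum_up,
        count_up=count_up,
        sum_down=sum_down,
        count_down=count_down,
        n_anchors=len(anchors),
    )
    if profile.total_contributions == 0:
        raise ValueError("no site contributed to any window around the anchors")
    return profile


# ---------------------------------------------------------------------------
# Depth of depression
# ---------------------------------------------------------------------------


@dataclass
class DepressionStat:
    """Distal-flank mean MAF minus the central minimum window MAF."""

    distal_mean_maf: float
    central_min_maf: float

    @property
    def depth(self) -> float:
        return self.distal_mean_maf - self.central_min_maf


def depth_of_depression(
    profile: WindowProfile,
    distal_range: tuple[int, int] = (500_000, 1_000_000),
    central_halfwidth: int = 50_000,
) -> DepressionStat:
    """Depth statistic for one profile.

    Distal windows lie entirely within ``[lo, hi]`` absolute offset on
    either flank; central windows lie entirely within ``central_halfwidth``
    of the anchor. Empty windows are skipped (never zero-filled); an empty
    distal flank or central region raises.
    """
    w, n = profile.window_size, profile.n_windows_per_side
    lo, hi = distal_range
    distal_j = [j for j in range(n) if j * w >= lo and (j + 1) * w <= hi]
    central_j = [j for j in range(n) if (j + 1) * w <= central_halfwidth]
    if not distal_j:
        raise ValueError("no window fits inside the distal offset range")
    if not central_j:
        raise ValueError("no window fits inside the central region")

    mu, md = profile.mean_up, profile.mean_down
    up_vals = [mu[j] for j in distal_j if profile.count_up[j] > 0]
    down_vals = [md[j] for j in distal_j if profile.count_down[j] > 0]
    if not up_vals:
        raise ValueError("distal upstream region has no populated window")
    if not down_vals:
        raise ValueError("distal downstream region has no populated window")
    central_vals = [mu[j] for j in central_j if profile.count_up[j] > 0]
    central_vals += [md[j] for j in central_j if profile.count_down[j] > 0]
    if not central_vals:
        raise ValueError("central region has no populated window")

    distal_mean = float(np.mean(up_vals + down_vals))
    central_min = float(np.min(central_vals))
    return DepressionStat(distal_mean_maf=distal_mean, central_min_maf=central_min)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_correlation(xs: Sequence[float], ys: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-reference p-value.

    p is computed from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom
    and clamped into (0, 1] (a numerically exact |r| = 1 would otherwise
    give p = 0).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt(np.sum(xd**2)))
    sy = float(np.sqrt(np.sum(yd**2)))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in xs or ys")
    r = float(np.clip(np.sum(xd * yd) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = float(np.finfo(float).tiny)
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = float(2 * sps.t.sf(abs(t), n - 2))
        p = min(1.0, max(p, float(np.finfo(float).tiny)))
    return CorrelationResult(r=r, p=p, n=n)


# ---------------------------------------------------------------------------
# Distal non-coding focal SNPs and the proximal-vs-distal contrast
# ---------------------------------------------------------------------------


def distance_to_nearest_gene(
    table: SiteTable, genes: Sequence[GeneRecord]
) -> np.ndarray:
    """Distance (bp) from each site to the nearest gene span; 0 inside one.

    Sites on chromosomes without genes get +inf.
    """
    out = np.full(table.n_sites, np.inf)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, sl in table.chrom_index().items():
        gs = by_chrom.get(chrom)
        if not gs:
            continue
        starts = np.array([g.span_start for g in gs])
        ends = np.array([g.span_end for g in gs])
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        pos = table.pos0[sl]
        i = np.searchsorted(starts, pos, side="right") - 1
        d_prev = np.where(
            i >= 0,
            np.maximum(pos - ends[np.clip(i, 0, None)] + 1, 0),
            np.inf,
        )
        # inside the previous gene's span -> distance 0
        inside = (i >= 0) & (pos < ends[np.clip(i, 0, None)])
        j = i + 1
        d_next = np.where(j < len(starts), starts[np.clip(j, None, len(starts) - 1)] - pos, np.inf)
        d = np.minimum(d_prev, d_next)
        d[inside] = 0
        out[sl] = d
    return out


def select_distal_noncoding_snps(
    table: SiteTable,
    genes: Sequence[GeneRecord],
    min_distance: int = 200_000,
    population: str | None = None,
    exclude_gerp_exact_zero: bool = False,
) -> np.ndarray:
    """Indices of segregating sites >= ``min_distance`` from every gene span.

    With ``exclude_gerp_exact_zero`` (used whenever the focal set is binned
    by per-site GERP), sites scored exactly 0 or unscored are dropped.
    """
    d = distance_to_nearest_gene(table, genes)
    keep = (d >= min_distance) & table.segregating(population)
    if exclude_gerp_exact_zero:
        keep &= np.isfinite(table.gerp) & (table.gerp != 0.0)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        logger.warning("no site is %d bp away from every gene", min_distance)
    return idx


def collect_offset_mafs(
    table: SiteTable,
    focal: Sequence[tuple[str, int]],
    max_offset: int,
    population: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(signed offsets, MAFs) of segregating sites around focal positions.

    A site contributes once per focal SNP within range; the focal site
    itself (offset 0) is excluded.
    """
    maf = table.maf(population)
    keep = table.segregating(population) & ~np.isnan(maf)
    chrom_slices = table.chrom_index()
    offs_out, maf_out = [], []
    for chrom, pos0 in focal:
        sl = chrom_slices.get(chrom)
        if sl is None:
            continue
        pos = table.pos0[sl]
        lo = np.searchsorted(pos, pos0 - max_offset, side="left")
        hi = np.searchsorted(pos, pos0 + max_offset + 1, side="left")
        sel = np.arange(lo, hi)[keep[sl][lo:hi]]
        offs = pos[sel] - pos0
        nz = offs != 0
        offs_out.append(offs[nz])
        maf_out.append(maf[sl][sel][nz])
    if offs_out:
        return np.concatenate(offs_out), np.concatenate(maf_out)
    return np.zeros(0, dtype=np.int64), np.zeros(0)


def proximal_distal_test(
    table: SiteTable,
    focal: Sequence[tuple[str, int]],
    proximal_bp: int = 200,
    distal_range: tuple[int, int] = (5_000, 10_000),
    population: str | None = None,
) -> float:
    """Two-sided Mann-Whitney U contrast of per-SNP MAFs near vs far.

    Proximal = sites within ``proximal_bp`` of a focal SNP (focal sites
    excluded); distal = sites with absolute offset in ``distal_range``.
    """
    from .load import mann_whitney_u

    offs, mafs = collect_offset_mafs(table, focal, distal_range[1], population)
    a = np.abs(offs)
    proximal = mafs[a <= proximal_bp]
    distal = mafs[(a >= distal_range[0]) & (a <= distal_range[1])]
    if proximal.size == 0:
        raise ValueError("no SNP in the proximal region")
    if distal.size == 0:
        raise ValueError("no SNP in the distal region")
    return mann_whitney_u(proximal, distal)
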