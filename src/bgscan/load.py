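"""Per-individual mutation-load distributions and nonparametric comparisons.

An individual's load distribution is the multiset of GERP scores at
nonsynonymous sites where they carry the minor allele; under the additive
model a homozygous-minor genotype contributes the score twice. Pairs of
individuals within a population are compared with two-sided Mann-Whitney U
(median shift) and two-sample Kolmogorov-Smirnov (distribution shape)
tests under Bonferroni control, and populations are summarized by binning
the positive GERP range.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import special as sp_special
from scipy import stats as sps

from .io import Consequence, PopulationPanel, VariantSite, logger
from .sites import CONS_CODE, MINOR_ALT, MINOR_TIE, SiteTable

_NONSYN = CONS_CODE[Consequence.NONSYNONYMOUS]

#: exact-null size limits (total observations) for the rank tests
MWU_EXACT_LIMIT = 16
KS_EXACT_LIMIT = 12


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each U value (no ties).

    f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u): the largest pooled
    observation either belongs to x (contributing n2 to U) or to y.
    """
    size = n1 * n2 + 1
    table: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if i == 0 or j == 0:
                table[(i, j)] = np.array([1] + [0] * (i * j), dtype=object)
                continue
            a = np.zeros(size, dtype=object)
            prev = table[(i - 1, j)]
            a[j : j + len(prev)] += prev
            prev = table[(i, j - 1)]
            a[: len(prev)] += prev
            table[(i, j)] = a[: i * j + 1]
    return tuple(int(v) for v in table[(n1, n2)])


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    return u1, pooled


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact (full rank-arrangement null) when the pooled sample has at most
    ``MWU_EXACT_LIMIT`` observations: a tie-free pooled sample uses the
    classical U-count recursion, a tied one enumerates all label
    assignments of the pooled multiset. Larger samples use the normal
    approximation with tie and continuity corrections. The two-sided p is
    the null probability of a U at least as far from its mean as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n1, n2 = len(x), len(y)
    u1, pooled = _u_statistic(x, y)
    mean = n1 * n2 / 2

    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= MWU_EXACT_LIMIT and not has_ties:
        counts = np.array(_u_counts(n1, n2), dtype=float)
        total = counts.sum()
        dev = abs(u1 - mean)
        u_vals = np.arange(len(counts))
        p = counts[np.abs(u_vals - mean) >= dev - 1e-9].sum() / total
        return min(1.0, float(p))
    if n1 + n2 <= MWU_EXACT_LIMIT:
        # ties: enumerate label assignments of the pooled multiset
        srt = np.sort(pooled)
        ranks = sps.rankdata(srt)
        dev = abs(u1 - mean)
        total = extreme = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = float(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
            total += 1
            if abs(u - mean) >= dev - 1e-9:
                extreme += 1
        return extreme / total

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all observations identical
    dev = abs(u1 - mean)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)  # continuity-corrected
    return min(1.0, float(2 * sps.norm.sf(z)))


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), grid, side="right") / len(x)
    cdf_y = np.searchsorted(np.sort(y), grid, side="right") / len(y)
    return float(np.max(np.abs(cdf_x - cdf_y)))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and two-sided p-value.

    D is the sup-distance between the two empirical CDFs. The p-value is
    exact (enumeration of all label assignments of the pooled multiset,
    tie-safe) for pooled sizes up to ``KS_EXACT_LIMIT``, else the
    asymptotic Kolmogorov distribution at sqrt(n m / (n+m)) D.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n1, n2 = len(x), len(y)
    d = _ks_statistic(x, y)

    if n1 + n2 <= KS_EXACT_LIMIT:
        pooled = np.sort(np.concatenate([x, y]))
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            total += 1
            if _ks_statistic(pooled[mask], pooled[~mask]) >= d - 1e-9:
                extreme += 1
        return d, extreme / total

    en = n1 * n2 / (n1 + n2)
    p = float(sp_special.kolmogorov(math.sqrt(en) * d))
    return d, min(1.0, max(p, float(np.finfo(float).tiny)))


# ---------------------------------------------------------------------------
# Individual load distributions
# ---------------------------------------------------------------------------


@dataclass
class LoadDistribution:
    """GERP scores at nonsynonymous minor-allele sites for one individual."""

    sample_id: str
    population: str
    mode: str  # "all" | "singletons"
    scores: np.ndarray
    n_het: int
    n_hom_minor: int

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != self.n_het + 2 * self.n_hom_minor:
            raise ValueError(
                f"{self.sample_id}: |scores|={len(self.scores)} != "
                f"n_het + 2*n_hom_minor = {self.n_het + 2 * self.n_hom_minor}"
            )

    @property
    def empty(self) -> bool:
        return len(self.scores) == 0


def _minor_carrier_counts(
    geno: np.ndarray, minor_code: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(het mask, hom-minor mask) per (site, sample) for given minor codes.

    Ties (alt frequency exactly 1/2) deterministically treat alt as the
    minor allele.
    """
    alt_is_minor = (minor_code == MINOR_ALT) | (minor_code == MINOR_TIE)
    het = geno == 1
    hom_minor = np.where(alt_is_minor[:, None], geno == 2, geno == 0)
    return het, hom_minor


def _nonsyn_mask(table: SiteTable) -> np.ndarray:
    return (table.cons == _NONSYN) & np.isfinite(table.gerp)


def individual_gerp_distribution(
    table: SiteTable,
    sample: str,
    mode: str = "all",
    minor_scope: str = "population",
) -> LoadDistribution:
    """Load distribution for one individual.

    Only nonsynonymous sites with a defined GERP score enter. The minor
    allele is resolved within the individual's population by default
    (``minor_scope="global"`` pools all samples). ``mode="singletons"``
    keeps only sites whose within-population minor-allele count is exactly
    1 (necessarily carried heterozygously by a single individual).
    """
    if mode not in ("all", "singletons"):
        raise ValueError(f"unknown mode {mode!r}")
    pop = table.panel.sample_to_pop[sample]
    scope = pop if minor_scope == "population" else None
    col = table.sample_index(sample)

    site_mask = _nonsyn_mask(table) & table.segregating(pop)
    if mode == "singletons":
        site_mask &= table.singleton(pop)

    geno = table.geno[:, col]
    minor = table.minor_code(scope)
    alt_is_minor = (minor == MINOR_ALT) | (minor == MINOR_TIE)
    het = site_mask & (geno == 1)
    hom = site_mask & np.where(alt_is_minor, geno == 2, geno == 0)

    scores = np.concatenate(
        [table.gerp[het], np.repeat(table.gerp[hom], 2)]
    )
    dist = LoadDistribution(
        sample_id=sample,
        population=pop,
        mode=mode,
        scores=scores,
        n_het=int(het.sum()),
        n_hom_minor=int(hom.sum()),
    )
    if dist.empty:
        logger.warning("individual %s carries no qualifying minor allele", sample)
    return dist


def population_load_distributions(
    table: SiteTable,
    population: str,
    mode: str = "all",
    minor_scope: str = "population",
) -> list[LoadDistribution]:
    """Load distributions for every individual of one population (vectorized)."""
    samples = table.panel.populations[population]
    cols = table.pop_columns(population)
    scope = population if minor_scope == "population" else None

    site_mask = _nonsyn_mask(table) & table.segregating(population)
    if mode == "singletons":
        site_mask &= table.singleton(population)

    geno = table.geno[np.ix_(np.flatnonzero(site_mask), cols)]
    gerp = table.gerp[site_mask]
    minor = table.minor_code(scope)[site_mask]
    het, hom = _minor_carrier_counts(geno, minor)

    out = []
    for k, sample in enumerate(samples):
        h, hm = het[:, k], hom[:, k]
        scores = np.concatenate([gerp[h], np.repeat(gerp[hm], 2)])
        out.append(
            LoadDistribution(
                sample_id=sample,
                population=population,
                mode=mode,
                scores=scores,
                n_het=int(h.sum()),
                n_hom_minor=int(hm.sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pairwise tests
# ---------------------------------------------------------------------------


@dataclass
class PairwiseTestResult:
    sample_a: str
    sample_b: str
    population: str
    u_p: float
    ks_p: float
    m: int
    significant_u: bool
    significant_ks: bool


def pairwise_load_tests(
    distributions: Sequence[LoadDistribution],
    alpha: float = 0.05,
    family_size: int | None = None,
) -> list[PairwiseTestResult]:
    """All-pairs U and KS tests within one population, Bonferroni-corrected.

    Empty distributions are dropped with a warning. The Bonferroni family
    defaults to all C(n, 2) pairs within the population, applied separately
    per test type; ``family_size`` overrides it (e.g. to pool populations).
    Results come back sorted by min(u_p, ks_p).
    """
    usable = [d for d in distributions if not d.empty]
    dropped = len(distributions) - len(usable)
    if dropped:
        logger.warning("%d empty load distribution(s) excluded from pairwise tests", dropped)
    if len(usable) < 2:
        raise ValueError("need >= 2 non-empty load distributions")
    pops = {d.population for d in usable}
    if len(pops) > 1:
        raise ValueError(f"distributions span several populations: {sorted(pops)}")
    population = usable[0].population

    m = family_size if family_size is not None else math.comb(len(usable), 2)
    out = []
    for a, b in itertools.combinations(usable, 2):
        u_p = mann_whitney_u(a.scores, b.scores)
        _, ks_p = ks_two_sample(a.scores, b.scores)
        out.append(
            PairwiseTestResult(
                sample_a=a.sample_id,
                sample_b=b.sample_id,
                population=population,
                u_p=u_p,
                ks_p=ks_p,
                m=m,
                significant_u=u_p <= alpha / m,
                significant_ks=ks_p <= alpha / m,
            )
        )
    out.sort(key=lambda r: min(r.u_p, r.ks_p))
    return out


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------


def polarize_derived(site: VariantSite) -> str | None:
    """Derived allele ("ref"/"alt") from the ancestral call, else None."""
    if site.ancestral is None:
        return None
    anc = site.ancestral.upper()
    if anc == site.ref:
        return "alt"
    if anc == site.alt:
        return "ref"
    return None


def derived_is_alt(table: SiteTable) -> np.ndarray:
    """Vectorized polarization: 1 alt-derived, 0 ref-derived, -1 undefined."""
    out = np.full(table.n_sites, -1, dtype=np.int8)
    anc = np.array([a.upper() if isinstance(a, str) else "" for a in table.ancestral])
    out[anc == table.ref.astype(str)] = 1
    out[anc == table.alt.astype(str)] = 0
    n_undef = int(np.sum(out == -1))
    if n_undef:
        logger.debug("%d site(s) with undefined polarization skipped", n_undef)
    return out


# ---------------------------------------------------------------------------
# Population bin summaries
# ---------------------------------------------------------------------------

QUANTITIES = ("minor_proportion", "het_count", "hom_derived_count", "singleton_count")


def default_bin_edges(quantity: str) -> np.ndarray:
    """Unit-width bins over the positive GERP range ([0,1)...[5,6), >=6);
    proportions additionally get a below-zero bin so they normalize to 1."""
    positive = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, np.inf])
    if quantity == "minor_proportion":
        return np.concatenate([[-np.inf], positive])
    return positive


@dataclass
class PopulationBinSummary:
    population: str
    quantity: str
    bin_edges: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_individuals: int
    per_individual: np.ndarray = field(repr=False, default=None)

    def bin_labels(self) -> list[str]:
        edges = self.bin_edges
        return [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]


def _per_individual_bins(
    table: SiteTable,
    population: str,
    quantity: str,
    bin_edges: np.ndarray,
    samples: Sequence[str],
) -> np.ndarray:
    """(individual x bin) matrix of counts (or proportions)."""
    cols = np.array([table.sample_index(s) for s in samples])
    nonsyn = _nonsyn_mask(table)
    n_bins = len(bin_edges) - 1

    if quantity in ("minor_proportion", "singleton_count"):
        site_mask = nonsyn & table.segregating(population)
        if quantity == "singleton_count":
            site_mask &= table.singleton(population)
        geno = table.geno[np.ix_(np.flatnonzero(site_mask), cols)]
        gerp = table.gerp[site_mask]
        minor = table.minor_code(population)[site_mask]
        het, hom = _minor_carrier_counts(geno, minor)
        weights = het.astype(float) + 2.0 * hom  # additive: hom-minor counts twice
        if quantity == "singleton_count":
            weights = het.astype(float) + hom  # carried sites (necessarily het)
    elif quantity == "het_count":
        site_mask = nonsyn
        geno = table.geno[np.ix_(np.flatnonzero(site_mask), cols)]
        gerp = table.gerp[site_mask]
        weights = (geno == 1).astype(float)
    elif quantity == "hom_derived_count":
        derived = derived_is_alt(table)
        site_mask = nonsyn & (derived >= 0)
        geno = table.geno[np.ix_(np.flatnonzero(site_mask), cols)]
        gerp = table.gerp[site_mask]
        hom_code = np.where(derived[site_mask] == 1, 2, 0)
        weights = (geno == hom_code[:, None]).astype(float)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")

    bin_idx = np.digitize(gerp, bin_edges) - 1
    in_range = (bin_idx >= 0) & (bin_idx < n_bins)
    mat = np.zeros((len(samples), n_bins))
    for b in range(n_bins):
        rows = in_range & (bin_idx == b)
        mat[:, b] = weights[rows].sum(axis=0)
    if quantity == "minor_proportion":
        totals = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(totals > 0, mat / totals, np.nan)
    return mat


def population_bin_summary(
    table: SiteTable,
    population: str,
    quantity: str,
    bin_edges: np.ndarray | None = None,
    samples: Sequence[str] | None = None,
    ci: str = "normal",
    n_boot: int = 1000,
    seed: int = 0,
) -> PopulationBinSummary:
    """Across-individual mean and 95% CI of per-bin GERP-load values.

    The per-individual value is the count (or proportion) of qualifying
    nonsynonymous sites in each GERP bin; the CI is the normal
    approximation mean +/- 1.96 sd/sqrt(n) by default, or a bootstrap
    percentile interval with ``ci="bootstrap"``.
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"quantity must be one of {QUANTITIES}")
    if samples is None:
        samples = table.panel.populations[population]
    if len(samples) == 0:
        raise ValueError(f"population {population!r} has no samples")
    edges = np.asarray(
        default_bin_edges(quantity) if bin_edges is None else bin_edges, dtype=float
    )
    mat = _per_individual_bins(table, population, quantity, edges, samples)
    n = mat.shape[0]
    mean = np.nanmean(mat, axis=0)
    if ci == "normal":
        sd = np.nanstd(mat, axis=0, ddof=1) if n > 1 else np.zeros(mat.shape[1])
        half = 1.96 * sd / math.sqrt(n)
        lo, hi = mean - half, mean + half
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, mat.shape[1]))
        for r in range(n_boot):
            reps[r] = np.nanmean(mat[rng.integers(0, n, size=n)], axis=0)
        lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return PopulationBinSummary(
        population=population,
        quantity=quantity,
        bin_edges=edges,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        n_individuals=n,
        per_individual=mat,
    )


def equalize_sample_sizes(
    panel: PopulationPanel, n: int, seed: int
) -> dict[str, list[str]]:
    """Deterministically draw ``n`` samples per population (without
    replacement); populations with fewer than ``n`` are excluded with a
    warning. Downstream singleton status must be re-evaluated on the
    subset (``SiteTable.subset_samples`` does)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for pop, samples in panel.populations.items():
        if len(samples) < n:
            logger.warning(
                "population %s excluded from equal-size sampling "
                "(%d < %d individuals)", pop, len(samples), n,
            )
            continue
        pick = rng.choice(len(samples), size=n, replace=False)
        out[pop] = [samples[i] for i in sorted(pick)]
    return out


def per_individual_positive_totals(
    table: SiteTable, population: str, quantity: str,
    samples: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-individual totals over all positive-GERP bins (for group tests)."""
    if samples is None:
        samples = table.panel.populations[population]
    edges = np.array([0.0, np.inf])
    mat = _per_individual_bins(table, population, quantity, edges, samples)
    return mat[:, 0]


def group_difference_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Two-sided Mann-Whitney U over per-individual positive-GERP totals."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    return mann_whitney_u(a, b)
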