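"""Column-oriented container for many variant sites.

Analyses over hundreds of thousands of sites need vectorized access to
positions, genotypes, and per-population allele frequencies; ``SiteTable``
stores one genotype matrix (sites x samples, alt-allele dosage, -1 missing)
plus per-site annotation arrays, sorted by (chrom, pos). It is equivalent to
a list of :class:`bgscan.io.VariantSite` (converters both ways) but supports
the windowed and per-individual computations without a Python-level loop
per site.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .io import Consequence, PopulationPanel, VariantSite

_CONS_ORDER = [
    Consequence.NONSYNONYMOUS,
    Consequence.SYNONYMOUS,
    Consequence.OTHER_CODING,
    Consequence.NONCODING,
    Consequence.UNKNOWN,
]
CONS_CODE = {c: i for i, c in enumerate(_CONS_ORDER)}
CODE_CONS = {i: c for i, c in enumerate(_CONS_ORDER)}

# minor-allele codes
MINOR_REF, MINOR_ALT, MINOR_TIE = 0, 1, 2
_MINOR_NAME = {MINOR_REF: "ref", MINOR_ALT: "alt", MINOR_TIE: "tie"}


class SiteTable:
    """Sorted table of biallelic SNVs with genotypes and annotations."""

    def __init__(
        self,
        chrom: np.ndarray,
        pos0: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        geno: np.ndarray,
        gerp: np.ndarray,
        cons: np.ndarray,
        ancestral: np.ndarray,
        panel: PopulationPanel,
    ):
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos0, dtype=np.int64)
        n = len(pos0)
        geno = np.asarray(geno, dtype=np.int8)
        if geno.shape != (n, len(panel.samples)):
            raise ValueError(
                f"genotype matrix shape {geno.shape} != ({n}, {len(panel.samples)})"
            )
        # sort by (chrom, pos)
        if n:
            _, codes = np.unique(chrom.astype(str), return_inverse=True)
        else:
            codes = np.zeros(0, dtype=np.int64)
        order = np.lexsort((pos0, codes))
        self.chrom = chrom[order]
        self.pos0 = pos0[order]
        self.ref = np.asarray(ref, dtype=object)[order]
        self.alt = np.asarray(alt, dtype=object)[order]
        self.geno = geno[order]
        self.gerp = np.asarray(gerp, dtype=np.float64)[order]
        self.cons = np.asarray(cons, dtype=np.int8)[order]
        self.ancestral = np.asarray(ancestral, dtype=object)[order]
        self.panel = panel
        self.samples = list(panel.samples)
        self._cache: dict = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_sites(
        cls, sites: Iterable[VariantSite], panel: PopulationPanel
    ) -> "SiteTable":
        rows = list(sites)
        n = len(rows)
        chrom = np.array([s.chrom for s in rows], dtype=object)
        pos0 = np.array([s.pos0 for s in rows], dtype=np.int64)
        ref = np.array([s.ref for s in rows], dtype=object)
        alt = np.array([s.alt for s in rows], dtype=object)
        geno = (
            np.vstack([s.genotypes for s in rows]).astype(np.int8)
            if rows
            else np.zeros((0, len(panel.samples)), dtype=np.int8)
        )
        gerp = np.array(
            [np.nan if s.gerp is None else s.gerp for s in rows], dtype=np.float64
        )
        cons = np.array([CONS_CODE[s.consequence] for s in rows], dtype=np.int8)
        anc = np.array([s.ancestral for s in rows], dtype=object)
        return cls(chrom, pos0, ref, alt, geno.reshape(n, -1), gerp, cons, anc, panel)

    # -- basic shape --------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos0)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return self.n_sites

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def pop_columns(self, pop: str | None = None) -> np.ndarray:
        """Genotype-matrix column indices for one population (or all)."""
        if pop is None:
            return np.arange(self.n_samples)
        samples = self.panel.populations[pop]
        return np.array([self.samples.index(s) for s in samples])

    def chrom_index(self) -> dict[str, slice]:
        """Per-chromosome row slices (table is sorted by chrom, pos)."""
        key = "chrom_index"
        if key not in self._cache:
            out: dict[str, slice] = {}
            if self.n_sites:
                bounds = np.flatnonzero(self.chrom[1:] != self.chrom[:-1]) + 1
                starts = np.concatenate([[0], bounds])
                ends = np.concatenate([bounds, [self.n_sites]])
                for s, e in zip(starts, ends):
                    out[self.chrom[s]] = slice(int(s), int(e))
            self._cache[key] = out
        return self._cache[key]

    # -- allele counts and frequencies -------------------------------------

    def _counts(self, pop: str | None) -> tuple[np.ndarray, np.ndarray]:
        key = ("counts", pop)
        if key not in self._cache:
            sub = self.geno[:, self.pop_columns(pop)]
            called_mask = sub >= 0
            alt = np.where(called_mask, sub, 0).sum(axis=1).astype(np.int64)
            called = 2 * called_mask.sum(axis=1).astype(np.int64)
            self._cache[key] = (alt, called)
        return self._cache[key]

    def alt_count(self, pop: str | None = None) -> np.ndarray:
        return self._counts(pop)[0]

    def called_alleles(self, pop: str | None = None) -> np.ndarray:
        return self._counts(pop)[1]

    def maf(self, pop: str | None = None) -> np.ndarray:
        """Folded MAF per site (NaN where no called alleles)."""
        key = ("maf", pop)
        if key not in self._cache:
            alt, called = self._counts(pop)
            with np.errstate(divide="ignore", invalid="ignore"):
                maf = np.minimum(alt, called - alt) / called
            maf[called == 0] = np.nan
            self._cache[key] = maf
        return self._cache[key]

    def minor_code(self, pop: str | None = None) -> np.ndarray:
        """Per-site minor-allele code (MINOR_REF/MINOR_ALT/MINOR_TIE)."""
        key = ("minor", pop)
        if key not in self._cache:
            alt, called = self._counts(pop)
            code = np.full(self.n_sites, MINOR_ALT, dtype=np.int8)
            code[2 * alt > called] = MINOR_REF
            code[2 * alt == called] = MINOR_TIE
            self._cache[key] = code
        return self._cache[key]

    def minor_count(self, pop: str | None = None) -> np.ndarray:
        alt, called = self._counts(pop)
        return np.minimum(alt, called - alt)

    def segregating(self, pop: str | None = None) -> np.ndarray:
        return self.minor_count(pop) >= 1

    def singleton(self, pop: str | None = None) -> np.ndarray:
        """Sites whose minor allele count (in scope) is exactly 1."""
        return self.minor_count(pop) == 1

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(n_hom_ref, n_het, n_hom_alt) per site over all samples."""
        key = "geno_counts"
        if key not in self._cache:
            g = self.geno
            self._cache[key] = (
                (g == 0).sum(axis=1),
                (g == 1).sum(axis=1),
                (g == 2).sum(axis=1),
            )
        return self._cache[key]

    # -- subsetting ---------------------------------------------------------

    def subset(self, mask_or_index: np.ndarray) -> "SiteTable":
        idx = np.asarray(mask_or_index)
        return SiteTable(
            self.chrom[idx],
            self.pos0[idx],
            self.ref[idx],
            self.alt[idx],
            self.geno[idx],
            self.gerp[idx],
            self.cons[idx],
            self.ancestral[idx],
            self.panel,
        )

    def subset_samples(self, keep: dict[str, Sequence[str]]) -> "SiteTable":
        """Restrict to a sample subset; frequencies/singletons re-derive."""
        panel = self.panel.subset(keep)
        cols = np.array([self.samples.index(s) for s in panel.samples])
        return SiteTable(
            self.chrom,
            self.pos0,
            self.ref,
            self.alt,
            self.geno[:, cols],
            self.gerp,
            self.cons,
            self.ancestral,
            panel,
        )

    # -- interop ------------------------------------------------------------

    def site(self, i: int) -> VariantSite:
        from .io import site_frequencies

        g = self.geno[i]
        freqs = site_frequencies(g, self.panel)
        gerp = None if np.isnan(self.gerp[i]) else float(self.gerp[i])
        minor = self.minor_count()[i]
        return VariantSite(
            chrom=str(self.chrom[i]),
            pos0=int(self.pos0[i]),
            ref=str(self.ref[i]),
            alt=str(self.alt[i]),
            genotypes=g.copy(),
            maf_global=freqs["maf_global"],
            maf_by_pop=freqs["maf_by_pop"],
            minor_allele_by_pop=freqs["minor_by_pop"],
            minor_allele_global=freqs["minor_global"],
            gerp=gerp,
            consequence=CODE_CONS[int(self.cons[i])],
            ancestral=self.ancestral[i],
            segregating=bool(minor >= 1),
        )

    def iter_sites(self) -> Iterable[VariantSite]:
        for i in range(self.n_sites):
            yield self.site(i)


def as_site_table(sites, panel: PopulationPanel | None = None) -> SiteTable:
    """Coerce a SiteTable or an iterable of VariantSite into a SiteTable."""
    if isinstance(sites, SiteTable):
        return sites
    if panel is None:
        raise ValueError("a panel is required to build a SiteTable from sites")
    return SiteTable.from_sites(sites, panel)
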