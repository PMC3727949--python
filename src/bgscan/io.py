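"""Readers and core data model for variant, annotation, and constraint inputs.

All genomic intervals are handled internally as 0-based half-open; VCF and
other 1-based inputs are converted on read. Readers are gzip-aware (by file
suffix) and report malformed input with the offending line number. Skipped
records (multiallelic, non-SNV, malformed genotypes) are tallied and logged
rather than silently dropped.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("bgscan")

MISSING = -1  # genotype code for a missing call

_AUTOSOME_RE = re.compile(r"^(chr)?(\d+)$")


class ParseError(ValueError):
    """Malformed input file; carries the path and 1-based line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        loc = f"{self.path}:{lineno}" if lineno is not None else self.path
        super().__init__(f"{loc}: {message}")


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _data_lines(path) -> Iterator[tuple[int, list[str]]]:
    """Yield (lineno, fields) for non-empty, non-comment lines of a TSV."""
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line.split("\t")


def is_autosome(chrom: str) -> bool:
    return _AUTOSOME_RE.match(chrom) is not None


# ---------------------------------------------------------------------------
# Population panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationPanel:
    """Sample-to-population assignment, with optional per-population Ne.

    ``populations`` preserves the order samples appear in the panel file;
    every sample belongs to exactly one population and the per-population
    sample lists are disjoint.
    """

    sample_to_pop: Mapping[str, str]
    populations: Mapping[str, tuple[str, ...]]
    ne: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for pop, samples in self.populations.items():
            for s in samples:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {pop!r}"
                    )
                if self.sample_to_pop.get(s) != pop:
                    raise ValueError(f"inconsistent population for sample {s!r}")
                seen[s] = pop
        if set(seen) != set(self.sample_to_pop):
            raise ValueError("sample_to_pop and populations are inconsistent")
        for pop, ne in self.ne.items():
            if not np.isfinite(ne) or ne <= 0:
                raise ValueError(f"Ne for population {pop!r} must be > 0, got {ne}")

    @classmethod
    def from_mapping(
        cls, sample_to_pop: Mapping[str, str], ne: Mapping[str, float] | None = None
    ) -> "PopulationPanel":
        pops: dict[str, list[str]] = {}
        for sample, pop in sample_to_pop.items():
            pops.setdefault(pop, []).append(sample)
        return cls(
            sample_to_pop=dict(sample_to_pop),
            populations={p: tuple(s) for p, s in pops.items()},
            ne=dict(ne or {}),
        )

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(s for pop in self.populations.values() for s in pop)

    @property
    def population_codes(self) -> tuple[str, ...]:
        return tuple(self.populations)

    def n_samples(self, pop: str | None = None) -> int:
        if pop is None:
            return len(self.sample_to_pop)
        return len(self.populations[pop])

    def with_ne(self, ne: Mapping[str, float]) -> "PopulationPanel":
        unknown = set(ne) - set(self.populations)
        if unknown:
            raise ValueError(f"Ne given for unknown population(s): {sorted(unknown)}")
        return PopulationPanel(self.sample_to_pop, self.populations, dict(ne))

    def subset(self, keep: Mapping[str, Sequence[str]]) -> "PopulationPanel":
        """Panel restricted to ``keep`` (population -> samples)."""
        s2p = {}
        pops = {}
        for pop, samples in keep.items():
            for s in samples:
                if self.sample_to_pop.get(s) != pop:
                    raise ValueError(f"sample {s!r} is not in population {pop!r}")
                s2p[s] = pop
            pops[pop] = tuple(samples)
        ne = {p: v for p, v in self.ne.items() if p in pops}
        return PopulationPanel(s2p, pops, ne)


def read_population_panel(path) -> PopulationPanel:
    """Read a 2/3-column TSV (sample, population[, Ne]) into a panel.

    Duplicate sample rows and non-numeric Ne raise :class:`ParseError` with
    the line number; Ne must be consistent within a population.
    """
    sample_to_pop: dict[str, str] = {}
    pops: dict[str, list[str]] = {}
    ne: dict[str, float] = {}
    n_rows = 0
    for lineno, fields in _data_lines(path):
        if len(fields) not in (2, 3):
            raise ParseError(path, lineno, f"expected 2 or 3 columns, got {len(fields)}")
        sample, pop = fields[0].strip(), fields[1].strip()
        if not sample or not pop:
            raise ParseError(path, lineno, "empty sample or population field")
        if sample in sample_to_pop:
            raise ParseError(path, lineno, f"duplicate sample {sample!r}")
        sample_to_pop[sample] = pop
        pops.setdefault(pop, []).append(sample)
        if len(fields) == 3 and fields[2].strip():
            try:
                value = float(fields[2])
            except ValueError:
                raise ParseError(
                    path, lineno, f"non-numeric Ne value {fields[2]!r}"
                ) from None
            if value <= 0:
                raise ParseError(path, lineno, f"Ne must be > 0, got {value}")
            prev = ne.setdefault(pop, value)
            if prev != value:
                raise ParseError(
                    path, lineno, f"conflicting Ne for population {pop!r}"
                )
        n_rows += 1
    if n_rows == 0:
        raise ParseError(path, None, "empty population panel")
    return PopulationPanel(
        sample_to_pop, {p: tuple(s) for p, s in pops.items()}, ne
    )


def read_ne_table(path) -> dict[str, float]:
    """Read a per-population effective-size table (population, Ne)."""
    out: dict[str, float] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "expected 2 columns (population, Ne)")
        pop = fields[0].strip()
        try:
            value = float(fields[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric Ne {fields[1]!r}") from None
        if value <= 0:
            raise ParseError(path, lineno, f"Ne must be > 0, got {value}")
        if pop in out and out[pop] != value:
            raise ParseError(path, lineno, f"conflicting Ne for {pop!r}")
        out[pop] = value
    return out


# ---------------------------------------------------------------------------
# Minor allele frequency
# ---------------------------------------------------------------------------


def compute_maf(alt_count: int, called_alleles: int) -> tuple[float, str]:
    """Folded minor-allele frequency over non-missing alleles.

    Returns ``(maf, minor)`` where ``minor`` is one of ``"ref"``, ``"alt"``,
    or ``"tie"`` (alt frequency exactly 1/2). Raises on zero called alleles
    (undefined frequency).
    """
    if called_alleles <= 0:
        raise ValueError("MAF undefined: no called alleles")
    if not 0 <= alt_count <= called_alleles:
        raise ValueError(
            f"alt_count {alt_count} outside [0, {called_alleles}]"
        )
    ref_count = called_alleles - alt_count
    if alt_count == ref_count:
        return alt_count / called_alleles, "tie"
    if alt_count < ref_count:
        return alt_count / called_alleles, "alt"
    return ref_count / called_alleles, "ref"


# ---------------------------------------------------------------------------
# GERP constraint track
# ---------------------------------------------------------------------------


class GerpTrack:
    """Per-base constraint scores as non-overlapping scored intervals.

    Positions without coverage are *absent* (``None``/NaN), never 0 — a score
    of exactly 0 is a meaningful value (too few aligned species) and distinct
    from "no data".
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = {}
        for chrom, (starts, ends, scores) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            scores = np.asarray(scores, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, scores = starts[order], ends[order], scores[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: interval with end <= start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping intervals")
            self._data[chrom] = (starts, ends, scores)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int, float]]
    ) -> "GerpTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in intervals:
            by_chrom.setdefault(chrom, []).append((start, end, score))
        data = {}
        for chrom, rows in by_chrom.items():
            starts, ends, scores = zip(*rows)
            data[chrom] = (np.array(starts), np.array(ends), np.array(scores))
        return cls(data)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._data)

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())

    def intervals(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom, (starts, ends, scores) in self._data.items():
            for s, e, v in zip(starts, ends, scores):
                yield chrom, int(s), int(e), float(v)

    def query(self, chrom: str, pos0: int) -> float | None:
        """Score at a single 0-based position, or None outside coverage."""
        entry = self._data.get(chrom)
        if entry is None:
            return None
        starts, ends, scores = entry
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i >= 0 and pos0 < ends[i]:
            return float(scores[i])
        return None

    def query_many(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`query`; absent positions come back as NaN."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.full(pos0.shape, np.nan)
        entry = self._data.get(chrom)
        if entry is None:
            return out
        starts, ends, scores = entry
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        covered = np.zeros_like(ok)
        covered[ok] = pos0[ok] < ends[idx[ok]]
        out[covered] = scores[idx[covered]]
        return out

    def overlap_sum(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """(sum of per-base scores, number of covered bases) over [start, end)."""
        entry = self._data.get(chrom)
        if entry is None or end <= start:
            return 0.0, 0
        starts, ends, scores = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0, 0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float(np.sum(ov * scores[lo:hi])), int(np.sum(ov))


def read_gerp_track(path) -> GerpTrack:
    """Read a 4-column bedGraph (chrom, start, end, score), 0-based half-open.

    Overlapping intervals or ``end <= start`` raise :class:`ParseError` with
    the offending line number.
    """
    rows: dict[str, list[tuple[int, int, float, int]]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end, score = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError:
            raise ParseError(path, lineno, "non-numeric start/end/score") from None
        if end <= start:
            raise ParseError(path, lineno, f"end {end} <= start {start}")
        rows.setdefault(chrom, []).append((start, end, score, lineno))
    data = {}
    for chrom, items in rows.items():
        items.sort(key=lambda r: r[0])
        for prev, cur in zip(items, items[1:]):
            if cur[0] < prev[1]:
                raise ParseError(
                    path,
                    cur[3],
                    f"interval {chrom}:{cur[0]}-{cur[1]} overlaps "
                    f"{chrom}:{prev[0]}-{prev[1]}",
                )
        starts, ends, scores, _ = zip(*items)
        data[chrom] = (np.array(starts), np.array(ends), np.array(scores))
    return GerpTrack(data)


def write_gerp_track(track: GerpTrack, path) -> None:
    with open(path, "wt") as fh:
        for chrom, start, end, score in track.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge overlapping/adjacent-overlapping 0-based half-open intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"interval with end {e} <= start {s}")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass
class GeneRecord:
    """A gene's coding footprint: span extent plus merged coding intervals."""

    gene_id: str
    chrom: str
    span_start: int
    span_end: int
    coding_intervals: tuple[tuple[int, int], ...]
    avg_gerp: float | None = None
    bin_index: int | None = None

    def __post_init__(self):
        if self.span_end <= self.span_start:
            raise ValueError(f"{self.gene_id}: empty span")
        self.coding_intervals = merge_intervals(self.coding_intervals)
        for s, e in self.coding_intervals:
            if s < self.span_start or e > self.span_end:
                raise ValueError(
                    f"{self.gene_id}: coding interval [{s},{e}) outside span "
                    f"[{self.span_start},{self.span_end})"
                )

    @property
    def n_coding_bases(self) -> int:
        return sum(e - s for s, e in self.coding_intervals)


def read_gene_annotations(path) -> list[GeneRecord]:
    """Read gene coding annotations from BED12 or grouped BED4/BED6.

    BED12 rows are one gene each (blocks = coding intervals). Grouped BED
    rows are one exon each, grouped by the name column; overlapping exons of
    a gene are merged and its span is the exon envelope. Genes come back
    sorted by (chrom, span_start).
    """
    bed12: dict[str, GeneRecord] = {}
    grouped: dict[str, list[tuple[str, int, int, int]]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) >= 12:
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != count or len(offsets) != count:
                raise ParseError(path, lineno, "blockCount does not match block lists")
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            for s, e in blocks:
                if s < start or e > end:
                    raise ParseError(
                        path, lineno, f"block [{s},{e}) outside gene span [{start},{end})"
                    )
            if name in bed12 or name in grouped:
                raise ParseError(path, lineno, f"duplicate gene id {name!r}")
            bed12[name] = GeneRecord(name, chrom, start, end, tuple(blocks))
        elif len(fields) >= 4:
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if end <= start:
                raise ParseError(path, lineno, f"end {end} <= start {start}")
            if name in bed12:
                raise ParseError(path, lineno, f"duplicate gene id {name!r}")
            rows = grouped.setdefault(name, [])
            if rows and rows[0][0] != chrom:
                raise ParseError(path, lineno, f"gene {name!r} spans two chromosomes")
            rows.append((chrom, start, end, lineno))
        else:
            raise ParseError(path, lineno, f"expected >= 4 BED columns, got {len(fields)}")
    genes = list(bed12.values())
    for name, rows in grouped.items():
        chrom = rows[0][0]
        ivs = merge_intervals((s, e) for _, s, e, _ in rows)
        genes.append(GeneRecord(name, chrom, ivs[0][0], ivs[-1][1], ivs))
    if not genes:
        logger.warning("gene annotation file %s contains no genes", path)
    genes.sort(key=lambda g: (g.chrom, g.span_start, g.gene_id))
    return genes


def write_gene_annotations(genes: Sequence[GeneRecord], path) -> None:
    """Write genes as BED12 (round-trips exactly through the reader)."""
    with open(path, "wt") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span_start, g.gene_id)):
            sizes = ",".join(str(e - s) for s, e in g.coding_intervals)
            offsets = ",".join(str(s - g.span_start) for s, e in g.coding_intervals)
            fh.write(
                f"{g.chrom}\t{g.span_start}\t{g.span_end}\t{g.gene_id}\t0\t+\t"
                f"{g.span_start}\t{g.span_end}\t0\t{len(g.coding_intervals)}\t"
                f"{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Functional consequences
# ---------------------------------------------------------------------------


class Consequence(Enum):
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    OTHER_CODING = "other_coding_functional"
    NONCODING = "noncoding"
    UNKNOWN = "unknown"


#: Mapping from SeattleSeq-style annotation strings onto the consequence enum.
CONSEQUENCE_ALIASES: dict[str, Consequence] = {
    "missense": Consequence.NONSYNONYMOUS,
    "missense-near-splice": Consequence.NONSYNONYMOUS,
    "nonsynonymous": Consequence.NONSYNONYMOUS,
    "coding-synonymous": Consequence.SYNONYMOUS,
    "coding-synonymous-near-splice": Consequence.SYNONYMOUS,
    "synonymous": Consequence.SYNONYMOUS,
    "stop-gained": Consequence.OTHER_CODING,
    "stop-gained-near-splice": Consequence.OTHER_CODING,
    "stop-lost": Consequence.OTHER_CODING,
    "splice-donor": Consequence.OTHER_CODING,
    "splice-acceptor": Consequence.OTHER_CODING,
    "coding-notmod3": Consequence.OTHER_CODING,
    "coding": Consequence.OTHER_CODING,
    "intron": Consequence.NONCODING,
    "intron-near-splice": Consequence.NONCODING,
    "utr-3": Consequence.NONCODING,
    "utr-5": Consequence.NONCODING,
    "3-prime-utr": Consequence.NONCODING,
    "5-prime-utr": Consequence.NONCODING,
    "intergenic": Consequence.NONCODING,
    "near-gene-3": Consequence.NONCODING,
    "near-gene-5": Consequence.NONCODING,
    "non-coding-exon": Consequence.NONCODING,
    "noncoding": Consequence.NONCODING,
}


def map_consequence(label: str, *, _warned: set = set()) -> Consequence:
    key = label.strip().lower()
    cons = CONSEQUENCE_ALIASES.get(key)
    if cons is None:
        if key not in _warned:
            logger.warning("unrecognized consequence string %r mapped to unknown", label)
            _warned.add(key)
        return Consequence.UNKNOWN
    return cons


def read_consequence_table(path) -> dict[tuple[str, int], Consequence]:
    """Read a (chrom, 1-based pos, consequence) TSV into a site->enum map.

    Duplicate positions with conflicting consequences raise; duplicates with
    the same consequence are tolerated.
    """
    out: dict[tuple[str, int], Consequence] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, "expected 3 columns (chrom, pos, consequence)")
        chrom = fields[0]
        try:
            pos0 = int(fields[1]) - 1
        except ValueError:
            raise ParseError(path, lineno, f"non-integer position {fields[1]!r}") from None
        cons = map_consequence(fields[2])
        key = (chrom, pos0)
        if key in out and out[key] is not cons:
            raise ParseError(
                path, lineno,
                f"conflicting consequence for {chrom}:{pos0 + 1} "
                f"({out[key].value} vs {cons.value})",
            )
        out[key] = cons
    return out


def read_ancestral_table(path) -> dict[tuple[str, int], str]:
    """Read (chrom, 1-based pos, ancestral base) rows; unknown bases skipped."""
    out: dict[tuple[str, int], str] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, "expected 3 columns (chrom, pos, base)")
        chrom = fields[0]
        try:
            pos0 = int(fields[1]) - 1
        except ValueError:
            raise ParseError(path, lineno, f"non-integer position {fields[1]!r}") from None
        base = fields[2].strip().upper()
        if base in {"A", "C", "G", "T"}:
            out[(chrom, pos0)] = base
    return out


# ---------------------------------------------------------------------------
# Variant sites
# ---------------------------------------------------------------------------


@dataclass
class VariantSite:
    """One biallelic SNV with genotypes and per-population folded MAF.

    ``genotypes`` holds the alt-allele count per sample (0/1/2, -1 missing)
    in panel sample order. MAF values are folded to [0, 0.5] and computed
    over non-missing alleles only.
    """

    chrom: str
    pos0: int
    ref: str
    alt: str
    genotypes: np.ndarray
    maf_global: float | None = None
    maf_by_pop: dict[str, float | None] = field(default_factory=dict)
    minor_allele_by_pop: dict[str, str | None] = field(default_factory=dict)
    minor_allele_global: str | None = None
    gerp: float | None = None
    consequence: Consequence = Consequence.UNKNOWN
    ancestral: str | None = None
    segregating: bool = True

    @property
    def pos(self) -> int:
        """1-based position (VCF convention)."""
        return self.pos0 + 1


def site_frequencies(genotypes: np.ndarray, panel: PopulationPanel) -> dict:
    """Global and per-population folded MAF for one genotype vector."""
    g = np.asarray(genotypes)
    called_mask = g >= 0
    alt = int(g[called_mask].sum())
    called = int(2 * called_mask.sum())
    out: dict = {"maf_by_pop": {}, "minor_by_pop": {}}
    if called > 0:
        maf, minor = compute_maf(alt, called)
        out["maf_global"], out["minor_global"] = maf, minor
    else:
        out["maf_global"], out["minor_global"] = None, None
    offset = 0
    for pop, samples in panel.populations.items():
        sub = g[offset : offset + len(samples)]
        offset += len(samples)
        m = sub >= 0
        c = int(2 * m.sum())
        if c > 0:
            maf, minor = compute_maf(int(sub[m].sum()), c)
            out["maf_by_pop"][pop] = maf
            out["minor_by_pop"][pop] = minor
        else:
            out["maf_by_pop"][pop] = None
            out["minor_by_pop"][pop] = None
    return out


_GT_RE = re.compile(r"^(\.|\d+)([/|](\.|\d+))?$")


def read_vcf_sites(
    path,
    panel: PopulationPanel,
    region: tuple[str, int, int] | None = None,
    chromosomes: str | Sequence[str] | None = "autosomes",
    counters: dict | None = None,
) -> Iterator[VariantSite]:
    """Stream biallelic SNVs from a VCF, with per-population folded MAF.

    Multiallelic records, indels, and malformed genotypes are skipped and
    tallied in ``counters`` (keys ``multiallelic``, ``non_snv``,
    ``malformed``). ``region`` is a 0-based half-open (chrom, start, end)
    filter applied in stream (no index required). ``chromosomes`` may be
    ``"autosomes"`` (default), ``None`` (everything), or an include-list.

    Panel samples missing from the VCF header raise ``ValueError``.
    Monomorphic-in-sample sites are emitted with ``segregating=False``.
    """
    from cyvcf2 import VCF

    if counters is None:
        counters = {}
    counters.setdefault("multiallelic", 0)
    counters.setdefault("non_snv", 0)
    counters.setdefault("malformed", 0)

    vcf = VCF(str(path), gts012=True)
    header_samples = list(vcf.samples)
    missing = [s for s in panel.samples if s not in set(header_samples)]
    if missing:
        raise ValueError(
            f"panel sample(s) absent from VCF header: {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    col = np.array([header_samples.index(s) for s in panel.samples])
    # with gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
    gt_lut = np.array([0, 1, 2, MISSING], dtype=np.int8)

    include: set[str] | None
    if chromosomes == "autosomes":
        include = None  # checked via is_autosome
    elif chromosomes is None:
        include = set()
    else:
        include = set(chromosomes)

    for variant in vcf:
        chrom = variant.CHROM
        if include is None:
            if not is_autosome(chrom):
                continue
        elif include and chrom not in include:
            continue
        pos0 = variant.POS - 1
        if region is not None:
            rchrom, rstart, rend = region
            if chrom != rchrom or not (rstart <= pos0 < rend):
                continue
        if len(variant.ALT) != 1:
            counters["multiallelic"] += 1
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
            counters["non_snv"] += 1
            continue
        try:
            gts = gt_lut[variant.gt_types]
        except (IndexError, TypeError):
            counters["malformed"] += 1
            logger.warning("malformed genotypes at %s:%d; site skipped", chrom, variant.POS)
            continue
        genotypes = gts[col].astype(np.int8)
        freqs = site_frequencies(genotypes, panel)
        if freqs["maf_global"] is None:
            counters["malformed"] += 1
            logger.warning("no called genotypes at %s:%d; site skipped", chrom, variant.POS)
            continue
        called = genotypes[genotypes >= 0]
        alt_count = int(called.sum())
        yield VariantSite(
            chrom=chrom,
            pos0=pos0,
            ref=ref,
            alt=alt,
            genotypes=genotypes,
            maf_global=freqs["maf_global"],
            maf_by_pop=freqs["maf_by_pop"],
            minor_allele_by_pop=freqs["minor_by_pop"],
            minor_allele_global=freqs["minor_global"],
            segregating=0 < alt_count < 2 * len(called),
        )
    if counters["multiallelic"] or counters["non_snv"] or counters["malformed"]:
        logger.info(
            "%s: skipped %d multiallelic, %d non-SNV, %d malformed records",
            path, counters["multiallelic"], counters["non_snv"], counters["malformed"],
        )


def annotate_sites(
    sites: Iterable[VariantSite],
    track: GerpTrack | None = None,
    consequences: Mapping[tuple[str, int], Consequence] | None = None,
    ancestral: Mapping[tuple[str, int], str] | None = None,
) -> list[VariantSite]:
    """Attach GERP scores, consequences, and ancestral alleles to sites."""
    out = []
    for site in sites:
        key = (site.chrom, site.pos0)
        if track is not None:
            site.gerp = track.query(site.chrom, site.pos0)
        if consequences is not None:
            site.consequence = consequences.get(key, Consequence.UNKNOWN)
        if ancestral is not None:
            site.ancestral = ancestral.get(key)
        out.append(site)
    return out
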