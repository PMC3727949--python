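"""Config-driven orchestration of the four analyses over one dataset.

Each ``run_*`` function loads the inputs named in an :class:`AnalysisConfig`,
executes one analysis end-to-end, and writes TSV reports plus a run log
(config echo and input checksums) into the output directory. Reruns with
identical config and inputs reproduce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import load as mload
from .io import (
    GeneRecord,
    GerpTrack,
    PopulationPanel,
    logger,
    read_ancestral_table,
    read_consequence_table,
    read_gene_annotations,
    read_gerp_track,
    read_ne_table,
    read_population_panel,
    read_vcf_sites,
)
from .profiles import (
    FilterConfig,
    annotate_gene_average_gerp,
    assign_quantile_bins,
    build_window_profile,
    depth_of_depression,
    pearson_correlation,
    proximal_distal_test,
    select_distal_noncoding_snps,
)
from .sites import SiteTable


@dataclass(frozen=True)
class AnalysisConfig:
    """Input paths and parameters for one pipeline run."""

    vcf: str
    genes: str
    gerp: str
    panel: str
    outdir: str
    consequences: str | None = None
    ancestral: str | None = None
    ne_table: str | None = None
    seed: int = 0
    chromosomes: str | list[str] | None = "autosomes"
    population: str | None = None  # MAF scope for profiles (None = global)
    # gene profiles
    n_bins: int = 10
    window_size: int = 10_000
    n_windows_per_side: int = 100
    distal_range: tuple[int, int] = (500_000, 1_000_000)
    central_halfwidth: int = 50_000
    top_fraction: float = 0.1
    # non-coding profiles
    noncoding_bins: int = 4
    noncoding_window_size: int = 100
    noncoding_windows_per_side: int = 100
    noncoding_min_distance: int = 200_000
    # individual comparisons / population summaries
    mode: str = "all"  # all | singletons
    minor_scope: str = "population"
    equalize_n: int | None = None
    population_groups: dict = field(default_factory=dict)
    filters: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("filters"), dict):
            raw["filters"] = FilterConfig(**raw["filters"])
        if "distal_range" in raw:
            raw["distal_range"] = tuple(raw["distal_range"])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters"] = dataclasses.asdict(self.filters)
        return d


@dataclass
class InputBundle:
    table: SiteTable
    genes: list[GeneRecord]
    track: GerpTrack
    panel: PopulationPanel
    checksums: dict[str, str]


@dataclass
class ReportBundle:
    outdir: Path
    paths: dict[str, Path]

    def frame(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.paths[name], sep="\t")


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_inputs(cfg: AnalysisConfig) -> InputBundle:
    """Read and cross-validate all inputs; fails before any output is
    written when a referenced file is missing."""
    paths = {
        "vcf": cfg.vcf,
        "genes": cfg.genes,
        "gerp": cfg.gerp,
        "panel": cfg.panel,
    }
    for name in ("consequences", "ancestral", "ne_table"):
        if getattr(cfg, name) is not None:
            paths[name] = getattr(cfg, name)
    missing = [n for n, p in paths.items() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing input file(s): {', '.join(f'{n}={paths[n]}' for n in missing)}"
        )
    checksums = {n: _checksum(p) for n, p in paths.items()}

    panel = read_population_panel(cfg.panel)
    if cfg.ne_table:
        panel = panel.with_ne(read_ne_table(cfg.ne_table))
    track = read_gerp_track(cfg.gerp)
    genes = read_gene_annotations(cfg.genes)
    cons = read_consequence_table(cfg.consequences) if cfg.consequences else None
    anc = read_ancestral_table(cfg.ancestral) if cfg.ancestral else None

    sites = read_vcf_sites(cfg.vcf, panel, chromosomes=cfg.chromosomes)
    table = SiteTable.from_sites(sites, panel)
    gerp = np.full(table.n_sites, np.nan)
    for chrom, sl in table.chrom_index().items():
        gerp[sl] = track.query_many(chrom, table.pos0[sl])
    table.gerp = gerp
    if cons is not None:
        from .sites import CONS_CODE
        from .io import Consequence

        codes = np.full(table.n_sites, CONS_CODE[Consequence.UNKNOWN], dtype=np.int8)
        for i in range(table.n_sites):
            c = cons.get((str(table.chrom[i]), int(table.pos0[i])))
            if c is not None:
                codes[i] = CONS_CODE[c]
        table.cons = codes
    if anc is not None:
        vals = np.array(
            [anc.get((str(c), int(p))) for c, p in zip(table.chrom, table.pos0)],
            dtype=object,
        )
        table.ancestral = vals
    return InputBundle(table=table, genes=genes, track=track, panel=panel, checksums=checksums)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_run_log(cfg: AnalysisConfig, checksums: dict, outdir: Path) -> Path:
    log_path = outdir / "run_log.txt"
    with open(log_path, "wt") as fh:
        fh.write("# bgscan run log\n## config\n")
        fh.write(yaml.safe_dump(cfg.echo(), sort_keys=True))
        fh.write("## input checksums (sha256)\n")
        for name in sorted(checksums):
            fh.write(f"{name}\t{checksums[name]}\n")
    return log_path


def _profile_frame(profile, extra: dict) -> pd.DataFrame:
    rows = profile.rows()
    for r in rows:
        r.update(extra)
    return pd.DataFrame(rows)


def run_gene_profile_analysis(
    cfg: AnalysisConfig, inputs: InputBundle | None = None
) -> ReportBundle:
    """Constraint-binned flank profiles, per-bin depth, and the
    depth-versus-constraint correlation (plus the per-population top-decile
    depth-versus-Ne correlation when an Ne table is supplied)."""
    inputs = inputs or load_inputs(cfg)
    table, genes = inputs.table, inputs.genes
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    annotate_gene_average_gerp(genes, inputs.track)
    scored = [g for g in genes if g.avg_gerp is not None]
    dropped = len(genes) - len(scored)
    if dropped:
        logger.warning("%d gene(s) without scored coding bases excluded", dropped)
    bins = assign_quantile_bins({g.gene_id: g.avg_gerp for g in scored}, cfg.n_bins)
    for g in scored:
        g.bin_index = bins[g.gene_id]

    profile_frames = []
    depth_rows = []
    for b in range(cfg.n_bins):
        members = [g for g in scored if g.bin_index == b]
        profile = build_window_profile(
            table,
            members,
            cfg.window_size,
            cfg.n_windows_per_side,
            population=cfg.population,
            cfg=cfg.filters,
        )
        stat = depth_of_depression(profile, cfg.distal_range, cfg.central_halfwidth)
        mean_g = float(np.mean([g.avg_gerp for g in members]))
        profile_frames.append(
            _profile_frame(
                profile,
                dict(bin=b, population=cfg.population or "ALL"),
            )
        )
        depth_rows.append(
            dict(
                bin=b,
                n_genes=len(members),
                mean_avg_gerp=mean_g,
                distal_mean_maf=stat.distal_mean_maf,
                central_min_maf=stat.central_min_maf,
                depth=stat.depth,
                population=cfg.population or "ALL",
            )
        )
    depth_df = pd.DataFrame(depth_rows)
    corr = pearson_correlation(depth_df["mean_avg_gerp"], depth_df["depth"])
    corr_rows = [
        dict(analysis="depth_vs_gene_gerp", r=corr.r, p=corr.p, n=corr.n)
    ]

    ne_rows = []
    if inputs.panel.ne:
        n_top = max(1, int(round(cfg.top_fraction * len(scored))))
        top = sorted(scored, key=lambda g: g.avg_gerp, reverse=True)[:n_top]
        for pop, ne in inputs.panel.ne.items():
            profile = build_window_profile(
                table,
                top,
                cfg.window_size,
                cfg.n_windows_per_side,
                population=pop,
                cfg=cfg.filters,
            )
            stat = depth_of_depression(profile, cfg.distal_range, cfg.central_halfwidth)
            ne_rows.append(
                dict(
                    population=pop,
                    ne=ne,
                    distal_mean_maf=stat.distal_mean_maf,
                    central_min_maf=stat.central_min_maf,
                    depth=stat.depth,
                )
            )
        if len(ne_rows) >= 3:
            ne_df = pd.DataFrame(ne_rows)
            c = pearson_correlation(ne_df["ne"], ne_df["depth"])
            corr_rows.append(dict(analysis="depth_vs_ne", r=c.r, p=c.p, n=c.n))

    paths = {}
    _write_tsv(pd.concat(profile_frames, ignore_index=True), outdir / "profiles.tsv")
    paths["profiles"] = outdir / "profiles.tsv"
    _write_tsv(depth_df, outdir / "depression.tsv")
    paths["depression"] = outdir / "depression.tsv"
    _write_tsv(pd.DataFrame(corr_rows), outdir / "correlations.tsv")
    paths["correlations"] = outdir / "correlations.tsv"
    if ne_rows:
        _write_tsv(pd.DataFrame(ne_rows), outdir / "population_depths.tsv")
        paths["population_depths"] = outdir / "population_depths.tsv"
    paths["run_log"] = _write_run_log(cfg, inputs.checksums, outdir)
    return ReportBundle(outdir=outdir, paths=paths)


def run_noncoding_analysis(
    cfg: AnalysisConfig, inputs: InputBundle | None = None
) -> ReportBundle:
    """Distal non-coding focal SNPs binned by GERP; 100-bp window profiles
    and the proximal-vs-distal MAF contrast per bin."""
    inputs = inputs or load_inputs(cfg)
    table, genes = inputs.table, inputs.genes
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    idx = select_distal_noncoding_snps(
        table,
        genes,
        min_distance=cfg.noncoding_min_distance,
        exclude_gerp_exact_zero=True,
    )
    if idx.size < cfg.noncoding_bins:
        raise ValueError(
            "no (or too few) distal non-coding SNPs with informative GERP scores"
        )
    bins = assign_quantile_bins(
        {str(i): float(table.gerp[i]) for i in idx}, cfg.noncoding_bins
    )

    profile_frames = []
    test_rows = []
    for b in range(cfg.noncoding_bins):
        members = [int(i) for i in idx if bins[str(i)] == b]
        focal = [(str(table.chrom[i]), int(table.pos0[i])) for i in members]
        profile = build_window_profile(
            table,
            focal,
            cfg.noncoding_window_size,
            cfg.noncoding_windows_per_side,
            population=cfg.population,
            cfg=cfg.filters,
            anchor_kind="snp",
        )
        p = proximal_distal_test(table, focal, population=cfg.population)
        profile_frames.append(
            _profile_frame(profile, dict(bin=b, population=cfg.population or "ALL"))
        )
        test_rows.append(
            dict(
                bin=b,
                n_focal=len(members),
                mean_gerp=float(np.mean([table.gerp[i] for i in members])),
                proximal_distal_p=p,
            )
        )

    paths = {}
    _write_tsv(
        pd.concat(profile_frames, ignore_index=True), outdir / "noncoding_profiles.tsv"
    )
    paths["noncoding_profiles"] = outdir / "noncoding_profiles.tsv"
    _write_tsv(pd.DataFrame(test_rows), outdir / "noncoding_tests.tsv")
    paths["noncoding_tests"] = outdir / "noncoding_tests.tsv"
    paths["run_log"] = _write_run_log(cfg, inputs.checksums, outdir)
    return ReportBundle(outdir=outdir, paths=paths)


def run_individual_comparison(
    cfg: AnalysisConfig, inputs: InputBundle | None = None
) -> ReportBundle:
    """Within-population all-pairs load-distribution tests (Table-1 shape)."""
    if cfg.mode not in ("all", "singletons"):
        raise ValueError(f"mode must be 'all' or 'singletons', got {cfg.mode!r}")
    inputs = inputs or load_inputs(cfg)
    table = inputs.table
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    summary = []
    for pop in inputs.panel.population_codes:
        dists = mload.population_load_distributions(
            table, pop, mode=cfg.mode, minor_scope=cfg.minor_scope
        )
        usable = [d for d in dists if not d.empty]
        if len(usable) < 2:
            logger.warning(
                "population %s skipped: fewer than 2 individuals with data", pop
            )
            continue
        results = mload.pairwise_load_tests(usable)
        n_u = sum(r.significant_u for r in results)
        n_ks = sum(r.significant_ks for r in results)
        n_both = sum(r.significant_u and r.significant_ks for r in results)
        summary.append(
            dict(
                population=pop,
                n_individuals=len(usable),
                n_pairs=len(results),
                bonferroni_m=results[0].m,
                significant_u=n_u,
                significant_ks=n_ks,
                significant_both=n_both,
            )
        )
        for r in results:
            rows.append(
                dict(
                    individual_1=r.sample_a,
                    individual_2=r.sample_b,
                    population=r.population,
                    mwu_p=r.u_p,
                    ks_p=r.ks_p,
                    bonferroni_m=r.m,
                    significant_u=r.significant_u,
                    significant_ks=r.significant_ks,
                )
            )

    paths = {}
    _write_tsv(pd.DataFrame(rows), outdir / "individual_tests.tsv")
    paths["individual_tests"] = outdir / "individual_tests.tsv"
    _write_tsv(pd.DataFrame(summary), outdir / "individual_tests_summary.tsv")
    paths["summary"] = outdir / "individual_tests_summary.tsv"
    paths["run_log"] = _write_run_log(cfg, inputs.checksums, outdir)
    return ReportBundle(outdir=outdir, paths=paths)


def run_population_summary(
    cfg: AnalysisConfig, inputs: InputBundle | None = None
) -> ReportBundle:
    """Per-population GERP-bin summaries (proportions, het, hom-derived,
    equal-n singletons) with CIs, plus configured group contrasts."""
    inputs = inputs or load_inputs(cfg)
    table = inputs.table
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.ancestral is None:
        raise ValueError("hom_derived_count summaries require an ancestral table")

    rows = []
    for pop in inputs.panel.population_codes:
        for quantity in ("minor_proportion", "het_count", "hom_derived_count"):
            s = mload.population_bin_summary(table, pop, quantity)
            labels = s.bin_labels()
            for b in range(len(labels)):
                rows.append(
                    dict(
                        population=pop,
                        quantity=quantity,
                        bin=labels[b],
                        mean=s.mean[b],
                        ci_low=s.ci_low[b],
                        ci_high=s.ci_high[b],
                        n_individuals=s.n_individuals,
                    )
                )

    # singleton summary on equal-size subsamples (singletons re-evaluated)
    sizes = [len(s) for s in inputs.panel.populations.values()]
    n_eq = cfg.equalize_n if cfg.equalize_n is not None else min(sizes)
    keep = mload.equalize_sample_sizes(inputs.panel, n_eq, cfg.seed)
    if keep:
        sub = table.subset_samples(keep)
        for pop in keep:
            s = mload.population_bin_summary(sub, pop, "singleton_count")
            labels = s.bin_labels()
            for b in range(len(labels)):
                rows.append(
                    dict(
                        population=pop,
                        quantity="singleton_count",
                        bin=labels[b],
                        mean=s.mean[b],
                        ci_low=s.ci_low[b],
                        ci_high=s.ci_high[b],
                        n_individuals=s.n_individuals,
                    )
                )

    group_rows = []
    groups = {k: list(v) for k, v in (cfg.population_groups or {}).items()}
    names = sorted(groups)
    for quantity in ("het_count", "hom_derived_count"):
        totals = {}
        for gname in names:
            vals = []
            for pop in groups[gname]:
                vals.extend(
                    mload.per_individual_positive_totals(table, pop, quantity).tolist()
                )
            totals[gname] = vals
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if totals[a] and totals[b]:
                    p = mload.group_difference_test(totals[a], totals[b])
                    group_rows.append(
                        dict(
                            quantity=quantity,
                            group_a=a,
                            group_b=b,
                            mean_a=float(np.mean(totals[a])),
                            mean_b=float(np.mean(totals[b])),
                            p=p,
                        )
                    )

    paths = {}
    _write_tsv(pd.DataFrame(rows), outdir / "population_summary.tsv")
    paths["population_summary"] = outdir / "population_summary.tsv"
    if group_rows:
        _write_tsv(pd.DataFrame(group_rows), outdir / "group_tests.tsv")
        paths["group_tests"] = outdir / "group_tests.tsv"
    paths["run_log"] = _write_run_log(cfg, inputs.checksums, outdir)
    return ReportBundle(outdir=outdir, paths=paths)
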