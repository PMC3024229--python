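"""Pipeline orchestration and headline summary tables.

Runs the full analysis in order — homology census, duplicate pairs, COG
statistics, quartet dating, cross-strain retention, Ka/Ks selection, HGT
overlap — and assembles the printed-ratio style summaries (copy-class
histogram, location classes, divergence bins, tree-type x bootstrap-band
matrix, strain match distribution). All percentages are computed with
:func:`pct` (round half-up) so printed values are reproducible exactly.

Every output file carries the config hash and master seed; rerunning with the
same config and seed yields byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import cog_stats, hgt_overlap, selection, strain_compare
from .genome_io import GenomeBundle, read_bundle
from .homology import (
    DuplicatePair,
    HomologyHit,
    KarlinAltschulParams,
    ScoringScheme,
    align_global,
    all_vs_all,
    build_families,
    call_duplicate_pairs,
)
from .quartet_phylo import (
    QuartetResult,
    align_quartet,
    bootstrap_support,
    fit_quartet,
    select_orthologs,
    wag_model,
)
from .selection import anova_oneway, backtranslate_pair, kaks_myn
from .synthetic_data import SimConfig, SimulatedCohort, read_ortholog_db, simulate_cohort

logger = logging.getLogger("dupcensus")

BOOTSTRAP_BANDS = (">=90", "70-90", "<70", "undefined")


def pct(count: float, denom: float, decimals: int = 1) -> float:
    """Percentage 100*count/denom, rounded half-up at ``decimals`` places."""
    if denom == 0:
        raise ValueError("denominator must be nonzero")
    q = Decimal(1).scaleb(-decimals)
    ratio = Decimal(str(count)) * 100 / Decimal(str(denom))
    return float(ratio.quantize(q, ROUND_HALF_UP))


def _band(support: float | None) -> str:
    if support is None:
        return "undefined"
    if support >= 90:
        return ">=90"
    if support >= 70:
        return "70-90"
    return "<70"


def tree_type_table(results: list[QuartetResult]) -> pd.DataFrame:
    """Location class x (tree type, bootstrap band) count matrix.

    Unresolvable pairs are excluded; cells sum to the number of classified
    pairs. Band edges: [90,100], [70,90), [0,70), plus 'undefined' for pairs
    without a bootstrap value.
    """
    from .homology import LOCATION_CLASSES

    cols = pd.MultiIndex.from_product([("TypeA", "TypeB"), BOOTSTRAP_BANDS])
    table = pd.DataFrame(0, index=list(LOCATION_CLASSES), columns=cols)
    for r in results:
        if r.call not in ("TypeA", "TypeB"):
            continue
        table.loc[r.location_class, (r.call, _band(r.bootstrap_support))] += 1
    return table


@dataclass
class PipelineConfig:
    """Resolved pipeline settings (see ``default_config`` for the YAML shape)."""

    simulate: dict | None = None
    bundles: dict | None = None
    e_max: float = 1e-20
    id_min: float = 30.0
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_lambda: float = 0.267
    ka_K: float = 0.041
    bootstrap_n: int = 100
    run_bootstrap: bool = True
    cog_window: int = 100_000
    cog_min_count: int = 3
    forced_pairs: list = field(default_factory=list)
    omega_marks: tuple = (0.3, 1.0, 3.0)
    master_seed: int = 0

    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.matrix, self.gap_open, self.gap_extend,
                             KarlinAltschulParams(self.ka_lambda, self.ka_K))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        d = dict(d)
        if "forced_pairs" in d:
            d["forced_pairs"] = [tuple(p) for p in d["forced_pairs"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["forced_pairs"] = [list(p) for p in d["forced_pairs"]]
        d["omega_marks"] = list(d["omega_marks"])
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    config: PipelineConfig
    focal: GenomeBundle
    hits: list[HomologyHit]
    families: list
    copy_histogram: dict[str, int]
    pairs: list[DuplicatePair]
    quartets: list[QuartetResult]
    profiles: list
    match_table: pd.DataFrame
    common_pair_ids: list[str]
    omega_table: pd.DataFrame
    anova: selection.AnovaResult | None
    summary: dict[str, Any]
    truth: pd.DataFrame | None = None


def _resolve_inputs(cfg: PipelineConfig) -> tuple[GenomeBundle, dict, list, Any, SimulatedCohort | None]:
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("master_seed", cfg.master_seed)
        cohort = simulate_cohort(SimConfig(**sim_kwargs))
        intervals = hgt_overlap.IntervalSet(
            {rid: hgt_overlap.merge_intervals(iv)
             for rid, iv in cohort.hgt_intervals.items()})
        return cohort.focal, cohort.strains, cohort.ortholog_db, intervals, cohort
    if not cfg.bundles or "focal" not in cfg.bundles:
        raise ValueError("config must provide either 'simulate' or 'bundles.focal'")
    focal = read_bundle(cfg.bundles["focal"])
    strains = {name: read_bundle(path)
               for name, path in sorted(cfg.bundles.get("strains", {}).items())}
    db = (read_ortholog_db(cfg.bundles["ortholog_db"])
          if cfg.bundles.get("ortholog_db") else [])
    intervals = None
    if cfg.bundles.get("hgt_bed"):
        intervals = hgt_overlap.read_bed(cfg.bundles["hgt_bed"], focal)
    return focal, strains, db, intervals, None


def run_pipeline(
    config: PipelineConfig | dict | str | Path,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run all stages in order and assemble the report bundle.

    ``seed`` overrides the config's master seed. When ``out_dir`` is given,
    TSV/CSV/JSON outputs stamped with the config hash and seed are written.
    """
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = config
    if seed is not None:
        cfg.master_seed = int(seed)
    scoring = cfg.scoring()

    focal, strains, ortholog_db, intervals, cohort = _resolve_inputs(cfg)
    logger.info("inputs: %d focal genes, %d strains, %d ortholog sequences",
                len(focal.genes), len(strains), len(ortholog_db))

    # Stage 1-2: homology census and duplicate pairs.
    hits = all_vs_all(focal, cfg.e_max, cfg.id_min, scoring)
    families, histogram = build_families(hits)
    pairs = call_duplicate_pairs(families, focal, cfg.forced_pairs, scoring)
    logger.info("homology: %d hits, %d families, %d duplicate pairs",
                len(hits), len(families), len(pairs))

    # Stage 3: COG statistics.
    dup_genes = [g for p in pairs for g in (p.gene_a, p.gene_b)]
    genome_general = cog_stats.tally_cogs(focal.genes, "general")
    dup_general = cog_stats.tally_cogs(dup_genes, "general")
    genome_sub = cog_stats.tally_cogs(focal.genes, "subgroup")
    dup_sub = cog_stats.tally_cogs(dup_genes, "subgroup")
    props_general = {c: n / genome_general.total for c, n in genome_general.counts.items()}
    props_sub = {c: n / genome_sub.total for c, n in genome_sub.counts.items()}
    if dup_genes:
        gof_general = cog_stats.chisq_gof(dup_general, props_general)
        gof_sub = cog_stats.chisq_gof(dup_sub, props_sub)
    else:
        gof_general = gof_sub = None
    div_by_locus = {}
    for p in pairs:
        div_by_locus[p.gene_a.locus_tag] = p.divergence
        div_by_locus[p.gene_b.locus_tag] = p.divergence
    divergence_bins = cog_stats.bin_divergence(pairs)
    clusters = cog_stats.find_cog_clusters(dup_genes, div_by_locus,
                                           cfg.cog_window, cfg.cog_min_count)

    # Stage 4: quartet dating.
    quartets: list[QuartetResult] = []
    model = wag_model()
    for idx, pair in enumerate(pairs):
        choice = select_orthologs(pair, ortholog_db, cfg.e_max, cfg.id_min, scoring)
        if not choice.resolved:
            quartets.append(QuartetResult(
                pair_id=pair.pair_id, topology_index=-1,
                branch_lengths=pd.array([0.0] * 5).to_numpy(dtype=float),
                log_likelihood=float("nan"), call="Unresolvable",
                location_class=pair.location_class))
            continue
        oid_a, sp_a, _ = choice.assignments[pair.gene_a.locus_tag]
        oid_b, sp_b, _ = choice.assignments[pair.gene_b.locus_tag]
        db_seqs = {oid: seq for oid, _, seq in ortholog_db}
        msa = align_quartet(
            [pair.gene_a.protein_seq, pair.gene_b.protein_seq,
             db_seqs[oid_a], db_seqs[oid_b]], scoring)
        names = (pair.gene_a.locus_tag, pair.gene_b.locus_tag, oid_a, oid_b)
        fit = fit_quartet(msa, model, pair_id=pair.pair_id, leaf_names=names)
        fit.location_class = pair.location_class
        if cfg.run_bootstrap:
            boot_seed = (cfg.master_seed * 1_000_003 + idx) % (2**31)
            fit.bootstrap_support = bootstrap_support(
                msa, model, n=cfg.bootstrap_n, seed=boot_seed, full_fit=fit)
        quartets.append(fit)
    n_typed = sum(1 for q in quartets if q.call in ("TypeA", "TypeB"))
    logger.info("quartets: %d classified, %d unresolvable",
                n_typed, len(quartets) - n_typed)

    # Stage 5: cross-strain retention.
    profiles = strain_compare.match_profiles(pairs, strains, cfg.e_max,
                                             cfg.id_min, scoring)
    match_table = strain_compare.match_distribution(profiles, sorted(strains))
    common_ids = strain_compare.common_pairs(profiles)

    # Stage 6: selection on common pairs, per pair per strain (focal included).
    omega_rows = []
    profile_by_id = {p.pair_id: p for p in profiles}
    for pair in pairs:
        if pair.pair_id not in common_ids:
            continue
        prof = profile_by_id[pair.pair_id]
        per_strain = {"focal": (pair.gene_a, pair.gene_b)}
        for sname in sorted(strains):
            la, lb = prof.loci[sname][:2]
            per_strain[sname] = (strains[sname].gene(la), strains[sname].gene(lb))
        for sname, (ga, gb) in per_strain.items():
            aln = align_global(ga.protein_seq, gb.protein_seq, scoring)
            codon_aln = backtranslate_pair(
                (aln.aligned_query, aln.aligned_subject), ga.cds_seq, gb.cds_seq)
            res = kaks_myn(codon_aln)
            omega_rows.append({
                "pair_id": pair.pair_id, "strain": sname,
                "ka": res.ka, "ks": res.ks, "omega": res.omega,
                "kappa_hat": res.kappa_hat, "label": res.label,
                "method": res.method,
            })
    omega_table = pd.DataFrame(
        omega_rows, columns=["pair_id", "strain", "ka", "ks", "omega",
                             "kappa_hat", "label", "method"])
    anova = None
    if not omega_table.empty:
        groups = [g["omega"].dropna().tolist()
                  for _, g in omega_table.groupby("strain")]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            anova = anova_oneway(groups)

    # Stage 7: HGT overlap.
    hgt_summary = {}
    if intervals is not None:
        coverage = hgt_overlap.replicon_coverage(intervals, focal)
        inside, dup_inside = hgt_overlap.genes_in_regions(intervals, focal.genes, pairs)
        hgt_summary = {
            "coverage": {rid: {"bp": bp, "fraction": frac}
                         for rid, (bp, frac) in sorted(coverage.items())},
            "genes_inside": len(inside),
            "duplicated_genes_inside": len(dup_inside),
        }

    summary = _build_summary(cfg, focal, families, histogram, pairs, quartets,
                             match_table, common_ids, omega_table, anova,
                             gof_general, gof_sub, divergence_bins, hgt_summary)

    report = PipelineReport(
        config=cfg, focal=focal, hits=hits, families=families,
        copy_histogram=histogram, pairs=pairs, quartets=quartets,
        profiles=profiles, match_table=match_table, common_pair_ids=common_ids,
        omega_table=omega_table, anova=anova, summary=summary,
        truth=cohort.truth if cohort is not None else None,
    )
    if out_dir is not None:
        _write_report(Path(out_dir), report, dup_general, dup_sub,
                      genome_general, genome_sub, divergence_bins, clusters)
    return report


def _build_summary(cfg, focal, families, histogram, pairs, quartets,
                   match_table, common_ids, omega_table, anova,
                   gof_general, gof_sub, divergence_bins, hgt_summary) -> dict:
    n_genes = len(focal.genes)
    genes_in_families = sum(f.copy_number for f in families)
    n_pairs = len(pairs)
    loc_counts: dict[str, int] = {}
    for p in pairs:
        loc_counts[p.location_class] = loc_counts.get(p.location_class, 0) + 1
    typed = [q for q in quartets if q.call in ("TypeA", "TypeB")]
    n_a = sum(1 for q in typed if q.call == "TypeA")
    n_b = len(typed) - n_a
    with_support = [q for q in typed if q.bootstrap_support is not None]
    high = sum(1 for q in with_support if q.bootstrap_support >= 95)
    summary = {
        "config_sha256": cfg.sha256(),
        "master_seed": cfg.master_seed,
        "n_genes": n_genes,
        "genes_in_families": genes_in_families,
        "pct_genes_in_families": pct(genes_in_families, n_genes) if n_genes else None,
        "copy_histogram": histogram,
        "n_duplicate_pairs": n_pairs,
        "mean_pair_identity": (round(sum(p.percent_identity for p in pairs) / n_pairs, 1)
                               if n_pairs else None),
        "location_counts": dict(sorted(loc_counts.items())),
        "divergence_bins": divergence_bins,
        "cog_chi2_general": (None if gof_general is None else
                             {"chi2": round(gof_general.chi2, 4),
                              "df": gof_general.df, "p": gof_general.p}),
        "cog_chi2_subgroup": (None if gof_sub is None else
                              {"chi2": round(gof_sub.chi2, 4),
                               "df": gof_sub.df, "p": gof_sub.p}),
        "n_typed_trees": len(typed),
        "n_type_a": n_a,
        "n_type_b": n_b,
        "pct_type_a": pct(n_a, len(typed)) if typed else None,
        "n_unresolvable": len(quartets) - len(typed),
        "n_high_support": high,
        "pct_high_support": (pct(high, len(with_support)) if with_support else None),
        "match_distribution": {s: {c: int(match_table.loc[s, c])
                                   for c in match_table.columns}
                               for s in match_table.index},
        "n_common_pairs": len(common_ids),
        "pct_common_pairs": pct(len(common_ids), n_pairs, 2) if n_pairs else None,
        "hgt": hgt_summary,
    }
    if anova is not None:
        summary["omega_anova"] = {
            "F": round(anova.F, 4), "p": round(anova.p, 4),
            "df_between": anova.df_between, "df_within": anova.df_within,
            "group_means": [round(m, 4) for m in anova.group_means],
            "pooled_sd": round(anova.pooled_sd, 4),
        }
    if not omega_table.empty:
        om = omega_table["omega"].dropna()
        summary["omega_mean"] = round(float(om.mean()), 4) if len(om) else None
    return summary


def _stamp(path: Path, cfg: PipelineConfig) -> None:
    text = path.read_text()
    path.write_text(f"# config_sha256={cfg.sha256()} seed={cfg.master_seed}\n" + text)


def _write_report(out_dir: Path, report: PipelineReport, dup_general, dup_sub,
                  genome_general, genome_sub, divergence_bins, clusters) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = report.config

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    pd.DataFrame(
        [(h.query_id, h.subject_id, h.score, round(h.percent_identity, 2),
          f"{h.evalue:.3e}") for h in report.hits],
        columns=["query", "subject", "score", "pident", "evalue"],
    ).to_csv(out_dir / "hits.tsv", sep="\t", index=False)

    pd.DataFrame(
        [(p.pair_id, p.gene_a.locus_tag, p.gene_b.locus_tag,
          round(p.percent_identity, 2), round(p.divergence, 2),
          p.location_class, p.forced) for p in report.pairs],
        columns=["pair_id", "gene_a", "gene_b", "pident", "divergence",
                 "location_class", "forced"],
    ).to_csv(out_dir / "pairs.tsv", sep="\t", index=False)

    qrows = []
    for i, q in enumerate(report.quartets):
        qrows.append((q.pair_id, q.call, q.topology_index,
                      "" if q.call == "Unresolvable" else round(q.log_likelihood, 4),
                      "" if q.bootstrap_support is None else q.bootstrap_support,
                      q.location_class, q.tied,
                      (cfg.master_seed * 1_000_003 + i) % (2**31)))
    pd.DataFrame(qrows, columns=["pair_id", "call", "topology_index", "logL",
                                 "bootstrap", "location_class", "tied",
                                 "bootstrap_seed"],
                 ).to_csv(out_dir / "quartets.tsv", sep="\t", index=False)

    with open(out_dir / "trees.nwk", "w") as fh:
        for q in report.quartets:
            if q.call != "Unresolvable":
                fh.write(q.newick() + "\n")

    report.omega_table.to_csv(out_dir / "kaks.tsv", sep="\t", index=False,
                              float_format="%.6g")
    report.match_table.to_csv(out_dir / "match_distribution.csv")
    tree_type_table(report.quartets).to_csv(out_dir / "tree_type_table.csv")

    def tally_frame(tally, genome_tally):
        rows = []
        for cat in tally.counts:
            rows.append((cat, tally.counts[cat],
                         pct(tally.counts[cat], tally.total),
                         genome_tally.counts.get(cat, 0),
                         pct(genome_tally.counts.get(cat, 0), genome_tally.total)))
        return pd.DataFrame(rows, columns=["category", "dup_count", "dup_pct",
                                           "genome_count", "genome_pct"])

    tally_frame(dup_general, genome_general).to_csv(
        out_dir / "cog_general.csv", index=False)
    tally_frame(dup_sub, genome_sub).to_csv(out_dir / "cog_subgroup.csv", index=False)

    pd.DataFrame(list(divergence_bins.items()), columns=["bin", "count"]
                 ).to_csv(out_dir / "divergence_bins.tsv", sep="\t", index=False)

    pd.DataFrame(
        [(c.replicon_id, c.window_start, c.window_end, c.category,
          ";".join(c.member_loci), round(c.mean_divergence, 2))
         for c in clusters],
        columns=["replicon", "window_start", "window_end", "cog_group",
                 "members", "mean_divergence"],
    ).to_csv(out_dir / "cog_clusters.tsv", sep="\t", index=False)

    for name in ("summary.json", "hits.tsv", "pairs.tsv", "quartets.tsv",
                 "kaks.tsv", "match_distribution.csv", "tree_type_table.csv",
                 "cog_general.csv", "cog_subgroup.csv", "divergence_bins.tsv",
                 "cog_clusters.tsv", "trees.nwk"):
        _stamp(out_dir / name, cfg)
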