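import json

import numpy as np
import pytest

from dupcensus.quartet_phylo import QuartetResult
from dupcensus.report import PipelineConfig, pct, run_pipeline, tree_type_table


@pytest.mark.parametrize("count,denom,decimals,expected", [
    (196, 234, 1, 83.8),
    (0, 10, 1, 0.0),
    (172, 180, 2, 95.56),
    (1, 8, 1, 12.5),
    (1, 16, 1, 6.3),      # half-up at the .25 boundary
    (180, 234, 0, 77.0),
])
def test_pct_round_half_up(count, denom, decimals, expected):
    assert pct(count, denom, decimals) == expected


def test_pct_zero_denominator_errors():
    with pytest.raises(ValueError):
        pct(1, 0)


def _qr(call, support, loc):
    return QuartetResult("p", 2 if call == "TypeB" else 0, np.zeros(5), -1.0,
                         call, bootstrap_support=support, location_class=loc)


def test_tree_type_table_cells_and_bands():
    table = tree_type_table([
        _qr("TypeA", 100.0, "CI-CI"),
        _qr("TypeA", 85.0, "CI-CII"),
        _qr("TypeB", 50.0, "CI-CI"),
        _qr("TypeB", None, "P-P"),
        _qr("Unresolvable", None, "CI-CI"),
    ])
    assert table.loc["CI-CI", ("TypeA", ">=90")] == 1
    assert table.loc["CI-CII", ("TypeA", "70-90")] == 1
    assert table.loc["CI-CI", ("TypeB", "<70")] == 1
    assert table.loc["P-P", ("TypeB", "undefined")] == 1
    assert table.values.sum() == 4  # unresolvable excluded


def test_tree_type_table_empty_is_all_zero():
    table = tree_type_table([])
    assert (table.values == 0).all()


def test_tree_type_table_row_sums_match_location_counts(mini_report):
    table = tree_type_table(mini_report.quartets)
    typed = [q for q in mini_report.quartets if q.call in ("TypeA", "TypeB")]
    for loc in table.index:
        assert table.loc[loc].sum() == sum(1 for q in typed if q.location_class == loc)


def test_config_rejects_unknown_keys_before_computation():
    with pytest.raises(ValueError, match="unknown config"):
        run_pipeline({"simulate": {"n_families": 2}, "bogus_key": 1})
    with pytest.raises(ValueError, match="bundles.focal"):
        run_pipeline({})


def test_summary_percentages_self_consistent(mini_report):
    s = mini_report.summary
    assert s["pct_genes_in_families"] == pct(s["genes_in_families"], s["n_genes"])
    if s["n_typed_trees"]:
        assert s["pct_type_a"] == pct(s["n_type_a"], s["n_typed_trees"])
    assert s["pct_common_pairs"] == pct(s["n_common_pairs"], s["n_duplicate_pairs"], 2)
    assert sum(s["copy_histogram"].values()) == sum(
        1 for _ in mini_report.families)
    assert s["n_type_a"] + s["n_type_b"] == s["n_typed_trees"]
    for strain, row in s["match_distribution"].items():
        assert sum(row.values()) == s["n_duplicate_pairs"]


def test_truth_carried_through_pipeline(mini_report):
    typed = {q.pair_id: q.call for q in mini_report.quartets
             if q.call in ("TypeA", "TypeB")}
    truth = mini_report.truth
    wrong = 0
    for _, row in truth[truth["duplicated"]].iterrows():
        pid = "|".join(sorted(row["loci"].split(",")))
        if pid in typed:
            wrong += typed[pid] != f"Type{row['true_type']}"
    assert wrong <= 1  # small cohort; near-perfect recovery expected


def test_pipeline_outputs_stamped_and_deterministic(tmp_path):
    cfg = {"simulate": {"n_families": 6, "n_codons": 150}, "bootstrap_n": 5}
    r1 = run_pipeline(cfg, seed=3, out_dir=tmp_path / "a")
    r2 = run_pipeline(cfg, seed=3, out_dir=tmp_path / "b")
    files = sorted(p.name for p in (tmp_path / "a").iterdir())
    assert "summary.json" in files and "pairs.tsv" in files
    for name in files:
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
    first = (tmp_path / "a" / "summary.json").read_text().splitlines()[0]
    assert first.startswith("# config_sha256=") and "seed=3" in first
    # a different seed changes the outputs
    run_pipeline(cfg, seed=4, out_dir=tmp_path / "c")
    assert (tmp_path / "a" / "pairs.tsv").read_bytes() != \
           (tmp_path / "c" / "pairs.tsv").read_bytes()


def test_yaml_config_round_trip(tmp_path):
    cfg_path = tmp_path / "cfg.yaml"
    cfg_path.write_text(
        "simulate:\n  n_families: 4\n  n_codons: 90\nbootstrap_n: 5\nmaster_seed: 9\n")
    cfg = PipelineConfig.from_yaml(cfg_path)
    assert cfg.simulate == {"n_families": 4, "n_codons": 90}
    assert cfg.bootstrap_n == 5 and cfg.master_seed == 9
    assert len(cfg.sha256()) == 16


def test_pipeline_from_on_disk_bundles(tmp_path):
    """The file-based input path (bundles + ortholog db + HGT BED) matches the
    in-memory simulate path."""
    from dupcensus.synthetic_data import SimConfig, simulate_cohort, write_cohort

    cohort = simulate_cohort(SimConfig(n_families=8, n_codons=150, master_seed=5))
    write_cohort(tmp_path / "cohort", cohort)
    report = run_pipeline({
        "bundles": {
            "focal": str(tmp_path / "cohort" / "focal"),
            "strains": {s: str(tmp_path / "cohort" / s) for s in cohort.strains},
            "ortholog_db": str(tmp_path / "cohort" / "ortholog_db.faa"),
            "hgt_bed": str(tmp_path / "cohort" / "hgt.bed"),
        },
        "bootstrap_n": 5,
    }, seed=5)
    ref = run_pipeline({"simulate": {"n_families": 8, "n_codons": 150},
                        "bootstrap_n": 5}, seed=5)
    assert report.summary["n_duplicate_pairs"] == ref.summary["n_duplicate_pairs"]
    assert report.summary["copy_histogram"] == ref.summary["copy_histogram"]
    assert report.summary["hgt"] == ref.summary["hgt"]
    assert report.summary["pct_type_a"] == ref.summary["pct_type_a"]
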