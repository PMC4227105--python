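"""Filter-cascade semantics: exact boundary behaviour, brute-force oracle
equivalence, set-algebra correctness, and planted-truth recovery."""

import numpy as np
import pytest

from gliomethyl.calling import (
    CallSet, FilterConfig, aggregate_genes, call_hypermethylated,
    exclusive_gene_lists, filter_detection, filter_normal_methylated,
    filter_sex_chromosomes, intersect_grades, run_grade_cascade, venn_partition,
)
from gliomethyl.model import GeneList

from conftest import make_beta, make_manifest, make_sheet


class TestBoundaries:
    """The six threshold boundary cases, exactly as the method defines them."""

    def test_detection_p_at_bound_survives(self):
        beta = make_beta([[0.5] * 4], detection_p=[[0.01, 0.0, 0.0, 0.0]])
        assert filter_detection(beta) == {"cg0000"}

    def test_detection_p_above_bound_removed(self):
        beta = make_beta([[0.5] * 4], detection_p=[[0.011, 0.0, 0.0, 0.0]])
        assert filter_detection(beta) == set()

    def test_normals_just_below_bound_kept(self):
        beta = make_beta([[0.24, 0.24, 0.24, 0.24]])
        assert filter_normal_methylated(beta, ["S0", "S1", "S2", "S3"]) == {"cg0000"}

    def test_normal_at_bound_removed(self):
        beta = make_beta([[0.10, 0.25, 0.10, 0.10]])
        assert filter_normal_methylated(beta, ["S0", "S1", "S2", "S3"]) == set()

    def test_three_of_ten_tumors_not_called(self):
        row = [0.6, 0.6, 0.6] + [0.1] * 7
        beta = make_beta([row])
        assert call_hypermethylated(beta, [f"S{j}" for j in range(10)]) == set()

    def test_four_of_ten_tumors_called(self):
        row = [0.6, 0.6, 0.6, 0.5] + [0.1] * 6
        beta = make_beta([row])
        assert call_hypermethylated(beta, [f"S{j}" for j in range(10)]) == {"cg0000"}


class TestOracles:
    def test_detection_matches_any_scan(self):
        rng = np.random.default_rng(10)
        p = rng.random((100, 10)) * 0.02
        beta = make_beta(np.full((100, 10), 0.5), detection_p=p)
        got = filter_detection(beta)
        expected = {
            f"cg{i:04d}" for i in range(100)
            if not any(p[i, j] > 0.01 for j in range(10))
        }
        assert got == expected

    def test_normal_filter_matches_scan(self):
        rng = np.random.default_rng(11)
        vals = rng.random((120, 4)) * 0.5
        beta = make_beta(vals)
        got = filter_normal_methylated(beta, [f"S{j}" for j in range(4)])
        expected = {
            f"cg{i:04d}" for i in range(120)
            if not any(vals[i, j] >= 0.25 for j in range(4))
        }
        assert got == expected

    def test_calling_matches_counting_scan(self):
        rng = np.random.default_rng(12)
        vals = rng.random((200, 15))
        beta = make_beta(vals)
        tumors = [f"S{j}" for j in range(15)]
        got = call_hypermethylated(beta, tumors)
        expected = {
            f"cg{i:04d}" for i in range(200)
            if sum(vals[i, j] >= 0.5 for j in range(15)) / 15 > 0.30
        }
        assert got == expected

    def test_sex_filter_matches_set_difference(self):
        rows, on_xy = [], set()
        rng = np.random.default_rng(13)
        for i in range(60):
            chrom = rng.choice(["1", "7", "X", "Y", "22"])
            if chrom in ("X", "Y"):
                on_xy.add(f"cg{i:04d}")
            rows.append((f"cg{i:04d}", chrom, i + 1, "II", "Both", (),
                         "Intergenic", "OpenSea", False))
        man = make_manifest(rows)
        probes = {f"cg{i:04d}" for i in range(60)}
        assert filter_sex_chromosomes(probes, man) == probes - on_xy

    def test_gene_aggregation_matches_inversion_oracle(self):
        rng = np.random.default_rng(14)
        rows = []
        for i in range(80):
            genes = tuple(sorted(rng.choice(
                ["A", "B", "C", "D", "E"], size=rng.integers(0, 3), replace=False
            )))
            rows.append((f"cg{i:04d}", "1", i + 1, "II", "Both", genes,
                         "Body" if genes else "Intergenic", "Island", False))
        man = make_manifest(rows)
        called = {f"cg{i:04d}" for i in range(80) if rng.random() < 0.5}
        gl = aggregate_genes(called, man)
        # brute-force inversion
        counts: dict = {}
        for i in range(80):
            pid = f"cg{i:04d}"
            if pid in called:
                for g in rows[i][5]:
                    counts.setdefault(g, set()).add(pid)
        expected = {g for g, ps in counts.items() if len(ps) >= 3}
        assert set(gl.genes) == expected
        for g in gl.genes:
            assert set(gl.supporting_probes[g]) == counts[g]

    def test_multi_gene_probe_supports_each_symbol(self):
        rows = [
            (f"cg{i}", "1", i + 1, "II", "Both", ("A", "B"), "Body", "Island", False)
            for i in range(3)
        ]
        man = make_manifest(rows)
        gl = aggregate_genes({"cg0", "cg1", "cg2"}, man)
        assert set(gl.genes) == {"A", "B"}

    def test_gene_boundary_three_vs_two_probes(self):
        rows = [
            (f"cg{i}", "1", i + 1, "II", "Both", ("A",) if i < 3 else ("B",),
             "Body", "Island", False)
            for i in range(8)
        ]
        man = make_manifest(rows)
        called = {"cg0", "cg1", "cg2", "cg3", "cg4"}  # A: 3 called, B: 2 called
        gl = aggregate_genes(called, man)
        assert set(gl.genes) == {"A"}


class TestCascade:
    def test_exclusion_log_partitions_input(self, small_cohort):
        _, manifest, beta, sheet, _ = small_cohort
        cs = run_grade_cascade(beta, sheet, "II", manifest)
        removed = set(cs.exclusion_log)
        assert removed.isdisjoint(cs.surviving_probes)
        assert removed | cs.surviving_probes == set(beta.probe_ids)
        assert cs.hyper_probes <= cs.surviving_probes

    def test_pure_filters_commute(self, small_cohort):
        _, manifest, beta, sheet, _ = small_cohort
        cfg = FilterConfig()
        normals = sheet.normals()
        a = filter_detection(beta, cfg)
        b = filter_sex_chromosomes(set(beta.probe_ids), manifest)
        c = filter_normal_methylated(beta, normals, cfg)
        assert (a & b) & c == (c & a) & b == b & (c & a)

    def test_full_tumor_fraction_limit(self, small_cohort):
        _, manifest, beta, sheet, _ = small_cohort
        cfg = FilterConfig(tumor_fraction_min=1.0)
        cs = run_grade_cascade(beta, sheet, "II", manifest, cfg)
        tumors = sheet.grade_group("II")
        # probe only called when ALL tumours >= 0.5 -> fraction 1 is never > 1
        assert cs.hyper_probes == set()

    def test_tightening_thresholds_never_enlarges_output(self, small_cohort):
        _, manifest, beta, sheet, _ = small_cohort
        loose = run_grade_cascade(beta, sheet, "III", manifest, FilterConfig())
        tight = run_grade_cascade(
            beta, sheet, "III", manifest,
            FilterConfig(detection_p_max=0.005, normal_beta_max=0.2,
                         hyper_beta_min=0.6, tumor_fraction_min=0.5,
                         min_probes_per_gene=4),
        )
        assert tight.surviving_probes <= loose.surviving_probes
        assert tight.hyper_probes <= loose.hyper_probes
        assert set(tight.hyper_genes.genes) <= set(loose.hyper_genes.genes)

    def test_planted_genes_recovered_without_false_positives(self):
        """With planted effect beta~0.8 vs background ~0.1 and no CIMP shift,
        the cascade recovers (almost) all planted grade II genes and calls no
        unplanted gene."""
        from gliomethyl.simulate import SimulationConfig, generate_cohort, generate_manifest
        cfg = SimulationConfig(seed=21, n_probes=8000, n_genes=800,
                               n_grade_genes=50, n_conserved_genes=0,
                               cimp_delta=0.0, detection_fail_rate=0.0)
        man = generate_manifest(cfg)
        beta, sheet, truth = generate_cohort(cfg, man)
        cs = run_grade_cascade(beta, sheet, "II", man)
        planted = set(truth.hyper_genes_by_grade["II"])
        called = set(cs.hyper_genes.genes)
        assert len(planted & called) >= 48
        assert called - planted == set()


class TestSetAlgebra:
    def _callset(self, label, probes, manifest):
        genes = aggregate_genes(probes, manifest, label=label)
        return CallSet(grade_label=label, surviving_probes=set(probes),
                       hyper_probes=set(probes),
                       hyper_probes_gene_associated=set(probes),
                       hyper_genes=genes)

    @pytest.fixture
    def toy_manifest(self):
        rows = []
        for i in range(30):
            rows.append((f"cg{i:02d}", "1", i + 1, "II", "Both",
                         (f"G{i // 3}",), "Body", "Island", False))
        return make_manifest(rows)

    def test_disjoint_callsets_intersect_empty(self, toy_manifest):
        a = self._callset("II", {f"cg{i:02d}" for i in range(6)}, toy_manifest)
        b = self._callset("III", {f"cg{i:02d}" for i in range(6, 12)}, toy_manifest)
        probes, genes = intersect_grades([a, b], toy_manifest)
        assert probes == set() and len(genes) == 0

    def test_identical_callsets_idempotent(self, toy_manifest):
        probes = {f"cg{i:02d}" for i in range(9)}
        a = self._callset("II", probes, toy_manifest)
        b = self._callset("III", probes, toy_manifest)
        got_probes, genes = intersect_grades([a, b], toy_manifest)
        assert got_probes == probes
        assert set(genes.genes) == set(a.hyper_genes.genes)

    def test_three_way_intersection_matches_set_oracle(self, toy_manifest):
        rng = np.random.default_rng(15)
        sets = [
            {f"cg{i:02d}" for i in range(30) if rng.random() < 0.6}
            for _ in range(3)
        ]
        css = [self._callset(g, s, toy_manifest)
               for g, s in zip(("II", "III", "IV"), sets)]
        probes, _ = intersect_grades(css, toy_manifest)
        assert probes == sets[0] & sets[1] & sets[2]

    def test_venn_identical_sets_all_in_center(self, toy_manifest):
        probes = {f"cg{i:02d}" for i in range(9)}
        css = [self._callset(g, probes, toy_manifest) for g in ("II", "III", "IV")]
        venn = venn_partition(css)
        assert venn["II&III&IV"] == 9
        assert sum(v for k, v in venn.items() if k != "II&III&IV") == 0

    def test_venn_disjoint_sets_only_exclusive(self, toy_manifest):
        css = [
            self._callset("II", {"cg00", "cg01", "cg02"}, toy_manifest),
            self._callset("III", {"cg03", "cg04", "cg05"}, toy_manifest),
        ]
        venn = venn_partition(css)
        assert venn == {"II": 3, "III": 3, "II&III": 0}

    def test_venn_matches_inclusion_exclusion(self, toy_manifest):
        rng = np.random.default_rng(16)
        sets = [
            {f"cg{i:02d}" for i in range(30) if rng.random() < 0.5}
            for _ in range(3)
        ]
        # keep only probes of >=3-probe genes, mirroring the reported counts
        css = [self._callset(g, s, toy_manifest)
               for g, s in zip(("II", "III", "IV"), sets)]
        venn = venn_partition(css)
        kept = [cs.hyper_genes.probes for cs in css]
        union = set().union(*kept)
        assert sum(venn.values()) == len(union)
        assert venn["II&III&IV"] == len(kept[0] & kept[1] & kept[2])
        assert venn["II"] == len(kept[0] - kept[1] - kept[2])

    def test_exclusive_lists_exact_partition(self):
        a = GeneList(label="sGBM", genes=("X", "Y"),
                     supporting_probes={"X": {"p1", "p2", "p3"}, "Y": {"p4", "p5", "p6"}})
        b = GeneList(label="pGBM", genes=("Y", "Z"),
                     supporting_probes={"Y": {"p4", "p5", "p6"}, "Z": {"p7", "p8", "p9"}})
        only_a, only_b, shared = exclusive_gene_lists(a, b)
        assert only_a.genes == ("X",)
        assert only_b.genes == ("Z",)
        assert shared.genes == ("Y",)

    def test_exclusive_lists_identical_inputs(self):
        a = GeneList(label="a", genes=("X",), supporting_probes={"X": {"p1"}})
        only_a, only_b, shared = exclusive_gene_lists(a, a)
        assert only_a.genes == () and only_b.genes == ()
        assert shared.genes == ("X",)

    def test_exclusive_lists_random_symbols_match_set_oracle(self):
        rng = np.random.default_rng(17)
        pool = [f"G{i}" for i in range(40)]
        ga = {g for g in pool if rng.random() < 0.5}
        gb = {g for g in pool if rng.random() < 0.5}
        mk = lambda label, gs: GeneList(
            label=label, genes=tuple(gs),
            supporting_probes={g: {f"{g}_p"} for g in gs})
        only_a, only_b, shared = exclusive_gene_lists(mk("a", ga), mk("b", gb))
        assert set(only_a.genes) == ga - gb
        assert set(only_b.genes) == gb - ga
        assert set(shared.genes) == ga & gb


def test_empty_tumor_or_normal_sets_are_hard_errors():
    beta = make_beta([[0.5, 0.5]])
    with pytest.raises(ValueError):
        call_hypermethylated(beta, [])
    with pytest.raises(ValueError):
        filter_normal_methylated(beta, [])
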