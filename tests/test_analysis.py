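"""Cohort assembly, enrichment orchestration, coverage and specificity."""

import numpy as np
import pytest

from domainscan import analysis, synthetic
from domainscan.mapping import filter_coding_nonsynonymous
from domainscan.synthetic import SyntheticConfig
from domainscan.types import (
    CancerCohort,
    CandidateProfile,
    DomainAnnotation,
    DomainHit,
    DomainSource,
    PAN_CANCER,
    RegionTestResult,
)

from conftest import make_mutation


def _result(region_id, candidate, **kw):
    base = dict(l=10, L=100, n=50, k=5, p=0.1, p_upper=0.5, m=10, alpha=0.05)
    base.update(kw)
    return RegionTestResult(region_id=region_id, candidate=candidate, **base)


def _profile(cancer, candidates, source="PFAM"):
    return CandidateProfile(
        cancer_type=cancer,
        source=source,
        results=[_result(c, True) for c in candidates],
    )


def _hit(patient, domain_id, gene="VPS25", residue=50, cancer="BRCA",
         source=DomainSource.PFAM):
    return DomainHit(
        mutation=make_mutation(1, gene=gene, patient=patient, cancer=cancer),
        domain_id=domain_id,
        source=source,
        gene=gene,
        residue=residue,
    )


@pytest.fixture
def pipeline_scenario():
    """Deterministic synthetic scenario pushed through filter and cohorts."""
    cfg = SyntheticConfig(
        n_genes=40,
        exons_per_gene=(1, 2),
        exon_length=(20, 40),
        n_domains_pfam=10,
        n_domains_cath=8,
        domain_length=(10, 25),
        cancer_types=("CA", "CB", "CC"),
        patients_per_cancer=25,
        mutations_per_patient=12.0,
        seed=17,
    )
    genes = synthetic.generate_gene_models(cfg)
    anns = synthetic.generate_domain_annotations(genes, cfg)
    records = synthetic.generate_cohort(genes, anns, cfg)
    filtered = filter_coding_nonsynonymous(records, genes)
    cohorts = analysis.build_cohorts(filtered, genes, anns)
    return cfg, genes, anns, filtered, cohorts


class TestBuildCohorts:
    def test_two_types_union_arithmetic(self, vps25_model, vps25_annotations):
        recs = [
            make_mutation(110, patient=f"A{i}", cancer="BRCA") for i in range(3)
        ] + [
            make_mutation(110, patient=f"B{i}", cancer="OV") for i in range(4)
        ]
        cohorts = analysis.build_cohorts(recs, [vps25_model], vps25_annotations)
        assert [c.cancer_type for c in cohorts] == ["BRCA", "OV", PAN_CANCER]
        assert cohorts[0].n_patients == 3
        assert cohorts[1].n_patients == 4
        assert cohorts[2].n_patients == 7

    def test_single_type_pan_equals_it(self, vps25_model, vps25_annotations):
        recs = [make_mutation(110, patient=f"P{i}") for i in range(5)]
        cohorts = analysis.build_cohorts(recs, [vps25_model], vps25_annotations)
        solo, pan = cohorts
        assert solo.patients == pan.patients
        assert solo.mutations == pan.mutations
        assert len(solo.hits) == len(pan.hits)

    def test_empty_input_warns(self, vps25_model, caplog):
        with caplog.at_level("WARNING"):
            assert analysis.build_cohorts([], [vps25_model], []) == []
        assert "no mutations" in caplog.text

    def test_pan_cancer_counts_conserve(self, pipeline_scenario):
        _, _, _, _, cohorts = pipeline_scenario
        pan = cohorts[-1]
        per_type = cohorts[:-1]
        pan_k: dict[str, int] = {}
        for h in pan.hits:
            pan_k[h.domain_id] = pan_k.get(h.domain_id, 0) + 1
        summed: dict[str, int] = {}
        for c in per_type:
            for h in c.hits:
                summed[h.domain_id] = summed.get(h.domain_id, 0) + 1
        assert pan_k == summed


class TestTestDomains:
    def test_single_domain_degenerate(self, vps25_model):
        anns = [DomainAnnotation("D1", DomainSource.PFAM, "VPS25", 1, 176)]
        recs = [make_mutation(110, patient=f"P{i}") for i in range(4)]
        cohorts = analysis.build_cohorts(recs, [vps25_model], anns)
        results = analysis.test_domains(cohorts[0], anns, DomainSource.PFAM, 1)
        (r,) = results
        assert r.p == 1.0 and r.p_upper == 1.0 and not r.candidate

    def test_counts_and_lengths_match_enumeration(self, pipeline_scenario):
        _, _, anns, _, cohorts = pipeline_scenario
        cohort = cohorts[-1]
        n_doms = len({a.domain_id for a in anns if a.source is DomainSource.PFAM})
        results = analysis.test_domains(
            cohort, anns, DomainSource.PFAM, m=n_doms * len(cohorts)
        )
        by_id = {r.region_id: r for r in results}
        pfam_hits = [h for h in cohort.hits if h.source is DomainSource.PFAM]
        assert all(r.n == len(pfam_hits) for r in results)
        for dom_id, r in by_id.items():
            assert r.k == sum(1 for h in pfam_hits if h.domain_id == dom_id)
            assert r.l == sum(
                a.length for a in anns
                if a.source is DomainSource.PFAM and a.domain_id == dom_id
            )
        assert sum(r.k for r in results) == len(pfam_hits)

    def test_planted_domain_recovered_end_to_end(self):
        cfg = SyntheticConfig(
            n_genes=40,
            exons_per_gene=(1, 2),
            exon_length=(30, 50),
            n_domains_pfam=12,
            n_domains_cath=4,
            domain_length=(15, 30),
            cancer_types=("CA", "CB"),
            patients_per_cancer=60,
            mutations_per_patient=40.0,
            planted_enrichments=(("PF00003", 50.0),),
            seed=23,
        )
        genes = synthetic.generate_gene_models(cfg)
        anns = synthetic.generate_domain_annotations(genes, cfg)
        records = synthetic.generate_cohort(genes, anns, cfg)
        filtered = filter_coding_nonsynonymous(records, genes)
        cohorts = analysis.build_cohorts(filtered, genes, anns)
        pan = cohorts[-1]
        m = 12 * len(cohorts)
        results = analysis.test_domains(pan, anns, DomainSource.PFAM, m)
        flagged = {r.region_id for r in results if r.candidate}
        assert "PF00003" in flagged


class TestTestGenes:
    def test_zero_count_gene_not_candidate(self, pipeline_scenario):
        _, genes, _, _, cohorts = pipeline_scenario
        results = analysis.test_genes(
            cohorts[0], genes, [g.gene for g in genes], m=len(genes) * 4
        )
        for r in results:
            if r.k == 0:
                assert not r.candidate

    def test_unknown_gene_listed(self, pipeline_scenario):
        _, genes, _, _, cohorts = pipeline_scenario
        with pytest.raises(ValueError, match="GHOST"):
            analysis.test_genes(cohorts[0], genes, ["GHOST"], m=1)

    def test_group_test_sums_members(self, pipeline_scenario):
        _, genes, _, _, cohorts = pipeline_scenario
        cfg = pipeline_scenario[0]
        gene_sets = synthetic.generate_gene_sets(genes, cfg)
        gs = gene_sets[0]
        cohort = cohorts[-1]
        per_gene = {
            r.region_id: r
            for r in analysis.test_genes(cohort, genes, gs.genes, m=1)
        }
        for r in analysis.test_gene_groups(cohort, genes, gs, m=1):
            members = gs.groups()[r.region_id]
            assert r.k == sum(per_gene[g].k for g in members)
            assert r.l == sum(per_gene[g].l for g in members)
            assert r.n == per_gene[members[0]].n


class TestCoverage:
    def _cohort(self):
        hits = [_hit(f"P{i}", "D1") for i in range(4)] + [_hit("P0", "D2")]
        return CancerCohort(
            cancer_type="BRCA",
            patients={f"P{i}" for i in range(10)},
            mutations=[],
            hits=hits,
        )

    def test_no_hits_is_zero(self):
        assert analysis.patient_coverage("MISSING", self._cohort()) == 0.0

    def test_every_patient_hit_is_100(self):
        cohort = CancerCohort(
            cancer_type="X",
            patients={"A", "B"},
            mutations=[],
            hits=[_hit("A", "D1"), _hit("B", "D1")],
        )
        assert analysis.patient_coverage("D1", cohort) == 100.0

    def test_fixture_four_of_ten(self):
        assert analysis.patient_coverage("D1", self._cohort()) == 40.0

    def test_cumulative_is_union_not_sum(self):
        cohort = self._cohort()
        assert analysis.cumulative_coverage([], cohort) == 0.0
        # P0 carries both D1 and D2: union stays at 4 patients
        assert analysis.cumulative_coverage(["D1", "D2"], cohort) == 40.0
        assert analysis.cumulative_coverage(
            ["D1", "D2"], cohort
        ) >= analysis.patient_coverage("D1", cohort)

    def test_empty_patient_set_is_error(self):
        cohort = CancerCohort("X", set(), [], [])
        with pytest.raises(ValueError):
            analysis.patient_coverage("D1", cohort)


class TestSpecificity:
    def test_unique_candidate_is_specific(self):
        profiles = [_profile("BRCA", ["D1"]), _profile("OV", ["D2"])]
        analysis.specific_regions(profiles)
        assert profiles[0].specific_regions == {"D1"}
        assert profiles[1].specific_regions == {"D2"}

    def test_shared_candidate_specific_nowhere(self):
        profiles = [_profile("BRCA", ["D1"]), _profile("OV", ["D1"])]
        analysis.specific_regions(profiles)
        assert profiles[0].specific_regions == set()
        assert profiles[1].specific_regions == set()

    def test_pan_cancer_does_not_block_specificity(self):
        profiles = [
            _profile("BRCA", ["D1"]),
            _profile(PAN_CANCER, ["D1", "D2"]),
        ]
        analysis.specific_regions(profiles)
        assert profiles[0].specific_regions == {"D1"}
        assert profiles[1].specific_regions == set()

    def test_disjoint_across_profiles_exhaustive(self):
        rng = np.random.default_rng(2)
        doms = [f"D{i}" for i in range(12)]
        profiles = [
            _profile(f"C{j}", rng.choice(doms, size=5, replace=False))
            for j in range(4)
        ]
        analysis.specific_regions(profiles)
        for i, a in enumerate(profiles):
            assert a.specific_regions <= a.candidate_ids
            for b in profiles[i + 1:]:
                assert not (a.specific_regions & b.specific_regions)


class TestSpecificProteins:
    def _setup(self, candidates, specific, hits):
        profile = _profile("BRCA", candidates)
        profile.specific_regions = set(specific)
        anns = [
            DomainAnnotation("D1", DomainSource.PFAM, "GENE_A", 1, 50),
            DomainAnnotation("D2", DomainSource.PFAM, "GENE_B", 1, 50),
            DomainAnnotation("D1", DomainSource.PFAM, "GENE_B", 60, 90),
        ]
        cohort = CancerCohort("BRCA", {"P1"}, [], hits)
        return profile, anns, cohort

    def test_gene_with_only_specific_candidate_included(self):
        profile, anns, cohort = self._setup(
            ["D1"], ["D1"], [_hit("P1", "D1", gene="GENE_A")]
        )
        assert analysis.specific_proteins(profile, anns, cohort) == {"GENE_A"}

    def test_gene_with_shared_candidate_excluded(self):
        # GENE_B carries specific D1 and shared candidate D2
        profile, anns, cohort = self._setup(
            ["D1", "D2"], ["D1"],
            [_hit("P1", "D1", gene="GENE_B"), _hit("P1", "D2", gene="GENE_B")],
        )
        assert "GENE_B" not in analysis.specific_proteins(profile, anns, cohort)

    def test_requires_a_mutated_candidate_domain(self):
        profile, anns, cohort = self._setup(["D1"], ["D1"], [])
        assert analysis.specific_proteins(profile, anns, cohort) == set()


class TestRestrictGeneCandidates:
    def test_monotone_filter_rule(self):
        anns = [
            DomainAnnotation("D1", DomainSource.PFAM, "GENE_A", 1, 50),
        ]
        gene_results = {
            "BRCA": [_result("GENE_A", True), _result("GENE_B", True),
                     _result("GENE_C", False)],
        }
        profiles = [_profile("BRCA", ["D1"])]
        out = analysis.restrict_gene_candidates(gene_results, profiles, anns)
        # GENE_B has no domains, GENE_C is not a candidate
        assert out == {"BRCA": ["GENE_A"]}

    def test_candidate_domain_in_other_cancer_does_not_count(self):
        anns = [DomainAnnotation("D1", DomainSource.PFAM, "GENE_A", 1, 50)]
        gene_results = {"BRCA": [_result("GENE_A", True)]}
        profiles = [_profile("OV", ["D1"]), _profile("BRCA", [])]
        out = analysis.restrict_gene_candidates(gene_results, profiles, anns)
        assert out == {"BRCA": []}


class TestCompareCausalList:
    def test_empty_list_gives_zero_rows(self):
        df = analysis.compare_causal_list([_profile("BRCA", [])], [], [], [])
        assert (df[["n_causal", "with_domain"]] == 0).all().all()

    def test_all_causal_genes_flagged_gives_100_percent(self):
        anns = [DomainAnnotation("D1", DomainSource.PFAM, "GENE_A", 1, 50)]
        cohort = CancerCohort("BRCA", {"P1"}, [],
                              [_hit("P1", "D1", gene="GENE_A")])
        profiles = [_profile("BRCA", ["D1"])]
        df = analysis.compare_causal_list(
            profiles, [("GENE_A", "BRCA")], anns, [cohort]
        )
        row = df[df.cancer_type == "BRCA"].iloc[0]
        assert row.pct_with_domain == 100.0
        assert row.pct_with_domain_mutation == 100.0
        assert row.pct_with_candidate_domain == 100.0

    def test_fixture_counts_match_enumeration(self):
        anns = [
            DomainAnnotation("D1", DomainSource.PFAM, "GENE_A", 1, 50),
            DomainAnnotation("D2", DomainSource.PFAM, "GENE_B", 1, 50),
        ]
        cohort = CancerCohort("BRCA", {"P1"}, [],
                              [_hit("P1", "D1", gene="GENE_A")])
        profiles = [_profile("BRCA", ["D1"])]
        causal = [("GENE_A", "BRCA"), ("GENE_B", "BRCA"), ("GENE_X", "BRCA")]
        df = analysis.compare_causal_list(profiles, causal, anns, [cohort])
        row = df[df.cancer_type == "BRCA"].iloc[0]
        assert row.n_causal == 3
        assert row.with_domain == 2  # A and B annotated
        assert row.with_domain_mutation == 1  # only A mutated
        assert row.with_candidate_domain == 1  # only A carries candidate D1


class TestExportBipartite:
    def test_edge_count_and_ordering(self):
        p1 = _profile("BRCA", ["D2", "D1"])
        p1.coverage = {"D1": 10.0, "D2": 20.0}
        p2 = _profile("OV", ["D3"])
        df = analysis.export_bipartite([p2, p1])
        assert len(df) == 3
        assert list(df.cancer_type) == ["BRCA", "BRCA", "OV"]
        assert list(df.region_id[:2]) == ["D1", "D2"]

    def test_round_trip_through_tsv(self, tmp_path):
        p1 = _profile("BRCA", ["D1"])
        p1.coverage = {"D1": 12.5}
        p1.specific_regions = {"D1"}
        df = analysis.export_bipartite([p1])
        path = tmp_path / "edges.tsv"
        df.to_csv(path, sep="\t", index=False)
        import pandas as pd

        back = pd.read_csv(path, sep="\t")
        assert back.equals(df)
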