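"""Candidate filtering, LD clustering and main-SNP selection."""

import numpy as np
import pytest

from estro_mr.errors import ConfigurationError, DataError, ValidationError
from estro_mr.instrument_selection import (
    STAGES,
    SelectionConfig,
    build_instruments,
    cluster_by_ld,
    filter_candidates,
    pick_main_snp,
)
from estro_mr.reference import BMD, gene_regions
from estro_mr.summary_data import LDMatrix
from estro_mr.synthetic_data import selection_fixture

from conftest import make_assoc

REGION = gene_regions()[0]  # ESR1
CONFIG = SelectionConfig(biomarker_allowlist=(BMD,))


def _ld_for(candidates, pairs=()):
    rsids = sorted({c.rsid for c in candidates})
    m = np.eye(len(rsids))
    idx = {r: i for i, r in enumerate(rsids)}
    for a, b, r2 in pairs:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r2
    return LDMatrix(rsids, m)


class TestFilterCandidates:
    def test_each_filter_excludes_its_rows(self):
        """Ten candidates: two sub-significant, one out of region, one
        male-only, one wrong ancestry, five clean -> five survive."""
        clean = [make_assoc(rsid=f"rs{i}") for i in range(5)]
        bad = [
            make_assoc(rsid="rs10", p=1e-6),
            make_assoc(rsid="rs11", p=1e-6),
            make_assoc(rsid="rs12", pos=REGION.end + REGION.flank_bp + 1),
            make_assoc(rsid="rs13", sex="male"),
            make_assoc(rsid="rs14", ancestry="East Asian"),
        ]
        candidates = clean + bad
        survivors, ledger = filter_candidates(candidates, REGION, CONFIG)

        # independent per-row predicate oracle
        def passes(c):
            return (
                c.p < CONFIG.p_threshold
                and REGION.contains(c.chrom, c.pos, CONFIG.flank_bp)
                and c.sex not in CONFIG.excluded_sex
                and c.ancestry in CONFIG.allowed_ancestries
                and c.trait in CONFIG.biomarker_allowlist
            )

        assert survivors == [c for c in candidates if passes(c)]
        assert ledger.counts() == {
            "significance": 2,
            "region": 1,
            "sex": 1,
            "ancestry": 1,
            "biomarker": 0,
        }
        assert ledger.conserved()

    def test_flank_boundary_is_inclusive(self):
        edge = make_assoc(rsid="rs_edge", pos=REGION.start - CONFIG.flank_bp)
        survivors, _ = filter_candidates([edge], REGION, CONFIG)
        assert survivors == [edge]

    def test_all_pass_gives_zero_ledger(self):
        candidates = [make_assoc(rsid=f"rs{i}") for i in range(4)]
        survivors, ledger = filter_candidates(candidates, REGION, CONFIG)
        assert survivors == candidates
        assert all(v == 0 for v in ledger.counts().values())
        assert ledger.retained == 4

    def test_empty_allowlist_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SelectionConfig(biomarker_allowlist=())

    def test_filter_is_idempotent(self):
        candidates = [make_assoc(rsid=f"rs{i}") for i in range(3)] + [
            make_assoc(rsid="rsx", p=0.5)
        ]
        survivors, _ = filter_candidates(candidates, REGION, CONFIG)
        again, ledger = filter_candidates(survivors, REGION, CONFIG)
        assert again == survivors
        assert ledger.excluded_total == 0


class TestClusterByLD:
    def test_one_correlated_pair_forms_one_cluster(self):
        cands = [make_assoc(rsid=r) for r in ("rsa", "rsb", "rsc")]
        ld = _ld_for(cands, [("rsa", "rsb", 0.5)])
        assert cluster_by_ld(cands, ld, 0.1) == [["rsa", "rsb"], ["rsc"]]

    def test_identity_ld_gives_singletons(self):
        cands = [make_assoc(rsid=r) for r in ("rsa", "rsb", "rsc")]
        assert cluster_by_ld(cands, _ld_for(cands), 0.1) == [["rsa"], ["rsb"], ["rsc"]]

    def test_transitive_chain_merges(self):
        cands = [make_assoc(rsid=r) for r in ("rsa", "rsb", "rsc")]
        ld = _ld_for(cands, [("rsa", "rsb", 0.2), ("rsb", "rsc", 0.2)])
        assert cluster_by_ld(cands, ld, 0.1) == [["rsa", "rsb", "rsc"]]

    def test_clusters_never_span_biomarkers(self):
        a = make_assoc(rsid="rsa")
        b = make_assoc(rsid="rsb", trait="other trait")
        ld = _ld_for([a, b], [("rsa", "rsb", 0.9)])
        assert cluster_by_ld([a, b], ld, 0.1) == [["rsa"], ["rsb"]]

    def test_missing_rsid_raises_naming_it(self):
        cands = [make_assoc(rsid="rs_missing")]
        ld = LDMatrix(["rs_other"], np.eye(1))
        with pytest.raises(DataError, match="rs_missing"):
            cluster_by_ld(cands, ld, 0.1)


class TestPickMainSnp:
    def test_multi_study_outranks_sample_size(self):
        reports = [
            make_assoc(rsid="rsa", study_id="S1", n=100_000),
            make_assoc(rsid="rsa", study_id="S2", n=90_000),
            make_assoc(rsid="rsb", study_id="S3", n=400_000),
        ]
        chosen = pick_main_snp(["rsa", "rsb"], reports)
        assert chosen.rsid == "rsa"
        assert chosen.study_id == "S1"  # largest-n study of the chosen SNP

    def test_singleton_cluster_returns_its_snp(self):
        rec = make_assoc(rsid="rsa")
        assert pick_main_snp(["rsa"], [rec]) == rec

    def test_residual_tie_broken_lexicographically(self):
        reports = [
            make_assoc(rsid="rsb", study_id="S1", n=100_000),
            make_assoc(rsid="rsa", study_id="S2", n=100_000),
        ]
        assert pick_main_snp(["rsb", "rsa"], reports).rsid == "rsa"

    def test_availability_ranks_below_sample_size(self):
        reports = [
            make_assoc(rsid="rsa", study_id="S1", n=200_000),
            make_assoc(rsid="rsb", study_id="S2", n=100_000),
        ]
        # rsa has no retrievable summary statistics but the larger study
        assert pick_main_snp(["rsa", "rsb"], reports, available={"rsb"}).rsid == "rsa"
        # equal n: availability decides
        reports[0] = make_assoc(rsid="rsa", study_id="S1", n=100_000)
        assert pick_main_snp(["rsa", "rsb"], reports, available={"rsb"}).rsid == "rsb"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValidationError):
            pick_main_snp([], [])


class TestBuildInstruments:
    def test_emulation_fixture_yields_published_structure(self):
        candidates, regions, ld, config = selection_fixture()
        instruments, ledger = build_instruments(candidates, regions, ld, config)
        sizes = {ins.biomarker: len(ins) for ins in instruments}
        assert len(instruments) == 3
        assert sorted(sizes.values()) == [1, 1, 7]
        bmd = next(ins for ins in instruments if len(ins) == 7)
        # largest-study dedup: rs2504069 stats come from the n=426,824 study
        rec = next(v for v in bmd.variants if v.rsid == "rs2504069")
        assert rec.study_id == "Morris (2019)" and rec.beta == -0.042
        # the LD satellite lost the main-SNP contest
        assert "rs9340799" not in bmd.rsids
        assert ledger.conserved()

    def test_ld_validity_of_instruments(self):
        candidates, regions, ld, config = selection_fixture()
        instruments, _ = build_instruments(candidates, regions, ld, config)
        for ins in instruments:
            ins.validate_independent(ld, config.ld_r2_threshold)

    def test_all_failing_significance_yields_no_instruments(self):
        candidates, regions, ld, config = selection_fixture()
        weak = [
            c.__class__(**{**vars(c), "p": 1e-4}) for c in candidates
        ]
        instruments, ledger = build_instruments(weak, regions, ld, config)
        assert instruments == []
        assert ledger.counts()["significance"] == len(candidates)
        assert ledger.conserved()

    def test_two_biomarkers_give_two_instrument_sets(self):
        a = make_assoc(rsid="rs1")
        b = make_assoc(rsid="rs2", trait="sex hormone-binding globulin levels")
        config = SelectionConfig(
            biomarker_allowlist=(BMD, "sex hormone-binding globulin levels")
        )
        ld = _ld_for([a, b])
        instruments, _ = build_instruments([a, b], [REGION], ld, config)
        assert [(i.biomarker, len(i)) for i in instruments] == [
            (BMD, 1),
            ("sex hormone-binding globulin levels", 1),
        ]

    def test_candidate_order_never_changes_selection(self):
        candidates, regions, ld, config = selection_fixture()
        instruments, _ = build_instruments(candidates, regions, ld, config)
        rng = np.random.default_rng(42)
        for _ in range(5):
            perm = list(candidates)
            rng.shuffle(perm)
            permuted, _ = build_instruments(perm, regions, ld, config)
            assert permuted == instruments
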