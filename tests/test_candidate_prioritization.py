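"""Workflow 2, workflow merge, exclusions, zygosity finalization, report."""

from __future__ import annotations

import itertools
import json

import numpy as np
import pytest

from trioprio.candidate_prioritization import (
    Candidate,
    call_pds,
    apply_exclusion_list,
    finalize_by_zygosity,
    merge_workflows,
    select_top_pathogenic,
    write_report,
)
from trioprio.models import (
    InheritanceMode,
    Outcome,
    Workflow,
    Zygosity,
    ZygosityObservation,
)

from conftest import make_variant


class TestCallPds:
    def test_damaging_both_scores_is_pds_with_combined(self):
        v = make_variant(sift=0.01, polyphen=0.95)
        call = call_pds([v])[0]
        assert call.is_pds
        assert call.combined == pytest.approx(1.94)

    def test_benign_sift_is_not_pds(self):
        call = call_pds([make_variant(sift=0.30, polyphen=0.95)])[0]
        assert not call.is_pds
        assert call.combined == pytest.approx(1.65)  # combined still computed

    def test_missing_either_score_is_never_pds(self):
        assert not call_pds([make_variant(sift=0.01)])[0].is_pds
        assert not call_pds([make_variant(polyphen=0.99)])[0].is_pds
        assert call_pds([make_variant(sift=0.01)])[0].combined is None

    def test_pds_set_matches_threshold_recount_on_random_cohort(self):
        rng = np.random.default_rng(6)
        vs = [
            make_variant(
                pos=i + 1,
                sift=round(float(rng.uniform(0, 1)), 3),
                polyphen=round(float(rng.uniform(0, 1)), 3),
            )
            for i in range(300)
        ]
        calls = call_pds(vs)
        expected = {v.key for v in vs if v.sift <= 0.05 and v.polyphen >= 0.447}
        assert {c.variant_key for c in calls if c.is_pds} == expected


class TestTopPathogenic:
    def make_cohort(self, scores):
        vs = [
            make_variant(pos=i + 1, gene=f"G{i}", sift=s, polyphen=p)
            for i, (s, p) in enumerate(scores)
        ]
        return vs, call_pds(vs), {v.key: v for v in vs}

    def test_top_two_by_combined_score(self):
        vs, calls, by_key = self.make_cohort(
            [(0.01, 0.99), (0.02, 0.60), (0.03, 0.95), (0.04, 0.50), (0.05, 0.70)]
        )
        top = select_top_pathogenic(calls, by_key, k=2)
        assert [c.variant_key for c in top] == [vs[0].key, vs[2].key]

    def test_fewer_than_k_returns_all(self):
        vs, calls, by_key = self.make_cohort([(0.01, 0.99), (0.9, 0.1)])
        top = select_top_pathogenic(calls, by_key, k=2)
        assert len(top) == 1

    def test_matches_brute_force_sort_on_random_scores(self):
        rng = np.random.default_rng(17)
        scores = [
            (round(float(rng.uniform(0, 0.05)), 4), round(float(rng.uniform(0.447, 1)), 4))
            for _ in range(50)
        ]
        vs, calls, by_key = self.make_cohort(scores)
        for k in (1, 3, 10):
            top = select_top_pathogenic(calls, by_key, k=k)
            brute = sorted(
                calls, key=lambda c: (-c.combined, c.sift, by_key[c.variant_key].gene)
            )[:k]
            assert [c.variant_key for c in top] == [c.variant_key for c in brute]


class TestMerge:
    def vset(self, n, gene_prefix, start_pos=1):
        return [
            make_variant(pos=start_pos + i, gene=f"{gene_prefix}{i}") for i in range(n)
        ]

    def test_disjoint_7_plus_2_gives_9(self):
        a, b = self.vset(7, "N"), self.vset(2, "P", start_pos=100)
        merged = merge_workflows(a, b, {})
        assert len(merged) == 9
        assert sum(1 for c in merged if c.workflow is Workflow.NETWORK) == 7
        assert sum(1 for c in merged if c.workflow is Workflow.PATHOGENICITY) == 2

    def test_identical_sets_all_tagged_both(self):
        a = self.vset(4, "G")
        merged = merge_workflows(a, a, {})
        assert len(merged) == 4
        assert all(c.workflow is Workflow.BOTH for c in merged)

    def test_union_size_matches_inclusion_exclusion(self):
        rng = np.random.default_rng(23)
        pool = self.vset(30, "G")
        for _ in range(20):
            a = [pool[i] for i in rng.choice(30, size=rng.integers(0, 20), replace=False)]
            b = [pool[i] for i in rng.choice(30, size=rng.integers(0, 20), replace=False)]
            merged = merge_workflows(a, b, {})
            ka, kb = {v.key for v in a}, {v.key for v in b}
            assert len(merged) == len(ka) + len(kb) - len(ka & kb)


class TestExclusionList:
    def test_four_of_nine_excluded(self):
        cands = merge_workflows(
            [make_variant(pos=i + 1, gene=f"G{i}") for i in range(9)], [], {}
        )
        retained = apply_exclusion_list(
            cands, {f"G{i}": "other disease" for i in range(4)}
        )
        assert len(retained) == 5

    def test_empty_list_is_identity_and_full_list_empties(self):
        cands = merge_workflows([make_variant(gene="A")], [], {})
        assert apply_exclusion_list(cands, {}) == cands
        assert apply_exclusion_list(cands, {"A": "reviewed out"}) == []


def _obs(candidate: Candidate, zygosity: Zygosity) -> ZygosityObservation:
    return ZygosityObservation(
        gene=candidate.gene or "?", variant_key=candidate.key, observed=zygosity
    )


class TestFinalization:
    def five_gene_candidates(self):
        """The five-finalist layout: two WGS false positives, two het calls
        on hemizygous/recessive models, one true hemizygous X variant."""
        specs = [
            ("DTX1", "12", {InheritanceMode.DE_NOVO}),
            ("NOTCH2", "1", {InheritanceMode.DE_NOVO}),
            ("GFRA2", "8", {InheritanceMode.AUTOSOMAL_RECESSIVE}),
            ("GART", "21", {InheritanceMode.AUTOSOMAL_RECESSIVE}),
            ("ATP7A", "X", {InheritanceMode.X_LINKED}),
        ]
        variants = [
            make_variant(chrom=c, pos=100 + i, gene=g) for i, (g, c, _) in enumerate(specs)
        ]
        modes = {v.key: m for v, (_, _, m) in zip(variants, specs)}
        return merge_workflows(variants, [], modes)

    def test_five_gene_outcome_yields_single_confirmed(self, pedigree):
        cands = self.five_gene_candidates()
        observations = [
            _obs(cands[0], Zygosity.WILD_TYPE),
            _obs(cands[1], Zygosity.WILD_TYPE),
            _obs(cands[2], Zygosity.HETEROZYGOUS),
            _obs(cands[3], Zygosity.HETEROZYGOUS),
            _obs(cands[4], Zygosity.HEMIZYGOUS_ALT),
        ]
        report = finalize_by_zygosity(cands, observations, pedigree)
        confirmed = [c for c in report.rows if c.outcome is Outcome.CONFIRMED]
        assert [c.gene for c in confirmed] == ["ATP7A"]
        assert report.final_ranks[confirmed[0].key] == 1
        outcomes = {c.gene: c.outcome for c in report.rows}
        assert outcomes["DTX1"] is Outcome.FALSE_POSITIVE
        assert outcomes["GFRA2"] is Outcome.ZYGOSITY_INCONSISTENT

    def test_no_observations_leaves_all_untested_and_retained(self, pedigree):
        cands = self.five_gene_candidates()
        report = finalize_by_zygosity(cands, [], pedigree)
        assert all(c.outcome is Outcome.UNTESTED for c in report.rows)
        assert len(report.final_ranks) == 5

    def test_random_outcomes_match_rule_table_oracle(self, pedigree):
        """Drop/keep decisions agree with an independent rule-table lookup."""
        rule_table = {
            # (observed, AR or male-X candidate?) -> dropped?
            (Zygosity.WILD_TYPE, True): True,
            (Zygosity.WILD_TYPE, False): True,
            (Zygosity.HETEROZYGOUS, True): True,
            (Zygosity.HETEROZYGOUS, False): False,
            (Zygosity.HOMOZYGOUS_ALT, True): False,
            (Zygosity.HOMOZYGOUS_ALT, False): False,
            (Zygosity.HEMIZYGOUS_ALT, True): False,
            (Zygosity.HEMIZYGOUS_ALT, False): False,
        }
        mode_sets = [
            {InheritanceMode.DE_NOVO},
            {InheritanceMode.AUTOSOMAL_RECESSIVE},
            {InheritanceMode.X_LINKED},
            {InheritanceMode.X_LINKED, InheritanceMode.DE_NOVO},
        ]
        for i, (zyg, modes) in enumerate(itertools.product(Zygosity, mode_sets)):
            chrom = "X" if InheritanceMode.X_LINKED in modes else "5"
            v = make_variant(chrom=chrom, pos=1000 + i, gene=f"G{i}")
            cands = merge_workflows([v], [], {v.key: modes})
            report = finalize_by_zygosity(cands, [_obs(cands[0], zyg)], pedigree)
            strict = (
                InheritanceMode.AUTOSOMAL_RECESSIVE in modes
                or InheritanceMode.X_LINKED in modes  # male proband
            )
            dropped = cands[0].key not in report.final_ranks
            assert dropped == rule_table[(zyg, strict)], (zyg, modes)

    def test_confirmed_ranked_above_untested(self, pedigree):
        cands = self.five_gene_candidates()
        report = finalize_by_zygosity(
            cands, [_obs(cands[4], Zygosity.HEMIZYGOUS_ALT)], pedigree
        )
        assert report.final_ranks[cands[4].key] == 1
        untested_ranks = [
            report.final_ranks[c.key] for c in cands[:4] if c.key in report.final_ranks
        ]
        assert min(untested_ranks) > 1


class TestWriteReport:
    def report(self, pedigree):
        cands = TestFinalization().five_gene_candidates()
        return finalize_by_zygosity(
            cands, [_obs(cands[4], Zygosity.HEMIZYGOUS_ALT)], pedigree
        )

    def test_byte_identical_across_runs(self, tmp_path, pedigree):
        r = self.report(pedigree)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_report(r, a, format="TSV")
        write_report(r, b, format="TSV")
        assert a.read_bytes() == b.read_bytes()

    def test_tsv_and_json_carry_identical_rows(self, tmp_path, pedigree):
        r = self.report(pedigree)
        t, j = tmp_path / "r.tsv", tmp_path / "r.json"
        write_report(r, t, format="TSV")
        write_report(r, j, format="JSON")
        payload = json.loads(j.read_text())
        tsv_lines = [l for l in t.read_text().splitlines() if not l.startswith("#")]
        header = tsv_lines[0].split("\t")
        assert len(tsv_lines) - 1 == len(payload["candidates"])
        for line, rec in zip(tsv_lines[1:], payload["candidates"]):
            row = dict(zip(header, line.split("\t")))
            assert row["gene"] == (rec["gene"] or ".")
            assert row["outcome"] == rec["outcome"]
            assert row["rank"] == (str(rec["rank"]) if rec["rank"] is not None else ".")

    def test_empty_report_is_header_only(self, tmp_path):
        from trioprio.candidate_prioritization import CandidateReport

        p = tmp_path / "empty.tsv"
        write_report(CandidateReport(), p, format="TSV")
        lines = p.read_text().splitlines()
        assert lines[-1].startswith("rank\t")
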