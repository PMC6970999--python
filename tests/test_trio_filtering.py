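"""The variant funnel: concordance, hard filters, modes, impact, frequency."""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trioprio.impact import ImpactClass, load_default_impact_table
from trioprio.models import InheritanceMode, Role
from trioprio.trio_filtering import (
    FrequencyThresholds,
    QualityThresholds,
    apply_frequency_exclusions,
    apply_quality_filters,
    assign_inheritance_modes,
    select_by_impact,
    select_rare_aj,
    trio_concordance,
)

from conftest import DATA_DIR, make_variant


def load_mode_fixture(name: str) -> list[tuple[str, str, str, set[str]]]:
    rows = []
    for line in (DATA_DIR / name).read_text().splitlines():
        if line.startswith("#") or line.startswith("proband"):
            continue
        pb, mo, fa, modes = line.split("\t")
        rows.append((pb, mo, fa, set() if modes == "-" else set(modes.split("+"))))
    return rows


class TestInheritanceModes:
    def test_autosomal_truth_table(self, pedigree):
        fixture = load_mode_fixture("autosomal_modes.tsv")
        assert len(fixture) == 27
        for pb, mo, fa, expected in fixture:
            v = make_variant(chrom="7", proband=pb, mother=mo, father=fa)
            got = {m.value for m in assign_inheritance_modes(v, pedigree)}
            assert got == expected, f"{pb},{mo},{fa}: {got} != {expected}"

    def test_chrx_truth_table(self, pedigree):
        fixture = load_mode_fixture("chrx_modes.tsv")
        assert len(fixture) == 12
        for pb, mo, fa, expected in fixture:
            v = make_variant(chrom="X", proband=pb, mother=mo, father=fa)
            got = {m.value for m in assign_inheritance_modes(v, pedigree)}
            assert got == expected, f"{pb},{mo},{fa}: {got} != {expected}"

    def test_x_linked_presence_pattern(self, pedigree):
        v = make_variant(chrom="X", proband="1", mother="0/1", father="0")
        assert assign_inheritance_modes(v, pedigree) == {InheritanceMode.X_LINKED}

    def test_de_novo_presence_pattern(self, pedigree):
        v = make_variant(chrom="5", proband="0/1", mother="0/0", father="0/0")
        assert assign_inheritance_modes(v, pedigree) == {InheritanceMode.DE_NOVO}

    def test_missing_genotype_gets_no_modes_and_tag(self, pedigree):
        v = make_variant(chrom="X", proband="1", mother=".", father="0")
        assert assign_inheritance_modes(v, pedigree) == set()
        assert "MISSING_GENOTYPE" in v.provenance

    def test_de_novo_and_recessive_are_mutually_exclusive(self, pedigree):
        # parents carry alt in the recessive pattern and none in de novo
        for pb, mo, fa in itertools.product(["0/0", "0/1", "1/1"], repeat=3):
            v = make_variant(chrom="3", proband=pb, mother=mo, father=fa)
            modes = assign_inheritance_modes(v, pedigree)
            assert not (
                InheritanceMode.DE_NOVO in modes
                and InheritanceMode.AUTOSOMAL_RECESSIVE in modes
            )

    def test_relaxed_recessive_model_allows_hom_parent_carrier_mix(self, pedigree):
        v = make_variant(chrom="3", proband="1/1", mother="0/1", father="0/1")
        assert assign_inheritance_modes(v, pedigree, recessive_model="relaxed") == {
            InheritanceMode.AUTOSOMAL_RECESSIVE
        }
        v2 = make_variant(chrom="3", proband="1/1", mother="1/1", father="0/1")
        assert (
            assign_inheritance_modes(v2, pedigree, recessive_model="relaxed") == set()
        )

    def test_par_exclusion_switch(self, pedigree):
        v = make_variant(chrom="X", pos=1_000_000, proband="1", mother="0/1", father="0")
        assert assign_inheritance_modes(v, pedigree) == {InheritanceMode.X_LINKED}
        v2 = make_variant(chrom="X", pos=1_000_000, proband="1", mother="0/1", father="0")
        assert assign_inheritance_modes(v2, pedigree, par_exclude=True) == set()


class TestQualityFilters:
    def test_single_violation_fails(self, pedigree):
        v = make_variant(qc={"QD": 1.5, "FS": 10.0, "MQ": 50.0})
        passed, failed = apply_quality_filters([v])
        assert failed == [v] and "QC_FAIL:QD" in v.provenance

    def test_equality_at_every_threshold_passes(self):
        v = make_variant(
            qc={"QD": 2.0, "FS": 60.0, "MQ": 40.0, "MQRankSum": -12.5, "ReadPosRankSum": -8.0}
        )
        passed, failed = apply_quality_filters([v])
        assert passed == [v]

    def test_absent_metrics_never_fail(self):
        passed, failed = apply_quality_filters([make_variant(qc={})])
        assert len(passed) == 1

    @pytest.mark.parametrize(
        "metric,bad",
        [("QD", 0.5), ("FS", 61.0), ("MQ", 39.0), ("MQRankSum", -13.0), ("ReadPosRankSum", -9.0)],
    )
    def test_each_metric_can_fail_alone(self, metric, bad):
        v = make_variant(qc={metric: bad})
        _, failed = apply_quality_filters([v])
        assert len(failed) == 1


class TestConcordance:
    def test_identical_genotypes_give_concordance_one(self, pedigree):
        vs = [
            make_variant(pos=i + 1, proband="0/1", mother="0/1", father="1/1")
            for i in range(10)
        ]
        conc = trio_concordance(vs, pedigree, min_sites=10)
        assert conc[(Role.PROBAND, Role.MOTHER)] == 1.0

    def test_opposite_homozygotes_give_zero(self, pedigree):
        vs = [
            make_variant(pos=i + 1, proband="1/1", mother="0/0", father="1/1")
            for i in range(10)
        ]
        conc = trio_concordance(vs, pedigree, min_sites=10)
        assert conc[(Role.PROBAND, Role.MOTHER)] == 0.0
        assert conc[(Role.PROBAND, Role.FATHER)] == 1.0

    def test_matches_brute_force_recount_on_simulated_sites(self, pedigree):
        from trioprio.synthetic_data import SimulationConfig, simulate_trio

        variants, sim_ped, _ = simulate_trio(
            SimulationConfig(seed=2, n_autosomal_sites=1000, n_x_sites=0, denovo_count=0)
        )
        conc = trio_concordance(variants, sim_ped, min_sites=500)
        usable = [v for v in variants if v.is_autosomal and v.is_snv]
        for pair in [(Role.PROBAND, Role.MOTHER), (Role.PROBAND, Role.FATHER)]:
            n = sum(
                1
                for v in usable
                if set(v.genotypes[pair[0]].alleles) & set(v.genotypes[pair[1]].alleles)
            )
            assert conc[pair] == pytest.approx(n / len(usable))

    def test_too_few_sites_is_fatal(self, pedigree):
        with pytest.raises(ValueError, match="usable"):
            trio_concordance([make_variant()], pedigree, min_sites=100)


class TestImpactSelection:
    def test_missense_retained_synonymous_dropped_unannotated_dropped(self):
        table = load_default_impact_table()
        keep = make_variant(consequence="missense_variant")
        drop = make_variant(pos=2, consequence="synonymous_variant")
        noann = make_variant(pos=3)
        unknown = make_variant(pos=4, consequence="mystery_term")
        retained = select_by_impact([keep, drop, noann, unknown], table)
        assert retained == [keep, unknown]
        assert "NO_ANNOTATION" in noann.provenance
        assert "UNKNOWN_CONSEQUENCE" in unknown.provenance

    def test_retained_set_matches_class_recount(self):
        table = load_default_impact_table()
        rng = np.random.default_rng(4)
        terms = list(table.classes)
        vs = [
            make_variant(pos=i + 1, consequence=str(rng.choice(terms)))
            for i in range(200)
        ]
        retained = select_by_impact(vs, table)
        expected = [
            v
            for v in vs
            if table.impact_of(v.consequence) in (ImpactClass.HIGH, ImpactClass.MODERATE)
        ]
        assert retained == expected


class TestFrequencyFilters:
    def test_headline_aj_frequency_passes_common_filter(self):
        v = make_variant(freqs={"gnomAD_AJ_MAF": 0.01991})
        assert apply_frequency_exclusions([v]) == [v]

    def test_kgp_above_two_percent_is_dropped(self):
        v = make_variant(freqs={"KGP_GMAF": 0.03})
        assert apply_frequency_exclusions([v]) == []

    def test_all_frequencies_absent_is_retained(self):
        v = make_variant()
        assert apply_frequency_exclusions([v]) == [v]
        assert select_rare_aj([v]) == [v]

    def test_headline_aj_frequency_fails_rare_workflow(self):
        v = make_variant(freqs={"gnomAD_AJ_MAF": 0.01991})
        assert select_rare_aj([v]) == []
        assert "AJ_NOT_RARE" in v.provenance

    @pytest.mark.parametrize(
        "aj,kept", [(0.0005, True), (0.001, False), (0.0009999, True)]
    )
    def test_rare_aj_strict_boundary(self, aj, kept):
        v = make_variant(freqs={"gnomAD_AJ_MAF": aj})
        assert (select_rare_aj([v]) == [v]) is kept

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            FrequencyThresholds(aj_rare_max=0.1, aj_maf_max=0.05)


@st.composite
def qc_dicts(draw):
    metrics = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"]
    qc = {}
    for m in metrics:
        if draw(st.booleans()):
            qc[m] = draw(
                st.floats(min_value=-50, max_value=300, allow_nan=False, allow_infinity=False)
            )
    return qc


class TestFunnelMonotonicity:
    @settings(max_examples=50, deadline=None)
    @given(qcs=st.lists(qc_dicts(), min_size=1, max_size=20), tighten=st.floats(0, 5))
    def test_tightening_quality_thresholds_never_enlarges_pass_set(self, qcs, tighten):
        vs = [make_variant(pos=i + 1, qc=qc) for i, qc in enumerate(qcs)]
        loose, _ = apply_quality_filters(vs, QualityThresholds())
        vs2 = [make_variant(pos=i + 1, qc=qc) for i, qc in enumerate(qcs)]
        strict_thresholds = QualityThresholds(
            qd_min=2.0 + tighten,
            fs_max=60.0 - tighten,
            mq_min=40.0 + tighten,
            mqranksum_min=-12.5 + tighten,
            readposranksum_min=-8.0 + tighten,
        )
        strict, _ = apply_quality_filters(vs2, strict_thresholds)
        assert {v.pos for v in strict} <= {v.pos for v in loose}

    @settings(max_examples=50, deadline=None)
    @given(
        freqs=st.lists(
            st.dictionaries(
                st.sampled_from(["dbSNP_GMAF", "KGP_GMAF", "ExAC_MAF", "gnomAD_AJ_MAF"]),
                st.floats(0, 1, allow_nan=False),
                max_size=4,
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_each_filter_output_is_subset_of_input(self, freqs):
        vs = [make_variant(pos=i + 1, freqs=f) for i, f in enumerate(freqs)]
        common = apply_frequency_exclusions(vs)
        assert set(id(v) for v in common) <= set(id(v) for v in vs)
        rare = select_rare_aj(common)
        assert set(id(v) for v in rare) <= set(id(v) for v in common)
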