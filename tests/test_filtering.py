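"""Somatic filter cascade, clonality EM, shared calling, indels, DBS."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetallineage.filtering import (
    FilterConfig, call_shared_variants, clonality_check, count_dbs,
    filter_clonal_snvs, filter_indels, flag_driver_candidates,
    germline_indel_positions,
)
from fetallineage.variant_io import SampleMeta

from conftest import make_call, make_record


def run_snv(records, meta, cfg, **kw):
    return filter_clonal_snvs(records, "clone1", "bulk1", meta, cfg, **kw)


class TestClonalSnvGates:
    def test_clean_clonal_variant_retained(self, filter_cfg, meta_pair):
        rec = make_record()  # VAF 0.5, GQ 99, DP 30; bulk 0/30
        assert run_snv([rec], meta_pair, filter_cfg).retained == [rec]

    @pytest.mark.parametrize("tweak, stage", [
        (dict(filter_pass=False), "caller_pass"),
        (dict(qual=49.0), "qual"),
        (dict(mq=59.0), "mq"),
        (dict(mq=None), "mq"),                 # missing MQ is conservative
        (dict(ref="C", alt=("A", "T")), "multiallelic"),
    ])
    def test_site_gates(self, filter_cfg, meta_pair, tweak, stage):
        rec = make_record(**tweak)
        res = run_snv([rec], meta_pair, filter_cfg)
        assert res.retained == [] and res.attrition[stage] == 1

    @pytest.mark.parametrize("call, stage", [
        (make_call(gq=98), "clone_quality"),
        (make_call(dp=19, ad=(10, 9)), "clone_quality"),
        (make_call(ad=(27, 3)), "clone_quality"),         # VAF 0.1 not > 0.1
        (make_call(ad=(25, 5)), "clonality_vaf"),         # VAF 0.167 < 0.3
        (make_call(ad=(26, 4)), "clonality_vaf"),         # VAF 0.133: spec example 0.15-ish
    ])
    def test_clone_quality_and_clonality(self, filter_cfg, meta_pair, call, stage):
        rec = make_record(clone_call=call)
        res = run_snv([rec], meta_pair, filter_cfg)
        assert res.retained == [] and res.attrition[stage] == 1

    @pytest.mark.parametrize("bulk", [
        make_call(gt=(0, 0), gq=9, dp=30, ad=(30, 0)),    # GQ below 10
        make_call(gt=(0, 0), gq=60, dp=19, ad=(19, 0)),   # DP below 20
        make_call(gt=(0, 0), gq=60, dp=30, ad=(29, 1)),   # one alt read: VAF != 0
    ])
    def test_bulk_quality(self, filter_cfg, meta_pair, bulk):
        rec = make_record(bulk_call=bulk)
        res = run_snv([rec], meta_pair, filter_cfg)
        assert res.retained == [] and res.attrition["bulk_quality"] == 1

    def test_trisomic_contig_lower_vaf_cut(self, filter_cfg, meta_t21):
        """chr21 of a T21 clone keeps VAF >= 0.2 (one copy of three)."""
        rec = make_record(contig="chr21", clone_call=make_call(ad=(22, 8)))
        assert run_snv([rec], meta_t21, filter_cfg).retained == [rec]

    def test_trisomic_cut_only_on_trisomy_contig(self, filter_cfg, meta_t21):
        rec = make_record(contig="chr1", clone_call=make_call(ad=(22, 8)))
        assert run_snv([rec], meta_t21, filter_cfg).retained == []

    def test_male_x_hemizygous_rule(self, filter_cfg, meta_male):
        ok = make_record(contig="chrX",
                         clone_call=make_call(gt=(1, 1), gq=45, dp=12, ad=(0, 12)),
                         bulk_call=make_call(gt=(0, 0), gq=30, dp=11, ad=(11, 0)))
        het = make_record(contig="chrX",
                          clone_call=make_call(gt=(0, 1), gq=99, dp=30, ad=(15, 15)))
        res_ok = run_snv([ok], meta_male, filter_cfg)
        res_het = run_snv([het], meta_male, filter_cfg)
        assert res_ok.retained == [ok]
        assert res_het.retained == []     # VAF 0.5 < 0.99 on male X

    def test_exclusion_list_and_rescue(self, filter_cfg, meta_pair):
        rec = make_record()
        rescued = make_record(pos=2000, ids=("COSM1",))
        excl = {rec.key, rescued.key}
        res = run_snv([rec, rescued], meta_pair, filter_cfg,
                      exclusion=excl, rescue_ids={"COSM1"})
        assert res.retained == [rescued]

    def test_unknown_clone_raises(self, filter_cfg, meta_pair):
        with pytest.raises(ValueError):
            filter_clonal_snvs([make_record()], "nope", "bulk1", meta_pair,
                               filter_cfg)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.integers(0, 200), st.integers(0, 60), st.integers(0, 60),
              st.floats(0, 1), st.integers(0, 99)),
    min_size=1, max_size=30),
    st.floats(50, 120), st.floats(50, 300))
def test_threshold_monotonicity(rows, q1, q2):
    """Raising any threshold never grows the retained set."""
    meta = [SampleMeta("clone1", "d1", "clone", "HSPC", False, "F", 0.25),
            SampleMeta("bulk1", "d1", "bulk", "other", False, "F", 0.25)]
    records = []
    for i, (qual, dp_c, dp_b, vaf, gq) in enumerate(rows):
        alt = int(round(vaf * dp_c))
        records.append(make_record(
            pos=100 + i, qual=float(qual),
            clone_call=make_call(gt=(0, 1), gq=gq, dp=dp_c, ad=(dp_c - alt, alt)),
            bulk_call=make_call(gt=(0, 0), gq=60, dp=dp_b, ad=(dp_b, 0))))
    lo, hi = sorted([q1, q2])
    base = FilterConfig()
    kept_lo = {r.key for r in run_snv(records, meta,
                                      dataclasses.replace(base, snv_qual_min=lo)).retained}
    kept_hi = {r.key for r in run_snv(records, meta,
                                      dataclasses.replace(base, snv_qual_min=hi)).retained}
    assert kept_hi <= kept_lo
    kept_dp = {r.key for r in run_snv(records, meta,
                                      dataclasses.replace(base, dp_min=25)).retained}
    assert kept_dp <= {r.key for r in run_snv(records, meta, base).retained}


class TestClonalityCheck:
    def test_clonal_clone_passes(self, filter_cfg, rng):
        depth = rng.poisson(30, 200) + 1
        alt = rng.binomial(depth, 0.5)
        rep = clonality_check(alt, depth, filter_cfg)
        assert rep.passed and rep.weights[0] > 0.95
        assert abs(rep.means[0] - 0.5) < 0.05

    def test_fully_subclonal_fails(self, filter_cfg, rng):
        depth = rng.poisson(30, 200) + 1
        alt = rng.binomial(depth, 0.1)
        rep = clonality_check(alt, depth, filter_cfg)
        assert not rep.passed

    def test_half_mixture_recovers_weights(self, filter_cfg, rng):
        depth = rng.poisson(30, 400) + 1
        p = np.where(np.arange(400) < 200, 0.5, 0.1)
        alt = rng.binomial(depth, p)
        rep = clonality_check(alt, depth, filter_cfg)
        assert abs(rep.weights[0] - 0.5) < 0.12
        assert abs(rep.means[0] - 0.5) < 0.05 and abs(rep.means[1] - 0.1) < 0.05

    def test_too_few_sites_rejected(self, filter_cfg):
        with pytest.raises(ValueError):
            clonality_check([5] * 10, [30] * 10, filter_cfg)


def _three_clone_records():
    meta = [SampleMeta(s, "d1", "clone", "HSPC", False, "F", 0.25)
            for s in ("A", "B", "C")]
    meta.append(SampleMeta("bulk1", "d1", "bulk", "other", False, "F", 0.25))
    return meta


class TestSharedVariants:
    def test_present_and_absent_required(self):
        meta = _three_clone_records()
        cfg = FilterConfig()
        rec = make_record(calls={
            "A": make_call(),                                  # qualifying present
            "B": make_call(gt=(0, 1), gq=50, dp=30, ad=(20, 10)),
            "C": make_call(gt=(0, 0), gq=60, dp=30, ad=(30, 0)),  # qualifying absent
            "bulk1": make_call(gt=(0, 0), gq=60, dp=30, ad=(27, 3)),
        })
        (sv,) = call_shared_variants([rec], ["A", "B", "C"], ["bulk1"], meta, cfg)
        assert set(sv.candidate_present) == {"A", "B"}
        assert sv.present == ("A",) and "C" in sv.absent
        assert sv.bulk_vafs["bulk1"] == pytest.approx(0.1)

    def test_no_confident_absence_drops_variant(self):
        meta = _three_clone_records()
        rec = make_record(calls={
            "A": make_call(), "B": make_call(), "C": make_call(),
            "bulk1": make_call(gt=(0, 0), gq=60, dp=30, ad=(30, 0)),
        })
        assert call_shared_variants([rec], ["A", "B", "C"], ["bulk1"], meta,
                                    FilterConfig()) == []

    def test_qual_not_gated_in_shared_route(self):
        meta = _three_clone_records()
        rec = make_record(qual=10.0, calls={
            "A": make_call(),
            "B": make_call(gt=(0, 0), gq=60, dp=30, ad=(30, 0)),
            "C": make_call(gt=(0, 0), gq=60, dp=30, ad=(30, 0)),
            "bulk1": make_call(gt=(0, 0), gq=60, dp=30, ad=(30, 0)),
        })
        assert len(call_shared_variants([rec], ["A", "B", "C"], ["bulk1"],
                                        meta, FilterConfig())) == 1

    def test_single_clone_warns_and_returns_empty(self):
        meta = _three_clone_records()
        with pytest.warns(UserWarning):
            out = call_shared_variants([make_record()], ["A"], ["bulk1"],
                                       meta, FilterConfig())
        assert out == []


class TestIndels:
    def _indel(self, pos=5000, qual=300.0, clone_call=None, bulk_call=None):
        return make_record(pos=pos, ref="AT", alt="A", qual=qual,
                           clone_call=clone_call or make_call(gq=99),
                           bulk_call=bulk_call or make_call(gt=(0, 0), gq=99,
                                                            dp=30, ad=(30, 0)))

    def test_clean_indel_retained(self, filter_cfg, meta_pair):
        rec = self._indel()
        res = filter_indels([rec], "clone1", "bulk1", [("chr1", 4750)],
                            meta_pair, filter_cfg)
        assert res.retained == [rec]

    def test_germline_proximity_removed(self, filter_cfg, meta_pair):
        rec = self._indel()
        res = filter_indels([rec], "clone1", "bulk1", [("chr1", 5040)],
                            meta_pair, filter_cfg)
        assert res.retained == [] and res.attrition["germline_proximity"] == 1

    def test_qual_250_required(self, filter_cfg, meta_pair):
        res = filter_indels([self._indel(qual=200.0)], "clone1", "bulk1", [],
                            meta_pair, filter_cfg)
        assert res.retained == [] and res.attrition["qual"] == 1

    def test_bulk_gq_99_required(self, filter_cfg, meta_pair):
        rec = self._indel(bulk_call=make_call(gt=(0, 0), gq=50, dp=30, ad=(30, 0)))
        res = filter_indels([rec], "clone1", "bulk1", [], meta_pair, filter_cfg)
        assert res.retained == []

    def test_germline_indels_from_bulk_genotypes(self, meta_pair):
        het = make_record(pos=100, ref="A", alt="AT",
                          bulk_call=make_call(gt=(0, 1), gq=99, dp=30, ad=(15, 15)))
        ref = make_record(pos=200, ref="A", alt="AT")
        snv = make_record(pos=300, bulk_call=make_call(gt=(0, 1)))
        assert germline_indel_positions([het, ref, snv], "bulk1") == [("chr1", 100)]


class TestDriverFlags:
    def _sets(self, **kw):
        rec = make_record(**kw)
        return {"clone1": [rec]}, rec

    def test_high_effect_in_listed_gene_flagged(self):
        sets, rec = self._sets(effect="HIGH", gene="GATA1")
        assert len(flag_driver_candidates(sets, {"GATA1"}, set())) == 1

    def test_unlisted_gene_without_id_not_flagged(self):
        sets, _ = self._sets(effect="HIGH", gene="OTHER")
        assert flag_driver_candidates(sets, {"GATA1"}, set()) == []

    def test_low_effect_with_listed_id_not_flagged(self):
        sets, _ = self._sets(effect="LOW", ids=("COSM7",))
        assert flag_driver_candidates(sets, set(), {"COSM7"}) == []


class TestCountDbs:
    def _clone(self, positions, clone="A"):
        return [make_record(pos=p, clone=clone) for p in positions]

    def test_adjacent_pair_is_one_dbs(self):
        sets = {"A": self._clone([100, 101])}
        assert count_dbs(sets, {"A": "d1"}) == {"A": 1}

    def test_gap_of_two_is_not_a_dbs(self):
        sets = {"A": self._clone([100, 102])}
        assert count_dbs(sets, {"A": "d1"}) == {"A": 0}

    def test_shared_pair_credited_once_per_donor(self):
        sets = {"A": self._clone([100, 101]), "B": self._clone([100, 101], "B")}
        counts = count_dbs(sets, {"A": "d1", "B": "d1"})
        assert counts == {"A": 1, "B": 0}

    def test_pair_in_different_donors_counted_twice(self):
        sets = {"A": self._clone([100, 101]), "B": self._clone([100, 101], "B")}
        counts = count_dbs(sets, {"A": "d1", "B": "d2"})
        assert counts == {"A": 1, "B": 1}
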