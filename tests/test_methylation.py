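"""DMR calling, feature density, and splice-anchored methylation profiles."""

import numpy as np
import pandas as pd
import pytest

from intronret.annotation import GenomeAnnotation, IntronUnit, build_feature_map
from intronret.methylation import (
    DMRParams,
    call_dmrs,
    dmr_feature_density,
    profile_group_test,
    splice_anchor_profile,
)
from intronret.simulate import CohortConfig, build_truth, simulate_methylome

from conftest import make_gene


def make_track(positions, m, depth=30, rng=None, chrom="chr1"):
    rng = rng or np.random.default_rng(0)
    m = np.broadcast_to(np.asarray(m, float), (len(positions),))
    total = rng.poisson(depth, size=len(positions))
    total = np.maximum(total, 1)
    meth = rng.binomial(total, m)
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions), "methylated": meth, "total": total}
    )


BLOCK = (2000, 3000)  # planted 1 kb DMR
POSITIONS = np.arange(0, 10000, 50)  # CpG every 50 bp -> 20 CpGs in block


def planted_tracks(delta=0.4, n=3, depth=30, seed=0):
    rng = np.random.default_rng(seed)
    in_block = (POSITIONS >= BLOCK[0]) & (POSITIONS < BLOCK[1])
    m_a = np.where(in_block, 0.8, 0.6)
    m_b = np.where(in_block, 0.8 - delta, 0.6)
    tracks_a = [make_track(POSITIONS, m_a, depth, rng) for _ in range(n)]
    tracks_b = [make_track(POSITIONS, m_b, depth, rng) for _ in range(n)]
    return tracks_a, tracks_b


def jaccard(a, b):
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    inter = max(0, hi - lo)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union


class TestCallDMRs:
    def test_identical_groups_zero_dmrs(self):
        tracks_a, _ = planted_tracks()
        assert len(call_dmrs(tracks_a, tracks_a)) == 0

    def test_planted_block_recovered(self):
        tracks_a, tracks_b = planted_tracks()
        dmrs = call_dmrs(tracks_a, tracks_b)
        assert len(dmrs) == 1
        dmr = dmrs.iloc[0]
        assert dmr["direction"] == "hyper" and dmr["delta"] > 0.3
        assert jaccard((dmr["start"], dmr["end"]), BLOCK) >= 0.8
        assert dmr["n_sig_cpg"] >= 15

    def test_two_blocks_beyond_max_gap_split(self):
        rng = np.random.default_rng(4)
        pos = np.arange(0, 4000, 50)
        in_b1 = pos < 500
        in_b2 = pos >= 3000
        m_a = np.where(in_b1 | in_b2, 0.9, 0.5)
        m_b = np.full(pos.shape, 0.5)
        tracks_a = [make_track(pos, m_a, 40, rng) for _ in range(3)]
        tracks_b = [make_track(pos, m_b, 40, rng) for _ in range(3)]
        dmrs = call_dmrs(tracks_a, tracks_b)
        assert len(dmrs) == 2

    def test_label_swap_negates_delta(self):
        tracks_a, tracks_b = planted_tracks()
        d1 = call_dmrs(tracks_a, tracks_b)
        d2 = call_dmrs(tracks_b, tracks_a)
        assert len(d1) == len(d2) == 1
        assert d1.iloc[0]["delta"] == pytest.approx(-d2.iloc[0]["delta"])
        assert d2.iloc[0]["direction"] == "hypo"

    def test_within_group_order_invariance(self):
        tracks_a, tracks_b = planted_tracks()
        d1 = call_dmrs(tracks_a, tracks_b)
        d2 = call_dmrs(tracks_a[::-1], tracks_b[::-1])
        pd.testing.assert_frame_equal(d1, d2)

    def test_disjoint_cpg_spaces_rejected(self):
        a = make_track(np.arange(0, 100, 10), 0.5)
        b = make_track(np.arange(1000, 1100, 10), 0.5)
        with pytest.raises(ValueError):
            call_dmrs([a], [b])


class TestDMRFeatureDensity:
    def _fmap(self):
        ann = GenomeAnnotation(
            genes={"G1": make_gene(exon_list=((1000, 2000), (3000, 4000)))},
            chrom_lengths={"chr1": 10000},
        )
        return build_feature_map(ann, promoter_span=500)

    def test_all_in_introns(self):
        fmap = self._fmap()
        dmrs = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [2100, 2400, 2800], "end": [2200, 2500, 2900]}
        )
        out = dmr_feature_density(dmrs, fmap).set_index("feature")
        assert out.loc["intron", "count"] == 3
        assert out["count"].sum() == 3  # conservation

    def test_empty_dmrs_all_zero(self):
        out = dmr_feature_density(pd.DataFrame(columns=["chrom", "start", "end"]), self._fmap())
        assert (out["count"] == 0).all()

    def test_uniform_dmrs_density_flat(self):
        """Uniformly placed DMRs give roughly equal densities per label."""
        fmap = self._fmap()
        rng = np.random.default_rng(8)
        mids = rng.integers(0, 10000, size=2000)
        dmrs = pd.DataFrame({"chrom": "chr1", "start": mids - 10, "end": mids + 10})
        out = dmr_feature_density(dmrs, fmap).set_index("feature")
        out = out[out["total_bp"] > 500]
        dens = out["density_per_mb"]
        expected = 2000 / (10000 / 1e6)
        assert ((dens > 0.6 * expected) & (dens < 1.4 * expected)).all()


def _profile_cohort(dip=0.3, seed=5, n_samples=2):
    # affected introns long enough (>= 2*window + 200) to carry a centre anchor
    cfg = CohortConfig(
        n_samples={"diagnosis": n_samples, "remission": 0, "control": 0},
        m0=0.8, dip_depth=dip, affected_intron_length=800,
    )
    truth = build_truth(cfg, seed=seed)
    tracks = [
        simulate_methylome(truth, s) for s in truth.sample_sheet["sample"]
    ]
    retained_ids = set(truth.retained_intron_ids("diagnosis"))
    retained = [iv for iv in truth.introns if iv.intron_id in retained_ids]
    non_retained = [iv for iv in truth.introns if iv.intron_id not in retained_ids]
    return truth, tracks, retained, non_retained


class TestSpliceAnchorProfile:
    def test_uniform_methylome_flat_profiles(self):
        truth, tracks, retained, non_retained = _profile_cohort(dip=0.0)
        prof = splice_anchor_profile(tracks, retained, non_retained)
        assert prof["meth"].between(0.55, 1.0).all()  # offset-level noise only
        for (_, _), sub in prof.groupby(["group", "anchor"]):
            mean = np.average(sub["meth"], weights=sub["coverage"])
            assert mean == pytest.approx(0.8, abs=0.02)
        assert set(prof["anchor"]) == {"5ss", "centre", "3ss"}
        assert set(prof["group"]) == {"retained", "non_retained"}

    def test_planted_dip_recovered_in_body_not_flank(self):
        truth, tracks, retained, non_retained = _profile_cohort(dip=0.3)
        prof = splice_anchor_profile(tracks, retained, non_retained)

        def pooled(group, anchor, side):
            sub = prof[(prof["group"] == group) & (prof["anchor"] == anchor)]
            sub = sub[sub["offset"] < 0 if side == "up" else sub["offset"] >= 0]
            w = sub["coverage"]
            return np.average(sub["meth"], weights=w)

        body_diff = pooled("retained", "centre", "dn") - pooled(
            "non_retained", "centre", "dn"
        )
        # exonic flank = upstream of the 5' splice site
        flank_diff = pooled("retained", "5ss", "up") - pooled(
            "non_retained", "5ss", "up"
        )
        assert body_diff == pytest.approx(-0.3, abs=0.05)
        assert flank_diff == pytest.approx(0.0, abs=0.05)

    def test_strand_mirror_symmetry(self):
        """Flipping intron strand mirrors the offset axis of its profile."""
        positions = np.arange(900, 1500, 10)
        m = np.where(positions < 1200, 0.9, 0.1)  # step at the intron middle
        track = make_track(positions, m, depth=200)
        plus = IntronUnit("i+", "G", "chr1", 1000, 1400, "+", [], 400)
        minus = IntronUnit("i-", "G", "chr1", 1000, 1400, "-", [], 400)
        p_plus = splice_anchor_profile([track], [plus], [plus], window=100)
        p_minus = splice_anchor_profile([track], [minus], [minus], window=100)
        a = p_plus[(p_plus["group"] == "retained") & (p_plus["anchor"] == "5ss")]
        b = p_minus[(p_minus["group"] == "retained") & (p_minus["anchor"] == "3ss")].copy()
        b["offset"] = -b["offset"]  # mirrored axis on the opposite strand
        merged = a.merge(b, on="offset", suffixes=("_p", "_m"))
        assert len(merged) > 10
        np.testing.assert_allclose(merged["meth_p"], merged["meth_m"])

    def test_empty_group_rejected(self):
        truth, tracks, retained, non_retained = _profile_cohort()
        with pytest.raises(ValueError, match="retained"):
            splice_anchor_profile(tracks, [], non_retained)


class TestProfileGroupTest:
    def test_planted_dip_significant(self):
        truth, tracks, retained, non_retained = _profile_cohort(dip=0.3)
        res = profile_group_test(tracks, retained, non_retained).set_index("anchor")
        assert res.loc["centre", "p_value"] < 0.01
        assert res.loc["centre", "effect"] == pytest.approx(-0.3, abs=0.05)

    def test_identical_groups_non_significant(self):
        truth, tracks, retained, non_retained = _profile_cohort(dip=0.0)
        res = profile_group_test(tracks, retained, non_retained)
        assert (res["p_value"] > 0.01).all()

    def test_permutation_fallback_agrees_on_signal(self):
        truth, tracks, retained, non_retained = _profile_cohort(dip=0.3)
        res = profile_group_test(
            tracks, retained, non_retained, method="permutation", n_permutations=200
        ).set_index("anchor")
        assert res.loc["centre", "p_value"] < 0.05

    def test_single_group_rejected(self):
        truth, tracks, retained, non_retained = _profile_cohort()
        with pytest.raises(ValueError):
            profile_group_test(tracks, retained, [])
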