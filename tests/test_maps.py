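import numpy as np
import pytest

from splicemap.maps import (cooccurrence_profile, event_window_presence,
                            linked_hits, permutation_test, profile_to_frame,
                            scan_regions, window_profile)
from splicemap.motifs import MotifHit, MotifSpec, RBPMS_DIMER, coverage_mask
from splicemap.regions import SEGMENT_LABELS, MapLayout, RegionSet, Segment


def _region_set(eid, seqs=None, seg_len=None, layout=None):
    """RegionSet with full-length (or given) all-background segments."""
    layout = layout or MapLayout()
    segments = []
    pos = 0
    for lab in SEGMENT_LABELS:
        L = seg_len[lab] if seg_len else layout.slot_len(lab)
        seq = (seqs or {}).get(lab, "A" * L)
        segments.append(Segment(label=lab, seq=seq, genomic_start=pos,
                                genomic_end=pos + len(seq)))
        pos += len(seq) + 10
    return RegionSet(event_id=eid, chrom="chr1", strand="+",
                     segments=tuple(segments))


def _hits_free(rs):
    return {seg.label: [] for seg in rs.segments}


def test_single_event_window_coverage(layout):
    """A motif covering [10,17) lights exactly the windows that reach it."""
    rs = _region_set("E0")
    hits = _hits_free(rs)
    hits["dn_intron_5p"] = [MotifHit(10, 17)]
    cov, n = window_profile([rs], {"E0": hits}, layout)
    s = layout.slot_starts["dn_intron_5p"]
    half = layout.window_len // 2
    on = np.flatnonzero(cov[s:s + 250] == 1.0)
    # window centred at p clipped to the segment touches [10,17) iff
    # p-15 <= 16 and p+15 >= 10
    expect = np.arange(max(0, 10 - half), min(250, 17 + half))
    assert list(on) == list(expect)
    assert (n >= 1).all()
    other = np.r_[cov[:s], cov[s + 250:]]
    assert (other == 0).all()


def test_half_of_events_covered_everywhere(layout):
    sets, hits = [], {}
    for i in range(10):
        rs = _region_set(f"E{i}")
        sets.append(rs)
        h = _hits_free(rs)
        if i < 5:
            h = {seg.label: [MotifHit(0, len(seg))] for seg in rs.segments}
        hits[rs.event_id] = h
    cov, _ = window_profile(sets, hits, layout)
    assert np.allclose(cov, 0.5)


def test_window_profile_matches_brute_force(layout, small_cohort):
    """Naive per-event per-position double loop on 20 events."""
    regions = list(small_cohort["regions"].values())[:20]
    hits = {rs.event_id: scan_regions(rs, RBPMS_DIMER) for rs in regions}
    cov, n_contrib = window_profile(regions, hits, layout)
    half = layout.window_len // 2
    num = np.zeros(layout.axis_len)
    den = np.zeros(layout.axis_len)
    for rs in regions:
        for seg in rs.segments:
            mask = coverage_mask(len(seg), hits[rs.event_id][seg.label])
            L = len(seg)
            slot = layout.slot_len(seg.label)
            start = layout.slot_starts[seg.label]
            shift = 0 if layout.anchor(seg.label) == "5p" else slot - L
            for p in range(L):
                lo, hi = max(0, p - half), min(L, p + half + 1)
                den[start + shift + p] += 1
                if mask[lo:hi].any():
                    num[start + shift + p] += 1
    expect = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    assert np.allclose(cov, expect, equal_nan=True)
    assert (n_contrib == den).all()


def test_empty_event_set_rejected(layout):
    with pytest.raises(ValueError):
        window_profile([], {}, layout)


def test_permutation_preconditions(layout):
    rs1, rs2 = _region_set("A"), _region_set("B")
    with pytest.raises(ValueError):
        permutation_test([rs1], [rs2], RBPMS_DIMER, layout, n_perm=0)
    with pytest.raises(ValueError):
        permutation_test([rs1], [], RBPMS_DIMER, layout)
    with pytest.raises(ValueError):
        permutation_test([rs1, rs1], [rs2], RBPMS_DIMER, layout, n_perm=5)
    with pytest.raises(ValueError):
        permutation_test([rs1], [rs1], RBPMS_DIMER, layout, n_perm=5)


def test_pvalues_honour_plus_one_correction(layout, small_cohort):
    regions = list(small_cohort["regions"].values())
    prof = permutation_test(regions[:20], regions[20:80], RBPMS_DIMER, layout,
                            n_perm=99, seed=2)
    assert (prof.pvalues >= 1 / 100).all()
    assert (prof.pvalues <= 1.0).all()
    # deterministic given seed
    again = permutation_test(regions[:20], regions[20:80], RBPMS_DIMER, layout,
                             n_perm=99, seed=2)
    assert np.array_equal(prof.pvalues, again.pvalues)


def test_significance_requires_test_above_reference(layout, small_cohort):
    regions = list(small_cohort["regions"].values())
    prof = permutation_test(regions[:30], regions[30:120], RBPMS_DIMER, layout,
                            n_perm=200, seed=4)
    above = prof.coverage > prof.coverage_ref
    assert not prof.significant[~np.nan_to_num(above, nan=False)].any()


def test_adding_hit_free_events_lowers_coverage(layout):
    sets, hits = [], {}
    for i in range(6):
        rs = _region_set(f"E{i}")
        sets.append(rs)
        hits[rs.event_id] = {seg.label: [MotifHit(0, len(seg))]
                             for seg in rs.segments}
    cov_before, _ = window_profile(sets, hits, layout)
    extra = _region_set("Z")
    sets.append(extra)
    hits["Z"] = _hits_free(extra)
    cov_after, _ = window_profile(sets, hits, layout)
    assert (cov_after <= cov_before + 1e-12).all()
    assert (cov_after < cov_before).any()


@pytest.mark.parametrize("a,b,gap,linked", [
    ((0, 7), (10, 15), 3, True),
    ((0, 7), (33, 38), 26, False),   # one past the 25-nt bound
    ((0, 7), (32, 37), 25, True),    # exactly at the bound
    ((10, 15), (0, 7), 3, True),     # order-independent
    ((0, 7), (5, 12), 0, True),      # overlapping -> gap 0
])
def test_linked_hits_gap_rule(a, b, gap, linked):
    pairs = linked_hits([MotifHit(*a)], [MotifHit(*b)], link_max_gap=25)
    assert bool(pairs) == linked
    if pairs:
        assert pairs[0][0] == a[0]   # anchored at the motif-A hit start


def test_linked_hits_matches_all_pairs_oracle():
    rng = np.random.default_rng(9)
    for _ in range(30):
        ha = [MotifHit(int(s), int(s) + 7)
              for s in rng.integers(0, 400, size=rng.integers(0, 8))]
        hb = [MotifHit(int(s), int(s) + 5)
              for s in rng.integers(0, 400, size=rng.integers(0, 8))]
        got = linked_hits(ha, hb, 25)
        expect = sum(1 for a in ha for b in hb
                     if max(a.start - b.end, b.start - a.end, 0) <= 25)
        assert len(got) == expect


def test_cooccurrence_with_itself_is_self_linkage(layout):
    """motif_b == motif_a reduces to the self-linked profile of A."""
    word = MotifSpec(name="w", kind="iupac_word", word="GCATG")
    seqs = {"dn_intron_5p": "A" * 40 + "GCATG" + "A" * 205}
    test = [_region_set("T", seqs=seqs)]
    ref = [_region_set(f"R{i}") for i in range(5)]
    prof, _ = cooccurrence_profile(test, ref, word, word, layout,
                                   n_perm=19, seed=0)
    s = layout.slot_starts["dn_intron_5p"]
    half = layout.window_len // 2
    on = np.flatnonzero(prof.coverage[s:s + 250] == 1.0)
    # the only anchor is the hit start (40): windows covering position 40
    assert list(on) == list(range(40 - half, 40 + half + 1))


def test_profile_frame_layout(layout, small_cohort):
    regions = list(small_cohort["regions"].values())
    prof = permutation_test(regions[:10], regions[10:40], RBPMS_DIMER, layout,
                            n_perm=19, seed=0)
    df = profile_to_frame(prof, layout)
    assert len(df) == layout.axis_len
    assert list(df["segment_label"].unique()) == list(SEGMENT_LABELS)
    assert df["offset"].iloc[0] == 0
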