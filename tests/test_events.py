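import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicemap.events import (SplicingEvent, SpliceTableFormatError, Thresholds,
                              classify_events, differential_test,
                              psi_from_counts, raw_pvalues, read_events,
                              write_events)
from splicemap.simulate import SimConfig, simulate_events


@pytest.mark.parametrize("inc,skip,ifl,sfl,expected", [
    (30, 10, 1, 1, 0.75),
    (0, 7, 1, 1, 0.0),
    (15, 5, 2, 1, 0.6),   # (7.5)/(7.5+5)
    (5, 0, 1, 1, 1.0),
])
def test_psi_from_counts_values(inc, skip, ifl, sfl, expected):
    assert psi_from_counts(inc, skip, ifl, sfl) == pytest.approx(expected)


def test_psi_from_counts_undefined_and_errors():
    assert math.isnan(psi_from_counts(0, 0, 1, 1))
    with pytest.raises(ValueError):
        psi_from_counts(-1, 3, 1, 1)
    with pytest.raises(ValueError):
        psi_from_counts(1, 3, 0, 1)


@settings(derandomize=True, max_examples=50)
@given(inc=st.integers(0, 1000), skip=st.integers(0, 1000),
       c=st.integers(1, 20))
def test_psi_scale_invariance(inc, skip, c):
    """Multiplying both counts by c leaves PSI unchanged."""
    if inc + skip == 0:
        return
    assert psi_from_counts(inc * c, skip * c, 2, 1) == pytest.approx(
        psi_from_counts(inc, skip, 2, 1))


def _demo_event(eid="E1", strand="+", psi1=(0.7, 0.75), psi2=(0.3, 0.35)):
    if strand == "+":
        coords = dict(cassette_start=2000, cassette_end=2100,
                      upstream_exon_start=1000, upstream_exon_end=1200,
                      downstream_exon_start=3000, downstream_exon_end=3200)
    else:
        coords = dict(cassette_start=2000, cassette_end=2100,
                      upstream_exon_start=3000, upstream_exon_end=3200,
                      downstream_exon_start=1000, downstream_exon_end=1200)
    return SplicingEvent(event_id=eid, gene_id="G1", event_class="SE",
                         chrom="chr1", strand=strand,
                         inc_counts=((30, 28), (10, 12)),
                         skip_counts=((10, 12), (30, 28)),
                         inc_form_len=1, skip_form_len=1,
                         psi1=psi1, psi2=psi2, **coords)


def test_event_invariants_enforced():
    with pytest.raises(ValueError):
        _demo_event(psi1=(1.5, 0.5))
    with pytest.raises(ValueError):
        # exon order violated for minus strand
        SplicingEvent(event_id="x", gene_id="g", event_class="SE",
                      chrom="chr1", strand="-",
                      cassette_start=2000, cassette_end=2100,
                      upstream_exon_start=1000, upstream_exon_end=1200,
                      downstream_exon_start=3000, downstream_exon_end=3200)


def test_table_round_trip(tmp_path):
    cfg = SimConfig(seed=5, n_events=20)
    events, _ = simulate_events(cfg)
    path = tmp_path / "events.tsv"
    write_events(events, path)
    back = read_events(path)
    assert [e.event_id for e in back] == [e.event_id for e in events]
    for a, b in zip(events, back):
        assert a.psi1 == pytest.approx(b.psi1)
        assert a.inc_counts == b.inc_counts
        assert a.strand == b.strand
        assert a.cassette_start == b.cassette_start
    # second write is byte-identical
    path2 = tmp_path / "events2.tsv"
    write_events(back, path2)
    assert path2.read_bytes() == path.read_bytes()


def test_psi_computed_from_counts_when_inclevels_absent(tmp_path):
    path = tmp_path / "t.tsv"
    write_events([_demo_event()], path)
    text = path.read_text().splitlines()
    header = text[0].split("\t")
    i1, i2 = header.index("IncLevel1"), header.index("IncLevel2")
    row = text[1].split("\t")
    row[i1] = row[i2] = ""
    path.write_text("\n".join([text[0], "\t".join(row)]) + "\n")
    (ev,) = read_events(path)
    assert ev.psi1 == pytest.approx((0.75, 0.70))


def test_read_errors(tmp_path):
    good = tmp_path / "good.tsv"
    write_events([_demo_event()], good)
    lines = good.read_text().splitlines()
    # drop a mandatory column
    cols = lines[0].split("\t")
    idx = cols.index("FDR")
    bad = tmp_path / "missing.tsv"
    bad.write_text("\n".join(
        "\t".join(v for i, v in enumerate(ln.split("\t")) if i != idx)
        for ln in lines) + "\n")
    with pytest.raises(SpliceTableFormatError, match="FDR"):
        read_events(bad)
    # malformed count vector names the line
    row = lines[1].split("\t")
    row[cols.index("IJC_SAMPLE_1")] = "3,x"
    bad2 = tmp_path / "badcounts.tsv"
    bad2.write_text("\n".join([lines[0], "\t".join(row)]) + "\n")
    with pytest.raises(SpliceTableFormatError, match="line 2"):
        read_events(bad2)


def test_differential_identical_vectors():
    ev = _demo_event(psi1=(0.5, 0.5, 0.5), psi2=(0.5, 0.5, 0.5))
    (out,) = differential_test([ev])
    assert out.delta_psi == 0.0
    assert out.fdr == 1.0


def test_differential_untestable_single_replicate():
    ev = _demo_event(psi1=(0.5,), psi2=(0.9, 0.8))
    (out,) = differential_test([ev])
    assert out.fdr == 1.0


def test_bh_fdr_monotone_in_p_rank(tested_cohort):
    """Reported FDRs are monotone non-decreasing in raw P rank."""
    raw = raw_pvalues(tested_cohort)
    pairs = sorted((raw[e.event_id], e.fdr) for e in tested_cohort
                   if e.event_id in raw)
    fdrs = [f for _, f in pairs]
    assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))


@pytest.mark.parametrize("dpsi,fdr,expected", [
    (+0.20, 0.01, "activated"),
    (-0.20, 0.01, "repressed"),
    (+0.05, 0.50, "reference"),
    (+0.10, 0.01, "neither"),   # between the regulated and reference cut-offs
])
def test_classification_thresholds(dpsi, fdr, expected):
    ev = _demo_event()
    ev = type(ev)(**{**ev.__dict__, "delta_psi": dpsi, "fdr": fdr})
    th = Thresholds(ref_sample_size=10)
    sets = classify_events([ev], th, seed=0)
    where = ("activated" if ev.event_id in sets.activated else
             "repressed" if ev.event_id in sets.repressed else
             "reference" if ev.event_id in sets.reference else "neither")
    assert where == expected


def test_classification_is_a_partition(tested_cohort, thresholds_small):
    sets = classify_events(tested_cohort, thresholds_small, seed=3)
    a, r, ref = set(sets.activated), set(sets.repressed), set(sets.reference)
    assert not (a & r or a & ref or r & ref)
    # deterministic given seed
    again = classify_events(tested_cohort, thresholds_small, seed=3)
    assert again == sets


def test_small_reference_pool_uses_all(tested_cohort):
    th = Thresholds(ref_sample_size=100000)
    sets = classify_events(tested_cohort, th, seed=1)
    pool = [e.event_id for e in tested_cohort
            if not math.isnan(e.fdr) and e.fdr > th.ref_fdr_min
            and abs(e.delta_psi) < th.ref_dpsi_max]
    assert sorted(sets.reference) == sorted(pool)


def test_detection_of_planted_effects():
    """ΔPSI=0.4 at n=4 with sd≈0.03 noise is detected almost always."""
    cfg = SimConfig(seed=77, n_events=200, planted_effects=((0.5, 0.4),))
    events, truth = simulate_events(cfg)
    events = differential_test(events)
    true_reg = {i for i, t in truth["events"].items() if t["regulated"]}
    called = {e.event_id for e in events if e.fdr < 0.05}
    assert len(called & true_reg) / len(true_reg) >= 0.95
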