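import numpy as np
import pytest

from splicemap.kmers import (KmerResult, cluster_kmers, decode_kmer,
                             embedded_word_score, encode_kmers, kmer_table,
                             pfm_to_meme)
from splicemap.regions import MapLayout

from .test_maps import _region_set


def _rand_regions(n, rng, plant=None, plant_frac=0.0, seg="dn_intron_5p"):
    """Random-sequence region sets, optionally planting a word in dn intron."""
    layout = MapLayout()
    out = []
    for i in range(n):
        seqs = {}
        for lab in ("dn_intron_5p", "up_intron_3p"):
            L = layout.slot_len(lab)
            s = "".join(rng.choice(list("ACGT"), size=L))
            if plant and lab == seg and rng.random() < plant_frac:
                pos = int(rng.integers(0, L - len(plant)))
                s = s[:pos] + plant + s[pos + len(plant):]
            seqs[lab] = s
        out.append(_region_set(f"S{i}", seqs=seqs))
    return out


def test_encode_decode_round_trip():
    ids = encode_kmers("ACGTACGT", 8)
    assert len(ids) == 1 and decode_kmer(int(ids[0]), 8) == "ACGTACGT"
    # N-containing windows are skipped (N at index 4 kills starts 0..4)
    assert len(encode_kmers("ACGTNACGTACGTACG", 8)) == 4
    assert len(encode_kmers("ACG", 8)) == 0


def test_frequencies_sum_to_one():
    rng = np.random.default_rng(1)
    test = _rand_regions(10, rng)
    ref = _rand_regions(10, rng)
    tab = kmer_table(test, ref, n_perm=9, seed=0)
    assert sum(r.freq_test for r in tab.results) == pytest.approx(1.0)
    assert sum(r.freq_ref for r in tab.results) == pytest.approx(1.0)


def test_enrichment_ratio_of_frequencies():
    """With large counts the score approaches freq_test / freq_ref."""
    rng = np.random.default_rng(2)
    test = _rand_regions(40, rng, plant="GCATGCAT", plant_frac=1.0)
    ref = _rand_regions(40, rng)
    tab = kmer_table(test, ref, n_perm=9, seed=0)
    r = tab.by_kmer()["GCATGCAT"]
    expect = (r.count_test + 0.5) / (r.count_ref + 0.5) * \
        sum(x.count_ref for x in tab.results) / sum(x.count_test for x in tab.results)
    assert r.enrichment_score == pytest.approx(expect, rel=1e-9)
    assert r.enrichment_score > 5


def test_score_inverts_when_sets_swap():
    rng = np.random.default_rng(3)
    test = _rand_regions(8, rng)
    ref = _rand_regions(8, rng)
    t1 = kmer_table(test, ref, n_perm=9, seed=0).by_kmer()
    t2 = kmer_table(ref, test, n_perm=9, seed=0).by_kmer()
    for km in list(t1)[:200]:
        assert t1[km].enrichment_score == pytest.approx(
            1.0 / t2[km].enrichment_score)


def test_null_has_few_significant_kmers():
    rng = np.random.default_rng(4)
    test = _rand_regions(60, rng)
    ref = _rand_regions(120, rng)
    tab = kmer_table(test, ref, n_perm=300, seed=1)
    frac = np.mean([r.significant for r in tab.results])
    assert frac < 0.02


def test_planted_word_dominates_top_kmers():
    rng = np.random.default_rng(5)
    test = _rand_regions(150, rng, plant="GCATG", plant_frac=0.95)
    ref = _rand_regions(300, rng)
    tab = kmer_table(test, ref, n_perm=500, seed=1)
    sig = [r for r in tab.results if r.significant]
    assert sig, "planted word produced no significant 8-mers"
    assert all("GCATG" in r.kmer for r in tab.results[:3])
    # the highest-scoring significant k-mers all carry the planted core
    top_sig = sorted(sig, key=lambda r: -r.enrichment_score)[:5]
    assert all("GCATG" in r.kmer for r in top_sig)
    cl = cluster_kmers(sig)
    assert cl[0].consensus5 == "GCATG"


def test_embedded_word_pooling_matches_direct_count():
    rng = np.random.default_rng(6)
    test = _rand_regions(30, rng, plant="GCATG", plant_frac=0.9)
    ref = _rand_regions(60, rng)
    tab = kmer_table(test, ref, n_perm=99, seed=1)
    ew = embedded_word_score(tab, "GCATG")
    # independent oracle: every k-window containing the word, counted
    # directly on the raw sequences
    def direct(regions):
        c = t = 0
        for rs in regions:
            seq = rs.segment("dn_intron_5p").seq
            k = tab.k
            for i in range(len(seq) - k + 1):
                t += 1
                if "GCATG" in seq[i:i + k]:
                    c += 1
        return c, t
    ct, nt = direct(test)
    cr, nr = direct(ref)
    assert ew.count_test == ct and ew.count_ref == cr
    expect = ((ct + 0.5) / nt) / ((cr + 0.5) / nr)
    assert ew.enrichment_score == pytest.approx(expect)
    assert ew.pvalue <= 0.05


def test_embedded_word_absent_is_low_support():
    a = _region_set("A", seqs={"dn_intron_5p": "A" * 250})
    b = _region_set("B", seqs={"dn_intron_5p": "A" * 250})
    tab = kmer_table([a], [b], n_perm=9, seed=0)
    ew = embedded_word_score(tab, "GCATG")
    assert ew.low_support and ew.enrichment_score == pytest.approx(1.0)


def test_kmer_longer_than_segment_rejected():
    short = _region_set("A", seg_len={lab: 40 for lab in
                                      ("up_exon_3p", "up_intron_5p", "up_intron_3p",
                                       "cassette_5p", "cassette_3p", "dn_intron_5p",
                                       "dn_intron_3p", "dn_exon_5p")})
    with pytest.raises(ValueError):
        kmer_table([short], [short], k=50, n_perm=5, seed=0)


def test_cluster_of_shared_core():
    kmers = ["AGCATGCA", "GGCATGCC", "CGCATGAT", "TGCATGGA"]
    results = [KmerResult(km, 10, 1, .01, .001, 5.0 - 0.1 * i, 0.001, True)
               for i, km in enumerate(kmers)]
    (cl,) = cluster_kmers(results)
    assert set(cl.members) == set(kmers)
    assert cl.consensus5 == "GCATG"
    assert cl.seed_kmer == "AGCATGCA"


def test_two_planted_families_give_two_clusters():
    fam1 = ["CACCACAC", "ACACCACA", "CCACCACC", "ACACCACC"]
    fam2 = ["AGCATGCA", "GGCATGCC", "TGCATGGA"]
    results = [KmerResult(km, 10, 1, .01, .001, 3.0, 0.001, True)
               for km in fam1 + fam2]
    clusters = cluster_kmers(results)
    assert len(clusters) == 2
    consensi = {c.consensus5 for c in clusters}
    assert "GCATG" in consensi
    parts = [set(c.members) for c in clusters]
    assert set(fam2) in parts


def test_singleton_cluster():
    (cl,) = cluster_kmers([KmerResult("ACGTACGT", 5, 1, .1, .01, 4.0, .001, True)])
    assert cl.members == ("ACGTACGT",)
    assert len(cl.consensus5) == 5


def test_cluster_determinism_and_meme_export(tmp_path):
    kmers = ["AGCATGCA", "GGCATGCC", "CGCATGAT"]
    results = [KmerResult(km, 10, 1, .01, .001, 5.0, 0.001, True) for km in kmers]
    c1 = cluster_kmers(results)
    c2 = cluster_kmers(list(reversed(results)))
    assert [set(c.members) for c in c1] == [set(c.members) for c in c2]
    assert [c.consensus5 for c in c1] == [c.consensus5 for c in c2]
    out = tmp_path / "motifs.meme"
    pfm_to_meme(c1, out)
    text = out.read_text()
    assert "MEME version 4" in text and "letter-probability matrix" in text


def test_empty_cluster_input_rejected():
    with pytest.raises(ValueError):
        cluster_kmers([])
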