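"""k-mer enrichment, clustering of enriched k-mers and consensus extraction.

Enrichment compares k-mer (default 8-mer) window frequencies between a
regulated and a reference region set: score = ratio of frequencies with
a 0.5 pseudocount on both counts, significance by event-label
permutation.  Significant k-mers are aligned (best gapless offset,
overlap >= 5) and average-linkage clustered; each cluster yields a
position-frequency matrix and the IUPAC consensus of its
maximum-information 5-column window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .regions import RegionSet

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

#: IUPAC letter for each non-empty subset of bases (frozenset -> letter).
_IUPAC_OF_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W", frozenset("GT"): "K",
    frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class KmerResult:
    kmer: str
    count_test: int
    count_ref: int
    freq_test: float
    freq_ref: float
    enrichment_score: float
    pvalue: float
    significant: bool


@dataclass
class KmerTable:
    """Enrichment results plus the per-event window data needed to permute."""

    k: int
    results: list[KmerResult]
    n_permutations: int
    seed: int
    segment_filter: tuple[str, ...]
    # per-event encoded k-mer id arrays; first n_test belong to the test set
    _event_kmer_ids: list[np.ndarray] = field(repr=False, default_factory=list)
    _n_test: int = 0

    def by_kmer(self) -> dict[str, KmerResult]:
        return {r.kmer: r for r in self.results}


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """Base-4 ids of every k-window of ``seq``; N-containing windows skipped."""
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int64)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    vals = lut[codes]
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    ok = (win < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return (win[ok] * powers).sum(axis=1)


def decode_kmer(kid: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[kid % 4])
        kid //= 4
    return "".join(reversed(out))


def _event_ids(rs: RegionSet, k: int, segment_filter: tuple[str, ...]) -> np.ndarray:
    parts = [encode_kmers(rs.segment(lab).seq, k) for lab in segment_filter]
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def _group_counts(id_arrays: list[np.ndarray], k: int) -> tuple[np.ndarray, int]:
    if id_arrays:
        allids = np.concatenate(id_arrays) if len(id_arrays) > 1 else id_arrays[0]
    else:
        allids = np.empty(0, dtype=np.int64)
    counts = np.bincount(allids, minlength=4 ** k)
    return counts, int(allids.size)


def _scores(c_test: np.ndarray, n_test: int, c_ref: np.ndarray, n_ref: int,
            pseudo: float = 0.5) -> np.ndarray:
    ft = (c_test + pseudo) / max(n_test, 1)
    fr = (c_ref + pseudo) / max(n_ref, 1)
    return ft / fr


def kmer_table(test_regions: list[RegionSet], ref_regions: list[RegionSet],
               k: int = 8,
               segment_filter: tuple[str, ...] = ("dn_intron_5p",),
               n_perm: int = 1000, seed: int = 0,
               alpha: float = 0.01) -> KmerTable:
    """k-mer frequency enrichment of test vs reference region sets.

    ``segment_filter`` selects which map segments are counted (default:
    the proximal downstream-intron segment).  Frequencies are raw
    occurrence fractions; the enrichment score carries a 0.5
    pseudocount on both counts.  Empirical P per k-mer comes from
    ``n_perm`` permutations of event labels between the two sets.
    """
    for rs in test_regions + ref_regions:
        for lab in segment_filter:
            if len(rs.segment(lab)) < k:
                raise ValueError(
                    f"k={k} exceeds segment {lab} length for event {rs.event_id}")
    ids_test = [_event_ids(rs, k, segment_filter) for rs in test_regions]
    ids_ref = [_event_ids(rs, k, segment_filter) for rs in ref_regions]
    c_test, n_test = _group_counts(ids_test, k)
    c_ref, n_ref = _group_counts(ids_ref, k)
    obs = _scores(c_test, n_test, c_ref, n_ref)

    all_ids = ids_test + ids_ref
    n_t = len(ids_test)
    rng = np.random.default_rng(seed)
    ge = np.zeros(4 ** k, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(len(all_ids))
        t_arrays = [all_ids[i] for i in perm[:n_t]]
        r_arrays = [all_ids[i] for i in perm[n_t:]]
        ct, nt = _group_counts(t_arrays, k)
        cr, nr = _group_counts(r_arrays, k)
        ge += _scores(ct, nt, cr, nr) >= obs
    pvals = (1.0 + ge) / (n_perm + 1.0)

    seen = np.flatnonzero((c_test > 0) | (c_ref > 0))
    results = []
    for kid in seen:
        results.append(KmerResult(
            kmer=decode_kmer(int(kid), k),
            count_test=int(c_test[kid]), count_ref=int(c_ref[kid]),
            freq_test=c_test[kid] / max(n_test, 1),
            freq_ref=c_ref[kid] / max(n_ref, 1),
            enrichment_score=float(obs[kid]),
            pvalue=float(pvals[kid]),
            significant=bool(pvals[kid] < alpha)))
    results.sort(key=lambda r: (-r.enrichment_score, r.kmer))
    return KmerTable(k=k, results=results, n_permutations=n_perm, seed=seed,
                     segment_filter=tuple(segment_filter),
                     _event_kmer_ids=all_ids, _n_test=n_t)


@dataclass(frozen=True)
class EmbeddedWordScore:
    word: str
    count_test: int
    count_ref: int
    enrichment_score: float
    pvalue: float
    low_support: bool


def _containing_mask(word: str, k: int) -> np.ndarray:
    """Boolean over all 4^k ids: k-mer contains ``word`` as a substring."""
    mask = np.zeros(4 ** k, dtype=bool)
    w = len(word)
    wid = 0
    for c in word:
        wid = wid * 4 + _CODE[c]
    # enumerate all k-mers with the word at each offset
    for off in range(k - w + 1):
        left_digits = off
        right_digits = k - w - off
        base = wid * (4 ** right_digits)
        lefts = np.arange(4 ** left_digits, dtype=np.int64) * (4 ** (w + right_digits))
        rights = np.arange(4 ** right_digits, dtype=np.int64)
        mask[(lefts[:, None] + base + rights[None, :]).ravel()] = True
    return mask


def embedded_word_score(table: KmerTable, word: str) -> EmbeddedWordScore:
    """Pooled enrichment of a shorter word across all k-mers containing it.

    Counts of all k-mers containing ``word`` are pooled in each set and
    the ratio/permutation machinery of :func:`kmer_table` is reused at
    the pooled level (same seed, same permutation count).
    """
    if len(word) > table.k:
        raise ValueError("word longer than k")
    mask = _containing_mask(word, table.k)
    # per-event scalars: windows containing the word, total windows
    word_cnt = np.array([int(mask[ids].sum()) for ids in table._event_kmer_ids])
    totals = np.array([ids.size for ids in table._event_kmer_ids])
    n_t = table._n_test

    def ratio(sel: np.ndarray) -> float:
        ct_, nt_ = word_cnt[sel].sum(), totals[sel].sum()
        other = np.setdiff1d(np.arange(len(totals)), sel, assume_unique=True)
        cr_, nr_ = word_cnt[other].sum(), totals[other].sum()
        return ((ct_ + 0.5) / max(nt_, 1)) / ((cr_ + 0.5) / max(nr_, 1))

    ct = int(word_cnt[:n_t].sum())
    cr = int(word_cnt[n_t:].sum())
    obs = ratio(np.arange(n_t))
    rng = np.random.default_rng(table.seed)
    ge = 0
    n_all = len(table._event_kmer_ids)
    for _ in range(table.n_permutations):
        sel = rng.choice(n_all, size=n_t, replace=False)
        ge += ratio(np.sort(sel)) >= obs
    pval = (1.0 + ge) / (table.n_permutations + 1.0)
    return EmbeddedWordScore(word=word, count_test=ct, count_ref=cr,
                             enrichment_score=float(obs), pvalue=float(pval),
                             low_support=(ct + cr == 0))


@dataclass(frozen=True)
class MotifCluster:
    members: tuple[str, ...]
    offsets: tuple[int, ...]      # member position relative to the seed
    seed_kmer: str
    pfm: np.ndarray               # 4 x L, columns sum to 1 where covered
    consensus5: str


def _best_alignment(a: str, b: str, min_overlap: int = 5) -> tuple[int, int, int]:
    """(offset, matches, overlap) maximising matches, then match fraction.

    ``offset`` o means b[j] aligns a[j + o].
    """
    best = None
    for o in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        lo = max(0, o)
        hi = min(len(a), len(b) + o)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        matches = sum(a[j] == b[j - o] for j in range(lo, hi))
        key = (matches, matches / overlap, -abs(o), -o)
        if best is None or key > best[0]:
            best = (key, o, matches, overlap)
    if best is None:
        raise ValueError("no alignment with sufficient overlap")
    return best[1], best[2], best[3]


def _kmer_distance(a: str, b: str) -> float:
    _, matches, overlap = _best_alignment(a, b)
    return 1.0 - matches / overlap


def _information_content(col: np.ndarray) -> float:
    p = col[col > 0]
    return 2.0 + float((p * np.log2(p)).sum())


def _iupac_column(col: np.ndarray, min_freq: float = 0.25) -> str:
    chosen = {b for i, b in enumerate(_BASES) if col[i] >= min_freq}
    if not chosen:
        chosen = {_BASES[int(np.argmax(col))]}
    return _IUPAC_OF_SET[frozenset(chosen)]


def cluster_kmers(significant: list[KmerResult], cut_height: float = 0.4,
                  consensus_len: int = 5) -> list[MotifCluster]:
    """Align and hierarchically cluster enriched k-mers; extract consensi.

    Distance between two k-mers is 1 − matches/overlap at their best
    gapless offset (overlap >= 5); average linkage, tree cut at
    ``cut_height``.  Within a cluster, members align to the seed (the
    highest-scoring member, ties broken lexicographically) and build an
    enrichment-weighted PFM whose maximum-information ``consensus_len``
    window is rendered as IUPAC.
    """
    if not significant:
        raise ValueError("no significant k-mers to cluster")
    kmers = [r.kmer for r in significant]
    score = {r.kmer: r.enrichment_score for r in significant}
    if len(kmers) == 1:
        groups = {1: kmers}
    else:
        dm = np.array([[_kmer_distance(a, b) for b in kmers] for a in kmers])
        Z = linkage(squareform(dm, checks=False), method="average")
        labels = fcluster(Z, t=cut_height, criterion="distance")
        groups = {}
        for km, lab in zip(kmers, labels):
            groups.setdefault(int(lab), []).append(km)

    clusters = []
    for members in groups.values():
        seed = max(members, key=lambda m: (score[m], [-ord(c) for c in m]))
        offsets = {}
        for m in members:
            offsets[m] = 0 if m == seed else _best_alignment(seed, m)[0]
        lo = min(offsets.values())
        hi = max(offsets[m] + len(m) for m in members)
        L = hi - lo
        pfm = np.zeros((4, L))
        for m in members:
            w = score[m]
            for j, c in enumerate(m):
                pfm[_CODE[c], offsets[m] + j - lo] += w
        colsum = pfm.sum(axis=0)
        norm = np.where(colsum > 0, colsum, 1.0)
        pfm = pfm / norm
        ic = np.array([_information_content(pfm[:, j]) if colsum[j] > 0 else 0.0
                       for j in range(L)])
        best_start = 0
        if L >= consensus_len:
            sums = np.convolve(ic, np.ones(consensus_len), mode="valid")
            best_start = int(np.argmax(sums))
            window = range(best_start, best_start + consensus_len)
        else:
            window = range(L)
        consensus = "".join(_iupac_column(pfm[:, j]) for j in window)
        order = sorted(members, key=lambda m: (offsets[m], m))
        clusters.append(MotifCluster(
            members=tuple(order), offsets=tuple(offsets[m] for m in order),
            seed_kmer=seed, pfm=pfm, consensus5=consensus))
    clusters.sort(key=lambda c: -score[c.seed_kmer])
    return clusters


def pfm_to_meme(clusters: list[MotifCluster], path,
                background: tuple[float, float, float, float] = (0.25,) * 4) -> None:
    """Write cluster PFMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.3f} C {:.3f} G {:.3f} T {:.3f}\n\n".format(*background))
        for i, cl in enumerate(clusters, 1):
            L = cl.pfm.shape[1]
            fh.write(f"MOTIF cluster{i}_{cl.consensus5}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {L} "
                     f"nsites= {len(cl.members)} E= 0\n")
            for j in range(L):
                fh.write(" ".join(f"{cl.pfm[b, j]:.6f}" for b in range(4)) + "\n")
            fh.write("\n")
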