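"""Sliding-window RNA maps with permutation significance.

An RNA map asks, for every position of the composite axis around a
cassette exon, what fraction of events carry a motif within a short
window centred there, comparing a regulated (test) event set against a
non-regulated reference set.  Windows are clipped at segment boundaries
and never span an exon-intron junction.  Significance per position is
an empirical one-sided permutation P obtained by resampling test-sized
subsets from the pooled test+reference events.

The same machinery drives linked two-motif co-occurrence maps, where an
event contributes at a position only if a linked motif pair (gap
between the two hit intervals at most ``link_max_gap``) is anchored in
the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from .motifs import MotifHit, MotifSpec, coverage_mask, scan
from .regions import SEGMENT_LABELS, MapLayout, RegionSet


@dataclass(frozen=True)
class RnaMapProfile:
    """Per-position motif coverage of a test set vs a reference, with P-values."""

    motif_name: str
    set_name: str
    positions: np.ndarray
    coverage: np.ndarray          # test-set fraction per position
    coverage_ref: np.ndarray
    n_events: int
    n_contrib: np.ndarray         # test events contributing per position
    pvalues: np.ndarray
    significant: np.ndarray
    alpha: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class CooccurrenceProfile(RnaMapProfile):
    """Linked-pair co-occurrence map of two motifs."""

    motif_a: str = ""
    motif_b: str = ""
    link_max_gap: int = 25


def scan_regions(region_set: RegionSet, motif: MotifSpec) -> dict[str, list[MotifHit]]:
    """Scan every segment of an event; hits in segment-local coordinates."""
    return {seg.label: scan(seg.seq, motif, sequence_id=region_set.event_id)
            for seg in region_set.segments}


def _axis_place(layout: MapLayout, label: str, seg_len: int) -> tuple[int, int]:
    """Global-axis [start, end) covered by a (possibly truncated) segment."""
    slot = layout.slot_len(label)
    start = layout.slot_starts[label]
    if seg_len > slot:
        raise ValueError(f"segment {label} longer ({seg_len}) than slot ({slot})")
    if layout.anchor(label) == "5p":      # junction at the left: left-aligned
        return start, start + seg_len
    return start + slot - seg_len, start + slot


def event_window_presence(region_set: RegionSet, base_masks: dict[str, np.ndarray],
                          layout: MapLayout) -> tuple[np.ndarray, np.ndarray]:
    """(presence, contrib) vectors over the shared layout axis for one event.

    ``base_masks`` holds a boolean per-base vector per segment (covered
    bases, or anchor points for co-occurrence maps).  presence[p] is
    True when the window centred at p, clipped to the segment, contains
    a True base; contrib[p] marks axis positions the (possibly
    truncated) segment actually covers.
    """
    axis_len = layout.axis_len
    presence = np.zeros(axis_len, dtype=bool)
    contrib = np.zeros(axis_len, dtype=bool)
    half = layout.window_len // 2
    for seg in region_set.segments:
        mask = base_masks.get(seg.label)
        if mask is None:
            mask = np.zeros(len(seg), dtype=bool)
        if len(mask) != len(seg):
            raise ValueError(f"mask length mismatch for segment {seg.label}")
        if len(seg) == 0:
            continue
        # clipped-window any-hit == max filter with zero padding
        win = maximum_filter1d(mask.astype(np.uint8), size=2 * half + 1,
                               mode="constant", cval=0).astype(bool)
        a, b = _axis_place(layout, seg.label, len(seg))
        presence[a:b] = win
        contrib[a:b] = True
    return presence, contrib


def _matrices(region_sets: list[RegionSet], masks_by_event: dict[str, dict[str, np.ndarray]],
              layout: MapLayout) -> tuple[np.ndarray, np.ndarray]:
    pres, contr = [], []
    for rs in region_sets:
        p, c = event_window_presence(rs, masks_by_event[rs.event_id], layout)
        pres.append(p)
        contr.append(c)
    return np.array(pres, dtype=bool), np.array(contr, dtype=bool)


def _coverage(pres: np.ndarray, contr: np.ndarray) -> np.ndarray:
    num = pres.sum(axis=0).astype(float)
    den = contr.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1.0), np.nan)


def window_profile(region_sets: list[RegionSet],
                   hits_by_event: dict[str, dict[str, list[MotifHit]]],
                   layout: MapLayout) -> tuple[np.ndarray, np.ndarray]:
    """Coverage fraction per axis position and contributing-event counts."""
    if not region_sets:
        raise ValueError("empty event set")
    masks = {
        rs.event_id: {seg.label: coverage_mask(len(seg),
                                               hits_by_event[rs.event_id][seg.label])
                      for seg in rs.segments}
        for rs in region_sets}
    pres, contr = _matrices(region_sets, masks, layout)
    return _coverage(pres, contr), contr.sum(axis=0)


def _check_disjoint(test_sets: list[RegionSet], ref_sets: list[RegionSet]) -> None:
    test_ids = [rs.event_id for rs in test_sets]
    ref_ids = [rs.event_id for rs in ref_sets]
    if len(set(test_ids)) != len(test_ids) or len(set(ref_ids)) != len(ref_ids):
        raise ValueError("duplicate event ids within a set are rejected")
    if set(test_ids) & set(ref_ids):
        raise ValueError("test and reference sets share event ids")


def _permute(pres: np.ndarray, contr: np.ndarray, n_test: int, n_perm: int,
             alpha: float, seed: int) -> tuple[np.ndarray, ...]:
    """Observed coverages + empirical permutation P over pooled rows.

    Rows [0, n_test) are the test events.  Per permutation a random
    test-sized subset of the pool replays the test coverage; the
    empirical one-sided P per position is (1 + #{null >= observed}) /
    (n_perm + 1).
    """
    presf = pres.astype(np.float64)
    contrf = contr.astype(np.float64)
    cov_test = _coverage(pres[:n_test], contr[:n_test])
    cov_ref = _coverage(pres[n_test:], contr[n_test:])
    obs = np.where(np.isnan(cov_test), np.inf, cov_test)  # nan -> never beaten
    rng = np.random.default_rng(seed)
    n_pool = pres.shape[0]
    ge = np.zeros(pres.shape[1], dtype=np.int64)
    for _ in range(n_perm):
        idx = rng.choice(n_pool, size=n_test, replace=False)
        num = presf[idx].sum(axis=0)
        den = contrf[idx].sum(axis=0)
        null = np.where(den > 0, num / np.maximum(den, 1.0), -np.inf)
        ge += null >= obs
    pvals = (1.0 + ge) / (n_perm + 1.0)
    significant = (pvals <= alpha) & np.greater(
        np.nan_to_num(cov_test, nan=-1.0), np.nan_to_num(cov_ref, nan=np.inf))
    return cov_test, cov_ref, pvals, significant


def permutation_test(test_sets: list[RegionSet], ref_sets: list[RegionSet],
                     motif: MotifSpec, layout: MapLayout,
                     n_perm: int = 1000, alpha: float = 0.05,
                     seed: int = 0, set_name: str = "test") -> RnaMapProfile:
    """RNA map of ``motif`` for a test set vs a reference set."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if not test_sets or not ref_sets:
        raise ValueError("both event sets must be non-empty")
    _check_disjoint(test_sets, ref_sets)
    pooled = list(test_sets) + list(ref_sets)
    masks = {}
    for rs in pooled:
        hits = scan_regions(rs, motif)
        masks[rs.event_id] = {seg.label: coverage_mask(len(seg), hits[seg.label])
                              for seg in rs.segments}
    pres, contr = _matrices(pooled, masks, layout)
    cov_t, cov_r, pvals, sig = _permute(pres, contr, len(test_sets), n_perm,
                                        alpha, seed)
    return RnaMapProfile(
        motif_name=motif.name, set_name=set_name,
        positions=np.arange(layout.axis_len),
        coverage=cov_t, coverage_ref=cov_r, n_events=len(test_sets),
        n_contrib=contr[:len(test_sets)].sum(axis=0),
        pvalues=pvals, significant=sig, alpha=alpha,
        n_permutations=n_perm, seed=seed)


def linked_hits(hits_a: list[MotifHit], hits_b: list[MotifHit],
                link_max_gap: int = 25) -> list[tuple[int, MotifHit, MotifHit]]:
    """All (anchor, hit_a, hit_b) pairs whose interval gap is <= link_max_gap.

    The gap between two hit intervals is 0 when they overlap; the
    anchor is the start of the motif-A hit.
    """
    pairs = []
    for a in hits_a:
        for b in hits_b:
            gap = max(a.start - b.end, b.start - a.end, 0)
            if gap <= link_max_gap:
                pairs.append((a.start, a, b))
    pairs.sort(key=lambda t: (t[0], t[1].end, t[2].start))
    return pairs


def _anchor_masks(region_set: RegionSet, motif_a: MotifSpec, motif_b: MotifSpec,
                  link_max_gap: int) -> dict[str, np.ndarray]:
    hits_a = scan_regions(region_set, motif_a)
    hits_b = scan_regions(region_set, motif_b)
    masks = {}
    for seg in region_set.segments:
        mask = np.zeros(len(seg), dtype=bool)
        for anchor, _, _ in linked_hits(hits_a[seg.label], hits_b[seg.label],
                                        link_max_gap):
            mask[anchor] = True
        masks[seg.label] = mask
    return masks


def cooccurrence_profile(test_sets: list[RegionSet], ref_sets: list[RegionSet],
                         motif_a: MotifSpec, motif_b: MotifSpec,
                         layout: MapLayout, link_max_gap: int = 25,
                         n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
                         set_name: str = "test",
                         control_b: MotifSpec | None = None
                         ) -> tuple[CooccurrenceProfile, CooccurrenceProfile | None]:
    """Linked-pair co-occurrence map, optionally with a mutated-control rerun.

    When ``control_b`` is given the same events are rescanned with the
    control word in place of motif B (same seed and permutation
    settings), yielding the specificity contrast in one call.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if not test_sets or not ref_sets:
        raise ValueError("both event sets must be non-empty")
    _check_disjoint(test_sets, ref_sets)
    pooled = list(test_sets) + list(ref_sets)

    def run(mb: MotifSpec) -> CooccurrenceProfile:
        masks = {rs.event_id: _anchor_masks(rs, motif_a, mb, link_max_gap)
                 for rs in pooled}
        pres, contr = _matrices(pooled, masks, layout)
        cov_t, cov_r, pvals, sig = _permute(pres, contr, len(test_sets),
                                            n_perm, alpha, seed)
        return CooccurrenceProfile(
            motif_name=f"{motif_a.name}+{mb.name}", set_name=set_name,
            positions=np.arange(layout.axis_len),
            coverage=cov_t, coverage_ref=cov_r, n_events=len(test_sets),
            n_contrib=contr[:len(test_sets)].sum(axis=0),
            pvalues=pvals, significant=sig, alpha=alpha,
            n_permutations=n_perm, seed=seed,
            motif_a=motif_a.name, motif_b=mb.name, link_max_gap=link_max_gap)

    main = run(motif_b)
    control = run(control_b) if control_b is not None else None
    return main, control


def profile_to_frame(profile: RnaMapProfile, layout: MapLayout) -> pd.DataFrame:
    """Tidy per-position table of a profile for TSV export."""
    labels = np.empty(layout.axis_len, dtype=object)
    offsets = np.empty(layout.axis_len, dtype=int)
    for lab in SEGMENT_LABELS:
        a = layout.slot_starts[lab]
        b = a + layout.slot_len(lab)
        labels[a:b] = lab
        offsets[a:b] = np.arange(b - a)
    return pd.DataFrame({
        "position": profile.positions,
        "segment_label": labels,
        "offset": offsets,
        "coverage_test": profile.coverage,
        "coverage_ref": profile.coverage_ref,
        "pvalue": profile.pvalues,
        "significant": profile.significant,
    })


def plot_profile(profile: RnaMapProfile, layout: MapLayout, path) -> None:
    """Line plot of test vs reference coverage with significant stretches bolded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(11, 3))
    x = profile.positions
    ax.plot(x, 100 * profile.coverage_ref, color="grey", lw=0.8, label="reference")
    ax.plot(x, 100 * profile.coverage, color="tab:blue", lw=0.8,
            label=profile.set_name)
    sigy = np.where(profile.significant, 100 * profile.coverage, np.nan)
    ax.plot(x, sigy, color="tab:blue", lw=2.5)
    for lab in SEGMENT_LABELS[1:]:
        ax.axvline(layout.slot_starts[lab], color="k", lw=0.4, ls=":")
    ax.set_xlabel("composite position")
    ax.set_ylabel("% region covered")
    ax.set_title(profile.motif_name)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
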