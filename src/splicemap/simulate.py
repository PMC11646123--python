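"""Synthetic cassette-exon cohorts with truth labels.

Generates everything the pipeline consumes — an event table with
replicate PSIs and junction counts, a genome FASTA with motif words
planted at controlled positions, annotation, and gene sets with a
planted overlap — from a single seeded configuration, so every analysis
stage can be validated against known ground truth without any external
download.

The generative model: each event has a baseline inclusion level μ drawn
uniformly; regulated events shift to μ+Δ in condition 2.  Replicate
PSIs are Beta-distributed around the condition mean with a common
concentration (precision) parameter, and junction counts are binomial
at a configurable read depth, length-weighted so that the inclusion
ratio recovers the PSI in expectation.  Sequence background is i.i.d.
from a fixed base composition; motif words are written in transcript
sense at uniformly drawn offsets inside a chosen map segment (and
reverse-complemented into the plus-strand genome for minus-strand
events).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .events import SplicingEvent
from .motifs import IUPAC, MotifSpec
from .regions import MapLayout, reverse_complement, segment_intervals

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class MotifPlant:
    """One planted-motif scenario: word, segment, window and plant rates."""

    motif: MotifSpec
    segment_label: str
    position_range: tuple[int, int]     # inclusive start-offset window
    fraction_test: float
    fraction_ref: float = 0.0
    target: str = "activated"           # activated | repressed | regulated | all

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_test <= 1 and 0 <= self.fraction_ref <= 1):
            raise ValueError("plant fractions must lie in [0,1]")
        if self.position_range[0] < 0 or self.position_range[1] < self.position_range[0]:
            raise ValueError("invalid position range")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the default synthetic cohort.

    Defaults mirror the analysed experimental design: four replicates
    per condition, PSI noise with sd ≈ 0.03 at mid-range inclusion
    (concentration 250), regulated fractions asymmetric towards
    repression, and full-length map geometry with deliberate
    truncation cases from the shorter introns/exons.
    """

    seed: int
    n_events: int = 1000
    n_replicates: int = 4
    read_depth: int = 100
    psi_noise_concentration: float = 250.0
    planted_effects: tuple[tuple[float, float], ...] = ((0.10, 0.35), (0.17, -0.35))
    motif_plants: tuple[MotifPlant, ...] = ()
    background_base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    congruent_fraction: float = 0.75
    layout: MapLayout = field(default_factory=MapLayout)
    cassette_len_range: tuple[int, int] = (80, 400)
    intron_len_range: tuple[int, int] = (600, 3000)
    const_exon_len_range: tuple[int, int] = (150, 300)
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(f for f, _ in self.planted_effects)
        if total > 1.0:
            raise ValueError("planted-effect fractions exceed 1")
        for f, d in self.planted_effects:
            if not 0 <= f <= 1 or abs(d) > 1:
                raise ValueError("invalid planted effect")
        if abs(sum(self.background_base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if not 0 <= self.congruent_fraction <= 1:
            raise ValueError("congruent_fraction must lie in [0,1]")


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


PSI_CLAMP = (0.02, 0.98)


def simulate_events(config: SimConfig) -> tuple[list[SplicingEvent], dict]:
    """Event cohort with planted ΔPSI effects; returns (events, truth).

    Truth maps event_id to {regulated, direction, true_delta, mu1}.
    Junction-count form lengths are 2 (inclusion) and 1 (skipping),
    emulating the two-junction inclusion form of a cassette exon.
    """
    rng = _rng_for(config.seed, 1)
    n = config.n_events
    # geometry, laid left-to-right; transcript-upstream exon is the
    # genomically-right block on the minus strand
    gap = 200
    pos = 1000
    events: list[SplicingEvent] = []
    truth: dict = {"events": {}, "config_seed": config.seed}

    # assign planted effects to deterministic index blocks
    deltas = np.zeros(n)
    start = 0
    for frac, delta in config.planted_effects:
        cnt = int(round(frac * n))
        deltas[start:start + cnt] = delta
        start += cnt
    order = rng.permutation(n)   # scatter regulated events across the cohort
    deltas = deltas[order]

    c = config.psi_noise_concentration
    ifl, sfl = 2, 1
    for i in range(n):
        e1 = rng.integers(*config.const_exon_len_range, endpoint=True)
        i1 = rng.integers(*config.intron_len_range, endpoint=True)
        cas = rng.integers(*config.cassette_len_range, endpoint=True)
        i2 = rng.integers(*config.intron_len_range, endpoint=True)
        e2 = rng.integers(*config.const_exon_len_range, endpoint=True)
        strand = "+" if rng.random() < 0.5 else "-"
        b0 = (pos, pos + e1)
        b1e = b0[1] + i1
        cas_iv = (b1e, b1e + cas)
        b3e = cas_iv[1] + i2
        b4 = (b3e, b3e + e2)
        pos = b4[1] + gap

        delta = float(deltas[i])
        if delta == 0.0:
            mu1 = rng.uniform(0.15, 0.85)
        else:
            lo = max(0.05, 0.05 - delta)
            hi = min(0.95, 0.95 - delta)
            if lo >= hi:
                raise ValueError(f"infeasible planted delta {delta}")
            mu1 = rng.uniform(lo, hi)
        mu2 = mu1 + delta

        def draw_psis(mu: float) -> tuple[float, ...]:
            a, b = mu * c, (1 - mu) * c
            ps = rng.beta(a, b, size=config.n_replicates)
            return tuple(float(np.clip(p, *PSI_CLAMP)) for p in ps)

        psi1 = draw_psis(mu1)
        psi2 = draw_psis(mu2)

        def draw_counts(psis: tuple[float, ...]) -> tuple[tuple[int, ...], tuple[int, ...]]:
            inc, skip = [], []
            for p in psis:
                p_inc = p * ifl / (p * ifl + (1 - p) * sfl)
                ic = int(rng.binomial(config.read_depth, p_inc))
                inc.append(ic)
                skip.append(config.read_depth - ic)
            return tuple(inc), tuple(skip)

        inc1, skip1 = draw_counts(psi1)
        inc2, skip2 = draw_counts(psi2)

        eid = f"EV{i:05d}"
        if strand == "+":
            ue, de = b0, b4
        else:
            ue, de = b4, b0
        events.append(SplicingEvent(
            event_id=eid, gene_id=f"GENE{i:05d}", event_class="SE",
            chrom=config.chrom, strand=strand,
            cassette_start=cas_iv[0], cassette_end=cas_iv[1],
            upstream_exon_start=ue[0], upstream_exon_end=ue[1],
            downstream_exon_start=de[0], downstream_exon_end=de[1],
            inc_counts=(inc1, inc2), skip_counts=(skip1, skip2),
            inc_form_len=ifl, skip_form_len=sfl,
            psi1=psi1, psi2=psi2,
            delta_psi=float(np.mean(psi2) - np.mean(psi1))))
        truth["events"][eid] = {
            "regulated": delta != 0.0,
            "direction": "activated" if delta > 0 else
                         "repressed" if delta < 0 else "none",
            "true_delta": delta,
            "mu1": mu1,
        }
    return events, truth


def _realise_word(motif: MotifSpec, rng: np.random.Generator,
                  composition: tuple[float, ...]) -> str:
    """A concrete instance of the motif to write into the genome."""
    def concretise(word: str) -> str:
        return "".join(c if c in "ACGT" else rng.choice(list(IUPAC[c]))
                       for c in word)
    if motif.kind == "iupac_word":
        return concretise(motif.word)
    gap = int(rng.integers(motif.gap_min, motif.gap_max + 1))
    middle = "".join(np.char.decode(
        rng.choice(_BASES, size=gap, p=composition), "ascii")) if gap else ""
    return concretise(motif.left) + middle + concretise(motif.right)


def simulate_genome(config: SimConfig, events: list[SplicingEvent],
                    truth: dict) -> dict[str, str]:
    """Background genome with planted motif words; updates truth in place.

    Plant positions are recorded under truth["plants"] as
    {event_id: [{motif, segment_label, offset, length}, ...]} with
    offsets in transcript-sense segment coordinates.
    """
    rng = _rng_for(config.seed, 2)
    chrom_len = max(e.upstream_exon_end for e in events)
    chrom_len = max(chrom_len, max(e.downstream_exon_end for e in events)) + 1000
    comp = np.asarray(config.background_base_composition)
    seq = rng.choice(_BASES, size=chrom_len, p=comp).copy()

    plants: dict[str, list[dict]] = {}
    by_group: dict[str, list[SplicingEvent]] = {"activated": [], "repressed": [],
                                                "regulated": [], "reference": []}
    for e in events:
        d = truth["events"][e.event_id]["direction"]
        if d == "activated":
            by_group["activated"].append(e)
            by_group["regulated"].append(e)
        elif d == "repressed":
            by_group["repressed"].append(e)
            by_group["regulated"].append(e)
        else:
            by_group["reference"].append(e)

    for plant in config.motif_plants:
        groups = ([(plant.target, plant.fraction_test)] if plant.target != "all"
                  else [("regulated", plant.fraction_test)])
        groups.append(("reference", plant.fraction_ref))
        for gname, frac in groups:
            members = by_group[gname]
            cnt = int(round(frac * len(members)))
            if cnt == 0:
                continue
            chosen = rng.choice(len(members), size=cnt, replace=False)
            for j in chosen:
                e = members[int(j)]
                intervals = segment_intervals(e, config.layout)
                gs, ge = intervals[plant.segment_label]
                seg_len = ge - gs
                word = _realise_word(plant.motif, rng, tuple(comp))
                lo, hi = plant.position_range
                if hi + len(word) > seg_len:
                    raise ValueError(
                        f"plant range {plant.position_range} + word length "
                        f"{len(word)} exceeds segment {plant.segment_label} "
                        f"length {seg_len} (event {e.event_id})")
                off = int(rng.integers(lo, hi + 1))
                if e.strand == "+":
                    g0 = gs + off
                    seq[g0:g0 + len(word)] = np.frombuffer(
                        word.encode(), dtype="S1")
                else:
                    g0 = ge - off - len(word)
                    seq[g0:g0 + len(word)] = np.frombuffer(
                        reverse_complement(word).encode(), dtype="S1")
                plants.setdefault(e.event_id, []).append({
                    "motif": plant.motif.name,
                    "segment_label": plant.segment_label,
                    "offset": off,
                    "length": len(word),
                    "word": word,
                })
    truth["plants"] = plants
    return {config.chrom: seq.tobytes().decode("ascii")}


def simulate_gene_sets(n_universe: int, size_a: int, size_b: int,
                       overlap_k: int, seed: int, prefix: str = "G"
                       ) -> tuple[set[str], set[str], set[str]]:
    """Universe plus two gene sets with exactly ``overlap_k`` common members."""
    if overlap_k > min(size_a, size_b):
        raise ValueError("overlap exceeds set sizes")
    if size_a + size_b - overlap_k > n_universe:
        raise ValueError("sets do not fit in the universe")
    rng = _rng_for(seed, 3)
    genes = [f"{prefix}{i:05d}" for i in range(n_universe)]
    order = rng.permutation(n_universe)
    shared = [genes[i] for i in order[:overlap_k]]
    only_a = [genes[i] for i in order[overlap_k:size_a]]
    only_b = [genes[i] for i in order[size_a:size_a + size_b - overlap_k]]
    return set(genes), set(shared + only_a), set(shared + only_b)


def simulate_contrast_pairs(n: int, seed: int, dpsi_min: float = 0.15,
                            fdr_max: float = 0.05,
                            category_fractions: dict[int, float] | None = None
                            ) -> tuple[list, dict]:
    """ContrastPair cohort with planted co-regulation categories.

    Values are drawn with a safety margin around the thresholds so the
    planted category is unambiguous.  Category 0 denotes events
    regulated in neither contrast.  Returns (pairs, truth) where truth
    maps event_id -> category.
    """
    from .coreg import ContrastPair

    fracs = category_fractions or {1: .12, 2: .12, 3: .06, 4: .06,
                                   5: .15, 6: .15, 7: .07, 8: .07, 0: .20}
    rng = _rng_for(seed, 4)
    cats: list[int] = []
    for cat, f in sorted(fracs.items()):
        cats.extend([cat] * int(round(f * n)))
    while len(cats) < n:
        cats.append(0)
    cats = cats[:n]
    rng.shuffle(cats)

    def sig_dpsi(sign: int) -> float:
        return sign * rng.uniform(dpsi_min + 0.05, 0.6)

    def nonsig_dpsi() -> float:
        return rng.uniform(-1, 1) * max(dpsi_min - 0.07, 0.0)

    def sig_fdr() -> float:
        return rng.uniform(1e-5, fdr_max * 0.5)

    def nonsig_fdr() -> float:
        return rng.uniform(0.2, 0.95)

    pairs, truth = [], {}
    for i, cat in enumerate(cats):
        eid = f"CP{i:05d}"
        if cat in (1, 3, 5):
            oe = sig_dpsi(+1)
        elif cat in (2, 4, 6):
            oe = sig_dpsi(-1)
        else:
            oe = nonsig_dpsi()
        # effect_kd_factor = -dpsi_kd; positive effect => co-factor promotes inclusion
        if cat in (1, 4, 7):
            kd = -abs(sig_dpsi(+1))
        elif cat in (2, 3, 8):
            kd = abs(sig_dpsi(+1))
        else:
            kd = nonsig_dpsi()
        f_oe = sig_fdr() if cat in (1, 2, 3, 4, 5, 6) else nonsig_fdr()
        f_kd = sig_fdr() if cat in (1, 2, 3, 4, 7, 8) else nonsig_fdr()
        pairs.append(ContrastPair(event_id=eid, dpsi_oe=oe, fdr_oe=f_oe,
                                  dpsi_kd=kd, fdr_kd=f_kd))
        truth[eid] = cat
    return pairs, truth


def simulate_congruence_cohort(n: int, congruent_fraction: float, seed: int,
                               dpsi_min: float = 0.15) -> tuple[list[dict], dict]:
    """Events significant in both the factor and tissue contrasts.

    Exactly round(congruent_fraction * n) events have matching signs.
    Returns (records, truth) where each record carries the arguments of
    :func:`splicemap.coreg.classify_congruence` and truth maps
    event_id -> {"congruent": bool, "group": str}.
    """
    rng = _rng_for(seed, 5)
    n_cong = int(round(congruent_fraction * n))
    flags = np.array([True] * n_cong + [False] * (n - n_cong))
    rng.shuffle(flags)
    records, truth = [], {}
    for i, cong in enumerate(flags):
        eid = f"CG{i:05d}"
        oe_sign = 1 if rng.random() < 0.5 else -1
        dpsi_oe = oe_sign * rng.uniform(dpsi_min + 0.05, 0.55)
        t_sign = oe_sign if cong else -oe_sign
        tdelta = t_sign * rng.uniform(dpsi_min + 0.05, 0.45)
        psi_cell = rng.uniform(0.05, 0.95 - abs(tdelta)) if t_sign > 0 else \
            rng.uniform(0.05 + abs(tdelta), 0.95)
        psi_tissue = psi_cell + tdelta
        records.append({
            "event_id": eid, "dpsi_oe": float(dpsi_oe),
            "fdr_oe": float(rng.uniform(1e-5, 0.02)),
            "psi_tissue": float(psi_tissue), "psi_cell": float(psi_cell),
            "tissue_fdr": float(rng.uniform(1e-5, 0.02)),
        })
        if cong:
            group = "congruent-activated" if oe_sign > 0 else "congruent-repressed"
        else:
            group = "discordant-1" if oe_sign > 0 else "discordant-2"
        truth[eid] = {"congruent": bool(cong), "group": group}
    return records, truth


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_annotation(events: list[SplicingEvent], path) -> None:
    """BED-like TSV of the exon architecture of every event."""
    with open(path, "w") as fh:
        fh.write("event_id\tchrom\tstrand\tfeature\tstart\tend\n")
        for e in events:
            for feat, s, t in (
                    ("upstream_exon", e.upstream_exon_start, e.upstream_exon_end),
                    ("cassette", e.cassette_start, e.cassette_end),
                    ("downstream_exon", e.downstream_exon_start,
                     e.downstream_exon_end)):
                fh.write(f"{e.event_id}\t{e.chrom}\t{e.strand}\t{feat}\t{s}\t{t}\n")


#: a tandem-CAC element directly followed (10-nt spacer) by the RBFOX word,
#: for planting linked motif pairs in one write
LINKED_CAC_GCATG = MotifSpec(name="linked_CAC_GCATG", kind="iupac_word",
                             word="CACGCAC" + "N" * 10 + "GCATG")


def default_map_plants() -> tuple[MotifPlant, ...]:
    """The default planted-motif scenario of the synthetic study.

    Activated events carry a tandem-CAC element in the proximal
    downstream intron (90%, vs 5% background in reference events) plus,
    in a subset, a linked CAC/GCATG pair 10 nt apart for the
    co-occurrence map; repressed events carry the tandem-CAC element in
    the distal part of the upstream intron, mirroring position-dependent
    splicing-factor logic.
    """
    from .motifs import RBPMS_DIMER
    return (
        MotifPlant(RBPMS_DIMER, "dn_intron_5p", (20, 50), 0.9, 0.05, "activated"),
        MotifPlant(LINKED_CAC_GCATG, "dn_intron_5p", (80, 110), 0.6, 0.02,
                   "activated"),
        MotifPlant(RBPMS_DIMER, "up_intron_3p", (150, 220), 0.8, 0.05,
                   "repressed"),
    )


def simulate_all(config: SimConfig, outdir) -> dict[str, str]:
    """Emit the full synthetic input bundle to ``outdir``; returns paths.

    Files: events.tsv (rMATS dialect, statistics unfilled), genome.fa,
    annotation.tsv, gene-set lists and truth.json.
    """
    import os

    from .events import write_events

    os.makedirs(outdir, exist_ok=True)
    events, truth = simulate_events(config)
    genome = simulate_genome(config, events, truth)
    # genome-scale gene universe; set sizes follow the regulated-genes vs
    # super-enhancer-gene overlap structure of the tissue analysis
    universe, set_a, set_b = simulate_gene_sets(
        n_universe=20000, size_a=144, size_b=703, overlap_k=21,
        seed=config.seed)
    truth["gene_sets"] = {"n_universe": 20000, "size_a": 144, "size_b": 703,
                          "overlap_k": 21}
    paths = {
        "events": os.path.join(outdir, "events.tsv"),
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "universe": os.path.join(outdir, "genes_universe.txt"),
        "set_a": os.path.join(outdir, "genes_regulated.txt"),
        "set_b": os.path.join(outdir, "genes_superenhancer.txt"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_events(events, paths["events"])
    write_fasta(genome, paths["genome"])
    write_annotation(events, paths["annotation"])
    for key, gene_set in (("universe", universe), ("set_a", set_a),
                          ("set_b", set_b)):
        with open(paths[key], "w") as fh:
            fh.write("\n".join(sorted(gene_set)) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
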