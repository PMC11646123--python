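"""Stage orchestration: one config object, seeded stages, run manifests.

Each stage reads its inputs from the configured paths, writes its
artifacts atomically (tmp file + rename) under the output directory and
drops a JSON manifest recording the config hash, seeds, package version
and input checksums, so a rerun with identical configuration is
bit-for-bit reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .events import Thresholds, classify_events, differential_test, read_events, write_events
from .kmers import cluster_kmers, embedded_word_score, kmer_table
from .maps import cooccurrence_profile, permutation_test, profile_to_frame
from .motifs import RBFOX_WORD, RBPMS_DIMER, default_rbfox_control
from .regions import MapLayout, extract_regions
from .simulate import SimConfig, default_map_plants, simulate_all

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "maps", "cooccur", "kmers",
          "coreg", "congruence", "overlap")


@dataclass
class RunConfig:
    """Paths, thresholds, layout and seeds for a pipeline run."""

    outdir: str
    seed: int = 0
    events_path: str | None = None
    genome_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    layout: MapLayout = field(default_factory=MapLayout)
    n_permutations: int = 1000
    alpha: float = 0.05
    link_max_gap: int = 25
    n_sim_events: int = 1000
    kmer_segments: tuple[str, ...] = ("dn_intron_5p",)

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        """Build a RunConfig from a YAML key-value file.

        Nested ``thresholds:`` and ``layout:`` blocks map onto
        :class:`Thresholds` and :class:`MapLayout` fields.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        if "layout" in raw:
            raw["layout"] = MapLayout(**raw["layout"])
        if "kmer_segments" in raw:
            raw["kmer_segments"] = tuple(raw["kmer_segments"])
        return cls(**raw)


def _atomic_write_text(path: str, text: str) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(stage: str, config: RunConfig, inputs: list[str],
                    outputs: list[str], started: float) -> None:
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "inputs": {os.path.basename(p): _checksum(p) for p in inputs},
        "outputs": [os.path.basename(p) for p in outputs],
        "elapsed_s": round(time.time() - started, 2),
    }
    _atomic_write_text(config.path(f"manifest_{stage}.json"),
                       json.dumps(manifest, indent=1, sort_keys=True))


def _require(config: RunConfig, filename: str, producer: str) -> str:
    path = config.path(filename)
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"missing artifact {filename!r}; run the {producer!r} stage first")
    return path


def _load_regions(config: RunConfig, event_ids: set[str]):
    import pyfaidx

    events = read_events(_require(config, "events.tsv", "simulate"))
    genome = pyfaidx.Fasta(_require(config, "genome.fa", "simulate"))
    return [extract_regions(e, genome, config.layout)
            for e in events if e.event_id in event_ids]


def _load_sets(config: RunConfig) -> dict[str, list[str]]:
    with open(_require(config, "event_sets.json", "classify")) as fh:
        return json.load(fh)


def run_stage(name: str, config: RunConfig) -> list[str]:
    """Run one pipeline stage; returns the artifact paths it wrote."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    os.makedirs(config.outdir, exist_ok=True)
    started = time.time()
    logger.info("stage %s starting", name)
    outputs = _STAGE_FNS[name](config, started)
    logger.info("stage %s done in %.1fs", name, time.time() - started)
    return outputs


def _stage_simulate(config: RunConfig, started: float) -> list[str]:
    sim = SimConfig(seed=config.seed, n_events=config.n_sim_events,
                    motif_plants=default_map_plants())
    paths = simulate_all(sim, config.outdir)
    _write_manifest("simulate", config, [], list(paths.values()), started)
    return list(paths.values())


def _stage_classify(config: RunConfig, started: float) -> list[str]:
    in_path = config.events_path or _require(config, "events.tsv", "simulate")
    events = read_events(in_path)
    events = differential_test(events)
    sets = classify_events(events, config.thresholds, seed=config.seed)
    tested = config.path("events_tested.tsv")
    write_events(events, tested)
    out = config.path("event_sets.json")
    _atomic_write_text(out, json.dumps({
        "activated": list(sets.activated),
        "repressed": list(sets.repressed),
        "reference": list(sets.reference),
        "seed": sets.seed,
        "note": "delta_psi/fdr from the Welch-on-logit synthetic-path "
                "stand-in test, BH-adjusted",
    }, indent=1))
    _write_manifest("classify", config, [in_path], [tested, out], started)
    return [tested, out]


def _stage_maps(config: RunConfig, started: float) -> list[str]:
    sets = _load_sets(config)
    ref = _load_regions(config, set(sets["reference"]))
    outputs = []
    for set_name in ("activated", "repressed"):
        test = _load_regions(config, set(sets[set_name]))
        for motif in (RBPMS_DIMER, RBFOX_WORD):
            prof = permutation_test(test, ref, motif, config.layout,
                                    n_perm=config.n_permutations,
                                    alpha=config.alpha, seed=config.seed,
                                    set_name=set_name)
            out = config.path(f"map_{motif.name}_{set_name}.tsv")
            profile_to_frame(prof, config.layout).to_csv(out, sep="\t", index=False)
            outputs.append(out)
    _write_manifest("maps", config,
                    [config.path("events.tsv"), config.path("event_sets.json")],
                    outputs, started)
    return outputs


def _stage_cooccur(config: RunConfig, started: float) -> list[str]:
    sets = _load_sets(config)
    test = _load_regions(config, set(sets["activated"]))
    ref = _load_regions(config, set(sets["reference"]))
    prof, ctrl = cooccurrence_profile(
        test, ref, RBPMS_DIMER, RBFOX_WORD, config.layout,
        link_max_gap=config.link_max_gap, n_perm=config.n_permutations,
        alpha=config.alpha, seed=config.seed, set_name="activated",
        control_b=default_rbfox_control())
    outputs = []
    for tag, p in (("true", prof), ("control", ctrl)):
        out = config.path(f"cooccurrence_{tag}.tsv")
        profile_to_frame(p, config.layout).to_csv(out, sep="\t", index=False)
        outputs.append(out)
    _write_manifest("cooccur", config,
                    [config.path("events.tsv"), config.path("event_sets.json")],
                    outputs, started)
    return outputs


def _stage_kmers(config: RunConfig, started: float) -> list[str]:
    import pandas as pd

    sets = _load_sets(config)
    test = _load_regions(config, set(sets["activated"]))
    ref = _load_regions(config, set(sets["reference"]))
    table = kmer_table(test, ref, segment_filter=config.kmer_segments,
                       n_perm=config.n_permutations, seed=config.seed)
    tab_path = config.path("kmer_table.tsv")
    pd.DataFrame([dataclasses.asdict(r) for r in table.results]).to_csv(
        tab_path, sep="\t", index=False)
    sig = [r for r in table.results if r.significant]
    clusters_out = config.path("kmer_clusters.json")
    payload = {"clusters": [], "tunables": {"pseudocount": 0.5,
                                            "cut_height": 0.4,
                                            "pfm_weights": "enrichment_score"}}
    if sig:
        for cl in cluster_kmers(sig):
            payload["clusters"].append({
                "members": list(cl.members), "offsets": list(cl.offsets),
                "seed": cl.seed_kmer, "consensus5": cl.consensus5,
                "pfm": np.round(cl.pfm, 6).tolist()})
    gcatg = embedded_word_score(table, "GCATG")
    payload["embedded_GCATG"] = dataclasses.asdict(gcatg)
    _atomic_write_text(clusters_out, json.dumps(payload, indent=1))
    _write_manifest("kmers", config,
                    [config.path("events.tsv"), config.path("event_sets.json")],
                    [tab_path, clusters_out], started)
    return [tab_path, clusters_out]


def _stage_coreg(config: RunConfig, started: float) -> list[str]:
    from .coreg import classify_coregulation, coregulation_table
    from .simulate import simulate_contrast_pairs

    pairs, truth = simulate_contrast_pairs(config.n_sim_events, config.seed,
                                           dpsi_min=config.thresholds.dpsi_min,
                                           fdr_max=config.thresholds.fdr_max)
    calls = [classify_coregulation(p, config.thresholds) for p in pairs]
    out = config.path("coregulation_calls.tsv")
    df = coregulation_table(calls)
    df["truth_category"] = [truth[c.event_id] for c in calls]
    df.to_csv(out, sep="\t", index=False)
    _write_manifest("coreg", config, [], [out], started)
    return [out]


def _stage_congruence(config: RunConfig, started: float) -> list[str]:
    from .coreg import classify_congruence, congruent_fraction
    from .simulate import simulate_congruence_cohort

    records, truth = simulate_congruence_cohort(
        234, 0.75, config.seed, dpsi_min=config.thresholds.dpsi_min)
    calls = [classify_congruence(thresholds=config.thresholds, **r)
             for r in records]
    out = config.path("congruence_calls.tsv")
    with open(out, "w") as fh:
        fh.write("event_id\tgroup\ttruth_group\n")
        for c in calls:
            fh.write(f"{c.event_id}\t{c.group}\t{truth[c.event_id]['group']}\n")
    frac = congruent_fraction(calls)
    _atomic_write_text(config.path("congruence_summary.json"),
                       json.dumps({"n_events": len(calls),
                                   "congruent_fraction": frac}, indent=1))
    _write_manifest("congruence", config, [],
                    [out, config.path("congruence_summary.json")], started)
    return [out]


def _stage_overlap(config: RunConfig, started: float) -> list[str]:
    from .coreg import overlap_test, read_gene_list

    universe = read_gene_list(_require(config, "genes_universe.txt", "simulate"))
    set_a = read_gene_list(_require(config, "genes_regulated.txt", "simulate"))
    set_b = read_gene_list(_require(config, "genes_superenhancer.txt", "simulate"))
    res = overlap_test(universe, set_a, set_b)
    out = config.path("overlap_result.json")
    _atomic_write_text(out, json.dumps(dataclasses.asdict(res), indent=1))
    _write_manifest("overlap", config,
                    [config.path("genes_universe.txt")], [out], started)
    return [out]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "maps": _stage_maps,
    "cooccur": _stage_cooccur,
    "kmers": _stage_kmers,
    "coreg": _stage_coreg,
    "congruence": _stage_congruence,
    "overlap": _stage_overlap,
}
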