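"""Splicing-event data model, rMATS-dialect table I/O and event-set classification.

The table dialect follows rMATS ``SE.MATS.JC.txt`` column naming with
0-based half-open coordinates.  One deliberate convention of this
dialect: ``IncLevelDifference`` / ``delta_psi`` is mean(condition 2) −
mean(condition 1), so that a factor over-expression contrast (low →
high) gives positive ΔPSI for exons whose inclusion the factor
promotes.

Differential testing here is a documented stand-in for synthetic data:
a two-sided Welch t-test on logit-transformed PSIs (clamped to
[0.01, 0.99]) with Benjamini–Hochberg correction across events.  Tables
derived from real rMATS runs carry their own ΔPSI/FDR and are consumed
as-is.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("SE", "MXE", "A5SS", "A3SS", "RI")

#: rMATS SE.MATS.JC.txt column order used on read and write.
TABLE_COLUMNS = [
    "ID", "GeneID", "chr", "strand",
    "exonStart_0base", "exonEnd",
    "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen",
    "IncLevel1", "IncLevel2", "IncLevelDifference", "FDR",
]


class SpliceTableFormatError(ValueError):
    """A splicing table violates the expected rMATS-dialect format."""


@dataclass(frozen=True)
class SplicingEvent:
    """One alternative-splicing event with genomic geometry and statistics.

    Coordinates are 0-based half-open genomic intervals.  ``psi1``/``psi2``
    are per-replicate PSIs for condition 1 (e.g. control / factor-low)
    and condition 2 (e.g. factor-high); ``delta_psi`` is
    mean(psi2) − mean(psi1).
    """

    event_id: str
    gene_id: str
    event_class: str
    chrom: str
    strand: str
    cassette_start: int
    cassette_end: int
    upstream_exon_start: int
    upstream_exon_end: int
    downstream_exon_start: int
    downstream_exon_end: int
    inc_counts: tuple[tuple[int, ...], tuple[int, ...]] = ((), ())
    skip_counts: tuple[tuple[int, ...], tuple[int, ...]] = ((), ())
    inc_form_len: int = 1
    skip_form_len: int = 1
    psi1: tuple[float, ...] = ()
    psi2: tuple[float, ...] = ()
    delta_psi: float = math.nan
    fdr: float = math.nan

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cassette_start < self.cassette_end:
            raise ValueError("cassette interval must be non-empty")
        if self.strand == "+":
            ordered = (self.upstream_exon_end <= self.cassette_start
                       and self.cassette_end <= self.downstream_exon_start)
        else:
            ordered = (self.downstream_exon_end <= self.cassette_start
                       and self.cassette_end <= self.upstream_exon_start)
        if not ordered:
            raise ValueError(
                f"{self.event_id}: exons not ordered upstream < cassette < "
                f"downstream in transcript sense on strand {self.strand}")
        for cond in (0, 1):
            if len(self.inc_counts[cond]) != len(self.skip_counts[cond]):
                raise ValueError(f"{self.event_id}: count vector length mismatch")
        for psis in (self.psi1, self.psi2):
            for p in psis:
                if not math.isnan(p) and not 0.0 <= p <= 1.0:
                    raise ValueError(f"{self.event_id}: PSI {p} outside [0,1]")
        if not math.isnan(self.delta_psi) and not -1.0 <= self.delta_psi <= 1.0:
            raise ValueError(f"{self.event_id}: delta_psi outside [-1,1]")
        if not math.isnan(self.fdr) and not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.event_id}: FDR outside [0,1]")

    @property
    def cassette_length(self) -> int:
        return self.cassette_end - self.cassette_start


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs defining regulated and reference (non-regulated) event sets.

    Regulated: FDR < ``fdr_max`` and |ΔPSI| ≥ ``dpsi_min``.  The reference
    set is a seeded sample of ``ref_sample_size`` events from the
    non-regulated pool (FDR > ``ref_fdr_min`` and |ΔPSI| < ``ref_dpsi_max``).
    ``stringent_dpsi_min`` is the stricter cut used for downstream
    functional-impact analyses.
    """

    fdr_max: float = 0.05
    dpsi_min: float = 0.15
    stringent_dpsi_min: float = 0.30
    ref_fdr_min: float = 0.10
    ref_dpsi_max: float = 0.10
    ref_sample_size: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.dpsi_min <= self.stringent_dpsi_min <= 1:
            raise ValueError("require 0 < dpsi_min <= stringent_dpsi_min <= 1")
        if not self.ref_dpsi_max < self.dpsi_min:
            raise ValueError("ref_dpsi_max must be below dpsi_min")


@dataclass(frozen=True)
class EventSets:
    """Disjoint activated / repressed / reference event-id lists."""

    activated: tuple[str, ...]
    repressed: tuple[str, ...]
    reference: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        a, r, ref = set(self.activated), set(self.repressed), set(self.reference)
        if a & r or a & ref or r & ref:
            raise ValueError("event sets must be pairwise disjoint")


def psi_from_counts(inc: int, skip: int, inc_form_len: int, skip_form_len: int) -> float:
    """Length-normalised inclusion ratio; NaN when no informative reads.

    PSI = (inc/inc_form_len) / (inc/inc_form_len + skip/skip_form_len).
    """
    if inc < 0 or skip < 0:
        raise ValueError("junction counts must be non-negative")
    if inc_form_len < 1 or skip_form_len < 1:
        raise ValueError("effective form lengths must be >= 1")
    if inc + skip == 0:
        return math.nan
    i = inc / inc_form_len
    s = skip / skip_form_len
    return i / (i + s)


def _parse_count_vector(cell: object, column: str, line_no: int) -> tuple[int, ...]:
    text = "" if cell is None or (isinstance(cell, float) and math.isnan(cell)) else str(cell)
    try:
        return tuple(int(tok) for tok in text.split(",") if tok != "")
    except ValueError as exc:
        raise SpliceTableFormatError(
            f"line {line_no}: malformed count vector in {column}: {text!r}") from exc


def _parse_psi_vector(cell: object) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    return tuple(
        math.nan if tok in ("NA", "nan", "") else float(tok)
        for tok in str(cell).split(","))


def read_events(path, event_class: str = "SE") -> list[SplicingEvent]:
    """Read an rMATS-dialect TSV into :class:`SplicingEvent` records.

    PSIs are taken from the IncLevel columns when present, otherwise
    computed from junction counts via :func:`psi_from_counts`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in TABLE_COLUMNS:
        if col not in df.columns:
            raise SpliceTableFormatError(f"missing mandatory column {col!r}")
    events: list[SplicingEvent] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        rec = dict(zip(df.columns, row))
        inc1 = _parse_count_vector(rec["IJC_SAMPLE_1"], "IJC_SAMPLE_1", line_no)
        skip1 = _parse_count_vector(rec["SJC_SAMPLE_1"], "SJC_SAMPLE_1", line_no)
        inc2 = _parse_count_vector(rec["IJC_SAMPLE_2"], "IJC_SAMPLE_2", line_no)
        skip2 = _parse_count_vector(rec["SJC_SAMPLE_2"], "SJC_SAMPLE_2", line_no)
        ifl = int(rec["IncFormLen"])
        sfl = int(rec["SkipFormLen"])
        psi1 = _parse_psi_vector(rec["IncLevel1"])
        psi2 = _parse_psi_vector(rec["IncLevel2"])
        if not psi1:
            psi1 = tuple(psi_from_counts(i, s, ifl, sfl) for i, s in zip(inc1, skip1))
        if not psi2:
            psi2 = tuple(psi_from_counts(i, s, ifl, sfl) for i, s in zip(inc2, skip2))
        dpsi_cell = rec["IncLevelDifference"]
        fdr_cell = rec["FDR"]
        events.append(SplicingEvent(
            event_id=str(rec["ID"]),
            gene_id=str(rec["GeneID"]),
            event_class=event_class,
            chrom=str(rec["chr"]),
            strand=str(rec["strand"]),
            cassette_start=int(rec["exonStart_0base"]),
            cassette_end=int(rec["exonEnd"]),
            upstream_exon_start=int(rec["upstreamES"]),
            upstream_exon_end=int(rec["upstreamEE"]),
            downstream_exon_start=int(rec["downstreamES"]),
            downstream_exon_end=int(rec["downstreamEE"]),
            inc_counts=(inc1, inc2),
            skip_counts=(skip1, skip2),
            inc_form_len=ifl,
            skip_form_len=sfl,
            psi1=psi1,
            psi2=psi2,
            delta_psi=math.nan if dpsi_cell in (None, "NA") or pd.isna(dpsi_cell)
            else float(dpsi_cell),
            fdr=math.nan if fdr_cell in (None, "NA") or pd.isna(fdr_cell)
            else float(fdr_cell),
        ))
    return events


def _fmt_float(x: float) -> str:
    return "NA" if math.isnan(x) else repr(round(x, 10))


def write_events(events: list[SplicingEvent], path) -> None:
    """Write events back to the rMATS-dialect TSV (inverse of read_events)."""
    rows = []
    for e in events:
        rows.append({
            "ID": e.event_id,
            "GeneID": e.gene_id,
            "chr": e.chrom,
            "strand": e.strand,
            "exonStart_0base": e.cassette_start,
            "exonEnd": e.cassette_end,
            "upstreamES": e.upstream_exon_start,
            "upstreamEE": e.upstream_exon_end,
            "downstreamES": e.downstream_exon_start,
            "downstreamEE": e.downstream_exon_end,
            "IJC_SAMPLE_1": ",".join(map(str, e.inc_counts[0])),
            "SJC_SAMPLE_1": ",".join(map(str, e.skip_counts[0])),
            "IJC_SAMPLE_2": ",".join(map(str, e.inc_counts[1])),
            "SJC_SAMPLE_2": ",".join(map(str, e.skip_counts[1])),
            "IncFormLen": e.inc_form_len,
            "SkipFormLen": e.skip_form_len,
            "IncLevel1": ",".join(_fmt_float(p) for p in e.psi1),
            "IncLevel2": ",".join(_fmt_float(p) for p in e.psi2),
            "IncLevelDifference": _fmt_float(e.delta_psi),
            "FDR": _fmt_float(e.fdr),
        })
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def _logit(p: np.ndarray, clamp: float) -> np.ndarray:
    q = np.clip(p, clamp, 1.0 - clamp)
    return np.log(q / (1.0 - q))


def differential_test(events: list[SplicingEvent], clamp: float = 0.01) -> list[SplicingEvent]:
    """Fill ``delta_psi``/``fdr`` with a Welch-on-logit stand-in test.

    Two-sided Welch t-test on logit PSIs (boundary-clamped at
    ``clamp``), BH-adjusted across all testable events.  Events with
    fewer than two defined replicate PSIs in either condition are
    flagged untestable (fdr = 1) and excluded from the BH step.
    """
    testable_idx: list[int] = []
    pvals: list[float] = []
    out: list[SplicingEvent] = list(events)
    for i, e in enumerate(events):
        p1 = np.array([p for p in e.psi1 if not math.isnan(p)], dtype=float)
        p2 = np.array([p for p in e.psi2 if not math.isnan(p)], dtype=float)
        if len(p1) != len(e.psi1) or len(p2) != len(e.psi2):
            logger.info("event %s has undefined replicate PSI; excluded from testing",
                        e.event_id)
        if len(p1) < 2 or len(p2) < 2:
            out[i] = replace(e, delta_psi=(
                float(p2.mean() - p1.mean()) if len(p1) and len(p2) else math.nan),
                fdr=1.0)
            continue
        delta = float(p2.mean() - p1.mean())
        l1, l2 = _logit(p1, clamp), _logit(p2, clamp)
        if l1.std() == 0.0 and l2.std() == 0.0:
            pv = 1.0 if l1.mean() == l2.mean() else 0.0
        else:
            pv = float(stats.ttest_ind(l2, l1, equal_var=False).pvalue)
            if math.isnan(pv):
                pv = 1.0
        testable_idx.append(i)
        pvals.append(pv)
        out[i] = replace(e, delta_psi=delta)
    if testable_idx:
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
        for i, q in zip(testable_idx, fdrs):
            out[i] = replace(out[i], fdr=float(q))
    return out


def raw_pvalues(events: list[SplicingEvent], clamp: float = 0.01) -> dict[str, float]:
    """Unadjusted Welch-on-logit P per testable event (for calibration checks)."""
    res: dict[str, float] = {}
    for e in events:
        p1 = np.array([p for p in e.psi1 if not math.isnan(p)], dtype=float)
        p2 = np.array([p for p in e.psi2 if not math.isnan(p)], dtype=float)
        if len(p1) < 2 or len(p2) < 2:
            continue
        l1, l2 = _logit(p1, clamp), _logit(p2, clamp)
        if l1.std() == 0.0 and l2.std() == 0.0:
            res[e.event_id] = 1.0 if l1.mean() == l2.mean() else 0.0
        else:
            pv = float(stats.ttest_ind(l2, l1, equal_var=False).pvalue)
            res[e.event_id] = 1.0 if math.isnan(pv) else pv
    return res


def classify_events(events: list[SplicingEvent], thresholds: Thresholds,
                    seed: int) -> EventSets:
    """Partition events into activated / repressed / sampled reference sets.

    Deterministic given ``seed``; the reference pool is ordered by
    event id before sampling without replacement.
    """
    activated, repressed, pool = [], [], []
    for e in events:
        if math.isnan(e.delta_psi) or math.isnan(e.fdr):
            continue
        if e.fdr < thresholds.fdr_max and e.delta_psi >= thresholds.dpsi_min:
            activated.append(e.event_id)
        elif e.fdr < thresholds.fdr_max and e.delta_psi <= -thresholds.dpsi_min:
            repressed.append(e.event_id)
        elif (e.fdr > thresholds.ref_fdr_min
              and abs(e.delta_psi) < thresholds.ref_dpsi_max):
            pool.append(e.event_id)
    pool.sort()
    rng = np.random.default_rng(seed)
    if len(pool) <= thresholds.ref_sample_size:
        if len(pool) < thresholds.ref_sample_size:
            logger.warning("reference pool (%d) smaller than requested sample (%d); "
                           "using the whole pool", len(pool), thresholds.ref_sample_size)
        reference = tuple(pool)
    else:
        take = rng.choice(len(pool), size=thresholds.ref_sample_size, replace=False)
        reference = tuple(pool[i] for i in sorted(take))
    return EventSets(activated=tuple(activated), repressed=tuple(repressed),
                     reference=reference, seed=seed)
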