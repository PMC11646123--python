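"""Two-factor co-regulation categories, tissue congruence and overlap tests.

Events tested in both a factor over-expression contrast (ΔPSI_OE,
condition high vs low) and a co-factor knockdown contrast (ΔPSI_KD,
knockdown vs control) are classified into eight categories.  The
knockdown ΔPSI is sign-flipped (effect = −ΔPSI_KD) so that a positive
effect always means the co-factor promotes inclusion:

    1 coordinate-included    both significant, both promote inclusion
    2 coordinate-skipped     both significant, both promote skipping
    3 antagonistic (OE+)     both significant, opposite signs, OE positive
    4 antagonistic (OE−)     both significant, opposite signs, OE negative
    5/6 factor-only included/skipped    only the OE contrast significant
    7/8 co-factor-only included/skipped only the KD contrast significant

Congruence compares the factor's ΔPSI direction with a reference tissue
versus cultured-cell PSI difference; events with matching signs are the
congruent (tissue-like) groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln, logsumexp

from .events import Thresholds

logger = logging.getLogger(__name__)

CATEGORY_LABELS = {
    1: "coordinate-included",
    2: "coordinate-skipped",
    3: "antagonistic-oe-included",
    4: "antagonistic-oe-skipped",
    5: "factor-only-included",
    6: "factor-only-skipped",
    7: "cofactor-only-included",
    8: "cofactor-only-skipped",
}


@dataclass(frozen=True)
class ContrastPair:
    """Per-event statistics from the OE and KD contrasts."""

    event_id: str
    dpsi_oe: float
    fdr_oe: float
    dpsi_kd: float
    fdr_kd: float

    @property
    def effect_kd_factor(self) -> float:
        """Co-factor effect with promoting-inclusion as positive."""
        return -self.dpsi_kd


@dataclass(frozen=True)
class CoregulationCall:
    event_id: str
    category: int | None      # 1..8, None when regulated in neither contrast
    label: str | None


@dataclass(frozen=True)
class CongruenceCall:
    event_id: str
    group: str | None  # congruent-activated/-repressed, discordant-1/-2, None


@dataclass(frozen=True)
class OverlapResult:
    population_size: int
    successes_in_population: int
    draws: int
    observed_overlap: int
    p_upper: float


def classify_coregulation(pair: ContrastPair,
                          thresholds: Thresholds | None = None) -> CoregulationCall:
    """Assign one of the eight co-regulation categories (or uncalled)."""
    th = thresholds or Thresholds()
    sig_oe = pair.fdr_oe < th.fdr_max and abs(pair.dpsi_oe) >= th.dpsi_min
    sig_kd = pair.fdr_kd < th.fdr_max and abs(pair.dpsi_kd) >= th.dpsi_min
    eff = pair.effect_kd_factor
    if sig_oe and sig_kd:
        if (pair.dpsi_oe > 0) == (eff > 0):
            cat = 1 if pair.dpsi_oe > 0 else 2
        else:
            cat = 3 if pair.dpsi_oe > 0 else 4
    elif sig_oe:
        cat = 5 if pair.dpsi_oe > 0 else 6
    elif sig_kd:
        cat = 7 if eff > 0 else 8
    else:
        return CoregulationCall(pair.event_id, None, None)
    return CoregulationCall(pair.event_id, cat, CATEGORY_LABELS[cat])


def classify_congruence(event_id: str, dpsi_oe: float, fdr_oe: float,
                        psi_tissue: float, psi_cell: float, tissue_fdr: float,
                        thresholds: Thresholds | None = None) -> CongruenceCall:
    """Congruence of factor regulation with the tissue-vs-cell difference."""
    th = thresholds or Thresholds()
    tissue_delta = psi_tissue - psi_cell
    sig_oe = fdr_oe < th.fdr_max and abs(dpsi_oe) >= th.dpsi_min
    sig_tissue = tissue_fdr < th.fdr_max and abs(tissue_delta) >= th.dpsi_min
    if not (sig_oe and sig_tissue):
        return CongruenceCall(event_id, None)
    if dpsi_oe == 0.0 or tissue_delta == 0.0:
        logger.warning("event %s has an exact zero delta; left uncalled", event_id)
        return CongruenceCall(event_id, None)
    if dpsi_oe > 0 and tissue_delta > 0:
        return CongruenceCall(event_id, "congruent-activated")
    if dpsi_oe < 0 and tissue_delta < 0:
        return CongruenceCall(event_id, "congruent-repressed")
    if dpsi_oe > 0:
        return CongruenceCall(event_id, "discordant-1")
    return CongruenceCall(event_id, "discordant-2")


def congruent_fraction(calls: list[CongruenceCall]) -> float:
    """Fraction of called events in a congruent group."""
    called = [c for c in calls if c.group is not None]
    if not called:
        return math.nan
    n_cong = sum(c.group.startswith("congruent") for c in called)
    return n_cong / len(called)


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) of Hypergeometric(N, K, n), in log space."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k <= max(0, n + K - N):
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0

    def logC(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    xs = np.arange(k, hi + 1)
    logpmf = logC(K, xs) + logC(N - K, n - xs) - logC(N, n)
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def overlap_test(universe: set[str], set_a: set[str], set_b: set[str]) -> OverlapResult:
    """Hypergeometric upper-tail test of |A ∩ B| given an explicit universe.

    The universe must be supplied by the caller (events tested in both
    contrasts, or the annotated gene count for gene-set tests); it is
    never defaulted.
    """
    a = set_a & universe
    b = set_b & universe
    k = len(a & b)
    p = hypergeom_upper(len(universe), len(b), len(a), k)
    return OverlapResult(population_size=len(universe),
                         successes_in_population=len(b),
                         draws=len(a), observed_overlap=k, p_upper=p)


def psi_heatmap_matrix(psi: pd.DataFrame, condition_order: list[str],
                       n_clusters: int = 2
                       ) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Row-z-scored PSI matrix with average-linkage row clustering.

    ``psi`` is events x conditions; rows with zero variance z-score to
    all-zero.  Returns (z-matrix, scipy linkage, cluster labels).
    """
    missing = [c for c in condition_order if c not in psi.columns]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    mat = psi[condition_order].to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    Z = linkage(z, method="average", metric="euclidean")
    labels = pd.Series(fcluster(Z, t=n_clusters, criterion="maxclust"),
                       index=psi.index, name="cluster")
    zdf = pd.DataFrame(z, index=psi.index, columns=condition_order)
    return zdf, Z, labels


def coregulation_table(calls: list[CoregulationCall]) -> pd.DataFrame:
    """TSV-ready table of calls (uncalled events carry category 0)."""
    return pd.DataFrame({
        "event_id": [c.event_id for c in calls],
        "category_index": [c.category or 0 for c in calls],
        "category_label": [c.label or "uncalled" for c in calls],
    })


def read_gene_list(path) -> set[str]:
    """One-gene-per-line text file (dbSUPER-style gene lists)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
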