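"""Two-stage permutation framework for cohort-level rewiring statistics.

Stage one (*global null*): random sets of regulatory, non-disease-
associated SNPs, size-matched to the observed cohort's SNP count, are run
through the switch pipeline; the observed percentage of GO terms gained
(or lost) is compared to the null distribution by the z-score

    z = (rv - mean_null) / sd_null        (sd with ddof = 1)

with a two-sided normal p. Stage two (*patient-matched null*): random
cohorts are built by sampling, per patient, the same number of SNPs as the
patient actually carries; per-term proportions of patients gaining/losing
the term yield per-term z-scores, BH-corrected across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .formats import PatientGenotype
from .switches import SNPSwitchRecord

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000


@dataclass
class PermutationNull:
    """An observed statistic against its permutation null."""

    statistic_name: str
    rv: float
    null_mean: float
    null_sd: float
    z: float              # nan when sd == 0
    p: float              # two-sided normal tail
    n_perm: int
    empirical_p: float | None = None  # (r + 1) / (n_perm + 1)


@dataclass(frozen=True)
class RandomSNPSet:
    draw_index: int
    rsids: frozenset[str]


def draw_random_sets(
    pool: Sequence[str],
    size: int,
    n_perm: int,
    seed: int,
) -> list[RandomSNPSet]:
    """Draw ``n_perm`` sets of ``size`` SNP ids from the null pool, without
    replacement within a draw, independently across draws."""
    pool = sorted(set(pool))
    if len(pool) < size:
        raise ValueError(f"pool of {len(pool)} smaller than requested size {size}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        RandomSNPSet(i, frozenset(rng.choice(pool, size=size, replace=False)))
        for i in range(n_perm)
    ]


def global_null(
    observed_stat: float,
    null_values: Sequence[float],
    statistic_name: str = "statistic",
) -> PermutationNull:
    """Summarize an observed statistic against permutation null values.

    z uses the sample SD (ddof = 1); p = 2 * Phi(-|z|). A degenerate null
    (sd = 0) leaves z undefined and reports p = 1 when the observation
    equals the null mean, else p = 0, with a warning.
    """
    null_values = np.asarray(null_values, dtype=float)
    if len(null_values) < 2:
        raise ValueError("need at least 2 null values")
    mean = float(null_values.mean())
    sd = float(null_values.std(ddof=1))
    rank_ge = int(np.sum(np.abs(null_values - mean) >= abs(observed_stat - mean)))
    emp_p = (rank_ge + 1) / (len(null_values) + 1)
    if sd == 0:
        log.warning("degenerate null for %s (sd = 0)", statistic_name)
        z = float("nan")
        p = 1.0 if observed_stat == mean else 0.0
    else:
        z = (observed_stat - mean) / sd
        p = float(2.0 * norm.sf(abs(z)))
    return PermutationNull(
        statistic_name=statistic_name, rv=float(observed_stat),
        null_mean=mean, null_sd=sd, z=z, p=p,
        n_perm=len(null_values), empirical_p=emp_p,
    )


# ---------------------------------------------------------------------------
# statistics over SNP sets


def gain_loss_percentages(
    rsids: Sequence[str] | frozenset[str],
    per_snp: Mapping[str, SNPSwitchRecord],
    n_universe_terms: int,
) -> tuple[float, float]:
    """Percentage of universe GO terms gained (resp. lost) by a SNP set.

    Gained terms are distinct disease-side terms across the set's GO
    switches; lost terms the healthy-side mirror. The universe is the
    number of annotated terms in the corpus.
    """
    if n_universe_terms <= 0:
        raise ValueError("n_universe_terms must be positive")
    gained: set[str] = set()
    lost: set[str] = set()
    for rsid in rsids:
        rec = per_snp.get(rsid)
        if rec is None:
            continue
        for s in rec.go_switches:
            gained.add(s.disease_term)
            lost.add(s.healthy_term)
    return (100.0 * len(gained) / n_universe_terms,
            100.0 * len(lost) / n_universe_terms)


def run_null_pipeline(
    random_sets: Sequence[RandomSNPSet],
    per_snp: Mapping[str, SNPSwitchRecord],
    n_universe_terms: int,
) -> pd.DataFrame:
    """Per-draw gained/lost percentages for each random SNP set.

    Per-SNP switch calls do not depend on set membership, so each draw is
    pure set algebra over precomputed records (the pipeline from SNP set to
    percentages). A draw yielding no switches contributes 0% to both, with
    a warning.
    """
    rows = []
    for rset in random_sets:
        pg, pl = gain_loss_percentages(rset.rsids, per_snp, n_universe_terms)
        if pg == 0 and pl == 0:
            log.warning("draw %d produced no switches", rset.draw_index)
        rows.append((rset.draw_index, pg, pl))
    return pd.DataFrame(rows, columns=["draw", "pct_gained", "pct_lost"])


# ---------------------------------------------------------------------------
# patient-matched null


def _term_patient_proportions(
    active_sets: Sequence[frozenset[str]],
    per_snp: Mapping[str, SNPSwitchRecord],
) -> dict[tuple[str, str], float]:
    """Fraction of patients gaining (resp. losing) each term, given each
    patient's active SNP set."""
    n = len(active_sets)
    counts: dict[tuple[str, str], int] = {}
    for active in active_sets:
        gained: set[str] = set()
        lost: set[str] = set()
        for rsid in active:
            rec = per_snp.get(rsid)
            if rec is None:
                continue
            for s in rec.go_switches:
                gained.add(s.disease_term)
                lost.add(s.healthy_term)
        for t in gained:
            counts[(t, "gained")] = counts.get((t, "gained"), 0) + 1
        for t in lost:
            counts[(t, "lost")] = counts.get((t, "lost"), 0) + 1
    return {key: c / n for key, c in counts.items()}


def patient_matched_null(
    cohort: Sequence[PatientGenotype],
    pool: Sequence[str],
    per_snp: Mapping[str, SNPSwitchRecord],
    n_perm: int,
    seed: int,
    min_dosage: int = 1,
) -> pd.DataFrame:
    """Per-term patient-proportion z-scores against patient-matched random
    cohorts.

    Every permuted patient samples exactly as many pool SNPs as real
    active SNPs (patients with none contribute none). The per-SNP switch
    records passed here should come from the cascade *without* the
    redundancy-reduction stage. Output columns: term, direction, rv,
    null_mean, null_sd, z, p, adj_p (BH across all rows).
    """
    pool = sorted(set(pool))
    rng = np.random.default_rng(seed)
    observed_active = [
        frozenset(p.active_rsids(min_dosage)) for p in cohort
    ]
    sizes = [len(a) for a in observed_active]
    if max(sizes, default=0) > len(pool):
        raise ValueError("null pool smaller than a patient's active SNP count")
    observed = _term_patient_proportions(observed_active, per_snp)
    terms = sorted(observed)
    null_draws: dict[tuple[str, str], np.ndarray] = {
        key: np.zeros(n_perm) for key in terms
    }
    for i in range(n_perm):
        perm_active = [
            frozenset(rng.choice(pool, size=s, replace=False)) if s else frozenset()
            for s in sizes
        ]
        props = _term_patient_proportions(perm_active, per_snp)
        for key in terms:
            null_draws[key][i] = props.get(key, 0.0)
    rows = []
    for (term, direction) in terms:
        rv = observed[(term, direction)]
        nulls = null_draws[(term, direction)]
        mean = float(nulls.mean())
        sd = float(nulls.std(ddof=1))
        if sd == 0:
            z = float("nan")
            p = 1.0 if rv == mean else 0.0
        else:
            z = (rv - mean) / sd
            p = float(2.0 * norm.sf(abs(z)))
        rows.append((term, direction, rv, mean, sd, z, p))
    df = pd.DataFrame(rows, columns=["term", "direction", "rv", "null_mean",
                                     "null_sd", "z", "p"])
    if len(df):
        df["adj_p"] = multipletests(df.p, method="fdr_bh")[1]
    else:
        df["adj_p"] = []
    return df
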