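"""Allele-aware PWM scanning with an exact score-distribution null.

The scanner scores both alleles of a SNP against a TF's position weight
matrix on both strands and converts scores to p-values using the exact
distribution of the (discretized) score under the background model,
computed by dynamic programming: the score of a random w-mer is the sum of
w independent per-column scores, so its distribution is the convolution of
the w column distributions. On the discretization grid this is exact —
identical to enumerating all 4^w words.

Binding gain/loss at a SNP is called from hits that overlap the SNP
position: a TF is *gained* when it hits the risk-allele window but not the
non-risk window, *lost* in the mirror case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_PERM = np.array([3, 2, 1, 0])  # A<->T, C<->G row swap
UNIFORM_BG = np.full(4, 0.25)

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_GRID_STEP = 1e-3  # bits
DEFAULT_PVALUE_THRESHOLD = 1e-4

PERTURBATION_STATUSES = ("gained", "lost", "unchanged_bound", "unbound")


@dataclass(frozen=True)
class MotifModel:
    """A TF binding model: count matrix plus log-odds PWM against a background.

    ``pwm[b, j] = log2(p[b, j] / background[b])`` where ``p`` is the
    column-stochastic probability matrix derived from the counts with a
    background-proportional pseudocount.
    """

    tf_name: str
    counts: np.ndarray       # 4 x w
    pwm: np.ndarray          # 4 x w, log-odds in bits
    background: np.ndarray   # length 4, sums to 1

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))

    def reverse_complement(self) -> "MotifModel":
        """The same model read on the opposite strand.

        The background stays expressed in forward-strand coordinates, so the
        reverse-complement log-odds are built against the complemented
        background probabilities.
        """
        rc_counts = self.counts[COMPLEMENT_PERM][:, ::-1].copy()
        rc_bg = self.background[COMPLEMENT_PERM].copy()
        rc_pwm = self.pwm[COMPLEMENT_PERM][:, ::-1].copy()
        # re-express odds against the forward background
        rc_pwm = rc_pwm + np.log2(rc_bg / self.background)[:, None]
        return MotifModel(
            tf_name=self.tf_name, counts=rc_counts, pwm=rc_pwm,
            background=self.background,
        )


def build_pwm(
    tf_name: str,
    counts: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] | None = None,
) -> MotifModel:
    """Turn a 4×w count matrix into a log-odds PWM.

    ``p[b, j] = (counts[b, j] + pseudocount * background[b]) /
    (colsum_j + pseudocount)``; the pseudocount is split across bases in
    proportion to the background, a common JASPAR convention.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError(f"{tf_name}: counts must be 4 x w, got {counts.shape}")
    if np.any(counts < 0):
        raise ValueError(f"{tf_name}: negative counts")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
        raise ValueError("background must be positive probabilities summing to 1")
    colsums = counts.sum(axis=0)
    if pseudocount == 0 and np.any(colsums == 0):
        raise ValueError(f"{tf_name}: all-zero column with zero pseudocount")
    p = (counts + pseudocount * bg[:, None]) / (colsums + pseudocount)
    pwm = np.log2(p / bg[:, None])
    return MotifModel(tf_name=tf_name, counts=counts, pwm=pwm, background=bg.copy())


@dataclass
class ScoreNull:
    """Exact distribution of the discretized PWM score under the background.

    Scores are mapped to an integer grid (``round(score / grid_step)``
    per column) and the total-score distribution is the convolution of the
    per-column distributions. ``pvalue_of_score`` is the tail mass
    P(score >= s), non-increasing in s, and equal to 1 at the minimum
    attainable score.
    """

    grid_step: float
    int_pwm: np.ndarray          # 4 x w integer column scores
    min_total: int               # minimum attainable integer score
    sf: np.ndarray               # sf[i] = P(S >= min_total + i)

    @property
    def max_total(self) -> int:
        return self.min_total + len(self.sf) - 1

    def pvalue_of_int(self, total: int) -> float:
        if total <= self.min_total:
            return 1.0
        if total > self.max_total:
            return 0.0
        return float(self.sf[total - self.min_total])

    def pvalue_of_score(self, score: float) -> float:
        return self.pvalue_of_int(int(round(score / self.grid_step)))


def exact_score_null(motif: MotifModel, grid_step: float = DEFAULT_GRID_STEP) -> ScoreNull:
    """Compute the exact null score distribution by column-wise convolution."""
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    int_pwm = np.rint(motif.pwm / grid_step).astype(np.int64)
    bg = motif.background
    pmf = np.ones(1)
    lo = 0
    for j in range(motif.width):
        col = int_pwm[:, j]
        cmin, cmax = int(col.min()), int(col.max())
        # the column distribution has at most 4 support points, so the
        # convolution is 4 shifted adds rather than a dense convolve
        new = np.zeros(len(pmf) + cmax - cmin)
        for b in range(4):
            off = int(col[b]) - cmin
            new[off:off + len(pmf)] += bg[b] * pmf
        pmf = new
        lo += cmin
    # survival function: P(S >= s), accumulated from the top
    sf = np.cumsum(pmf[::-1])[::-1]
    return ScoreNull(grid_step=grid_step, int_pwm=int_pwm, min_total=lo, sf=sf)


@dataclass(frozen=True)
class BindingCall:
    """One motif hit overlapping a SNP on one allele's window."""

    rsid: str
    tf_name: str
    allele: str          # nonrisk | risk
    offset: int          # window start of the hit relative to the SNP
    strand: str          # + | -
    score: float         # discretized score, bits
    pvalue: float


def _encode(sequence: str) -> np.ndarray:
    """Map a DNA string to row indices; ambiguous bases become -1."""
    return np.array([BASE_INDEX.get(c, -1) for c in sequence.upper()], dtype=np.int64)


def _score_placements(int_pwm: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Integer score at every placement; ambiguous bases force -inf (min int)."""
    w = int_pwm.shape[1]
    n = len(encoded) - w + 1
    scores = np.empty(n, dtype=float)
    for i in range(n):
        window = encoded[i:i + w]
        if np.any(window < 0):
            scores[i] = -np.inf
        else:
            scores[i] = int_pwm[window, np.arange(w)].sum()
    return scores


def scan_window(
    motif: MotifModel,
    sequence: str,
    pvalue_threshold: float = DEFAULT_PVALUE_THRESHOLD,
    *,
    null: ScoreNull | None = None,
    rc_null: ScoreNull | None = None,
    snp_index: int | None = None,
    rsid: str = "",
    allele: str = "",
    grid_step: float = DEFAULT_GRID_STEP,
) -> list[BindingCall]:
    """Scan a window on both strands, returning placements with p <= threshold.

    The reverse strand is scored with the reverse-complement PWM against the
    same forward-strand coordinates (its own exact null). When ``snp_index``
    is given, only placements overlapping that position are reported and
    offsets are expressed relative to it; otherwise offsets are absolute.
    Ties at the threshold are kept (<=).
    """
    if not 0 < pvalue_threshold <= 1:
        raise ValueError("pvalue_threshold must be in (0, 1]")
    w = motif.width
    if len(sequence) < w:
        log.warning("sequence shorter than motif %s (w=%d); no hits", motif.tf_name, w)
        return []
    if null is None:
        null = exact_score_null(motif, grid_step)
    if rc_null is None:
        rc_null = exact_score_null(motif.reverse_complement(), null.grid_step)
    encoded = _encode(sequence)
    hits: list[BindingCall] = []
    for strand, strand_null in (("+", null), ("-", rc_null)):
        scores = _score_placements(strand_null.int_pwm, encoded)
        for start, s in enumerate(scores):
            if snp_index is not None and not (start <= snp_index <= start + w - 1):
                continue
            if not np.isfinite(s):
                continue
            p = strand_null.pvalue_of_int(int(s))
            if p <= pvalue_threshold:
                offset = start if snp_index is None else start - snp_index
                hits.append(BindingCall(
                    rsid=rsid, tf_name=motif.tf_name, allele=allele,
                    offset=offset, strand=strand,
                    score=float(s) * strand_null.grid_step, pvalue=p,
                ))
    return hits


@dataclass(frozen=True)
class PerturbationCall:
    """Per-(SNP, TF) binding change between the non-risk and risk alleles."""

    rsid: str
    tf_name: str
    status: str                      # gained | lost | unchanged_bound | unbound
    best_nonrisk_pvalue: float = 1.0
    best_risk_pvalue: float = 1.0

    def __post_init__(self) -> None:
        if self.status not in PERTURBATION_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def call_perturbation(
    motif: MotifModel,
    nonrisk_window: str,
    risk_window: str,
    pvalue_threshold: float = DEFAULT_PVALUE_THRESHOLD,
    *,
    rsid: str = "",
    null: ScoreNull | None = None,
    rc_null: ScoreNull | None = None,
) -> PerturbationCall:
    """Call binding gain/loss for one TF at one SNP.

    The two windows must be identical except at the SNP position; only hits
    whose placement covers the SNP count, so any gain/loss is attributable
    to the allele change by construction.
    """
    if len(nonrisk_window) != len(risk_window):
        raise ValueError(f"{rsid}: allele windows differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(nonrisk_window.upper(),
                                              risk_window.upper())) if a != b]
    if len(diffs) > 1:
        raise ValueError(
            f"{rsid}: windows differ at {len(diffs)} positions; not a bi-allelic SNP"
        )
    snp_index = diffs[0] if diffs else len(nonrisk_window) // 2
    kwargs = dict(null=null, rc_null=rc_null, snp_index=snp_index, rsid=rsid)
    nonrisk_hits = scan_window(motif, nonrisk_window, pvalue_threshold,
                               allele="nonrisk", **kwargs)
    risk_hits = scan_window(motif, risk_window, pvalue_threshold,
                            allele="risk", **kwargs)
    if nonrisk_hits and risk_hits:
        status = "unchanged_bound"
    elif risk_hits:
        status = "gained"
    elif nonrisk_hits:
        status = "lost"
    else:
        status = "unbound"
    best = lambda hits: min((h.pvalue for h in hits), default=1.0)
    return PerturbationCall(
        rsid=rsid, tf_name=motif.tf_name, status=status,
        best_nonrisk_pvalue=best(nonrisk_hits), best_risk_pvalue=best(risk_hits),
    )


def snp_window(sequence: str, snp_pos_in_seq: int, flank: int,
               allele: str) -> str:
    """Cut the SNP ± ``flank`` window from a sequence and substitute the allele."""
    lo, hi = snp_pos_in_seq - flank, snp_pos_in_seq + flank + 1
    if lo < 0 or hi > len(sequence):
        raise ValueError("window extends beyond the available sequence")
    chars = list(sequence[lo:hi].upper())
    chars[flank] = allele
    return "".join(chars)
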