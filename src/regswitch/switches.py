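"""TF switches and GO switches: the per-SNP set algebra of healthy-state vs
disease-state binding, plus the filter cascade that shortlists
disease-relevant switches.

A *TF switch* at a SNP contrasts the TFs predicted to bind the non-risk
(healthy-state) allele with those predicted to bind the risk
(disease-state) allele. A *GO switch* lifts this to biological processes:
each exclusive healthy-side term paired with each exclusive disease-side
term, the "incoming signal" rewired by the SNP. Terms present on both
sides are shared-state (grey) and never enter switch pairs.

The filter cascade runs in a fixed order: redundancy reduction (terms
mapped to representatives before pairing) → curated disease-term filter →
contrast filter (Relevance similarity < cutoff) → enrichment filter
(disease term over-represented among patient DEGs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .formats import PatientGenotype
from .motifs import PerturbationCall
from .ontology import OntologyGraph, relevance_similarity

log = logging.getLogger(__name__)

DEFAULT_CONTRAST_CUTOFF = 0.5
TERM_STATES = ("gained", "lost", "both", "shared")


@dataclass(frozen=True)
class TFSwitch:
    """Healthy-state vs disease-state TF sets at one SNP."""

    rsid: str
    healthy_tfs: frozenset[str]
    disease_tfs: frozenset[str]

    @property
    def gained(self) -> frozenset[str]:
        return self.disease_tfs - self.healthy_tfs

    @property
    def lost(self) -> frozenset[str]:
        return self.healthy_tfs - self.disease_tfs

    @property
    def shared(self) -> frozenset[str]:
        return self.healthy_tfs & self.disease_tfs


@dataclass(frozen=True)
class GOSwitch:
    """One healthy-term → disease-term incoming-signal switch at a SNP."""

    rsid: str
    healthy_term: str
    disease_term: str
    supporting_pairs: frozenset[tuple[str, str]]  # (lost TF, gained TF)
    similarity: float | None = None

    def __post_init__(self) -> None:
        if self.healthy_term == self.disease_term:
            raise ValueError(
                f"{self.rsid}: GO switch between a term and itself "
                f"({self.healthy_term})"
            )


@dataclass
class SNPSwitchRecord:
    """Everything derived from one SNP: TF switch, GO switches, shared terms."""

    rsid: str
    tf_switch: TFSwitch
    go_switches: list[GOSwitch] = field(default_factory=list)
    shared_terms: frozenset[str] = frozenset()


def tf_switch(rsid: str, calls: Iterable[PerturbationCall]) -> TFSwitch:
    """Derive the TF switch from this SNP's perturbation calls.

    Healthy-state TFs bind the non-risk allele (status lost or
    unchanged_bound); disease-state TFs bind the risk allele (gained or
    unchanged_bound). Conflicting duplicate calls for a TF are an error.
    """
    seen: dict[str, str] = {}
    for call in calls:
        if call.rsid != rsid:
            raise ValueError(f"call for {call.rsid} passed to tf_switch({rsid})")
        if call.tf_name in seen and seen[call.tf_name] != call.status:
            raise ValueError(
                f"{rsid}: conflicting statuses for {call.tf_name}: "
                f"{seen[call.tf_name]} vs {call.status}"
            )
        seen[call.tf_name] = call.status
    healthy = frozenset(t for t, s in seen.items() if s in ("lost", "unchanged_bound"))
    disease = frozenset(t for t, s in seen.items() if s in ("gained", "unchanged_bound"))
    return TFSwitch(rsid=rsid, healthy_tfs=healthy, disease_tfs=disease)


def go_switch_pairs(
    switch: TFSwitch,
    tf_annotations: Mapping[str, Iterable[str]],
    term_map: Mapping[str, str] | None = None,
) -> tuple[list[GOSwitch], frozenset[str]]:
    """Lift a TF switch to GO switches.

    H = union of terms of lost TFs, D = union of terms of gained TFs;
    terms of shared TFs and H∩D are shared-state and excluded from pairing.
    Switches are the full cross product of exclusive healthy terms with
    exclusive disease terms, each carrying its supporting (lost, gained) TF
    pairs. ``term_map`` (removed → representative, from redundancy
    reduction) is applied to every annotation term before pairing.
    """
    term_map = term_map or {}

    def terms_of(tf: str) -> set[str]:
        raw = tf_annotations.get(tf)
        if raw is None:
            log.warning("TF %s has no GO annotations; skipped", tf)
            return set()
        return {term_map.get(t, t) for t in raw}

    h_terms: dict[str, set[str]] = {tf: terms_of(tf) for tf in sorted(switch.lost)}
    d_terms: dict[str, set[str]] = {tf: terms_of(tf) for tf in sorted(switch.gained)}
    shared_tf_terms: set[str] = set()
    for tf in switch.shared:
        shared_tf_terms |= terms_of(tf)
    H = set().union(*h_terms.values()) if h_terms else set()
    D = set().union(*d_terms.values()) if d_terms else set()
    S = shared_tf_terms | (H & D)
    h_excl = H - D - S
    d_excl = D - H - S
    switches = []
    for h in sorted(h_excl):
        for d in sorted(d_excl):
            support = frozenset(
                (lt, gt)
                for lt, lset in h_terms.items() if h in lset
                for gt, gset in d_terms.items() if d in gset
            )
            switches.append(GOSwitch(
                rsid=switch.rsid, healthy_term=h, disease_term=d,
                supporting_pairs=support,
            ))
    return switches, frozenset(S)


# ---------------------------------------------------------------------------
# filter cascade


def filter_curated(
    switches: Sequence[GOSwitch],
    curated_terms: set[str],
    enabled: bool = True,
) -> list[GOSwitch]:
    """Keep switches with the healthy or the disease term on the curated
    disease-relevant list. Disabling this stage (sensitivity mode) is the
    identity."""
    if not enabled:
        return list(switches)
    if not curated_terms:
        raise ValueError("curated filter enabled but the curated term list is empty")
    return [
        s for s in switches
        if s.healthy_term in curated_terms or s.disease_term in curated_terms
    ]


def filter_contrast(
    switches: Sequence[GOSwitch],
    onto: OntologyGraph,
    cutoff: float = DEFAULT_CONTRAST_CUTOFF,
) -> list[GOSwitch]:
    """Attach Relevance similarity and keep only contrasting switches
    (similarity strictly below ``cutoff``). Switches whose terms are missing
    from the ontology are dropped with a warning."""
    kept = []
    for s in switches:
        if s.healthy_term not in onto or s.disease_term not in onto:
            log.warning("switch %s->%s: term missing from ontology; dropped",
                        s.healthy_term, s.disease_term)
            continue
        sim = relevance_similarity(onto, s.healthy_term, s.disease_term).score
        s = replace(s, similarity=sim)
        if sim < cutoff:
            kept.append(s)
    return kept


def filter_by_enrichment(
    switches: Sequence[GOSwitch],
    enriched_terms: set[str],
    side: str = "disease",
) -> list[GOSwitch]:
    """Keep switches whose disease term (default) is over-represented among
    the disease cohort's DEGs. ``side`` may be disease, healthy or either."""
    if side == "disease":
        keep = lambda s: s.disease_term in enriched_terms
    elif side == "healthy":
        keep = lambda s: s.healthy_term in enriched_terms
    elif side == "either":
        keep = lambda s: (s.disease_term in enriched_terms
                          or s.healthy_term in enriched_terms)
    else:
        raise ValueError(f"side must be disease, healthy or either: {side!r}")
    out = [s for s in switches if keep(s)]
    if switches and not out:
        log.warning("enrichment filter removed every switch")
    return out


def apply_filter_cascade(
    switches: Sequence[GOSwitch],
    onto: OntologyGraph,
    curated_terms: set[str] | None,
    enriched_terms: set[str] | None,
    contrast_cutoff: float = DEFAULT_CONTRAST_CUTOFF,
    curated_enabled: bool = True,
    enrichment_side: str = "disease",
) -> list[GOSwitch]:
    """Run curated → contrast → enrichment in the fixed stage order.

    (Redundancy reduction happens earlier, as a term map inside
    :func:`go_switch_pairs`.) Each stage shrinks its input; the cascade is
    idempotent.
    """
    out = filter_curated(switches, curated_terms or set(), enabled=curated_enabled)
    out = filter_contrast(out, onto, cutoff=contrast_cutoff)
    if enriched_terms is not None:
        out = filter_by_enrichment(out, enriched_terms, side=enrichment_side)
    return out


# ---------------------------------------------------------------------------
# patient profiles


@dataclass
class PatientSwitchProfile:
    """Per-patient switch state: the union of switches at the SNPs where the
    patient carries at least one risk allele."""

    patient_id: str
    disease: str
    active_rsids: frozenset[str]
    term_states: dict[str, str] = field(default_factory=dict)
    # (term, direction) -> rsids supporting it; direction in {gained, lost}
    term_support: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    tf_support: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    switches: list[GOSwitch] = field(default_factory=list)


def patient_profile(
    patient: PatientGenotype,
    per_snp: Mapping[str, SNPSwitchRecord],
    min_dosage: int = 1,
) -> PatientSwitchProfile:
    """Restrict the per-SNP switch tables to the patient's carried SNPs.

    Per-term state: gained if the term is a disease term at >= 1 active SNP
    and never a healthy term; lost in the mirror case; both if each occurs
    at some active SNP; shared if it only ever appears shared-state.
    """
    active = frozenset(r for r in patient.active_rsids(min_dosage) if r in per_snp)
    gained_at: dict[str, set[str]] = {}
    lost_at: dict[str, set[str]] = {}
    shared_only: set[str] = set()
    tf_gained_at: dict[str, set[str]] = {}
    tf_lost_at: dict[str, set[str]] = {}
    active_switches: list[GOSwitch] = []
    for rsid in sorted(active):
        rec = per_snp[rsid]
        for s in rec.go_switches:
            gained_at.setdefault(s.disease_term, set()).add(rsid)
            lost_at.setdefault(s.healthy_term, set()).add(rsid)
            active_switches.append(s)
        shared_only |= rec.shared_terms
        for tf in rec.tf_switch.gained:
            tf_gained_at.setdefault(tf, set()).add(rsid)
        for tf in rec.tf_switch.lost:
            tf_lost_at.setdefault(tf, set()).add(rsid)
    states: dict[str, str] = {}
    for term in set(gained_at) | set(lost_at):
        if term in gained_at and term in lost_at:
            states[term] = "both"
        elif term in gained_at:
            states[term] = "gained"
        else:
            states[term] = "lost"
    for term in shared_only - set(states):
        states[term] = "shared"
    support = {
        **{(t, "gained"): frozenset(r) for t, r in gained_at.items()},
        **{(t, "lost"): frozenset(r) for t, r in lost_at.items()},
    }
    tf_support = {
        **{(t, "gained"): frozenset(r) for t, r in tf_gained_at.items()},
        **{(t, "lost"): frozenset(r) for t, r in tf_lost_at.items()},
    }
    return PatientSwitchProfile(
        patient_id=patient.patient_id, disease=patient.disease,
        active_rsids=active, term_states=states,
        term_support=support, tf_support=tf_support,
        switches=active_switches,
    )
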