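"""Synthetic mini-study generator with planted ground truth.

Emulates every input of the real workflow — SNP windows (FASTA), TF
motifs (JASPAR PFM), patient genotypes (TSV dialect), regulatory regions
(BED), a GO ontology (OBO), TF→GO and gene→GO annotations, curated term
list, DEG tables, and a null SNP pool — small enough that every pipeline
stage can be checked against closed-form expectations.

Planting scheme per disease SNP: one TF's near-degenerate consensus ends
at the SNP with its last base equal to the non-risk allele (binding is
*lost* on the risk allele), and a second TF's consensus starts at the SNP
with its first base equal to the risk allele (binding is *gained*). The
two embeddings share only the SNP base. Filler sequence is redrawn until
a scan of both allele windows reproduces exactly the planted calls, so
the planted truth holds by construction at the default p-value threshold.

Expected per-stage record counts (`fixture_expected_counts`) are computed
from the planted maps with a self-contained re-implementation of the set
algebra, similarity and reduction rules, independent of the pipeline
modules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from math import log as _ln
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom as _hypergeom

from . import motifs as me

log = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale cohort: 20 disease SNPs (16 of them
    cluster-specific, 4 carried cohort-wide), 10 TFs with widths 7-10,
    40 patients split over UC and CD in 4 planted clusters, a 3-level
    31-term ontology with one cross-link, and a 150-SNP null pool of
    which ~60% perturb some motif.
    """

    seed: int = 0
    n_tfs: int = 10
    motif_width_range: tuple[int, int] = (7, 10)
    n_clusters: int = 4
    snps_per_cluster: int = 4
    n_shared_snps: int = 4
    n_pool: int = 150
    pool_active_frac: float = 0.6
    n_patients_uc: int = 20
    n_patients_cd: int = 20
    noise_rate: float = 0.0
    terms_per_tf: int = 2
    n_branches: int = 5
    leaves_per_branch: int = 5
    curated_fraction: float = 0.7
    enriched_fraction: float = 0.6
    genes_per_term: int = 6
    n_extra_genes: int = 10
    pvalue_threshold: float = me.DEFAULT_PVALUE_THRESHOLD
    max_rejection_tries: int = 25

    @property
    def n_snps(self) -> int:
        return self.n_clusters * self.snps_per_cluster + self.n_shared_snps

    def validate(self) -> None:
        if self.motif_width_range[0] < 7:
            raise ValueError(
                "motif width must be >= 7: narrower consensus words cannot "
                "reach the default 1e-4 p-value threshold under a uniform "
                "background"
            )
        if self.n_tfs < 2:
            raise ValueError("need at least 2 TFs to plant a switch")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if self.terms_per_tf * self.n_tfs > 4 * self.n_branches * self.leaves_per_branch:
            raise ValueError("ontology too small for the requested annotations")


@dataclass
class GroundTruth:
    """Everything planted, plus independently computed expectations."""

    spec: FixtureSpec
    snp_planted: dict[str, tuple[str, str]]          # rsid -> (lost_tf, gained_tf)
    pool_planted: dict[str, tuple[str, str] | None]  # rsid -> pair or None (neutral)
    patient_clusters: dict[str, int]
    patient_disease: dict[str, str]
    tf_terms: dict[str, frozenset[str]]
    gene_terms: dict[str, frozenset[str]]
    term_parents: dict[str, frozenset[str]]
    curated_terms: frozenset[str]
    enriched_terms: frozenset[str]                   # planted + verified by ORA math
    reduction_map: dict[str, str]
    expected_switches: dict[str, list[tuple[str, str]]]  # rsid -> post-filter pairs
    expected_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# independent oracle helpers (no imports from the pipeline's ontology module)


def _bf_ancestors(term: str, parents: dict[str, frozenset[str]]) -> frozenset[str]:
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents.get(t, ()):  # noqa: B023 - simple closure
            if p not in out:
                out.add(p)
                frontier.append(p)
    return frozenset(out)


def _bf_ic_table(
    gene_terms: dict[str, frozenset[str]],
    parents: dict[str, frozenset[str]],
) -> tuple[dict[str, float], dict[str, float]]:
    """(IC, p) per term from a gene→terms corpus with true-path propagation."""
    genes_at: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        for t in terms:
            for anc in _bf_ancestors(t, parents):
                genes_at.setdefault(anc, set()).add(gene)
    total = len(gene_terms)
    p = {t: len(g) / total for t, g in genes_at.items()}
    ic = {t: -_ln(v) for t, v in p.items()}
    return ic, p


def _bf_sim(
    a: str, b: str,
    parents: dict[str, frozenset[str]],
    ic: dict[str, float], p: dict[str, float],
) -> float:
    common = [
        t for t in _bf_ancestors(a, parents) & _bf_ancestors(b, parents)
        if t in ic
    ]
    if not common:
        return 0.0
    mica = max(common, key=lambda t: (ic[t], t))
    denom = ic[a] + ic[b]
    if denom == 0:
        return 0.0
    return (2.0 * ic[mica] / denom) * (1.0 - p[mica])


def _bf_reduce(
    terms: list[str],
    parents: dict[str, frozenset[str]],
    ic: dict[str, float], p: dict[str, float],
    cutoff: float = 0.5,
) -> dict[str, str]:
    """Greedy highest-pair-first reduction; returns removed -> representative."""
    alive = sorted(set(terms))
    sims = {(a, b): _bf_sim(a, b, parents, ic, p)
            for i, a in enumerate(alive) for b in alive[i + 1:]}
    removed: dict[str, str] = {}
    alive = set(alive)
    while True:
        cands = [(s, a, b) for (a, b), s in sims.items()
                 if s >= cutoff and a in alive and b in alive]
        if not cands:
            break
        s, a, b = max(cands, key=lambda c: (c[0], c[1], c[2]))
        if ic[a] > ic[b]:
            keep, drop = a, b
        elif ic[b] > ic[a]:
            keep, drop = b, a
        else:
            keep, drop = min(a, b), max(a, b)
        alive.discard(drop)
        removed[drop] = keep
    def resolve(t):
        while t in removed:
            t = removed[t]
        return t
    return {t: resolve(r) for t, r in removed.items()}


def fixture_expected_counts(gt: GroundTruth) -> dict[str, int]:
    """Closed-form per-stage record counts from the planted maps alone."""
    ic, p = _bf_ic_table({tf: ts for tf, ts in gt.tf_terms.items()}, gt.term_parents)
    red = gt.reduction_map
    n_raw = n_cur = n_con = n_enr = 0
    final: dict[str, list[tuple[str, str]]] = {}
    for rsid, (lost_tf, gained_tf) in sorted(gt.snp_planted.items()):
        H = {red.get(t, t) for t in gt.tf_terms[lost_tf]}
        D = {red.get(t, t) for t in gt.tf_terms[gained_tf]}
        S = H & D
        pairs = [(h, d) for h in sorted(H - D - S) for d in sorted(D - H - S)]
        n_raw += len(pairs)
        pairs = [(h, d) for (h, d) in pairs
                 if h in gt.curated_terms or d in gt.curated_terms]
        n_cur += len(pairs)
        pairs = [(h, d) for (h, d) in pairs
                 if _bf_sim(h, d, gt.term_parents, ic, p) < 0.5]
        n_con += len(pairs)
        pairs = [(h, d) for (h, d) in pairs if d in gt.enriched_terms]
        n_enr += len(pairs)
        final[rsid] = pairs
    return {
        "n_tf_switch_records": len(gt.snp_planted),
        "n_go_switches_raw": n_raw,
        "n_after_curated": n_cur,
        "n_after_contrast": n_con,
        "n_after_enrichment": n_enr,
    }


# ---------------------------------------------------------------------------
# generation


def _random_motif(rng: np.random.Generator, width: int) -> np.ndarray:
    """Near-degenerate count matrix: dominant base 97 counts, others 1."""
    counts = np.ones((4, width))
    for j in range(width):
        counts[rng.integers(0, 4), j] = 97
    return counts


def _consensus(counts: np.ndarray) -> str:
    return "".join(_BASES[i] for i in counts.argmax(axis=0))


def _write_jaspar(path: Path, motifs: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for i, (name, counts) in enumerate(sorted(motifs.items()), 1):
            fh.write(f">MA{i:04d}.1 {name}\n")
            for b, row in zip(_BASES, counts):
                cells = " ".join(f"{int(v):6d}" for v in row)
                fh.write(f"{b}  [ {cells} ]\n")


def _write_obo(path: Path, names: dict[str, str],
               parents: dict[str, frozenset[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n\n")
        for term in sorted(names):
            fh.write(f"[Term]\nid: {term}\nname: {names[term]}\n")
            fh.write("namespace: biological_process\n")
            for parent in sorted(parents.get(term, ())):
                fh.write(f"is_a: {parent} ! {names[parent]}\n")
            fh.write("\n")


def _build_ontology(spec: FixtureSpec) -> tuple[dict[str, str],
                                                dict[str, frozenset[str]],
                                                list[str]]:
    """3-level tree (root, branches, leaves) plus one cross-link."""
    counter = 1

    def next_id() -> str:
        nonlocal counter
        t = f"GO:{counter:07d}"
        counter += 1
        return t

    root = next_id()
    names = {root: "biological_process"}
    parents: dict[str, frozenset[str]] = {}
    branches, leaves = [], []
    for b in range(spec.n_branches):
        mid = next_id()
        names[mid] = f"branch process {b + 1}"
        parents[mid] = frozenset({root})
        branches.append(mid)
    for b, mid in enumerate(branches):
        for l in range(spec.leaves_per_branch):
            leaf = next_id()
            names[leaf] = f"leaf process {b + 1}.{l + 1}"
            parents[leaf] = frozenset({mid})
            leaves.append(leaf)
    # one cross-link: first leaf of branch 2 is also a child of branch 1
    if len(branches) >= 2:
        cross = leaves[spec.leaves_per_branch]
        parents[cross] = parents[cross] | {branches[0]}
    return names, parents, leaves


def _plant_window(
    rng: np.random.Generator,
    lost_model: me.MotifModel,
    gained_model: me.MotifModel,
    all_models: dict[str, me.MotifModel],
    nulls: dict[str, tuple[me.ScoreNull, me.ScoreNull]],
    wmax: int,
    threshold: float,
    max_tries: int,
) -> tuple[str, str, str, str]:
    """Build (nonrisk_window, risk_window, nonrisk, risk) realizing exactly
    one lost and one gained call, rejecting windows with stray hits."""
    cons_a, cons_b = lost_model.consensus, gained_model.consensus
    nonrisk, risk = cons_a[-1], cons_b[0]
    if nonrisk == risk:
        raise ValueError("planted consensus bases collide at the SNP")
    center = wmax - 1
    length = 2 * wmax - 1
    for _ in range(max_tries):
        seq = [
            _BASES[i] for i in rng.integers(0, 4, size=length)
        ]
        # lost motif ends at the SNP; gained motif starts at it
        wa, wb = lost_model.width, gained_model.width
        seq[center - wa + 1:center] = list(cons_a[:-1])
        seq[center + 1:center + wb] = list(cons_b[1:])
        base = "".join(seq)
        nonrisk_win = base[:center] + nonrisk + base[center + 1:]
        risk_win = base[:center] + risk + base[center + 1:]
        ok = True
        # planted TFs first: a deterministically conflicting pair (e.g. one
        # consensus re-created by the other's embedding) fails immediately
        ordered = [lost_model.tf_name, gained_model.tf_name] + [
            t for t in all_models if t not in (lost_model.tf_name,
                                               gained_model.tf_name)
        ]
        for tf in ordered:
            model = all_models[tf]
            null, rc_null = nulls[tf]
            call = me.call_perturbation(
                model, nonrisk_win, risk_win, threshold,
                rsid="fixture", null=null, rc_null=rc_null,
            )
            want = ("lost" if tf == lost_model.tf_name
                    else "gained" if tf == gained_model.tf_name
                    else "unbound")
            if call.status != want:
                ok = False
                break
        if ok:
            return nonrisk_win, risk_win, nonrisk, risk
    raise RuntimeError("could not realize planted window within retry budget")


def _neutral_window(
    rng: np.random.Generator,
    all_models: dict[str, me.MotifModel],
    nulls: dict[str, tuple[me.ScoreNull, me.ScoreNull]],
    wmax: int,
    threshold: float,
    max_tries: int,
) -> tuple[str, str, str, str]:
    """A window where neither allele hits any motif."""
    center = wmax - 1
    length = 2 * wmax - 1
    for _ in range(max_tries):
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        a1, a2 = rng.choice(list(_BASES), size=2, replace=False)
        w1 = seq[:center] + a1 + seq[center + 1:]
        w2 = seq[:center] + a2 + seq[center + 1:]
        ok = all(
            me.call_perturbation(m, w1, w2, threshold, rsid="fixture",
                                 null=nulls[tf][0], rc_null=nulls[tf][1]
                                 ).status == "unbound"
            for tf, m in all_models.items()
        )
        if ok:
            return w1, w2, a1, a2
    raise RuntimeError("could not realize neutral window within retry budget")


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> GroundTruth:
    """Write the full synthetic input bundle to ``outdir`` and return the
    planted ground truth. Deterministic: the same spec (seed included)
    produces a byte-identical bundle."""
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # --- motifs ----------------------------------------------------------
    wmin, wmax_r = spec.motif_width_range
    tf_names = [f"TF{i + 1:02d}" for i in range(spec.n_tfs)]
    motif_counts: dict[str, np.ndarray] = {}
    for tf in tf_names:
        w = int(rng.integers(wmin, wmax_r + 1))
        motif_counts[tf] = _random_motif(rng, w)
    models = {tf: me.build_pwm(tf, c) for tf, c in motif_counts.items()}
    nulls = {
        tf: (me.exact_score_null(m), me.exact_score_null(m.reverse_complement()))
        for tf, m in models.items()
    }
    wmax = max(m.width for m in models.values())
    _write_jaspar(outdir / "motifs.jaspar", motif_counts)

    # --- ontology + annotations -----------------------------------------
    names, parents, leaves = _build_ontology(spec)
    _write_obo(outdir / "ontology.obo", names, parents)
    # spread TF annotations over leaves round-robin so branches stay balanced
    leaf_cycle = list(leaves)
    tf_terms: dict[str, frozenset[str]] = {}
    li = 0
    for tf in tf_names:
        terms = set()
        while len(terms) < spec.terms_per_tf:
            terms.add(leaf_cycle[li % len(leaf_cycle)])
            li += 1
        tf_terms[tf] = frozenset(terms)
    with open(outdir / "tf_go.tsv", "w") as fh:
        for tf in sorted(tf_terms):
            for t in sorted(tf_terms[tf]):
                fh.write(f"{tf}\t{t}\n")

    annotated_leaves = sorted(set().union(*tf_terms.values()))

    # --- curated + enriched term sets ------------------------------------
    n_cur = max(1, int(round(spec.curated_fraction * len(annotated_leaves))))
    curated = frozenset(
        rng.choice(annotated_leaves, size=n_cur, replace=False)
    )
    n_enr = max(1, int(round(spec.enriched_fraction * len(annotated_leaves))))
    planted_enriched = sorted(rng.choice(annotated_leaves, size=n_enr, replace=False))
    with open(outdir / "curated_terms.txt", "w") as fh:
        for t in sorted(curated):
            fh.write(t + "\n")

    # --- gene->GO corpus and DEG tables ----------------------------------
    gene_terms: dict[str, frozenset[str]] = {}
    gene_i = 1
    for t in annotated_leaves:
        for _ in range(spec.genes_per_term):
            gene_terms[f"G{gene_i:04d}"] = frozenset({t})
            gene_i += 1
    all_genes = sorted(gene_terms) + [
        f"G{gene_i + j:04d}" for j in range(spec.n_extra_genes)
    ]
    with open(outdir / "gene_go.tsv", "w") as fh:
        for g in sorted(gene_terms):
            for t in sorted(gene_terms[g]):
                fh.write(f"{g}\t{t}\n")
    # split the planted-enriched terms across two tissues; union recovers all
    half = (len(planted_enriched) + 1) // 2
    tissue_terms = {"colon": set(planted_enriched[:half]),
                    "rectum": set(planted_enriched[half:])}
    for tissue, terms in tissue_terms.items():
        deg_genes = {g for g, ts in gene_terms.items() if ts & terms}
        with open(outdir / f"deg_{tissue}.tsv", "w") as fh:
            fh.write("gene\tlog2fc\tadj_p\n")
            for g in all_genes:
                if g in deg_genes:
                    lfc = 0.8 + 1.7 * rng.random()
                    adj = 10 ** (-5 + 3 * rng.random())  # 1e-5 .. 1e-2
                else:
                    lfc = -0.4 + 0.8 * rng.random()
                    adj = 0.2 + 0.8 * rng.random()
                fh.write(f"{g}\t{lfc:.4f}\t{adj:.6g}\n")
    # verify the planted enrichment arithmetic per tissue (hypergeometric + BH)
    for tissue, terms in tissue_terms.items():
        deg_genes = {g for g, ts in gene_terms.items() if ts & terms}
        pvals, tested = [], []
        for t in annotated_leaves:
            genes = {g for g, ts in gene_terms.items() if t in ts}
            k = len(genes & deg_genes)
            pvals.append(float(_hypergeom.sf(k - 1, len(all_genes), len(genes),
                                             len(deg_genes))))
            tested.append(t)
        order = np.argsort(pvals, kind="stable")
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            running = min(running, pvals[idx] * m / (rank_pos + 1))
            adj[idx] = running
        significant = {t for t, a in zip(tested, adj) if a < 0.01}
        if significant != terms:
            raise RuntimeError(
                f"planted enrichment for {tissue} not recovered: {significant}"
            )
    enriched = frozenset(planted_enriched)

    # --- reduction map (independent greedy) -------------------------------
    ic, pfreq = _bf_ic_table(dict(tf_terms), parents)
    reduction_map = _bf_reduce(annotated_leaves, parents, ic, pfreq, cutoff=0.5)

    # --- SNPs: planted windows -------------------------------------------
    snp_planted: dict[str, tuple[str, str]] = {}
    fasta_records: list[tuple[str, str]] = []
    variant_rows: list[tuple[str, str, int, str, str]] = []
    pos = 10_000

    def plant_one() -> tuple[str, str, str, str, str, str]:
        """Draw TF pairs until a window realizing the planted calls exists."""
        for _ in range(50):
            lost_tf, gained_tf = rng.choice(tf_names, size=2, replace=False)
            if models[lost_tf].consensus[-1] == models[gained_tf].consensus[0]:
                continue
            try:
                nw, rw, nr, rk = _plant_window(
                    rng, models[lost_tf], models[gained_tf], models, nulls,
                    wmax, spec.pvalue_threshold, spec.max_rejection_tries,
                )
            except RuntimeError:
                continue
            return str(lost_tf), str(gained_tf), nw, rw, nr, rk
        raise RuntimeError("no feasible TF pair for a planted SNP")

    for i in range(spec.n_snps):
        rsid = f"rs{i + 1:04d}"
        lost_tf, gained_tf, nonrisk_win, risk_win, nonrisk, risk = plant_one()
        snp_planted[rsid] = (lost_tf, gained_tf)
        fasta_records += [(f"{rsid}|nonrisk", nonrisk_win), (f"{rsid}|risk", risk_win)]
        variant_rows.append((rsid, "chr1", pos, nonrisk, risk))
        pos += 1_000

    # --- null pool --------------------------------------------------------
    pool_planted: dict[str, tuple[str, str] | None] = {}
    for i in range(spec.n_pool):
        rsid = f"rp{i + 1:04d}"
        if rng.random() < spec.pool_active_frac:
            lost_tf, gained_tf, nw, rw, nr, rk = plant_one()
            pool_planted[rsid] = (lost_tf, gained_tf)
        else:
            nw, rw, nr, rk = _neutral_window(
                rng, models, nulls, wmax, spec.pvalue_threshold,
                spec.max_rejection_tries,
            )
            pool_planted[rsid] = None
        fasta_records += [(f"{rsid}|nonrisk", nw), (f"{rsid}|risk", rw)]
        variant_rows.append((rsid, "chr2", pos, nr, rk))
        pos += 1_000

    with open(outdir / "windows.fasta", "w") as fh:
        for rec_id, seq in fasta_records:
            fh.write(f">{rec_id}\n{seq}\n")

    # --- regions (BED): alternate promoters/enhancers around each SNP -----
    with open(outdir / "promoters.bed", "w") as fp, \
            open(outdir / "enhancers.bed", "w") as fe:
        for i, (rsid, chrom, pos1, _, _) in enumerate(variant_rows):
            line = f"{chrom}\t{pos1 - 51}\t{pos1 + 50}\tregion_{rsid}\n"
            (fp if i % 2 == 0 else fe).write(line)

    # --- patients: planted clusters + genotype TSV ------------------------
    disease_rsids = sorted(snp_planted)
    cluster_snps = {
        c: disease_rsids[c * spec.snps_per_cluster:(c + 1) * spec.snps_per_cluster]
        for c in range(spec.n_clusters)
    }
    shared_snps = disease_rsids[spec.n_clusters * spec.snps_per_cluster:]
    patient_clusters: dict[str, int] = {}
    patient_disease: dict[str, str] = {}
    pids = []
    for label, count in (("UC", spec.n_patients_uc), ("CD", spec.n_patients_cd)):
        for j in range(count):
            pid = f"{label}{j + 1:03d}"
            pids.append(pid)
            patient_disease[pid] = label
            patient_clusters[pid] = j % spec.n_clusters
    dosage = {pid: {} for pid in pids}
    for pid in pids:
        c = patient_clusters[pid]
        for rsid in disease_rsids:
            carrier = rsid in cluster_snps[c] or rsid in shared_snps
            if spec.noise_rate and rng.random() < spec.noise_rate:
                carrier = not carrier
            dosage[pid][rsid] = int(1 + rng.integers(0, 2)) if carrier else 0
    with open(outdir / "genotypes.tsv", "w") as fh:
        fh.write("rsid\tchrom\tpos_1based\tnonrisk\trisk\t" + "\t".join(pids) + "\n")
        for rsid, chrom, pos0, nr, rk in variant_rows:
            if rsid not in snp_planted:
                continue
            cells = "\t".join(str(dosage[p][rsid]) for p in pids)
            fh.write(f"{rsid}\t{chrom}\t{pos0 + 1}\t{nr}\t{rk}\t{cells}\n")
    with open(outdir / "pool_variants.tsv", "w") as fh:
        fh.write("rsid\tchrom\tpos_1based\tnonrisk\trisk\n")
        for rsid, chrom, pos0, nr, rk in variant_rows:
            if rsid in snp_planted:
                continue
            fh.write(f"{rsid}\t{chrom}\t{pos0 + 1}\t{nr}\t{rk}\n")
    with open(outdir / "patients.tsv", "w") as fh:
        fh.write("patient_id\tdisease\tcluster\n")
        for pid in pids:
            fh.write(f"{pid}\t{patient_disease[pid]}\t{patient_clusters[pid]}\n")

    gt = GroundTruth(
        spec=spec, snp_planted=snp_planted, pool_planted=pool_planted,
        patient_clusters=patient_clusters, patient_disease=patient_disease,
        tf_terms=tf_terms, gene_terms=gene_terms, term_parents=parents,
        curated_terms=curated, enriched_terms=enriched,
        reduction_map=reduction_map, expected_switches={},
    )
    gt.expected_counts = fixture_expected_counts(gt)
    # final post-cascade pairs per SNP, recomputed for the manifest
    final: dict[str, list[tuple[str, str]]] = {}
    for rsid, (lost_tf, gained_tf) in sorted(snp_planted.items()):
        H = {reduction_map.get(t, t) for t in tf_terms[lost_tf]}
        D = {reduction_map.get(t, t) for t in tf_terms[gained_tf]}
        S = H & D
        pairs = [
            (h, d) for h in sorted(H - D - S) for d in sorted(D - H - S)
            if (h in curated or d in curated)
            and _bf_sim(h, d, parents, ic, pfreq) < 0.5
            and d in enriched
        ]
        final[rsid] = pairs
    gt.expected_switches = final

    manifest = {
        "spec": asdict(spec),
        "files": sorted(p.name for p in outdir.iterdir() if p.is_file()
                        and p.name != "manifest.json"),
        "expected_counts": gt.expected_counts,
        "snp_planted": {r: list(v) for r, v in sorted(snp_planted.items())},
        "patient_clusters": dict(sorted(patient_clusters.items())),
        "curated_terms": sorted(curated),
        "enriched_terms": sorted(enriched),
        "reduction_map": dict(sorted(reduction_map.items())),
        "expected_switches": {r: [list(p) for p in v]
                              for r, v in sorted(final.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return gt
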