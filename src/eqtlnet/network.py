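"""eQTL-guided co-expression: master regulators, iGA networks, enrichment.

A candidate regulator is an e-trait with a cis-eQTL whose support interval
captures the trans-eQTLs of many co-expressed e-traits.  Correlation
significance is calibrated empirically: a million random e-trait pairs give
the null distribution of Pearson r, and its alpha/2 tails become the
(generally asymmetric) positive and negative cuts.

For function-related gene sets the iterative group analysis (iGA) replaces
hard correlation cuts with a rank statistic: all regulator-target pairs are
sorted by correlation strength, and for each candidate regulator the
probability of change (PC) is the minimum over prefix sizes j of the
hypergeometric tail P(X >= j) of finding j of its members within the top
r_j pairs by chance.  The members contributing to the minimizing prefix
are the "changed" targets and become signed network edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import AnnotationTable, ExpressionSet, GeneSet, QtlRecord
from .pipeline import EqtlCatalog

log = logging.getLogger("eqtlnet")


@dataclass
class CorrelationThresholds:
    pos_cut: float
    neg_cut: float
    alpha: float
    n_pairs: int

    def __post_init__(self):
        if not self.neg_cut < 0 < self.pos_cut:
            raise ValueError("thresholds must straddle zero")

    def passes(self, r: float) -> bool:
        return r >= self.pos_cut or r <= self.neg_cut


@dataclass
class RegulatorCandidate:
    regulator: str
    cis_record: QtlRecord
    targets: List[Tuple[str, float]]  # (target e-trait, Pearson r)
    label: str = "none"  # master / secondary / none

    @property
    def n_targets(self) -> int:
        return len(self.targets)


@dataclass
class IgaGroup:
    group: str
    members: List[str]
    member_ranks: List[int]
    member_r: List[float]
    n_members: int
    n_changed: int
    pc_value: float
    significant: bool = False


@dataclass
class NetworkEdge:
    regulator: str
    target: str
    r: float

    @property
    def sign(self) -> str:
        return "+" if self.r >= 0 else "-"


def _zscore_rows(V: np.ndarray) -> np.ndarray:
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (V - mu) / sd


def correlation_thresholds(
    E: ExpressionSet,
    n_group: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> CorrelationThresholds:
    """Empirical correlation cuts from random cross-group pair correlations.

    Two disjoint groups of ``n_group`` e-traits are drawn uniformly; all
    n_group^2 cross correlations form the null; the cuts are the upper and
    lower alpha/2 quantiles (splitting alpha across the two tails lets a
    skewed expression distribution give asymmetric cuts).
    """
    if E.n_lines < 4:
        raise ValueError("need at least 4 lines to correlate")
    rng = np.random.default_rng(seed)
    m = E.n_etraits
    if m < 2 * n_group:
        n_group = m // 2
        log.warning("too few e-traits; shrinking correlation groups to %d", n_group)
    sel = rng.choice(m, size=2 * n_group, replace=False)
    V = E.values.to_numpy()
    Z = _zscore_rows(V[sel])
    A, B = Z[:n_group], Z[n_group:]
    R = (A @ B.T) / E.n_lines
    flat = R[np.isfinite(R)].ravel()
    return CorrelationThresholds(
        pos_cut=float(np.quantile(flat, 1.0 - alpha / 2.0)),
        neg_cut=float(np.quantile(flat, alpha / 2.0)),
        alpha=alpha,
        n_pairs=flat.size,
    )


def _pearson_matrix(E: ExpressionSet, rows: Sequence[str], cols: Sequence[str]) -> pd.DataFrame:
    idx = {t: i for i, t in enumerate(E.etrait_ids)}
    V = E.values.to_numpy()
    Z = _zscore_rows(V)
    R = (Z[[idx[r] for r in rows]] @ Z[[idx[c] for c in cols]].T) / E.n_lines
    return pd.DataFrame(R, index=list(rows), columns=list(cols))


def find_master_regulators(
    catalog: EqtlCatalog,
    E: ExpressionSet,
    cuts: CorrelationThresholds,
    min_targets: int = 100,
    secondary_range: Tuple[int, int] = (20, 100),
) -> List[RegulatorCandidate]:
    """Nominate regulators: cis genes whose SI captures co-expressed trans-eQTLs.

    For each cis-eQTL record g, candidate targets are e-traits with a
    trans-eQTL whose peak position falls inside g's support interval (same
    chromosome) and whose Pearson correlation with g passes the calibrated
    cuts.  Candidates are ranked by target count N: master if
    N > min_targets, secondary if N falls in ``secondary_range``.
    """
    cis_records = [r for r in catalog.records if r.regulation == "cis"]
    trans_records = [r for r in catalog.records if r.regulation == "trans"]
    if not cis_records or not trans_records:
        return []
    known = set(E.etrait_ids)

    out: List[RegulatorCandidate] = []
    for g in cis_records:
        if g.trait_id not in known:
            continue
        pool = [
            t for t in trans_records
            if t.trait_id != g.trait_id
            and t.trait_id in known
            and t.chromosome == g.chromosome
            and g.si_lo <= t.peak_pos <= g.si_hi
        ]
        if not pool:
            continue
        target_ids = sorted({t.trait_id for t in pool})
        R = _pearson_matrix(E, [g.trait_id], target_ids).iloc[0]
        targets = [(tid, float(R[tid])) for tid in target_ids if cuts.passes(float(R[tid]))]
        if not targets:
            continue
        cand = RegulatorCandidate(regulator=g.trait_id, cis_record=g, targets=targets)
        if cand.n_targets > min_targets:
            cand.label = "master"
        elif secondary_range[0] <= cand.n_targets <= secondary_range[1]:
            cand.label = "secondary"
        out.append(cand)
    out.sort(key=lambda c: -c.n_targets)
    return out


def regulators_to_frame(cands: List[RegulatorCandidate]) -> pd.DataFrame:
    """Master-regulator table: N, bin, LOD, SI bounds in Mb, variance explained."""
    return pd.DataFrame(
        [
            {
                "regulator": c.regulator,
                "N": c.n_targets,
                "bin": c.cis_record.peak_bin,
                "chrom": c.cis_record.chromosome,
                "LOD": round(c.cis_record.lod, 2),
                "Inf_Mb": round(c.cis_record.si_lo / 1e6, 2),
                "Sup_Mb": round(c.cis_record.si_hi / 1e6, 2),
                "Var": f"{c.cis_record.var_explained * 100:.2f}%",
                "label": c.label,
            }
            for c in cands
        ]
    )


def iga_pc(
    member_ranks: Sequence[int], N_total: int, n_members: Optional[int] = None
) -> Tuple[float, int]:
    """Probability-of-change statistic for one group.

    ``member_ranks`` are the strictly increasing positions of the group's
    members in the pooled sorted pair list of length ``N_total``.  For each
    prefix size j, PC_j = P(X >= j) with X ~ Hypergeom(N_total, n_members,
    r_j); the PC value is min_j PC_j and n_changed the smallest j attaining
    it.
    """
    ranks = list(member_ranks)
    if not ranks:
        raise ValueError("empty member rank list")
    if any(b <= a for a, b in zip(ranks, ranks[1:])):
        raise ValueError("member ranks must be strictly increasing")
    if ranks[0] < 1 or ranks[-1] > N_total:
        raise ValueError("ranks must lie within [1, N_total]")
    m = n_members if n_members is not None else len(ranks)
    if not 1 <= len(ranks) <= m <= N_total:
        raise ValueError("inconsistent group size")
    pcs = [float(sps.hypergeom.sf(j - 1, N_total, m, r)) for j, r in enumerate(ranks, start=1)]
    best = min(pcs)
    # ties (within float tolerance) resolve to the smallest prefix
    j_best = next(j for j, p in enumerate(pcs, start=1) if p <= best + 1e-12)
    return pcs[j_best - 1], j_best


def _si_overlaps(a: QtlRecord, b: QtlRecord) -> bool:
    return a.chromosome == b.chromosome and a.si_lo <= b.si_hi and b.si_lo <= a.si_hi


def run_iga(
    gene_set: GeneSet,
    catalog: EqtlCatalog,
    E: ExpressionSet,
    alpha: float = 0.05,
) -> Tuple[List[IgaGroup], List[NetworkEdge]]:
    """iGA over a functional gene set: groups, PC values, signed edges.

    Set members with a cis-eQTL whose SI overlaps the SI of at least one
    trans-eQTL of another member become groups (potential regulators);
    members of a group are set e-traits whose trans-eQTL SI overlaps the
    group's cis SI.  E-traits carrying both cis- and trans-eQTLs are
    disregarded in the pairing.  All group-member pairs are pooled, sorted
    by |Pearson r| descending, and each group's PC value is computed over
    the pooled list; groups with PC < alpha are significant and contribute
    one signed edge per changed member.
    """
    resolved, unresolved = gene_set.resolve(E.etrait_ids)
    if unresolved:
        log.info("gene set %s: %d labels not resolvable against the expression set",
                 gene_set.name, len(unresolved))
    members = set(resolved)
    cis_by_trait: dict = {}
    trans_by_trait: dict = {}
    for r in catalog.records:
        if r.trait_id not in members:
            continue
        if r.regulation == "cis":
            cis_by_trait.setdefault(r.trait_id, []).append(r)
        elif r.regulation == "trans":
            trans_by_trait.setdefault(r.trait_id, []).append(r)
    both = set(cis_by_trait) & set(trans_by_trait)
    cis_only = {t: recs for t, recs in cis_by_trait.items() if t not in both}
    trans_only = {t: recs for t, recs in trans_by_trait.items() if t not in both}

    pairs: List[Tuple[str, str]] = []
    group_members: dict = {}
    for g, g_recs in cis_only.items():
        mem = sorted(
            t for t, t_recs in trans_only.items()
            if t != g and any(_si_overlaps(gr, tr) for gr in g_recs for tr in t_recs)
        )
        if mem:
            group_members[g] = mem
            pairs.extend((g, t) for t in mem)
    if not group_members:
        log.info("gene set %s: no regulator groups formed", gene_set.name)
        return [], []

    rows = sorted(group_members)
    cols = sorted({t for mem in group_members.values() for t in mem})
    R = _pearson_matrix(E, rows, cols)
    scored = sorted(pairs, key=lambda p: -abs(R.at[p[0], p[1]]))
    rank_of = {p: i + 1 for i, p in enumerate(scored)}
    N_total = len(scored)

    groups: List[IgaGroup] = []
    edges: List[NetworkEdge] = []
    for g in rows:
        mem = group_members[g]
        ranked = sorted(((rank_of[(g, t)], t) for t in mem))
        ranks = [rk for rk, _ in ranked]
        pc, n_changed = iga_pc(ranks, N_total, n_members=len(ranks))
        grp = IgaGroup(
            group=g,
            members=[t for _, t in ranked],
            member_ranks=ranks,
            member_r=[float(R.at[g, t]) for _, t in ranked],
            n_members=len(ranks),
            n_changed=n_changed,
            pc_value=pc,
            significant=pc < alpha,
        )
        groups.append(grp)
        if grp.significant:
            for _, t in ranked[:n_changed]:
                edges.append(NetworkEdge(regulator=g, target=t, r=float(R.at[g, t])))
    groups.sort(key=lambda g: g.pc_value)
    return groups, edges


def iga_to_frame(groups: List[IgaGroup]) -> pd.DataFrame:
    """Group table: members, number changed, PC value."""
    return pd.DataFrame(
        [
            {
                "group": g.group,
                "members": g.n_members,
                "number_changed": g.n_changed,
                "P_value_changed": g.pc_value,
                "significant": g.significant,
            }
            for g in groups
        ]
    )


def edges_to_frame(edges: List[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"regulator": e.regulator, "target": e.target, "r": round(e.r, 4), "sign": e.sign}
         for e in edges],
        columns=["regulator", "target", "r", "sign"],
    )


def corr_test(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation: t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def term_enrichment(
    targets: GeneSet, ann: AnnotationTable, universe: GeneSet
) -> pd.DataFrame:
    """Hypergeometric term enrichment with Benjamini-Hochberg adjustment.

    Per term: overlap k of targets with the term's genes inside the
    universe; p = P(X >= k), X ~ Hypergeom(|universe|, term size in
    universe, |targets|).
    """
    uni = set(universe.members)
    tgt = set(targets.members) & uni
    if set(targets.members) - uni:
        log.info("%d target labels outside the universe were ignored",
                 len(set(targets.members) - uni))
    N, n = len(uni), len(tgt)
    rows = []
    for term in ann.terms:
        term_genes = set(ann.genes_for(term)) & uni
        K = len(term_genes)
        if K == 0:
            continue
        k = len(tgt & term_genes)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"term": term, "overlap": k, "term_size": K, "p": p})
    if not rows:
        return pd.DataFrame(columns=["term", "overlap", "term_size", "p", "p_adj"])
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("p").reset_index(drop=True)
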