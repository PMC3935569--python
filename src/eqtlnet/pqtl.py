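"""Phenotypic QTL mapping and cis-eQTL colocalization.

Phenotypes go through the same composite-interval-mapping engine as
expression traits (default LOD threshold 5.0).  Candidate genes for a pQTL
are e-traits whose cis-eQTL support interval overlaps the pQTL support
interval by at least one base pair; they are ranked by the significance of
the Pearson correlation between trait scores and expression across lines,
with Benjamini-Hochberg adjustment reported alongside the raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import BinMap, ExpressionSet, GenotypeMatrix, PhenotypeTable, QtlRecord
from .network import corr_test
from .pipeline import EqtlCatalog, _records_from_profile
from .qtl import ScanSettings, cim_scan, select_covariates


@dataclass
class CandidateGene:
    trait: str
    pqtl: QtlRecord
    etrait: str
    overlap_bp: int
    r: float
    p: float
    p_adj: float = float("nan")
    significant: bool = False


def map_pqtls(
    P: PhenotypeTable,
    G: GenotypeMatrix,
    binmap: BinMap,
    settings: Optional[ScanSettings] = None,
    threshold: Optional[float] = None,
) -> List[QtlRecord]:
    """CIM scan per phenotype; chromosome-wise peaks at or above threshold."""
    settings = settings or ScanSettings()
    thr = settings.lod_threshold_p if threshold is None else threshold
    X = G.numeric()
    records: List[QtlRecord] = []
    for trait in P.traits:
        y = P.values[trait].to_numpy()
        cov = select_covariates(y, X, settings.n_covariates) if settings.n_covariates else []
        profile = cim_scan(y, X, binmap, settings, covariates=cov)
        records.extend(
            _records_from_profile(trait, y, X, profile, thr, settings.si_drop)
        )
    return records


def colocalize(
    pqtls: List[QtlRecord],
    catalog: EqtlCatalog,
    P: PhenotypeTable,
    E: ExpressionSet,
    alpha: float = 0.05,
) -> List[CandidateGene]:
    """Nominate candidate genes for each pQTL by cis-eQTL interval overlap.

    For every cis-eQTL whose SI intersects the pQTL SI, compute the Pearson
    correlation between trait scores and expression (lines with missing
    values dropped pairwise), its two-sided p, and a per-pQTL
    Benjamini-Hochberg flag at ``alpha``.  Candidates come back sorted by p
    within each pQTL.
    """
    cis_records = [r for r in catalog.records if r.regulation == "cis"]
    line_order = [ln for ln in P.lines if ln in set(E.lines)]
    expr = E.values[line_order]

    out: List[CandidateGene] = []
    for q in pqtls:
        found = []
        y = P.values.loc[line_order, q.trait_id].to_numpy()
        for c in cis_records:
            if c.chromosome != q.chromosome:
                continue
            lo = max(c.si_lo, q.si_lo)
            hi = min(c.si_hi, q.si_hi)
            if hi < lo:
                continue
            e = expr.loc[c.trait_id].to_numpy()
            keep = ~(np.isnan(y) | np.isnan(e))
            if keep.sum() < 4:
                continue
            r = float(np.corrcoef(y[keep], e[keep])[0, 1])
            p = corr_test(max(min(r, 0.999999), -0.999999), int(keep.sum()))
            found.append(
                CandidateGene(
                    trait=q.trait_id,
                    pqtl=q,
                    etrait=c.trait_id,
                    overlap_bp=int(hi - lo + 1),
                    r=r,
                    p=p,
                )
            )
        if found:
            rej, adj, *_ = multipletests([c.p for c in found], alpha=alpha, method="fdr_bh")
            for c, pa, rj in zip(found, adj, rej):
                c.p_adj = float(pa)
                c.significant = bool(rj)
            found.sort(key=lambda c: c.p)
            out.extend(found)
    return out


def candidates_to_frame(cands: List[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": c.trait,
                "pqtl_bin": c.pqtl.peak_bin,
                "etrait": c.etrait,
                "overlap_bp": c.overlap_bp,
                "r": round(c.r, 4),
                "p": c.p,
                "p_adj": c.p_adj,
                "significant": c.significant,
            }
            for c in cands
        ],
        columns=["trait", "pqtl_bin", "etrait", "overlap_bp", "r", "p", "p_adj", "significant"],
    )
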