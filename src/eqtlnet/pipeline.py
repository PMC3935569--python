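"""Genome-wide eQTL mapping, presence filtering, and cis/trans classification.

One eQTL is kept per chromosome per e-trait (the chromosome-wise LOD
maximum above threshold).  An eQTL is cis when the e-trait's own genomic
anchor lies inside the 1.5-LOD-drop support interval on the same
chromosome, trans otherwise; unanchored e-traits stay unclassified and are
counted separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .datamodel import BinMap, ExpressionSet, GenotypeMatrix, QtlRecord
from .qtl import LodProfile, ScanSettings, cim_scan, qtl_effects, select_covariates, support_interval
from .stats import goodness_of_fit

log = logging.getLogger("eqtlnet")


@dataclass
class EqtlCatalog:
    """All mapped eQTLs plus bookkeeping."""

    records: List[QtlRecord] = field(default_factory=list)
    unanchored: List[str] = field(default_factory=list)

    @property
    def n_cis(self) -> int:
        return sum(r.regulation == "cis" for r in self.records)

    @property
    def n_trans(self) -> int:
        return sum(r.regulation == "trans" for r in self.records)

    def per_etrait_counts(self) -> pd.Series:
        ids = [r.trait_id for r in self.records]
        return pd.Series(ids).value_counts()

    def for_trait(self, trait_id: str) -> List[QtlRecord]:
        return [r for r in self.records if r.trait_id == trait_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait_id": r.trait_id,
                    "chrom": r.chromosome,
                    "peak_bin": r.peak_bin,
                    "peak_pos": r.peak_pos,
                    "LOD": r.lod,
                    "si_lo": r.si_lo,
                    "si_hi": r.si_hi,
                    "additive": r.additive,
                    "var_explained": r.var_explained,
                    "regulation": r.regulation,
                }
                for r in self.records
            ]
        )


def filter_etraits(E: ExpressionSet, min_fraction: float = 1.0 / 3.0) -> ExpressionSet:
    """Keep e-traits called present (P or M) in at least ceil(f * n_lines) lines.

    With 210 lines and the default third, an e-trait needs 70 present
    calls.  Without a presence matrix everything is kept.
    """
    if E.presence is None or min_fraction <= 0:
        return E
    need = math.ceil(min_fraction * E.n_lines)
    pm = E.presence.isin(["P", "M"]).sum(axis=1)
    keep = pm[pm >= need].index
    dropped = E.n_etraits - len(keep)
    if dropped:
        log.info("presence filter dropped %d of %d e-traits (< %d P/M calls)",
                 dropped, E.n_etraits, need)
    return E.subset(list(keep))


def _records_from_profile(
    trait_id: str,
    y: np.ndarray,
    X: np.ndarray,
    profile: LodProfile,
    threshold: float,
    si_drop: float,
) -> List[QtlRecord]:
    t = profile.binmap.table
    records = []
    for chrom, grp in t.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        j = idx[int(np.argmax(profile.lod[idx]))]
        if profile.lod[j] < threshold:
            continue
        si_lo, si_hi = support_interval(profile, int(j), si_drop)
        try:
            additive, ve = qtl_effects(y, X[:, j])
        except ValueError:
            continue
        peak_pos = int((t["phys_start"].iloc[j] + t["phys_end"].iloc[j]) // 2)
        records.append(
            QtlRecord(
                trait_id=trait_id,
                chromosome=str(chrom),
                peak_bin=str(t["bin_id"].iloc[j]),
                peak_pos=peak_pos,
                lod=float(profile.lod[j]),
                si_lo=si_lo,
                si_hi=si_hi,
                additive=additive,
                var_explained=ve,
            )
        )
    return records


def map_all_etraits(
    E: ExpressionSet,
    G: GenotypeMatrix,
    binmap: BinMap,
    settings: Optional[ScanSettings] = None,
    threshold: Optional[float] = None,
) -> EqtlCatalog:
    """Scan every e-trait and collect chromosome-wise peaks above threshold.

    Each record carries the 1.5-LOD-drop support interval, the additive
    effect and the marginal variance explained at the peak; classification
    happens afterwards via :func:`classify_catalog`.
    """
    settings = settings or ScanSettings()
    thr = settings.lod_threshold_e if threshold is None else threshold
    X = G.numeric()
    V = E.values.to_numpy()
    catalog = EqtlCatalog()
    for g, trait_id in enumerate(E.etrait_ids):
        y = V[g]
        cov = select_covariates(y, X, settings.n_covariates) if settings.n_covariates else []
        profile = cim_scan(y, X, binmap, settings, covariates=cov)
        catalog.records.extend(
            _records_from_profile(trait_id, y, X, profile, thr, settings.si_drop)
        )
    return catalog


def classify_cis_trans(rec: QtlRecord, anchor) -> QtlRecord:
    """Set the regulation flag from the e-trait's genomic anchor.

    ``anchor`` is (chrom, position bp) or None.  cis iff the anchor sits on
    the record's chromosome inside [si_lo, si_hi]; anchored elsewhere is
    trans; unanchored stays not-applicable.
    """
    if anchor is None or anchor[0] is None or pd.isna(anchor[0]) or pd.isna(anchor[1]):
        rec.regulation = "not-applicable"
        return rec
    chrom, pos = str(anchor[0]), float(anchor[1])
    if chrom == rec.chromosome and rec.si_lo <= pos <= rec.si_hi:
        rec.regulation = "cis"
    else:
        rec.regulation = "trans"
    return rec


def classify_catalog(catalog: EqtlCatalog, anchors: pd.DataFrame) -> EqtlCatalog:
    """Classify every record; anchors indexed by trait id with chrom/position."""
    unanchored = set()
    for rec in catalog.records:
        if rec.trait_id in anchors.index:
            row = anchors.loc[rec.trait_id]
            classify_cis_trans(rec, (row["chrom"], row["position"]))
        else:
            rec.regulation = "not-applicable"
        if rec.regulation == "not-applicable":
            unanchored.add(rec.trait_id)
    catalog.unanchored = sorted(unanchored)
    if unanchored:
        log.info("%d e-traits lacked a usable anchor and were left unclassified",
                 len(unanchored))
    return catalog


def summarize_by_chromosome(catalog: EqtlCatalog, binmap: BinMap) -> pd.DataFrame:
    """Per-chromosome eQTL statistics with size-based expectations and SRs.

    Mirrors the classic per-chromosome summary: observed totals plus cis and
    trans counts, chromosome sizes in Mb and cM, and for both size scales
    the expected count under proportionality and its standardized residue.
    The chi-square statistics are exposed as frame attrs ``chi2_physical``
    and ``chi2_genetic``.
    """
    if not catalog.records:
        raise ValueError("empty catalog")
    chroms = binmap.chromosomes
    counts = {c: [0, 0, 0] for c in chroms}  # all, cis, trans
    for r in catalog.records:
        row = counts[r.chromosome]
        row[0] += 1
        if r.regulation == "cis":
            row[1] += 1
        elif r.regulation == "trans":
            row[2] += 1
    obs = np.array([counts[c][0] for c in chroms], dtype=float)
    size_mb = binmap.chrom_sizes_bp().reindex(chroms).to_numpy() / 1e6
    size_cm = binmap.chrom_sizes_cm().reindex(chroms).to_numpy()

    fit_p = goodness_of_fit(obs, size_mb)
    fit_g = goodness_of_fit(obs, size_cm)
    out = pd.DataFrame(
        {
            "chrom": chroms,
            "n_eqtl": obs.astype(int),
            "n_cis": [counts[c][1] for c in chroms],
            "n_trans": [counts[c][2] for c in chroms],
            "size_Mb": size_mb,
            "expected_physical": fit_p.expected,
            "SR_physical": fit_p.sr,
            "size_cM": size_cm,
            "expected_genetic": fit_g.expected,
            "SR_genetic": fit_g.sr,
            "cM_per_Mb": size_cm / size_mb,
        }
    )
    out.attrs["chi2_physical"] = fit_p.chi2
    out.attrs["chi2_genetic"] = fit_g.chi2
    return out
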