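"""Genome distribution statistics.

Counts per category (chromosome or bin) are compared with size-proportional
expectations by a chi-square goodness-of-fit test.  The per-category
standardized residue SR = (observed - expected) / sqrt(expected) is
asymptotically standard normal, so |SR| > 2.33 marks P < 0.01 departures;
the chi-square statistic is exactly the sum of squared SRs.

The trans-eQTL hotspot screen combines two tests per bin: the SR of the
trans-eQTL count against the bin's physical-size expectation, and a
hypergeometric upper tail asking whether the eQTLs peaking in the bin are
unexpectedly enriched in trans (relative to the genome-wide cis/trans
composition).  A bin is a hotspot when both reject at alpha; a coldspot
when SR < -cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import BinMap


@dataclass
class FitResult:
    observed: np.ndarray
    expected: np.ndarray
    sr: np.ndarray
    chi2: float
    df: int
    pvalue: float

    def __post_init__(self):
        assert np.isclose(self.chi2, float((self.sr**2).sum())), "chi2 must equal sum of SR^2"

    def to_frame(self, labels=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"observed": self.observed, "expected": self.expected, "SR": self.sr}
        )
        if labels is not None:
            df.index = list(labels)
        return df


def goodness_of_fit(observed, sizes) -> FitResult:
    """Chi-square goodness of fit of counts against size-proportional expectations.

    expected_i = total * size_i / sum(sizes); SR_i = (obs_i - exp_i) /
    sqrt(exp_i); chi2 = sum SR_i^2 with df = k - 1.
    """
    obs = np.asarray(observed, dtype=float)
    sz = np.asarray(sizes, dtype=float)
    if (sz <= 0).any():
        raise ValueError("all category sizes must be positive")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    exp = obs.sum() * sz / sz.sum()
    sr = (obs - exp) / np.sqrt(exp)
    chi2 = float((sr**2).sum())
    df = len(obs) - 1
    return FitResult(obs, exp, sr, chi2, df, float(sps.chi2.sf(chi2, df)))


def sr_cutoff(alpha: float = 0.01) -> float:
    """Upper-tail standard-normal quantile for SR significance, to 2 decimals.

    sr_cutoff(0.01) = 2.33: the conventional P < 0.01 cut for a
    standardized residue.
    """
    if not 0.0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 0.5]")
    return round(float(sps.norm.isf(alpha)), 2)


@dataclass
class HotspotTable:
    """Per-bin hotspot screen results plus the screen parameters."""

    table: pd.DataFrame
    alpha: float
    cutoff: float

    @property
    def hotspots(self) -> pd.DataFrame:
        return self.table[self.table["hotspot"]]

    @property
    def coldspots(self) -> pd.DataFrame:
        return self.table[self.table["coldspot"]]


def hotspot_screen(catalog, binmap: BinMap, alpha: float = 0.01) -> HotspotTable:
    """Dual-test screen for trans-eQTL hotspot bins.

    Each trans-eQTL is assigned to its peak bin.  Per bin i:

    * SR of the trans count k_i against the expectation from the bin's
      physical size fraction of all trans-eQTLs;
    * hypergeometric upper tail P(X >= k_i) with X ~ Hypergeom(population
      N = all classified eQTLs, successes K = all trans-eQTLs, draws
      n_i = eQTLs peaking in bin i) — is the bin's eQTL content
      unexpectedly trans-heavy given its cis content?

    hotspot iff SR > sr_cutoff(alpha) AND p < alpha; coldspot iff
    SR < -cutoff.
    """
    records = catalog.records if hasattr(catalog, "records") else list(catalog)
    classified = [r for r in records if r.regulation in ("cis", "trans")]
    if not classified:
        raise ValueError("empty or unclassified catalog")
    t = binmap.table
    bin_index = {b: i for i, b in enumerate(t["bin_id"])}
    n_bins = binmap.n_bins

    k_trans = np.zeros(n_bins, dtype=int)
    n_all = np.zeros(n_bins, dtype=int)
    for r in classified:
        i = bin_index[r.peak_bin]
        n_all[i] += 1
        if r.regulation == "trans":
            k_trans[i] += 1

    widths = (t["phys_end"] - t["phys_start"] + 1).to_numpy(dtype=float)
    K = int(k_trans.sum())
    N = int(n_all.sum())
    expected = K * widths / widths.sum()
    sr = (k_trans - expected) / np.sqrt(expected)
    pvals = sps.hypergeom.sf(k_trans - 1, N, K, n_all)
    cutoff = sr_cutoff(alpha)
    hot = (sr > cutoff) & (pvals < alpha)
    cold = sr < -cutoff

    table = pd.DataFrame(
        {
            "bin_id": t["bin_id"],
            "chrom": t["chrom"],
            "trans_count": k_trans,
            "expected": expected,
            "SR": sr,
            "sr_significant": np.abs(sr) > cutoff,
            "cis_count": n_all - k_trans,
            "hypergeom_p": pvals,
            "hotspot": hot,
            "coldspot": cold,
        }
    )
    return HotspotTable(table=table, alpha=alpha, cutoff=cutoff)
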