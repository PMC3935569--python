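"""Synthetic RIL populations with a planted regulatory architecture.

The generator emulates a biparental recombinant-inbred-line study: 210 lines
genotyped on an ultrahigh-density bin map (1619 bins over 12 chromosomes,
~372 Mb / ~1625 cM by default), thousands of log2-scale expression traits
with local (cis) variants and regulator-driven trans effects — including
hotspot regulators with >100 targets — plus quantitative phenotypes
controlled by pleiotropic loci.  Every run is reproducible from a single
seed and returns a ground-truth ledger, so downstream mapping, hotspot and
network stages can be tested by parameter recovery.

RILs are modelled at fixation (fully homozygous): along each chromosome a
line is a two-state Markov chain whose switch probability between adjacent
bins at genetic distance d cM is R = 2r / (1 + 2r), with r the single-meiosis
Haldane recombination fraction r = (1 - exp(-2d/100)) / 2.  R >= r, is
monotone in d, and tends to 1/2 as d grows (map expansion under selfing).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .datamodel import BinMap, ExpressionSet, GenotypeMatrix, PhenotypeTable


def haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Single-meiosis recombination fraction for distance d (cM), no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_switch_prob(d_cm: np.ndarray) -> np.ndarray:
    """Probability that adjacent bins differ in a RIL at fixation: R = 2r/(1+2r)."""
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass
class RegulatorSpec:
    """One planted trans regulator.

    n_targets
        number of downstream e-traits; >100 makes a hotspot.
    pos_frac
        fraction of target coefficients that are positive (activation).
    cis_ve
        variance fraction the regulator's own local variant explains.
    target_ve
        fraction of each target's variance contributed by the regulator's
        expression (sets the coefficient magnitude).
    parent
        index of another RegulatorSpec regulating this one (chains); the
        regulator graph must be acyclic.
    """

    n_targets: int = 150
    pos_frac: float = 0.7
    cis_ve: float = 0.5
    target_ve: float = 0.5
    parent: Optional[int] = None


@dataclass
class TraitSpec:
    """One quantitative phenotype.

    causal_bins may be explicit bin indices; otherwise n_causal bins are
    drawn.  linked_etrait adds a lambda * expression term contributing
    link_ve of the trait variance (linked_regulator refers to an entry of
    SimConfig.regulators instead, resolved after regulator placement).
    h2 is the fraction of trait variance that is non-noise.
    """

    name: str = "trait"
    causal_bins: Optional[List[int]] = None
    n_causal: int = 2
    h2: float = 0.5
    linked_etrait: Optional[int] = None
    linked_regulator: Optional[int] = None
    link_ve: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic population.

    Defaults mirror the emulated study: 210 lines, 12 chromosomes,
    1619 bins, 372.2 Mb / 1625 cM (whole-genome average 4.37 cM/Mb),
    Gaussian expression noise on the log2 scale, and cis variants that
    explain 25% of expression variance — the regime in which the bulk of
    real cis effects were reported (most explained >= 20%).
    """

    n_lines: int = 210
    n_chromosomes: int = 12
    n_bins: int = 1619
    genome_mb: float = 372.2
    genome_cm: float = 1625.0
    n_etraits: int = 2000
    n_cis: int = 1200
    regulators: List[RegulatorSpec] = field(default_factory=lambda: [RegulatorSpec()])
    cis_ve: float = 0.25
    noise_sd: float = 1.0
    n_traits: int = 5
    trait_specs: Optional[List[TraitSpec]] = None
    absent_fraction: float = 0.0
    coanchored_cis: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_lines", "n_chromosomes", "n_bins", "n_etraits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_bins < self.n_chromosomes:
            raise ValueError("n_bins must be >= n_chromosomes")
        if not 0.0 < self.cis_ve < 1.0:
            raise ValueError("cis_ve must lie in (0, 1)")
        for reg in self.regulators:
            if not 0.0 < reg.cis_ve < 1.0 or not 0.0 < reg.target_ve < 1.0:
                raise ValueError("regulator variance fractions must lie in (0, 1)")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for start in range(len(self.regulators)):
            seen, node = [start], self.regulators[start].parent
            while node is not None:
                if node in seen:
                    cycle = " -> ".join(f"R{i}" for i in seen + [node])
                    raise ValueError(f"regulator graph contains a cycle: {cycle}")
                seen.append(node)
                node = self.regulators[node].parent


@dataclass
class GroundTruth:
    """Planted parameters, for recovery tests.

    cis_coef[g] is the local additive coefficient of e-trait g (0 if none);
    anchor_bin[g] its bin index on the map; edges are
    (regulator e-trait index, target e-trait index, coefficient).
    """

    anchor_bin: np.ndarray
    anchor_pos: np.ndarray
    cis_coef: np.ndarray
    edges: List[Tuple[int, int, float]]
    regulator_etraits: List[int]
    regulator_bin: dict
    trait_models: List[dict] = field(default_factory=list)

    def targets_of(self, regulator: int) -> List[int]:
        return [t for (r, t, _) in self.edges if r == regulator]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _largest_remainder(weights: np.ndarray, total: int, minimum: int = 1) -> np.ndarray:
    """Integer allocation proportional to weights, each cell >= minimum."""
    weights = np.asarray(weights, dtype=float)
    base = weights / weights.sum() * (total - minimum * len(weights))
    out = np.floor(base).astype(int) + minimum
    rem = total - out.sum()
    order = np.argsort(-(base - np.floor(base)))
    out[order[:rem]] += 1
    return out


def generate_bin_map(cfg: SimConfig) -> BinMap:
    """Draw a bin map whose physical and genetic totals match the config.

    Chromosome sizes are jittered around equal shares and renormalized so
    the genome sums to exactly genome_mb and genome_cm; per-chromosome
    cM/Mb therefore scatters around the genome average (4.37 by default).
    """
    cfg.validate()
    rng = _rng(cfg.seed, 1)
    k = cfg.n_chromosomes

    mb_share = 1.0 + 0.30 * rng.uniform(-1, 1, size=k)
    mb_share /= mb_share.sum()
    chrom_bp = np.round(mb_share * cfg.genome_mb * 1e6).astype(np.int64)

    cm_share = mb_share * (1.0 + 0.15 * rng.uniform(-1, 1, size=k))
    chrom_cm = cm_share / cm_share.sum() * cfg.genome_cm

    bins_per_chrom = _largest_remainder(mb_share, cfg.n_bins)

    rows = []
    for c in range(k):
        n = int(bins_per_chrom[c])
        chrom = f"chr{c+1}"
        w = rng.gamma(5.0, 1.0, size=n)
        bounds = np.round(np.cumsum(w) / w.sum() * chrom_bp[c]).astype(np.int64)
        bounds = np.maximum.accumulate(np.maximum(bounds, np.arange(1, n + 1)))
        starts = np.concatenate([[1], bounds[:-1] + 1])
        ends = bounds
        # genetic position = cumulative cM at bin start; increments follow
        # physical widths with multiplicative jitter (local cM/Mb variation)
        widths = ends - starts + 1
        jitter = rng.lognormal(0.0, 0.3, size=n)
        incr = widths * jitter
        if n > 1:
            cm = np.concatenate([[0.0], np.cumsum(incr[:-1])])
            cm = cm / cm[-1] * chrom_cm[c] if cm[-1] > 0 else cm
        else:
            cm = np.array([chrom_cm[c]])
        for i in range(n):
            rows.append((None, chrom, starts[i], ends[i], cm[i]))

    table = pd.DataFrame(rows, columns=["bin_id", "chrom", "phys_start", "phys_end", "genetic_pos"])
    table["bin_id"] = [f"Bin{i+1}" for i in range(len(table))]
    return BinMap(table)


def simulate_ril_genotypes(binmap: BinMap, cfg: SimConfig) -> GenotypeMatrix:
    """Simulate fully homozygous RIL genotypes along the bin map.

    Per line and chromosome: first bin A or B with probability 1/2, then a
    switch between adjacent bins with probability R(d) = 2r/(1+2r) derived
    from the Haldane recombination fraction at their genetic distance.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 2)
    n = cfg.n_lines
    t = binmap.table
    cols = np.empty((n, binmap.n_bins), dtype=np.int8)

    for chrom, grp in t.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        d = np.diff(grp["genetic_pos"].to_numpy())
        R = ril_switch_prob(d)
        first = rng.random(n) < 0.5
        if len(idx) > 1:
            switches = rng.random((n, len(idx) - 1)) < R
            flips = np.concatenate([first[:, None], switches], axis=1)
        else:
            flips = first[:, None]
        state = np.cumsum(flips, axis=1) % 2  # 0 = A, 1 = B
        cols[:, idx] = state

    lines = [f"RIL{i+1:03d}" for i in range(n)]
    calls = pd.DataFrame(
        np.where(cols == 1, "B", "A"), index=lines, columns=binmap.bin_ids
    )
    return GenotypeMatrix(calls)


def _cis_coef(ve: float, noise_sd: float, trans_var: float = 0.0) -> float:
    """Additive coefficient a with a^2 / (a^2 + trans_var + noise_sd^2) = ve.

    Genotypes are coded -1/+1, so Var(x) = 1 in a balanced RIL population.
    """
    return float(np.sqrt(ve / (1.0 - ve) * (trans_var + noise_sd**2)))


def plant_model(binmap: BinMap, cfg: SimConfig) -> GroundTruth:
    """Assign anchors, cis effects, and the regulator->target coefficient lists.

    Cis coefficients are scaled so the local variant explains the configured
    variance fraction; regulator->target coefficients are scaled so the
    regulator's expression contributes target_ve of the target's variance,
    with signs drawn from the configured mix.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 3)
    m = cfg.n_etraits
    sd = cfg.noise_sd

    anchor_bin = rng.integers(0, binmap.n_bins, size=m)
    t = binmap.table
    lo = t["phys_start"].to_numpy()[anchor_bin]
    hi = t["phys_end"].to_numpy()[anchor_bin]
    anchor_pos = rng.integers(lo, hi + 1)

    n_cis = min(cfg.n_cis, m)
    cis_idx = rng.choice(m, size=n_cis, replace=False)
    cis_coef = np.zeros(m)
    cis_coef[cis_idx] = _cis_coef(cfg.cis_ve, sd) * rng.choice([-1.0, 1.0], size=n_cis)

    # regulators are drawn from the cis set (a regulator needs its own local
    # variant so its expression maps to its bin); targets from the remainder
    n_reg = len(cfg.regulators)
    if n_reg > len(cis_idx):
        raise ValueError("more regulators than cis e-traits")
    reg_etraits = list(rng.choice(cis_idx, size=n_reg, replace=False))
    for j, spec in enumerate(cfg.regulators):
        cis_coef[reg_etraits[j]] = _cis_coef(spec.cis_ve, sd) * np.sign(
            cis_coef[reg_etraits[j]] or 1.0
        )

    expr_var = cis_coef**2 + sd**2  # marginal variance before trans terms
    edges: List[Tuple[int, int, float]] = []
    pool = np.setdiff1d(np.arange(m), np.concatenate([cis_idx, reg_etraits]))
    rng.shuffle(pool)
    cursor = 0
    for j, spec in enumerate(cfg.regulators):
        reg = reg_etraits[j]
        if spec.parent is not None:
            parent = reg_etraits[spec.parent]
            beta = _parent_beta(spec.target_ve, expr_var[parent], expr_var[reg])
            beta *= 1.0 if rng.random() < spec.pos_frac else -1.0
            edges.append((parent, reg, beta))
            expr_var[reg] += beta**2 * expr_var[parent]
        take = spec.n_targets
        if cursor + take > len(pool):
            raise ValueError("not enough free e-traits for the configured targets")
        targets = pool[cursor : cursor + take]
        cursor += take
        signs = np.where(rng.random(take) < spec.pos_frac, 1.0, -1.0)
        for tgt, s in zip(targets, signs):
            beta = s * _parent_beta(spec.target_ve, expr_var[reg], expr_var[tgt])
            edges.append((int(reg), int(tgt), float(beta)))
            expr_var[tgt] += beta**2 * expr_var[reg]

    # co-anchor additional cis e-traits in the first regulator's bin: a
    # hotspot bin realistically harbours several genes with local variants,
    # which become the competing candidate regulators downstream
    if cfg.coanchored_cis > 0 and reg_etraits:
        bin0 = int(anchor_bin[reg_etraits[0]])
        free_cis = [i for i in cis_idx if i not in reg_etraits]
        rng.shuffle(free_cis)
        moved = free_cis[: cfg.coanchored_cis]
        anchor_bin[moved] = bin0
        lo0, hi0 = t["phys_start"].iloc[bin0], t["phys_end"].iloc[bin0]
        anchor_pos[moved] = rng.integers(lo0, hi0 + 1, size=len(moved))

    truth = GroundTruth(
        anchor_bin=anchor_bin,
        anchor_pos=anchor_pos,
        cis_coef=cis_coef,
        edges=edges,
        regulator_etraits=[int(r) for r in reg_etraits],
        regulator_bin={int(r): int(anchor_bin[r]) for r in reg_etraits},
    )
    truth.trait_models = _plan_traits(cfg, binmap, truth, rng)
    return truth


def _parent_beta(ve: float, var_parent: float, var_child_base: float) -> float:
    """|beta| with beta^2 var_parent / (beta^2 var_parent + var_child_base) = ve."""
    return float(np.sqrt(ve / (1.0 - ve) * var_child_base / var_parent))


def _plan_traits(cfg, binmap, truth, rng) -> List[dict]:
    specs = cfg.trait_specs
    if specs is None:
        specs = [TraitSpec(name=f"trait{i+1}") for i in range(cfg.n_traits)]
        if len(specs) >= 2:
            shared = int(rng.integers(0, binmap.n_bins))
            for s in specs[:2]:  # a pleiotropic locus shared by the first two traits
                s.causal_bins = [shared] + list(rng.integers(0, binmap.n_bins, size=max(s.n_causal - 1, 0)))
    models = []
    for s in specs:
        bins = s.causal_bins
        if bins is None:
            bins = list(rng.integers(0, binmap.n_bins, size=s.n_causal))
        gammas = [(int(b), 1.0) for b in bins]
        linked = s.linked_etrait
        if s.linked_regulator is not None:
            linked = truth.regulator_etraits[s.linked_regulator]
        models.append(
            {
                "name": s.name,
                "causal": gammas,
                "linked_etrait": linked,
                "link_ve": s.link_ve,
                "h2": s.h2,
            }
        )
    return models


def _topo_order(m: int, edges: List[Tuple[int, int, float]]) -> List[int]:
    children: dict = {}
    indeg = np.zeros(m, dtype=int)
    for r, t, _ in edges:
        children.setdefault(r, []).append(t)
        indeg[t] += 1
    order = [i for i in range(m) if indeg[i] == 0]
    head = 0
    while head < len(order):
        node = order[head]
        head += 1
        for ch in children.get(node, ()):
            indeg[ch] -= 1
            if indeg[ch] == 0:
                order.append(ch)
    if len(order) != m:
        raise ValueError("regulator edges contain a cycle")
    return order


def _line_noise(seed: int, label: str, size: int, stream: int = 4) -> np.ndarray:
    """Per-line noise stream keyed by the line label, not its position.

    Keying by label makes the generator equivariant: permuting the line
    order of the genotype input permutes the expression output identically.
    """
    key = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, key])).standard_normal(size)


def simulate_expression(G: GenotypeMatrix, truth: GroundTruth, cfg: SimConfig) -> ExpressionSet:
    """Generate log2 expression from the planted model.

    In topological order over the regulator DAG:
    e_g = mu_g + a_g * x_g + sum_r beta_gr * e_r + eps, with x in {-1, +1}
    and eps ~ Normal(0, noise_sd^2) on the log2 scale.
    """
    m = cfg.n_etraits
    X = G.numeric()
    n = X.shape[0]

    mu_rng = _rng(cfg.seed, 6)
    mu = mu_rng.normal(8.0, 1.0, size=m)

    noise = np.column_stack([_line_noise(cfg.seed, lab, m) for lab in G.lines]) * cfg.noise_sd
    # noise is (m, n): column j is the stream of line j

    parents: dict = {}
    for r, t, b in truth.edges:
        parents.setdefault(t, []).append((r, b))

    E = np.empty((m, n))
    x_anchor = X[:, truth.anchor_bin]  # (n, m)
    for g in _topo_order(m, truth.edges):
        e = mu[g] + truth.cis_coef[g] * x_anchor[:, g] + noise[g]
        for r, b in parents.get(g, ()):
            e = e + b * E[r]
        E[g] = e

    etrait_ids = [f"ET{i+1:05d}" for i in range(m)]
    values = pd.DataFrame(E, index=etrait_ids, columns=G.lines)

    anchors = pd.DataFrame(
        {
            "gene_id": [f"GENE{i+1:05d}" for i in range(m)],
            "chrom": pd.NA,
            "position": truth.anchor_pos.astype(float),
        },
        index=etrait_ids,
    )
    # chromosome labels come from the map via the anchor bin; the caller
    # attaches them through attach_anchors when the map is in scope
    presence = None
    if cfg.absent_fraction > 0:
        pres_rng = _rng(cfg.seed, 7)
        pres = np.full((m, n), "P", dtype=object)
        hit = pres_rng.random(m) < cfg.absent_fraction
        absent = pres_rng.random((m, n)) < 0.8
        pres[hit[:, None] & absent] = "A"
        presence = pd.DataFrame(pres, index=etrait_ids, columns=G.lines)
    return ExpressionSet(values, anchors, presence)


def attach_anchors(E: ExpressionSet, binmap: BinMap, truth: GroundTruth) -> ExpressionSet:
    """Fill anchor chromosome labels from the planted anchor bins."""
    chroms = binmap.table["chrom"].to_numpy()[truth.anchor_bin]
    anchors = E.anchors.copy()
    anchors["chrom"] = chroms[: len(anchors)]
    return ExpressionSet(E.values, anchors, E.presence)


def simulate_phenotypes(
    G: GenotypeMatrix, E: ExpressionSet, truth: GroundTruth, cfg: SimConfig
) -> PhenotypeTable:
    """Generate phenotypes: trait = sum gamma_b x_b + lambda * e_reg + noise.

    Effect sizes are rescaled so the genetic plus linked-expression part
    accounts for h2 of the trait variance; traits sharing a causal bin are
    pleiotropic by construction.
    """
    X = G.numeric()
    vals = E.values.to_numpy()
    n = X.shape[0]
    cols = {}
    for k, model in enumerate(truth.trait_models):
        genetic = np.zeros(n)
        for b, gamma in model["causal"]:
            genetic += gamma * X[:, b]
        signal = genetic
        if model["linked_etrait"] is not None and model["link_ve"] > 0:
            e = vals[model["linked_etrait"]]
            var_g = genetic.var() if model["causal"] else 0.0
            rest = var_g if var_g > 0 else 1.0
            lam = np.sqrt(model["link_ve"] / (1 - model["link_ve"]) * rest / e.var())
            signal = genetic + lam * (e - e.mean())
        var_sig = signal.var()
        if var_sig == 0:
            noise_sd = 1.0
        else:
            h2 = model["h2"]
            noise_sd = np.sqrt(var_sig * (1 - h2) / h2) if h2 > 0 else 1.0
        noise = np.array(
            [_line_noise(cfg.seed, lab, len(truth.trait_models), stream=5)[k] for lab in G.lines]
        )
        cols[model["name"]] = signal + noise_sd * noise
    return PhenotypeTable(pd.DataFrame(cols, index=G.lines))


def simulate_population(cfg: SimConfig):
    """End-to-end convenience: map, genotypes, truth, expression, phenotypes."""
    binmap = generate_bin_map(cfg)
    G = simulate_ril_genotypes(binmap, cfg)
    truth = plant_model(binmap, cfg)
    E = attach_anchors(simulate_expression(G, truth, cfg), binmap, truth)
    P = simulate_phenotypes(G, E, truth, cfg)
    return binmap, G, truth, E, P
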