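"""Synthetic networks and cohorts with planted neighbourhood mutation
signal, plus the parameter-sweep tile analysis.

The generative model mirrors the design used to calibrate the propagation
step: a two-ring star network (an unmutated hub gene, a first ring attached
to the hub, a second ring attached to the first ring) carries rare-variant
status that is planted independently per gene and subject with carrier
frequency ``f_case`` in cases and ``f_control`` in controls. Which rings are
mutated depends on the scenario: 1 = first ring only, 2 = second ring only,
3 = both. The hub itself is never mutated, so any case/control difference in
its smoothed score is created entirely by network propagation from its
neighbourhood; the difference is assessed with a two-sided rank-sum test and
Bonferroni correction over the sweep grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, ttest_ind

from .burden import BurdenMatrix
from .network import GeneNetwork, binarize_top_edges, degree_normalize
from .propagate import PropagationConfig, propagate

__all__ = [
    "SimulationSpec",
    "TileResult",
    "generate_fixture_network",
    "simulate_cohort",
    "hub_score_test",
    "parameter_sweep",
]

HUB = "HUB"


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated cohort.

    Defaults define a desk-scale experiment: 200 cases / 200 controls over a
    star topology with 10 first-ring and 50 second-ring genes, diffusion
    length 0.5 and no quantile normalization, 20 replicates per condition.
    """

    n_cases: int = 200
    n_controls: int = 200
    f_case: float = 0.5
    f_control: float = 0.05
    scenario: int = 3
    n_first_ring: int = 10
    n_second_ring: int = 50
    alpha: float = 0.5
    top_pct: float | None = None  # binarize a weighted substrate before diffusion
    quantile_normalize: bool = False
    n_reps: int = 20
    seed: int | None = None
    network: GeneNetwork | None = field(default=None, compare=False)
    hub: str = HUB

    def __post_init__(self):
        if not (0 <= self.f_case <= 1 and 0 <= self.f_control <= 1):
            raise ValueError("carrier frequencies must lie in [0, 1]")
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be positive")
        if self.network is not None and self.hub not in set(self.network.genes):
            raise ValueError(f"hub gene {self.hub!r} not in supplied network")


@dataclass
class TileResult:
    """Long-format sweep results, one row per grid cell and replicate."""

    table: pd.DataFrame
    n_tests: int

    def median_by_cell(self) -> pd.DataFrame:
        keys = [
            "scenario",
            "alpha",
            "top_pct",
            "quantile_normalize",
            "f_control",
            "f_case",
        ]
        agg = (
            self.table.groupby(keys, as_index=False, dropna=False)
            .agg(
                median_p_corrected=("p_corrected", "median"),
                n_significant=("significant", "sum"),
                n_reps=("rep", "count"),
            )
        )
        agg["neg_log10_p"] = -np.log10(agg["median_p_corrected"].clip(lower=1e-300))
        return agg


def generate_fixture_network(
    m: int = 61,
    topology: str = "star2",
    n_first_ring: int = 10,
    density: float = 0.1,
    seed: int | None = None,
) -> GeneNetwork:
    """Deterministic test/demo networks.

    ``star2``: hub + first ring of ``n_first_ring`` genes attached to the
    hub + second ring of ``m - n_first_ring - 1`` genes attached round-robin
    to the first ring, all unit weights. ``random_weighted``: Erdos-Renyi
    support at the given density with uniform(0, 1) weights.
    """
    if m < 3:
        raise ValueError("need at least 3 genes")
    if topology == "star2":
        n2 = m - n_first_ring - 1
        if n_first_ring < 1 or n2 < 1:
            raise ValueError(
                f"star2 with {m} genes cannot host {n_first_ring} first-ring genes"
            )
        genes = (
            [HUB]
            + [f"R1_{i:03d}" for i in range(n_first_ring)]
            + [f"R2_{i:03d}" for i in range(n2)]
        )
        index = {g: i for i, g in enumerate(genes)}
        edges = [(HUB, f"R1_{i:03d}") for i in range(n_first_ring)]
        edges += [
            (f"R1_{i % n_first_ring:03d}", f"R2_{i:03d}") for i in range(n2)
        ]
        rows, cols = [], []
        for a, b in edges:
            i, j = index[a], index[b]
            rows.extend((i, j))
            cols.extend((j, i))
        w = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
        # constructor sorts nothing: keep hub-first order for readability
        return GeneNetwork(np.array(genes, dtype=object), w, is_binary=True)
    if topology == "random_weighted":
        rng = np.random.default_rng(seed)
        genes = np.array([f"G{i:04d}" for i in range(m)], dtype=object)
        iu = np.triu_indices(m, k=1)
        present = rng.random(iu[0].size) < density
        weights = rng.random(iu[0].size)
        w = np.zeros((m, m))
        w[iu[0][present], iu[1][present]] = weights[present]
        w = w + w.T
        return GeneNetwork(genes, sp.csr_matrix(w))
    raise ValueError(f"unknown topology {topology!r}")


def _tier_genes(net: GeneNetwork, hub: str, scenario: int) -> list[str]:
    import networkx as nx

    g = net.to_networkx()
    dist = nx.single_source_shortest_path_length(g, hub, cutoff=2)
    first = [n for n, d in dist.items() if d == 1]
    second = [n for n, d in dist.items() if d == 2]
    tiers = {1: first, 2: second, 3: first + second}
    return tiers[scenario]


def simulate_cohort(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[BurdenMatrix, np.ndarray]:
    """Draw one cohort: planted burden matrix plus case/control labels.

    Mutated-tier genes carry status 1 independently with probability
    ``f_case`` (cases) or ``f_control`` (controls); the hub and all
    off-tier genes stay zero. Returns (burden, phenotype) with cases first.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    net = spec.network
    if net is None:
        net = generate_fixture_network(
            m=1 + spec.n_first_ring + spec.n_second_ring,
            topology="star2",
            n_first_ring=spec.n_first_ring,
        )
    genes = net.genes
    tier = _tier_genes(net, spec.hub, spec.scenario)
    tier_idx = np.array([net.index_of(g) for g in tier], dtype=int)
    s = spec.n_cases + spec.n_controls
    phenotype = np.concatenate(
        [np.ones(spec.n_cases), np.zeros(spec.n_controls)]
    )
    values = np.zeros((s, len(genes)))
    freq = np.where(phenotype == 1, spec.f_case, spec.f_control)
    draws = rng.random((s, tier_idx.size)) < freq[:, None]
    values[:, tier_idx] = draws
    subjects = np.array(
        [f"case_{i:04d}" for i in range(spec.n_cases)]
        + [f"ctrl_{i:04d}" for i in range(spec.n_controls)],
        dtype=object,
    )
    burden = BurdenMatrix(subjects, genes, sp.csr_matrix(values), encoding="status")
    return burden, phenotype


def hub_score_test(
    scores,
    phenotype: np.ndarray,
    hub: str = HUB,
    n_tests_for_bonferroni: int = 1,
    method: str = "ranksum",
) -> tuple[float, float, float]:
    """Case/control difference in the hub gene's smoothed score.

    Two-sided Mann-Whitney rank-sum test by default (``method='ttest'`` for
    sensitivity analysis); the p-value is Bonferroni-multiplied by the number
    of sweep cells and capped at 1. Identical constant scores in both groups
    give p = 1 by convention.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if hasattr(scores, "values") and hasattr(scores, "genes"):
        col = np.flatnonzero(scores.genes == hub)
        if col.size != 1:
            raise KeyError(f"hub gene {hub!r} not found in scores")
        x = np.asarray(scores.values)[:, col[0]]
    else:
        x = np.asarray(scores, dtype=float).ravel()
    cases = x[phenotype == 1]
    ctrls = x[phenotype == 0]
    if cases.size == 0 or ctrls.size == 0:
        raise ValueError("both classes must be present")
    if np.ptp(x) == 0:
        return 0.0, 1.0, 1.0
    if method == "ranksum":
        stat, p = mannwhitneyu(cases, ctrls, alternative="two-sided")
    elif method == "ttest":
        stat, p = ttest_ind(cases, ctrls)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(p)
    return float(stat), p, min(1.0, p * n_tests_for_bonferroni)


def parameter_sweep(
    base: SimulationSpec,
    f_case_grid,
    f_control_grid,
    alphas=(0.5,),
    scenarios=(3,),
    top_pcts=(None,),
    quantile_normalize=(False,),
    n_reps: int | None = None,
    seed: int | None = None,
    sig_level: float = 0.05,
    method: str = "ranksum",
) -> TileResult:
    """Tile sweep over planted frequencies and propagation settings.

    Every cell (scenario, alpha, quantile-normalization flag, f_control,
    f_case) is simulated ``n_reps`` times; each replicate runs cohort
    generation, propagation and the hub-score test, with the Bonferroni
    multiplier equal to the number of cells in the sweep.
    """
    f_case_grid = list(f_case_grid)
    f_control_grid = list(f_control_grid)
    cells = list(
        itertools.product(
            scenarios, alphas, top_pcts, quantile_normalize,
            f_control_grid, f_case_grid,
        )
    )
    if not cells:
        raise ValueError("empty sweep grid")
    n_tests = len(cells)
    if n_reps is None:
        n_reps = base.n_reps
    rng = np.random.default_rng(base.seed if seed is None else seed)
    rows = []
    for scenario, alpha, top_pct, qn, f_ctrl, f_case in cells:
        spec = replace(
            base,
            scenario=scenario,
            alpha=alpha,
            top_pct=top_pct,
            quantile_normalize=qn,
            f_case=f_case,
            f_control=f_ctrl,
        )
        for rep in range(n_reps):
            burden, phenotype = simulate_cohort(spec, rng=rng)
            net = spec.network
            if net is None:
                net = generate_fixture_network(
                    m=1 + spec.n_first_ring + spec.n_second_ring,
                    topology="star2",
                    n_first_ring=spec.n_first_ring,
                )
            if top_pct is not None and not net.is_binary:
                net = binarize_top_edges(net, top_pct)
            cfg = PropagationConfig(alpha=alpha, quantile_normalize=qn)
            scores = propagate(burden, degree_normalize(net), cfg)
            stat, p, p_corr = hub_score_test(
                scores,
                phenotype,
                hub=spec.hub,
                n_tests_for_bonferroni=n_tests,
                method=method,
            )
            rows.append(
                {
                    "scenario": scenario,
                    "alpha": alpha,
                    "top_pct": top_pct,
                    "quantile_normalize": qn,
                    "f_control": f_ctrl,
                    "f_case": f_case,
                    "rep": rep,
                    "statistic": stat,
                    "p": p,
                    "p_corrected": p_corr,
                    "significant": p_corr < sig_level,
                }
            )
    return TileResult(table=pd.DataFrame(rows), n_tests=n_tests)
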