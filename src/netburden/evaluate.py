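"""Downstream characterization of selected genes.

Three independent lines of evidence for a selected gene set:

- added value over established covariates, via a likelihood-ratio test
  between nested logistic models (baseline covariates vs baseline plus the
  gene's smoothed score) with McFadden pseudo-R-squared for both models;
- network coherence, via a randomization test on the overlap between the
  selected set and the interaction neighbourhood of a seed gene;
- functional enrichment, via one-sided Fisher exact tests against curated
  gene sets (GMT format) with Benjamini-Hochberg control and an optional
  random-query calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .network import GeneNetwork, neighbourhood

__all__ = [
    "ModelComparison",
    "RandomizationTest",
    "compare_models",
    "neighbour_overlap_test",
    "enrichment_test",
    "enrichment_randomization",
    "read_gmt",
]


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of nested logistic models."""

    covariates: list
    lr_statistic: float
    chi_squared_p: float
    chi_squared_p_corrected: float
    pseudo_r2_baseline: float
    pseudo_r2_extended: float
    bonferroni_multiplier: int
    separation_flag: bool = False


@dataclass
class RandomizationTest:
    """Observed statistic against an empirical null distribution."""

    observed_statistic: float
    null_values: np.ndarray
    empirical_p: float

    @property
    def null_draws(self) -> int:
        return len(self.null_values)


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return np.sort(piv[:rank])


def _fit_logit(y, X):
    # rank-reduce first: a dependent column leaves the likelihood unchanged
    keep = _independent_columns(X)
    model = sm.Logit(y, X[:, keep])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            separated = not np.isfinite(res.llf)
        except Exception:
            res = model.fit(disp=0, maxiter=500, method="bfgs")
            separated = True
    return res, separated


def compare_models(
    phenotype,
    covariates,
    gene_score,
    n_genes_tested: int = 1,
) -> ModelComparison:
    """Added value of one smoothed gene score over baseline covariates.

    Fits ``phenotype ~ covariates`` and ``phenotype ~ covariates + score``
    (both with intercept) on complete cases, compares them with a
     1-degree-of-freedom likelihood-ratio chi-squared test (Bonferroni
    multiplied by ``n_genes_tested``), and reports McFadden pseudo-R-squared
    (1 - ll_model / ll_null) for both fits.
    """
    y = np.asarray(phenotype, dtype=float)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    score = np.asarray(gene_score, dtype=float)
    if len(y) != len(cov) or len(y) != len(score):
        raise ValueError("phenotype, covariates and score lengths differ")
    frame = cov.copy()
    frame["_score"] = score
    frame["_y"] = y
    complete = frame.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d incomplete-case subjects", n_dropped
        )
    frame = frame[complete]
    y = frame.pop("_y").to_numpy()
    score = frame.pop("_score").to_numpy()
    x_base = sm.add_constant(frame.to_numpy(dtype=float), has_constant="add")
    x_ext = np.column_stack([x_base, score])
    base, sep_b = _fit_logit(y, x_base)
    ext, sep_e = _fit_logit(y, x_ext)
    null_ll = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
    lr = 2.0 * (ext.llf - base.llf)
    lr = max(0.0, float(lr))
    from scipy.stats import chi2

    p = float(chi2.sf(lr, df=1))
    separated = bool(sep_b or sep_e)
    if separated:
        p = max(p, np.finfo(float).tiny)
    return ModelComparison(
        covariates=list(cov.columns),
        lr_statistic=lr,
        chi_squared_p=p,
        chi_squared_p_corrected=min(1.0, p * n_genes_tested),
        pseudo_r2_baseline=float(1.0 - base.llf / null_ll) if null_ll != 0 else 0.0,
        pseudo_r2_extended=float(1.0 - ext.llf / null_ll) if null_ll != 0 else 0.0,
        bonferroni_multiplier=n_genes_tested,
        separation_flag=separated,
    )


def neighbour_overlap_test(
    selected,
    seed_gene: str,
    net: GeneNetwork,
    radius: int = 2,
    universe=None,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> RandomizationTest:
    """Is the selected set enriched in the seed gene's interactome?

    Observed statistic: |selected ∩ neighbourhood(seed_gene, radius)|. Null:
    the same count for ``n_draws`` uniformly drawn gene sets of equal size
    from the tested-gene universe (default: all network genes). Empirical
    p = (1 + #{null >= observed}) / (n_draws + 1), never zero.
    """
    selected = set(selected)
    hood = neighbourhood(net, seed_gene, radius=radius)
    if universe is None:
        universe = list(net.genes)
    universe = np.asarray(sorted(set(universe)), dtype=object)
    in_universe = selected & set(universe)
    n_excluded = len(selected) - len(in_universe)
    if n_excluded:
        import logging

        logging.getLogger(__name__).info(
            "excluded %d selected genes outside the universe", n_excluded
        )
    observed = len(in_universe & hood)
    hood_mask = np.isin(universe, sorted(hood))
    rng = np.random.default_rng(seed)
    k = len(in_universe)
    null = np.empty(n_draws, dtype=int)
    for i in range(n_draws):
        draw = rng.choice(len(universe), size=k, replace=False)
        null[i] = int(hood_mask[draw].sum())
    p = (1 + int((null >= observed).sum())) / (n_draws + 1)
    return RandomizationTest(
        observed_statistic=float(observed), null_values=null, empirical_p=p
    )


def enrichment_test(
    query,
    annotation_sets: dict,
    background,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact overrepresentation per annotation set.

    Annotation sets are intersected with the background before testing;
    ``expected`` is |query| * |set| / |background|; p-values are adjusted by
    Benjamini-Hochberg across sets. Returns a DataFrame with columns
    set, hits, set_size, expected, odds_ratio, p, p_adjusted, significant.
    """
    background = set(background)
    if not background:
        raise ValueError("background universe is empty")
    query = set(query) & background
    n_bg = len(background)
    rows = []
    for name, genes in annotation_sets.items():
        genes = set(genes) & background
        hits = len(query & genes)
        a = hits
        b = len(query) - hits
        c = len(genes) - hits
        d = n_bg - len(query) - len(genes) + hits
        if len(genes) in (0, n_bg) or len(query) in (0, n_bg):
            odds, p = np.nan, 1.0
        else:
            odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "set": name,
                "hits": hits,
                "set_size": len(genes),
                "expected": len(query) * len(genes) / n_bg,
                "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
                "p": float(p),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] < fdr
    return df


def enrichment_randomization(
    query_size: int,
    annotation_sets: dict,
    background,
    observed_p: dict | None = None,
    n_draws: int = 1000,
    seed: int | None = None,
) -> dict[str, RandomizationTest]:
    """Random-query calibration of enrichment p-values.

    Draws ``n_draws`` random query sets of ``query_size`` genes from the
    background and records, per annotation set, the Fisher p-value
    distribution. When ``observed_p`` maps set names to the real query's
    p-values, each set's empirical p is the (+1-corrected) fraction of
    random replicates at least as enriched (null p <= observed p).
    """
    background = sorted(set(background))
    if query_size > len(background):
        raise ValueError("query_size exceeds the background size")
    rng = np.random.default_rng(seed)
    bg_arr = np.asarray(background, dtype=object)
    null_ps: dict[str, list[float]] = {name: [] for name in annotation_sets}
    for _ in range(n_draws):
        draw = set(bg_arr[rng.choice(len(bg_arr), size=query_size, replace=False)])
        res = enrichment_test(draw, annotation_sets, background)
        for name, p in zip(res["set"], res["p"]):
            null_ps[name].append(float(p))
    out = {}
    for name, ps in null_ps.items():
        ps = np.asarray(ps)
        obs = float(observed_p[name]) if observed_p and name in observed_p else np.nan
        if np.isnan(obs):
            emp = np.nan
        else:
            emp = (1 + int((ps <= obs).sum())) / (n_draws + 1)
        out[name] = RandomizationTest(
            observed_statistic=obs, null_values=ps, empirical_p=emp
        )
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
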