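"""Posterior comparison of two fitted strains: mean change, noise change,
EFDR calibration, and the noise-only-change classifier.

For each gene the stored draws of the two fits are paired by index and the
statistics are

* ``mean_log2fc`` — median over draws of ``log2(mu_A / mu_B)``,
* ``resdisp_distance`` — median over paired draws of ``eps_A - eps_B``
  (the noise difference after correcting for mean dependence),
* ``p_mean`` — posterior probability that ``|log2(mu_A/mu_B)| > tau0``,
* ``p_noise`` — posterior probability that ``|eps_A - eps_B| > omega0``.

Decision thresholds on the tail probabilities are calibrated so the
expected false discovery rate (EFDR) of the discovery set matches a target
level (default 0.01).  A gene is *MeanChange* when its mean change is
significant (regardless of noise), *NoiseOnly* when its noise change is
significant but its mean change is not — the signature of functionally
compensated regulation — and *NoChange* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSet, filter_expressed
from .model import ModelSpec, PosteriorSummary, estimate_size_factors, fit_noise_model

__all__ = [
    "CALLS",
    "EFDRCalibration",
    "PairComparison",
    "compare_strains",
    "calibrate_efdr",
    "classify_changes",
    "change_proportion",
    "compare_pair",
]

CALLS = ("MeanChange", "NoiseOnly", "NoChange", "Excluded")

DEFAULT_TAU0 = 0.4     # log2 fold-change deemed negligible
DEFAULT_OMEGA0 = 0.4   # residual-over-dispersion distance deemed negligible


@dataclass
class EFDRCalibration:
    """A calibrated posterior-probability cutoff.

    ``achieved_efdr`` is ``sum (1-p_i) 1[p_i >= alpha] / max(1, #{p_i >= alpha})``
    at the chosen cutoff ``prob_threshold``.
    """

    target: float
    prob_threshold: float
    achieved_efdr: float
    on_target: bool = True  # False when no grid point reaches the target level


def _achieved_efdr(p: np.ndarray, alpha: float) -> float:
    disc = p >= alpha
    return float(((1.0 - p) * disc).sum() / max(1, int(disc.sum())))


def calibrate_efdr(
    p,
    target: float = 0.01,
    grid: np.ndarray | None = None,
) -> EFDRCalibration:
    """Grid-search the probability cutoff whose EFDR is closest to ``target``.

    The grid defaults to 0.50, 0.51, ..., 0.99.  Ties are broken toward the
    larger (stricter) cutoff.  An empty discovery set has EFDR 0 by the
    ``max(1, .)`` convention.
    """
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("tail probabilities must lie in [0, 1]")
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie in (0, 1)")
    if grid is None:
        grid = np.round(np.arange(0.50, 1.00, 0.01), 10)
    efdrs = np.array([_achieved_efdr(p, a) for a in grid])
    dist = np.abs(efdrs - target)
    # closest to target; ties -> larger alpha
    best = len(grid) - 1 - int(np.argmin(dist[::-1]))
    on_target = bool(efdrs.min() <= target)
    return EFDRCalibration(
        target=target,
        prob_threshold=float(grid[best]),
        achieved_efdr=float(efdrs[best]),
        on_target=on_target,
    )


def compare_strains(
    psA: PosteriorSummary,
    psB: PosteriorSummary,
    genes: GeneSet,
    tau0: float = DEFAULT_TAU0,
    omega0: float = DEFAULT_OMEGA0,
) -> pd.DataFrame:
    """Per-gene differential table for strains A vs B (uncalled).

    Draws are paired by stored index, so both posteriors must hold the same
    number of draws.  Genes in ``genes`` missing from either posterior are
    reported as ``Excluded`` with NaN statistics.  Swapping A and B negates
    ``mean_log2fc`` and ``resdisp_distance`` and leaves the probabilities
    unchanged.
    """
    if psA.n_draws != psB.n_draws:
        raise ValueError(
            f"stored draw counts differ ({psA.n_draws} vs {psB.n_draws}); "
            "fit both strains with the same chain settings"
        )
    gene_list = sorted(genes.members)
    inA = {g: i for i, g in enumerate(psA.gene_ids)}
    inB = {g: i for i, g in enumerate(psB.gene_ids)}
    shared = [g for g in gene_list if g in inA and g in inB]
    ia = np.array([inA[g] for g in shared], dtype=int)
    ib = np.array([inB[g] for g in shared], dtype=int)

    l2fc = (np.log(psA.mu[:, ia]) - np.log(psB.mu[:, ib])) / np.log(2.0)
    dres = psA.eps[:, ia] - psB.eps[:, ib]

    out = pd.DataFrame(
        index=pd.Index(gene_list, name="gene"),
        columns=["mean_log2fc", "resdisp_distance", "p_mean", "p_noise", "call"],
    )
    out.loc[shared, "mean_log2fc"] = np.median(l2fc, axis=0)
    out.loc[shared, "resdisp_distance"] = np.median(dres, axis=0)
    out.loc[shared, "p_mean"] = (np.abs(l2fc) > tau0).mean(axis=0)
    out.loc[shared, "p_noise"] = (np.abs(dres) > omega0).mean(axis=0)
    out["call"] = "Excluded"
    out.loc[shared, "call"] = ""
    for col in ("mean_log2fc", "resdisp_distance", "p_mean", "p_noise"):
        out[col] = out[col].astype(float)
    return out


def classify_changes(
    dt: pd.DataFrame,
    cal_mean: EFDRCalibration,
    cal_noise: EFDRCalibration,
) -> pd.DataFrame:
    """Assign a change class to every tested gene.

    Mean change is significant when ``p_mean >= cal_mean.prob_threshold``;
    likewise for noise.  ``MeanChange`` means *at least* mean change (genes
    with both changes are MeanChange, not NoiseOnly); ``NoiseOnly`` requires
    significant noise without significant mean change.
    """
    out = dt.copy()
    tested = out["call"] != "Excluded"
    mean_sig = tested & (out["p_mean"] >= cal_mean.prob_threshold)
    noise_sig = tested & (out["p_noise"] >= cal_noise.prob_threshold)
    out.loc[tested, "call"] = "NoChange"
    out.loc[noise_sig & ~mean_sig, "call"] = "NoiseOnly"
    out.loc[mean_sig, "call"] = "MeanChange"
    out["noise_significant"] = noise_sig
    out["mean_significant"] = mean_sig
    return out


def change_proportion(changes: GeneSet, universe: GeneSet) -> float:
    """``|changes ∩ universe| / |universe|``."""
    if len(universe) == 0:
        raise ValueError("empty universe")
    if not changes.members <= universe.members:
        raise ValueError("changes must be a subset of the universe")
    return len(changes.members & universe.members) / len(universe)


@dataclass
class PairComparison:
    """Everything produced by one wildtype-vs-deletion comparison."""

    table: pd.DataFrame
    cal_mean: EFDRCalibration
    cal_noise: EFDRCalibration
    genes: GeneSet
    posteriors: dict[str, PosteriorSummary]


def compare_pair(
    cm: CountMatrix,
    meta: pd.DataFrame,
    strain_pair: tuple[str, str],
    spec: ModelSpec,
    efdr_target: float = 0.01,
    min_detect_fraction: float = 0.01,
    tau0: float = DEFAULT_TAU0,
    omega0: float = DEFAULT_OMEGA0,
    pool_sizes=None,
) -> PairComparison:
    """Full single-comparison workflow on the given cells.

    Filters expressed genes for the pair, estimates size factors and fits
    the noise model per strain, compares the posteriors, calibrates the
    EFDR cutoffs on the comparison's own tail probabilities, and classifies
    every tested gene.
    """
    strain_of = dict(zip(meta["cell_id"], meta["strain"]))
    genes = filter_expressed(cm, meta, strain_pair, min_detect_fraction)
    if len(genes) == 0:
        raise ValueError(f"no genes pass the expression filter for {strain_pair}")
    posts: dict[str, PosteriorSummary] = {}
    for st in strain_pair:
        cells = [c for c in cm.cell_ids if strain_of[c] == st]
        sub = cm.subset_cells(cells).subset_genes(sorted(genes.members))
        sf = estimate_size_factors(sub, pool_sizes)
        posts[st] = fit_noise_model(sub, meta, sf, spec)
    dt = compare_strains(posts[strain_pair[0]], posts[strain_pair[1]], genes, tau0, omega0)
    cal_mean = calibrate_efdr(dt["p_mean"].dropna().to_numpy(), efdr_target)
    cal_noise = calibrate_efdr(dt["p_noise"].dropna().to_numpy(), efdr_target)
    called = classify_changes(dt, cal_mean, cal_noise)
    return PairComparison(called, cal_mean, cal_noise, genes, posts)


def call_sets(dt: pd.DataFrame) -> dict[str, GeneSet]:
    """Gene sets per call class from a called differential table."""
    return {
        call: GeneSet(call, set(dt.index[dt["call"] == call]))
        for call in CALLS
    }
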