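"""Manifold-consistent kinetics (MacK) scoring and cell-specific rates.

A gene's velocity is manifold-consistent when its sign agrees with the sign
of the expression change per unit time toward neighboring cells on the
manifold.  For gene g and cell i with neighbors 𝓝_i,

    score_i(g) = (1/n_i) Σ_{j∈𝓝_i} I[ sgn(Δx_ij^g / Δt_ij) = sgn(v_i^g) ],

with Δx_ij = x_j − x_i, Δt_ij = t_j − t_i from any monotone per-cell time
(pseudotime, latent time, lineage-tracing time, or a viral-load proxy).  The
gene score is the unweighted mean of score_i over evaluable cells.  Genes
scoring high are candidates for anchoring whole-genome velocity inference;
genes scoring low typically violate constant-rate splicing assumptions
(transcription bursts, regulated degradation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CellStateSet, NeighborGraph, VelocityField

__all__ = [
    "TimeVector",
    "MacKResult",
    "KineticRates",
    "mack_score",
    "select_mack_genes",
    "cell_specific_rates",
    "modality_fraction",
]


@dataclass
class TimeVector:
    """Per-cell (pseudo)time in arbitrary monotone units."""

    t: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if not np.isfinite(self.t).all():
            raise ValueError("time vector contains non-finite values")
        if np.ptp(self.t) == 0:
            raise ValueError("time vector is constant")


@dataclass
class MacKResult:
    gene_ids: list[str]
    scores: np.ndarray            # per-gene, in [0, 1]
    cell_scores: np.ndarray       # per-cell-per-gene agreement fractions (NaN = abstained)
    n_evaluated: np.ndarray       # per-gene count of (cell, neighbor) pairs used

    def as_series(self):
        import pandas as pd

        return pd.Series(self.scores, index=self.gene_ids, name="mack_score")


@dataclass
class KineticRates:
    """Cell-specific transcription (α) and degradation (γ) rates.

    γ is NaN where the mature abundance is below a stability floor.
    """

    alpha: np.ndarray
    gamma: np.ndarray
    beta: float = 1.0
    gamma_defined: np.ndarray | None = None


def mack_score(
    states_g: CellStateSet,
    vel_g: VelocityField,
    time: TimeVector,
    graph: NeighborGraph,
    zero_handling: str = "abstain",
) -> MacKResult:
    """MacK score per gene; see module docstring for the definition.

    Pairs with Δt_ij = 0 are skipped.  With ``zero_handling='abstain'``
    (default) pairs where exactly one of sgn(Δx/Δt), sgn(v) is zero are
    excluded; both-zero pairs count as matches.  With ``'strict'`` all
    Δt≠0 pairs count and zeros match only zeros.
    """
    graph.check_cells(states_g)
    vel_g.check_paired(states_g)
    if time.t.shape[0] != states_g.n_cells:
        raise ValueError("time vector length does not match cell count")
    if zero_handling not in ("abstain", "strict"):
        raise ValueError("zero_handling must be 'abstain' or 'strict'")

    x = states_g.values                      # (n, g)
    v = vel_g.values
    idx = graph.indices                      # (n, k)
    dt = time.t[idx] - time.t[:, None]       # (n, k)
    valid_dt = dt != 0
    if not valid_dt.any(axis=1).any():
        raise ValueError("all neighbor time differences are zero")

    dx = x[idx] - x[:, None, :]              # (n, k, g)
    slope_sign = np.sign(dx) * np.sign(dt)[:, :, None]
    v_sign = np.sign(v)[:, None, :]          # (n, 1, g)

    match = slope_sign == v_sign
    evaluated = np.broadcast_to(valid_dt[:, :, None], match.shape).copy()
    if zero_handling == "abstain":
        one_sided_zero = (slope_sign == 0) ^ (v_sign == 0)
        evaluated &= ~one_sided_zero
    n_pairs = evaluated.sum(axis=1)          # (n, g)
    n_match = (match & evaluated).sum(axis=1)
    with np.errstate(invalid="ignore"):
        cell_scores = np.where(n_pairs > 0, n_match / np.maximum(n_pairs, 1), np.nan)
    cell_scores[n_pairs == 0] = np.nan

    import warnings

    with warnings.catch_warnings():
        # genes where every cell abstained produce an all-NaN column; the
        # resulting NaN is mapped to 0 below, so silence the empty-slice note
        warnings.simplefilter("ignore", RuntimeWarning)
        scores = np.nanmean(cell_scores, axis=0)
    scores = np.where(np.isnan(scores), 0.0, scores)
    return MacKResult(
        gene_ids=list(states_g.feature_ids),
        scores=scores,
        cell_scores=cell_scores,
        n_evaluated=n_pairs.sum(axis=0),
    )


def select_mack_genes(
    result: MacKResult,
    top_n: int | None = None,
    threshold: float | None = None,
) -> list[str]:
    """Genes sorted by score descending (ties by gene id), filtered.

    Exactly one of ``top_n``/``threshold`` must be given; ``top_n`` larger
    than the gene count is clipped with a warning.
    """
    if (top_n is None) == (threshold is None):
        raise ValueError("give exactly one of top_n or threshold")
    order = sorted(
        range(len(result.gene_ids)),
        key=lambda i: (-result.scores[i], result.gene_ids[i]),
    )
    ranked = [(result.gene_ids[i], result.scores[i]) for i in order]
    if top_n is not None:
        if top_n > len(ranked):
            import warnings

            warnings.warn(
                f"top_n={top_n} exceeds gene count {len(ranked)}; clipped",
                RuntimeWarning,
            )
            top_n = len(ranked)
        return [g for g, _ in ranked[:top_n]]
    return [g for g, s in ranked if s >= threshold]


def cell_specific_rates(
    u: np.ndarray,
    s: np.ndarray,
    du_dt: np.ndarray,
    ds_dt: np.ndarray,
    beta: float = 1.0,
    s_floor_frac: float = 1e-6,
) -> KineticRates:
    """Per-cell kinetic rates from the splicing ODE, inverted pointwise.

    From du/dt = α − βu and ds/dt = βu − γs:
        α_i = du/dt_i + β u_i ,   γ_i = (β u_i − ds/dt_i) / s_i .
    γ is flagged undefined (NaN) where s_i < s_floor_frac · max(s).
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    du_dt = np.asarray(du_dt, dtype=float)
    ds_dt = np.asarray(ds_dt, dtype=float)
    alpha = du_dt + beta * u
    floor = s_floor_frac * (s.max() if s.size else 0.0)
    defined = s > floor
    gamma = np.full_like(s, np.nan)
    gamma[defined] = (beta * u[defined] - ds_dt[defined]) / s[defined]
    return KineticRates(alpha=alpha, gamma=gamma, beta=beta, gamma_defined=defined)


def modality_fraction(states: CellStateSet, feature_set: list[str]) -> np.ndarray:
    """Per-cell fraction of total signal carried by a feature subset.

    E.g. the percentage of viral transcripts per cell, used as an infection
    time proxy.  Cells with zero total get 0.
    """
    if len(feature_set) == 0:
        raise ValueError("feature_set is empty")
    missing = set(feature_set) - set(states.feature_ids)
    if missing:
        raise KeyError(f"features not in dataset: {sorted(missing)}")
    if (states.values < 0).any():
        raise ValueError("modality_fraction requires nonnegative counts")
    cols = [states.feature_ids.index(f) for f in feature_set]
    subset = states.values[:, cols].sum(axis=1)
    total = states.values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, subset / np.maximum(total, 1e-300), 0.0)
    return frac
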