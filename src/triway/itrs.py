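"""Information-theoretic threshold learning (ITRS).

The (α,β) thresholds are chosen to minimize the total region uncertainty

    Δ(α,β) = Δ_P + Δ_N + Δ_B,   Δ_R = P(R) · δ_R,

where P(R) is the probability mass of region R and δ_R is the conditional
uncertainty of the concept split {C, C^c} inside R — Shannon entropy in
bits, H(p) = −p log2 p − (1−p) log2(1−p), or the Gini coefficient
G(p) = 1 − p² − (1−p)², with p = P(C|R).  An empty region contributes 0.

Because the regions only change when a threshold crosses one of the block
probabilities, Δ is piecewise constant in (α,β) and the exact optimum is
found by exhaustively scoring every valid pair drawn from the distinct
block probabilities augmented with {0, 1}.  A dense uniform grid is kept
as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .table import Concept, ConfigurationError, Partition, ValidationError, conditional_probability
from .regions import ThresholdPair, TriPartition, probabilistic_regions, _TOL

__all__ = [
    "UncertaintyReport",
    "ItrsResult",
    "binary_uncertainty",
    "region_uncertainty",
    "itrs_learn_thresholds",
]


def binary_uncertainty(p: float, measure: str) -> float:
    """Uncertainty of a two-way split with success probability ``p``.

    Shannon entropy in bits, or Gini; 0·log 0 = 0 by convention.
    """
    if measure == "shannon":
        if p <= 0.0 or p >= 1.0:
            return 0.0
        return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))
    if measure == "gini":
        return float(1.0 - p * p - (1 - p) * (1 - p))
    raise ConfigurationError(f"unknown uncertainty measure {measure!r}")


@dataclass(frozen=True)
class UncertaintyReport:
    """Region probabilities, per-region uncertainties and their weighted sum."""

    measure: str
    region_probs: tuple[float, float, float]  # P(POS), P(NEG), P(BND)
    delta_p: float
    delta_n: float
    delta_b: float

    @property
    def weighted(self) -> tuple[float, float, float]:
        pp, pn, pb = self.region_probs
        return (pp * self.delta_p, pn * self.delta_n, pb * self.delta_b)

    @property
    def total(self) -> float:
        return float(sum(self.weighted))


def region_uncertainty(tri: TriPartition, concept: Concept, measure: str) -> UncertaintyReport:
    """Evaluate the Δ decomposition for an existing trisection."""
    universe = tri.universe
    if not universe:
        raise ValidationError("uncertainty undefined on an empty universe")
    if universe != concept.universe:
        raise ValidationError("trisection and concept cover different universes")
    n = len(universe)
    probs, deltas = [], []
    for region in (tri.pos, tri.neg, tri.bnd):
        w = len(region) / n
        probs.append(w)
        if not region:
            deltas.append(0.0)  # empty region: defined as zero uncertainty
        else:
            p = len(region & concept.members) / len(region)
            deltas.append(binary_uncertainty(p, measure))
    return UncertaintyReport(measure, tuple(probs), *deltas)


@dataclass(frozen=True)
class ItrsResult:
    thresholds: ThresholdPair
    report: UncertaintyReport
    candidates_examined: int
    tie_set: tuple[ThresholdPair, ...]
    degenerate: bool = False


def _uncertainty_vec(p: np.ndarray, measure: str) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    if measure == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -p * np.log2(p) - (1 - p) * np.log2(1 - p)
        return np.nan_to_num(h, nan=0.0, posinf=0.0, neginf=0.0)
    if measure == "gini":
        return 1.0 - p * p - (1 - p) * (1 - p)
    raise ConfigurationError(f"unknown uncertainty measure {measure!r}")


def delta_surface(
    block_probs: np.ndarray,
    block_weights: np.ndarray,
    alphas: np.ndarray,
    betas: np.ndarray,
    measure: str,
) -> np.ndarray:
    """Δ(α,β) for every alpha x beta combination, vectorized.

    Invalid pairs (β >= α) are set to +inf.  Region assignment uses the
    same >= α − tol / <= β + tol rule as :func:`probabilistic_regions`.
    """
    p = np.asarray(block_probs, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    c = w * p  # concept mass per block
    total_w, total_c = w.sum(), c.sum()

    pos_mask = p[None, :] >= alphas[:, None] - _TOL  # (A, n)
    wp = pos_mask @ w
    cp = pos_mask @ c
    neg_mask = p[None, :] <= betas[:, None] + _TOL  # (B, n)
    wn = neg_mask @ w
    cn = neg_mask @ c

    pp = np.divide(cp, wp, out=np.zeros_like(cp), where=wp > 0)
    pn = np.divide(cn, wn, out=np.zeros_like(cn), where=wn > 0)
    dp = np.where(wp > 0, wp * _uncertainty_vec(pp, measure), 0.0)
    dn = np.where(wn > 0, wn * _uncertainty_vec(pn, measure), 0.0)
    wb = total_w - wp[:, None] - wn[None, :]
    cb = total_c - cp[:, None] - cn[None, :]
    wb = np.clip(wb, 0.0, None)
    pb = np.divide(cb, wb, out=np.zeros_like(cb), where=wb > 0)
    db = np.where(wb > 1e-15, wb * _uncertainty_vec(pb, measure), 0.0)
    delta = dp[:, None] + dn[None, :] + db
    invalid = betas[None, :] >= alphas[:, None] - _TOL
    return np.where(invalid, np.inf, delta)


def _blocks_to_arrays(partition: Partition, concept: Concept) -> tuple[np.ndarray, np.ndarray]:
    n = len(partition.universe)
    probs = np.array(
        [float(conditional_probability(b, concept)) for b in partition.blocks]
    )
    weights = np.array([len(b) / n for b in partition.blocks])
    return probs, weights


def itrs_learn_thresholds(
    partition: Partition,
    concept: Concept,
    measure: str = "shannon",
    search: str = "candidate_grid",
    grid_step: float = 0.01,
) -> ItrsResult:
    """Find argmin Δ(α,β) over the candidate set.

    ``candidate_grid`` scores all valid pairs drawn from the distinct block
    probabilities augmented with {0, 1} — sufficient because Δ is piecewise
    constant between adjacent block probabilities.  ``dense_grid`` scores a
    uniform grid of resolution ``grid_step`` (the cross-check oracle).
    Ties are broken toward largest α, then smallest β (closest to Pawlak).
    """
    if not partition.blocks:
        raise ValidationError("cannot learn thresholds on an empty partition")
    probs, weights = _blocks_to_arrays(partition, concept)

    if search == "candidate_grid":
        candidates = np.unique(np.concatenate([probs, [0.0, 1.0]]))
        alphas = candidates
        betas = candidates
    elif search == "dense_grid":
        grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
        alphas = grid
        betas = grid
    else:
        raise ConfigurationError(f"unknown search {search!r}")

    surface = delta_surface(probs, weights, alphas, betas, measure)
    finite = np.isfinite(surface)
    if not finite.any():
        # no valid (beta < alpha) pair in the candidate set
        fallback = ThresholdPair(1.0, 0.0)
        tri = probabilistic_regions(partition, concept, fallback)
        return ItrsResult(fallback, region_uncertainty(tri, concept, measure),
                          int(surface.size), (fallback,), degenerate=True)
    best = surface[finite].min()
    ai, bi = np.nonzero(finite & (surface <= best + 1e-12))
    tie_pairs = sorted(
        (ThresholdPair(float(alphas[i]), float(betas[j])) for i, j in zip(ai, bi)),
        key=lambda t: (-t.alpha, t.beta),
    )
    chosen = tie_pairs[0]
    tri = probabilistic_regions(partition, concept, chosen)
    report = region_uncertainty(tri, concept, measure)
    return ItrsResult(
        chosen,
        report,
        candidates_examined=int(np.isfinite(surface).sum()),
        tie_set=tuple(tie_pairs),
        degenerate=len(np.unique(probs)) <= 1,
    )
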