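"""Robust junction correspondence by 2-point RANSAC.

Minimal samples are pairs of source junctions matched against
distance-ratio-compatible pairs of destination junctions; each hypothesis
is scored by its mutual-nearest-neighbour inliers within a metric gate
(default 50 um). The best hypothesis is refit on its inliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .transform import (EstimationError, PointSet, SimilarityTransform,
                        estimate_similarity, rmse_um)


class MatchFailure(RuntimeError):
    """No consistent correspondence found; manual correction needed."""


@dataclass(frozen=True)
class MatchConfig:
    gate_um: float = 50.0
    min_inliers: int = 4
    n_iterations: int = 12000
    scale_bounds: tuple[float, float] = (0.25, 4.0)
    #: source pairs closer than this fraction of the source spread are skipped
    min_pair_separation_frac: float = 0.25
    refit_rounds: int = 3
    #: stop sampling once a hypothesis reaches this many inliers
    early_exit_inliers: int = 32


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]        # (src index, dst index) inliers
    transform: SimilarityTransform      # src -> dst
    rmse: float


def _mutual_nn_inliers(src_t: np.ndarray, dst: np.ndarray,
                       gate: float) -> list[tuple[int, int]]:
    tree_d = cKDTree(dst)
    tree_s = cKDTree(src_t)
    d_sd, nn_sd = tree_d.query(src_t)
    _, nn_ds = tree_s.query(dst)
    pairs = []
    for i, (dist, j) in enumerate(zip(d_sd, nn_sd)):
        if dist <= gate and nn_ds[j] == i:
            pairs.append((i, int(j)))
    return pairs


def match_junctions(src: PointSet, dst: PointSet,
                    init: SimilarityTransform | None = None,
                    seed: int = 0,
                    config: MatchConfig | None = None) -> MatchResult:
    """Estimate correspondences and the src -> dst similarity.

    ``src`` and ``dst`` may live in different frames (e.g. device pixels
    vs en-face um); the gate is expressed in destination units. With an
    ``init`` transform, hypotheses are additionally seeded from points
    projected through it. Deterministic for a fixed ``seed``.
    """
    if config is None:
        config = MatchConfig()
    if len(src) == 0 or len(dst) == 0:
        raise MatchFailure("empty point set")
    rng = np.random.default_rng(seed)
    s_xy = src.xy
    d_xy = dst.xy
    n_s, n_d = len(s_xy), len(d_xy)

    best: tuple[int, float, SimilarityTransform] | None = None

    # precompute dst pair distances for ratio gating
    di, dj = np.triu_indices(n_d, k=1)
    d_dists = np.hypot(*(d_xy[di] - d_xy[dj]).T)
    src_spread = float(np.hypot(*np.ptp(s_xy, axis=0))) if n_s > 1 else 0.0
    min_sep = src_spread * config.min_pair_separation_frac

    def score_hypothesis(T: SimilarityTransform):
        nonlocal best
        pairs = _mutual_nn_inliers(T.apply(s_xy), d_xy, config.gate_um)
        if len(pairs) < 2:
            return 0
        idx_s = [i for i, _ in pairs]
        idx_d = [j for _, j in pairs]
        try:
            T_ref = estimate_similarity(s_xy[idx_s], d_xy[idx_d])
        except EstimationError:
            return 0
        err = rmse_um(T_ref, s_xy[idx_s], d_xy[idx_d])
        if best is None or (len(pairs), -err) > (best[0], -best[1]):
            best = (len(pairs), err, T_ref)
        return len(pairs)

    if init is not None:
        score_hypothesis(init)
    # escalate the budget when no strong consensus emerges
    budget = config.n_iterations
    done = 0
    while done < budget:
        done += 1
        if n_s < 2:
            break
        if best is not None and best[0] >= config.early_exit_inliers:
            break
        if (done == config.n_iterations
                and (best is None or best[0] < config.early_exit_inliers // 2)):
            budget = 4 * config.n_iterations
        a, b = rng.choice(n_s, size=2, replace=False)
        sep = float(np.hypot(*(s_xy[a] - s_xy[b])))
        if sep <= max(min_sep, 1e-9):
            continue
        lo = sep * config.scale_bounds[0]
        hi = sep * config.scale_bounds[1]
        ok = np.flatnonzero((d_dists >= lo) & (d_dists <= hi))
        if len(ok) == 0:
            continue
        k = int(rng.choice(ok))
        p, q = int(di[k]), int(dj[k])
        if rng.uniform() < 0.5:
            p, q = q, p
        try:
            T = estimate_similarity(s_xy[[a, b]], d_xy[[p, q]])
        except EstimationError:
            continue
        score_hypothesis(T)

    if best is None or best[0] < config.min_inliers:
        raise MatchFailure(
            f"no transform with >= {config.min_inliers} inliers "
            f"(best: {0 if best is None else best[0]})")

    T = best[2]
    # annealed refinement: recover inliers with a generous gate, tighten
    gates = [2.0 * config.gate_um, 1.5 * config.gate_um]
    gates += [config.gate_um] * config.refit_rounds
    pairs = _mutual_nn_inliers(T.apply(s_xy), d_xy, gates[0])
    for gate in gates:
        if len(pairs) < 2:
            break
        idx_s = [i for i, _ in pairs]
        idx_d = [j for _, j in pairs]
        T = estimate_similarity(s_xy[idx_s], d_xy[idx_d])
        new_pairs = _mutual_nn_inliers(T.apply(s_xy), d_xy, gate)
        if new_pairs == pairs and gate == config.gate_um:
            break
        if len(new_pairs) >= 2:
            pairs = new_pairs
    idx_s = [i for i, _ in pairs]
    idx_d = [j for _, j in pairs]
    if len(pairs) < config.min_inliers:
        raise MatchFailure("inlier set collapsed during refinement")
    return MatchResult(pairs=pairs, transform=T,
                       rmse=rmse_um(T, s_xy[idx_s], d_xy[idx_d]))
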