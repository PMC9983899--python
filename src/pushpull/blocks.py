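"""Push-pull block discovery and spectral ordering of interaction matrices.

A push-pull block is a pair of disjoint biomarker sets (V sources,
V' targets) such that every V -> V' interaction is excitatory while every
reciprocal V' -> V interaction is inhibitory; in the phase plane such pairs
produce rotational flow.  Blocks are found by greedily maximizing a
size-normalized antisymmetry score over a signed score matrix
Z[target, source] (sign of the estimate times |z|, or signed -log p), and
their significance is assessed against a null that randomly reassigns the
reciprocal value pairs to biomarker slots.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("pushpull")

__all__ = ["signed_score_matrix", "pushpull_score", "PushPullBlock",
           "find_pushpull_blocks", "reorganize_null_draw", "spectral_order"]


def signed_score_matrix(sign: pd.DataFrame, z: pd.DataFrame,
                        use: str = "z") -> pd.DataFrame:
    """Z[target, source] = sign(estimate) * |z| (default) with zero diagonal.

    ``use="z"`` avoids the saturation of p-based scores in the far tail;
    pass ``use="logp"`` with a (negated) log-p frame instead if preferred.
    """
    out = (sign * z.abs()).fillna(0.0)
    np.fill_diagonal(out.values, 0.0)
    return out


def _score(Z: np.ndarray, V: np.ndarray, W: np.ndarray) -> float:
    # sum over sources v in V, targets w in W of Z[w, v] - Z[v, w]
    return float((Z[np.ix_(W, V)].sum() - Z[np.ix_(V, W)].sum())
                 / np.sqrt(len(V) * len(W)))


def pushpull_score(Z, V, W) -> float:
    """Size-normalized push-pull score of source set V and target set W.

    Positive when V -> W interactions are excitatory and the reciprocals
    inhibitory; the sqrt(|V| |W|) normalization makes blocks of different
    areas comparable.
    """
    Z = np.asarray(Z, dtype=float)
    V = np.asarray(list(V), dtype=int)
    W = np.asarray(list(W), dtype=int)
    if V.size == 0 or W.size == 0:
        raise ValueError("V and V' must be nonempty")
    if np.intersect1d(V, W).size:
        raise ValueError("V and V' must be disjoint")
    return _score(Z, V, W)


@dataclass
class PushPullBlock:
    sources: list[str]
    targets: list[str]
    score: float
    mc_p: float
    n_draws: int


def _greedy_best(Z: np.ndarray, active: np.ndarray):
    """Greedy peeling maximizer of the push-pull score on the active set.

    Every active biomarker starts on its locally best side; single-element
    side swaps run to convergence; then elements are peeled one at a time,
    keeping the best-scoring configuration seen with both sides nonempty.
    """
    act = list(active)
    if len(act) < 2:
        return None
    # initial side: net outgoing minus incoming signed weight
    net = {b: sum(Z[c, b] - Z[b, c] for c in act if c != b) for b in act}
    side = {b: (0 if net[b] > 0 else 1) for b in act}  # 0 = source, 1 = target
    if all(v == 0 for v in side.values()):
        side[min(act, key=lambda b: net[b])] = 1
    if all(v == 1 for v in side.values()):
        side[max(act, key=lambda b: net[b])] = 0

    def sets():
        V = np.array([b for b in act if side[b] == 0], dtype=int)
        W = np.array([b for b in act if side[b] == 1], dtype=int)
        return V, W

    def safe_score():
        V, W = sets()
        if V.size == 0 or W.size == 0:
            return -np.inf, V, W
        return _score(Z, V, W), V, W

    # local improvement: move single elements across
    for _ in range(2 * len(act)):
        improved = False
        cur, _, _ = safe_score()
        for b in act:
            side[b] ^= 1
            new, _, _ = safe_score()
            if new > cur + 1e-12:
                cur = new
                improved = True
            else:
                side[b] ^= 1
        if not improved:
            break

    best = None
    while True:
        cur, V, W = safe_score()
        if np.isfinite(cur) and (best is None or cur > best[0]):
            best = (cur, V.copy(), W.copy())
        if len(act) <= 2:
            break
        # peel the element whose removal maximizes the score
        cand_best, cand_elem = -np.inf, None
        for b in act:
            Vr = np.array([c for c in act if c != b and side[c] == 0],
                          dtype=int)
            Wr = np.array([c for c in act if c != b and side[c] == 1],
                          dtype=int)
            if Vr.size == 0 or Wr.size == 0:
                continue
            sc = _score(Z, Vr, Wr)
            if sc > cand_best:
                cand_best, cand_elem = sc, b
        if cand_elem is None:
            break
        act.remove(cand_elem)
    return best


def reorganize_null_draw(Z, seed) -> np.ndarray:
    """Randomly reassign reciprocal value pairs (Z_ij, Z_ji) to slots.

    The multiset of ordered reciprocal pairs — hence the joint distribution
    of interaction values — is preserved; which biomarkers carry them is
    destroyed.  A fair coin decides each pair's orientation.
    """
    Z = np.asarray(Z, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = Z.shape[0]
    slots = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = [(Z[i, j], Z[j, i]) for i, j in slots]
    order = rng.permutation(len(slots))
    out = np.zeros_like(Z)
    for (i, j), k in zip(slots, order):
        a, b = vals[k]
        if rng.random() < 0.5:
            a, b = b, a
        out[i, j] = a
        out[j, i] = b
    return out


def find_pushpull_blocks(Z, names: list[str] | None = None,
                         n_null_draws: int = 200, seed: int = 0,
                         max_blocks: int = 5, alpha: float = 0.05,
                         keep_rejected: bool = False) -> list[PushPullBlock]:
    """Iteratively extract significant push-pull blocks by greedy peeling.

    Each accepted block's Monte-Carlo p compares its score with the best
    greedy score on ``n_null_draws`` reorganized matrices (smoothed
    (1 + count) / (n + 1)); accepted biomarkers are removed and the search
    repeats, stopping at the first non-significant candidate (which is
    included in the result only when ``keep_rejected`` is set).
    """
    if isinstance(Z, pd.DataFrame):
        names = list(Z.index)
        Z = Z.to_numpy(dtype=float)
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if names is None:
        names = [str(i) for i in range(n)]
    if n < 3:
        raise ValueError("need at least 3 biomarkers")
    rng = np.random.default_rng(seed)
    active = np.arange(n)
    blocks: list[PushPullBlock] = []
    while len(blocks) < max_blocks and active.size >= 3:
        found = _greedy_best(Z, active)
        if found is None:
            break
        score, V, W = found
        # null distribution of the best greedy score on reorganized matrices
        exceed = 0
        sub = Z[np.ix_(active, active)]
        for _ in range(n_null_draws):
            Znull = reorganize_null_draw(sub, rng)
            null_best = _greedy_best(Znull, np.arange(active.size))
            if null_best is not None and null_best[0] >= score:
                exceed += 1
        mc_p = (1.0 + exceed) / (n_null_draws + 1.0)
        block = PushPullBlock(sources=[names[i] for i in V],
                              targets=[names[i] for i in W],
                              score=score, mc_p=mc_p, n_draws=n_null_draws)
        if mc_p >= alpha:
            if keep_rejected:
                blocks.append(block)
            break
        blocks.append(block)
        used = set(V.tolist()) | set(W.tolist())
        active = np.array([i for i in active if i not in used], dtype=int)
    return blocks


def spectral_order(S, names: list[str] | None = None) -> list[str]:
    """Order biomarkers by the leading eigenvector of a symmetric matrix.

    The eigenvector of the largest-magnitude eigenvalue is sign-fixed so the
    larger group of same-signed entries is positive; ties are broken
    lexicographically by name.  Used to expose covariance clusters in the
    drive matrix BB^T.
    """
    if isinstance(S, pd.DataFrame):
        names = list(S.index)
        S = S.to_numpy(dtype=float)
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if names is None:
        names = [str(i) for i in range(n)]
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if np.allclose(S, 0.0):
        return sorted(names)
    w, V = np.linalg.eigh(S)
    mags = np.abs(w)
    lead = int(np.argmax(mags))
    if n > 1:
        gap = np.sort(mags)[-1] - np.sort(mags)[-2]
        if gap < 1e-10:
            logger.warning("degenerate leading eigenspace; ordering uses a "
                           "deterministic tie-break")
    vec = V[:, lead]
    npos = int((vec > 0).sum())
    nneg = int((vec < 0).sum())
    if nneg > npos or (nneg == npos and vec.sum() < 0):
        vec = -vec
    order = sorted(range(n), key=lambda i: (-vec[i], names[i]))
    return [names[i] for i in order]
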