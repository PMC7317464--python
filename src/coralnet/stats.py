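"""Randomization tests on simulation ensembles and significance letters.

Two ensembles (e.g., 100 replicate resistance values of two networks) are
compared with a pooled-relabeling permutation test on the absolute difference
of means. Pairwise p-values across several ensembles are condensed into the
compact-letter display used on bar charts: groups sharing a letter are
pairwise non-significant at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["permutation_test", "letter_groups", "compare_ensembles", "EnsembleComparison"]


def permutation_test(a, b, n_perm: int = 9999,
                     rng: np.random.Generator | None = None) -> float:
    """Two-sided pooled permutation test on |mean(a) - mean(b)|.

    p = (1 + #{permutations with |delta| >= observed}) / (n_perm + 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each ensemble needs at least 2 replicate values")
    rng = rng if rng is not None else np.random.default_rng()
    observed = abs(a.mean() - b.mean())
    # sorting the pool makes the Monte Carlo p exactly invariant to
    # swapping a and b when the groups have equal size
    pooled = np.sort(np.concatenate([a, b]))
    if np.all(pooled == pooled[0]):
        return 1.0
    na, n = len(a), len(pooled)
    # vectorized: each row of the argsorted uniform matrix is one relabeling
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    pa = pooled[perms[:, :na]].mean(axis=1)
    pb = pooled[perms[:, na:]].mean(axis=1)
    exceed = np.abs(pa - pb) >= observed - 1e-12
    return float((1 + exceed.sum()) / (n_perm + 1))


def letter_groups(p_matrix: np.ndarray, alpha: float = 0.05,
                  labels: list | None = None) -> list[str]:
    """Compact letter display by greedy clique cover.

    ``p_matrix[i, j]`` is the pairwise p-value; groups i and j may share a
    letter iff p > alpha. Deterministic given input order.
    """
    p = np.asarray(p_matrix, dtype=float)
    k = p.shape[0]
    if p.shape != (k, k):
        raise ValueError("p matrix must be square")
    compatible = p > alpha
    np.fill_diagonal(compatible, True)
    cliques: list[set[int]] = []
    for i in range(k):
        placed = False
        for c in cliques:
            if all(compatible[i, j] for j in c):
                c.add(i)
                placed = True
        if not placed:
            # grow a new maximal clique around i so earlier-compatible
            # groups still share its letter
            c = {i}
            for j in range(k):
                if j != i and all(compatible[j, m] for m in c):
                    c.add(j)
            cliques.append(c)
    # drop cliques fully contained in another (redundant letters)
    uniq = []
    for c in cliques:
        if c not in uniq:
            uniq.append(c)
    cliques = [c for c in uniq if not any(c < other for other in uniq)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = []
    for i in range(k):
        letters = "".join(alphabet[j % 26] for j, c in enumerate(cliques) if i in c)
        out.append(letters)
    return out


@dataclass
class EnsembleComparison:
    labels: list
    p_matrix: np.ndarray
    letters: list
    alpha: float

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "alpha": self.alpha,
            "p_matrix": self.p_matrix.tolist(),
            "letters": list(self.letters),
        }


def holm_adjust(p_matrix: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment over the upper triangle of a p matrix."""
    p = np.asarray(p_matrix, dtype=float).copy()
    iu = np.triu_indices_from(p, k=1)
    raw = p[iu]
    order = np.argsort(raw)
    m = len(raw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * raw[idx]))
        adj[idx] = running
    p[iu] = adj
    p.T[iu] = adj
    return p


def compare_ensembles(groups: dict, alpha: float = 0.05, n_perm: int = 9999,
                      seed: int = 0, holm: bool = False) -> EnsembleComparison:
    """All-pairs permutation tests plus the letter display.

    ``groups`` maps label -> replicate value vector. Each pair gets its own
    substream of the master seed, so results do not depend on dict order.
    """
    labels = list(groups)
    k = len(labels)
    p = np.ones((k, k))
    ss = np.random.SeedSequence(seed).spawn(k * k)
    for i in range(k):
        for j in range(i + 1, k):
            rng = np.random.default_rng(ss[i * k + j])
            p[i, j] = p[j, i] = permutation_test(
                groups[labels[i]], groups[labels[j]], n_perm=n_perm, rng=rng
            )
    return EnsembleComparison(labels, p, letter_groups(holm_adjust(p) if holm else p, alpha, labels), alpha)
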