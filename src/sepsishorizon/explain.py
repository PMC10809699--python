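"""Channel-level Shapley attribution for fitted sequence classifiers.

Feature channels are the players of a cooperative game: the value of a
coalition S is the model's positive-class probability when the channels in S
keep their observed time-course and every other channel is replaced by a
background window (averaged over a background sample).  The empty coalition's
value is the base value y_base — the mean model output over the background —
and the full coalition recovers the model's output y_i on the explained
window, so the attributions phi satisfy the efficiency identity
``y_i = y_base + sum(phi)``.

Three routes are provided and cross-checked against each other:

* :func:`shapley_exact` — the classical subset-weighted sum
  phi_i = sum over T containing i of (|T|-1)!(n-|T|)!/n! * (v(T) - v(T\\{i})),
  enumerating all 2^n coalitions (capped at n <= 15);
* :func:`shapley_permutation_oracle` — the average of marginal contributions
  over all n! arrival orders (n <= 8), an independent formulation used as the
  test oracle;
* :func:`shapley_sampled` — unbiased Monte-Carlo over random arrival orders
  with per-channel standard errors, for routine use.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .preprocess import Dataset

__all__ = [
    "CoalitionProblem", "ShapExplanation", "make_coalition_problem",
    "subset_weight", "shapley_exact", "shapley_permutation_oracle",
    "shapley_sampled", "additivity_check", "feature_ranking",
    "explain_dataset",
]


@dataclass
class CoalitionProblem:
    """A value function over coalitions of the n feature channels.

    ``v`` maps a frozenset of channel indices (subset of {0..n-1}) to a real.
    ``batch_v``, when provided, evaluates a list of coalitions in one call
    (used to batch model forward passes).  Evaluations are memoized.
    """
    n: int
    v: Callable[[frozenset], float]
    batch_v: Callable[[list[frozenset]], np.ndarray] | None = None
    _memo: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def value(self, subset) -> float:
        S = frozenset(subset)
        if not S <= frozenset(range(self.n)):
            raise ValueError(f"subset {sorted(S)} not within {{0..{self.n - 1}}}")
        if S not in self._memo:
            self._memo[S] = float(self.v(S))
        return self._memo[S]

    def values(self, subsets: Sequence[frozenset]) -> np.ndarray:
        todo = [S for S in dict.fromkeys(map(frozenset, subsets)) if S not in self._memo]
        if todo:
            if self.batch_v is not None:
                for S, val in zip(todo, np.asarray(self.batch_v(todo), dtype=float)):
                    self._memo[S] = float(val)
            else:
                for S in todo:
                    self._memo[S] = float(self.v(S))
        return np.array([self._memo[frozenset(S)] for S in subsets])


@dataclass
class ShapExplanation:
    """Per-channel attributions and the additivity bookkeeping."""
    phi: np.ndarray
    y_base: float
    y_i: float
    additivity_residual: float
    standard_errors: np.ndarray | None = None
    feature_names: list[str] | None = None

    def to_dict(self) -> dict:
        d = {"phi": self.phi.tolist(), "y_base": self.y_base, "y_i": self.y_i,
             "additivity_residual": self.additivity_residual}
        if self.standard_errors is not None:
            d["standard_errors"] = self.standard_errors.tolist()
        if self.feature_names is not None:
            d["feature_names"] = self.feature_names
        return d


def make_coalition_problem(fitted, window: np.ndarray, valid: np.ndarray,
                           background: np.ndarray,
                           chunk_size: int = 4096) -> CoalitionProblem:
    """Wrap a fitted classifier as a coalition game over its feature channels.

    ``window`` is (T, N), ``valid`` is (T,), ``background`` is (B, T, N) —
    typically a seeded subsample of training windows, padded to the same T.
    A coalition keeps the explained window's whole time-course on its
    channels and takes every other channel from each background window in
    turn; the value is the mean positive-class probability over the
    background.  The composite inherits the explained window's valid mask;
    background padding rows are standardized zeros (the training mean), a
    neutral reference.
    """
    window = np.asarray(window, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if window.ndim != 2 or background.ndim != 3:
        raise ValueError("window must be (T, N) and background (B, T, N)")
    if background.shape[1:] != window.shape:
        raise ValueError(
            f"background windows {background.shape[1:]} do not match "
            f"the explained window {window.shape}")
    n = window.shape[1]
    B = background.shape[0]
    valid = np.asarray(valid, dtype=bool)

    def batch_v(subsets: list[frozenset]) -> np.ndarray:
        out = np.empty(len(subsets))
        pos = 0
        per_call = max(1, chunk_size // B)
        for a in range(0, len(subsets), per_call):
            chunk = subsets[a:a + per_call]
            comps = np.repeat(background[None, :, :, :], len(chunk), axis=0)  # (m,B,T,N)
            for j, S in enumerate(chunk):
                cols = sorted(S)
                if cols:
                    comps[j, :, :, cols] = window[:, cols].T[:, None, :]
            flat = comps.reshape(-1, window.shape[0], n)
            vmask = np.broadcast_to(valid, (flat.shape[0], valid.shape[0]))
            proba = fitted.predict_proba(flat, vmask)[:, 1]
            out[pos:pos + len(chunk)] = proba.reshape(len(chunk), B).mean(axis=1)
            pos += len(chunk)
        return out

    return CoalitionProblem(n=n, v=lambda S: batch_v([frozenset(S)])[0], batch_v=batch_v)


def subset_weight(t: int, n: int) -> float:
    """The exact-Shapley weight (t-1)!(n-t)!/n! of a coalition of size t
    containing the player, in a game of n players."""
    if not (1 <= t <= n):
        raise ValueError("need 1 <= t <= n")
    return math.factorial(t - 1) * math.factorial(n - t) / math.factorial(n)


def shapley_exact(problem: CoalitionProblem, cap: int = 15) -> ShapExplanation:
    """Exact Shapley values by full coalition enumeration (2^n evaluations)."""
    n = problem.n
    if n > cap:
        raise ValueError(
            f"n={n} exceeds the exact-enumeration cap ({cap}); "
            "use shapley_sampled for larger channel counts")
    masks = [frozenset(i for i in range(n) if m >> i & 1) for m in range(2 ** n)]
    vals = problem.values(masks)
    v = {S: val for S, val in zip(masks, vals)}
    w = [0.0] + [subset_weight(t, n) for t in range(1, n + 1)]
    phi = np.zeros(n)
    for S, vS in v.items():
        t = len(S)
        if t == 0:
            continue
        for i in S:
            phi[i] += w[t] * (vS - v[S - {i}])
    y_base = v[frozenset()]
    y_i = v[frozenset(range(n))]
    return ShapExplanation(phi=phi, y_base=y_base, y_i=y_i,
                           additivity_residual=float(y_base + phi.sum() - y_i))


def shapley_permutation_oracle(problem: CoalitionProblem) -> np.ndarray:
    """Shapley values as the average marginal contribution over all n!
    arrival orders.  Exponential-factorial cost; n <= 8 only.  Kept as an
    independent cross-check of the subset-weight formula."""
    n = problem.n
    if n > 8:
        raise ValueError(f"permutation oracle limited to n <= 8, got {n}")
    phi = np.zeros(n)
    count = 0
    for order in itertools.permutations(range(n)):
        S: frozenset = frozenset()
        prev = problem.value(S)
        for i in order:
            S = S | {i}
            cur = problem.value(S)
            phi[i] += cur - prev
            prev = cur
        count += 1
    return phi / count


def shapley_sampled(problem: CoalitionProblem, n_samples: int = 200,
                    seed: int = 0) -> ShapExplanation:
    """Monte-Carlo Shapley: average marginal contributions over random
    arrival orders.  Unbiased for the exact value; per-channel standard
    errors from the sample of per-permutation contribution vectors.  Each
    permutation's contributions telescope to v(full) - v(empty), so the
    estimate satisfies additivity exactly."""
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    n = problem.n
    rng = np.random.default_rng(seed)
    full = frozenset(range(n))
    y_base = problem.value(frozenset())
    y_i = problem.value(full)

    contribs = np.empty((n_samples, n))
    for s in range(n_samples):
        order = rng.permutation(n)
        prefixes = [frozenset()]
        for i in order:
            prefixes.append(prefixes[-1] | {i})
        vals = problem.values(prefixes)
        contribs[s, order] = np.diff(vals)
    phi = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_samples)
    return ShapExplanation(phi=phi, y_base=y_base, y_i=y_i,
                           additivity_residual=float(y_base + phi.sum() - y_i),
                           standard_errors=se)


def additivity_check(explanation: ShapExplanation) -> float:
    """The efficiency residual y_base + sum(phi) - y_i (0 for exact values)."""
    return float(explanation.y_base + explanation.phi.sum() - explanation.y_i)


def feature_ranking(explanations: Sequence[ShapExplanation],
                    feature_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Rank channels by mean |phi| over the explained records (descending,
    ties alphabetical), with the fraction of records where phi > 0."""
    if not explanations:
        raise ValueError("at least one explanation required")
    if feature_names is None:
        feature_names = explanations[0].feature_names
    if feature_names is None:
        feature_names = [f"feature_{i}" for i in range(len(explanations[0].phi))]
    phis = np.stack([e.phi for e in explanations])
    if phis.shape[1] != len(feature_names):
        raise ValueError("feature_names length does not match phi length")
    df = pd.DataFrame({
        "feature": list(feature_names),
        "mean_abs_phi": np.abs(phis).mean(axis=0),
        "frac_positive": (phis > 0).mean(axis=0),
    })
    return (df.sort_values(["mean_abs_phi", "feature"],
                           ascending=[False, True], kind="mergesort")
              .reset_index(drop=True))


def explain_dataset(fitted, dataset: Dataset, record_indices=None,
                    n_background: int = 20, method: str = "sampled",
                    n_samples: int = 200, seed: int = 0,
                    background: str = "all") -> list[ShapExplanation]:
    """Explain selected windows of a dataset against a seeded background
    subsample of the same dataset (training windows by convention).

    ``background`` selects the reference population: ``"all"`` (a draw from
    every window), or ``"control"`` / ``"case"`` to restrict to one arm.
    For contrastive questions — why does the model call *this* patient
    septic? — the control arm is the natural reference: a mixed background
    contains drifted windows and dilutes the contrast on informative
    channels.
    """
    rng = np.random.default_rng(seed)
    n = dataset.n
    if background == "all":
        pool = np.arange(n)
    elif background == "control":
        pool = np.flatnonzero(dataset.y == 0)
    elif background == "case":
        pool = np.flatnonzero(dataset.y == 1)
    else:
        raise ValueError("background must be 'all', 'control' or 'case'")
    if pool.size == 0:
        raise ValueError(f"no windows available for background={background!r}")
    bg_idx = rng.choice(pool, size=min(n_background, pool.size), replace=False)
    if record_indices is None:
        record_indices = np.arange(n)
    background = dataset.X[bg_idx]
    out = []
    for ridx in np.asarray(record_indices):
        problem = make_coalition_problem(fitted, dataset.X[ridx],
                                         dataset.valid[ridx], background)
        if method == "exact":
            exp = shapley_exact(problem)
        elif method == "sampled":
            exp = shapley_sampled(problem, n_samples=n_samples,
                                  seed=int(rng.integers(2 ** 31)))
        else:
            raise ValueError(f"unknown method {method!r}; use 'exact' or 'sampled'")
        exp.feature_names = list(dataset.feature_names)
        out.append(exp)
    return out
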