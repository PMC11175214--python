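"""All-relevant feature selection with shadow features (Boruta scheme).

The selector duplicates the feature matrix, permutes each copy to
destroy its association with the labels ("shadow" features), fits a
Random Forest on the joined matrix, and counts a *hit* for every real
feature whose importance exceeds the best shadow importance.  Over the
iterations, a two-sided binomial test (Bonferroni-corrected) decides
whether a feature scores hits significantly more often than chance
(confirmed) or significantly less (rejected); the remainder stay
tentative.  Unlike minimal-subset selectors, duplicated informative
features are both retained — the algorithm targets *all* relevant
features.

The shadow pool is rebuilt each iteration from the *full* original
feature set (not just the still-undecided candidates), so the
best-shadow reference stays equally demanding as candidates are
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier


@dataclass
class SelectionResult:
    """Outcome of a shadow-feature selection run."""

    status: dict[str, str]  # feature -> confirmed | rejected | tentative
    hits: dict[str, int]
    n_iterations: int
    seed: int
    importance_history: pd.DataFrame = field(repr=False, default=None)

    @property
    def confirmed(self) -> list[str]:
        return [f for f, s in self.status.items() if s == "confirmed"]

    @property
    def rejected(self) -> list[str]:
        return [f for f, s in self.status.items() if s == "rejected"]

    @property
    def tentative(self) -> list[str]:
        return [f for f, s in self.status.items() if s == "tentative"]

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "hits": self.hits,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }


def boruta_select(
    X: pd.DataFrame,
    y,
    max_iter: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int | None = 5,
) -> SelectionResult:
    """Run the shadow-feature selection on a feature matrix.

    Parameters
    ----------
    X : feature matrix (rows = samples).
    y : class labels (>= 2 classes, >= 20 rows).
    max_iter : maximum number of shadow/Random-Forest rounds.
    alpha : significance level of the binomial hit test; Bonferroni
        corrected by the number of candidate features.
    seed : seeds both the permutations and the forests; identical seeds
        and inputs give identical results.
    """
    y = np.asarray(y)
    if len(X) < 20:
        raise ValueError("need at least 20 samples for a stable selection")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    names = list(X.columns)

    # constant columns carry no information and break importance ranking
    status: dict[str, str] = {}
    for f in names:
        if np.ptp(X[f].to_numpy()) == 0:
            status[f] = "rejected"
            warnings.warn(f"constant feature {f!r} auto-rejected", stacklevel=2)
        else:
            status[f] = "tentative"

    hits = {f: 0 for f in names}
    trials = {f: 0 for f in names}
    history = []
    n_tests = max(sum(1 for s in status.values() if s != "rejected"), 1)
    pool = [f for f, s in status.items() if s != "rejected"]  # non-constant
    Xpool = X[pool].to_numpy(dtype=float)
    it = 0
    for it in range(1, max_iter + 1):
        active = [f for f, s in status.items() if s == "tentative"]
        if not active:
            break
        Xa = X[active].to_numpy(dtype=float)
        # shadows: permuted copies of every original feature (>= 5 columns)
        shadow_cols = list(range(Xpool.shape[1]))
        while len(shadow_cols) < 5:
            shadow_cols.append(int(rng.integers(Xpool.shape[1])))
        shadows = np.column_stack(
            [rng.permutation(Xpool[:, j]) for j in shadow_cols]
        )
        Xfull = np.hstack([Xa, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(Xfull, y)
        imp = forest.feature_importances_
        real_imp = imp[: len(active)]
        shadow_max = imp[len(active) :].max()
        history.append(dict(zip(active, real_imp), _shadow_max=shadow_max))
        for f, v in zip(active, real_imp):
            trials[f] += 1
            if v > shadow_max:
                hits[f] += 1
        # two-sided binomial decision, Bonferroni-corrected over features
        # and over the repeated looks at the accumulating hit counts
        threshold = alpha / (n_tests * it)
        for f in active:
            k, n = hits[f], trials[f]
            if stats.binom.sf(k - 1, n, 0.5) < threshold:
                status[f] = "confirmed"
            elif stats.binom.cdf(k, n, 0.5) < threshold:
                status[f] = "rejected"

    return SelectionResult(
        status=status,
        hits=hits,
        n_iterations=it,
        seed=seed,
        importance_history=pd.DataFrame(history),
    )
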