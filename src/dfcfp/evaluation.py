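"""Parameter grid search and 5×2 cross-validated significance testing.

The 5×2 CV paired t-test (Dietterich) repeats a random 2-fold split five
times. Per replication i and fold k the paired score difference is d_i^(k);
with d̄_i the replication mean and s_i² = (d_i^(1)−d̄_i)² + (d_i^(2)−d̄_i)²,

    t = d_1^(1) / sqrt((1/5) Σᵢ s_i²)

follows a t distribution with 5 degrees of freedom under the null of equal
scores. Bonferroni correction divides alpha by the number of comparisons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cobe import apply_cobe, max_components, train_cobe
from .dfc import num_frames, sliding_window_dfc, upper_tri_dim
from .errors import ConfigError, DataError, NumericalError
from .identifiability import identifiability_matrix, score_identifiability

logger = logging.getLogger(__name__)


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Bonferroni-corrected significance level, alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    if n_comparisons < 1:
        raise ConfigError(f"need at least one comparison, got {n_comparisons}")
    return alpha / n_comparisons


@dataclass(frozen=True)
class Cv5x2Result:
    """Paired 5×2 CV comparison of two score sets (replication-major order)."""

    scores_a: np.ndarray
    scores_b: np.ndarray
    t: float
    p: float
    alpha_corrected: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.alpha_corrected is None:
            return None
        return self.p < self.alpha_corrected


def cv5x2_ttest(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    numerator: str = "first",
    alpha_corrected: float | None = None,
) -> Cv5x2Result:
    """Dietterich's 5×2 CV paired t-test on two sets of 10 scores.

    Scores are ordered replication-major: (r1f1, r1f2, r2f1, …, r5f2).
    ``numerator="first"`` uses d_1^(1) as in the original test;
    ``numerator="mean"`` substitutes the grand mean difference, a common
    variant. A two-sided p-value with 5 df is returned.
    """
    if numerator not in ("first", "mean"):
        raise ConfigError(f"numerator must be 'first' or 'mean', got {numerator!r}")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != (10,) or b.shape != (10,):
        raise ConfigError(
            f"need exactly 10 paired scores (5 replications x 2 folds), "
            f"got {a.shape} and {b.shape}"
        )
    d = (a - b).reshape(5, 2)
    dbar = d.mean(axis=1, keepdims=True)
    s2 = ((d - dbar) ** 2).sum(axis=1)
    if np.all(s2 == 0):
        raise NumericalError(
            "degenerate variance: all per-replication variances are zero, t undefined"
        )
    num = d[0, 0] if numerator == "first" else d.mean()
    t = float(num / np.sqrt(s2.mean()))
    p = float(2.0 * stats.t.sf(abs(t), df=5))
    return Cv5x2Result(scores_a=a, scores_b=b, t=t, p=p, alpha_corrected=alpha_corrected)


@dataclass(frozen=True)
class Split:
    """One train/test fold of a 5×2 replication."""

    replication: int
    fold: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_session: int


def make_5x2_splits(
    subject_ids: Sequence[str], seed: int, n_replications: int = 5
) -> list[Split]:
    """Five random halvings, two folds each, deterministic under ``seed``.

    Per replication the subjects are split into two halves; fold 1 trains on
    one randomly chosen session of half A and tests both sessions of half B,
    fold 2 swaps the halves (with its own random training session). With an
    odd subject count the first half receives the extra subject (logged).
    """
    ids = [str(s) for s in subject_ids]
    if len(ids) < 4:
        raise ConfigError(f"need at least 4 subjects for 5x2 CV, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise DataError("subject ids are not unique")
    rng = np.random.default_rng(seed)
    if len(ids) % 2:
        logger.info("odd subject count %d: first half gets the extra subject", len(ids))
    splits = []
    for rep in range(1, n_replications + 1):
        perm = list(rng.permutation(ids))
        cut = (len(ids) + 1) // 2
        half_a, half_b = tuple(perm[:cut]), tuple(perm[cut:])
        for fold, (train, test) in enumerate([(half_a, half_b), (half_b, half_a)], start=1):
            splits.append(
                Split(
                    replication=rep,
                    fold=fold,
                    train_ids=train,
                    test_ids=test,
                    train_session=int(rng.integers(1, 3)),
                )
            )
    return splits


def evaluate_split(
    cohort,
    split: Split,
    window: int,
    stride: int,
    n_components: int,
    others: str = "topj",
) -> dict[str, float]:
    """Train a dictionary on one fold's training half and score the test half.

    Returns IR and dIdiff(1) for both the raw dFC and the COBE
    subject-specific dFC of the held-out subjects' two sessions. The cohort
    must expose ``timeseries[(subject_id, session)] -> RoiTimeSeries``.
    """
    overlap = set(split.train_ids) & set(split.test_ids)
    if overlap:
        raise DataError(f"test subjects leaked into training: {sorted(overlap)}")
    train_dfc = [
        sliding_window_dfc(cohort.timeseries[(s, split.train_session)], window, stride)
        for s in split.train_ids
    ]
    dictionary = train_cobe(train_dfc, n_components)
    s1 = [sliding_window_dfc(cohort.timeseries[(s, 1)], window, stride) for s in split.test_ids]
    s2 = [sliding_window_dfc(cohort.timeseries[(s, 2)], window, stride) for s in split.test_ids]

    raw = score_identifiability(
        identifiability_matrix(s1, s2, subject_ids=split.test_ids), others=others
    )
    spec1 = [apply_cobe(dictionary, d).subject_specific for d in s1]
    spec2 = [apply_cobe(dictionary, d).subject_specific for d in s2]
    specific = score_identifiability(
        identifiability_matrix(spec1, spec2, subject_ids=split.test_ids), others=others
    )
    return {
        "ir_raw": raw.identification_rate,
        "ir_specific": specific.identification_rate,
        "didiff1_raw": raw.didiff1,
        "didiff1_specific": specific.didiff1,
    }


def run_cv5x2(
    cohort,
    window: int,
    stride: int,
    n_components: int,
    seed: int,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> tuple[pd.DataFrame, dict[str, Cv5x2Result]]:
    """Full 5×2 CV comparing raw vs COBE subject-specific identifiability.

    Returns the 10-row fold table and, per metric (``ir``, ``didiff1``), the
    paired t-test of subject-specific against raw scores.
    """
    splits = make_5x2_splits(cohort.subject_ids, seed=seed)
    rows = []
    for split in splits:
        scores = evaluate_split(cohort, split, window, stride, n_components)
        rows.append(
            {"replication": split.replication, "fold": split.fold,
             "train_session": split.train_session, **scores}
        )
    table = pd.DataFrame(rows)
    corrected = bonferroni_alpha(alpha, n_comparisons)
    results: dict[str, Cv5x2Result | None] = {}
    for name in ("ir", "didiff1"):
        try:
            results[name] = cv5x2_ttest(
                table[f"{name}_specific"], table[f"{name}_raw"],
                alpha_corrected=corrected,
            )
        except NumericalError:
            # both methods scored identically in every fold (e.g. saturated
            # at 100%); there is no variance to test against
            logger.warning("5x2 comparison for %s is degenerate (identical scores)", name)
            results[name] = None
    return table, results


def grid_search(
    cohort,
    windows: Sequence[int],
    strides: Sequence[int],
    c_values: Sequence[int],
    n_blocks: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate (window, stride, C) combinations over subject blocks.

    Subjects are partitioned into ``n_blocks`` blocks; within each block half
    the subjects (one random session) train the dictionary and the other
    half's two sessions are scored. Combinations violating
    C ≤ min(r̃, w̃) are skipped with a logged reason. Windows and strides are
    in timepoints (the CLI converts from seconds).
    """
    ids = [str(s) for s in cohort.subject_ids]
    if n_blocks < 1 or len(ids) < 4 * n_blocks:
        raise ConfigError(
            f"need at least {4 * n_blocks} subjects for {n_blocks} blocks, got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(ids))
    blocks = [tuple(perm[i::n_blocks]) for i in range(n_blocks)]

    r = next(iter(cohort.timeseries.values())).n_regions
    t = next(iter(cohort.timeseries.values())).n_timepoints
    r_tilde = upper_tri_dim(r)

    rows = []
    skipped = []
    for window, stride, c in itertools.product(windows, strides, c_values):
        if window > t:
            skipped.append((window, stride, c, f"window {window} exceeds T={t}"))
            continue
        w_tilde = num_frames(t, window, stride)
        bound = max_components(r_tilde, w_tilde)
        if c > bound:
            skipped.append(
                (window, stride, c, f"C={c} exceeds min(r_tilde, w_tilde)={bound}")
            )
            continue
        for b, block_ids in enumerate(blocks, start=1):
            cut = (len(block_ids) + 1) // 2
            split = Split(
                replication=b,
                fold=1,
                train_ids=block_ids[:cut],
                test_ids=block_ids[cut:],
                train_session=int(rng.integers(1, 3)),
            )
            scores = evaluate_split(cohort, split, window, stride, c)
            rows.append(
                {"window": window, "stride": stride, "C": c, "block": b,
                 "ir": scores["ir_specific"], "didiff1": scores["didiff1_specific"]}
            )
    for combo in skipped:
        logger.info("skipped grid combination %s: %s", combo[:3], combo[3])
    if not rows:
        raise ConfigError("no valid (window, stride, C) combinations in the grid")
    return pd.DataFrame(rows)


def select_best(grid: pd.DataFrame) -> dict[str, int]:
    """Pick the (window, stride, C) combination with maximal block-mean IR."""
    means = grid.groupby(["window", "stride", "C"])["ir"].mean()
    window, stride, c = means.idxmax()
    return {"window": int(window), "stride": int(stride), "C": int(c),
            "mean_ir": float(means.max())}
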