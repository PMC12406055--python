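"""Dynamic identifiability: the cross-session frame-correlation matrix and
the dIdiff / identification-rate scores derived from it.

With nsub subjects, each contributing w̃ frames per session, the
identifiability matrix A is (nsub·w̃) × (nsub·w̃): entry (p, q) is the
Pearson correlation between frame p of session 1 and frame q of session 2.
A decomposes into w̃ × w̃ sub-blocks; diagonal blocks compare a subject with
itself across sessions, off-diagonal blocks compare different subjects.

dIdiff(j) is the mean of each diagonal block's top-j correlations (averaged
over subjects) minus the analogous off-diagonal average, on a percent scale.
The identification rate (IR) assigns each session-2 frame to the subject
owning its best-matching session-1 frame and reports percent correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dfc import DfcMatrix
from .errors import ConfigError, DataError, NumericalError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdentMatrix:
    """Cross-session frame-correlation matrix with subject-block structure.

    Rows index session-1 frames, columns session-2 frames; both axes carry
    the same subjects in the same order, ``frames_per_subject`` consecutive
    frames per subject.
    """

    values: np.ndarray
    n_subjects: int
    frames_per_subject: int
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = self.n_subjects * self.frames_per_subject
        if values.shape != (n, n):
            raise DataError(
                f"matrix shape {values.shape} does not match "
                f"{self.n_subjects} subjects x {self.frames_per_subject} frames"
            )
        if np.abs(values).max(initial=0.0) > 1.0 + 1e-9:
            raise DataError("identifiability matrix has entries outside [-1, 1]")
        if len(self.subject_ids) != self.n_subjects:
            raise DataError("subject_ids length does not match n_subjects")

    def block(self, p: int, q: int) -> np.ndarray:
        """The w̃ × w̃ sub-block for row-subject p, column-subject q."""
        w = self.frames_per_subject
        return self.values[p * w : (p + 1) * w, q * w : (q + 1) * w]


@dataclass(frozen=True)
class IdentScores:
    """dIself/dIothers/dIdiff over j = 1..w̃ plus IR, all on percent scale."""

    di_self: np.ndarray
    di_others: np.ndarray
    di_diff: np.ndarray
    identification_rate: float | None = None
    confusion: np.ndarray | None = None

    @property
    def didiff1(self) -> float:
        """The headline scalar: dIdiff at j = 1 (single best frame)."""
        return float(self.di_diff[0])


def _frame_array(item) -> np.ndarray:
    return item.values if isinstance(item, DfcMatrix) else np.atleast_2d(np.asarray(item, dtype=float))


def identifiability_matrix(
    session1: Sequence, session2: Sequence, subject_ids: Sequence[str] | None = None
) -> IdentMatrix:
    """Correlate every session-1 frame with every session-2 frame.

    Both sequences must hold the same subjects in the same order with equal
    frame counts and (for :class:`~dfcfp.dfc.DfcMatrix` inputs) identical
    region-pair orderings. Frames are correlated with full Pearson — mean
    removed over the r̃ entries — since after common-component subtraction a
    frame is an arbitrary vector, not a bounded correlation pattern.
    """
    if len(session1) != len(session2) or len(session1) == 0:
        raise DataError(
            f"sessions have {len(session1)} and {len(session2)} subjects; "
            "need equal, nonzero counts"
        )
    pair_index = None
    for item in list(session1) + list(session2):
        if isinstance(item, DfcMatrix):
            if pair_index is None:
                pair_index = item.pair_index
            elif item.pair_index != pair_index:
                raise DataError("dFC matrices have incompatible region-pair orderings")
    arrays1 = [_frame_array(x) for x in session1]
    arrays2 = [_frame_array(x) for x in session2]
    shapes = {a.shape for a in arrays1 + arrays2}
    if len(shapes) != 1:
        raise DataError(f"frame blocks have differing shapes: {sorted(shapes)}")
    n_subjects = len(arrays1)
    w = arrays1[0].shape[1]
    if subject_ids is None:
        subject_ids = tuple(str(i) for i in range(n_subjects))
    else:
        subject_ids = tuple(str(s) for s in subject_ids)
        if len(subject_ids) != n_subjects:
            raise DataError("subject_ids length does not match the session lists")

    def standardize(frames: np.ndarray) -> np.ndarray:
        centered = frames - frames.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(centered, axis=0)
        if np.any(norms == 0):
            raise NumericalError("a frame is constant; its Pearson correlation is undefined")
        return centered / norms

    z1 = standardize(np.concatenate(arrays1, axis=1))
    z2 = standardize(np.concatenate(arrays2, axis=1))
    values = np.clip(z1.T @ z2, -1.0, 1.0)
    return IdentMatrix(
        values=values,
        n_subjects=n_subjects,
        frames_per_subject=w,
        subject_ids=subject_ids,
    )


def didiff_scores(ident: IdentMatrix, others: str = "topj") -> IdentScores:
    """Differential identifiability dIdiff(j) for j = 1..w̃, percent scale.

    Each diagonal block's w̃² entries are sorted descending; dIself(j) is the
    mean of its top j entries, averaged over subjects. ``others="topj"``
    (default) applies the same sorting to every off-diagonal block;
    ``others="all"`` instead averages all off-diagonal entries, constant in j.
    """
    if others not in ("topj", "all"):
        raise ConfigError(f"others must be 'topj' or 'all', got {others!r}")
    w = ident.frames_per_subject
    if w < 1:
        raise DataError("identifiability matrix has no frames")
    n = ident.n_subjects
    denom = np.arange(1, w + 1)

    def top_means(block: np.ndarray) -> np.ndarray:
        top = np.sort(block.ravel())[::-1][:w]
        return np.cumsum(top) / denom

    self_means = np.mean([top_means(ident.block(i, i)) for i in range(n)], axis=0)
    off_blocks = [ident.block(p, q) for p in range(n) for q in range(n) if p != q]
    if not off_blocks:
        raise DataError("need at least 2 subjects to compute dIothers")
    if others == "topj":
        others_means = np.mean([top_means(b) for b in off_blocks], axis=0)
    else:
        others_means = np.full(w, np.mean([b.mean() for b in off_blocks]))

    di_self = 100.0 * self_means
    di_others = 100.0 * others_means
    return IdentScores(di_self=di_self, di_others=di_others, di_diff=di_self - di_others)


def identification_rate(
    ident: IdentMatrix, symmetric: bool = False
) -> tuple[float, np.ndarray]:
    """Frame-level identification accuracy, percent, plus confusion matrix.

    Each column (a session-2 frame) is assigned to the subject owning the
    row with the maximum correlation; ties break to the lowest row index and
    are logged. The confusion matrix counts frames by (true, predicted)
    subject, so each row sums to w̃. ``symmetric=True`` additionally scores
    the row direction and returns the average of both rates (the confusion
    matrix stays column-direction).
    """
    a = ident.values
    n, w = ident.n_subjects, ident.frames_per_subject

    def score_columns(mat: np.ndarray) -> tuple[float, np.ndarray]:
        confusion = np.zeros((n, n), dtype=int)
        best = mat.argmax(axis=0)
        ties = int(((mat == mat.max(axis=0, keepdims=True)).sum(axis=0) > 1).sum())
        if ties:
            logger.warning(
                "%d column(s) had tied argmax; broke ties to the lowest row index", ties
            )
        for q, p in enumerate(best):
            confusion[q // w, p // w] += 1
        rate = 100.0 * np.trace(confusion) / (n * w)
        return rate, confusion

    rate, confusion = score_columns(a)
    if symmetric:
        rate_rows, _ = score_columns(a.T)
        rate = 0.5 * (rate + rate_rows)
    return rate, confusion


def score_identifiability(ident: IdentMatrix, others: str = "topj") -> IdentScores:
    """Convenience: dIdiff scores and IR from one identifiability matrix."""
    scores = didiff_scores(ident, others=others)
    rate, confusion = identification_rate(ident)
    return replace(scores, identification_rate=rate, confusion=confusion)


def export_ident_matrix(ident: IdentMatrix, path: str | Path) -> None:
    """Write A as TSV with subject:frame axis labels (for external plotting)."""
    labels = [
        f"{sid}:f{k}" for sid in ident.subject_ids for k in range(ident.frames_per_subject)
    ]
    pd.DataFrame(ident.values, index=labels, columns=labels).to_csv(path, sep="\t")
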