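"""Common orthogonal basis extraction (COBE) over multi-subject dFC.

COBE treats each training subject's dFC as one data block Yₙ (r̃ × w̃ₙ) and
finds a single orthonormal basis D (r̃ × C) whose span carries the
connectivity structure shared by all blocks. For any scan — including
subjects never seen in training — the decomposition is then a plain
orthogonal projection:

    X       = Dᵀ · Y          (least-squares coefficients)
    common  = D · X
    specific = Y − common     (the subject-specific residual)

The residual is exactly orthogonal to span(D) and is what makes individual
scans distinguishable once the shared component is removed.

Training extracts components one at a time with deflation. For component j,
alternate (i) zₙ = Yₙᵀ·d per block and (ii) d ← Σₙ Yₙ·zₙ, re-orthogonalized
against the accepted columns and normalized, until the update moves d by
less than ``tol``. This is a power iteration on the deflated pooled
covariance, so each accepted column is the dominant remaining direction of
Σₙ YₙYₙᵀ — consistent with the canonical-correlation initialization, which
seeds the search with the leading eigenvectors of that pooled covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dfc import DfcMatrix
from .errors import ConfigError, DataError
from .timeseries import NETWORK_LABELS, NetworkMap

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


def max_components(r_tilde: int, w_tilde: int) -> int:
    """Largest admissible number of common components, min(r̃, w̃).

    The canonical-correlation initialization uses eigenvectors of the pooled
    frame covariance, of which at most min(r̃, w̃) exist.
    """
    if r_tilde < 1 or w_tilde < 1:
        raise ConfigError(f"dimensions must be positive, got ({r_tilde}, {w_tilde})")
    return min(int(r_tilde), int(w_tilde))


@dataclass(frozen=True)
class CobeDictionary:
    """Learned common basis with provenance metadata.

    ``basis`` is r̃ × C with orthonormal columns; ``pair_index`` records the
    region-pair ordering the dictionary was trained on and acts as a
    compatibility fingerprint: a dictionary can only be applied to dFC with
    the identical pair ordering.
    """

    basis: np.ndarray
    pair_index: tuple[tuple[str, str], ...]
    meta: dict

    def __post_init__(self) -> None:
        basis = np.asarray(self.basis, dtype=float)
        object.__setattr__(self, "basis", basis)
        pairs = tuple((str(a), str(b)) for a, b in self.pair_index)
        object.__setattr__(self, "pair_index", pairs)
        if basis.ndim != 2 or basis.shape[0] != len(pairs):
            raise DataError(
                f"basis shape {basis.shape} incompatible with {len(pairs)} pairs"
            )
        gram = basis.T @ basis
        if np.abs(gram - np.eye(basis.shape[1])).max() > 1e-8:
            raise DataError("dictionary columns are not orthonormal (tol 1e-8)")

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.basis.shape[0]


@dataclass(frozen=True)
class DfcDecomposition:
    """Split of one dFC into common and subject-specific parts.

    ``common + subject_specific`` reconstructs the input exactly (floating-
    point subtraction identity), ``common = basis @ coefficients``, and
    ``basisᵀ @ subject_specific ≈ 0``.
    """

    common: np.ndarray
    subject_specific: np.ndarray
    coefficients: np.ndarray


def _as_blocks(dfc_list: Sequence) -> tuple[list[np.ndarray], tuple]:
    """Validate a list of DfcMatrix (or bare arrays) sharing one pair order."""
    if len(dfc_list) == 0:
        raise ConfigError("need at least one training dFC")
    pair_index = None
    blocks = []
    for item in dfc_list:
        if isinstance(item, DfcMatrix):
            if pair_index is None:
                pair_index = item.pair_index
            elif item.pair_index != pair_index:
                raise DataError(
                    "training dFC matrices have incompatible region-pair orderings"
                )
            blocks.append(np.asarray(item.values, dtype=float))
        else:
            blocks.append(np.atleast_2d(np.asarray(item, dtype=float)))
    rows = {b.shape[0] for b in blocks}
    if len(rows) != 1:
        raise DataError(f"blocks have differing pair counts: {sorted(rows)}")
    return blocks, pair_index


def _fix_column_signs(basis: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (determinism)."""
    idx = np.abs(basis).argmax(axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    return basis * signs


def init_canonical(dfc_list: Sequence, n_components: int) -> np.ndarray:
    """Canonical-correlation initialization of the common basis.

    Returns the ``n_components`` leading eigenvectors (descending eigenvalue)
    of Σₙ YₙYₙᵀ, with each block's columns normalized to unit length first.
    Computed via an economy SVD of the column-concatenated blocks, whose left
    singular vectors are exactly those eigenvectors.
    """
    blocks, _ = _as_blocks(dfc_list)
    r_tilde = blocks[0].shape[0]
    w_min = min(b.shape[1] for b in blocks)
    bound = max_components(r_tilde, w_min)
    if not 1 <= n_components <= bound:
        raise ConfigError(
            f"n_components={n_components} outside 1..min(r_tilde, w_tilde) = {bound}"
        )
    normed = []
    for block in blocks:
        norms = np.linalg.norm(block, axis=0)
        norms[norms == 0] = 1.0
        normed.append(block / norms)
    concat = np.concatenate(normed, axis=1)
    u, _, _ = np.linalg.svd(concat, full_matrices=False)
    return _fix_column_signs(u[:, :n_components])


def train_cobe(
    dfc_list: Sequence,
    n_components: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    normalize_blocks: bool = True,
) -> CobeDictionary:
    """Learn the common orthogonal basis from training subjects' dFC.

    ``normalize_blocks`` scales each subject's block to unit Frobenius norm
    so that subjects with more frames (or stronger overall connectivity) do
    not dominate the pooled covariance; disable to train on raw blocks.

    Non-convergence of a component within ``max_iter`` is recorded in the
    returned metadata (``converged=False``) rather than raised: the basis is
    still orthonormal and usable, merely not fully settled.
    """
    blocks, pair_index = _as_blocks(dfc_list)
    r_tilde = blocks[0].shape[0]
    if pair_index is None:
        # bare arrays (generic multiblock data): synthesize a placeholder
        # fingerprint so the dictionary still refuses mismatched inputs
        pair_index = tuple((f"row{i}", f"row{i}'") for i in range(r_tilde))
    w_min = min(b.shape[1] for b in blocks)
    bound = max_components(r_tilde, w_min)
    if not 1 <= n_components <= bound:
        raise ConfigError(
            f"n_components={n_components} outside 1..min(r_tilde, w_tilde) = {bound}"
        )
    if normalize_blocks:
        blocks = [b / max(np.linalg.norm(b), np.finfo(float).tiny) for b in blocks]

    d_init = init_canonical(blocks, n_components)
    basis = np.zeros((r_tilde, n_components))
    iterations: list[int] = []
    converged = True
    rng = np.random.default_rng(0)  # only for degenerate restarts
    for j in range(n_components):
        accepted = basis[:, :j]
        d = d_init[:, j].copy()
        d -= accepted @ (accepted.T @ d)
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            d = rng.standard_normal(r_tilde)
            d -= accepted @ (accepted.T @ d)
            nrm = np.linalg.norm(d)
        d /= nrm
        n_iter = max_iter
        for it in range(1, max_iter + 1):
            d_new = np.zeros(r_tilde)
            for block in blocks:
                d_new += block @ (block.T @ d)
            d_new -= accepted @ (accepted.T @ d_new)
            nrm = np.linalg.norm(d_new)
            if nrm < 1e-14:
                # no remaining common energy orthogonal to accepted columns;
                # keep the current direction
                d_new = d
                n_iter = it
                break
            d_new /= nrm
            delta = np.linalg.norm(d_new - d)
            d = d_new
            if delta < tol:
                n_iter = it
                break
        else:
            converged = False
            logger.warning(
                "COBE component %d did not converge in %d iterations", j + 1, max_iter
            )
        iterations.append(n_iter)
        basis[:, j] = d
    basis = _fix_column_signs(basis)

    residual = float(
        sum(np.linalg.norm(b - basis @ (basis.T @ b)) ** 2 for b in blocks)
    )
    first = dfc_list[0] if isinstance(dfc_list[0], DfcMatrix) else None
    meta = {
        "format_version": _FORMAT_VERSION,
        "n_components": int(n_components),
        "n_train": len(blocks),
        "window": int(first.window) if first is not None else None,
        "stride": int(first.stride) if first is not None else None,
        "iterations": iterations,
        "converged": bool(converged),
        "final_residual": residual,
        "normalize_blocks": bool(normalize_blocks),
        "tol": float(tol),
    }
    return CobeDictionary(basis=basis, pair_index=pair_index, meta=meta)


def apply_cobe(dictionary: CobeDictionary, dfc) -> DfcDecomposition:
    """Split a dFC into common and subject-specific parts by projection.

    The dFC's region-pair ordering must match the dictionary's fingerprint —
    this is the contract that lets one dictionary serve unseen subjects, and
    it fails loudly on a different atlas or ordering.
    """
    if isinstance(dfc, DfcMatrix):
        if dfc.pair_index != dictionary.pair_index:
            raise DataError(
                "dFC region-pair ordering does not match the dictionary fingerprint "
                "(different atlas or region order)"
            )
        values = dfc.values
    else:
        values = np.atleast_2d(np.asarray(dfc, dtype=float))
        if values.shape[0] != dictionary.n_pairs:
            raise DataError(
                f"dFC has {values.shape[0]} pairs, dictionary expects {dictionary.n_pairs}"
            )
    coefficients = dictionary.basis.T @ values
    common = dictionary.basis @ coefficients
    specific = values - common
    return DfcDecomposition(
        common=common, subject_specific=specific, coefficients=coefficients
    )


def network_average_basis(
    dictionary: CobeDictionary, network_map: NetworkMap, component: int = 0
) -> pd.DataFrame:
    """Average one basis column within and between the 8 networks.

    Entry (a, b) is the mean of the chosen column over all region pairs with
    one region in network a and the other in b (both in a, on the diagonal).
    Network pairs with no member region pairs get NaN and are logged.
    """
    if not 0 <= component < dictionary.n_components:
        raise ConfigError(
            f"component {component} out of range 0..{dictionary.n_components - 1}"
        )
    order = {lab: i for i, lab in enumerate(NETWORK_LABELS)}
    sums = np.zeros((8, 8))
    counts = np.zeros((8, 8), dtype=int)
    column = dictionary.basis[:, component]
    for value, (rid_a, rid_b) in zip(column, dictionary.pair_index):
        a = order[network_map.label(rid_a)]
        b = order[network_map.label(rid_b)]
        lo, hi = min(a, b), max(a, b)
        sums[lo, hi] += value
        counts[lo, hi] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    means = np.where(np.triu(np.ones((8, 8), dtype=bool)), means, means.T)
    empty = [
        (NETWORK_LABELS[i], NETWORK_LABELS[j])
        for i in range(8)
        for j in range(i, 8)
        if counts[i, j] == 0
    ]
    if empty:
        logger.warning("network pairs with no region pairs (NaN entries): %s", empty)
    return pd.DataFrame(means, index=list(NETWORK_LABELS), columns=list(NETWORK_LABELS))


# ---------------------------------------------------------------------------
# Persistence (.npz container)
# ---------------------------------------------------------------------------
# keys: format_version, basis (r̃ × C), pair_a, pair_b, plus flat meta_* keys

def save_dictionary(dictionary: CobeDictionary, path: str | Path) -> None:
    meta = dictionary.meta
    np.savez_compressed(
        path,
        format_version=_FORMAT_VERSION,
        basis=dictionary.basis,
        pair_a=np.array([p[0] for p in dictionary.pair_index]),
        pair_b=np.array([p[1] for p in dictionary.pair_index]),
        meta_n_train=meta.get("n_train", -1),
        meta_window=meta.get("window") or -1,
        meta_stride=meta.get("stride") or -1,
        meta_iterations=np.asarray(meta.get("iterations", []), dtype=int),
        meta_converged=bool(meta.get("converged", True)),
        meta_final_residual=float(meta.get("final_residual", np.nan)),
        meta_normalize_blocks=bool(meta.get("normalize_blocks", True)),
        meta_tol=float(meta.get("tol", np.nan)),
    )


def load_dictionary(path: str | Path) -> CobeDictionary:
    with np.load(path, allow_pickle=False) as npz:
        if int(npz["format_version"]) != _FORMAT_VERSION:
            raise DataError(f"unsupported dictionary container version in {path}")
        basis = npz["basis"]
        pairs = tuple(zip(npz["pair_a"].tolist(), npz["pair_b"].tolist()))
        meta = {
            "format_version": _FORMAT_VERSION,
            "n_components": basis.shape[1],
            "n_train": int(npz["meta_n_train"]),
            "window": None if int(npz["meta_window"]) < 0 else int(npz["meta_window"]),
            "stride": None if int(npz["meta_stride"]) < 0 else int(npz["meta_stride"]),
            "iterations": npz["meta_iterations"].tolist(),
            "converged": bool(npz["meta_converged"]),
            "final_residual": float(npz["meta_final_residual"]),
            "normalize_blocks": bool(npz["meta_normalize_blocks"]),
            "tol": float(npz["meta_tol"]),
        }
    return CobeDictionary(basis=basis, pair_index=pairs, meta=meta)


def describe_dictionary(dictionary: CobeDictionary) -> str:
    """Human-readable summary (used by ``dfcfp cobe inspect``)."""
    gram = dictionary.basis.T @ dictionary.basis
    ortho = float(np.abs(gram - np.eye(dictionary.n_components)).max())
    meta = dictionary.meta
    lines = [
        f"COBE dictionary: {dictionary.n_pairs} pairs x {dictionary.n_components} components",
        f"orthonormality residual (max |D'D - I|): {ortho:.3e}",
        f"trained on {meta.get('n_train')} blocks "
        f"(window={meta.get('window')}, stride={meta.get('stride')} timepoints)",
        f"iterations per component: {meta.get('iterations')}",
        f"converged: {meta.get('converged')}, "
        f"final residual: {meta.get('final_residual'):.6g}",
        f"block normalization: {meta.get('normalize_blocks')}",
    ]
    return "\n".join(lines)
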