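"""Synthetic multi-subject, two-session cohorts with planted structure.

Every stage of the fingerprinting pipeline is testable without any download
because the generator plants the very structure the method is built to
separate:

* a set of *common* connectivity patterns shared by all subjects, whose
  amplitudes drift over time (so windowed connectivity genuinely varies
  frame to frame and the common component has frame-specific coefficients);
* a per-subject *signature* — a few connectivity factors held fixed across
  that subject's two sessions (optionally partially shared within twin
  pairs), which is what makes a subject identifiable;
* session and measurement noise: fresh latent draws per session, a small
  rotation of the signature mixing vectors per session (magnitude tied to
  ``noise_sd``), and additive Gaussian sensor noise.

Time series are realized by latent-source mixing, ``X = sources @ Mᵀ + ε``:
the target covariance is carried by the mixing matrix's factor form, which
keeps every realized covariance positive semi-definite by construction and
produces genuinely dynamic windowed correlations.

A second, lower-level generator, :func:`planted_dfc_blocks`, plants a known
orthonormal basis directly in dFC (pair) space — the exact data model of the
dictionary learner — for tight recovery tests free of windowing effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import subspace_angles

from .cobe import CobeDictionary
from .dfc import make_pair_index, upper_tri_dim
from .errors import ConfigError, DataError
from .timeseries import NETWORK_LABELS, NetworkMap, RoiTimeSeries, write_network_map, write_timeseries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized resting-state cohort: 30 subjects, 40
    regions, 600 timepoints at TR 0.72 s (432 s of scan), five shared
    connectivity patterns of unit relative strength, three subject-signature
    factors at strength 0.45, and sensor noise of 0.35 — a regime in which
    raw dFC identifies most but not all subjects (~90%), leaving headroom
    that removing the common component can close.
    """

    nsub: int = 30
    r: int = 40
    T: int = 600
    tr: float = 0.72
    n_common: int = 5
    n_subject_factors: int = 3
    common_strength: float = 1.0
    subject_strength: float = 0.45
    noise_sd: float = 0.35
    twin_pairs: int = 0
    twin_share: float = 0.5
    network_sizes: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nsub < 2:
            raise ConfigError(f"need at least 2 subjects, got {self.nsub}")
        if self.r < 2 or self.T < 2:
            raise ConfigError(f"need r >= 2 and T >= 2, got r={self.r}, T={self.T}")
        if self.tr <= 0:
            raise ConfigError(f"tr must be positive, got {self.tr}")
        for name in ("common_strength", "subject_strength", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0 (mixing scales are variances)")
        if not 0 <= self.twin_share <= 1:
            raise ConfigError(f"twin_share must lie in [0, 1], got {self.twin_share}")
        if 2 * self.twin_pairs > self.nsub:
            raise ConfigError(
                f"{self.twin_pairs} twin pairs need {2 * self.twin_pairs} subjects, "
                f"cohort has {self.nsub}"
            )
        if self.n_common >= min(self.r, upper_tri_dim(self.r)):
            raise ConfigError(
                f"n_common={self.n_common} must be below min(r, r_tilde) = "
                f"{min(self.r, upper_tri_dim(self.r))}"
            )
        if self.n_subject_factors < 1:
            raise ConfigError("need at least one subject-signature factor")
        if self.network_sizes is not None:
            sizes = tuple(int(s) for s in self.network_sizes)
            if len(sizes) != len(NETWORK_LABELS) or sum(sizes) != self.r or min(sizes) < 0:
                raise ConfigError(
                    f"network_sizes must be {len(NETWORK_LABELS)} non-negative counts "
                    f"summing to r={self.r}"
                )
            object.__setattr__(self, "network_sizes", sizes)


@dataclass(frozen=True)
class SynthCohort:
    """Generated cohort plus the ground truth it was built from."""

    config: SynthConfig
    subject_ids: tuple[str, ...]
    timeseries: dict  # (subject_id, session) -> RoiTimeSeries
    common_basis: np.ndarray  # r̃ × n_common, orthonormal, pair space
    common_patterns: np.ndarray  # r × n_common, orthonormal, region space
    signatures: dict = field(repr=False, default_factory=dict)  # subject -> (r, m)
    twin_table: pd.DataFrame = field(repr=False, default=None)
    network_map: NetworkMap = None

    @property
    def region_ids(self) -> tuple[str, ...]:
        return next(iter(self.timeseries.values())).region_ids


def _orthonormal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((rows, cols)))
    idx = np.abs(q).argmax(axis=0)
    signs = np.sign(q[idx, np.arange(cols)])
    signs[signs == 0] = 1.0
    return q * signs


def _smooth_envelope(rng: np.random.Generator, t: int, smooth: int) -> np.ndarray:
    """Slowly varying positive amplitude envelope with mean 1."""
    g = rng.standard_normal(t + 2 * smooth)
    kernel = np.hanning(max(smooth, 3))
    kernel /= kernel.sum()
    g = np.convolve(g, kernel, mode="same")[smooth : smooth + t]
    g = g / (g.std() + 1e-12)
    env = np.exp(0.6 * g)
    return env / env.mean()


def _vec_upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def default_network_sizes(r: int) -> tuple[int, ...]:
    """Split r regions as evenly as possible over the 8 network labels."""
    base, extra = divmod(r, len(NETWORK_LABELS))
    return tuple(base + (1 if i < extra else 0) for i in range(len(NETWORK_LABELS)))


def generate_cohort(cfg: SynthConfig) -> SynthCohort:
    """Generate a two-session cohort with planted common/specific structure.

    Deterministic under ``cfg.seed``: the same configuration yields
    bit-identical cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    r, t, m = cfg.r, cfg.T, cfg.n_subject_factors
    region_ids = tuple(f"R{i + 1:03d}" for i in range(r))
    subject_ids = tuple(f"sub{i + 1:02d}" for i in range(cfg.nsub))

    # shared connectivity patterns (orthonormal region-space factors)
    common_patterns = _orthonormal(rng, r, cfg.n_common)

    # subject signatures; a twin's factors blend in a twin_share fraction of
    # the partner's signature variance (sqrt-weights keep unit scale), so the
    # configured fraction is represented exactly rather than rounded to a
    # whole number of factors
    signatures: dict[str, np.ndarray] = {}
    for sid in subject_ids:
        b = rng.standard_normal((r, m))
        signatures[sid] = b / np.linalg.norm(b, axis=0)
    twin_rows = []
    for k in range(cfg.twin_pairs):
        sid_a, sid_b = subject_ids[2 * k], subject_ids[2 * k + 1]
        blended = (
            np.sqrt(cfg.twin_share) * signatures[sid_a]
            + np.sqrt(1.0 - cfg.twin_share) * signatures[sid_b]
        )
        signatures[sid_b] = blended / np.linalg.norm(blended, axis=0)
        twin_rows.append({"subject_a": sid_a, "subject_b": sid_b,
                          "shared_fraction": cfg.twin_share})
    twin_table = pd.DataFrame(
        twin_rows, columns=["subject_a", "subject_b", "shared_fraction"]
    )

    rot_sd = 0.3 * cfg.noise_sd  # session-to-session signature perturbation
    smooth = max(t // 8, 5)
    sq_common = np.sqrt(cfg.common_strength)
    sq_subject = np.sqrt(cfg.subject_strength)

    timeseries: dict[tuple[str, int], RoiTimeSeries] = {}
    for sid in subject_ids:
        for session in (1, 2):
            if rot_sd > 0:
                perturbed = signatures[sid] + rot_sd * rng.standard_normal((r, m))
                mixing = perturbed / np.linalg.norm(perturbed, axis=0)
            else:
                # keep the draw order stable so noise_sd=0 stays comparable
                rng.standard_normal((r, m))
                mixing = signatures[sid]
            envelopes = np.column_stack(
                [_smooth_envelope(rng, t, smooth) for _ in range(cfg.n_common)]
            )
            z = rng.standard_normal((t, cfg.n_common))
            u = rng.standard_normal((t, m))
            data = (
                sq_common * (np.sqrt(envelopes) * z) @ common_patterns.T
                + sq_subject * u @ mixing.T
                + cfg.noise_sd * rng.standard_normal((t, r))
            )
            timeseries[(sid, session)] = RoiTimeSeries(
                data=data, tr=cfg.tr, region_ids=region_ids
            )

    # planted common span in pair space: orthonormalized vec(a_c a_cᵀ)
    pair_patterns = np.column_stack(
        [_vec_upper(np.outer(common_patterns[:, c], common_patterns[:, c]))
         for c in range(cfg.n_common)]
    )
    common_basis, _ = np.linalg.qr(pair_patterns)

    sizes = cfg.network_sizes or default_network_sizes(r)
    assignment = {}
    cursor = 0
    for label, size in zip(NETWORK_LABELS, sizes):
        for rid in region_ids[cursor : cursor + size]:
            assignment[rid] = label
        cursor += size
    return SynthCohort(
        config=cfg,
        subject_ids=subject_ids,
        timeseries=timeseries,
        common_basis=common_basis,
        common_patterns=common_patterns,
        signatures=signatures,
        twin_table=twin_table,
        network_map=NetworkMap(assignment),
    )


def planted_dfc_blocks(
    n_subjects: int,
    r_tilde: int,
    n_frames: int,
    n_common: int,
    individual_rank: int = 2,
    individual_strength: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Plant a shared orthonormal basis directly in dFC (pair) space.

    Each subject's block is ``D0 @ X_s + E_s @ W_s + noise``: random common
    coefficients ``X_s``, per-subject individual directions ``E_s``
    orthogonal to the shared span ``D0``, and optional Gaussian noise. The
    individual coefficients ``W_s`` are made orthogonal to the rows of
    ``X_s`` and the individual strength is kept below the common one, so in
    the noise-free model the pooled covariance splits exactly into the
    common span plus weaker individual terms — the ideal case in which the
    dictionary learner recovers span(D0) to machine precision. Returns the
    blocks and ``D0`` (r̃ × n_common, orthonormal).
    """
    if n_common + individual_rank > min(r_tilde, n_frames):
        raise ConfigError(
            f"n_common + individual_rank = {n_common + individual_rank} exceeds "
            f"min(r_tilde, n_frames) = {min(r_tilde, n_frames)}"
        )
    rng = np.random.default_rng(seed)
    d0 = _orthonormal(rng, r_tilde, n_common)
    blocks = []
    for _ in range(n_subjects):
        coeffs = rng.standard_normal((n_common, n_frames))
        individual = rng.standard_normal((r_tilde, individual_rank))
        individual -= d0 @ (d0.T @ individual)
        individual, _ = np.linalg.qr(individual)
        weights = rng.standard_normal((individual_rank, n_frames))
        # zero cross-covariance with the common coefficients
        weights -= (weights @ coeffs.T) @ np.linalg.solve(coeffs @ coeffs.T, coeffs)
        block = d0 @ coeffs + individual_strength * (individual @ weights)
        if noise_sd > 0:
            block = block + noise_sd * rng.standard_normal((r_tilde, n_frames))
        blocks.append(block)
    return blocks, d0


def ground_truth_check(cohort_or_basis, dictionary: CobeDictionary) -> np.ndarray:
    """Principal angles (radians) between span(D) and the planted common span.

    Accepts a :class:`SynthCohort` (uses its pair-space ``common_basis``) or
    a bare orthonormal basis array. Angles near 0 mean the dictionary
    recovered the planted subspace; for unrelated subspaces in high dimension
    they concentrate near π/2.
    """
    basis = (
        cohort_or_basis.common_basis
        if isinstance(cohort_or_basis, SynthCohort)
        else np.asarray(cohort_or_basis, dtype=float)
    )
    if basis.shape[0] != dictionary.n_pairs:
        raise DataError(
            f"planted basis has {basis.shape[0]} pair rows, "
            f"dictionary has {dictionary.n_pairs}"
        )
    return subspace_angles(dictionary.basis, basis)


def write_cohort(cohort: SynthCohort, outdir: str | Path) -> None:
    """Write per-subject-session TSVs, the network map, and the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (sid, session), ts in cohort.timeseries.items():
        write_timeseries(ts, outdir / f"{sid}_ses-{session}.tsv")
    write_network_map(cohort.network_map, outdir / "network_map.tsv")
    cohort.twin_table.to_csv(outdir / "twin_table.tsv", sep="\t", index=False)
    sig_ids = list(cohort.subject_ids)
    np.savez_compressed(
        outdir / "ground_truth.npz",
        common_basis=cohort.common_basis,
        common_patterns=cohort.common_patterns,
        signatures=np.stack([cohort.signatures[s] for s in sig_ids]),
        signature_subjects=np.array(sig_ids),
        pair_a=np.array([p[0] for p in make_pair_index(cohort.region_ids)]),
        pair_b=np.array([p[1] for p in make_pair_index(cohort.region_ids)]),
    )
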