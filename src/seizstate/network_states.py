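"""Seizure network states via NMF with stability-based rank selection.

The concatenated window-by-feature connectivity matrix of one patient is
soft-clustered with non-negative matrix factorization, X ~ W H, where each
column of W is the connectivity pattern of one seizure network state (SNS)
and H gives its expression per window. Because NMF is non-deterministic, the
number of states is chosen by stability: the rank at which independently
seeded fits keep producing the same set of basis patterns. Each window is
then hard-labelled by the dominant state, and two per-seizure features are
derived — occurrence (does the state appear in the seizure at all) and
duration (how many windows the seizure spends in it).

States are patient-specific: the factorization is never pooled across
patients, and states from different patients are not comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "NMFModel",
    "SeizureRecord",
    "nmf_fit",
    "stability_select_rank",
    "assign_states",
    "records_from_labels",
    "extract_features",
    "match_states",
]

UNASSIGNED = -1


@dataclass
class NMFModel:
    """Fitted factorization: W (feature x state, unit-L2 columns), H (state x window)."""

    W: np.ndarray
    H: np.ndarray
    k: int
    reconstruction_error: float
    stability_curve: dict[int, float] | None = None


@dataclass
class SeizureRecord:
    """One seizure's state progression and derived features."""

    id: object
    onset_day: float
    state_sequence: np.ndarray          # per-window labels; UNASSIGNED allowed
    durations: dict[int, int]           # state -> window count, present states only
    contains: frozenset[int]

    def __post_init__(self) -> None:
        if self.onset_day < 0:
            raise ValueError("onset_day must be >= 0")


def nmf_fit(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 500, tol: float = 1e-6) -> NMFModel:
    """Frobenius NMF by multiplicative updates from a seeded random init.

    Columns of W are rescaled to unit L2 norm with the scale moved into H,
    so basis patterns are comparable across fits.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("NMF requires a non-negative matrix")
    if not 1 <= k < min(X.shape):
        raise ValueError(f"rank {k} must be in [1, min(X.shape) - 1]")
    model = NMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # the iteration cap is part of the contract, not a convergence failure
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(X)
    H = model.components_
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]
    return NMFModel(W=W, H=H, k=k, reconstruction_error=float(model.reconstruction_err_))


def _matched_cosine(W1: np.ndarray, W2: np.ndarray) -> float:
    """Mean cosine similarity of the Hungarian-matched columns of W1, W2."""
    sim = W1.T @ W2  # columns are unit-norm
    row, col = linear_sum_assignment(-sim)
    return float(sim[row, col].mean())


def stability_select_rank(
    X: np.ndarray,
    rank_range: Sequence[int],
    n_repeats: int = 20,
    seed: int = 0,
    tau: float = 0.01,
    max_iter: int = 500,
) -> tuple[int, dict[int, float]]:
    """Pick the NMF rank whose basis patterns replicate across random restarts.

    For each candidate rank, ``n_repeats`` independently seeded fits are run
    and instability is the mean over fit pairs of (1 - mean Hungarian-matched
    cosine similarity between the two W matrices). The selected rank is the
    largest with instability <= ``tau``; if none qualifies, the rank with the
    smallest instability. Returns (k*, {rank: instability}).
    """
    X = np.asarray(X, dtype=float)
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 (pairwise instability undefined)")
    if np.any(~np.isfinite(X)):
        raise ValueError("non-finite entries in X")
    col_norms = np.linalg.norm(X, axis=0)
    if np.all(col_norms == 0):
        raise ValueError("degenerate input: all-zero columns")
    rank_range = sorted(set(int(r) for r in rank_range))
    if rank_range[0] < 2 or rank_range[-1] >= min(X.shape):
        raise ValueError("rank_range must lie within [2, min(X.shape) - 1]")

    ss = np.random.SeedSequence(seed)
    curve: dict[int, float] = {}
    for rank in rank_range:
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_repeats)]
        Ws = [nmf_fit(X, rank, seed=s, max_iter=max_iter).W for s in seeds]
        sims = [_matched_cosine(Ws[i], Ws[j]) for i, j in combinations(range(n_repeats), 2)]
        curve[rank] = 1.0 - float(np.mean(sims))
    stable = [r for r in rank_range if curve[r] <= tau]
    k_star = max(stable) if stable else min(curve, key=curve.get)
    return k_star, curve


def assign_states(model: NMFModel) -> np.ndarray:
    """Hard labels: per window, the state with the largest H coefficient.

    Ties break toward the lowest state index (argmax convention); windows
    whose H column is entirely zero get the sentinel ``UNASSIGNED`` and are
    excluded from occurrence/duration features.
    """
    labels = np.argmax(model.H, axis=0)
    labels[model.H.sum(axis=0) == 0] = UNASSIGNED
    return labels


def records_from_labels(
    labels: np.ndarray,
    window_seizure: np.ndarray,
    onset_days: Sequence[float],
    seizure_ids: Sequence | None = None,
) -> list[SeizureRecord]:
    """Group window labels into per-seizure records using the window->seizure map."""
    labels = np.asarray(labels)
    window_seizure = np.asarray(window_seizure)
    n_seiz = len(onset_days)
    if seizure_ids is None:
        seizure_ids = list(range(n_seiz))
    records = []
    for s in range(n_seiz):
        seq = labels[window_seizure == s]
        assigned = seq[seq != UNASSIGNED]
        states, counts = np.unique(assigned, return_counts=True)
        durations = {int(st): int(c) for st, c in zip(states, counts)}
        records.append(
            SeizureRecord(
                id=seizure_ids[s],
                onset_day=float(onset_days[s]),
                state_sequence=seq,
                durations=durations,
                contains=frozenset(durations),
            )
        )
    return records


def extract_features(
    records: Sequence[SeizureRecord], n_states: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occurrence and duration tables for downstream association tests.

    The occurrence table is seizure x state boolean with a
    ``excluded_from_occurrence`` attribute listing states present in every
    seizure (no variability, nothing to test) — those states remain in the
    duration table. The duration table has one (seizure_id, onset_day, sns,
    windows) row per state actually visited; zero durations never appear, so
    duration effects are not driven by occurrence.
    """
    occ = pd.DataFrame(
        [[s in r.contains for s in range(n_states)] for r in records],
        index=pd.Index([r.id for r in records], name="seizure_id"),
        columns=pd.Index(range(n_states), name="sns"),
    )
    always = [int(s) for s in occ.columns[occ.all(axis=0)]]
    occ.attrs["excluded_from_occurrence"] = always
    occ.attrs["onset_day"] = {r.id: r.onset_day for r in records}
    dur_rows = [
        {"seizure_id": r.id, "onset_day": r.onset_day, "sns": s, "windows": w}
        for r in records
        for s, w in sorted(r.durations.items())
    ]
    dur = pd.DataFrame(dur_rows, columns=["seizure_id", "onset_day", "sns", "windows"])
    return occ, dur


def match_states(W_fit: np.ndarray, W_true: np.ndarray) -> np.ndarray:
    """Permutation mapping fitted state indices onto reference states.

    Hungarian assignment on the cosine-similarity matrix of (unit-normalised)
    columns; returns ``perm`` with ``perm[fitted_index] = reference_index``.
    """
    a = W_fit / np.maximum(np.linalg.norm(W_fit, axis=0), 1e-12)
    b = W_true / np.maximum(np.linalg.norm(W_true, axis=0), 1e-12)
    row, col = linear_sum_assignment(-(a.T @ b))
    perm = np.empty(W_fit.shape[1], dtype=int)
    perm[row] = col
    return perm
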