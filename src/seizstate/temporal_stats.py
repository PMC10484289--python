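"""Association tests between seizure network-state features and temporal factors.

Four analyses, applied per patient and pooled into one cohort-wide FDR family:

* occurrence vs. time since implantation — Wilcoxon rank-sum on seizure times,
  reported as the equivalent ROC AUC;
* duration vs. time since implantation — Spearman correlation on non-zero
  state durations;
* occurrence vs. cycle phase — phase-locking value (PLV, the modulus of the
  mean resultant vector of seizure phases) with a subset-resampling
  permutation null that absorbs the phase preference of seizure timing
  itself;
* duration vs. cycle phase — rank circular-linear correlation D with a
  shuffle permutation null.

Permutation p-values use the add-one rule p = (#{T_perm >= T_obs} + 1) /
(n_perm + 1), so they are never exactly zero and remain valid at any
permutation count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhaseLocking",
    "AssociationResult",
    "occurrence_vs_time",
    "duration_vs_time",
    "plv",
    "plv_occurrence_test",
    "circ_linear_rank_corr",
    "duration_phase_test",
    "fdr_correct",
]


@dataclass(frozen=True)
class PhaseLocking:
    """Mean resultant vector of a circular sample: R e^{-i psi} = mean e^{-i phi_s}."""

    R: float
    psi: float
    S: int


@dataclass
class AssociationResult:
    """One (state feature x temporal factor) test for one patient."""

    patient: str
    sns: int
    feature: str               # "occurrence" | "duration"
    factor: str                # "time_since_implantation" | cycle id
    statistic: str             # "AUC" | "spearman_rho" | "PLV" | "D"
    value: float
    effect: float | None       # e.g. delta-PLV vs all-seizure PLV
    p_raw: float
    p_method: str              # "rank-sum" | "spearman-t" | "permutation"
    n_permutations: int = 0
    p_adj: float | None = None
    fdr_significant: bool | None = None
    excluded: bool = False     # precondition failed -> outside the FDR family
    extra: dict = field(default_factory=dict)


def occurrence_vs_time(
    times_with: Sequence[float], times_without: Sequence[float]
) -> tuple[float, float]:
    """AUC and two-sided rank-sum p for separating seizures with/without a state.

    AUC = P(T_with > T_without) + 0.5 P(T_with = T_without) over all pairs
    (= Mann-Whitney U / (n1*n2)); AUC > 0.5 means the state favours later
    seizures. The p-value is the tie-corrected normal approximation of the
    Wilcoxon rank-sum test.
    """
    x = np.asarray(times_with, dtype=float)
    y = np.asarray(times_without, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty (filter always/never-present states)")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    auc = res.statistic / (x.size * y.size)
    return float(auc), float(res.pvalue)


def duration_vs_time(
    durations: Sequence[float], times: Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation (midranks, t-approximation p) of durations vs times."""
    d = np.asarray(durations, dtype=float)
    t = np.asarray(times, dtype=float)
    if d.size < 5:
        raise ValueError("need >= 5 non-zero durations")
    if np.ptp(d) == 0 or np.ptp(t) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = sps.spearmanr(d, t)
    return float(rho), float(p)


def plv(phases: Sequence[float]) -> PhaseLocking:
    """Phase-locking value: modulus R and angle psi of the mean resultant vector."""
    phi = np.asarray(phases, dtype=float)
    if phi.size == 0:
        raise ValueError("empty phase sample")
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite phases")
    z = np.exp(-1j * phi).mean()
    # R e^{-i psi} = mean(e^{-i phi})  =>  psi = -angle(mean)
    return PhaseLocking(R=float(np.abs(z)), psi=float(-np.angle(z)), S=phi.size)


def _subset_plvs(phases_all: np.ndarray, S: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """PLV of ``n_perm`` random size-S subsets drawn without replacement."""
    n = phases_all.size
    # argsort of uniforms = random permutation per row; keep first S columns
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :S]
    z = np.exp(-1j * phases_all)[order]
    return np.abs(z.mean(axis=1))


def plv_occurrence_test(
    phases_with: Sequence[float],
    phases_all: Sequence[float],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Permutation test of a state's phase preference beyond seizure timing.

    The null redraws S seizures (without replacement) from all analysed
    seizures and recomputes the PLV, so any phase locking of seizure timing
    itself is preserved under the null. Returns (R_obs, delta_R, p) where
    delta_R = R_obs - R(all seizures).
    """
    phi_w = np.asarray(phases_with, dtype=float)
    phi_a = np.asarray(phases_all, dtype=float)
    S = phi_w.size
    if S < 3:
        raise ValueError("need >= 3 seizures with the state")
    if S > phi_a.size:
        raise ValueError("subset larger than the full seizure sample")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r_obs = plv(phi_w).R
    r_all = plv(phi_a).R
    null = _subset_plvs(phi_a, S, n_perm, rng)
    # ">= observed" with a float-noise guard so exact ties (e.g. S = n) count
    p = (np.count_nonzero(null >= r_obs - 1e-12) + 1) / (n_perm + 1)
    return float(r_obs), float(r_obs - r_all), float(p)


def _rank_uniform_scores(x: np.ndarray) -> np.ndarray:
    """Midrank-based uniform circular scores u_i = 2 pi rank_i / n."""
    return 2.0 * np.pi * sps.rankdata(x) / x.size


def circ_linear_rank_corr(
    durations: Sequence[float], phases: Sequence[float]
) -> float:
    """Rank circular-linear correlation D in [0, 1].

    Durations are replaced by rank-uniform circular scores u; D is the
    squared circular-linear correlation of (u, phi): with r_c = corr(u, cos
    phi), r_s = corr(u, sin phi), r_cs = corr(cos phi, sin phi),

        D = (r_c^2 + r_s^2 - 2 r_c r_s r_cs) / (1 - r_cs^2),

    clipped to [0, 1]. Monotone-invariant in the durations; significance is
    assessed by permutation (`duration_phase_test`), so the normalization
    does not affect calibration.
    """
    d = np.asarray(durations, dtype=float)
    phi = np.asarray(phases, dtype=float)
    if d.size != phi.size or d.size < 5:
        raise ValueError("need matched samples with n >= 5")
    if np.ptp(d) == 0:
        raise ValueError("constant durations: correlation undefined")
    u = _rank_uniform_scores(d)
    c, s = np.cos(phi), np.sin(phi)
    cm = np.corrcoef(np.vstack([u, c, s]))
    r_c, r_s, r_cs = cm[0, 1], cm[0, 2], cm[1, 2]
    denom = 1.0 - r_cs**2
    if not np.isfinite(denom) or denom < 1e-12:
        raise ValueError("degenerate phase spread")
    D = (r_c**2 + r_s**2 - 2 * r_c * r_s * r_cs) / denom
    return float(np.clip(D, 0.0, 1.0))


def duration_phase_test(
    durations: Sequence[float],
    phases: Sequence[float],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Shuffle test of duration-phase coupling: (D_obs, p).

    Durations are shuffled against the fixed phases; the p-value is the
    add-one fraction of shuffled D at least as large as the observed D.
    """
    d = np.asarray(durations, dtype=float)
    phi = np.asarray(phases, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    D_obs = circ_linear_rank_corr(d, phi)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = d.size
    u = _rank_uniform_scores(d)
    c, s = np.cos(phi), np.sin(phi)
    # permuting durations == permuting their rank scores against fixed phases;
    # compute all shuffled correlations with one matrix product
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    U = u[order]                            # (n_perm, n)
    Uc = U - U.mean(axis=1, keepdims=True)
    su = np.sqrt((Uc**2).sum(axis=1))
    cc = c - c.mean()
    ss = s - s.mean()
    r_c = Uc @ cc / (su * np.linalg.norm(cc))
    r_s = Uc @ ss / (su * np.linalg.norm(ss))
    r_cs = float(np.corrcoef(c, s)[0, 1])
    D_null = (r_c**2 + r_s**2 - 2 * r_c * r_s * r_cs) / (1.0 - r_cs**2)
    D_null = np.clip(D_null, 0.0, 1.0)
    p = (np.count_nonzero(D_null >= D_obs - 1e-12) + 1) / (n_perm + 1)
    return float(D_obs), float(p)


def fdr_correct(
    results: Iterable[AssociationResult], alpha: float = 0.05
) -> list[AssociationResult]:
    """Benjamini-Hochberg step-up over the full cohort-wide test family.

    Results flagged ``excluded`` (failed preconditions) are left out of the
    family and keep ``p_adj = None``. Annotates and returns the list.
    """
    results = list(results)
    family = [r for r in results if not r.excluded]
    if family:
        pvals = np.array([r.p_raw for r in family])
        reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for r, rej, pa in zip(family, reject, p_adj):
            r.fdr_significant = bool(rej)
            r.p_adj = float(pa)
    return results
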