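"""Per-window two-group differential coverage testing.

The count model is negative binomial with a common dispersion phi shared
across windows, parameterised so that Var(Y) = mu + phi * mu**2 (phi = 0 is
the Poisson limit).  The pipeline is:

1. TMM normalisation factors (trimmed mean of M-values) turn raw library
   sizes into effective library sizes.
2. Counts are scaled (and rounded) to a common effective library size --
   the geometric mean -- so that samples are exchangeable within a group.
3. A single common dispersion is estimated by maximising the conditional
   log-likelihood summed over windows (the conditional law given a group's
   total count does not involve the mean, only the dispersion).
4. Each window gets a two-sided exact test: conditional on the pooled count
   S = yA + yB, the probability of each split (a, S - a) is the product of
   the two group-sum NB masses, and the p-value sums every split whose
   probability does not exceed that of the observed split.  The sum of n
   iid NB(mu, phi) variables is NB(n*mu, phi/n), which gives the group-sum
   laws in closed form.
5. Benjamini-Hochberg adjustment across all tested windows.

All mass-function arithmetic is in log space; ties in the two-sided
summation are resolved with a relative tolerance of 1e-12 so that float
evaluation order cannot change a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .coverage import WindowCountMatrix

__all__ = [
    "GroupDesign",
    "DispersionModel",
    "WindowTestResult",
    "tmm_norm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "test_all_windows",
    "adjust_fdr",
]

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class GroupDesign:
    """Two-group design: disease vs nondisease sample assignment."""

    sample_ids: tuple[str, ...]
    group: dict[str, str]  # sample -> "disease" | "nondisease"

    def __post_init__(self) -> None:
        for s in self.sample_ids:
            if self.group.get(s) not in ("disease", "nondisease"):
                raise ValueError(f"sample {s!r} lacks a disease/nondisease label")
        if not self.disease_samples() or not self.nondisease_samples():
            raise ValueError("both groups must be non-empty")

    @classmethod
    def from_labels(cls, labels: Mapping[str, bool]) -> "GroupDesign":
        return cls(
            sample_ids=tuple(labels),
            group={s: "disease" if v else "nondisease" for s, v in labels.items()},
        )

    def disease_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.group[s] == "disease"]

    def nondisease_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.group[s] == "nondisease"]


@dataclass(frozen=True)
class DispersionModel:
    common_dispersion: float
    norm_factors: dict[str, float]


@dataclass(frozen=True)
class WindowTestResult:
    chrom: str
    start: int
    end: int
    mean_disease: float
    mean_nondisease: float
    log2_fold_change: float
    fold_change_ratio: float
    p_value: float
    fdr: float = float("nan")


def tmm_norm_factors(
    matrix: WindowCountMatrix,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> dict[str, float]:
    """Trimmed-mean-of-M-values normalisation factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions.  For every other sample the
    per-window log2 ratio M and log2 abundance A (both on library-size
    scale) are computed over windows with positive counts in both samples;
    the top/bottom ``logratio_trim`` of M and ``abundance_trim`` of A are
    discarded; the remaining M are averaged with inverse asymptotic-variance
    weights and exponentiated.  Factors are re-centred to geometric mean 1.
    """
    counts = matrix.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    colsum = counts.sum(axis=0)
    if np.any(colsum == 0):
        bad = [s for s, t in zip(matrix.sample_ids, colsum) if t == 0]
        raise ValueError(f"all-zero counts for samples: {bad}")
    lib = matrix.library_size_vector()
    f75 = np.array(
        [np.percentile(counts[:, j], 75) / lib[j] for j in range(counts.shape[1])]
    )
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(counts.shape[1])
    yr = counts[:, ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        yk = counts[:, j]
        ok = (yk > 0) & (yr > 0)
        if not np.any(ok):
            continue
        pk = yk[ok] / lib[j]
        pr = yr[ok] / lib[ref]
        M = np.log2(pk / pr)
        A = 0.5 * np.log2(pk * pr)
        if np.allclose(M, M[0]):
            factors[j] = 2.0 ** M[0]
            continue
        lo_M, hi_M = np.quantile(M, [logratio_trim, 1 - logratio_trim])
        lo_A, hi_A = np.quantile(A, [abundance_trim, 1 - abundance_trim])
        keep = (M >= lo_M) & (M <= hi_M) & (A >= lo_A) & (A <= hi_A)
        if not np.any(keep):
            keep = np.ones_like(M, dtype=bool)
        # delta-method variance of M for binomial-like counts
        v = (lib[j] - yk[ok]) / (lib[j] * yk[ok]) + (lib[ref] - yr[ok]) / (
            lib[ref] * yr[ok]
        )
        w = 1.0 / v
        factors[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return dict(zip(matrix.sample_ids, factors))


def _equalized_pseudocounts(
    matrix: WindowCountMatrix, norm_factors: Mapping[str, float]
) -> tuple[np.ndarray, float]:
    """Counts linearly scaled and rounded to the geometric-mean effective
    library size (an approximation to full quantile adjustment)."""
    lib = matrix.library_size_vector()
    f = np.array([norm_factors[s] for s in matrix.sample_ids])
    eff = lib * f
    geo = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.rint(matrix.counts * (geo / eff)[None, :]).astype(np.int64)
    return pseudo, geo


def _group_indices(matrix: WindowCountMatrix, design: GroupDesign) -> tuple[np.ndarray, np.ndarray]:
    if set(design.sample_ids) - set(matrix.sample_ids):
        missing = set(design.sample_ids) - set(matrix.sample_ids)
        raise ValueError(f"design samples absent from matrix: {sorted(missing)}")
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    iA = np.array([col[s] for s in design.disease_samples()])
    iB = np.array([col[s] for s in design.nondisease_samples()])
    return iA, iB


def _conditional_loglik(pseudo_group: np.ndarray, phi: float) -> float:
    """Sum over windows of the NB conditional log-likelihood given the
    group total (mean-free; depends only on the dispersion)."""
    n = pseudo_group.shape[1]
    z = pseudo_group.sum(axis=1)
    r = 1.0 / phi
    ll = (
        gammaln(pseudo_group + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    matrix: WindowCountMatrix,
    design: GroupDesign,
    norm_factors: Mapping[str, float] | None = None,
) -> float:
    """Common dispersion by conditional maximum likelihood.

    Counts are first equalised to a common effective library size; within
    each group the conditional likelihood of the counts given their total
    is a function of phi alone, and the summed conditional log-likelihood
    over windows and groups is maximised on log10(phi) in [1e-6, 10].
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    if norm_factors is None:
        norm_factors = tmm_norm_factors(matrix)
    pseudo, _ = _equalized_pseudocounts(matrix, norm_factors)
    iA, iB = _group_indices(matrix, design)
    keep = matrix.counts.sum(axis=1) > 0
    groups = [pseudo[keep][:, idx] for idx in (iA, iB) if len(idx) >= 2]
    if not groups:
        raise ValueError("no group with >=2 samples; dispersion not estimable")

    def neg(log10_phi: float) -> float:
        phi = 10.0**log10_phi
        return -sum(_conditional_loglik(g, phi) for g in groups)

    res = minimize_scalar(neg, bounds=(-6.0, 1.0), method="bounded")
    return float(10.0**res.x)


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log NB mass with Var = mean + phi*mean**2; phi = 0 is Poisson."""
    k = np.asarray(k, dtype=float)
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if phi == 0.0:
        return k * np.log(mean) - mean - gammaln(k + 1)
    r = 1.0 / phi
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1)
        + r * np.log(r / (r + mean))
        + k * np.log(mean / (r + mean))
    )


def nb_exact_test(
    yA: int, yB: int, nA: int, nB: int, mu: float, phi: float
) -> float:
    """Two-sided exact NB test conditional on the pooled count.

    With S = yA + yB fixed, P(a) is proportional to
    f_NB(a; nA*mu, phi/nA) * f_NB(S - a; nB*mu, phi/nB) for a = 0..S, and
    the p-value is the normalised sum of P(a) over every split at least as
    extreme (probability <= that of the observed split, with a 1e-12
    relative tie tolerance).  S = 0 gives p = 1.
    """
    if yA < 0 or yB < 0 or nA < 1 or nB < 1 or phi < 0:
        raise ValueError("counts must be >= 0, group sizes >= 1, phi >= 0")
    S = int(yA) + int(yB)
    if S == 0:
        return 1.0
    if mu <= 0:
        raise ValueError("mu must be positive when S > 0")
    a = np.arange(S + 1)
    logp = _nb_logpmf(a, nA * mu, phi / nA) + _nb_logpmf(S - a, nB * mu, phi / nB)
    logp -= logsumexp(logp)
    obs = logp[int(yA)]
    mask = logp <= obs + np.log1p(_TIE_RTOL)
    if mask.all():  # observed split is (tied with) the mode: every term counts
        return 1.0
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_all_windows(
    matrix: WindowCountMatrix,
    design: GroupDesign,
    model: DispersionModel,
) -> list[WindowTestResult]:
    """Exact test for every retained window (total count > 0).

    Group means are reported on the equalised-library scale; the fold
    change is disease / nondisease with a 0.5 pseudocount added to both
    group means whenever either is zero, so log ratios stay finite.
    """
    iA, iB = _group_indices(matrix, design)
    pseudo, _ = _equalized_pseudocounts(matrix, model.norm_factors)
    keep = np.flatnonzero(matrix.counts.sum(axis=1) > 0)
    nA, nB = len(iA), len(iB)
    phi = model.common_dispersion
    grid = matrix.grid
    results: list[WindowTestResult] = []
    pvals = np.empty(len(keep))
    for k, w in enumerate(keep):
        yA = int(pseudo[w, iA].sum())
        yB = int(pseudo[w, iB].sum())
        S = yA + yB
        mu = S / (nA + nB)
        pvals[k] = nb_exact_test(yA, yB, nA, nB, mu, phi) if S > 0 else 1.0
    fdr = adjust_fdr(np.clip(pvals, np.nextafter(0, 1), 1.0))
    for k, w in enumerate(keep):
        mA = float(pseudo[w, iA].mean())
        mB = float(pseudo[w, iB].mean())
        if mA == 0.0 or mB == 0.0:
            ratio = (mA + 0.5) / (mB + 0.5)
        else:
            ratio = mA / mB
        results.append(
            WindowTestResult(
                chrom=str(grid.chroms[w]),
                start=int(grid.starts[w]),
                end=int(grid.ends[w]),
                mean_disease=mA,
                mean_nondisease=mB,
                log2_fold_change=float(np.log2(ratio)),
                fold_change_ratio=float(ratio),
                p_value=float(pvals[k]),
                fdr=float(fdr[k]),
            )
        )
    return results


def results_to_frame(results: Sequence[WindowTestResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in results],
            "start": [r.start for r in results],
            "end": [r.end for r in results],
            "mean_disease": [r.mean_disease for r in results],
            "mean_nondisease": [r.mean_nondisease for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "fold_change_ratio": [r.fold_change_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
        }
    )
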