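"""Per-group SD tables, the two-component normal mixture of SDs, and the
dual-group variance filter.

The filter's premise: across a small panel of single cells, most probesets
show only measurement-level variability (a low-SD normal component) while a
minority vary because of genuine expression differences (a high-SD
component).  Fitting a two-component normal mixture to the distribution of
per-group SDs makes that split explicit; the operative filter then retains
probesets whose SD exceeds a cutoff (study practice: 2.5 on log2 signal) in
*both* the target and the comparison group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrixio import ExpressionMatrix

DEFAULT_SD_THRESHOLD = 2.5


def per_group_sd(
    matrix: ExpressionMatrix, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Sample SD (ddof=1) per probe within the target and comparison groups.

    Computed on log2(x+1)-transformed signal.  Each group must contain at
    least two of the matrix's cells.
    """
    log2 = matrix.log2()
    out = {}
    for group in ("target", "comparison"):
        cells = [c for c in matrix.cell_ids if groups.get(c) == group]
        if len(cells) < 2:
            raise ValueError(
                f"group {group!r} has {len(cells)} cell(s); need at least 2 to "
                "compute an SD"
            )
        out[f"sd_{group}"] = log2[cells].std(axis=1, ddof=1)
    return pd.DataFrame(out)


@dataclass
class SDMixtureResult:
    """EM fit of a two-component normal mixture, components in increasing-mean
    order."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    ll_path: list[float]
    n_iterations: int
    converged: bool
    n_obs: int

    def __post_init__(self) -> None:
        if not (self.means[0] < self.means[1]):
            raise ValueError("components must be ordered by increasing mean")
        if not all(0.0 < w < 1.0 for w in self.weights):
            raise ValueError("weights must lie in (0, 1)")
        if not all(s > 0.0 for s in self.sds):
            raise ValueError("component SDs must be positive")

    def component_density(self, x: np.ndarray) -> np.ndarray:
        """Weighted component densities, shape (2, len(x))."""
        x = np.asarray(x, dtype=float)
        return np.stack(
            [
                w * stats.norm.pdf(x, m, s)
                for w, m, s in zip(self.weights, self.means, self.sds)
            ]
        )

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        dens = self.component_density(x)
        return dens / dens.sum(axis=0, keepdims=True)

    def summary(self) -> str:
        w, m, s = self.weights, self.means, self.sds
        lines = [
            "Two-component normal mixture of per-group SDs",
            "=" * 52,
            f"{'component':<14}{'weight':>10}{'mean':>10}{'sd':>10}",
            f"{'noise (low)':<14}{w[0]:>10.4f}{m[0]:>10.4f}{s[0]:>10.4f}",
            f"{'informative':<14}{w[1]:>10.4f}{m[1]:>10.4f}{s[1]:>10.4f}",
            "-" * 52,
            f"n = {self.n_obs}, log-likelihood = {self.log_likelihood:.4f}",
            f"iterations = {self.n_iterations}, converged = {self.converged}",
            f"suggested threshold (density crossing) = {suggest_threshold(self):.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "weights": list(self.weights),
            "means": list(self.means),
            "sds": list(self.sds),
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def _em_init(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Median-split initialisation: per-half moments; degenerate halves fall
    back to (min, max) means with the pooled SD."""
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    pooled = float(np.std(x)) or 1.0
    if len(lo) >= 2 and len(hi) >= 2 and np.ptp(lo) > 0 and np.ptp(hi) > 0:
        mu = np.array([lo.mean(), hi.mean()])
        sig = np.array([max(lo.std(), 1e-3 * pooled), max(hi.std(), 1e-3 * pooled)])
        w = np.array([len(lo), len(hi)], dtype=float) / len(x)
    else:
        mu = np.array([float(x.min()), float(x.max())])
        sig = np.array([pooled, pooled])
        w = np.array([0.5, 0.5])
    if mu[0] == mu[1]:
        mu[1] = mu[0] + pooled
    return w, mu, sig


def fit_sd_mixture(
    sds: Sequence[float],
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> SDMixtureResult:
    """Fit a two-component normal mixture to SD values by EM.

    Deterministic: the moment-based initialisation does not consume
    randomness, so the ``seed`` only matters for future stochastic restarts
    and is recorded for reproducibility.  The log-likelihood is monotone
    nondecreasing across iterations (a property of EM, asserted each step);
    convergence is declared when its relative change drops below ``tol``.
    """
    x = np.asarray(sds, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if len(x) < 10:
        raise ValueError("need at least 10 SD values to fit a mixture")
    if np.ptp(x) == 0:
        raise ValueError("degenerate SD distribution: all values identical")

    w, mu, sig = _em_init(x)
    sig_floor = max(1e-6, 1e-6 * float(np.std(x)))
    ll_path: list[float] = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step (log-space for numerical safety)
        log_dens = np.stack(
            [np.log(w[k]) + stats.norm.logpdf(x, mu[k], sig[k]) for k in range(2)]
        )
        log_norm = np.logaddexp(log_dens[0], log_dens[1])
        ll = float(log_norm.sum())
        if ll + 1e-9 * max(1.0, abs(ll)) < prev_ll:
            raise AssertionError("EM log-likelihood decreased")
        ll_path.append(ll)
        resp = np.exp(log_dens - log_norm)
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / len(x)
        mu = resp @ x / nk
        sig = np.sqrt(np.maximum(resp @ (x**2) / nk - mu**2, sig_floor**2))
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            converged = True
            break
        prev_ll = ll

    order = np.argsort(mu)
    return SDMixtureResult(
        weights=tuple(float(w[k]) for k in order),
        means=tuple(float(mu[k]) for k in order),
        sds=tuple(float(sig[k]) for k in order),
        log_likelihood=ll_path[-1],
        ll_path=ll_path,
        n_iterations=n_iter,
        converged=converged,
        n_obs=len(x),
    )


@dataclass
class FilterResult:
    threshold: float
    retained_probe_ids: list[str]
    n_input: int
    n_retained: int
    strict: bool = True

    def __post_init__(self) -> None:
        if self.n_retained != len(self.retained_probe_ids) or self.n_retained > self.n_input:
            raise ValueError("inconsistent filter counts")

    def to_frame(self, sd_table: pd.DataFrame) -> pd.DataFrame:
        out = sd_table.copy()
        out["retained"] = out.index.isin(set(self.retained_probe_ids))
        return out


def dual_sd_filter(
    sd_table: pd.DataFrame,
    threshold: float = DEFAULT_SD_THRESHOLD,
    strict: bool = True,
) -> FilterResult:
    """Retain probes whose SD exceeds ``threshold`` in both groups.

    ``strict`` uses ``>`` (the default reading of "above"); set False for
    ``>=``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    st, sc = sd_table["sd_target"], sd_table["sd_comparison"]
    if strict:
        keep = (st > threshold) & (sc > threshold)
    else:
        keep = (st >= threshold) & (sc >= threshold)
    retained = list(sd_table.index[keep])
    return FilterResult(
        threshold=float(threshold),
        retained_probe_ids=retained,
        n_input=int(len(sd_table)),
        n_retained=int(len(retained)),
        strict=strict,
    )


def suggest_threshold(fit: SDMixtureResult) -> float:
    """The point in (mu1, mu2) where the weighted component densities cross.

    Solves the quadratic equality of the two weighted normal log-densities;
    falls back to the midpoint when no crossing lies between the means.
    """
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    midpoint = 0.5 * (m1 + m2)
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m1**2 / s1**2 - m2**2 / s2**2 - 2.0 * math.log((w1 * s2) / (w2 * s1))
    roots: list[float]
    if abs(a) < 1e-12:
        roots = [-c / b] if abs(b) > 1e-12 else []
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if m1 < r < m2]
    if not inside:
        return midpoint
    return min(inside, key=lambda r: abs(r - midpoint))
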