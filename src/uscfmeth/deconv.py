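"""Tissue-of-origin deconvolution by expectation-maximisation.

The generative model: each sequenced read covering reference site ``i``
originates from tissue ``t`` with probability ``alpha_t`` and is methylated
with that tissue's site-specific probability ``beta_ti``.  The E-step
computes posterior tissue memberships separately for the methylated and
unmethylated reads at each site; the M-step re-estimates ``alpha`` (and,
optionally, ``beta`` jointly from pooled reference-panel and sample counts,
the full CelFiE-style update).  The log-likelihood is non-decreasing at
every iteration, a property the implementation asserts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ReferencePanel", "ProportionEstimate", "em_deconvolve", "simulate_mixture"]

_EPS = 1e-10


@dataclass
class ReferencePanel:
    """Tissues x sites reference methylation (counts or proportions)."""

    tissues: list[str]
    meth: np.ndarray  # (T, S) methylated counts
    total: np.ndarray  # (T, S) total counts
    site_chrom: list[str] = field(default_factory=list)
    site_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if self.meth.shape != self.total.shape:
            raise ValueError("meth and total must have the same shape")
        if np.any(self.meth > self.total):
            raise ValueError("methylated counts exceed totals")

    @property
    def beta(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            b = np.where(self.total > 0, self.meth / np.maximum(self.total, 1), 0.5)
        return np.clip(b, _EPS, 1 - _EPS)

    @property
    def n_sites(self) -> int:
        return self.meth.shape[1]

    @classmethod
    def from_proportions(
        cls, tissues: list[str], beta: np.ndarray, depth: int = 1000
    ) -> "ReferencePanel":
        beta = np.asarray(beta, dtype=float)
        return cls(tissues=tissues, meth=beta * depth, total=np.full_like(beta, depth))

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        chroms = self.site_chrom or ["panel"] * self.n_sites
        pos = self.site_pos if len(self.site_pos) else np.arange(self.n_sites)
        for t, tissue in enumerate(self.tissues):
            rows.append(
                pd.DataFrame(
                    {
                        "tissue": tissue,
                        "chrom": chroms,
                        "pos": pos,
                        "meth_count": self.meth[t],
                        "total_count": self.total[t],
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t")
        tissues = sorted(df["tissue"].unique())
        pivot_m = df.pivot_table(index="tissue", columns=["chrom", "pos"], values="meth_count")
        pivot_t = df.pivot_table(index="tissue", columns=["chrom", "pos"], values="total_count")
        pivot_m = pivot_m.loc[tissues]
        pivot_t = pivot_t.loc[tissues]
        return cls(
            tissues=tissues,
            meth=pivot_m.to_numpy(),
            total=pivot_t.to_numpy(),
            site_chrom=[c for c, _ in pivot_m.columns],
            site_pos=np.array([p for _, p in pivot_m.columns]),
        )


@dataclass
class ProportionEstimate:
    proportions: dict[str, float]
    log_likelihood: list[float]
    iterations: int
    converged: bool

    @property
    def alpha(self) -> np.ndarray:
        return np.array(list(self.proportions.values()))


def em_deconvolve(
    sample_meth: np.ndarray,
    sample_total: np.ndarray,
    panel: ReferencePanel,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    reestimate_reference: bool = False,
    unknown_tissues: int = 0,
) -> ProportionEstimate:
    """Estimate mixture proportions of the panel tissues in one sample.

    ``sample_meth``/``sample_total`` are per-site methylated and total read
    counts over the panel's sites.  With ``reestimate_reference`` the betas
    are re-estimated jointly from pooled panel + sample counts; extra
    ``unknown_tissues`` components with free betas can absorb signal absent
    from the panel.
    """
    m = np.asarray(sample_meth, dtype=float)
    tot = np.asarray(sample_total, dtype=float)
    u = tot - m
    if m.shape != tot.shape or m.ndim != 1:
        raise ValueError("sample counts must be matching 1-D arrays")
    if len(m) != panel.n_sites:
        raise ValueError("sample sites do not match the panel")
    keep = tot > 0
    if not keep.any():
        raise ValueError("no covered sites shared between sample and panel")
    m, u = m[keep], u[keep]
    pm, pt = panel.meth[:, keep], panel.total[:, keep]
    beta = panel.beta[:, keep]

    names = list(panel.tissues)
    if unknown_tissues:
        rng = np.random.default_rng(seed)
        extra = rng.uniform(0.1, 0.9, size=(unknown_tissues, beta.shape[1]))
        beta = np.vstack([beta, extra])
        pm = np.vstack([pm, np.zeros((unknown_tissues, beta.shape[1]))])
        pt = np.vstack([pt, np.zeros((unknown_tissues, beta.shape[1]))])
        names += [f"unknown_{i}" for i in range(unknown_tissues)]
    T = beta.shape[0]
    if T > 1 and any(
        np.allclose(beta[i], beta[j]) for i in range(T) for j in range(i + 1, T)
    ):
        warnings.warn(
            "panel contains (near-)identical tissues; proportions are not identifiable",
            stacklevel=2,
        )

    learn_beta = reestimate_reference or unknown_tissues > 0
    alpha = np.full(T, 1.0 / T)

    def loglik(alpha: np.ndarray, beta: np.ndarray) -> float:
        pmix = alpha @ beta
        qmix = alpha @ (1 - beta)
        ll = float(np.sum(m * np.log(pmix + _EPS) + u * np.log(qmix + _EPS)))
        if learn_beta:
            ll += float(
                np.sum(pm * np.log(beta) + (pt - pm) * np.log(1 - beta))
            )
        return ll

    trace = [loglik(alpha, beta)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pmix = alpha @ beta + _EPS
        qmix = alpha @ (1 - beta) + _EPS
        r = (alpha[:, None] * beta) / pmix  # posterior for methylated reads
        s = (alpha[:, None] * (1 - beta)) / qmix  # ... unmethylated reads
        w = r * m + s * u
        alpha = w.sum(axis=1) / (m + u).sum()
        alpha = alpha / alpha.sum()
        if learn_beta:
            num = pm + r * m
            den = pt + r * m + s * u
            beta = np.clip(np.where(den > 0, num / np.maximum(den, _EPS), 0.5), _EPS, 1 - _EPS)
        ll = loglik(alpha, beta)
        if ll < trace[-1] - 1e-8:
            raise AssertionError(f"EM log-likelihood decreased: {trace[-1]} -> {ll}")
        delta = ll - trace[-1]
        trace.append(ll)
        if delta < tol:
            converged = True
            break
    return ProportionEstimate(
        proportions={n: float(a) for n, a in zip(names, alpha)},
        log_likelihood=trace,
        iterations=it,
        converged=converged,
    )


def simulate_mixture(
    panel: ReferencePanel,
    alpha: np.ndarray | list[float],
    depth: int,
    n_sites: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial read counts for a known tissue mixture over the panel sites."""
    alpha = np.asarray(alpha, dtype=float)
    if abs(alpha.sum() - 1.0) > 1e-9:
        raise ValueError("alpha must sum to 1")
    rng = np.random.default_rng(seed)
    beta = panel.beta
    if n_sites is not None:
        beta = beta[:, :n_sites]
    p = alpha @ beta
    total = np.full(beta.shape[1], depth)
    meth = rng.binomial(depth, p)
    return meth.astype(float), total.astype(float)
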