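"""Network inference: activity estimation, MRA inversion, jackknife
confidence, multi-experiment consensus and per-edge gene contributions.

The estimated activity of component i after perturbing component j is the
weighted sum ``S_ij = sum_k W_ik G_jk``; subtracting the unperturbed
estimate ``S0_i = sum_k W_ik A_k`` gives the global response matrix ``R``.
Modular response analysis (MRA) inverts the global responses into local
interaction coefficients

    r = -[dg(R^-1)]^-1 R^-1

where ``dg`` keeps the diagonal; ``r_ij`` is the linearised effect of
component j on the steady state of component i and the diagonal is -1 by
construction.  Because the activity estimates carry unknown per-component
positive scale factors, only the *sign* of a coefficient is meaningful;
edges are therefore screened by resampling genes (leave-one-out by
default), keeping a directed edge only when its coefficient keeps one sign
with 95% confidence, and — when several independent experiments are
available — only when at least K of E experiments agree on that sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_data import ExpressionDataset
from .scoring import ScoringConfig, compute_scores

__all__ = [
    "InferenceConfig", "ActivityEstimate", "InteractionMatrix", "EdgeSet",
    "ConsensusNetwork", "SingularResponseError", "estimate_activity", "mra",
    "jackknife_edges", "sign_filter", "infer_edges", "consensus",
    "gene_contributions", "edges_to_frame", "write_sif",
]


class SingularResponseError(np.linalg.LinAlgError):
    """The global response matrix cannot be inverted reliably."""


@dataclass(frozen=True)
class InferenceConfig:
    alpha: float = 0.05              # sign-consistency confidence level
    two_sided: bool = False          # one-sided by default (sign consistency)
    rcond_min: float = 1e-10         # reciprocal condition number guard for R
    max_missing: float = 0.2         # tolerated fraction of failed resamples
    resampler: str = "jackknife"     # or "bootstrap"
    n_bootstrap: int = 0             # 0 -> m resamples
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.resampler not in ("jackknife", "bootstrap"):
            raise ValueError(f"unknown resampler {self.resampler!r}")


@dataclass(frozen=True)
class ActivityEstimate:
    """Estimated component activities and the global response matrix."""

    S: np.ndarray   # n x n, component i after perturbation j
    S0: np.ndarray  # length n, unperturbed
    R: np.ndarray   # n x n, R_ij = S_ij - S0_i


@dataclass(frozen=True)
class InteractionMatrix:
    """Local interaction coefficients with diagonal -1."""

    r: np.ndarray
    rcond: float = float("nan")


@dataclass(frozen=True)
class EdgeSet:
    """Resampled interaction coefficients and per-edge statistics.

    ``samples`` stacks one coefficient matrix per resample (NaN where the
    resampled problem was singular).  ``significant``/``sign`` are filled by
    :func:`sign_filter`; ``unresolvable`` marks pairs with too many failed
    resamples to call.
    """

    components: tuple[str, ...]
    samples: np.ndarray            # B x n x n
    mu: np.ndarray                 # n x n
    sigma: np.ndarray              # n x n (sample SD over resamples)
    significant: np.ndarray        # n x n bool
    sign: np.ndarray               # n x n in {-1, 0, +1}
    unresolvable: np.ndarray       # n x n bool
    alpha: float = float("nan")

    @property
    def n(self) -> int:
        return len(self.components)

    def edge_pairs(self) -> list[tuple[int, int]]:
        """Ordered pairs flagged significant, as (target i, source j)."""
        return [(i, j) for i in range(self.n) for j in range(self.n)
                if i != j and self.significant[i, j]]


@dataclass(frozen=True)
class ConsensusNetwork:
    """Edges retained across E experiments by K-of-E signed majority."""

    components: tuple[str, ...]
    K: int
    E: int
    support: np.ndarray       # n x n count of experiments backing the edge
    sign: np.ndarray          # n x n consensus sign in {-1, 0, +1}
    retained: np.ndarray      # n x n bool
    mean_coeff: np.ndarray    # n x n mean coefficient over supporting experiments
    per_experiment_mu: np.ndarray  # E x n x n
    conflicts: tuple[tuple[int, int], ...] = ()

    @property
    def n(self) -> int:
        return len(self.components)

    def interaction_matrix(self) -> InteractionMatrix:
        """Signed consensus coefficients (zero where no edge), diagonal -1."""
        r = np.where(self.retained, self.mean_coeff, 0.0)
        np.fill_diagonal(r, -1.0)
        return InteractionMatrix(r=r)

    def to_graph(self):
        """The consensus network as a signed directed :mod:`networkx` graph."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.components)
        for i in range(self.n):
            for j in range(self.n):
                if i != j and self.retained[i, j]:
                    g.add_edge(self.components[j], self.components[i],
                               sign=int(self.sign[i, j]),
                               support=int(self.support[i, j]),
                               coeff=float(self.mean_coeff[i, j]))
        return g


def estimate_activity(W: np.ndarray, ds: ExpressionDataset) -> ActivityEstimate:
    """Weighted-sum activity estimates ``S = W G^T``, ``S0 = W A`` and ``R = S - S0 1^T``."""
    W = np.asarray(W, dtype=float)
    if W.shape != (ds.n, ds.m):
        raise ValueError(f"weight matrix shape {W.shape} != {(ds.n, ds.m)}")
    S = W @ ds.G.T
    S0 = W @ ds.A
    return ActivityEstimate(S=S, S0=S0, R=S - S0[:, None])


def mra(R: np.ndarray, rcond_min: float = 1e-10) -> InteractionMatrix:
    """Invert global responses into local interaction coefficients.

    Raises
    ------
    SingularResponseError
        If the reciprocal condition number of ``R`` falls below
        ``rcond_min`` or the inverse has a zero diagonal entry.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    sv = np.linalg.svd(R, compute_uv=False)
    rcond = float(sv[-1] / sv[0]) if sv[0] > 0 else 0.0
    if not np.isfinite(rcond) or rcond < rcond_min:
        raise SingularResponseError(
            f"response matrix is ill-conditioned (reciprocal condition number "
            f"{rcond:.3e} < {rcond_min:.1e})")
    Rinv = np.linalg.inv(R)
    d = np.diag(Rinv)
    if np.any(d == 0):
        raise SingularResponseError("zero diagonal entry in R^-1")
    r = -Rinv / d[:, None]
    return InteractionMatrix(r=r, rcond=rcond)


def _batched_mra(R: np.ndarray, rcond_min: float) -> np.ndarray:
    """MRA over a stack of response matrices; NaN where ill-conditioned."""
    B, n, _ = R.shape
    out = np.full((B, n, n), np.nan)
    sv = np.linalg.svd(R, compute_uv=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        rcond = sv[:, -1] / sv[:, 0]
    ok = np.isfinite(rcond) & (rcond >= rcond_min)
    if ok.any():
        Rinv = np.linalg.inv(R[ok])
        d = np.diagonal(Rinv, axis1=1, axis2=2)
        good = np.all(d != 0, axis=1)
        sel = np.flatnonzero(ok)[good]
        out[sel] = -Rinv[good] / d[good][:, :, None]
    return out


def jackknife_edges(ds: ExpressionDataset,
                    config: InferenceConfig = InferenceConfig(),
                    rng: np.random.Generator | None = None) -> EdgeSet:
    """Resample genes and collect the interaction-coefficient distribution.

    The default leave-one-out scheme drops each gene in turn and reruns the
    complete pipeline — scoring followed by activity estimation and MRA —
    yielding m coefficient samples per ordered component pair.  Because
    every score is a per-gene quantity taken across perturbations, rerunning
    the scoring on a gene subset provably equals dropping the corresponding
    columns of the full weight matrix, which is how the resamples are
    evaluated (in one batched pass).  Singular resamples are recorded as
    missing; pairs missing more than ``config.max_missing`` of their
    samples are flagged unresolvable.
    """
    n, m = ds.n, ds.m
    if m < n + 1:
        raise ValueError(f"need at least n+1 = {n + 1} genes for leave-one-out, got {m}")
    W = compute_scores(ds, config.scoring).W
    dG = ds.G - ds.A[None, :]                       # n x m, per-gene response
    R_full = W @ dG.T                               # == estimate_activity(...).R

    if config.resampler == "jackknife":
        B = m
        # leave-one-out via rank-one downdates of the full response matrix
        R_stack = R_full[None] - np.einsum("ig,jg->gij", W, dG)
    else:
        B = config.n_bootstrap or m
        rng = rng or np.random.default_rng()
        R_stack = np.empty((B, n, n))
        for b in range(B):
            idx = rng.integers(0, m, size=m)
            R_stack[b] = W[:, idx] @ dG[:, idx].T

    samples = _batched_mra(R_stack, config.rcond_min)
    n_failed = int(np.isnan(samples[:, 0, 0]).sum())
    if n_failed:
        warnings.warn(f"{n_failed}/{B} resamples had a singular response matrix",
                      stacklevel=2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(samples, axis=0)
        sigma = np.nanstd(samples, axis=0, ddof=1)
    valid = np.isfinite(samples).sum(axis=0)
    unresolvable = valid < (1 - config.max_missing) * B
    mu = np.where(valid > 0, mu, np.nan)
    sigma = np.where(valid > 1, sigma, np.nan)
    zeros = np.zeros((n, n))
    return EdgeSet(components=ds.panel.components, samples=samples, mu=mu,
                   sigma=sigma, significant=zeros.astype(bool),
                   sign=zeros.astype(int), unresolvable=unresolvable)


def sign_filter(edges: EdgeSet, alpha: float = 0.05,
                two_sided: bool = False) -> EdgeSet:
    """Flag edges whose coefficient sign is consistent at the given level.

    Assuming the resampled coefficients are normal, an ordered pair is
    significant iff ``|mu| / sigma >= z_crit`` with ``z_crit`` the one-sided
    (default) normal quantile at ``1 - alpha``; a degenerate resample
    distribution (sigma = 0) with nonzero mean counts as significant.
    Unresolvable pairs and the diagonal are never flagged.
    """
    q = 1 - alpha / 2 if two_sided else 1 - alpha
    z_crit = float(stats.norm.ppf(q))
    mu, sigma = edges.mu, edges.sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        zratio = np.abs(mu) / sigma
    sig = np.where(sigma > 0, zratio >= z_crit, mu != 0)
    sig &= np.isfinite(mu) & ~edges.unresolvable
    np.fill_diagonal(sig, False)
    sign = np.where(sig, np.sign(mu), 0).astype(int)
    return replace(edges, significant=sig.astype(bool), sign=sign, alpha=alpha)


def infer_edges(ds: ExpressionDataset,
                config: InferenceConfig = InferenceConfig(),
                rng: np.random.Generator | None = None) -> EdgeSet:
    """Resampling plus sign filtering in one call (the per-experiment pipeline)."""
    edges = jackknife_edges(ds, config, rng=rng)
    return sign_filter(edges, alpha=config.alpha, two_sided=config.two_sided)


def consensus(per_experiment: Sequence[EdgeSet], K: int) -> ConsensusNetwork:
    """Retain edges significant with one common sign in at least K experiments.

    With ``K <= E/2`` both signs of a pair can in principle reach K; such
    conflicting pairs are dropped and reported in ``conflicts``.
    """
    E = len(per_experiment)
    if E < 1:
        raise ValueError("need at least one experiment")
    if not 1 <= K <= E:
        raise ValueError(f"K must be in [1, {E}], got {K}")
    comps = per_experiment[0].components
    for es in per_experiment[1:]:
        if es.components != comps:
            raise ValueError("experiments cover different component panels")
    n = len(comps)
    sig = np.stack([es.significant for es in per_experiment])   # E x n x n
    sgn = np.stack([es.sign for es in per_experiment])
    mus = np.stack([es.mu for es in per_experiment])
    pos = ((sgn > 0) & sig).sum(axis=0)
    neg = ((sgn < 0) & sig).sum(axis=0)
    conflicts = []
    support = np.zeros((n, n), dtype=int)
    csign = np.zeros((n, n), dtype=int)
    retained = np.zeros((n, n), dtype=bool)
    mean_coeff = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            p, q = pos[i, j], neg[i, j]
            if p >= K and q >= K:
                conflicts.append((i, j))
                continue
            if p >= K or q >= K:
                s = 1 if p >= K else -1
                backing = sig[:, i, j] & (sgn[:, i, j] == s)
                retained[i, j] = True
                csign[i, j] = s
                support[i, j] = int(backing.sum())
                mean_coeff[i, j] = float(mus[backing, i, j].mean())
    return ConsensusNetwork(components=comps, K=K, E=E, support=support,
                            sign=csign, retained=retained, mean_coeff=mean_coeff,
                            per_experiment_mu=mus, conflicts=tuple(conflicts))


def gene_contributions(W: np.ndarray, ds: ExpressionDataset,
                       source: int | str, target: int | str) -> pd.DataFrame:
    """Per-gene terms of the response of ``target`` to perturbing ``source``.

    The response entry decomposes exactly as
    ``R_ji = sum_k W_jk (G_ik - A_k)`` (j = target, i = source); the
    returned frame holds one row per gene with its term ``contribution``,
    ranked so that genes driving the observed response come first
    (descending ``contribution * sign(R_ji)``).  For an inhibitory
    perturbation of the source, a top-ranked positive term marks a gene
    whose hyper-induction supports functional inhibition of the target by
    the source.
    """
    i = source if isinstance(source, int) else ds.panel.index_of(source)
    j = target if isinstance(target, int) else ds.panel.index_of(target)
    if i == j:
        raise ValueError("source and target must differ")
    W = np.asarray(W, dtype=float)
    terms = W[j, :] * (ds.G[i, :] - ds.A)
    total = float(terms.sum())
    orient = np.sign(total) if total != 0 else 1.0
    order = np.argsort(-(terms * orient), kind="stable")
    return pd.DataFrame({
        "gene": [ds.genes[k] for k in order],
        "contribution": terms[order],
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def edges_to_frame(edges: EdgeSet,
                   net: ConsensusNetwork | None = None,
                   ds: ExpressionDataset | None = None,
                   W: np.ndarray | None = None,
                   top_genes: int = 3) -> pd.DataFrame:
    """Tabulate per-pair statistics (source, target, sign, mu, sd, zratio, ...)."""
    rows = []
    n = edges.n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            mu, sd = edges.mu[i, j], edges.sigma[i, j]
            zr = abs(mu) / sd if sd and np.isfinite(sd) and sd > 0 else np.inf
            row = {
                "source": edges.components[j],
                "target": edges.components[i],
                "sign": int(edges.sign[i, j]),
                "mean_coeff": mu,
                "sd_coeff": sd,
                "zratio": zr,
                "significant": bool(edges.significant[i, j]),
                "unresolvable": bool(edges.unresolvable[i, j]),
            }
            if net is not None:
                row["support_count"] = int(net.support[i, j])
            if ds is not None and W is not None:
                contrib = gene_contributions(W, ds, source=j, target=i)
                row["top_genes"] = ";".join(contrib["gene"].head(top_genes))
            rows.append(row)
    return pd.DataFrame(rows)


def write_sif(net: ConsensusNetwork | EdgeSet, path: str | Path) -> None:
    """Write `source relation target` lines, relation in
    {functional-activation, functional-inhibition}."""
    if isinstance(net, ConsensusNetwork):
        keep, sign, comps = net.retained, net.sign, net.components
    else:
        keep, sign, comps = net.significant, net.sign, net.components
    lines = []
    for i in range(len(comps)):
        for j in range(len(comps)):
            if i != j and keep[i, j]:
                rel = "functional-activation" if sign[i, j] > 0 else "functional-inhibition"
                lines.append(f"{comps[j]}\t{rel}\t{comps[i]}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
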