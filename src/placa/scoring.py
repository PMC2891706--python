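"""Gene scoring and the weight matrix mapping expression to component activity.

Three per-gene, per-perturbation scores are combined multiplicatively:

* **activity score** ``D`` — the change in mean activity after each
  perturbation, multiplied by the perturbation sign and normalised across
  perturbations (Euclidean norm by default), measuring the *relative*
  magnitude of a gene's response without favouring highly or weakly
  expressed genes;
* **P-score** ``P`` — the probability that the observed change is not noise,
  from a two-sample Z statistic on log activities (expression is close to
  log-normal, so logs are close to Gaussian);
* **information score** ``I`` — an entropy-based specificity measure in
  ``[0, ln n]``: maximal for a gene responding to exactly one perturbation,
  zero for a gene responding equally to all of them.

The final weight ``W_ik = D_ik * P_ik * I_k / A_k`` divides by the
unperturbed activity so that the weighted sums downstream are not driven by
highly expressed genes; it also makes every product ``W_ik * G_jk``
invariant under per-gene rescaling of the raw activities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .expression_data import ExpressionDataset, PerturbationPanel

__all__ = ["ScoringConfig", "ScoreSet", "change_matrix", "activity_score",
           "z_matrix", "p_score", "information_score", "compute_scores",
           "weight_matrix"]

#: relative tolerance for "means equal" when both log-SEs vanish
_ZERO_SE_RTOL = 1e-9


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs of the scoring stage.

    activity_norm
        Normalisation of the change-in-activity across perturbations:
        ``"L2"`` (default; gives the unit-sum-of-squares column property) or
        ``"L1"``.
    p_distribution
        Distribution turning |Z| into a P-score: ``"normal"`` (default; the
        erf form) or ``"t"`` with Welch–Satterthwaite degrees of freedom.
    """

    activity_norm: str = "L2"
    p_distribution: str = "normal"

    def __post_init__(self) -> None:
        if self.activity_norm not in ("L2", "L1"):
            raise ValueError(f"unknown activity_norm {self.activity_norm!r}")
        if self.p_distribution not in ("normal", "t"):
            raise ValueError(f"unknown p_distribution {self.p_distribution!r}")


@dataclass(frozen=True)
class ScoreSet:
    """All intermediate scores plus the final n x m weight matrix."""

    C: np.ndarray  # change in activity, n x m
    D: np.ndarray  # activity scores, n x m
    Z: np.ndarray  # two-sample Z values (may hold +/-inf sentinels), n x m
    P: np.ndarray  # P-scores in [0, 1], n x m
    I: np.ndarray  # information scores in [0, ln n], length m
    W: np.ndarray  # weight matrix, n x m


def change_matrix(ds: ExpressionDataset) -> np.ndarray:
    """Change in mean activity ``C_jk = A_k - G_jk`` (n x m)."""
    return ds.A[None, :] - ds.G


def activity_score(C: np.ndarray, panel: PerturbationPanel,
                   norm: str = "L2") -> np.ndarray:
    """Signed, per-gene-normalised change in activity.

    ``D_jk = s_j * C_jk / ||C_.k||`` with the norm taken across the n
    perturbations of gene k; all-zero columns stay all-zero.
    """
    C = np.asarray(C, dtype=float)
    if norm == "L2":
        norms = np.linalg.norm(C, axis=0)
    elif norm == "L1":
        norms = np.abs(C).sum(axis=0)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    safe = np.where(norms > 0, norms, 1.0)
    return panel.sign_array()[:, None] * C / safe[None, :]


def z_matrix(ds: ExpressionDataset) -> np.ndarray:
    """Two-sample Z statistic in log space.

    ``Z_jk = (LogA_k - LogG_jk) / sqrt(dA_k^2 + dG_jk^2)``, so a decrease
    after perturbation gives positive Z, matching the sign of ``C``.  When
    both standard errors vanish the statistic degenerates: equal log-means
    (to relative tolerance 1e-9) give Z = 0, differing log-means give a
    ±inf sentinel meaning "certainly changed".
    """
    num = ds.logA[None, :] - ds.logG
    denom = np.sqrt(ds.dA[None, :] ** 2 + ds.dG ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = num / denom
    degenerate = denom == 0
    if np.any(degenerate):
        same = np.isclose(ds.logG, ds.logA[None, :], rtol=_ZERO_SE_RTOL, atol=1e-300)
        with np.errstate(invalid="ignore"):
            sentinel = np.sign(num) * np.inf
        Z = np.where(degenerate & same, 0.0, Z)
        Z = np.where(degenerate & ~same, sentinel, Z)
    return Z


def p_score(Z: np.ndarray, distribution: str = "normal",
            df: np.ndarray | None = None) -> np.ndarray:
    """Probability that the change is real, from the Z statistic.

    The default is twice the standard-normal CDF integrated from zero to
    |Z|, i.e. ``erf(|Z| / sqrt(2))``; infinite sentinels map to 1.  The
    ``"t"`` option uses a Student-t CDF with the given per-entry degrees of
    freedom (Welch–Satterthwaite), falling back to the normal form where
    ``df`` is not finite.
    """
    Z = np.asarray(Z, dtype=float)
    absZ = np.abs(Z)
    if distribution == "normal":
        P = special.erf(absZ / np.sqrt(2.0))
    elif distribution == "t":
        if df is None:
            raise ValueError("t distribution needs degrees of freedom")
        df = np.broadcast_to(np.asarray(df, dtype=float), Z.shape)
        ok = np.isfinite(df) & (df > 0)
        P = np.where(ok, 2.0 * (stats.t.cdf(np.where(np.isfinite(absZ), absZ, 0.0),
                                            np.where(ok, df, 1.0)) - 0.5),
                     special.erf(absZ / np.sqrt(2.0)))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return np.where(np.isinf(Z), 1.0, P)


def information_score(Z_col: np.ndarray,
                      log_changes: np.ndarray | None = None) -> float:
    """Entropy-based specificity of one gene's Z profile, in ``[0, ln n]``.

    The squared Z values are normalised to a probability vector
    ``z~_j = Z_j^2 / sum(Z^2)`` and scored as ``ln n - H(z~)`` with
    ``H(z~) = -sum z~ ln z~`` (and ``0 ln 0 = 0``): zero iff the gene
    changes equally significantly under every perturbation, the maximum
    ``ln n`` iff it changes under exactly one.  An all-zero column scores 0
    (an uninformative gene).

    Sentinel-infinite entries (zero replicate variance with a real change,
    the regime of noise-free simulated data) take the limiting form of
    z~ as all standard errors shrink at a common rate: the mass lands on
    the infinite entries in proportion to the squared log-changes when
    ``log_changes`` is supplied, uniformly otherwise.
    """
    z = np.asarray(Z_col, dtype=float)
    n = z.size
    inf = np.isinf(z)
    if inf.any():
        if log_changes is not None:
            w = np.where(inf, np.asarray(log_changes, dtype=float) ** 2, 0.0)
            zt = w / w.sum()
        else:
            zt = inf / inf.sum()
    else:
        z2 = z * z
        total = z2.sum()
        if total == 0:
            return 0.0
        zt = z2 / total
    nz = zt[zt > 0]
    H = float(-(nz * np.log(nz)).sum())
    I = float(np.log(n)) - H
    # snap float residue so the exact endpoint I = 0 (uniform z~) holds
    return 0.0 if abs(I) < 1e-12 else I


def _welch_df(ds: ExpressionDataset) -> np.ndarray:
    """Welch–Satterthwaite degrees of freedom per (perturbation, gene)."""
    vA = ds.dA[None, :] ** 2
    vG = ds.dG ** 2
    nA = ds.baseline.n_rep[None, :]
    nG = np.stack([c.n_rep for c in ds.perturbed])
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (vA + vG) ** 2 / (vA**2 / np.maximum(nA - 1, 1) + vG**2 / np.maximum(nG - 1, 1))
    return df


def compute_scores(ds: ExpressionDataset,
                   config: ScoringConfig = ScoringConfig()) -> ScoreSet:
    """Run the full scoring stage and assemble the weight matrix.

    Row i of ``W`` is the gene-weight vector estimating component i; since
    each component is perturbed exactly once, the activity and P-scores
    entering row i are those observed under perturbation i.
    """
    C = change_matrix(ds)
    D = activity_score(C, ds.panel, norm=config.activity_norm)
    Z = z_matrix(ds)
    if config.p_distribution == "t":
        P = p_score(Z, "t", df=_welch_df(ds))
    else:
        P = p_score(Z)
    dlog = ds.logA[None, :] - ds.logG
    I = np.array([information_score(Z[:, k], log_changes=dlog[:, k])
                  for k in range(ds.m)])
    W = D * P * I[None, :] / ds.A[None, :]
    return ScoreSet(C=C, D=D, Z=Z, P=P, I=I, W=W)


def weight_matrix(ds: ExpressionDataset,
                  config: ScoringConfig = ScoringConfig()) -> np.ndarray:
    """The n x m weight matrix ``W`` (see :func:`compute_scores`)."""
    return compute_scores(ds, config).W


def dump_scores(scores: ScoreSet, ds: ExpressionDataset, directory) -> None:
    """Write each score table (C, D, Z, P, I, W) as a TSV for auditing.

    Matrices are genes x perturbations; the information score is a single
    column.  Files are named ``score_<name>.tsv``.
    """
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = list(ds.panel.components)
    for name in ("C", "D", "Z", "P", "W"):
        pd.DataFrame(getattr(scores, name).T, index=list(ds.genes),
                     columns=cols).to_csv(directory / f"score_{name}.tsv",
                                          sep="\t", index_label="gene")
    pd.DataFrame({"I": scores.I}, index=list(ds.genes)).to_csv(
        directory / "score_I.tsv", sep="\t", index_label="gene")
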