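"""Loading, validation and summarisation of perturbation expression data.

The algorithm consumes early-gene expression measured under ``n + 1``
conditions: one unperturbed baseline and one condition per perturbed
signaling component.  Each condition carries, per gene, the arithmetic mean
activity, the mean of the natural log of the replicate activities, the
standard error of those logs, and the replicate count.  Activities are
whatever unit the table carries (fold-change, copy number, ...); every
downstream statistic is invariant to per-gene rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PerturbationPanel",
    "ConditionSummary",
    "ExpressionDataset",
    "summarize_replicates",
    "read_expression_table",
    "read_panel_table",
    "write_expression_table",
    "write_panel_table",
]

#: column suffixes of the summary table layout, in fixed order
SUMMARY_FIELDS = ("mean", "logmean", "logsd", "n")

BASELINE = "baseline"


class ExpressionDataError(ValueError):
    """Raised for structurally invalid expression or panel inputs."""


@dataclass(frozen=True)
class PerturbationPanel:
    """Ordered list of perturbed signaling components with perturbation signs.

    Parameters
    ----------
    components
        Unique component names, one per perturbation condition, in the order
        the conditions appear in the expression table.
    signs
        Perturbation direction per component: ``-1`` for inhibition, ``+1``
        for activation.
    labels
        Optional free-text perturbagen description per component.
    conditions
        Condition names as used in the expression table; defaults to the
        component names themselves.
    """

    components: tuple[str, ...]
    signs: tuple[int, ...]
    labels: tuple[str, ...] = ()
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        signs = tuple(int(s) for s in self.signs)
        labels = tuple(self.labels) if self.labels else ("",) * len(comps)
        conds = tuple(self.conditions) if self.conditions else comps
        if len(comps) < 2:
            raise ExpressionDataError("panel needs at least 2 components")
        if len(set(comps)) != len(comps):
            raise ExpressionDataError("component names must be unique")
        if len(signs) != len(comps) or any(s not in (-1, 1) for s in signs):
            raise ExpressionDataError("each perturbation sign must be -1 or +1")
        if len(labels) != len(comps) or len(conds) != len(comps):
            raise ExpressionDataError("labels/conditions length mismatch")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "signs", signs)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "conditions", conds)

    @property
    def n(self) -> int:
        return len(self.components)

    def sign_array(self) -> np.ndarray:
        return np.asarray(self.signs, dtype=float)

    def index_of(self, component: str) -> int:
        try:
            return self.components.index(component)
        except ValueError:
            raise KeyError(f"unknown component {component!r}") from None


@dataclass(frozen=True)
class ConditionSummary:
    """Per-gene replicate summaries for one condition (arrays of length m)."""

    mean: np.ndarray      # arithmetic mean of raw activities, > 0
    log_mean: np.ndarray  # mean of natural logs
    log_se: np.ndarray    # sample SD of natural logs / sqrt(n_rep)
    n_rep: np.ndarray     # replicate count per gene, >= 1

    def __post_init__(self) -> None:
        for name in ("mean", "log_mean", "log_se", "n_rep"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(self.mean > 0):
            raise ExpressionDataError("non-positive activity")
        if not np.all(self.log_se >= 0):
            raise ExpressionDataError("negative log-SE")


@dataclass(frozen=True)
class ExpressionDataset:
    """Gene panel plus baseline and per-perturbation condition summaries.

    ``perturbed`` holds one :class:`ConditionSummary` per panel component, in
    panel order, each over the same ordered gene panel as ``baseline``.
    """

    genes: tuple[str, ...]
    baseline: ConditionSummary
    perturbed: tuple[ConditionSummary, ...]
    panel: PerturbationPanel

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "perturbed", tuple(self.perturbed))
        m = len(self.genes)
        if len(set(self.genes)) != m:
            raise ExpressionDataError("gene names must be unique")
        if len(self.perturbed) != self.panel.n:
            raise ExpressionDataError(
                f"{len(self.perturbed)} perturbation conditions for a panel of {self.panel.n}"
            )
        for cond in (self.baseline, *self.perturbed):
            if cond.mean.shape != (m,):
                raise ExpressionDataError("gene panel mismatch across conditions")

    @property
    def m(self) -> int:
        """Number of genes."""
        return len(self.genes)

    @property
    def n(self) -> int:
        """Number of perturbed components."""
        return self.panel.n

    # stacked n x m views used by the scoring stage -------------------------

    @property
    def A(self) -> np.ndarray:
        """Baseline mean activities, length m."""
        return self.baseline.mean

    @property
    def G(self) -> np.ndarray:
        """Perturbed mean activities, n x m."""
        return np.stack([c.mean for c in self.perturbed])

    @property
    def logA(self) -> np.ndarray:
        return self.baseline.log_mean

    @property
    def logG(self) -> np.ndarray:
        return np.stack([c.log_mean for c in self.perturbed])

    @property
    def dA(self) -> np.ndarray:
        return self.baseline.log_se

    @property
    def dG(self) -> np.ndarray:
        return np.stack([c.log_se for c in self.perturbed])

    def drop_gene(self, index: int) -> "ExpressionDataset":
        """Dataset with gene ``index`` removed (the jackknife primitive)."""
        keep = np.ones(self.m, dtype=bool)
        keep[index] = False

        def _sub(c: ConditionSummary) -> ConditionSummary:
            return ConditionSummary(c.mean[keep], c.log_mean[keep], c.log_se[keep], c.n_rep[keep])

        genes = tuple(g for i, g in enumerate(self.genes) if keep[i])
        return ExpressionDataset(genes, _sub(self.baseline),
                                 tuple(_sub(c) for c in self.perturbed), self.panel)

    def rescale_genes(self, factors: Sequence[float]) -> "ExpressionDataset":
        """Multiply every condition of gene k by ``factors[k]`` (> 0).

        Used to exercise the per-gene scale invariance of the pipeline.
        """
        f = np.asarray(factors, dtype=float)
        if f.shape != (self.m,) or not np.all(f > 0):
            raise ExpressionDataError("need one positive factor per gene")

        def _sc(c: ConditionSummary) -> ConditionSummary:
            return ConditionSummary(c.mean * f, c.log_mean + np.log(f), c.log_se, c.n_rep)

        return ExpressionDataset(self.genes, _sc(self.baseline),
                                 tuple(_sc(c) for c in self.perturbed), self.panel)


def summarize_replicates(values: Sequence[float]) -> tuple[float, float, float, int]:
    """Summarise raw replicate activities of one gene under one condition.

    Returns ``(mean, log_mean, log_se, n_rep)`` where ``mean`` is the
    arithmetic mean of the raw values, ``log_mean`` the mean of their natural
    logs, and ``log_se`` the sample (n-1) standard deviation of the logs
    divided by sqrt(n_rep) — the standard error entering the two-sample Z
    statistic downstream.

    Raises
    ------
    ExpressionDataError
        On fewer than 2 replicates or any non-positive value.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ExpressionDataError("need at least 2 replicates")
    if not np.all(v > 0):
        raise ExpressionDataError("non-positive activity")
    logs = np.log(v)
    return (float(v.mean()), float(logs.mean()),
            float(logs.std(ddof=1) / math.sqrt(v.size)), int(v.size))


# ---------------------------------------------------------------------------
# Tabular IO.  Expression tables are TSV/CSV with genes as rows and a `gene`
# column; conditions are named in the header.  Two layouts:
#   summaries  : four columns per condition, `<cond>:mean`, `<cond>:logmean`,
#                `<cond>:logsd`, `<cond>:n`  (logsd is the sample SD of the
#                logs, not the standard error)
#   replicates : one column per replicate, `<cond>:rep1`, `<cond>:rep2`, ...
# The baseline condition is named `baseline`.  The companion panel table is a
# TSV with columns condition, component, sign, label.
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: Path) -> pd.DataFrame:
    """Read TSV/CSV, or Excel when openpyxl/xlrd is installed (same layout)."""
    if path.suffix.lower() in (".xls", ".xlsx"):
        return pd.read_excel(path)
    return pd.read_csv(path, sep=_sep_for(path))


def read_panel_table(path: str | Path) -> PerturbationPanel:
    """Read the perturbation panel TSV (columns condition, component, sign, label)."""
    path = Path(path)
    df = _read_table(path)
    required = {"condition", "component", "sign"}
    if not required.issubset(df.columns):
        raise ExpressionDataError(f"panel table needs columns {sorted(required)}")
    labels = df["label"].fillna("").astype(str) if "label" in df else [""] * len(df)
    return PerturbationPanel(
        components=tuple(df["component"].astype(str)),
        signs=tuple(int(s) for s in df["sign"]),
        labels=tuple(labels),
        conditions=tuple(df["condition"].astype(str)),
    )


def write_panel_table(panel: PerturbationPanel, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({
        "condition": panel.conditions,
        "component": panel.components,
        "sign": panel.signs,
        "label": panel.labels,
    }).to_csv(path, sep=_sep_for(path), index=False)


def _split_header(columns: Sequence[str]) -> dict[str, dict[str, str]]:
    """Map condition -> field/repN -> column name from `<cond>:<field>` headers."""
    out: dict[str, dict[str, str]] = {}
    for col in columns:
        if col == "gene" or ":" not in col:
            continue
        cond, fld = col.rsplit(":", 1)
        out.setdefault(cond, {})[fld] = col
    return out


def read_expression_table(
    path: str | Path,
    panel: PerturbationPanel | str | Path,
    layout: str = "summaries",
    baseline: str = BASELINE,
) -> ExpressionDataset:
    """Read an expression table plus its perturbation panel into a dataset.

    Parameters
    ----------
    path
        TSV/CSV expression table, genes in rows (see module docstring for the
        two column layouts).
    panel
        A :class:`PerturbationPanel` or the path of the panel table.
    layout
        ``"summaries"`` (four columns per condition) or ``"replicates"``
        (raw replicate columns, summarised via :func:`summarize_replicates`).
    baseline
        Name of the unperturbed condition.
    """
    if layout not in ("summaries", "replicates"):
        raise ExpressionDataError(f"unknown layout {layout!r}")
    if not isinstance(panel, PerturbationPanel):
        panel = read_panel_table(panel)
    path = Path(path)
    df = _read_table(path)
    if "gene" not in df.columns:
        raise ExpressionDataError("expression table needs a `gene` column")
    genes = tuple(df["gene"].astype(str))
    groups = _split_header(df.columns)
    if baseline not in groups:
        raise ExpressionDataError(f"missing baseline condition {baseline!r}")
    for cond in panel.conditions:
        if cond not in groups:
            raise ExpressionDataError(f"missing perturbation condition {cond!r}")

    def _summary(cond: str) -> ConditionSummary:
        cols = groups[cond]
        if layout == "summaries":
            missing = [f for f in SUMMARY_FIELDS if f not in cols]
            if missing:
                raise ExpressionDataError(f"condition {cond!r} lacks columns {missing}")
            n = df[cols["n"]].to_numpy(float)
            if np.any(n < 1):
                raise ExpressionDataError("replicate count < 1")
            return ConditionSummary(
                mean=df[cols["mean"]].to_numpy(float),
                log_mean=df[cols["logmean"]].to_numpy(float),
                log_se=df[cols["logsd"]].to_numpy(float) / np.sqrt(n),
                n_rep=n,
            )
        rep_cols = [cols[f] for f in sorted(cols, key=lambda s: (len(s), s)) if f.startswith("rep")]
        if len(rep_cols) < 2:
            raise ExpressionDataError(f"condition {cond!r} has fewer than 2 replicates")
        reps = df[rep_cols].to_numpy(float)
        stats = [summarize_replicates(row) for row in reps]
        mean, log_mean, log_se, n_rep = map(np.asarray, zip(*stats))
        return ConditionSummary(mean, log_mean, log_se, n_rep)

    return ExpressionDataset(
        genes=genes,
        baseline=_summary(baseline),
        perturbed=tuple(_summary(c) for c in panel.conditions),
        panel=panel,
    )


def write_expression_table(ds: ExpressionDataset, path: str | Path,
                           baseline: str = BASELINE) -> None:
    """Write a dataset in the summary layout read back by :func:`read_expression_table`."""
    path = Path(path)
    data: dict[str, object] = {"gene": list(ds.genes)}

    def _emit(cond: str, c: ConditionSummary) -> None:
        data[f"{cond}:mean"] = c.mean
        data[f"{cond}:logmean"] = c.log_mean
        data[f"{cond}:logsd"] = c.log_se * np.sqrt(c.n_rep)
        data[f"{cond}:n"] = c.n_rep.astype(int)

    _emit(baseline, ds.baseline)
    for cond, c in zip(ds.panel.conditions, ds.perturbed):
        _emit(cond, c)
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)
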